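"""Generalized two-dimensional correlation spectroscopy (2DCoS).

Given a series of spectra collected along an ordered perturbation axis
(here: fouling time), the synchronous map Φ captures in-phase intensity
changes between every pair of wavenumbers and the asynchronous map Ψ,
built with the discrete Hilbert–Noda transform, captures out-of-phase
(sequential) changes.  The signs of Φ and Ψ at a cross-peak give the order
in which two bands change (Noda's rule): with Φ(ν1,ν2)·Ψ(ν1,ν2) > 0 the
ν1 band changes before ν2, with a negative product it changes after, and
Ψ ≈ 0 marks simultaneous change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "SpectraSeries",
    "CorrelationMaps",
    "dynamic_spectra",
    "hilbert_noda_matrix",
    "synchronous_map",
    "asynchronous_map",
    "correlation_maps",
    "autopeaks",
    "sequence_order",
]


@dataclass
class SpectraSeries:
    """Absorbance matrix [wavenumber × time] on strictly monotone axes."""

    wavenumbers: np.ndarray  # cm⁻¹
    times: np.ndarray  # perturbation axis (days)
    absorbance: np.ndarray  # [n_wavenumbers × n_times]

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        dnu = np.diff(self.wavenumbers)
        if self.wavenumbers.ndim != 1 or not (np.all(dnu > 0) or np.all(dnu < 0)):
            raise ValueError("wavenumbers must be strictly monotone")
        if self.times.ndim != 1 or not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.absorbance.shape != (self.wavenumbers.size, self.times.size):
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} does not match axes "
                f"({self.wavenumbers.size}, {self.times.size})"
            )

    @property
    def n_times(self) -> int:
        return self.times.size


@dataclass
class CorrelationMaps:
    """Synchronous (Φ) and asynchronous (Ψ) maps on a common wavenumber axis."""

    wavenumbers: np.ndarray
    synchronous: np.ndarray
    asynchronous: np.ndarray


def dynamic_spectra(
    series: SpectraSeries,
    reference: Literal["mean", "first", "custom"] = "mean",
    custom_reference: np.ndarray | None = None,
) -> SpectraSeries:
    """Subtract a reference spectrum from every time slice.

    With the default time-mean reference every wavenumber row of the result
    sums to zero over time, the usual pre-processing for generalized 2D
    correlation analysis.
    """
    if series.n_times < 2:
        raise ValueError("at least 2 time points are required")
    if reference == "mean":
        ref = series.absorbance.mean(axis=1)
    elif reference == "first":
        ref = series.absorbance[:, 0]
    elif reference == "custom":
        if custom_reference is None:
            raise ValueError("custom reference requested but none supplied")
        ref = np.asarray(custom_reference, dtype=float)
        if ref.shape != (series.wavenumbers.size,):
            raise ValueError(
                f"custom reference length {ref.shape} does not match "
                f"{series.wavenumbers.size} wavenumbers"
            )
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return SpectraSeries(
        wavenumbers=series.wavenumbers.copy(),
        times=series.times.copy(),
        absorbance=series.absorbance - ref[:, None],
    )


def hilbert_noda_matrix(m: int) -> np.ndarray:
    """Discrete Hilbert–Noda transform matrix N (m × m).

    N_jk = 0 on the diagonal and 1/(π(k − j)) off it; antisymmetric, so the
    asynchronous map built with it is antisymmetric too.  Presumes evenly
    spaced perturbation sampling.
    """
    j, k = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    with np.errstate(divide="ignore"):
        N = 1.0 / (np.pi * (k - j))
    np.fill_diagonal(N, 0.0)
    return N


def _require_uniform_times(times: np.ndarray) -> None:
    dt = np.diff(times)
    if dt.size and not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
        raise ValueError(
            "the Hilbert–Noda transform presumes evenly spaced time points; "
            "resample the series onto a uniform grid first"
        )


def synchronous_map(dyn: SpectraSeries) -> np.ndarray:
    """Synchronous map Φ(ν1,ν2) = Σ_j ỹ(ν1,t_j)·ỹ(ν2,t_j) / (m − 1)."""
    m = dyn.n_times
    if m < 2:
        raise ValueError("synchronous map requires at least 2 time points")
    Y = dyn.absorbance
    return (Y @ Y.T) / (m - 1)


def asynchronous_map(dyn: SpectraSeries) -> np.ndarray:
    """Asynchronous map Ψ(ν1,ν2) = Σ_j ỹ(ν1,t_j)·(N ỹ(ν2,·))_j / (m − 1)."""
    m = dyn.n_times
    if m < 3:
        raise ValueError("asynchronous map requires at least 3 time points")
    _require_uniform_times(dyn.times)
    Y = dyn.absorbance
    N = hilbert_noda_matrix(m)
    return (Y @ N @ Y.T) / (m - 1)


def correlation_maps(
    series: SpectraSeries,
    reference: Literal["mean", "first", "custom"] = "mean",
    custom_reference: np.ndarray | None = None,
) -> CorrelationMaps:
    """Convenience wrapper: dynamic spectra, then both correlation maps."""
    dyn = dynamic_spectra(series, reference, custom_reference)
    return CorrelationMaps(
        wavenumbers=series.wavenumbers.copy(),
        synchronous=synchronous_map(dyn),
        asynchronous=asynchronous_map(dyn),
    )


def autopeaks(
    synchronous: np.ndarray,
    wavenumbers: np.ndarray,
    min_prominence: float = 0.05,
) -> list[tuple[float, float]]:
    """Auto-peaks: local maxima of the Φ diagonal above a relative floor.

    ``min_prominence`` is a fraction of the diagonal maximum; peaks below
    ``min_prominence · max(diag Φ)`` are discarded.  Returns (wavenumber,
    intensity) pairs sorted by wavenumber.
    """
    diag = np.diag(synchronous)
    top = diag.max()
    if top <= 0 or np.allclose(diag, diag[0]):
        return []
    idx, _ = find_peaks(diag, height=min_prominence * top)
    order = np.argsort(wavenumbers[idx])
    return [(float(wavenumbers[i]), float(diag[i])) for i in idx[order]]


@dataclass
class SequenceResult:
    """Band appearance order inferred from Noda's rule.

    ``ranks`` maps each band wavenumber to its order rank (1 = earliest);
    bands tied under the Ψ ≈ 0 criterion share a rank.  ``pairwise`` holds
    the raw verdicts ('before', 'after', 'simultaneous') keyed by band
    pairs; ``inconsistent_triads`` lists any non-transitive triples.
    """

    ranks: dict[float, int]
    pairwise: dict[tuple[float, float], str]
    inconsistent_triads: list[tuple[float, float, float]] = field(default_factory=list)


def sequence_order(
    synchronous: np.ndarray,
    asynchronous: np.ndarray,
    wavenumbers: np.ndarray,
    bands: Sequence[float],
    tol: float | None = None,
) -> SequenceResult:
    """Order band appearance by Noda's rule from Φ and Ψ at band pairs.

    For each pair (ν1, ν2): |Ψ| ≤ tol ⇒ simultaneous; Φ·Ψ > 0 ⇒ ν1 before
    ν2; otherwise ν1 after ν2.  ``tol`` defaults to 1 % of max |Ψ|, floored
    at 1e-10 of the largest auto-peak so numerically-zero asynchronous maps
    (perfectly synchronized bands) read as simultaneous.
    Pairwise verdicts are aggregated into ranks by win counting; a band's
    rank is 1 + number of distinct earlier groups, so ties share ranks.
    """
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    lo, hi = wavenumbers.min(), wavenumbers.max()
    idx = []
    for b in bands:
        if not (lo <= b <= hi):
            raise ValueError(f"band {b} cm⁻¹ outside the wavenumber grid [{lo}, {hi}]")
        idx.append(int(np.argmin(np.abs(wavenumbers - b))))
    if tol is None:
        tol = max(
            0.01 * np.abs(asynchronous).max(),
            1e-10 * np.abs(np.diag(synchronous)).max(),
        )

    n = len(bands)
    verdict: dict[tuple[float, float], str] = {}
    # wins[i][j] = True if band i changes before band j
    before = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(a + 1, n):
            phi = synchronous[idx[a], idx[b]]
            psi = asynchronous[idx[a], idx[b]]
            if abs(psi) <= tol:
                verdict[(bands[a], bands[b])] = "simultaneous"
            elif phi * psi > 0:
                verdict[(bands[a], bands[b])] = "before"
                before[a, b] = True
            else:
                verdict[(bands[a], bands[b])] = "after"
                before[b, a] = True

    wins = before.sum(axis=1)
    # dense ranks: more wins = earlier appearance
    order = sorted(set(wins), reverse=True)
    rank_of_wins = {w: r + 1 for r, w in enumerate(order)}
    ranks = {bands[i]: rank_of_wins[wins[i]] for i in range(n)}

    triads = []
    for a in range(n):
        for b in range(n):
            for c in range(n):
                if before[a, b] and before[b, c] and before[c, a]:
                    triads.append(tuple(sorted((bands[a], bands[b], bands[c]))))
    inconsistent = sorted(set(triads))
    return SequenceResult(ranks=ranks, pairwise=verdict, inconsistent_triads=list(inconsistent))
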