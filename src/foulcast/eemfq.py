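"""EEM normalization, fluorescence-quotient (FQ) maps and significance masks.

Excitation–emission matrices from paired foulant samples are min–max
normalized per sample into [0.01, 0.10],

    FI′ = 0.01 + 0.09 · (FI − FI_min) / (FI_max − FI_min),

and compared through the fluorescence quotient FQ_A/B = log10(FI′_A / FI′_B)
taken per paired sample and aggregated by the median.  A positive FQ_A/B at a
pixel means the fluorophore is relatively depleted going from A to B.  A
one-tailed Wilcoxon signed-rank test on the paired FI′ differences (default
p < 0.1) masks pixels whose shift is not statistically supported, and the
three pairwise FQ maps of the Ctrl/Al/Fe scenarios combine into a
"prominent region" label map via their sign patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

__all__ = [
    "EEMCube",
    "FQMap",
    "normalize_eem",
    "fq_map",
    "wilcoxon_mask",
    "prominent_regions",
    "NORM_FLOOR",
    "NORM_CEIL",
]

NORM_FLOOR = 0.01
NORM_CEIL = 0.10


@dataclass
class EEMCube:
    """Stack of EEM grids: intensity[ex, em, sample] ≥ 0 on increasing axes."""

    ex_axis: np.ndarray  # nm
    em_axis: np.ndarray  # nm
    intensity: np.ndarray  # [n_ex × n_em × n_samples]

    def __post_init__(self) -> None:
        self.ex_axis = np.asarray(self.ex_axis, dtype=float)
        self.em_axis = np.asarray(self.em_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim == 2:
            self.intensity = self.intensity[:, :, None]
        if not np.all(np.diff(self.ex_axis) > 0) or not np.all(np.diff(self.em_axis) > 0):
            raise ValueError("excitation and emission axes must be strictly increasing")
        if self.intensity.shape[:2] != (self.ex_axis.size, self.em_axis.size):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match axes "
                f"({self.ex_axis.size}, {self.em_axis.size})"
            )
        if self.intensity.shape[2] < 1:
            raise ValueError("at least one sample layer required")
        if np.any(self.intensity < 0):
            raise ValueError("fluorescence intensities must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]


@dataclass
class FQMap:
    """Median FQ map with its per-pixel significance mask."""

    ex_axis: np.ndarray
    em_axis: np.ndarray
    values: np.ndarray  # [n_ex × n_em], median over pairs
    mask: np.ndarray  # boolean, True = significant shift
    n_pairs: int


def _check_axes(a: EEMCube, b: EEMCube) -> None:
    if not (np.array_equal(a.ex_axis, b.ex_axis) and np.array_equal(a.em_axis, b.em_axis)):
        raise ValueError("EEM cubes must share identical Ex and Em axes")


def scatter_mask(
    cube: EEMCube,
    rayleigh_width: float = 15.0,
    raman_shift: float = 3400.0,
    raman_width: float = 10.0,
) -> np.ndarray:
    """Boolean mask of first-order Rayleigh and Raman scatter bands.

    Rayleigh: |Em − Ex| ≤ ``rayleigh_width`` nm.  Raman (water, ~3400 cm⁻¹
    shift): Em within ``raman_width`` nm of 1/(1/Ex − shift·1e−7).  Marked
    pixels can be zeroed before normalization; optional, off by default.
    """
    ex = cube.ex_axis[:, None]
    em = cube.em_axis[None, :]
    mask = np.abs(em - ex) <= rayleigh_width
    with np.errstate(divide="ignore"):
        raman_em = 1.0 / (1.0 / ex - raman_shift * 1e-7)
    raman_em = np.where(raman_em > 0, raman_em, np.inf)
    mask |= np.abs(em - raman_em) <= raman_width
    return mask


def normalize_eem(cube: EEMCube) -> EEMCube:
    """Per-sample min–max normalization onto [0.01, 0.10].

    The sample minimum maps to 0.01 and the maximum to 0.10; the 0.01 floor
    keeps the subsequent log-ratio finite everywhere.
    """
    fi = cube.intensity
    lo = fi.min(axis=(0, 1), keepdims=True)
    hi = fi.max(axis=(0, 1), keepdims=True)
    flat = np.isclose(hi - lo, 0.0).ravel()
    if flat.any():
        bad = int(np.flatnonzero(flat)[0])
        raise ValueError(f"sample {bad} is constant (FImax = FImin); cannot normalize")
    out = NORM_FLOOR + (NORM_CEIL - NORM_FLOOR) * (fi - lo) / (hi - lo)
    return EEMCube(cube.ex_axis.copy(), cube.em_axis.copy(), out)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank machinery (vectorized exact test, scipy fallback)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _signed_rank_tail(n: int) -> np.ndarray:
    """P(W+ ≥ w) for w = 0..n(n+1)/2 under the exact signed-rank null."""
    counts = np.zeros(n * (n + 1) // 2 + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    tail = np.cumsum(counts[::-1])[::-1] / counts.sum()
    return tail


def _exact_p_greater(w_plus: np.ndarray, n: int) -> np.ndarray:
    tail = _signed_rank_tail(n)
    return tail[np.rint(w_plus).astype(int)]


def wilcoxon_mask(
    a: EEMCube,
    b: EEMCube,
    alpha: float = 0.1,
    zero_tol: float = 1e-9,
) -> np.ndarray:
    """Per-pixel one-tailed paired Wilcoxon signed-rank mask (p < alpha).

    The alternative is taken in the direction of the observed median
    difference at each pixel.  Differences below ``zero_tol`` in magnitude
    (numerical noise on the fixed [0.01, 0.10] normalized scale) count as
    zeros and are dropped, the usual zero handling of the signed-rank test;
    pixels whose remaining differences all vanish, or whose median
    difference is zero, are masked False.  Pixels without tied magnitudes
    use a vectorized exact null (grouped by the number of non-zero pairs);
    genuinely tied pixels fall back to :func:`scipy.stats.wilcoxon`.
    """
    _check_axes(a, b)
    if a.n_samples != b.n_samples:
        raise ValueError("cubes must have equal, index-paired sample counts")
    n = a.n_samples
    if n < 5:
        raise ValueError(f"paired Wilcoxon needs at least 5 pairs, got {n}")
    d = (a.intensity - b.intensity).reshape(-1, n).copy()
    d[np.abs(d) <= zero_tol] = 0.0
    med = np.median(d, axis=1)
    nonzero = d != 0
    m = nonzero.sum(axis=1)

    # rank |d| with zeros pushed past the end so non-zero ranks are 1..m
    absd = np.where(nonzero, np.abs(d), np.inf)
    sorted_abs = np.sort(absd, axis=1)
    finite_pairs = np.isfinite(sorted_abs[:, :-1]) & np.isfinite(sorted_abs[:, 1:])
    with np.errstate(invalid="ignore"):
        tied = np.any(finite_pairs & (np.diff(sorted_abs, axis=1) == 0), axis=1)

    p = np.ones(d.shape[0])
    clean = ~tied & (m > 0) & (med != 0)
    ranks = stats.rankdata(absd, axis=1)
    w_plus = np.where(nonzero & (d > 0), ranks, 0.0).sum(axis=1)
    for mi in np.unique(m[clean]):
        sel = clean & (m == mi)
        total = mi * (mi + 1) / 2
        p_greater = _exact_p_greater(w_plus[sel], int(mi))
        p_less = _exact_p_greater(total - w_plus[sel], int(mi))  # null symmetry
        p[sel] = np.where(med[sel] > 0, p_greater, p_less)
    for i in np.flatnonzero(tied & (m > 0) & (med != 0)):
        di = d[i][nonzero[i]]
        alt = "greater" if med[i] > 0 else "less"
        p[i] = stats.wilcoxon(di, alternative=alt).pvalue

    mask = (p < alpha) & (med != 0)
    return mask.reshape(a.intensity.shape[:2])


def fq_map(
    a: EEMCube,
    b: EEMCube,
    alpha: float = 0.1,
    significance: bool = True,
) -> FQMap:
    """Median fluorescence-quotient map FQ_A/B = log10(FI′_A / FI′_B).

    ``a`` and ``b`` must already be normalized (see :func:`normalize_eem`)
    and paired sample-by-sample.  The per-pair FQ maps are aggregated by the
    pixelwise median; with ``significance`` a Wilcoxon mask at ``alpha`` is
    attached, otherwise the mask is all True.
    """
    _check_axes(a, b)
    if a.n_samples != b.n_samples:
        raise ValueError("cubes must have equal, index-paired sample counts")
    fq = np.log10(a.intensity / b.intensity)
    values = np.median(fq, axis=2)
    if significance:
        mask = wilcoxon_mask(a, b, alpha=alpha)
    else:
        mask = np.ones(values.shape, dtype=bool)
    return FQMap(a.ex_axis.copy(), a.em_axis.copy(), values, mask, a.n_samples)


#: integer codes of the label map returned by :func:`prominent_regions`
REGION_CODES = {"none": 0, "Ctrl": 1, "Al": 2, "Fe": 3}


def prominent_regions(
    fq_ctrl_al: FQMap,
    fq_ctrl_fe: FQMap,
    fq_al_fe: FQMap,
) -> tuple[np.ndarray, dict[str, int]]:
    """Three-way prominent-region classification of the scenario FQ maps.

    Pixel rules (applied only where both relevant significance masks hold):

    * Al prominent:   FQ_Ctrl/Al < 0 and FQ_Al/Fe > 0
    * Fe prominent:   FQ_Ctrl/Fe < 0 and FQ_Al/Fe < 0
    * Ctrl prominent: FQ_Ctrl/Al > 0 and FQ_Ctrl/Fe > 0

    The three sign patterns are mutually exclusive, so each pixel receives
    at most one label; everything else is "none".  Returns the label array
    (codes per ``REGION_CODES``) and per-label pixel counts (including a
    "conflict" count, zero by construction, kept as a guard).
    """
    for m in (fq_ctrl_fe, fq_al_fe):
        if not (
            np.array_equal(fq_ctrl_al.ex_axis, m.ex_axis)
            and np.array_equal(fq_ctrl_al.em_axis, m.em_axis)
        ):
            raise ValueError("FQ maps must share identical axes")
    al = (
        (fq_ctrl_al.values < 0) & (fq_al_fe.values > 0) & fq_ctrl_al.mask & fq_al_fe.mask
    )
    fe = (
        (fq_ctrl_fe.values < 0) & (fq_al_fe.values < 0) & fq_ctrl_fe.mask & fq_al_fe.mask
    )
    ctrl = (
        (fq_ctrl_al.values > 0) & (fq_ctrl_fe.values > 0) & fq_ctrl_al.mask & fq_ctrl_fe.mask
    )
    overlap = (al & fe) | (al & ctrl) | (fe & ctrl)
    labels = np.zeros(al.shape, dtype=int)
    labels[ctrl & ~overlap] = REGION_CODES["Ctrl"]
    labels[al & ~overlap] = REGION_CODES["Al"]
    labels[fe & ~overlap] = REGION_CODES["Fe"]
    counts = {
        "Ctrl": int((labels == REGION_CODES["Ctrl"]).sum()),
        "Al": int((labels == REGION_CODES["Al"]).sum()),
        "Fe": int((labels == REGION_CODES["Fe"]).sum()),
        "none": int((labels == REGION_CODES["none"]).sum()),
        "conflict": int(overlap.sum()),
    }
    return labels, counts
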