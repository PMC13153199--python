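"""Flux, resistance-in-series and concentration-polarization analytics.

Permeate flux is reported in the field's customary units, L m⁻² h⁻¹ (LMH),
and converted to m s⁻¹ only inside the Darcy resistance and film-model
formulas.  The resistance-in-series picture splits the total hydraulic
resistance ``R_T = ΔP / (μ · J)`` into the intrinsic membrane resistance
``R_m`` and the fouling-layer resistance ``R_f = R_T − R_m``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FluxRecord",
    "ResistanceDecomposition",
    "LMH_TO_MS",
    "compute_flux",
    "total_resistance",
    "fouling_resistance",
    "percent_flux_decline",
    "cp_enrichment",
    "mass_transfer_coefficient",
    "resistance_series",
]

#: 1 L m⁻² h⁻¹ expressed in m s⁻¹ (1e-3 m³ / m² / 3600 s).
LMH_TO_MS = 1.0 / 3.6e6


@dataclass(frozen=True)
class FluxRecord:
    """One filtration interval of a flux log.

    Parameters
    ----------
    time : float
        Time stamp at the end of the interval, h.
    permeate_volume : float
        Permeate volume ΔV collected over the interval, L.
    area : float
        Effective filtration area A, m².
    interval : float
        Interval duration ΔT, h.
    pressure : float
        Transmembrane pressure ΔP, Pa.
    viscosity : float
        Permeate viscosity μ, Pa·s.
    """

    time: float
    permeate_volume: float
    area: float
    interval: float
    pressure: float
    viscosity: float

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError(f"area must be positive, got {self.area}")
        if not self.interval > 0:
            raise ValueError(f"interval must be positive, got {self.interval}")
        if not self.viscosity > 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity}")
        if self.permeate_volume < 0:
            raise ValueError(
                f"permeate_volume must be non-negative, got {self.permeate_volume}"
            )


@dataclass(frozen=True)
class ResistanceDecomposition:
    """Resistance-in-series split R_T = R_m + R_f (all m⁻¹)."""

    R_T: float
    R_m: float
    R_f: float

    def __post_init__(self) -> None:
        for name in ("R_T", "R_m", "R_f"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def compute_flux(record: FluxRecord) -> float:
    """Permeate flux J = ΔV / (A · ΔT) in L m⁻² h⁻¹."""
    return record.permeate_volume / (record.area * record.interval)


def total_resistance(pressure: float, viscosity: float, flux_lmh: float) -> float:
    """Total hydraulic resistance R_T = ΔP / (μ · J) in m⁻¹.

    ``flux_lmh`` is given in L m⁻² h⁻¹ and converted to m s⁻¹ internally.
    """
    if flux_lmh <= 0:
        raise ValueError(f"flux must be positive for a defined resistance, got {flux_lmh}")
    if viscosity <= 0:
        raise ValueError(f"viscosity must be positive, got {viscosity}")
    return pressure / (viscosity * flux_lmh * LMH_TO_MS)


def fouling_resistance(R_T: float, R_m: float) -> float:
    """Fouling-layer resistance R_f = R_T − R_m in m⁻¹.

    A negative result (total below the virgin-membrane baseline) is returned
    as-is with a warning; it usually indicates an inconsistent R_m.
    """
    if not (math.isfinite(R_T) and math.isfinite(R_m)):
        raise ValueError("R_T and R_m must be finite")
    R_f = R_T - R_m
    if R_f < 0:
        warnings.warn(
            f"fouling resistance is negative (R_T={R_T:.4g} < R_m={R_m:.4g}); "
            "check the virgin-membrane resistance",
            stacklevel=2,
        )
    return R_f


def percent_flux_decline(
    flux: "np.ndarray | pd.Series | list[float]",
    head_window: int = 1,
    tail_window: int = 1,
) -> float:
    """Percent flux decline 100 · (J_first − J_last) / J_first.

    ``J_first``/``J_last`` are means over the first ``head_window`` and last
    ``tail_window`` points (defaults: single endpoints).
    """
    j = np.asarray(flux, dtype=float)
    if j.ndim != 1 or j.size < 2:
        raise ValueError("flux series must be 1-D with at least 2 points")
    if head_window < 1 or tail_window < 1:
        raise ValueError("head_window and tail_window must be >= 1")
    j_first = float(j[:head_window].mean())
    j_last = float(j[-tail_window:].mean())
    if j_first == 0:
        raise ValueError("initial flux is zero; percent decline undefined")
    return 100.0 * (j_first - j_last) / j_first


def cp_enrichment(flux_lmh: float, k: float) -> float:
    """Film-model concentration-polarization enrichment factor exp(J / k).

    Parameters
    ----------
    flux_lmh : float
        Permeate flux in L m⁻² h⁻¹.
    k : float
        Mass-transfer coefficient of the feed channel, m s⁻¹.
    """
    if k <= 0:
        raise ValueError(f"mass-transfer coefficient must be positive, got {k}")
    return math.exp(flux_lmh * LMH_TO_MS / k)


def mass_transfer_coefficient(
    diffusivity: float,
    hydraulic_diameter: float,
    crossflow_velocity: float,
    kinematic_viscosity: float = 8.9e-7,
) -> float:
    """Mass-transfer coefficient from a laminar Sherwood correlation.

    Uses Sh = 1.85 · (Re · Sc · d_h / L)^(1/3) with channel length L taken
    equal to 100·d_h — a generic rectangular crossflow-cell correlation; the
    correlation choice is an assumption, adequate for order-of-magnitude CP
    estimates only.
    """
    if min(diffusivity, hydraulic_diameter, crossflow_velocity, kinematic_viscosity) <= 0:
        raise ValueError("all arguments must be positive")
    Re = crossflow_velocity * hydraulic_diameter / kinematic_viscosity
    Sc = kinematic_viscosity / diffusivity
    Sh = 1.85 * (Re * Sc / 100.0) ** (1.0 / 3.0)
    return Sh * diffusivity / hydraulic_diameter


def resistance_series(
    log: pd.DataFrame,
    R_m: float | None = None,
) -> pd.DataFrame:
    """Flux and resistance trajectory from a flux log.

    ``log`` needs columns ``time_h, volume_L, area_m2, interval_h,
    pressure_Pa, viscosity_Pa_s`` (the flux-log CSV schema).  Returns a frame
    with ``flux_lmh, R_T, R_f`` per row; ``R_m`` defaults to the total
    resistance of the first row (virgin-membrane estimate).
    """
    required = ["time_h", "volume_L", "area_m2", "interval_h", "pressure_Pa", "viscosity_Pa_s"]
    missing = [c for c in required if c not in log.columns]
    if missing:
        raise ValueError(f"flux log is missing columns: {missing}")
    flux = log["volume_L"] / (log["area_m2"] * log["interval_h"])
    R_T = np.array(
        [
            total_resistance(p, mu, j)
            for p, mu, j in zip(log["pressure_Pa"], log["viscosity_Pa_s"], flux)
        ]
    )
    if R_m is None:
        R_m = float(R_T[0])
    out = pd.DataFrame(
        {
            "time_h": log["time_h"].to_numpy(),
            "flux_lmh": flux.to_numpy(),
            "R_T": R_T,
            "R_m": R_m,
            "R_f": R_T - R_m,
        }
    )
    return out
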