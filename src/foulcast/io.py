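"""Readers and writers for the plain-text formats the pipeline exchanges.

All tabular data travel as CSV/TSV: flux logs (one row per filtration
interval), FTIR series (first column wavenumber, remaining columns labelled
by time), EEM grids (one CSV per sample; header row/column carry the Em/Ex
wavelengths) and taxa-abundance tables (taxa rows × sample columns).
Graphs are written as GraphML or weighted edge lists via networkx.
"""

from __future__ import annotations

import json
from pathlib import Path
import networkx as nx
import numpy as np
import pandas as pd

from .cos2d import SpectraSeries
from .eemfq import EEMCube, FQMap

FLUX_LOG_COLUMNS = ["time_h", "volume_L", "interval_h", "pressure_Pa", "viscosity_Pa_s"]


def read_flux_log(path: "str | Path", area_m2: float | None = None) -> pd.DataFrame:
    """Read a flux-log CSV.

    The file needs the columns ``time_h, volume_L, interval_h, pressure_Pa,
    viscosity_Pa_s`` and either an ``area_m2`` column or an explicit
    ``area_m2`` argument (m²).
    """
    df = pd.read_csv(path)
    missing = [c for c in FLUX_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"flux log {path} is missing columns: {missing}")
    if "area_m2" not in df.columns:
        if area_m2 is None:
            raise ValueError(
                "flux log has no area_m2 column; pass the filtration area explicitly"
            )
        df["area_m2"] = float(area_m2)
    return df


def write_flux_log(df: pd.DataFrame, path: "str | Path") -> None:
    df.to_csv(path, index=False)


def read_spectra_csv(path: "str | Path") -> SpectraSeries:
    """Read a spectra series: first column wavenumber, time-labelled columns."""
    df = pd.read_csv(path)
    wavenumbers = df.iloc[:, 0].to_numpy(dtype=float)
    times = np.array([float(c) for c in df.columns[1:]])
    order = np.argsort(times)
    return SpectraSeries(
        wavenumbers=wavenumbers,
        times=times[order],
        absorbance=df.iloc[:, 1:].to_numpy(dtype=float)[:, order],
    )


def write_spectra_csv(series: SpectraSeries, path: "str | Path") -> None:
    df = pd.DataFrame(
        series.absorbance, columns=[f"{t:g}" for t in series.times]
    )
    df.insert(0, "wavenumber_cm-1", series.wavenumbers)
    df.to_csv(path, index=False)


def write_matrix_csv(
    matrix: np.ndarray, axis: np.ndarray, path: "str | Path", label: str = "wavenumber_cm-1"
) -> None:
    """Write a square map (Φ/Ψ) with the shared axis as header and index."""
    pd.DataFrame(matrix, index=axis, columns=axis).to_csv(path, index_label=label)


def read_eem_csv(path: "str | Path") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read one EEM grid: header row = Em (nm), first column = Ex (nm)."""
    df = pd.read_csv(path, index_col=0)
    ex = df.index.to_numpy(dtype=float)
    em = np.array([float(c) for c in df.columns])
    return ex, em, df.to_numpy(dtype=float)


def read_eem_dir(directory: "str | Path", pattern: str = "*.csv") -> EEMCube:
    """Stack every per-sample EEM CSV in a directory (sorted by name)."""
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise ValueError(f"no EEM files matching {pattern!r} in {directory}")
    layers = []
    ex = em = None
    for p in paths:
        exi, emi, grid = read_eem_csv(p)
        if ex is None:
            ex, em = exi, emi
        elif not (np.array_equal(ex, exi) and np.array_equal(em, emi)):
            raise ValueError(f"EEM axes in {p} differ from the first sample")
        layers.append(grid)
    return EEMCube(ex_axis=ex, em_axis=em, intensity=np.stack(layers, axis=2))


def write_eem_cube(cube: EEMCube, directory: "str | Path", prefix: str = "sample") -> list[Path]:
    """Write each sample layer of a cube as ``<prefix>_<idx>.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for s in range(cube.n_samples):
        df = pd.DataFrame(
            cube.intensity[:, :, s],
            index=cube.ex_axis,
            columns=[f"{v:g}" for v in cube.em_axis],
        )
        p = directory / f"{prefix}_{s:02d}.csv"
        df.to_csv(p, index_label="ex_nm")
        written.append(p)
    return written


def write_fq_map(fq: FQMap, path_values: "str | Path", path_mask: "str | Path | None" = None) -> None:
    pd.DataFrame(
        fq.values, index=fq.ex_axis, columns=[f"{v:g}" for v in fq.em_axis]
    ).to_csv(path_values, index_label="ex_nm")
    if path_mask is not None:
        pd.DataFrame(
            fq.mask.astype(int), index=fq.ex_axis, columns=[f"{v:g}" for v in fq.em_axis]
        ).to_csv(path_mask, index_label="ex_nm")


def read_abundance_tsv(path: "str | Path") -> pd.DataFrame:
    """Read a taxa × samples abundance TSV (taxa identifiers in column 0)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate taxon identifiers in {path}")
    return df


def write_abundance_tsv(table: pd.DataFrame, path: "str | Path") -> None:
    table.to_csv(path, sep="\t", index_label="taxon")


def write_graph(graph: nx.Graph, path: "str | Path", fmt: str = "graphml") -> None:
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "edgelist":
        nx.write_weighted_edgelist(graph, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def write_json(obj: dict, path: "str | Path") -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset, tuple)):
        return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
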