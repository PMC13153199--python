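"""Commonality-analysis variance partitioning over three predictor blocks.

The flux-decline response is regressed on three blocks of fouling
predictors — biological (B), inorganic (I), organic (O) — and the full-model
R² is decomposed into seven commonality components: three unique (U_B, U_I,
U_O), three pairwise (C_BI, C_BO, C_IO) and one triadic (C_BIO).  The
components are signed (negative values indicate suppression) and sum to the
full-model R² exactly.  Blocks may enter with all their columns or be
reduced to their first principal component first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "FoulingDataset",
    "CommonalityPartition",
    "BLOCKS",
    "COMPONENTS",
    "reduce_blocks",
    "subset_r2",
    "commonality",
    "percent_contributions",
    "variance_partition",
]

BLOCKS = ("B", "I", "O")
#: commonality components, in canonical order
COMPONENTS = ("U_B", "U_I", "U_O", "C_BI", "C_BO", "C_IO", "C_BIO")
SUBSETS = (("B",), ("I",), ("O",), ("B", "I"), ("B", "O"), ("I", "O"), ("B", "I", "O"))


@dataclass
class FoulingDataset:
    """Response (flux decline per observation) plus three predictor blocks."""

    response: pd.Series
    blocks: Mapping[str, pd.DataFrame]

    def __post_init__(self) -> None:
        self.response = pd.Series(self.response).astype(float)
        missing = [b for b in BLOCKS if b not in self.blocks]
        if missing:
            raise ValueError(f"missing predictor blocks: {missing}")
        n = len(self.response)
        if n < 8:
            raise ValueError(f"at least 8 observations required, got {n}")
        for name in BLOCKS:
            df = pd.DataFrame(self.blocks[name])
            if len(df) != n:
                raise ValueError(f"block {name} has {len(df)} rows, response has {n}")
            if df.shape[1] == 0:
                raise ValueError(f"block {name} is empty")
            if df.isna().any().any() or self.response.isna().any():
                raise ValueError("missing values present; apply listwise deletion first")

    @property
    def n_obs(self) -> int:
        return len(self.response)


def reduce_blocks(
    dataset: FoulingDataset,
    mode: Literal["pca_first_component", "raw_multicolumn"] = "raw_multicolumn",
) -> FoulingDataset:
    """Optionally collapse each block to its standardized first PC.

    The component is sign-aligned to correlate positively with the response
    so block loadings are comparable across fits.  ``raw_multicolumn`` keeps
    every measured column (the packaged default: shared variance between a
    response and a multi-indicator block is not in general recoverable from
    a single summary column).
    """
    if mode == "raw_multicolumn":
        return dataset
    if mode != "pca_first_component":
        raise ValueError(f"unknown reduction mode {mode!r}")
    y = dataset.response.to_numpy()
    reduced = {}
    for name in BLOCKS:
        X = pd.DataFrame(dataset.blocks[name]).to_numpy(dtype=float)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = pd.DataFrame(dataset.blocks[name]).columns[np.flatnonzero(sd == 0)[0]]
            raise ValueError(f"constant column {bad!r} in block {name}")
        Z = (X - X.mean(axis=0)) / sd
        pc = PCA(n_components=1).fit_transform(Z)[:, 0]
        pc /= pc.std(ddof=1)
        if np.corrcoef(pc, y)[0, 1] < 0:
            pc = -pc
        reduced[name] = pd.DataFrame({f"{name}_pc1": pc})
    return FoulingDataset(response=dataset.response.copy(), blocks=reduced)


def _ols_r2(X: np.ndarray, y: np.ndarray, subset_name: str) -> float:
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"rank-deficient design in subset {subset_name}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("response has zero variance")
    return 1.0 - float((resid**2).sum()) / sst


def subset_r2(dataset: FoulingDataset) -> dict[str, float]:
    """OLS R² for the seven non-empty block subsets {B}, {I}, …, {B,I,O}."""
    y = dataset.response.to_numpy(dtype=float)
    mats = {b: pd.DataFrame(dataset.blocks[b]).to_numpy(dtype=float) for b in BLOCKS}
    p_full = sum(m.shape[1] for m in mats.values())
    if dataset.n_obs <= p_full + 1:
        raise ValueError(
            f"need n > p + 1 for the full model (n={dataset.n_obs}, p={p_full})"
        )
    out = {}
    for subset in SUBSETS:
        name = "".join(subset)
        X = np.hstack([mats[b] for b in subset])
        out[name] = _ols_r2(X, y, name)
    return out


@dataclass
class CommonalityPartition:
    """Signed commonality components plus the full-model R²."""

    components: dict[str, float]
    R2_full: float
    suppression: list[str] = field(default_factory=list)

    def as_array(self) -> np.ndarray:
        return np.array([self.components[c] for c in COMPONENTS])


def commonality(r2: Mapping[str, float]) -> CommonalityPartition:
    """Decompose R²(B,I,O) into the seven commonality components.

    Classical three-set commonality formulas; the components sum to the
    full-model R² identically.  Negative components (suppression) are kept
    and listed in ``suppression``.
    """
    needed = {"B", "I", "O", "BI", "BO", "IO", "BIO"}
    missing = needed - set(r2)
    if missing:
        raise ValueError(f"missing subset R² entries: {sorted(missing)}")
    comp = {
        "U_B": r2["BIO"] - r2["IO"],
        "U_I": r2["BIO"] - r2["BO"],
        "U_O": r2["BIO"] - r2["BI"],
        "C_BI": r2["BO"] + r2["IO"] - r2["O"] - r2["BIO"],
        "C_BO": r2["BI"] + r2["IO"] - r2["I"] - r2["BIO"],
        "C_IO": r2["BI"] + r2["BO"] - r2["B"] - r2["BIO"],
        "C_BIO": (
            r2["B"] + r2["I"] + r2["O"] - r2["BI"] - r2["BO"] - r2["IO"] + r2["BIO"]
        ),
    }
    suppression = [k for k, v in comp.items() if v < 0]
    return CommonalityPartition(components=comp, R2_full=r2["BIO"], suppression=suppression)


def percent_contributions(
    partition: CommonalityPartition,
    baseline: Literal["explained", "total"] = "explained",
) -> dict[str, float]:
    """Express the partition as percentages.

    ``explained``: components ÷ R²_full × 100 (sums to 100).  ``total``:
    components × 100 as shares of total response variance (sums to
    100·R²_full).  Negative components stay negative.
    """
    if baseline == "explained":
        if partition.R2_full <= 0:
            raise ValueError("R2_full must be positive for the explained baseline")
        denom = partition.R2_full
    elif baseline == "total":
        denom = 1.0
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    return {k: 100.0 * v / denom for k, v in partition.components.items()}


def variance_partition(
    dataset: FoulingDataset,
    mode: Literal["pca_first_component", "raw_multicolumn"] = "raw_multicolumn",
    baseline: Literal["explained", "total"] = "explained",
) -> tuple[CommonalityPartition, dict[str, float]]:
    """End-to-end partition: reduce → subset R² → commonality → percentages."""
    reduced = reduce_blocks(dataset, mode)
    r2 = subset_r2(reduced)
    part = commonality(r2)
    return part, percent_contributions(part, baseline)
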