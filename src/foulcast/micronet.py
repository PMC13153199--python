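"""Microbial co-occurrence networks and topological node roles.

Taxa co-occurrence graphs are built by thresholding pairwise rank (or
product-moment) correlations of abundance profiles.  Modules come from
greedy modularity maximization; each node is then placed on the Zi–Pi
plane — within-module degree z-score Zi against participation coefficient
Pi = 1 − Σ_s (κ_is / k_i)² — and classified with the conventional
thresholds: module hubs (Zi > 2.5, Pi ≤ 0.62), connectors (Zi ≤ 2.5,
Pi > 0.62), network hubs (both exceeded), peripherals otherwise.  A
simplified random-matrix threshold scan (nearest-neighbour eigenvalue
spacings against the Poisson form) helps pick the correlation cutoff.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RoleAssignment",
    "build_network",
    "rmt_threshold_scan",
    "detect_modules",
    "zi_pi",
    "otu_venn",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class RoleAssignment:
    """Zi/Pi coordinates and role label for one node."""

    node: str
    zi: float
    pi: float
    role: Literal["peripheral", "connector", "module_hub", "network_hub"]


def _correlation_matrix(
    table: pd.DataFrame, method: Literal["spearman", "pearson"]
) -> tuple[np.ndarray, list[str]]:
    if table.index.has_duplicates:
        raise ValueError("duplicate taxon identifiers in the abundance table")
    if table.shape[1] < 3:
        raise ValueError("at least 3 samples required for correlation estimation")
    X = table.to_numpy(dtype=float)
    keep = X.std(axis=1) > 0
    if not keep.all():
        dropped = list(table.index[~keep])
        warnings.warn(f"excluding constant taxa: {dropped}", stacklevel=3)
    taxa = list(table.index[keep])
    X = X[keep]
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    R = np.corrcoef(X)
    return R, taxa


def build_network(
    table: pd.DataFrame,
    method: Literal["spearman", "pearson"] = "spearman",
    threshold: float = 0.8,
    drop_isolated: bool = True,
) -> nx.Graph:
    """Co-occurrence graph: edge (i, j) iff |r_ij| ≥ threshold.

    ``table`` holds taxa as rows and samples as columns.  Edge weight is
    |r|, and the correlation sign is kept as the ``sign`` edge attribute.
    Constant taxa are excluded with a warning; isolated nodes are dropped
    unless ``drop_isolated`` is False.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    R, taxa = _correlation_matrix(table, method)
    G = nx.Graph()
    G.add_nodes_from(taxa)
    n = len(taxa)
    for i in range(n):
        for j in range(i + 1, n):
            r = R[i, j]
            if abs(r) >= threshold:
                G.add_edge(taxa[i], taxa[j], weight=abs(r), sign=int(np.sign(r)))
    if drop_isolated:
        G.remove_nodes_from([v for v, d in dict(G.degree()).items() if d == 0])
    return G


def _poisson_spacing_distance(eigvals: np.ndarray, n_bins: int = 7) -> float:
    """χ²/dof distance of the unfolded nearest-neighbour spacings to exp(−s)."""
    lam = np.sort(eigvals)
    n = lam.size
    # polynomial unfolding of the cumulative spectral function; heavily
    # degenerate spectra condition the fit poorly, which is fine — their
    # clustered spacings land far from the Poisson form regardless
    deg = min(9, max(3, n // 4))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        coef = np.polynomial.polynomial.polyfit(lam, np.arange(1, n + 1, dtype=float), deg)
    unfolded = np.polynomial.polynomial.polyval(lam, coef)
    s = np.diff(unfolded)
    s = np.clip(s, 0.0, None)
    if s.mean() <= 0:
        return np.inf
    s = s / s.mean()
    edges = np.linspace(0.0, 3.0, n_bins)
    edges = np.append(edges, np.inf)
    obs, _ = np.histogram(s, bins=edges)
    cdf = 1.0 - np.exp(-edges)
    probs = np.diff(cdf)
    exp = probs * s.size
    valid = exp > 0
    return float(((obs[valid] - exp[valid]) ** 2 / exp[valid]).sum() / valid.sum())


def rmt_threshold_scan(
    table_or_corr: "pd.DataFrame | np.ndarray",
    thresholds: Sequence[float],
    method: Literal["spearman", "pearson"] = "spearman",
    tolerance: float = 2.0,
    min_network_size: int = 10,
) -> tuple[float | None, pd.DataFrame]:
    """Scan correlation cutoffs for Poisson-like eigenvalue spacings.

    For each threshold the correlation matrix is hard-thresholded, rows
    with no remaining off-diagonal entries (unconnected taxa) are removed,
    and the nearest-neighbour spacing distribution of the unfolded
    eigenvalues is compared to the Poisson form exp(−s) by a χ²/dof
    distance.  Networks smaller than ``min_network_size`` are considered
    trivially compatible (distance 0).  Returns the smallest threshold with
    distance ≤ ``tolerance`` (or None) plus the full diagnostic table.
    Deterministic: no randomness is involved.
    """
    thresholds = sorted(float(t) for t in thresholds)
    if len(thresholds) < 3:
        raise ValueError("threshold grid must have at least 3 points")
    if any(not 0 < t < 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    if isinstance(table_or_corr, pd.DataFrame):
        R, _ = _correlation_matrix(table_or_corr, method)
    else:
        R = np.asarray(table_or_corr, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("correlation input must be a square matrix")
    rows = []
    for t in thresholds:
        A = np.where(np.abs(R) >= t, R, 0.0)
        np.fill_diagonal(A, 1.0)
        off = A - np.diag(np.diag(A))
        connected = np.abs(off).sum(axis=1) > 0
        size = int(connected.sum())
        if size < min_network_size:
            dist = 0.0
        else:
            sub = A[np.ix_(connected, connected)]
            dist = _poisson_spacing_distance(np.linalg.eigvalsh(sub))
        rows.append({"threshold": t, "network_size": size, "poisson_distance": dist})
    diag = pd.DataFrame(rows)
    ok = diag[diag["poisson_distance"] <= tolerance]
    suggested = float(ok["threshold"].iloc[0]) if len(ok) else None
    return suggested, diag


def detect_modules(graph: nx.Graph) -> tuple[dict[str, int], float]:
    """Greedy modularity modules and the modularity score Q.

    Uses Clauset–Newman–Moore greedy modularity maximization on the
    unsigned graph; deterministic for a fixed node ordering.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot detect modules on an empty graph")
    communities = list(nx.community.greedy_modularity_communities(graph))
    partition = {node: k for k, comm in enumerate(communities) for node in comm}
    Q = nx.community.modularity(graph, communities) if graph.number_of_edges() else 0.0
    return partition, Q


def zi_pi(graph: nx.Graph, partition: Mapping[str, int]) -> list[RoleAssignment]:
    """Within-module degree z-score and participation coefficient per node.

    Zi = (κ_i − mean κ of the node's module) / sd, with the population sd
    over module members and Zi = 0 where the module's within-degrees have
    zero variance.  Pi = 1 − Σ_s (κ_is / k_i)²; degree-0 nodes get Pi = 0
    with a warning.  Role thresholds: hubs at Zi > 2.5, connectors at
    Pi > 0.62 (boundary values are peripheral).
    """
    missing = [v for v in graph.nodes if v not in partition]
    if missing:
        raise ValueError(f"nodes without a module assignment: {missing[:5]}")
    modules: dict[int, list] = {}
    for v in graph.nodes:
        modules.setdefault(partition[v], []).append(v)

    within = {
        v: sum(1 for u in graph.neighbors(v) if partition[u] == partition[v])
        for v in graph.nodes
    }
    mod_stats = {}
    for m, members in modules.items():
        k = np.array([within[v] for v in members], dtype=float)
        mod_stats[m] = (k.mean(), k.std())  # population sd (MENA convention)

    out = []
    for v in graph.nodes:
        mean, sd = mod_stats[partition[v]]
        zi = (within[v] - mean) / sd if sd > 0 else 0.0
        k_i = graph.degree(v)
        if k_i == 0:
            warnings.warn(f"node {v!r} has degree 0; Pi set to 0", stacklevel=2)
            pi = 0.0
        else:
            per_mod: dict[int, int] = {}
            for u in graph.neighbors(v):
                per_mod[partition[u]] = per_mod.get(partition[u], 0) + 1
            pi = 1.0 - sum((c / k_i) ** 2 for c in per_mod.values())
        if zi > ZI_THRESHOLD and pi > PI_THRESHOLD:
            role = "network_hub"
        elif zi > ZI_THRESHOLD:
            role = "module_hub"
        elif pi > PI_THRESHOLD:
            role = "connector"
        else:
            role = "peripheral"
        out.append(RoleAssignment(node=v, zi=float(zi), pi=float(pi), role=role))
    return out


def otu_venn(sets: Mapping[str, Iterable]) -> dict[str, int]:
    """Exact membership-class counts for up to four OTU sets.

    For k named sets, returns counts for every non-empty membership class
    (2^k − 1 of them; 15 for the feed/Ctrl/Al/Fe comparison), keyed by the
    '&'-joined set names in input order.  Unique-per-set counts are the
    single-name keys.
    """
    names = list(sets)
    as_sets = {n: set(sets[n]) for n in names}
    universe = set().union(*as_sets.values()) if names else set()
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(as_sets[n] for n in combo)) if combo else set()
            outside = set().union(*(as_sets[n] for n in names if n not in combo), set())
            counts["&".join(combo)] = len(inside - outside)
    assert sum(counts.values()) == len(universe)
    return counts
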