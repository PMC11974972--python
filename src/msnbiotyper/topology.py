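"""Graph hubness metrics over a sparsity grid, summarised as AUC.

Each subject's similarity matrix is binarised at every sparsity level s in a
grid (default 0.10 to 0.34 in steps of 0.01) by keeping the m = floor(s *
R(R-1)/2) strongest off-diagonal weights as undirected edges.  At each level
three nodal metrics are computed:

* degree centrality (DC): the number of incident edges;
* nodal efficiency (NE): mean inverse shortest-path length to all other
  nodes (unreachable pairs contribute 0);
* participation coefficient (PC): 1 - sum_m (k_im / k_i)^2 over the modules
  of a greedy modularity partition, 0 for isolated nodes.

The per-region curve of each metric over the grid is reduced to its
trapezoidal area under the curve, giving a threshold-free hubness profile of
shape (region, metric).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "METRICS",
    "ThresholdGrid",
    "BinaryGraph",
    "ModulePartition",
    "HubnessProfile",
    "binarize_at_sparsity",
    "degree_centrality",
    "nodal_efficiency",
    "detect_modules",
    "participation_coefficient",
    "auc_over_sparsity",
    "compute_hubness",
]

METRICS = ("DC", "NE", "PC")


@dataclass
class ThresholdGrid:
    """Strictly increasing sparsity levels, all in (0, 1)."""

    sparsities: np.ndarray = None

    def __post_init__(self):
        if self.sparsities is None:
            self.sparsities = np.round(np.arange(0.10, 0.3401, 0.01), 10)
        self.sparsities = np.asarray(self.sparsities, dtype=float)
        if np.any(np.diff(self.sparsities) <= 0):
            raise ValueError("sparsities must be strictly increasing")
        if np.any((self.sparsities <= 0) | (self.sparsities >= 1)):
            raise ValueError("sparsities must lie in (0, 1)")

    @property
    def span(self) -> float:
        return float(self.sparsities[-1] - self.sparsities[0])

    def __len__(self) -> int:
        return len(self.sparsities)


@dataclass
class BinaryGraph:
    adjacency: np.ndarray
    sparsity: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class ModulePartition:
    assignment: np.ndarray  # region -> contiguous community id from 0
    modularity_q: float


@dataclass
class HubnessProfile:
    """Subject x region x metric AUC-summarised hubness features."""

    subject_ids: Sequence[str]
    region_ids: Sequence[str]
    values: np.ndarray  # (n_subjects, R, 3)
    metrics: Sequence[str] = field(default=METRICS)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, R, M = self.values.shape
        if n != len(self.subject_ids) or R != len(self.region_ids):
            raise ValueError("values shape inconsistent with labels")
        if M != len(self.metrics):
            raise ValueError("metric axis inconsistent")

    def to_long(self) -> pd.DataFrame:
        n, R, M = self.values.shape
        return pd.DataFrame(
            {
                "subject_id": np.repeat(list(self.subject_ids), R * M),
                "region": np.tile(np.repeat(list(self.region_ids), M), n),
                "metric": np.tile(list(self.metrics), n * R),
                "value": self.values.ravel(),
            }
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "HubnessProfile":
        subjects = list(pd.unique(df["subject_id"]))
        regions = list(pd.unique(df["region"]))
        metrics = [m for m in METRICS if m in set(df["metric"])]
        wide = df.pivot_table(
            index="subject_id", columns=["region", "metric"], values="value", sort=False
        )
        cols = pd.MultiIndex.from_product([regions, metrics])
        arr = wide.loc[subjects, cols].to_numpy().reshape(
            len(subjects), len(regions), len(metrics)
        )
        return cls(subjects, regions, arr, tuple(metrics))

    def matrix(self) -> np.ndarray:
        """Flatten to (n_subjects, R * n_metrics), region-major."""
        n = self.values.shape[0]
        return self.values.reshape(n, -1)

    def feature_names(self) -> list:
        return [f"{r}:{m}" for r in self.region_ids for m in self.metrics]


def binarize_at_sparsity(W: np.ndarray, s: float) -> BinaryGraph:
    """Keep the floor(s * R(R-1)/2) strongest off-diagonal weights as edges.

    Ties are broken by ascending (row, col) index so the result is fully
    deterministic.
    """
    W = np.asarray(W, dtype=float)
    R = W.shape[0]
    if not 0 < s < 1:
        raise ValueError("sparsity must lie in (0, 1)")
    m = math.floor(s * R * (R - 1) / 2)
    if m == 0:
        raise ValueError(f"sparsity {s} keeps zero edges for R={R}")
    ii, jj = np.triu_indices(R, k=1)
    w = W[ii, jj]
    # sort by weight descending, then (row, col) ascending
    order = np.lexsort((jj, ii, -w))
    keep = order[:m]
    A = np.zeros((R, R), dtype=bool)
    A[ii[keep], jj[keep]] = True
    A |= A.T
    return BinaryGraph(A, float(s))


def degree_centrality(G: BinaryGraph) -> np.ndarray:
    return G.adjacency.sum(axis=1).astype(int)


def nodal_efficiency(G: BinaryGraph) -> np.ndarray:
    """NE(i) = mean over j != i of 1/d(i, j); unreachable pairs contribute 0."""
    R = G.n_nodes
    d = shortest_path(G.adjacency.astype(np.int8), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (R - 1)


def detect_modules(G: BinaryGraph, seed: int = 0) -> ModulePartition:
    """Greedy (agglomerative, Newman-style) modularity partition.

    Deterministic for a given graph; ``seed`` is accepted for interface
    stability but the greedy merge order is already fully determined.
    An edgeless graph collapses to a single community.
    """
    R = G.n_nodes
    if G.n_edges == 0:
        return ModulePartition(np.zeros(R, dtype=int), 0.0)
    g = nx.from_numpy_array(G.adjacency.astype(int))
    comms = nx.algorithms.community.greedy_modularity_communities(g)
    assignment = np.empty(R, dtype=int)
    for cid, members in enumerate(comms):
        for node in members:
            assignment[node] = cid
    q = nx.algorithms.community.modularity(g, comms)
    return ModulePartition(assignment, float(q))


def participation_coefficient(G: BinaryGraph, part: ModulePartition) -> np.ndarray:
    """PC(i) = 1 - sum_m (k_im / k_i)^2; 0 by convention for isolated nodes."""
    A = G.adjacency.astype(float)
    k = A.sum(axis=1)
    n_modules = int(part.assignment.max()) + 1
    onehot = np.eye(n_modules)[part.assignment]  # (R, M)
    k_im = A @ onehot
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = k_im / k[:, None]
    pc = 1.0 - np.nansum(frac**2, axis=1)
    pc[k == 0] = 0.0
    return pc


def auc_over_sparsity(curve, grid: ThresholdGrid) -> float:
    """Trapezoidal area of a per-sparsity metric curve over the grid."""
    curve = np.asarray(curve, dtype=float)
    if curve.shape[0] != len(grid):
        raise ValueError("curve length must match grid")
    return float(np.trapezoid(curve, grid.sparsities))


def compute_hubness(
    W, grid: ThresholdGrid = None, seed: int = 0, subject_id: str = None, region_ids=None
) -> HubnessProfile:
    """DC/NE/PC AUC profile of one similarity matrix over the sparsity grid.

    At every sparsity the matrix is binarised, the three nodal metrics are
    computed (PC against that graph's own greedy partition), and each
    region-metric curve is reduced to its trapezoidal AUC.
    """
    if hasattr(W, "W"):
        subject_id = subject_id or W.subject_id
        region_ids = region_ids if region_ids is not None else W.region_ids
        W = W.W
    W = np.asarray(W, dtype=float)
    grid = grid or ThresholdGrid()
    R = W.shape[0]
    curves = np.empty((len(grid), R, 3))
    for t, s in enumerate(grid.sparsities):
        G = binarize_at_sparsity(W, s)
        part = detect_modules(G, seed=seed)
        curves[t, :, 0] = degree_centrality(G)
        curves[t, :, 1] = nodal_efficiency(G)
        curves[t, :, 2] = participation_coefficient(G, part)
    auc = np.trapezoid(curves, grid.sparsities, axis=0)  # (R, 3)
    if region_ids is None:
        region_ids = [f"region_{i:03d}" for i in range(R)]
    return HubnessProfile([subject_id or "subject"], list(region_ids), auc[None, :, :])


def stack_profiles(profiles: Sequence[HubnessProfile]) -> HubnessProfile:
    """Concatenate single-subject profiles into one cohort profile."""
    base = profiles[0]
    subj = [s for p in profiles for s in p.subject_ids]
    vals = np.concatenate([p.values for p in profiles], axis=0)
    return HubnessProfile(subj, list(base.region_ids), vals, base.metrics)
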