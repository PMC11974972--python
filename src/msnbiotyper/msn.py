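"""Individual morphometric similarity networks (MSNs).

Each subject contributes, for every brain parcel, a sample of regional
morphometric values (e.g. voxel-wise gray-matter volumes within the parcel).
The similarity of two parcels is measured on their estimated value
distributions: a Gaussian kernel density estimate of each region's values is
evaluated on a shared grid, the symmetric Kullback-Leibler divergence D
between the two discrete densities is computed, and the Kullback-Leibler
divergence similarity

    KLS(p, q) = exp(-D(p, q)),  D = sum p ln(p/q) + sum q ln(q/p)

maps divergence into (0, 1], with 1 meaning identical distributions.  Doing
this for every pair of parcels yields an R x R morphometric similarity
network per subject with unit diagonal.

The default grid has 2**7 = 128 abscissae per region pair, spanning the
pooled range of the pair's values extended by 10% on each side.  Densities
are floored at 1e-12 before renormalisation so the divergence is always
finite and KLS stays strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionalMorphometry",
    "SimilarityMatrix",
    "estimate_density",
    "kl_symmetric",
    "kls",
    "build_msn",
    "read_morphometry_tsv",
    "write_similarity_tsv",
    "read_similarity_tsv",
]

DENSITY_FLOOR = 1e-12
DEFAULT_GRID_POINTS = 128  # 2**7
GRID_EXTENSION = 0.10  # fraction of the pooled range added on each side


@dataclass
class RegionalMorphometry:
    """Per-subject regional value samples: the raw material for one MSN."""

    subject_id: str
    values: list  # length-R list of 1-D float arrays (ragged allowed)
    region_ids: Sequence[str] = field(default=None)

    def __post_init__(self):
        self.values = [np.asarray(v, dtype=float).ravel() for v in self.values]
        if self.region_ids is None:
            self.region_ids = [f"region_{i:03d}" for i in range(len(self.values))]
        if len(self.values) < 2:
            raise ValueError("morphometry needs at least 2 regions")
        for rid, v in zip(self.region_ids, self.values):
            if v.size == 0 or not np.isfinite(v).any():
                raise ValueError(f"region {rid!r} has no finite values")

    @property
    def n_regions(self) -> int:
        return len(self.values)


@dataclass
class SimilarityMatrix:
    """Symmetric R x R KLS matrix with unit diagonal, entries in (0, 1]."""

    subject_id: str
    W: np.ndarray
    region_ids: Sequence[str] = None

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        R = self.W.shape[0]
        if self.W.shape != (R, R):
            raise ValueError("W must be square")
        if self.region_ids is None:
            self.region_ids = [f"region_{i:03d}" for i in range(R)]

    @property
    def n_regions(self) -> int:
        return self.W.shape[0]

    def validate(self, atol: float = 1e-12) -> None:
        if not np.allclose(self.W, self.W.T, atol=atol):
            raise ValueError("similarity matrix not symmetric")
        if not np.all(np.diag(self.W) == 1.0):
            raise ValueError("diagonal must be exactly 1")
        off = self.W[~np.eye(self.n_regions, dtype=bool)]
        if np.any(off <= 0) or np.any(off > 1):
            raise ValueError("off-diagonal entries must lie in (0, 1]")


def silverman_bandwidth(values: np.ndarray, grid_span: float) -> float:
    """Silverman rule-of-thumb bandwidth with a degenerate-sample fallback.

    Zero-variance samples (all values identical) get a bandwidth of
    1e-3 * grid span so the density remains a well-defined narrow peak.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = values.size
    if n == 0:
        raise ValueError("no finite values")
    sd = values.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(values, [75, 25])) if n > 1 else 0.0
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return max(1e-3 * grid_span, np.finfo(float).tiny)
    return 0.9 * spread * n ** (-0.2)


def estimate_density(values, grid) -> np.ndarray:
    """Gaussian-KDE density of ``values`` on ``grid``, as a discrete pmf.

    The result is floored at 1e-12 and renormalised to sum to exactly 1
    over the grid points, which is the normalisation the divergence sums
    assume.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("all values are non-finite")
    grid = np.asarray(grid, dtype=float).ravel()
    span = float(grid[-1] - grid[0]) if grid.size > 1 else 1.0
    bw = silverman_bandwidth(values, span)
    z = (grid[:, None] - values[None, :]) / bw
    dens = np.exp(-0.5 * z * z).sum(axis=1)
    dens = np.maximum(dens, 0.0) + 0.0
    dens /= dens.sum() if dens.sum() > 0 else 1.0
    dens = np.maximum(dens, DENSITY_FLOOR)
    dens /= dens.sum()
    return dens


def kl_symmetric(p: np.ndarray, q: np.ndarray) -> float:
    """Symmetric KL divergence sum(p ln p/q) + sum(q ln q/p) on a shared grid."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("densities must share the same grid")
    return float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))


def kls(p: np.ndarray, q: np.ndarray) -> float:
    """Kullback-Leibler divergence similarity exp(-D_sym); in (0, 1]."""
    return float(np.exp(-kl_symmetric(p, q)))


def _pair_grid(vi: np.ndarray, vj: np.ndarray, grid_points: int) -> np.ndarray:
    lo = min(vi.min(), vj.min())
    hi = max(vi.max(), vj.max())
    span = hi - lo
    if span <= 0:
        span = max(abs(lo), 1.0)
    lo -= GRID_EXTENSION * span
    hi += GRID_EXTENSION * span
    return np.linspace(lo, hi, grid_points)


def build_msn(
    morph: RegionalMorphometry, grid_points: int = DEFAULT_GRID_POINTS
) -> SimilarityMatrix:
    """Build a subject's MSN: KLS over all region pairs on pairwise grids.

    For each unordered pair (i, j) the grid spans the pooled min/max of the
    two regions' values, extended by 10% on each side, with ``grid_points``
    abscissae; W[i, j] = KLS of the two densities, and the diagonal is 1.
    """
    R = morph.n_regions
    vals = [v[np.isfinite(v)] for v in morph.values]
    for rid, v in zip(morph.region_ids, vals):
        if v.size == 0:
            raise ValueError(f"region {rid!r} is empty")
    W = np.eye(R)
    # Precompute per-region spread stats for the bandwidth rule.
    for i in range(R):
        for j in range(i + 1, R):
            grid = _pair_grid(vals[i], vals[j], grid_points)
            di = estimate_density(vals[i], grid)
            dj = estimate_density(vals[j], grid)
            W[i, j] = W[j, i] = kls(di, dj)
    out = SimilarityMatrix(morph.subject_id, W, morph.region_ids)
    out.validate()
    return out


def build_msn_equal_voxels(
    subject_id: str,
    values: np.ndarray,
    region_ids=None,
    grid_points: int = DEFAULT_GRID_POINTS,
) -> SimilarityMatrix:
    """Vectorised MSN construction for the common equal-voxel-count case.

    ``values`` is an (R, n_voxels) array.  Numerically identical to
    :func:`build_msn` on the same data, but evaluates all pair densities with
    chunked broadcasting instead of a Python loop per pair, which matters
    when R is large.
    """
    values = np.asarray(values, dtype=float)
    R, nv = values.shape
    mins, maxs = values.min(axis=1), values.max(axis=1)
    sds = values.std(axis=1, ddof=1) if nv > 1 else np.zeros(R)
    iqrs = np.percentile(values, 75, axis=1) - np.percentile(values, 25, axis=1)
    spread = np.where(iqrs > 0, np.minimum(sds, iqrs / 1.34), sds)

    ii, jj = np.triu_indices(R, k=1)
    lo = np.minimum(mins[ii], mins[jj])
    hi = np.maximum(maxs[ii], maxs[jj])
    span = hi - lo
    span = np.where(span <= 0, np.maximum(np.abs(lo), 1.0), span)
    lo = lo - GRID_EXTENSION * span
    hi = hi + GRID_EXTENSION * span

    W = np.eye(R)
    chunk = max(1, int(4e6 // (nv * grid_points)))
    t = np.linspace(0.0, 1.0, grid_points)
    for start in range(0, ii.size, chunk):
        sl = slice(start, min(start + chunk, ii.size))
        grids = lo[sl, None] + (hi[sl] - lo[sl])[:, None] * t[None, :]
        gspan = grids[:, -1] - grids[:, 0]
        dens = []
        for idx in (ii[sl], jj[sl]):
            v = values[idx]  # (c, nv)
            bw = np.where(
                spread[idx] > 0,
                0.9 * spread[idx] * nv ** (-0.2),
                np.maximum(1e-3 * gspan, np.finfo(float).tiny),
            )
            z = (grids[:, :, None] - v[:, None, :]) / bw[:, None, None]
            d = np.exp(-0.5 * z * z).sum(axis=2)
            d /= d.sum(axis=1, keepdims=True)
            d = np.maximum(d, DENSITY_FLOOR)
            d /= d.sum(axis=1, keepdims=True)
            dens.append(d)
        di, dj = dens
        D = (di * np.log(di / dj)).sum(axis=1) + (dj * np.log(dj / di)).sum(axis=1)
        W[ii[sl], jj[sl]] = W[jj[sl], ii[sl]] = np.exp(-D)
    out = SimilarityMatrix(subject_id, W, region_ids)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# I/O


def read_morphometry_tsv(path, subject_id: str) -> RegionalMorphometry:
    """Read one subject's TSV with columns ``region`` and ``value``."""
    df = pd.read_csv(path, sep="\t")
    groups = df.groupby("region", sort=True)["value"]
    region_ids = [str(r) for r in groups.groups]
    values = [g.to_numpy(dtype=float) for _, g in groups]
    return RegionalMorphometry(subject_id, values, region_ids)


def write_similarity_tsv(sim: SimilarityMatrix, path) -> None:
    pd.DataFrame(sim.W, index=sim.region_ids, columns=sim.region_ids).to_csv(
        path, sep="\t", index_label="region"
    )


def read_similarity_tsv(path, subject_id: str) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(subject_id, df.to_numpy(dtype=float), list(df.columns))
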