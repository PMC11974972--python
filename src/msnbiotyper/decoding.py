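"""Spatial decoding of deviation maps against annotation maps.

Correspondence between a region-level deviation map and annotation maps
(receptor densities, cognitive-term activations) is quantified with Spearman
correlation, and significance is assessed against spin surrogates: random
3-D rotations of the parcel centroid cloud, applied per hemisphere, with
values reassigned to the nearest rotated centroid so each surrogate is a
permutation of the input values that approximately preserves spatial
autocorrelation.  Subcortical parcels cannot ride a spherical rotation, so
they are permuted uniformly among themselves.

A one-component partial least squares regression (PLS1) relates the
deviation map (response) to a region-by-term annotation matrix (predictors);
term weights are stabilised by bootstrap resampling of regions, giving a
Z-score per term (weight / bootstrap SD), and component significance comes
from refitting against spin-rotated responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .deviations import bh_fdr

__all__ = [
    "AnnotationMaps",
    "SpinNull",
    "PlsResult",
    "generate_spin_surrogates",
    "spearman_with_spin",
    "decode_receptors",
    "pls_decode",
]


@dataclass
class AnnotationMaps:
    """Named region-level maps with parcel centroids and a cortical mask."""

    names: Sequence[str]
    M: np.ndarray  # (n_maps, R)
    centroids: np.ndarray  # (R, 3) mm
    cortical_mask: np.ndarray  # (R,) bool
    weights: Optional[np.ndarray] = None  # per-map averaging weights, if any

    def __post_init__(self):
        self.M = np.atleast_2d(np.asarray(self.M, dtype=float))
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.cortical_mask = np.asarray(self.cortical_mask, dtype=bool)
        if self.M.shape[1] != self.centroids.shape[0]:
            raise ValueError("map length does not match centroid count")
        if np.isnan(self.M).any():
            raise ValueError("annotation maps must not contain NaN")

    @property
    def n_regions(self) -> int:
        return self.M.shape[1]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.M.T, columns=list(self.names)).to_csv(
            path, sep="\t", index_label="region"
        )


@dataclass
class SpinNull:
    surrogates: np.ndarray  # (n_perm, R), each row a permutation of the input
    seed: int
    method: str = "spin"

    @property
    def n_perm(self) -> int:
        return self.surrogates.shape[0]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation in SO(3) via QR of a Gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, Rm = np.linalg.qr(A)
    Q *= np.sign(np.diag(Rm))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _greedy_core(order: np.ndarray, n: int) -> np.ndarray:
    perm = np.full(n, -1, dtype=np.int64)
    used_src = np.zeros(n, dtype=np.bool_)
    filled = 0
    for flat in order:
        j = flat // n
        i = flat - j * n
        if perm[j] >= 0 or used_src[i]:
            continue
        perm[j] = i
        used_src[i] = True
        filled += 1
        if filled == n:
            break
    return perm


try:  # the serial collision loop dominates surrogate generation; JIT it
    from numba import njit

    _greedy_core = njit(cache=True)(_greedy_core)
except Exception:  # pragma: no cover - numba is optional
    pass


def _greedy_assign(orig: np.ndarray, rotated: np.ndarray) -> np.ndarray:
    """Match rotated centroids to original ones, closest pairs first.

    Returns ``perm`` with perm[j] = index of the original centroid whose
    value is carried to position j.  Collisions (two rotated points nearest
    to the same original) are resolved greedily by ascending distance.
    """
    n = orig.shape[0]
    d2 = ((rotated[:, None, :] - orig[None, :, :]) ** 2).sum(-1)
    order = np.argsort(d2, axis=None, kind="stable")
    return _greedy_core(order.astype(np.int64), n)


def generate_spin_surrogates(
    values: np.ndarray,
    centroids: np.ndarray,
    cortical_mask: Optional[np.ndarray] = None,
    n_perm: int = 5000,
    seed: int = 0,
) -> SpinNull:
    """Spin surrogates of a region map: rotations for cortex, shuffles elsewhere.

    Each surrogate applies one random rotation to the left-hemisphere
    centroid cloud (x < 0) and its mirror image to the right, reassigns
    cortical values by greedy nearest-centroid matching, and uniformly
    permutes the non-cortical values among themselves.  Every surrogate row
    is an exact permutation of the input values.
    """
    values = np.asarray(values, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    R = values.size
    if cortical_mask is None:
        cortical_mask = np.ones(R, dtype=bool)
    cortical_mask = np.asarray(cortical_mask, dtype=bool)
    rng = child_rng(seed, "spin")
    # jitter duplicate centroids so nearest-neighbour matching is well posed
    cort_idx = np.flatnonzero(cortical_mask)
    sub_idx = np.flatnonzero(~cortical_mask)
    cort = centroids[cort_idx].copy()
    if len(cort) and len(np.unique(cort, axis=0)) < len(cort):
        import warnings

        warnings.warn("duplicate centroids: jittering by 1e-6")
        cort = cort + rng.normal(0.0, 1e-6, size=cort.shape)
    left = cort[:, 0] < 0
    mirror = np.diag([-1.0, 1.0, 1.0])
    surrogates = np.empty((n_perm, R))
    for p in range(n_perm):
        surr = np.empty(R)
        if len(cort):
            Q = _random_rotation(rng)
            rotated = cort.copy()
            if left.any():
                rotated[left] = cort[left] @ Q.T
            if (~left).any():
                rotated[~left] = cort[~left] @ (mirror @ Q @ mirror).T
            perm = _greedy_assign(cort, rotated)
            surr[cort_idx] = values[cort_idx][perm]
        if len(sub_idx):
            surr[sub_idx] = values[sub_idx][rng.permutation(len(sub_idx))]
        surrogates[p] = surr
    return SpinNull(surrogates, seed)


def spearman_with_spin(map_a, map_b, null: SpinNull):
    """Spearman rho of two maps with a two-tailed spin p-value.

    The surrogates must have been generated from ``map_a``.  Returns
    (rho, p_spin); rho is NaN for a constant map.
    """
    map_a = np.asarray(map_a, dtype=float)
    map_b = np.asarray(map_b, dtype=float)
    if np.ptp(map_a) == 0 or np.ptp(map_b) == 0:
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(map_a, map_b).statistic)
    rb = stats.rankdata(map_b)
    rs = np.apply_along_axis(stats.rankdata, 1, null.surrogates)
    rs = (rs - rs.mean(axis=1, keepdims=True)) / rs.std(axis=1, keepdims=True)
    zb = (rb - rb.mean()) / rb.std()
    null_rho = rs @ zb / len(zb)
    p = (1.0 + np.sum(np.abs(null_rho) >= abs(rho))) / (null.n_perm + 1.0)
    return rho, float(p)


def decode_receptors(
    fused: np.ndarray,
    maps: AnnotationMaps,
    n_perm: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman + spin test of a fused deviation map against every receptor map.

    One spin null is generated from the fused map and shared across
    receptors; p-values are BH-FDR corrected across the maps.  Multi-tracer
    receptors are assumed to be pre-averaged into one map each (the
    synthetic generator emits one map per name); per-map averaging weights,
    when present, are applied before correlation.
    """
    fused = np.asarray(fused, dtype=float)
    null = generate_spin_surrogates(
        fused, maps.centroids, maps.cortical_mask, n_perm=n_perm, seed=seed
    )
    rows = []
    for i, name in enumerate(maps.names):
        rho, p = spearman_with_spin(fused, maps.M[i], null)
        rows.append({"map": name, "rho": rho, "p_spin": p})
    df = pd.DataFrame(rows)
    df["p_spin_fdr"] = bh_fdr(df["p_spin"].to_numpy())
    return df


@dataclass
class PlsResult:
    component_loadings: np.ndarray  # per-term weights of component 1
    scores: np.ndarray  # per-region scores of component 1
    explained_variance: float  # fraction of response variance explained
    p_spin: float
    bootstrap_z: np.ndarray
    ranking: np.ndarray  # term indices sorted by |bootstrap_z| descending
    term_names: Sequence[str] = None


def _pls1(X: np.ndarray, y: np.ndarray):
    """First PLS component for a single response: w ∝ X^T y."""
    w = X.T @ y
    norm = np.linalg.norm(w)
    if norm == 0:
        return np.zeros_like(w), np.zeros_like(y), 0.0
    w = w / norm
    t = X @ w
    tt = float(t @ t)
    if tt == 0:
        return w, t, 0.0
    q = float(y @ t) / tt
    ev = 1.0 - float(np.sum((y - q * t) ** 2)) / float(np.sum((y - y.mean()) ** 2))
    return w, t, max(ev, 0.0)


def pls_decode(
    fused: np.ndarray,
    terms: AnnotationMaps,
    n_boot: int = 10000,
    n_perm: int = 5000,
    seed: int = 0,
) -> PlsResult:
    """PLS1 of a fused deviation map on a cognitive-term matrix.

    Terms are column-standardised across regions; the component is oriented
    so its region scores correlate positively with the response.  Bootstrap
    resampling of regions (with replacement) yields Z = weight / bootstrap
    SD per term, sign-aligned to the original component; the component's
    spin p-value is the fraction of surrogate responses achieving at least
    the observed explained variance.
    """
    y = np.asarray(fused, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant response map")
    X = terms.M.T.copy()  # (R, T)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    yc = y - y.mean()
    w, t, ev = _pls1(X, yc)
    if np.corrcoef(t, yc)[0, 1] < 0:
        w, t = -w, -t
    R = len(y)
    rng = child_rng(seed, "pls-bootstrap")
    idx = rng.integers(0, R, size=(n_boot, R))
    Xb = X[idx]  # (B, R, T)
    yb = yc[idx]
    Wb = np.einsum("brt,br->bt", Xb, yb)
    Wb /= np.maximum(np.linalg.norm(Wb, axis=1, keepdims=True), 1e-30)
    flip = np.sign(Wb @ w)
    flip[flip == 0] = 1.0
    Wb *= flip[:, None]
    boot_sd = Wb.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(boot_sd > 0, w / boot_sd, 0.0)
    if n_perm > 0:
        null = generate_spin_surrogates(
            y, terms.centroids, terms.cortical_mask, n_perm=n_perm, seed=seed
        )
        null_ev = np.empty(n_perm)
        for p in range(n_perm):
            ys = null.surrogates[p] - null.surrogates[p].mean()
            _, _, null_ev[p] = _pls1(X, ys)
        p_spin = (1.0 + np.sum(null_ev >= ev)) / (n_perm + 1.0)
    else:
        p_spin = np.nan
    ranking = np.argsort(-np.abs(z), kind="stable")
    return PlsResult(w, t, ev, float(p_spin), z, ranking, list(terms.names))
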