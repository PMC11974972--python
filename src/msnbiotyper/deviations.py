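"""Extreme-deviation maps and their permutation-based significance.

A subject shows an extreme deviation at a region-metric when |Z| >= 2.0
against the normative model.  Group maps record the proportion of subjects
with suprathreshold positive or negative deviations at each region; case
maps minus control maps give difference maps.  Two nulls assess these
differences: group permutation (random reassignment of case/control labels,
two-tailed with add-one correction) and spatial permutation (spin
surrogates of the difference map).  Benjamini-Hochberg FDR is applied per
metric across regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._rng import child_rng
from .normative import DeviationMatrix

__all__ = [
    "ExtremeDeviationMap",
    "PermutationResult",
    "extreme_map",
    "subject_any_extreme_rate",
    "group_permutation_test",
    "spatial_permutation_test",
    "bh_fdr",
    "fuse_metric_maps",
]

EXTREME_Z = 2.0


@dataclass
class ExtremeDeviationMap:
    group: str
    direction: str  # 'positive' | 'negative'
    proportion: np.ndarray  # (R, M) in [0, 1]
    threshold: float = EXTREME_Z


@dataclass
class PermutationResult:
    observed: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    n_perm: int
    method: str


def _group_rows(dev: DeviationMatrix, groups, which):
    groups = np.asarray(groups)
    mask = groups == which
    if not mask.any():
        raise ValueError(f"no subjects in group {which!r}")
    return dev.Z[mask]


def extreme_map(
    dev: DeviationMatrix,
    groups,
    which: str,
    direction: str = "positive",
    threshold: float = EXTREME_Z,
) -> ExtremeDeviationMap:
    """Proportion of the group with supra-threshold deviations per region-metric."""
    Z = _group_rows(dev, groups, which)
    if direction == "positive":
        hits = Z >= threshold
    elif direction == "negative":
        hits = Z <= -threshold
    else:
        raise ValueError("direction must be 'positive' or 'negative'")
    return ExtremeDeviationMap(which, direction, hits.mean(axis=0), threshold)


def subject_any_extreme_rate(
    dev: DeviationMatrix, groups, which: str, metric: str, threshold: float = EXTREME_Z
) -> float:
    """Fraction of the group's subjects with >=1 extreme region for the metric."""
    Z = _group_rows(dev, groups, which)
    m = list(dev.metrics).index(metric)
    return float(np.any(np.abs(Z[:, :, m]) >= threshold, axis=1).mean())


def group_permutation_test(
    dev: DeviationMatrix,
    labels,
    threshold: float = EXTREME_Z,
    direction: str = "net",
    n_perm: int = 5000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of case-control extreme-proportion differences.

    The observed statistic per region-metric is the case minus control
    difference in extreme-deviation proportion ('positive', 'negative', or
    'net' = positive - negative).  Labels are randomly reassigned ``n_perm``
    times; two-tailed p-values use the add-one rule
    p = (1 + #{|null| >= |obs|}) / (n_perm + 1), then BH-FDR across regions
    within each metric.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p-value")
    labels = np.asarray(labels)
    is_case = labels == "case" if labels.dtype.kind in "SU" else labels.astype(bool)
    n = len(is_case)
    n_cases = int(is_case.sum())
    if n_cases == 0 or n_cases == n:
        raise ValueError("both groups must be non-empty")
    pos = (dev.Z >= threshold).reshape(n, -1).astype(float)
    neg = (dev.Z <= -threshold).reshape(n, -1).astype(float)
    if direction == "positive":
        E = pos
    elif direction == "negative":
        E = neg
    elif direction == "net":
        E = pos - neg
    else:
        raise ValueError("direction must be 'positive', 'negative' or 'net'")
    case_f = is_case.astype(float)
    obs = E[is_case].mean(axis=0) - E[~is_case].mean(axis=0)
    rng = child_rng(seed, "group-perm")
    # vectorised permutation: delta = (P @ E)/n_case - ((1-P) @ E)/n_ctrl
    exceed = np.zeros(E.shape[1])
    chunk = max(1, int(2e7 // (n * E.shape[1]) + 1))
    done = 0
    colsum = E.sum(axis=0)
    while done < n_perm:
        b = min(chunk, n_perm - done)
        P = np.empty((b, n))
        for i in range(b):
            P[i] = rng.permutation(case_f)
        case_sum = P @ E
        delta = case_sum / n_cases - (colsum - case_sum) / (n - n_cases)
        exceed += (np.abs(delta) >= np.abs(obs)[None, :] - 1e-15).sum(axis=0)
        done += b
    p = (1.0 + exceed) / (n_perm + 1.0)
    R, M = dev.Z.shape[1], dev.Z.shape[2]
    p_fdr = _fdr_per_metric(p.reshape(R, M))
    return PermutationResult(
        obs.reshape(R, M), p.reshape(R, M), p_fdr, n_perm, "group"
    )


def spatial_permutation_test(
    delta: np.ndarray,
    centroids: np.ndarray,
    cortical_mask: Optional[np.ndarray] = None,
    n_perm: int = 5000,
    seed: int = 0,
) -> PermutationResult:
    """Spin-surrogate test of a region difference map.

    Surrogates relocate the observed map over the parcellation; per region,
    p = (1 + #{|surrogate value| >= |observed|}) / (n_perm + 1), two-tailed,
    then BH-FDR across regions.
    """
    from .decoding import generate_spin_surrogates  # deferred: avoids a cycle

    delta = np.asarray(delta, dtype=float)
    null = generate_spin_surrogates(
        delta, centroids, cortical_mask, n_perm=n_perm, seed=seed
    )
    exceed = (np.abs(null.surrogates) >= np.abs(delta)[None, :] - 1e-15).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return PermutationResult(delta, p, bh_fdr(p), n_perm, "spatial")


def bh_fdr(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=alpha, method="fdr_bh")[1]


def _fdr_per_metric(p_rm: np.ndarray) -> np.ndarray:
    """BH families are the regions of each metric, mirroring per-metric reporting."""
    out = np.empty_like(p_rm)
    for m in range(p_rm.shape[1]):
        out[:, m] = bh_fdr(p_rm[:, m])
    return out


def fuse_metric_maps(deltas) -> np.ndarray:
    """Aggregate per-metric net difference maps into one fused region vector.

    Each metric's net map (positive minus negative proportion difference)
    is standardised to zero mean and unit SD across regions, then the
    metrics are averaged.  Constant maps contribute zeros.
    """
    deltas = [np.asarray(d, dtype=float) for d in deltas]
    if len(deltas) != 3:
        warnings.warn(f"expected 3 metric maps, got {len(deltas)}; fusing available")
    zs = []
    for d in deltas:
        sd = d.std()
        zs.append((d - d.mean()) / sd if sd > 0 else np.zeros_like(d))
    return np.mean(zs, axis=0)
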