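"""Normalized symptom indices and between-biotype association tests.

Raw symptom subscale scores from different sites live on different scales,
so each score is rescaled by the maximum observed at its own site within
its domain, giving a normalized symptom index in [0, 1].  Biotype profiling
uses Kruskal-Wallis tests for continuous measures, Pearson chi-square for
categorical distributions, and Welch t post-hoc pairwise comparisons with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .deviations import bh_fdr

__all__ = [
    "GroupTestResult",
    "normalized_symptom_index",
    "kruskal_wallis",
    "chi_square_homogeneity",
    "posthoc_pairwise",
]


@dataclass
class GroupTestResult:
    statistic: float
    p: float
    df: float = None
    p_adjusted: float = None
    group_sizes: tuple = None


def normalized_symptom_index(raw, sites) -> pd.DataFrame:
    """Rescale raw scores by the observed maximum of their site.

    Returns a frame with raw, site, normalized columns; a site whose scores
    are all zero (or missing) gets NaN normalized values with a warning.
    Negative raw scores are a data error.
    """
    raw = np.asarray(raw, dtype=float)
    sites = np.asarray(sites)
    if np.any(raw[np.isfinite(raw)] < 0):
        raise ValueError("raw symptom scores must be nonnegative")
    normalized = np.full_like(raw, np.nan)
    for s in np.unique(sites):
        m = sites == s
        vals = raw[m]
        finite = vals[np.isfinite(vals)]
        site_max = finite.max() if finite.size else np.nan
        if not np.isfinite(site_max) or site_max == 0:
            warnings.warn(f"site {s!r}: maximum undefined or zero; normalized is NaN")
            continue
        normalized[m] = vals / site_max
    return pd.DataFrame({"raw": raw, "site": sites, "normalized": normalized})


def kruskal_wallis(*groups) -> GroupTestResult:
    """Rank-based Kruskal-Wallis H with tie correction (chi-square reference)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        # all values identical: H = 0 by definition, p = 1
        return GroupTestResult(0.0, 1.0, df=len(groups) - 1,
                               group_sizes=tuple(len(g) for g in arrays))
    h, p = stats.kruskal(*arrays)
    return GroupTestResult(float(h), float(p), df=len(groups) - 1,
                           group_sizes=tuple(len(g) for g in arrays))


def chi_square_homogeneity(counts) -> GroupTestResult:
    """Pearson chi-square on a biotype x category contingency table.

    Expected cells below 1 trigger a warning (no automatic switch to an
    exact test); a row or column of zeros is an error.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
        raise ValueError("contingency table has an empty row or column")
    chi2, p, dof, expected = stats.chi2_contingency(counts, correction=False)
    if np.any(expected < 1):
        warnings.warn("expected cell count below 1: chi-square approximation is poor")
    return GroupTestResult(float(chi2), float(p), df=float(dof))


def posthoc_pairwise(groups: dict, adjust: str = "bh") -> pd.DataFrame:
    """Welch t-tests for every group pair, BH-adjusted across pairs.

    ``groups`` maps label -> value vector.  Pairs where either group has
    fewer than 3 observations get NaN statistics (flagged, still listed).
    """
    labels = list(groups)
    rows = []
    for a, b in combinations(labels, 2):
        ga = np.asarray(groups[a], dtype=float)
        gb = np.asarray(groups[b], dtype=float)
        if len(ga) < 3 or len(gb) < 3:
            t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_ind(ga, gb, equal_var=False)
        rows.append({"group_a": a, "group_b": b, "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    adj = np.full(len(df), np.nan)
    if ok.any():
        if adjust == "bh":
            adj[ok.to_numpy()] = bh_fdr(df.loc[ok, "p"].to_numpy())
        else:
            raise ValueError("only BH adjustment is supported")
    df["p_adjusted"] = adj
    return df
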