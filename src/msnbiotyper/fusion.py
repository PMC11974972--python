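"""Multimodal fusion of deviation modalities: mCCA followed by joint ICA.

The three hubness deviation modalities (DC, NE, PC Z-score matrices, subjects
x regions) are first aligned by multiset canonical correlation analysis: a
SUMCOR-style iteration maximises the sum of pairwise correlations of the
canonical variates across modalities after per-modality PCA whitening, with
deflation yielding successive components.  The per-modality canonical maps
C_k (components x regions) are then concatenated along the region axis and
unmixed with Infomax ICA into maximally independent joint sources S_k, with
subject-specific mixing coefficients A_k obtained by least-squares
projection of each subject's modality vector onto the source maps.

A component is called joint group-discriminative when Welch two-sample
t-tests on its mixing coefficients separate cases from controls in all
three modalities at p < .05.  The number of components is chosen by the
minimum description length criterion or fixed by the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .normative import DeviationMatrix
from .topology import METRICS

__all__ = [
    "FusionModel",
    "build_stacks",
    "select_n_components",
    "mcca",
    "joint_ica",
    "mixing_coefficients",
    "threshold_sources",
    "component_group_test",
    "component_clinical_correlation",
    "run_fusion",
]


def build_stacks(dev: DeviationMatrix, standardize: bool = True) -> Dict[str, np.ndarray]:
    """Per-metric subject x region matrices, column-centred (unit variance
    by default) — the modality stacks fed to mCCA."""
    stacks = {}
    for m, metric in enumerate(dev.metrics):
        X = dev.Z[:, :, m].astype(float).copy()
        X -= X.mean(axis=0)
        if standardize:
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            X /= sd
        stacks[metric] = X
    return stacks


# ---------------------------------------------------------------------------
# component count


def select_n_components(stacks: Dict[str, np.ndarray], method="mdl") -> int:
    """Number of joint components: MDL (Wax-Kailath/Rissanen) or fixed.

    MDL operates on the eigenspectrum of the concatenated, centred data;
    ``method=('fixed', k)`` or an integer returns k (clipped to the
    achievable rank with a warning).
    """
    X = np.hstack(list(stacks.values()))
    n, D = X.shape
    rank = min(n - 1, D)
    if isinstance(method, int):
        method = ("fixed", method)
    if isinstance(method, (tuple, list)) and method[0] == "fixed":
        k = int(method[1])
        if k > rank:
            warnings.warn(f"requested {k} components exceeds rank {rank}; clipping")
            k = rank
        return k
    if method != "mdl":
        raise ValueError("method must be 'mdl', an int, or ('fixed', k)")
    # centring only: per-column rescaling would break the flat noise
    # eigenspectrum the Rissanen criterion assumes
    Xc = X - X.mean(axis=0)
    ev = np.linalg.svd(Xc, compute_uv=False) ** 2 / max(n - 1, 1)
    ev = np.maximum(ev[:rank], 1e-12)
    p = len(ev)
    mdl = np.empty(p)
    for k in range(p):
        tail = ev[k:]
        geo = np.exp(np.mean(np.log(tail)))
        arith = np.mean(tail)
        mdl[k] = -n * (p - k) * np.log(geo / arith) + 0.5 * k * (2 * p - k + 1) * np.log(n)
    return max(int(np.argmin(mdl)), 1)


# ---------------------------------------------------------------------------
# mCCA (SUMCOR with deflation)


def _whiten(X: np.ndarray, rank: int):
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    keep = min(rank, np.sum(s > 1e-10 * s[0]))
    Y = U[:, :keep] * np.sqrt(X.shape[0] - 1)  # whitened scores, unit column var
    back = (Vt[:keep].T * (s[:keep] / np.sqrt(X.shape[0] - 1)))  # Y @ back.T ≈ X
    return Y, back


def mcca(
    stacks: Dict[str, np.ndarray],
    n_components: int,
    max_iter: int = 200,
    tol: float = 1e-8,
):
    """SUMCOR multiset CCA across the modality stacks.

    Returns ``(D_k, C_k, variates, varexp)``: per-modality transforms in
    the whitened PCA space, component-by-region canonical maps, the shared
    n x n_components canonical variates (averaged across modalities), and
    the fraction of each modality's variance explained by its variates.
    Non-convergence returns the best iterate with a warning.
    """
    names = list(stacks.keys())
    n = stacks[names[0]].shape[0]
    rank = min(n - 1, min(X.shape[1] for X in stacks.values()))
    if n_components > rank:
        warnings.warn("n_components exceeds rank; clipping")
        n_components = rank
    Ys = {}
    backs = {}
    for k in names:
        Y, back = _whiten(stacks[k] - stacks[k].mean(axis=0), rank)
        Ys[k] = Y
        backs[k] = back
    resid = {k: Ys[k].copy() for k in names}
    A = {k: np.zeros((Ys[k].shape[1], n_components)) for k in names}
    V = {k: np.zeros((n, n_components)) for k in names}
    for c in range(n_components):
        # initialise from the dominant direction of the summed residuals
        concat = np.hstack([resid[k] for k in names])
        u0 = np.linalg.svd(concat, full_matrices=False)[0][:, 0]
        v = {k: u0.copy() for k in names}
        last = -np.inf
        for it in range(max_iter):
            for k in names:
                target = np.sum([v[l] for l in names if l != k], axis=0)
                a = resid[k].T @ target
                norm = np.linalg.norm(resid[k] @ a)
                if norm < 1e-12:
                    a = np.zeros_like(a)
                    v[k] = np.zeros(n)
                    continue
                a /= norm / np.sqrt(n - 1)  # unit-variance variate
                v[k] = resid[k] @ a
                A[k][:, c] = a
            obj = 0.0
            for i, k in enumerate(names):
                for l in names[i + 1 :]:
                    denom = np.linalg.norm(v[k]) * np.linalg.norm(v[l])
                    if denom > 0:
                        obj += float(v[k] @ v[l]) / denom
            if abs(obj - last) < tol:
                break
            last = obj
        else:
            warnings.warn(f"mCCA component {c} did not converge; best iterate kept")
        for k in names:
            V[k][:, c] = v[k]
            nv = float(v[k] @ v[k])
            if nv > 0:
                resid[k] = resid[k] - np.outer(v[k], v[k] @ resid[k]) / nv
    C = {}
    varexp = {}
    variates = np.mean([V[k] for k in names], axis=0)
    for k in names:
        X = stacks[k]
        C[k] = V[k].T @ X / (n - 1)  # (components, R) canonical maps
        Vk = V[k]
        coef, *_ = np.linalg.lstsq(Vk, X, rcond=None)
        resid_norm = np.linalg.norm(X - Vk @ coef) ** 2
        varexp[k] = 1.0 - resid_norm / np.linalg.norm(X) ** 2
    return A, C, variates, varexp


# ---------------------------------------------------------------------------
# joint ICA (Infomax)


def _logistic(u):
    return 1.0 / (1.0 + np.exp(-u))


def joint_ica(
    C: Dict[str, np.ndarray],
    seed: int = 0,
    lr: float = 0.01,
    max_iter: int = 2000,
    tol: float = 1e-7,
    n_restarts: int = 5,
):
    """Infomax ICA on the concatenated canonical maps.

    The per-modality maps are concatenated along the region axis (rows =
    components as mixtures, columns = region samples), sphered, and unmixed
    by natural-gradient Infomax with a logistic nonlinearity and annealed
    learning rate.  Deterministic for a fixed seed; up to ``n_restarts``
    reseeded restarts on non-convergence.  Returns ``(W_total, S, trace)``
    with S row-signed so each source's largest-|value| entry is positive.
    """
    names = list(C.keys())
    Xc = np.hstack([C[k] for k in names])  # (n_comp, total_regions)
    n_comp, n_samp = Xc.shape
    Xc = Xc - Xc.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / n_samp
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 1e-12)
    K = evecs @ np.diag(evals**-0.5) @ evecs.T  # symmetric sphering
    Xw = K @ Xc

    best = None
    for restart in range(n_restarts):
        rng = child_rng(seed, f"ica-init-{restart}")
        W = np.linalg.qr(rng.normal(size=(n_comp, n_comp)))[0]
        rate = lr
        trace = []
        converged = False
        for step in range(max_iter):
            U = W @ Xw
            Y = _logistic(U)
            grad = (np.eye(n_comp) + (1.0 - 2.0 * Y) @ U.T / n_samp) @ W
            W_new = W + rate * grad
            delta = np.linalg.norm(W_new - W) / np.linalg.norm(W)
            # log-likelihood of the Infomax model (up to constants)
            ll = float(
                np.log(np.abs(np.linalg.det(W_new)))
                + np.mean(np.sum(np.log(Y * (1 - Y) + 1e-300), axis=0))
            )
            trace.append(ll)
            W = W_new
            if delta > 1.0:
                rate *= 0.5
            elif step and step % 200 == 0:
                rate *= 0.7  # anneal toward a fixed point
            if delta < tol:
                converged = True
                break
        U = W @ Xw
        score = float(np.mean(np.log(_logistic(U) * (1 - _logistic(U)) + 1e-300)))
        if best is None or (converged and not best[0]) or (
            converged == best[0] and score > best[1]
        ):
            best = (converged, score, W, trace)
        if converged:
            break
    converged, _, W, trace = best
    if not converged:
        warnings.warn("Infomax ICA did not fully converge; best restart kept")
    W_total = W @ K
    S = W_total @ Xc
    # deterministic sign: largest-|value| region of each source is positive
    flip = np.sign(S[np.arange(n_comp), np.argmax(np.abs(S), axis=1)])
    flip[flip == 0] = 1.0
    S *= flip[:, None]
    W_total *= flip[:, None]
    bounds = np.cumsum([0] + [C[k].shape[1] for k in names])
    S_k = {k: S[:, bounds[i] : bounds[i + 1]] for i, k in enumerate(names)}
    return W_total, S_k, np.asarray(trace)


def mixing_coefficients(
    stacks: Dict[str, np.ndarray], S_k: Dict[str, np.ndarray], ridge: float = 1e-10
) -> Dict[str, np.ndarray]:
    """Least-squares subject loadings A_k of each modality on its source maps."""
    A = {}
    for k, X in stacks.items():
        S = S_k[k]
        G = S @ S.T
        G = G + ridge * np.trace(G) / max(len(G), 1) * np.eye(len(G))
        A[k] = X @ S.T @ np.linalg.inv(G)
    return A


def threshold_sources(S_k: Dict[str, np.ndarray], z: float = 2.0) -> Dict[str, np.ndarray]:
    """Standardise each source map across regions and zero |Z| < z entries."""
    out = {}
    for k, S in S_k.items():
        sd = S.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            warnings.warn("constant source map: thresholded to all zeros")
        Zm = np.where(sd > 0, (S - S.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1, sd), 0.0)
        out[k] = np.where(np.abs(Zm) >= z, Zm, 0.0)
    return out


def component_group_test(A_k: Dict[str, np.ndarray], labels) -> pd.DataFrame:
    """Welch t-tests on mixing coefficients, cases vs controls, per modality.

    Returns a tidy frame (modality, component, t, p) plus a boolean
    ``joint`` column on component level: True when every modality's test is
    significant at p < .05.
    """
    labels = np.asarray(labels)
    is_case = labels == "case" if labels.dtype.kind in "SU" else labels.astype(bool)
    if is_case.sum() < 3 or (~is_case).sum() < 3:
        warnings.warn("a group has fewer than 3 subjects; t statistics are NaN")
    rows = []
    for k, A in A_k.items():
        for c in range(A.shape[1]):
            if is_case.sum() >= 3 and (~is_case).sum() >= 3:
                t, p = stats.ttest_ind(A[is_case, c], A[~is_case, c], equal_var=False)
            else:
                t, p = np.nan, np.nan
            rows.append({"modality": k, "component": c, "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    joint = df.groupby("component")["p"].apply(lambda p: bool((p < 0.05).all()))
    df["joint"] = df["component"].map(joint)
    return df


def component_clinical_correlation(
    A_k: Dict[str, np.ndarray], symptom: np.ndarray, component: int
) -> pd.DataFrame:
    """Pearson r between a component's mixing coefficients and a symptom index.

    Intended for case subjects only; missing scores are dropped pairwise
    (with a warning above 50% missingness).  Constant input gives NaN.
    """
    symptom = np.asarray(symptom, dtype=float)
    rows = []
    for k, A in A_k.items():
        a = A[:, component]
        ok = np.isfinite(symptom) & np.isfinite(a)
        if ok.mean() < 0.5:
            warnings.warn("more than half of the symptom scores are missing")
        if ok.sum() < 3 or np.ptp(symptom[ok]) == 0 or np.ptp(a[ok]) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(a[ok], symptom[ok])
        rows.append({"modality": k, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# high-level driver


@dataclass
class FusionModel:
    n_components: int
    canonical_transforms: Dict[str, np.ndarray]  # D_k, whitened-space weights
    canonical_maps: Dict[str, np.ndarray]  # C_k (components x regions)
    unmixing: np.ndarray  # W (joint ICA)
    sources: Dict[str, np.ndarray]  # S_k (components x regions)
    mixing: Dict[str, np.ndarray]  # A_k (subjects x components)
    varexp: Dict[str, float]
    ica_trace: np.ndarray = field(default=None, repr=False)


def run_fusion(
    dev: DeviationMatrix,
    n_components="mdl",
    seed: int = 0,
    standardize: bool = True,
) -> FusionModel:
    """mCCA + jICA end to end on a deviation matrix."""
    stacks = build_stacks(dev, standardize=standardize)
    k = select_n_components(stacks, n_components)
    D, C, _, varexp = mcca(stacks, k)
    W, S_k, trace = joint_ica(C, seed=seed)
    A = mixing_coefficients(stacks, S_k)
    return FusionModel(k, D, C, W, S_k, A, varexp, trace)
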