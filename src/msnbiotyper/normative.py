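"""Bayesian linear regression normative models for hubness phenotypes.

For every region-metric feature a normative model is fitted on typically
developing controls: the response is optionally Yeo-Johnson transformed (and
optionally warped with a sinh-arcsinh output warp), regressed on a cubic
B-spline basis of age plus one-hot sex and site columns under a conjugate
Gaussian prior whose precisions are set by evidence (type-II maximum
likelihood).  Held-out subjects are scored as deviation Z-scores

    Z = (t(y) - predictive mean) / sqrt(predictive variance),

where the predictive variance is the noise variance plus the design-projected
posterior weight uncertainty.  Fit quality is summarised per region-metric by
explained variance (EV), standardized mean squared error (SMSE) and mean
standardized log-loss (MSLL).  Models transfer to unseen sites by
re-estimating a site mean offset and variance scale on a small adaptation
sample while keeping the reference posterior fixed.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from sklearn.linear_model import BayesianRidge
from sklearn.metrics import balanced_accuracy_score
from sklearn.svm import LinearSVC

from ._rng import child_rng, child_seed
from .topology import METRICS, HubnessProfile

__all__ = [
    "DesignSpec",
    "BLRFit",
    "NormativeModelSet",
    "DeviationMatrix",
    "FitMetrics",
    "yeo_johnson",
    "split_cohort",
    "fit_blr",
    "predict",
    "deviation_z",
    "evaluate",
    "fit_normative_models",
    "score_deviations",
    "crossval_control_deviations",
    "transfer_recalibrate",
    "site_predictability_check",
    "exclude_outliers",
]

OUTLIER_Z = 7.0


# ---------------------------------------------------------------------------
# design


@dataclass
class DesignSpec:
    """Covariate design: cubic age B-spline + one-hot sex and site.

    Interior knots sit at quantiles of the training ages; boundary knots are
    extended by ``margin`` years so mildly out-of-range test ages remain
    representable.  The spline basis sums to one and therefore doubles as
    the intercept; the first site is the reference level (all site columns
    zero).
    """

    knots: np.ndarray = None
    degree: int = 3
    n_interior_knots: int = 5
    margin: float = 0.5
    site_levels: Sequence[int] = None

    def fit(self, cov: pd.DataFrame) -> "DesignSpec":
        ages = cov["age"].to_numpy(dtype=float)
        lo, hi = ages.min() - self.margin, ages.max() + self.margin
        qs = np.linspace(0, 1, self.n_interior_knots + 2)[1:-1]
        interior = np.quantile(ages, qs)
        self.knots = np.r_[[lo] * (self.degree + 1), interior, [hi] * (self.degree + 1)]
        self.site_levels = sorted(int(s) for s in cov["site"].unique())
        return self

    def matrix(self, cov: pd.DataFrame) -> np.ndarray:
        if self.knots is None:
            raise ValueError("DesignSpec must be fitted before use")
        ages = np.clip(
            cov["age"].to_numpy(dtype=float), self.knots[0] + 1e-9, self.knots[-1] - 1e-9
        )
        B = BSpline.design_matrix(ages, self.knots, self.degree).toarray()
        sex = cov["sex"].to_numpy(dtype=float)[:, None]
        site = cov["site"].to_numpy(dtype=int)
        site_cols = np.column_stack(
            [(site == lvl).astype(float) for lvl in self.site_levels[1:]]
        ) if len(self.site_levels) > 1 else np.empty((len(cov), 0))
        return np.hstack([B, sex, site_cols])


# ---------------------------------------------------------------------------
# transforms


def yeo_johnson(values: np.ndarray, lmbda: Optional[float] = None):
    """Yeo-Johnson transform; lambda by maximum likelihood when not given.

    Constant input leaves the data untouched (identity, lambda = 1) with a
    warning, since the likelihood is flat.
    """
    values = np.asarray(values, dtype=float)
    if lmbda is None:
        if np.ptp(values) == 0:
            warnings.warn("constant input: Yeo-Johnson lambda undefined, using identity")
            return values.copy(), 1.0
        transformed, lmbda = stats.yeojohnson(values)
        return transformed, float(lmbda)
    return stats.yeojohnson(values, lmbda=lmbda), float(lmbda)


def _sinh_arcsinh(y, eps, delta):
    return np.sinh(delta * np.arcsinh(y) - eps)


def _sinh_arcsinh_logjac(y, eps, delta):
    # d/dy sinh(delta*asinh(y) - eps) = cosh(delta*asinh(y)-eps) * delta/sqrt(1+y^2)
    u = delta * np.arcsinh(y) - eps
    return np.log(np.cosh(u)) + np.log(delta) - 0.5 * np.log1p(y**2)


# ---------------------------------------------------------------------------
# single-feature Bayesian linear regression


@dataclass
class BLRFit:
    """Posterior of one region-metric normative regression."""

    region: str = ""
    metric: str = ""
    weights: np.ndarray = None  # posterior mean
    weight_cov: np.ndarray = None  # posterior covariance
    noise_precision: float = 1.0
    prior_precision: float = 1.0
    yeo_johnson_lambda: Optional[float] = None
    warp: str = "none"
    warp_params: Optional[tuple] = None  # (eps, delta)
    train_mean: float = 0.0  # moments of the transformed training response
    train_var: float = 1.0
    n_train: int = 0
    site_offset: float = 0.0  # transfer recalibration
    site_scale: float = 1.0

    def transform(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.yeo_johnson_lambda is not None:
            y = stats.yeojohnson(y, lmbda=self.yeo_johnson_lambda)
        if self.warp == "sinh-arcsinh" and self.warp_params is not None:
            y = _sinh_arcsinh(y, *self.warp_params)
        return y


def fit_blr(
    y: np.ndarray,
    X: np.ndarray,
    prior_precision: Optional[float] = None,
    warp: str = "none",
) -> BLRFit:
    """Conjugate Gaussian BLR with evidence-optimised precisions.

    With ``prior_precision=None`` both the weight and noise precisions are
    set by type-II maximum likelihood (evidence maximisation); a fixed
    ``prior_precision`` switches to a closed-form ridge posterior with the
    noise precision estimated from the residuals.  ``warp='sinh-arcsinh'``
    fits a two-parameter output warp by marginal-likelihood ascent and falls
    back to no warp when the optimiser fails to improve on it.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    fit = _fit_blr_gaussian(y, X, prior_precision)
    if warp == "sinh-arcsinh":
        warped = _fit_warp(y, X, prior_precision)
        if warped is not None:
            return warped
    return fit


def _fit_blr_gaussian(y, X, prior_precision) -> BLRFit:
    n, d = X.shape
    if prior_precision is None:
        model = BayesianRidge(fit_intercept=False, tol=1e-6, max_iter=500)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        w = model.coef_
        cov = model.sigma_
        alpha = float(model.alpha_)
        lam = float(model.lambda_)
    else:
        lam = float(prior_precision)
        resid_var = None
        # two-pass: noise precision from regularized residuals
        alpha = 1.0
        for _ in range(20):
            A = alpha * X.T @ X + lam * np.eye(d)
            cov = np.linalg.inv(A)
            w = alpha * cov @ X.T @ y
            resid = y - X @ w
            resid_var = float(resid @ resid) / max(n - 1, 1)
            new_alpha = 1.0 / max(resid_var, 1e-12)
            if abs(new_alpha - alpha) < 1e-9 * alpha:
                alpha = new_alpha
                break
            alpha = new_alpha
        A = alpha * X.T @ X + lam * np.eye(d)
        cov = np.linalg.inv(A)
        w = alpha * cov @ X.T @ y
    return BLRFit(
        weights=np.asarray(w, dtype=float),
        weight_cov=np.asarray(cov, dtype=float),
        noise_precision=alpha,
        prior_precision=lam,
        train_mean=float(y.mean()),
        train_var=float(y.var(ddof=1)) if n > 1 else 1.0,
        n_train=n,
    )


def _fit_warp(y, X, prior_precision):
    """Sinh-arcsinh output warp by (approximate) marginal-likelihood ascent."""

    ys = (y - y.mean()) / (y.std() + 1e-12)

    def negloglik(params):
        eps, logdelta = params
        delta = np.exp(logdelta)
        z = _sinh_arcsinh(ys, eps, delta)
        if not np.all(np.isfinite(z)):
            return 1e12
        f = _fit_blr_gaussian(z, X, prior_precision)
        mean, var = predict(f, X)
        ll = -0.5 * np.log(2 * np.pi * var) - (z - mean) ** 2 / (2 * var)
        ll = ll + _sinh_arcsinh_logjac(ys, eps, delta)
        return -float(ll.sum())

    try:
        res = minimize(
            negloglik, x0=[0.0, 0.0], method="Nelder-Mead",
            options={"maxiter": 80, "xatol": 1e-3, "fatol": 1e-3},
        )
        base = negloglik([0.0, 0.0])
        if not res.success or res.fun >= base - 1e-6:
            return None
        eps, delta = res.x[0], float(np.exp(res.x[1]))
        z = _sinh_arcsinh(ys, eps, delta)
        fit = _fit_blr_gaussian(z, X, prior_precision)
        fit.warp = "sinh-arcsinh"
        # store the standardisation inside the warp by composing transforms
        fit.warp_params = (eps, delta)
        fit._warp_standardize = (float(y.mean()), float(y.std() + 1e-12))
        return fit
    except Exception:
        return None


def predict(fit: BLRFit, X_new: np.ndarray):
    """Posterior predictive mean and variance (noise + weight uncertainty)."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != fit.weights.shape[0]:
        raise ValueError("design matrix columns do not match the fitted model")
    mean = X_new @ fit.weights
    var = 1.0 / fit.noise_precision + np.einsum(
        "ij,jk,ik->i", X_new, fit.weight_cov, X_new
    )
    return mean, var


def deviation_z(fit: BLRFit, y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Z = (t(y) - predictive mean - site offset) / (site scale * sqrt(var))."""
    yt = _apply_transform(fit, y)
    mean, var = predict(fit, X)
    return (yt - mean - fit.site_offset) / (fit.site_scale * np.sqrt(var))


def _apply_transform(fit: BLRFit, y):
    y = np.asarray(y, dtype=float)
    if fit.yeo_johnson_lambda is not None:
        y = stats.yeojohnson(y, lmbda=fit.yeo_johnson_lambda)
    if fit.warp == "sinh-arcsinh" and fit.warp_params is not None:
        mu, sd = getattr(fit, "_warp_standardize", (0.0, 1.0))
        y = _sinh_arcsinh((y - mu) / sd, *fit.warp_params)
    return y


@dataclass
class FitMetrics:
    explained_variance: float
    smse: float
    msll: float


def evaluate(fit: BLRFit, y_test: np.ndarray, X_test: np.ndarray) -> FitMetrics:
    """EV, SMSE and MSLL of a fitted model on held-out data.

    EV = 1 - var(residual)/var(y); SMSE = MSE / mean squared deviation of
    y_test about the training mean; MSLL = mean negative predictive
    log-density minus that of the trivial Gaussian with training moments.
    All in the transformed response space.
    """
    yt = _apply_transform(fit, y_test)
    mean, var = predict(fit, X_test)
    resid = yt - mean
    vy = float(np.var(yt))
    if vy == 0:
        return FitMetrics(np.nan, np.nan, np.nan)
    ev = 1.0 - float(np.var(resid)) / vy
    smse = float(np.mean(resid**2)) / float(np.mean((yt - fit.train_mean) ** 2))
    nll_model = 0.5 * np.log(2 * np.pi * var) + resid**2 / (2 * var)
    nll_trivial = 0.5 * np.log(2 * np.pi * fit.train_var) + (
        (yt - fit.train_mean) ** 2
    ) / (2 * fit.train_var)
    msll = float(np.mean(nll_model - nll_trivial))
    return FitMetrics(ev, smse, msll)


# ---------------------------------------------------------------------------
# cohort-level API


@dataclass
class DeviationMatrix:
    """Subject x region x metric deviation Z-scores."""

    subject_ids: Sequence[str]
    region_ids: Sequence[str]
    Z: np.ndarray  # (n, R, M)
    metrics: Sequence[str] = field(default=METRICS)
    split_tag: str = "test"

    def matrix(self) -> np.ndarray:
        return self.Z.reshape(self.Z.shape[0], -1)

    def to_long(self) -> pd.DataFrame:
        n, R, M = self.Z.shape
        return pd.DataFrame(
            {
                "subject_id": np.repeat(list(self.subject_ids), R * M),
                "region": np.tile(np.repeat(list(self.region_ids), M), n),
                "metric": np.tile(list(self.metrics), n * R),
                "z": self.Z.ravel(),
                "split": self.split_tag,
            }
        )


@dataclass
class NormativeModelSet:
    design: DesignSpec
    fits: dict  # (region_index, metric_index) -> BLRFit
    region_ids: Sequence[str]
    metrics: Sequence[str] = METRICS


def split_cohort(cov: pd.DataFrame, train_frac: float = 0.9, seed: int = 0):
    """Per-site stratified control split; cases always go to the test set."""
    rng = child_rng(seed, "split-cohort")
    train_ids, test_ids = [], []
    cases = cov[cov["group"] == "case"]
    test_ids.extend(cases["subject_id"].tolist())
    for _, site_df in cov[cov["group"] == "control"].groupby("site"):
        ids = site_df["subject_id"].to_numpy()
        if len(ids) < 2:
            warnings.warn("site with <2 controls: all allocated to training")
            train_ids.extend(ids.tolist())
            continue
        perm = rng.permutation(len(ids))
        n_train = int(round(train_frac * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train_ids.extend(ids[perm[:n_train]].tolist())
        test_ids.extend(ids[perm[n_train:]].tolist())
    return train_ids, test_ids


def _subset(profile: HubnessProfile, cov: pd.DataFrame, ids):
    order = {s: i for i, s in enumerate(profile.subject_ids)}
    idx = [order[s] for s in ids]
    sub_cov = cov.set_index("subject_id").loc[ids].reset_index()
    return profile.values[idx], sub_cov


def fit_normative_models(
    profile: HubnessProfile,
    cov: pd.DataFrame,
    train_ids,
    use_yeo_johnson: bool = True,
    warp: str = "none",
    prior_precision: Optional[float] = None,
    outlier_pass: str = "off",
) -> NormativeModelSet:
    """Fit one BLR per region-metric on the training controls.

    ``outlier_pass='post'`` performs one initial fit, drops training
    subjects with any |Z| > 7, and refits on the retained subjects.
    """
    y_train, cov_train = _subset(profile, cov, train_ids)
    design = DesignSpec().fit(cov_train)
    modelset = _fit_all(y_train, cov_train, design, use_yeo_johnson, warp,
                        prior_precision, profile)
    if outlier_pass == "post":
        Z = _score(modelset, y_train, cov_train)
        keep = np.all(np.abs(Z.reshape(len(Z), -1)) <= OUTLIER_Z, axis=1)
        if not keep.all() and keep.sum() >= 10:
            modelset = _fit_all(
                y_train[keep], cov_train[keep].reset_index(drop=True), design,
                use_yeo_johnson, warp, prior_precision, profile,
            )
    return modelset


def _fit_all(y_train, cov_train, design, use_yeo_johnson, warp, prior_precision,
             profile):
    X = design.matrix(cov_train)
    fits = {}
    for r in range(y_train.shape[1]):
        for m, metric in enumerate(profile.metrics):
            y = y_train[:, r, m]
            if use_yeo_johnson:
                yt, lam = yeo_johnson(y)
            else:
                yt, lam = y, None
            fit = fit_blr(yt, X, prior_precision=prior_precision, warp=warp)
            fit.region = profile.region_ids[r]
            fit.metric = metric
            fit.yeo_johnson_lambda = lam
            fits[(r, m)] = fit
    return NormativeModelSet(design, fits, list(profile.region_ids), profile.metrics)


def _score(modelset: NormativeModelSet, values, cov) -> np.ndarray:
    X = modelset.design.matrix(cov)
    n, R, M = values.shape
    Z = np.empty((n, R, M))
    for (r, m), fit in modelset.fits.items():
        yt = _apply_transform(fit, values[:, r, m])
        mean, var = predict(fit, X)
        Z[:, r, m] = (yt - mean - fit.site_offset) / (fit.site_scale * np.sqrt(var))
    return Z


def score_deviations(
    modelset: NormativeModelSet,
    profile: HubnessProfile,
    cov: pd.DataFrame,
    ids=None,
    split_tag: str = "test",
) -> DeviationMatrix:
    ids = list(ids) if ids is not None else list(profile.subject_ids)
    values, sub_cov = _subset(profile, cov, ids)
    Z = _score(modelset, values, sub_cov)
    return DeviationMatrix(ids, list(profile.region_ids), Z, profile.metrics, split_tag)


def exclude_outliers(dev: DeviationMatrix, threshold: float = OUTLIER_Z):
    """Drop subjects with any |Z| above threshold; returns (retained, mask)."""
    keep = np.all(np.abs(dev.matrix()) <= threshold, axis=1)
    retained = DeviationMatrix(
        [s for s, k in zip(dev.subject_ids, keep) if k],
        list(dev.region_ids),
        dev.Z[keep],
        dev.metrics,
        dev.split_tag,
    )
    return retained, keep


def crossval_control_deviations(
    profile: HubnessProfile,
    cov: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    use_yeo_johnson: bool = True,
) -> DeviationMatrix:
    """Score every control with a model not trained on it (site-stratified CV)."""
    controls = cov[cov["group"] == "control"].reset_index(drop=True)
    n = len(controls)
    if k > n:
        raise ValueError("more folds than control subjects")
    rng = child_rng(seed, "cv-folds")
    fold = np.empty(n, dtype=int)
    for _, site_df in controls.groupby("site"):
        idx = site_df.index.to_numpy()
        perm = rng.permutation(len(idx))
        fold[idx[perm]] = np.arange(len(idx)) % k
    ids = controls["subject_id"].to_numpy()
    order = {s: i for i, s in enumerate(profile.subject_ids)}
    R, M = len(profile.region_ids), len(profile.metrics)
    Z = np.full((n, R, M), np.nan)
    for f in range(k):
        train_ids = ids[fold != f]
        test_ids = ids[fold == f]
        if len(test_ids) == 0:
            continue
        modelset = fit_normative_models(
            profile, cov, list(train_ids), use_yeo_johnson=use_yeo_johnson
        )
        dev = score_deviations(modelset, profile, cov, list(test_ids), f"cv-{f}")
        for i, sid in enumerate(test_ids):
            Z[np.flatnonzero(ids == sid)[0]] = dev.Z[i]
    return DeviationMatrix(list(ids), list(profile.region_ids), Z, profile.metrics, "cv")


def transfer_recalibrate(fit: BLRFit, y_adapt, X_adapt) -> BLRFit:
    """Recalibrate a reference fit to a new site from adaptation controls.

    The reference posterior is held fixed; a site mean offset and variance
    scale are estimated in the transformed Gaussian space from the
    adaptation residuals.  Fewer than 10 adaptation controls triggers a
    warning but the estimate proceeds.
    """
    y_adapt = np.asarray(y_adapt, dtype=float)
    if y_adapt.size < 10:
        warnings.warn("fewer than 10 adaptation controls: recalibration is noisy")
    yt = _apply_transform(fit, y_adapt)
    mean, var = predict(fit, X_adapt)
    resid = yt - mean
    offset = float(resid.mean())
    scale = float(np.sqrt(np.mean((resid - offset) ** 2 / var)))
    out = copy.copy(fit)
    out.site_offset = fit.site_offset + offset
    out.site_scale = max(scale, 1e-6)
    out.offset_se = float(np.sqrt(np.mean(var)) * out.site_scale / np.sqrt(y_adapt.size))
    return out


def site_predictability_check(dev: DeviationMatrix, sites, seed: int = 0) -> float:
    """Mean 2-fold balanced accuracy of a linear SVM predicting site from Z.

    One-vs-one over site pairs; chance level 0.5 indicates residual site
    information has been removed.  Returns NaN for a single site.
    """
    sites = np.asarray(sites)
    levels = np.unique(sites)
    if len(levels) < 2:
        return float("nan")
    X = dev.matrix()
    rng = child_rng(seed, "site-check")
    accs = []
    for a in range(len(levels)):
        for b in range(a + 1, len(levels)):
            mask = (sites == levels[a]) | (sites == levels[b])
            Xp, yp = X[mask], (sites[mask] == levels[b]).astype(int)
            if len(np.unique(yp)) < 2:
                continue
            perm = rng.permutation(len(yp))
            half = len(yp) // 2
            folds = [(perm[:half], perm[half:]), (perm[half:], perm[:half])]
            for tr, te in folds:
                if len(np.unique(yp[tr])) < 2:
                    continue
                clf = LinearSVC(C=1.0, dual=True, max_iter=5000,
                                random_state=child_seed(seed, "svc"))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(Xp[tr], yp[tr])
                accs.append(balanced_accuracy_score(yp[te], clf.predict(Xp[te])))
    return float(np.mean(accs)) if accs else float("nan")
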