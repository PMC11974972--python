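"""Synthetic cohorts with planted ground truth.

The generators in this module emulate the structure of a multisite
case-control neurodevelopmental study so that every downstream stage —
similarity networks, hubness, normative modelling, fusion, biotyping and
spatial decoding — can be exercised against a known answer:

* covariate tables with age, sex, site and symptom scores;
* control hubness features following smooth age trends with sex and site
  offsets plus heteroscedastic Gaussian noise (the normative family);
* k planted case biotypes, each shifting a chosen region set by a chosen
  number of control standard deviations per metric;
* regional voxel samples with a block (module) covariance so the resulting
  MSNs are modular;
* spatially autocorrelated annotation maps with a controlled population
  correlation to a target map;
* three-modality deviation stacks carrying one shared (joint) component
  whose subject loadings differ between cases and controls.

All randomness flows through labelled child streams of a single root seed
(see :mod:`msnbiotyper._rng`), so outputs are bit-identical for identical
seeds and specifications.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .topology import METRICS, HubnessProfile
from .msn import RegionalMorphometry

__all__ = [
    "CohortSpec",
    "BiotypePlan",
    "GroundTruth",
    "generate_covariates",
    "generate_control_hubness",
    "plant_biotypes",
    "symptom_scores_for_biotypes",
    "generate_regional_samples",
    "generate_centroids",
    "generate_annotation_maps",
    "generate_fusion_stacks",
]

SYMPTOM_DOMAINS = ("inattention", "hyperimpulsivity")


@dataclass
class CohortSpec:
    n_cases: int
    n_controls: int
    n_sites: int = 3
    age_range: tuple = (7.0, 14.0)
    sex_ratio: float = 0.7  # proportion male (sex=1)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cases", "n_controls", "n_sites"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a nonnegative finite count")
        lo, hi = self.age_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("age_range must be finite with low < high")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if self.n_sites < 1:
            raise ValueError("need at least one site")


@dataclass
class BiotypePlan:
    """Ground-truth biotype structure planted into case subjects."""

    k_true: int
    affected_regions: Sequence[Sequence[int]]  # per biotype
    effect_sizes: np.ndarray  # (k_true, n_metrics) signed shifts in control-SD units
    assignment_probs: Optional[np.ndarray] = None
    symptom_means: Optional[np.ndarray] = None  # (k_true, 2) on the 0-1 scale
    symptom_sd: float = 0.12

    def __post_init__(self):
        self.effect_sizes = np.atleast_2d(np.asarray(self.effect_sizes, dtype=float))
        if self.effect_sizes.shape[0] != self.k_true:
            raise ValueError("effect_sizes must have one row per biotype")
        if self.assignment_probs is None:
            self.assignment_probs = np.full(self.k_true, 1.0 / self.k_true)
        self.assignment_probs = np.asarray(self.assignment_probs, dtype=float)
        if not np.isclose(self.assignment_probs.sum(), 1.0):
            raise ValueError("assignment_probs must sum to 1")
        if self.symptom_means is None:
            # evenly spaced severity profiles, opposite ordering per domain
            base = np.linspace(0.35, 0.75, self.k_true)
            self.symptom_means = np.column_stack([base, base[::-1]])
        self.symptom_means = np.asarray(self.symptom_means, dtype=float)


@dataclass
class GroundTruth:
    """Everything the generators planted, for recovery tests."""

    age_coefficients: np.ndarray = None  # (R, M, 4) cubic polynomial coeffs
    sex_offsets: np.ndarray = None  # (R, M)
    site_offsets: np.ndarray = None  # (n_sites, R, M)
    noise_sd: np.ndarray = None  # (M,)
    age_range: tuple = None
    biotype_labels: Optional[np.ndarray] = None  # per-case, 1-based
    affected_regions: Optional[list] = None
    effect_sizes: Optional[np.ndarray] = None
    planted_component_map: Optional[np.ndarray] = None
    planted_loadings: Optional[np.ndarray] = None
    planted_term_index: Optional[int] = None

    def mean_function(self, region: int, metric: int, age, sex=0, site=0):
        """Evaluate the generating mean response at the given covariates."""
        a = _standardize_age(np.asarray(age, dtype=float), self.age_range)
        c = self.age_coefficients[region, metric]
        out = c[0] + c[1] * a + c[2] * a**2 + c[3] * a**3
        out = out + np.asarray(sex) * self.sex_offsets[region, metric]
        return out + self.site_offsets[np.asarray(site, dtype=int), region, metric]

    def to_json(self, path) -> None:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        with open(path, "w") as fh:
            json.dump({k: conv(v) for k, v in self.__dict__.items()}, fh, indent=1)


def _standardize_age(age, age_range):
    lo, hi = age_range
    return (2.0 * (age - lo) / (hi - lo)) - 1.0


def generate_covariates(spec: CohortSpec) -> pd.DataFrame:
    """Covariate table: id, group, age, sex, site, symptom placeholders.

    Sites are assigned round-robin over a randomly permuted subject order
    (jitter), ages are uniform over the age range, and sex is Bernoulli with
    the requested male fraction.  Symptom scores start as 0 for cases and
    missing for controls; :func:`plant_biotypes` overwrites the case scores
    with biotype-dependent values.
    """
    rng = child_rng(spec.seed, "covariates")
    n = spec.n_cases + spec.n_controls
    group = np.array(["case"] * spec.n_cases + ["control"] * spec.n_controls)
    age = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
    sex = (rng.uniform(size=n) < spec.sex_ratio).astype(int)
    site = np.tile(np.arange(spec.n_sites), n // spec.n_sites + 1)[:n]
    site = site[rng.permutation(n)]
    df = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:05d}" for i in range(n)],
            "group": group,
            "age": age,
            "sex": sex,
            "site": site,
            "inattention": np.where(group == "case", 0.0, np.nan),
            "hyperimpulsivity": np.where(group == "case", 0.0, np.nan),
        }
    )
    return df


def generate_control_hubness(
    cov: pd.DataFrame,
    R: int,
    noise_sd=0.25,
    seed: int = 0,
) -> tuple:
    """Normative-family hubness features for every subject in ``cov``.

    Each region-metric response is a smooth cubic-in-age trend (monotone by
    construction: the linear coefficient dominates the curvature terms) plus
    a sex offset, a per-site offset drawn once from N(0, 0.5 * noise_sd),
    and Gaussian noise with per-metric standard deviation ``noise_sd``.

    Returns ``(HubnessProfile, GroundTruth)`` with the generating functions
    recorded for recovery tests.
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    noise = np.broadcast_to(np.asarray(noise_sd, dtype=float), (len(METRICS),)).copy()
    if np.any(noise <= 0) or not np.all(np.isfinite(noise)):
        raise ValueError("noise_sd must be positive and finite")
    rng = child_rng(seed, "control-hubness")
    M = len(METRICS)
    coeffs = np.empty((R, M, 4))
    coeffs[..., 0] = rng.normal(0.0, 1.0, size=(R, M))
    coeffs[..., 1] = rng.uniform(0.3, 0.8, size=(R, M))
    coeffs[..., 2] = rng.uniform(-0.05, 0.05, size=(R, M))
    coeffs[..., 3] = rng.uniform(-0.05, 0.05, size=(R, M))
    sex_off = rng.normal(0.0, 0.3, size=(R, M))
    n_sites = int(cov["site"].max()) + 1
    site_off = rng.normal(0.0, 0.5 * noise[None, None, :], size=(n_sites, R, M))

    ages = cov["age"].to_numpy(dtype=float)
    lo, hi = float(ages.min()), float(ages.max())
    age_range = (lo - 1e-9, hi + 1e-9) if lo < hi else (lo - 0.5, lo + 0.5)
    a = _standardize_age(ages, age_range)[:, None, None]
    mean = (
        coeffs[None, :, :, 0]
        + coeffs[None, :, :, 1] * a
        + coeffs[None, :, :, 2] * a**2
        + coeffs[None, :, :, 3] * a**3
    )
    mean = mean + cov["sex"].to_numpy()[:, None, None] * sex_off[None]
    mean = mean + site_off[cov["site"].to_numpy(dtype=int)]
    values = mean + rng.normal(0.0, noise[None, None, :], size=mean.shape)
    profile = HubnessProfile(
        list(cov["subject_id"]), [f"region_{i:03d}" for i in range(R)], values
    )
    truth = GroundTruth(
        age_coefficients=coeffs,
        sex_offsets=sex_off,
        site_offsets=site_off,
        noise_sd=noise,
        age_range=age_range,
    )
    return profile, truth


def plant_biotypes(
    features: HubnessProfile,
    cov: pd.DataFrame,
    plan: BiotypePlan,
    seed: int = 0,
    truth: Optional[GroundTruth] = None,
) -> tuple:
    """Shift case subjects on each biotype's affected regions; controls untouched.

    Effect sizes are expressed in control standard deviations of each
    region-metric feature.  Returns a new ``(HubnessProfile, GroundTruth)``;
    biotype labels are 1-based, defined only for case rows.
    """
    case_mask = (cov["group"] == "case").to_numpy()
    n_cases = int(case_mask.sum())
    if n_cases == 0:
        raise ValueError("biotype plan requires at least one case subject")
    rng = child_rng(seed, "plant-biotypes")
    labels = rng.choice(plan.k_true, size=n_cases, p=plan.assignment_probs) + 1
    ctrl_sd = features.values[~case_mask].std(axis=0, ddof=1)  # (R, M)
    values = features.values.copy()
    case_idx = np.flatnonzero(case_mask)
    for b in range(plan.k_true):
        rows = case_idx[labels == b + 1]
        regions = np.asarray(plan.affected_regions[b], dtype=int)
        if regions.size and np.any(regions >= features.values.shape[1]):
            raise ValueError("affected region index out of range")
        if rows.size == 0 or regions.size == 0:
            continue
        for m in range(len(features.metrics)):
            values[rows[:, None], regions[None, :], m] += (
                plan.effect_sizes[b, m] * ctrl_sd[regions, m]
            )
    out = HubnessProfile(
        list(features.subject_ids), list(features.region_ids), values, features.metrics
    )
    truth = truth or GroundTruth()
    truth.biotype_labels = labels
    truth.affected_regions = [list(map(int, r)) for r in plan.affected_regions]
    truth.effect_sizes = plan.effect_sizes
    return out, truth


def symptom_scores_for_biotypes(
    cov: pd.DataFrame, labels: np.ndarray, plan: BiotypePlan, seed: int = 0
) -> pd.DataFrame:
    """Biotype-dependent symptom scores for cases, truncated to [0, 1]."""
    rng = child_rng(seed, "symptoms")
    out = cov.copy()
    case_idx = np.flatnonzero((cov["group"] == "case").to_numpy())
    for d, domain in enumerate(SYMPTOM_DOMAINS):
        means = plan.symptom_means[labels - 1, d]
        scores = np.clip(rng.normal(means, plan.symptom_sd), 0.0, 1.0)
        col = out[domain].to_numpy(dtype=float)
        col[case_idx] = scores
        out[domain] = col
    return out


def generate_regional_samples(
    cov: pd.DataFrame,
    R: int,
    n_voxels_per_region: int = 50,
    module_partition: Optional[np.ndarray] = None,
    within_block_corr: float = 0.6,
    mean_spread: float = 1.0,
    voxel_sd: float = 0.5,
    seed: int = 0,
) -> list:
    """Per-subject regional voxel samples with a block (module) covariance.

    For each subject, region r's mean is sqrt(c) * b_{block(r)} +
    sqrt(1 - c) * e_r with independent standard-normal block and region
    effects scaled by ``mean_spread`` (c = ``within_block_corr``); the
    region's ``n_voxels_per_region`` values are then drawn around that mean
    with ``voxel_sd``.  Same-block regions therefore have more similar value
    distributions, which induces modular structure in the downstream MSNs.
    """
    if not 0.0 <= within_block_corr < 1.0:
        raise ValueError("within_block_corr must lie in [0, 1)")
    if module_partition is None:
        module_partition = np.arange(R) * 3 // R  # three contiguous blocks
    module_partition = np.asarray(module_partition, dtype=int)
    n_blocks = int(module_partition.max()) + 1
    rng = child_rng(seed, "regional-samples")
    c = within_block_corr
    out = []
    for sid in cov["subject_id"]:
        b = rng.normal(0.0, 1.0, size=n_blocks)
        e = rng.normal(0.0, 1.0, size=R)
        means = mean_spread * (np.sqrt(c) * b[module_partition] + np.sqrt(1 - c) * e)
        vox = rng.normal(means[:, None], voxel_sd, size=(R, n_voxels_per_region))
        out.append(RegionalMorphometry(str(sid), list(vox)))
    return out


def generate_centroids(R: int, n_subcortical: int = 0, seed: int = 0) -> tuple:
    """Random parcel centroids: cortical points on a 70 mm sphere split into
    hemispheres by the sign of x, plus optional subcortical points near the
    origin.  Returns (centroids (R, 3) in mm, cortical_mask (R,))."""
    rng = child_rng(seed, "centroids")
    n_cort = R - n_subcortical
    pts = rng.normal(size=(n_cort, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= 70.0
    sub = rng.normal(0.0, 12.0, size=(n_subcortical, 3))
    centroids = np.vstack([pts, sub])
    mask = np.zeros(R, dtype=bool)
    mask[:n_cort] = True
    return centroids, mask


def generate_annotation_maps(
    target: np.ndarray,
    rho: float,
    n_maps: int,
    smoothness: float,
    centroids: np.ndarray,
    seed: int = 0,
    names: Optional[Sequence[str]] = None,
):
    """Spatially autocorrelated maps with population correlation rho to target.

    Each map is a zero-mean Gaussian field over the centroids with a
    squared-exponential kernel of length-scale ``smoothness`` (mm),
    standardised and mixed with the standardised target as
    rho * z(target) + sqrt(1 - rho^2) * z(field).
    """
    from .decoding import AnnotationMaps  # local import avoids a cycle

    if abs(rho) > 1:
        raise ValueError("|rho| must not exceed 1")
    target = np.asarray(target, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    R = target.size
    rng = child_rng(seed, "annotation-maps")
    d2 = ((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
    if smoothness > 0:
        K = np.exp(-0.5 * d2 / smoothness**2) + 1e-8 * np.eye(R)
    else:
        K = np.eye(R)
    L = np.linalg.cholesky(K)
    if target.std() > 0:
        zt = (target - target.mean()) / target.std()
    elif rho != 0:
        raise ValueError("constant target map with nonzero rho")
    else:
        zt = np.zeros(R)
    maps = np.empty((n_maps, R))
    for i in range(n_maps):
        f = L @ rng.normal(size=R)
        zf = (f - f.mean()) / f.std()
        maps[i] = rho * zt + np.sqrt(1.0 - rho**2) * zf
    if names is None:
        names = [f"map_{i:02d}" for i in range(n_maps)]
    return AnnotationMaps(
        names=list(names),
        M=maps,
        centroids=centroids,
        cortical_mask=np.ones(R, dtype=bool),
    )


def generate_fusion_stacks(
    n_cases: int,
    n_controls: int,
    R: int = 90,
    loading_shift: float = 0.8,
    map_scale: float = 1.5,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple:
    """Three deviation modalities sharing one planted joint component.

    Every modality k gets X_k = u * v_k^T * map_scale + noise where the
    subject loading u is standard normal shifted by ``loading_shift`` SD for
    cases and v_k is a unit-norm modality-specific spatial map.  Returns
    ``(stacks, labels, truth)`` with stacks a dict metric -> (n, R) array,
    labels 1 for cases / 0 for controls, and the planted maps and loadings
    in ``truth``.
    """
    rng = child_rng(seed, "fusion-stacks")
    n = n_cases + n_controls
    labels = np.r_[np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)]
    u = rng.normal(size=n) + loading_shift * labels
    maps = rng.normal(size=(3, R))
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    stacks = {}
    for k, metric in enumerate(METRICS):
        X = map_scale * np.outer(u, maps[k]) + rng.normal(0.0, noise_sd, size=(n, R))
        stacks[metric] = X
    truth = GroundTruth(planted_component_map=maps, planted_loadings=u)
    return stacks, labels, truth


def write_covariates_tsv(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t", index=False)


def read_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
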