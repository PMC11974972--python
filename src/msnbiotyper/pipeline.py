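"""End-to-end orchestration of the synthetic biotyping study.

One JSON-serialisable configuration drives the full flow: simulate a cohort
(regional voxel samples or direct hubness features), build per-subject
similarity networks, compute hubness AUC profiles, plant case biotypes, fit
normative models on controls and score deviations, map extreme deviations
with permutation tests, fuse the modalities (mCCA + jICA), cluster cases
into biotypes (HYDRA) with stability checks, decode the fused map against
synthetic annotation maps, and profile biotypes clinically.  Every stage is
seeded from the root seed, all artifacts land in a run directory as
TSV/JSON, and a manifest records the config hash, per-artifact SHA-256
checksums and wall-clock times so deterministic stages are verifiably
reproducible and can be skipped on re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical, decoding, deviations, fusion, hydra, normative, synthetic
from ._rng import child_seed
from .msn import build_msn_equal_voxels
from .synthetic import BiotypePlan, CohortSpec
from .topology import METRICS, HubnessProfile, ThresholdGrid, compute_hubness, stack_profiles

__all__ = ["PipelineConfig", "RunManifest", "run_all"]

STAGES = (
    "simulate",
    "msn",
    "normative",
    "deviations",
    "fusion",
    "hydra",
    "decoding",
    "clinical",
)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "run"
    stages: tuple = STAGES
    # cohort
    n_cases: int = 60
    n_controls: int = 80
    n_sites: int = 2
    age_range: tuple = (7.0, 14.0)
    sex_ratio: float = 0.7
    # features
    R: int = 30
    msn_route: bool = True  # regional samples -> MSN -> topology
    n_voxels: int = 40
    within_block_corr: float = 0.5
    grid_points: int = 128
    noise_sd: float = 0.25  # direct-hubness route only
    save_msn: bool = False
    # biotypes
    k_true: int = 2
    effect_size: float = 2.0
    # normative
    train_frac: float = 0.9
    use_yeo_johnson: bool = True
    # deviations
    n_perm: int = 500
    extreme_z: float = 2.0
    # fusion
    n_components: object = 4
    # hydra
    k_range: tuple = (2, 3)
    n_folds: int = 5
    hydra_n_init: int = 2
    # decoding
    n_annotation_maps: int = 8
    annotation_rho: float = 0.6
    annotation_smoothness: float = 25.0
    decode_n_perm: int = 500
    pls_n_boot: int = 1000

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        cfg = cls(**d)
        cfg.age_range = tuple(cfg.age_range)
        cfg.stages = tuple(cfg.stages)
        cfg.k_range = tuple(cfg.k_range)
        return cfg

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    checksums: dict = field(default_factory=dict)  # artifact path -> sha256
    wallclock: dict = field(default_factory=dict)  # stage -> seconds
    stages_run: list = field(default_factory=list)
    version: str = "0.1.0"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    """Mutable pipeline state with disk-backed artifact loading."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = RunManifest(cfg.config_hash())
        self.cov = None
        self.hubness = None
        self.truth = None
        self.dev = None
        self.fused = None
        self.labels_case = None

    def record(self, stage: str, paths, t0: float) -> None:
        for p in paths:
            p = Path(p)
            self.manifest.checksums[str(p.relative_to(self.out))] = _sha256(p)
        self.manifest.wallclock[stage] = round(time.time() - t0, 3)
        self.manifest.stages_run.append(stage)

    # -- loading helpers for disabled stages -------------------------------
    def need_cov(self):
        if self.cov is None:
            self.cov = pd.read_csv(self.out / "covariates.tsv", sep="\t")
        return self.cov

    def need_hubness(self):
        if self.hubness is None:
            df = pd.read_csv(self.out / "hubness.tsv", sep="\t")
            self.hubness = HubnessProfile.from_long(df)
        return self.hubness

    def need_dev(self):
        if self.dev is None:
            df = pd.read_csv(self.out / "deviations.tsv", sep="\t")
            subjects = list(pd.unique(df["subject_id"]))
            regions = list(pd.unique(df["region"]))
            Z = (
                df.pivot_table(index="subject_id", columns=["region", "metric"],
                               values="z", sort=False)
                .loc[subjects, pd.MultiIndex.from_product([regions, list(METRICS)])]
                .to_numpy()
                .reshape(len(subjects), len(regions), len(METRICS))
            )
            self.dev = normative.DeviationMatrix(subjects, regions, Z)
        return self.dev

    def need_fused(self):
        if self.fused is None:
            df = pd.read_csv(self.out / "fused_map.tsv", sep="\t")
            self.fused = df["fused"].to_numpy()
        return self.fused


def _stage_simulate(run: _Run):
    cfg = run.cfg
    spec = CohortSpec(cfg.n_cases, cfg.n_controls, cfg.n_sites, cfg.age_range,
                      cfg.sex_ratio, seed=child_seed(cfg.seed, "cohort"))
    run.cov = synthetic.generate_covariates(spec)
    synthetic.write_covariates_tsv(run.cov, run.out / "covariates.tsv")
    return [run.out / "covariates.tsv"]


def _stage_msn(run: _Run):
    """Feature construction: either the MSN route or direct hubness draws."""
    cfg = run.cfg
    cov = run.need_cov()
    paths = []
    if cfg.msn_route:
        morphs = synthetic.generate_regional_samples(
            cov, cfg.R, cfg.n_voxels, within_block_corr=cfg.within_block_corr,
            seed=child_seed(cfg.seed, "morphometry"),
        )
        grid = ThresholdGrid()
        profiles = []
        for morph in morphs:
            vals = np.vstack(morph.values)
            sim = build_msn_equal_voxels(morph.subject_id, vals,
                                         grid_points=cfg.grid_points)
            if cfg.save_msn:
                from .msn import write_similarity_tsv

                msn_dir = run.out / "msn"
                msn_dir.mkdir(exist_ok=True)
                p = msn_dir / f"{morph.subject_id}.tsv"
                write_similarity_tsv(sim, p)
                paths.append(p)
            profiles.append(compute_hubness(sim, grid))
        hub = stack_profiles(profiles)
        truth = synthetic.GroundTruth()
    else:
        hub, truth = synthetic.generate_control_hubness(
            cov, cfg.R, noise_sd=cfg.noise_sd, seed=child_seed(cfg.seed, "hubness")
        )
    k = cfg.k_true
    region_sets = np.array_split(np.arange(cfg.R), max(k, 1))
    signs = np.resize([1.0, -1.0], k)
    plan = BiotypePlan(
        k_true=k,
        affected_regions=[list(r[: max(2, len(r) // 2)]) for r in region_sets],
        effect_sizes=np.outer(signs, np.full(len(METRICS), cfg.effect_size) * signs[0]),
    )
    hub, truth = synthetic.plant_biotypes(
        hub, cov, plan, seed=child_seed(cfg.seed, "biotypes"), truth=truth
    )
    run.cov = synthetic.symptom_scores_for_biotypes(
        cov, truth.biotype_labels, plan, seed=child_seed(cfg.seed, "symptoms")
    )
    synthetic.write_covariates_tsv(run.cov, run.out / "covariates.tsv")
    run.hubness, run.truth = hub, truth
    hub.to_long().to_csv(run.out / "hubness.tsv", sep="\t", index=False)
    truth.to_json(run.out / "ground_truth.json")
    return paths + [run.out / "covariates.tsv", run.out / "hubness.tsv",
                    run.out / "ground_truth.json"]


def _stage_normative(run: _Run):
    cfg = run.cfg
    cov, hub = run.need_cov(), run.need_hubness()
    train_ids, test_ids = normative.split_cohort(
        cov, cfg.train_frac, seed=child_seed(cfg.seed, "split")
    )
    models = normative.fit_normative_models(
        hub, cov, train_ids, use_yeo_johnson=cfg.use_yeo_johnson
    )
    dev_all = normative.score_deviations(models, hub, cov, split_tag="all")
    run.dev = dev_all
    dev_all.to_long().to_csv(run.out / "deviations.tsv", sep="\t", index=False)
    # held-out calibration summary on test controls
    ctrl_test = [s for s in test_ids
                 if cov.set_index("subject_id").loc[s, "group"] == "control"]
    dev_test = normative.score_deviations(models, hub, cov, ctrl_test, "test")
    Z = dev_test.matrix()
    summary = {
        "n_train": len(train_ids),
        "n_test_controls": len(ctrl_test),
        "control_z_mean": float(Z.mean()),
        "control_z_sd": float(Z.std()),
        "control_extreme_rate": float((np.abs(Z) >= cfg.extreme_z).mean()),
    }
    with open(run.out / "normative_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return [run.out / "deviations.tsv", run.out / "normative_summary.json"]


def _stage_deviations(run: _Run):
    cfg = run.cfg
    cov, dev = run.need_cov(), run.need_dev()
    groups = cov.set_index("subject_id").loc[dev.subject_ids, "group"].to_numpy()
    rows = []
    deltas = []
    for m, metric in enumerate(dev.metrics):
        pos_c = deviations.extreme_map(dev, groups, "case", "positive", cfg.extreme_z)
        neg_c = deviations.extreme_map(dev, groups, "case", "negative", cfg.extreme_z)
        pos_t = deviations.extreme_map(dev, groups, "control", "positive", cfg.extreme_z)
        neg_t = deviations.extreme_map(dev, groups, "control", "negative", cfg.extreme_z)
        net = (pos_c.proportion[:, m] - neg_c.proportion[:, m]) - (
            pos_t.proportion[:, m] - neg_t.proportion[:, m]
        )
        deltas.append(net)
        rows.append(pd.DataFrame({
            "region": dev.region_ids, "metric": metric,
            "case_pos": pos_c.proportion[:, m], "case_neg": neg_c.proportion[:, m],
            "control_pos": pos_t.proportion[:, m],
            "control_neg": neg_t.proportion[:, m], "net_delta": net,
        }))
    perm = deviations.group_permutation_test(
        dev, groups == "case", threshold=cfg.extreme_z, n_perm=cfg.n_perm,
        seed=child_seed(cfg.seed, "group-perm"),
    )
    maps_df = pd.concat(rows, ignore_index=True)
    maps_df["p_perm"] = perm.p.ravel(order="F")
    maps_df["p_fdr"] = perm.p_fdr.ravel(order="F")
    maps_df.to_csv(run.out / "extreme_maps.tsv", sep="\t", index=False)
    run.fused = deviations.fuse_metric_maps(deltas)
    pd.DataFrame({"region": dev.region_ids, "fused": run.fused}).to_csv(
        run.out / "fused_map.tsv", sep="\t", index=False
    )
    return [run.out / "extreme_maps.tsv", run.out / "fused_map.tsv"]


def _stage_fusion(run: _Run):
    cfg = run.cfg
    cov, dev = run.need_cov(), run.need_dev()
    groups = cov.set_index("subject_id").loc[dev.subject_ids, "group"].to_numpy()
    model = fusion.run_fusion(dev, n_components=cfg.n_components,
                              seed=child_seed(cfg.seed, "fusion"))
    stats_df = fusion.component_group_test(model.mixing, groups == "case")
    stats_df.to_csv(run.out / "fusion_component_stats.tsv", sep="\t", index=False)
    mix = pd.concat(
        [pd.DataFrame(A, index=dev.subject_ids).add_prefix(f"{k}_c")
         for k, A in model.mixing.items()], axis=1
    )
    mix.to_csv(run.out / "fusion_mixing.tsv", sep="\t", index_label="subject_id")
    return [run.out / "fusion_component_stats.tsv", run.out / "fusion_mixing.tsv"]


def _stage_hydra(run: _Run):
    cfg = run.cfg
    cov, dev = run.need_cov(), run.need_dev()
    groups = cov.set_index("subject_id").loc[dev.subject_ids, "group"].to_numpy()
    X = dev.matrix()
    Xc, Xt = X[groups == "case"], X[groups == "control"]
    report = hydra.select_k(Xc, Xt, k_range=cfg.k_range, n_folds=cfg.n_folds,
                            seed=child_seed(cfg.seed, "hydra"),
                            n_init=cfg.hydra_n_init)
    model, sol = hydra.fit_hydra(Xc, Xt, report.chosen_k,
                                 n_init=cfg.hydra_n_init,
                                 seed=child_seed(cfg.seed, "hydra-final"))
    with open(run.out / "hydra_model.json", "w") as fh:
        json.dump(model.to_dict(), fh)
    case_ids = np.asarray(dev.subject_ids)[groups == "case"]
    pd.DataFrame({"subject_id": case_ids, "biotype": sol.labels}).to_csv(
        run.out / "hydra_labels.tsv", sep="\t", index=False
    )
    with open(run.out / "hydra_stability.json", "w") as fh:
        json.dump({"chosen_k": report.chosen_k,
                   "ari_by_k": {str(k): v for k, v in report.ari_by_k.items()}},
                  fh, indent=1)
    run.labels_case = sol.labels
    return [run.out / "hydra_model.json", run.out / "hydra_labels.tsv",
            run.out / "hydra_stability.json"]


def _stage_decoding(run: _Run):
    cfg = run.cfg
    fused = run.need_fused()
    R = len(fused)
    centroids, mask = synthetic.generate_centroids(
        R, seed=child_seed(cfg.seed, "centroids")
    )
    maps = synthetic.generate_annotation_maps(
        fused, cfg.annotation_rho, cfg.n_annotation_maps, cfg.annotation_smoothness,
        centroids, seed=child_seed(cfg.seed, "annotations"),
    )
    rec = decoding.decode_receptors(fused, maps, n_perm=cfg.decode_n_perm,
                                    seed=child_seed(cfg.seed, "decode"))
    rec.to_csv(run.out / "receptor_decoding.tsv", sep="\t", index=False)
    pls = decoding.pls_decode(fused, maps, n_boot=cfg.pls_n_boot,
                              n_perm=cfg.decode_n_perm,
                              seed=child_seed(cfg.seed, "pls"))
    pd.DataFrame({
        "term": list(maps.names), "loading": pls.component_loadings,
        "bootstrap_z": pls.bootstrap_z,
    }).to_csv(run.out / "pls_terms.tsv", sep="\t", index=False)
    with open(run.out / "pls_summary.json", "w") as fh:
        json.dump({"explained_variance": pls.explained_variance,
                   "p_spin": pls.p_spin}, fh, indent=1)
    return [run.out / "receptor_decoding.tsv", run.out / "pls_terms.tsv",
            run.out / "pls_summary.json"]


def _stage_clinical(run: _Run):
    cov = run.need_cov()
    labels_path = run.out / "hydra_labels.tsv"
    results = {}
    cases = cov[cov["group"] == "case"].set_index("subject_id")
    for domain in synthetic.SYMPTOM_DOMAINS:
        idx = clinical.normalized_symptom_index(
            cases[domain].to_numpy(), cases["site"].to_numpy()
        )
        cases[f"{domain}_norm"] = idx["normalized"].to_numpy()
    if labels_path.exists():
        lab = pd.read_csv(labels_path, sep="\t").set_index("subject_id")["biotype"]
        cases = cases.join(lab, how="inner")
        for domain in synthetic.SYMPTOM_DOMAINS:
            groups = [g[f"{domain}_norm"].dropna().to_numpy()
                      for _, g in cases.groupby("biotype")]
            if len(groups) >= 2 and all(len(g) for g in groups):
                res = clinical.kruskal_wallis(*groups)
                results[domain] = {"H": res.statistic, "p": res.p}
        tab = pd.crosstab(cases["biotype"], cases["sex"]).to_numpy()
        if tab.shape[0] >= 2 and (tab.sum(axis=0) > 0).all():
            res = clinical.chi_square_homogeneity(tab)
            results["sex_chi2"] = {"chi2": res.statistic, "p": res.p}
    with open(run.out / "clinical_tests.json", "w") as fh:
        json.dump(results, fh, indent=1)
    return [run.out / "clinical_tests.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "msn": _stage_msn,
    "normative": _stage_normative,
    "deviations": _stage_deviations,
    "fusion": _stage_fusion,
    "hydra": _stage_hydra,
    "decoding": _stage_decoding,
    "clinical": _stage_clinical,
}


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in dependency order; returns the manifest.

    A stage failure raises with the stage name attached; the manifest
    written so far is saved as ``manifest.partial.json``.
    """
    run = _Run(config)
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        try:
            paths = _STAGE_FUNCS[stage](run)
        except Exception as exc:
            run.manifest.to_json(run.out / "manifest.partial.json")
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        run.record(stage, paths, t0)
    run.manifest.to_json(run.out / "manifest.json")
    config.to_json(run.out / "config.json")
    return run.manifest
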