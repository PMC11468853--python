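"""End-to-end pipeline orchestration.

Ties the stages together on file-based inputs/outputs:

    simulate/extract -> network -> metrics -> stats -> nbs -> classify

Every stage reads what the previous one wrote under ``config.out_dir``, so
stages can also be run individually (the CLI exposes one subcommand per
stage).  A manifest records the configuration, the per-stage random seeds,
the outputs written, and the conventions the pipeline commits to (bandwidth
rule, tie-breaking, NBS tail, edge-count rounding).

All randomness flows from ``config.seed``: per-stage seeds are derived from
it with a seed sequence, so a rerun with the same configuration and inputs
is numerically identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import AtlasSpec, SubjectParcellation, extract_roi_values
from .density import build_similarity_matrix, cohort_grid_bounds, make_grid, SimilarityMatrix
from .graph import ThresholdSpec, cohort_metric_table, GLOBAL_METRIC_NAMES, NODAL_METRIC_NAMES
from .ml import MODELS, nested_cv, permutation_significance, feature_contributions, roc_curve
from .stats import adjusted_group_test, fdr_correct, nbs, demographic_tests
from .simulate import CohortSpec, generate_cohort, planted_test_spec, small_test_spec

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "StageError", "STAGES"]

STAGES = ("simulate", "network", "metrics", "stats", "nbs", "classify")


class StageError(RuntimeError):
    """Failure inside a pipeline stage, tagged with the stage name."""


@dataclass
class PipelineConfig:
    """All pipeline settings in one serialisable object.

    Defaults describe the desk-scale synthetic study (12 regions, 20 + 20
    subjects, planted subnetwork + node); at full scale ``n_rand`` would be
    1000 and the permutation counts 5000.
    """

    out_dir: str = "klsnet_out"
    seed: int = 0
    # input mode: a synthetic cohort ("planted" | "null") or on-disk inputs
    synthetic: str | None = "planted"
    parcellation_dir: str | None = None
    phenotype_path: str | None = None
    atlas_table: str | None = None
    # KDE / similarity settings
    grid_size: int = 256
    eps: float = 1e-12
    bw_method: str = "scott"
    # sparsity sweep
    s_min: float = 0.05
    s_max: float = 0.30
    step: float = 0.01
    n_rand: int = 20           # surrogates per threshold for lambda/gamma/sigma
    # NBS settings
    edge_p: float = 0.001
    nbs_n_perm: int = 1000
    nbs_tail: str = "decrease"
    # classification settings
    outer_k: int = 10
    inner_k: int = 5
    cv_n_perm: int = 50
    rf_grid_max: int = 30      # largest RF n_estimators searched (200 at full scale)
    alpha: float = 0.05

    def validate(self) -> None:
        ThresholdSpec(self.s_min, self.s_max, self.step)  # raises on bad sweep
        if self.synthetic not in (None, "planted", "null"):
            raise ValueError("synthetic must be 'planted', 'null' or null")
        if self.synthetic is None and not (self.parcellation_dir and self.phenotype_path):
            raise ValueError("non-synthetic runs need parcellation_dir and phenotype_path")
        if not (0 < self.edge_p < 1):
            raise ValueError("edge_p must lie in (0, 1)")
        if self.nbs_tail not in ("decrease", "increase", "both"):
            raise ValueError("nbs_tail must be decrease/increase/both")
        if self.grid_size < 2 or self.eps <= 0 or self.n_rand < 0:
            raise ValueError("invalid KDE / surrogate settings")
        if self.outer_k < 2 or self.inner_k < 2 or self.cv_n_perm < 0:
            raise ValueError("invalid cross-validation settings")
        if self.rf_grid_max < 10:
            raise ValueError("rf_grid_max must be at least 10")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def thresholds(self) -> ThresholdSpec:
        return ThresholdSpec(self.s_min, self.s_max, self.step)

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence(self.seed).generate_state(len(STAGES))[idx] % (2**31))

    # -- serialisation ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _out(config: PipelineConfig) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _stage(name: str):
    def deco(fn):
        def wrapped(config: PipelineConfig, *a, **kw):
            try:
                return fn(config, *a, **kw)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        wrapped.__name__ = fn.__name__
        wrapped.__doc__ = fn.__doc__
        return wrapped
    return deco


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

@_stage("simulate")
def stage_simulate(config: PipelineConfig) -> dict:
    """Generate (or load) the cohort; write parcellations + phenotype."""
    out = _out(config) / "parcellations"
    out.mkdir(exist_ok=True)
    seed = config.stage_seed("simulate")
    if config.synthetic is not None:
        spec = (
            planted_test_spec(seed) if config.synthetic == "planted"
            else small_test_spec(seed)
        )
        parcs, phenotype, truth = generate_cohort(spec)
        (_out(config) / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    else:
        pdir = Path(config.parcellation_dir)
        phenotype = pd.read_csv(config.phenotype_path)
        parcs = [
            SubjectParcellation.from_tsv(pdir / f"{sid}.tsv", sid)
            for sid in phenotype["subject_id"]
        ]
        truth = None
    for p in parcs:
        p.to_tsv(out / f"{p.subject_id}.tsv")
    phenotype.to_csv(_out(config) / "phenotype.csv", index=False)
    demo = demographic_tests(
        phenotype.drop(columns=["subject_id"]), group_col="group", categorical=("sex",)
    )
    demo.to_csv(_out(config) / "demographics.tsv", sep="\t", index=False)
    return {
        "parcellations": str(out),
        "phenotype": str(_out(config) / "phenotype.csv"),
        "demographics": str(_out(config) / "demographics.tsv"),
        "n_subjects": len(parcs),
    }


def _load_parcellations(config: PipelineConfig) -> tuple[list[SubjectParcellation], pd.DataFrame]:
    phenotype = pd.read_csv(_out(config) / "phenotype.csv")
    pdir = _out(config) / "parcellations"
    parcs = [
        SubjectParcellation.from_tsv(pdir / f"{sid}.tsv", str(sid))
        for sid in phenotype["subject_id"]
    ]
    return parcs, phenotype


@_stage("network")
def stage_network(config: PipelineConfig) -> dict:
    """KLS similarity matrix per subject, on one cohort-wide grid."""
    parcs, phenotype = _load_parcellations(config)
    bounds = cohort_grid_bounds(parcs)
    grid = make_grid(bounds, config.grid_size)
    out = _out(config) / "kls"
    out.mkdir(exist_ok=True)
    for p in parcs:
        try:
            W = build_similarity_matrix(
                p, grid=grid, bw_method=config.bw_method, eps=config.eps
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage 'network' failed for subject {p.subject_id}: {exc}") from exc
        np.savetxt(out / f"{W.subject_id}.tsv", W.W, delimiter="\t")
    sidecar = {
        "kernel": "gaussian",
        "bw_method": config.bw_method,
        "grid_size": config.grid_size,
        "grid_bounds": [float(bounds[0]), float(bounds[1])],
        "eps": config.eps,
        "log_base": "e",
        "node_ids": list(parcs[0].region_ids),
    }
    (out / "kls_meta.json").write_text(json.dumps(sidecar, indent=2))
    return {"kls_dir": str(out), "meta": str(out / "kls_meta.json")}


def _load_matrices(config: PipelineConfig) -> tuple[list[SimilarityMatrix], pd.DataFrame, list[int]]:
    phenotype = pd.read_csv(_out(config) / "phenotype.csv")
    kdir = _out(config) / "kls"
    meta = json.loads((kdir / "kls_meta.json").read_text())
    node_ids = meta["node_ids"]
    mats = []
    for sid in phenotype["subject_id"]:
        W = np.loadtxt(kdir / f"{sid}.tsv", delimiter="\t")
        mats.append(SimilarityMatrix(str(sid), tuple(node_ids), W, meta))
    return mats, phenotype, node_ids


@_stage("metrics")
def stage_metrics(config: PipelineConfig) -> dict:
    """Per-subject AUC-over-sparsity of all global and nodal metrics."""
    mats, _, _ = _load_matrices(config)
    table = cohort_metric_table(
        mats, config.thresholds, n_rand=config.n_rand,
        rng_seed=config.stage_seed("metrics"),
    )
    path = _out(config) / "metric_aucs.tsv"
    table.to_csv(path, sep="\t", index=False)
    return {"metric_aucs": str(path)}


@_stage("stats")
def stage_stats(config: PipelineConfig) -> dict:
    """Covariate-adjusted group tests on every metric AUC, with FDR on
    nodal metrics (across nodes, within each metric family)."""
    table = pd.read_csv(_out(config) / "metric_aucs.tsv", sep="\t")
    phenotype = pd.read_csv(_out(config) / "phenotype.csv")
    cov = phenotype[["sex", "age", "education"]]
    group = phenotype["group"].to_numpy()
    order = {str(s): i for i, s in enumerate(phenotype["subject_id"].astype(str))}

    rows = []
    skipped = []
    for (metric, node), sub in table.groupby(["metric", "node"], sort=False):
        sub = sub.copy()
        sub["order"] = sub["subject_id"].astype(str).map(order)
        sub = sub.sort_values("order")
        y = sub["auc"].to_numpy()
        if not np.all(np.isfinite(y)):
            skipped.append(f"{metric}/{node}")
            continue
        res = adjusted_group_test(y, group, cov, metric=f"{metric}/{node}")
        rows.append((metric, node, res.mean_a, res.sd_a, res.mean_b, res.sd_b,
                     res.t, res.p))
    stats_df = pd.DataFrame(
        rows, columns=["metric", "node", "mean_patients", "sd_patients",
                       "mean_controls", "sd_controls", "t", "p"],
    )
    stats_df["p_fdr"] = np.nan
    for metric in NODAL_METRIC_NAMES:
        mask = stats_df["metric"] == metric
        if mask.any():
            stats_df.loc[mask, "p_fdr"] = fdr_correct(stats_df.loc[mask, "p"].to_numpy())
    path = _out(config) / "group_stats.tsv"
    stats_df.to_csv(path, sep="\t", index=False)
    if skipped:
        logger.info("skipped non-finite metric AUCs: %s", skipped)
    return {"group_stats": str(path), "skipped": skipped}


@_stage("nbs")
def stage_nbs(config: PipelineConfig) -> dict:
    """Network-based statistics on the KLS edge weights."""
    mats, phenotype, node_ids = _load_matrices(config)
    stack = np.stack([m.W for m in mats])
    cov = phenotype[["sex", "age", "education"]]
    group = phenotype["group"].to_numpy()
    result = nbs(
        stack, group, cov, edge_p=config.edge_p, n_perm=config.nbs_n_perm,
        tail=config.nbs_tail, rng_seed=config.stage_seed("nbs"),
    )
    atlas_names = None
    if config.atlas_table:
        atlas_names = AtlasSpec.from_table(config.atlas_table)
    report = {
        "edge_threshold_p": result.edge_threshold_p,
        "tail": result.tail,
        "n_perm": result.n_perm,
        "seed": result.seed,
        "components": [
            {
                "nodes": [int(node_ids[v]) for v in c.nodes],
                "node_names": (
                    [atlas_names.name_of(int(node_ids[v])) for v in c.nodes]
                    if atlas_names else None
                ),
                "edges": [[int(node_ids[i]), int(node_ids[j])] for i, j in c.edges],
                "size": c.size,
                "p_fwe": c.p_fwe,
            }
            for c in result.components
        ],
    }
    path = _out(config) / "nbs_report.json"
    path.write_text(json.dumps(report, indent=2))
    return {"nbs_report": str(path)}


def _feature_matrix(config: PipelineConfig) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Assemble the classification features: significant metric AUCs
    (globals at p < alpha, nodals at FDR p < alpha) plus the KLS weights of
    every edge in a significant NBS component."""
    stats_df = pd.read_csv(_out(config) / "group_stats.tsv", sep="\t")
    table = pd.read_csv(_out(config) / "metric_aucs.tsv", sep="\t")
    report = json.loads((_out(config) / "nbs_report.json").read_text())
    mats, phenotype, node_ids = _load_matrices(config)
    index = {nid: k for k, nid in enumerate(node_ids)}
    subjects = phenotype["subject_id"].astype(str).tolist()

    cols, names = [], []
    wide = table.pivot_table(
        index="subject_id", columns=["metric", "node"], values="auc", sort=False
    ).loc[[*subjects]] if len(table) else None
    for _, row in stats_df.iterrows():
        is_global = row["node"] == "global"
        p_use = row["p"] if is_global else row["p_fdr"]
        if np.isfinite(p_use) and p_use < config.alpha:
            cols.append(wide[(row["metric"], row["node"])].to_numpy())
            names.append(f"{row['metric']}_auc[{row['node']}]")
    stack = np.stack([m.W for m in mats])
    for comp in report["components"]:
        if comp["p_fwe"] < config.alpha:
            for i, j in comp["edges"]:
                cols.append(stack[:, index[i], index[j]])
                names.append(f"kls[{i}-{j}]")
    if not cols:
        return np.empty((len(subjects), 0)), phenotype["group"].to_numpy(), ()
    return np.column_stack(cols), phenotype["group"].to_numpy(), tuple(names)


@_stage("classify")
def stage_classify(config: PipelineConfig) -> dict:
    """LR/SVM/RF nested CV on the significant connectome features."""
    X, y, names = _feature_matrix(config)
    path = _out(config) / "classification.json"
    if X.shape[1] == 0:
        logger.warning("no significant features; classification skipped")
        path.write_text(json.dumps({"skipped": "no significant features"}, indent=2))
        return {"classification": str(path), "n_features": 0}
    seed = config.stage_seed("classify")
    results = {}
    payload = {"feature_names": list(names), "models": {}}
    roc_rows = []
    for model in MODELS:
        grid = (
            list(range(10, config.rf_grid_max + 1, 10)) if model == "rf" else None
        )
        res = nested_cv(
            X, y, model, outer_k=config.outer_k, inner_k=config.inner_k,
            grid=grid, rng_seed=seed, feature_names=names,
        )
        if config.cv_n_perm:
            permutation_significance(
                X, y, model, n_perm=config.cv_n_perm, rng_seed=seed,
                observed=res, grid=grid, outer_k=config.outer_k,
                inner_k=config.inner_k, feature_names=names,
            )
        results[model] = res
        fpr, tpr, auc = roc_curve(res.scores, res.y_true)
        roc_rows.extend((model, f, t) for f, t in zip(fpr, tpr))
        payload["models"][model] = {
            "accuracy": res.accuracy,
            "auc": auc,
            "sensitivity": res.sensitivity,
            "specificity": res.specificity,
            "p_accuracy": res.p_accuracy,
            "p_auc": res.p_auc,
            "best_params": res.best_params,
            "contributions": dict(zip(names, res.contributions.tolist())),
        }
    payload["top_shared_features"] = feature_contributions(results)
    path.write_text(json.dumps(payload, indent=2))
    pd.DataFrame(roc_rows, columns=["model", "fpr", "tpr"]).to_csv(
        _out(config) / "roc_curves.tsv", sep="\t", index=False
    )
    return {
        "classification": str(path),
        "roc_curves": str(_out(config) / "roc_curves.tsv"),
        "n_features": X.shape[1],
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and write a manifest.

    Returns the manifest dictionary.  Deterministic for a fixed config.
    """
    config.validate()
    stage_fns = {
        "simulate": stage_simulate,
        "network": stage_network,
        "metrics": stage_metrics,
        "stats": stage_stats,
        "nbs": stage_nbs,
        "classify": stage_classify,
    }
    manifest = {
        "klsnet_version": __version__,
        "config": asdict(config),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "conventions": {
            "bandwidth_rule": config.bw_method,
            "log_base": "e",
            "probability_floor": config.eps,
            "edge_count_rounding": "round half away from zero",
            "threshold_tie_break": "weight desc, then (i, j) lexicographic",
            "disconnected_pairs": "excluded from Lp; contribute 0 to efficiency",
            "nbs_tail": config.nbs_tail,
            "nbs_component_statistic": "edge count",
        },
        "stages": {},
    }
    for name in STAGES:
        logger.info("running stage %s", name)
        manifest["stages"][name] = stage_fns[name](config)
    path = _out(config) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return manifest
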