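"""End-to-end orchestration: preprocess -> t-filter -> stability selection ->
backward elimination -> tuning -> classifier training -> evaluation.

A single :class:`PipelineConfig` (one master seed) drives every stage; each
stage draws its randomness from a named substream of that seed, so the whole
run is a pure function of (inputs, config). Validation-split outcome labels
are sealed behind an access guard until the evaluation stage: any fitting
stage that tried to read them would raise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, evaluate, io
from ._rng import child_seed
from .classifier import (
    ClinicalClassifier,
    ForestConfig,
    GenomicClassifier,
    IntegratedClassifier,
    risk_calls,
)
from .preprocess import (
    filter_features_by_metadata,
    filter_features_by_technical_variance,
    remove_batch_components,
)
from .select import SelectionConfig, stability_select, t_filter
from .simulate import SimulationConfig, generate_cohort, generate_technical_replicates

__all__ = [
    "PipelineConfig",
    "LabelGuard",
    "run_pipeline",
    "PipelineReport",
    "demo_config",
    "null_config",
]

log = logging.getLogger("earlymet")

OUTCOME_COLUMNS = ["is_case", "group", "t_met", "e_met", "t_pcsm", "e_pcsm", "t_os", "e_os"]


class LabelGuard:
    """Seals validation outcome labels until evaluation.

    Fitting stages receive only :attr:`train` (full annotation of training
    samples) or :attr:`validation_covariates` (validation rows with outcome
    columns removed). :attr:`validation` raises until :meth:`release` is
    called by the evaluation stage.
    """

    def __init__(self, annot: pd.DataFrame):
        self._annot = annot
        self._released = False

    @property
    def train(self) -> pd.DataFrame:
        return self._annot[self._annot["split"] == "train"]

    @property
    def validation_covariates(self) -> pd.DataFrame:
        val = self._annot[self._annot["split"] == "validation"]
        return val.drop(columns=[c for c in OUTCOME_COLUMNS if c in val.columns])

    def release(self) -> pd.DataFrame:
        self._released = True
        return self._annot[self._annot["split"] == "validation"]

    @property
    def validation(self) -> pd.DataFrame:
        if not self._released:
            raise RuntimeError(
                "validation outcome labels are sealed until the evaluation stage"
            )
        return self._annot[self._annot["split"] == "validation"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs. Supply either ``simulation`` or the three
    input paths (matrix, feature annotation, sample annotation) — not both."""

    simulation: SimulationConfig | None = None
    matrix_path: str | None = None
    feature_annotation_path: str | None = None
    sample_annotation_path: str | None = None
    tech_matrix_path: str | None = None

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)

    tech_top_frac: float = 0.10
    batch_n_examine: int = 10
    batch_n_remove: int = 2
    batch_fit_on: str = "all"  # or "train"
    min_selected: int = 10  # fallback floor when stability selects fewer
    auc_boot: int = 2000
    master_seed: int = 0
    outdir: str | None = None
    write_matrices: bool = False

    def __post_init__(self) -> None:
        has_paths = self.matrix_path is not None
        if has_paths == (self.simulation is not None):
            raise ValueError("supply exactly one of simulation config or input paths")
        if has_paths and (
            self.feature_annotation_path is None or self.sample_annotation_path is None
        ):
            raise ValueError("input paths require feature and sample annotation paths")
        if self.batch_fit_on not in ("all", "train"):
            raise ValueError("batch_fit_on must be 'all' or 'train'")

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class PipelineReport:
    """Evaluation report plus the run manifest."""

    funnel: dict
    aucs: dict
    odds_ratios: dict
    km: dict
    reclassification: pd.DataFrame
    median_followup_years: float
    selected_features: list[str]
    recovery: dict | None
    manifest: dict
    scores: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = {
            "funnel": self.funnel,
            "aucs": self.aucs,
            "odds_ratios": self.odds_ratios,
            "km": self.km,
            "reclassification": self.reclassification.reset_index().to_dict("records"),
            "median_followup_years": self.median_followup_years,
            "selected_features": self.selected_features,
            "recovery": self.recovery,
            "manifest": self.manifest,
        }
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, default=_jsonable, **kw)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        v = float(x)
        return v if np.isfinite(v) else None
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, float) and not np.isfinite(x):
        return None
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _or_entry(r: evaluate.ORResult) -> dict:
    return {"or": r.or_, "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
            "method": r.method}


def demo_config(master_seed: int = 0, outdir: str | None = None) -> PipelineConfig:
    """Desk-scale demonstration run: the generator's default cohort
    (5,000 features, 300 samples, 30 planted markers) with bootstrap counts
    reduced to keep a single-CPU run in the minutes range (100 stability
    bootstraps, 200-tree forests, 20 tuning resamples)."""
    return PipelineConfig(
        simulation=SimulationConfig(),
        selection=SelectionConfig(n_boot=100),
        forest=ForestConfig(n_trees=200, tune_boot=20),
        auc_boot=1000,
        master_seed=master_seed,
        outdir=outdir,
    )


def null_config(master_seed: int = 0) -> PipelineConfig:
    """A no-signal control cohort (effect size zero): the validation AUC of
    the resulting classifier should be statistically indistinguishable from
    chance."""
    return PipelineConfig(
        simulation=SimulationConfig(
            n_features=1500, n_informative=0, effect_size=0.0,
            n_cases=80, n_ned=60, n_psa=60,
        ),
        selection=SelectionConfig(n_boot=40),
        forest=ForestConfig(n_trees=100, tune_boot=10,
                            mtry_grid=(1, 3), nodesize_grid=(1, 5)),
        auc_boot=500,
        master_seed=master_seed,
    )


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulation is not None:
        sim = cfg.simulation.replace(seed=child_seed(cfg.master_seed, "sim"))
        expr, feats, annot = generate_cohort(sim)
        tech = generate_technical_replicates(sim, feats)
        return expr, feats, annot, tech
    expr = io.read_matrix(cfg.matrix_path)
    feats = io.read_annotation(cfg.feature_annotation_path)
    annot = io.read_annotation(cfg.sample_annotation_path)
    missing = expr.columns.difference(annot.index)
    if len(missing) > 0:
        raise ValueError(f"samples missing from annotation: {list(missing[:5])}")
    tech = io.read_matrix(cfg.tech_matrix_path) if cfg.tech_matrix_path else None
    return expr, feats, annot, tech


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Run every stage and return the evaluation report.

    Writes intermediate artifacts (tally table, elimination curve, scores,
    report, manifest) to ``cfg.outdir`` when given. A failing stage aborts
    with the stage name; a partial manifest (progress so far) is still
    written when an output directory is configured.
    """
    progress = {"stage": "load", "funnel": {}}
    try:
        return _run_pipeline(cfg, progress)
    except Exception as exc:
        if cfg.outdir is not None:
            out = Path(cfg.outdir)
            out.mkdir(parents=True, exist_ok=True)
            partial = {
                "failed_stage": progress["stage"],
                "error": str(exc),
                "funnel": progress["funnel"],
                "master_seed": cfg.master_seed,
            }
            (out / "manifest.json").write_text(
                json.dumps(partial, indent=2, sort_keys=True, default=_jsonable)
            )
        raise RuntimeError(
            f"pipeline stage {progress['stage']!r} failed: {exc}"
        ) from exc


def _run_pipeline(cfg: PipelineConfig, progress: dict) -> PipelineReport:
    expr, feats, annot, tech = _load_inputs(cfg)
    funnel = {"input_features": int(expr.shape[0]), "samples": int(expr.shape[1])}
    progress["funnel"] = funnel
    log.info("input: %d features x %d samples", *expr.shape)

    # ------------------------------------------------------------------ QC
    progress["stage"] = "preprocess"
    expr = filter_features_by_metadata(expr, feats)
    funnel["after_metadata_filter"] = int(expr.shape[0])
    if tech is not None:
        expr, tech_ann = filter_features_by_technical_variance(
            expr, tech, top_frac=cfg.tech_top_frac
        )
    funnel["after_technical_filter"] = int(expr.shape[0])
    log.info("reliable features: %d", expr.shape[0])

    guard = LabelGuard(annot)
    train_ids = guard.train.index
    if cfg.batch_fit_on == "train":
        bc = remove_batch_components(
            expr[train_ids], guard.train["batch"], cfg.batch_n_examine, cfg.batch_n_remove
        )
        expr = bc.apply(expr)
        batch_result = bc
    else:
        batch_result = remove_batch_components(
            expr, annot["batch"], cfg.batch_n_examine, cfg.batch_n_remove
        )
        expr = batch_result.corrected
    funnel["batch_components_removed"] = batch_result.removed_component_indices

    # ------------------------------------------------- selection (train only)
    progress["stage"] = "select"
    train_annot = guard.train
    expr_train = expr[train_ids]
    sel_cfg = cfg.selection.replace(seed=child_seed(cfg.master_seed, "select"))
    t_pass = t_filter(
        expr_train, train_annot["is_case"], sel_cfg.t_p_threshold, sel_cfg.equal_var
    )
    funnel["t_filter_pass"] = len(t_pass)
    log.info("t-filter retained %d features", len(t_pass))
    if len(t_pass) == 0:
        raise RuntimeError("t-filter retained no features; nothing to model")

    stab = stability_select(expr_train.loc[t_pass], train_annot["is_case"], sel_cfg)
    selected = stab.selected
    funnel["stability_selected"] = len(selected)
    if len(selected) < cfg.min_selected:
        warnings.warn(
            f"stability selection kept {len(selected)} feature(s); "
            f"falling back to the top {cfg.min_selected} by tally",
            stacklevel=2,
        )
        selected = list(stab.tally.sort_values(ascending=False).index[: cfg.min_selected])
    log.info("stability selection kept %d features", len(selected))

    # ------------------------------------------------------------ classifiers
    progress["stage"] = "classify"
    f_cfg = cfg.forest.replace(seed=child_seed(cfg.master_seed, "forest"))
    gc = GenomicClassifier(
        expr_train, train_annot["is_case"], candidates=selected, config=f_cfg
    ).fit()
    funnel["final_markers"] = len(gc.features)
    log.info("final classifier: %d markers", len(gc.features))

    cc = ClinicalClassifier(train_annot).fit()
    gc_train = gc.predict(expr_train)
    cc_train = cc.predict(train_annot)
    gcc = IntegratedClassifier(gc_train, cc_train, train_annot["is_case"]).fit()
    gcc_train = gcc.predict(gc_train, cc_train)

    # -------------------------------------------------------------- evaluate
    progress["stage"] = "evaluate"
    val_annot = guard.release()
    expr_val = expr[val_annot.index]
    gc_val = gc.predict(expr_val)
    cc_val = cc.predict(val_annot)
    gcc_val = gcc.predict(gc_val, cc_val)
    y_val = val_annot["is_case"].to_numpy(dtype=bool)
    y_train = train_annot["is_case"].to_numpy(dtype=bool)

    seed_auc = child_seed(cfg.master_seed, "auc")
    aucs = {}
    for name, tr, va in (
        ("gc", gc_train, gc_val),
        ("cc", cc_train, cc_val),
        ("gcc", gcc_train, gcc_val),
    ):
        a_tr = evaluate.auc_with_ci(tr, y_train, n_boot=cfg.auc_boot, seed=seed_auc)
        a_va = evaluate.auc_with_ci(va, y_val, n_boot=cfg.auc_boot, seed=seed_auc)
        aucs[name] = {
            "train": {"auc": a_tr.auc, "ci_low": a_tr.ci_low, "ci_high": a_tr.ci_high},
            "validation": {"auc": a_va.auc, "ci_low": a_va.ci_low, "ci_high": a_va.ci_high},
        }
    a_gs = evaluate.auc_with_ci(
        val_annot["gleason"].to_numpy(float), y_val, n_boot=cfg.auc_boot, seed=seed_auc
    )
    aucs["gleason"] = {
        "validation": {"auc": a_gs.auc, "ci_low": a_gs.ci_low, "ci_high": a_gs.ci_high}
    }

    odds = {"univariable": {}, "multivariable": {}}
    odds["univariable"]["gc_per_10pct"] = _or_entry(
        evaluate.univariable_logistic_or(gc_val, y_val, "per_10pct_score")
    )
    odds["univariable"]["gc_high_vs_low"] = _or_entry(
        evaluate.odds_ratio_2x2(
            evaluate.ContingencyTable2x2.from_labels(gc_val > 0.5, y_val)
        )
    )
    for name, col in (
        ("gleason_ge8", val_annot["gleason"] >= 8),
        ("svi", val_annot["svi"]),
        ("sm_pos", val_annot["sm_pos"]),
        ("ece", val_annot["ece"]),
        ("node_pos", val_annot["node_pos"]),
    ):
        try:
            odds["univariable"][name] = _or_entry(
                evaluate.odds_ratio_2x2(
                    evaluate.ContingencyTable2x2.from_labels(col.to_numpy(bool), y_val)
                )
            )
        except ValueError:
            odds["univariable"][name] = None

    from .classifier import encode_clinical

    X_val, _ = encode_clinical(val_annot, ppsa_median=cc.ppsa_median)
    mva_X = pd.concat(
        [pd.Series(gc_val / 0.10, index=val_annot.index, name="gc_per_10pct"), X_val],
        axis=1,
    ).drop(columns=["ppsa_missing"])
    treat = val_annot[["adj_radiation", "adj_adt", "salv_radiation", "salv_adt"]]
    mva = evaluate.multivariable_logistic(
        mva_X, y_val, treatment=treat, adjust_for_treatment=True
    )
    odds["multivariable"] = {
        k: {"or": float(r["or"]), "ci_low": float(r["ci_low"]),
            "ci_high": float(r["ci_high"]), "p": float(r["p"])}
        for k, r in mva.iterrows()
    }

    # KM among validation cases, split by GC risk; times in years from BCR
    km = {}
    cases = val_annot[y_val]
    gc_case_risk = risk_calls(gc_val[cases.index])
    if gc_case_risk.nunique() == 2:
        for ev, (tcol, ecol) in {
            "pcsm": ("t_pcsm", "e_pcsm"),
            "os": ("t_os", "e_os"),
        }.items():
            r = evaluate.km_logrank(
                cases[tcol], cases[ecol], gc_case_risk.to_numpy(), event_label=ev
            )
            km[ev] = {"logrank_p": r.logrank_p, "medians": r.medians}
    recls = evaluate.reclassification_table(
        val_annot["gleason"], gc_val, val_annot["e_met"], val_annot["e_pcsm"]
    )
    followup = evaluate.median_followup(annot["t_os"], annot["e_os"])

    recovery = None
    if "is_informative" in feats.columns:
        truth_all = set(feats.index[feats["is_informative"]])
        # markers removed by the blind QC filters never reach selection, so
        # recovery of the selection stages is measured over survivors
        truth = truth_all & set(expr.index)
        if truth:
            hits = truth & set(selected)
            recovery = {
                "n_informative": len(truth_all),
                "n_informative_post_qc": len(truth),
                "selected_recall": len(hits) / len(truth),
                "selected_recall_all_planted": len(truth_all & set(selected)) / len(truth_all),
                "final_recall": len(truth & set(gc.features)) / len(truth),
                "final_precision": (
                    len(truth & set(gc.features)) / len(gc.features) if gc.features else 0.0
                ),
            }

    scores = pd.DataFrame(
        {
            "gc": pd.concat([gc_train, gc_val]),
            "cc": pd.concat([cc_train, cc_val]),
            "gcc": pd.concat([gcc_train, gcc_val]),
        }
    )
    scores["risk"] = risk_calls(scores["gc"])
    scores["split"] = annot.loc[scores.index, "split"]

    manifest = {
        "earlymet_version": __version__,
        "master_seed": cfg.master_seed,
        "stage_seeds": {
            "sim": child_seed(cfg.master_seed, "sim"),
            "select": child_seed(cfg.master_seed, "select"),
            "forest": child_seed(cfg.master_seed, "forest"),
            "auc": child_seed(cfg.master_seed, "auc"),
        },
        "funnel": funnel,
        "batch_r2_per_pc": [float(v) for v in batch_result.batch_r2_per_pc],
        "variance_captured": batch_result.variance_captured,
        "hashes": {},
    }

    report = PipelineReport(
        funnel=funnel,
        aucs=aucs,
        odds_ratios=odds,
        km=km,
        reclassification=recls,
        median_followup_years=followup,
        selected_features=list(gc.features),
        recovery=recovery,
        manifest=manifest,
        scores=scores,
    )

    if cfg.outdir is not None:
        progress["stage"] = "write"
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        stab.table().to_csv(out / "tally.tsv", sep="\t")
        if gc.elimination is not None:
            pd.DataFrame(
                {"size": gc.elimination.sizes, "cv_mse": gc.elimination.cv_mse}
            ).to_csv(out / "elimination_curve.tsv", sep="\t", index=False)
        scores.to_csv(out / "scores.tsv", sep="\t")
        recls.to_csv(out / "reclassification.tsv", sep="\t")
        if cfg.write_matrices:
            io.write_matrix(expr, out / "corrected_matrix.tsv.gz")
        gc.save(out / "gc_model")
        cc.save(out / "cc_model")
        (out / "report.json").write_text(report.to_json(indent=2))
        for f in sorted(out.rglob("*")):
            if f.is_file() and f.name != "manifest.json":
                manifest["hashes"][str(f.relative_to(out))] = _sha256(f)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
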