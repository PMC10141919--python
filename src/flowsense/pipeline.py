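"""End-to-end orchestration: ingest -> trim -> features -> measurement ->
selection -> evaluation -> importance, with report artifacts.

Every stage output is a pure function of (inputs, config, seed); two runs
with the same configuration produce byte-identical reports.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import features as ft
from . import preprocessing as pp
from . import rasch
from . import synthetic as syn
from .io import read_e4_session
from .selection import StepwiseFlowLogit, StepwiseResults

__all__ = ["PipelineConfig", "PipelineReport", "PipelineError", "run_pipeline",
           "load_study_sessions", "fss_matrix_from_sessions"]

log = logging.getLogger("flowsense")


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    Exactly one of ``input_dir`` (a directory of on-disk session
    directories) or ``simulate`` ("study1" or "study2") must be set.
    """

    input_dir: Optional[str] = None
    simulate: Optional[str] = "study1"
    baseline_mode: str = "preceding"
    trim_overrides: dict = field(default_factory=dict)
    kurtosis: str = "excess"  # "excess" | "raw"
    stepwise_alpha: float = 0.10
    cv_schemes: tuple = ("between_participant", "stratified_10fold", "resubstitution")
    classifiers: tuple = ("logistic", "gaussian_nb")
    n_shuffles: int = 1000
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self):
        if (self.input_dir is None) == (self.simulate is None):
            raise PipelineError("set exactly one of input_dir and simulate")
        if self.simulate is not None and self.simulate not in ("study1", "study2"):
            raise PipelineError(f"unknown simulate spec {self.simulate!r}")
        if self.kurtosis not in ("excess", "raw"):
            raise PipelineError(f"unknown kurtosis convention {self.kurtosis!r}")
        if not 0 < self.stepwise_alpha < 1:
            raise PipelineError("stepwise_alpha must lie in (0, 1)")
        bad = set(self.cv_schemes) - set(ev.CV_SCHEMES)
        if bad:
            raise PipelineError(f"unknown CV schemes: {sorted(bad)}")
        bad = set(self.classifiers) - set(ev.CLASSIFIERS)
        if bad:
            raise PipelineError(f"unknown classifiers: {sorted(bad)}")
        if self.n_shuffles < 1:
            raise PipelineError("n_shuffles must be >= 1")
        self.seed = int(self.seed)


@dataclass
class PipelineReport:
    config: PipelineConfig
    feature_table: pd.DataFrame
    rsm_results: rasch.RatingScaleResults
    stepwise: StepwiseResults
    evaluated_features: list
    cv_results: dict  # (classifier, scheme) -> CVResult
    importance: Optional[ev.PermImportance]
    timings: dict

    def metrics_table(self) -> pd.DataFrame:
        rows = []
        for (clf, scheme), res in self.cv_results.items():
            m = res.metrics
            rows.append({
                "classifier": clf, "scheme": scheme, "auc": m.auc, "f1": m.f1,
                "precision": m.precision, "recall": m.recall,
                "n": res.confusion.total, "skipped_folds": res.skipped_folds,
            })
        return pd.DataFrame(rows)

    def confusion_table(self) -> pd.DataFrame:
        rows = []
        for (clf, scheme), res in self.cv_results.items():
            cm = res.confusion
            rows.append({"classifier": clf, "scheme": scheme, "tn": cm.tn,
                         "fp": cm.fp, "fn": cm.fn, "tp": cm.tp})
        return pd.DataFrame(rows)


def load_study_sessions(input_dir) -> list:
    """Read every session directory (one containing annotations.csv)."""
    input_dir = Path(input_dir)
    dirs = sorted(p.parent for p in input_dir.glob("*/annotations.csv"))
    if not dirs:
        raise PipelineError(f"no session directories under {input_dir}")
    return [read_e4_session(d) for d in dirs]


def fss_matrix_from_sessions(sessions) -> pd.DataFrame:
    rows, keys = [], []
    for session in sessions:
        for seg in session.task_segments:
            rows.append(list(seg.fss_response))
            keys.append((session.participant_id, seg.task_id))
    if not rows:
        raise PipelineError("no task segments with FSS responses")
    return pd.DataFrame(rows, columns=list(rasch.ITEM_NAMES),
                        index=pd.MultiIndex.from_tuples(
                            keys, names=["participant_id", "task_id"]))


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all stages and (optionally) write report artifacts."""
    timings = {}

    def stage(name):
        timings[name] = time.perf_counter()
        log.info("stage %s", name)

    def done(name):
        timings[name] = time.perf_counter() - timings[name]
        log.info("stage %s finished in %.2fs", name, timings[name])

    stage("ingest")
    if config.simulate is not None:
        gen_config = (syn.GeneratorConfig(seed=config.seed)
                      if config.simulate == "study1"
                      else syn.study2_config(seed=config.seed))
        bundle = syn.generate_study(gen_config)
        sessions = bundle.sessions
    else:
        sessions = load_study_sessions(config.input_dir)
    done("ingest")

    stage("trim_and_window")
    policy_map = dict(pp.TrimPolicy().trim_seconds_by_channel)
    for k, v in config.trim_overrides.items():
        policy_map[k] = float(v)
    policy = pp.TrimPolicy(policy_map)
    windows = []
    for session in sessions:
        windows.extend(pp.build_task_windows(session, policy,
                                             baseline_mode=config.baseline_mode))
    done("trim_and_window")

    stage("features")
    table = ft.build_feature_table(windows,
                                   kurtosis_excess=(config.kurtosis == "excess"))
    done("features")

    stage("measurement")
    responses = fss_matrix_from_sessions(sessions)
    rsm_results = rasch.RatingScaleModel(responses).fit()
    labels = rasch.label_flow(responses)
    key = pd.MultiIndex.from_frame(table[["participant_id", "task_id"]])
    table = table.assign(flow=labels.reindex(key).to_numpy())
    if table["flow"].isna().any():
        raise PipelineError("flow labels missing for some tasks")
    table["flow"] = table["flow"].astype(int)
    done("measurement")

    stage("selection")
    feature_cols = list(ft.FEATURE_NAMES)
    stepwise = StepwiseFlowLogit(
        table[feature_cols], table["flow"], table["participant_id"]
    ).fit(alpha=config.stepwise_alpha)
    selected = stepwise.selected_features
    if not selected:
        warnings.warn("no feature met the entry criterion; evaluating the five "
                      "smallest screening p-values instead")
        selected = list(stepwise.screen.sort_values("p_value").index[:5])
    done("selection")

    stage("evaluation")
    schemes = config.cv_schemes
    if config.simulate == "study2" or table["participant_id"].nunique() == 1:
        schemes = tuple(s for s in schemes if s != "between_participant")
        if "leave_one_out" not in schemes:
            schemes = schemes + ("leave_one_out",)
    cv_results = {}
    for clf in config.classifiers:
        for scheme in schemes:
            cv_results[(clf, scheme)] = ev.cross_validate(
                table, scheme, clf, selected, seed=config.seed)
    done("evaluation")

    stage("importance")
    importance = None
    if "logistic" in config.classifiers:
        model = ev.train_classifier("logistic", table[selected], table["flow"])
        importance = ev.permutation_importance(
            model, table[selected], table["flow"],
            n_shuffles=config.n_shuffles, seed=config.seed)
    done("importance")

    report = PipelineReport(
        config=config, feature_table=table, rsm_results=rsm_results,
        stepwise=stepwise, evaluated_features=selected,
        cv_results=cv_results, importance=importance, timings=timings,
    )
    if config.output_dir is not None:
        _write_reports(report, Path(config.output_dir))
    return report


def _write_reports(report: PipelineReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    ft.write_feature_table(report.feature_table, out / "feature_table.csv")

    res = report.rsm_results
    fs = res.fit_statistics()
    pca = res.residual_pca()
    person_rel, item_rel = res.separation_reliability()
    items = pd.DataFrame({
        "difficulty": res.item_difficulties,
        "se": res.item_se,
        "infit": fs.item_infit.reindex(res.item_difficulties.index),
        "outfit": fs.item_outfit.reindex(res.item_difficulties.index),
        "loading_first_residual": pca.loadings.reindex(res.item_difficulties.index),
    }).sort_values("difficulty")
    with open(out / "rasch_report.csv", "w") as fh:
        fh.write(f"# person_reliability,{person_rel:.6f}\n")
        fh.write(f"# item_reliability,{item_rel:.6f}\n")
        fh.write(f"# first_residual_eigenvalue,{pca.first_eigenvalue:.6f}\n")
        fh.write("# thresholds," + ",".join(f"{t:.6f}" for t in res.thresholds) + "\n")
        items.to_csv(fh)
    res.wright_map().to_csv(out / "wright_map.csv", index=False)

    report.stepwise.wald_summary(features_only=False).to_csv(out / "selection_report.csv")
    pd.DataFrame(report.stepwise.trace,
                 columns=["feature", "lrt_chi2", "df", "p_value"]
                 ).to_csv(out / "selection_trace.csv", index=False)
    report.metrics_table().to_csv(out / "cv_metrics.csv", index=False)
    report.confusion_table().to_csv(out / "confusion_matrices.csv", index=False)
    if report.importance is not None:
        report.importance.importance.to_csv(out / "importance.csv")
    try:
        from .plotting import plot_importance, plot_wright_map
        plot_wright_map(res, out / "wright_map.png")
        if report.importance is not None:
            plot_importance(report.importance, out / "importance.png")
    except Exception as exc:  # plotting must never sink a run
        log.warning("plotting failed: %s", exc)
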