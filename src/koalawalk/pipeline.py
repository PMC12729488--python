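"""End-to-end orchestration: simulate -> features -> train -> classify ->
post-process -> visits/budgets -> diel models -> report.

Each stage reads its inputs from and writes its outputs to a run directory,
so stages are independently invocable (see the ``koalawalk`` CLI). Every
output table embeds the run-config hash and seed in a leading comment line;
identical config + seed reproduces byte-identical numeric tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, io, postprocess, visits as visits_mod
from .activity import compare_vedba, fit_cyclic_activity, fit_walking_curve
from .features import extract_feature_table, vedba_seconds
from .reference import validate_report
from .simulate import (
    SimConfig,
    captive_config,
    individual_meta,
    sequence_labels_per_second,
    simulate_behaviour_sequence,
    simulate_stream,
    wild_config,
)

log = logging.getLogger("koalawalk")


@dataclass(frozen=True)
class RunConfig:
    """Every stage parameter of one pipeline run, fully serialisable."""

    seed: int = 0
    # simulation scale
    captive_individuals: int = 2
    captive_days: float = 0.25
    wild_individuals: int = 9
    wild_days: float = 0.5
    sample_rate: float = 50.0
    # features
    window_s: float = 1.0
    overlap: float = 0.5
    smooth_s: float = 2.0
    purity_threshold: float = 0.7
    # classifier
    search_budget: int = 4
    search: str = "random"
    # post-processing
    modal_half_width: int = 2
    min_run_s: int = 3
    bin_s: int = 20
    max_gap_s: float = 60.0
    # diel models
    n_harmonics: int = 4

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def captive_sim(self) -> SimConfig:
        return captive_config(
            n_individuals=self.captive_individuals,
            days_per_individual=self.captive_days,
            sample_rate=self.sample_rate, seed=self.seed,
        )

    def wild_sim(self) -> SimConfig:
        return wild_config(
            n_individuals=self.wild_individuals,
            days_per_individual=self.wild_days,
            sample_rate=self.sample_rate, seed=self.seed + 1,
        )


def _write_csv(frame: pd.DataFrame, path: Path, cfg: RunConfig,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# koalawalk config={cfg.config_hash} seed={cfg.seed}\n")
        frame.to_csv(fh, index=index)


def _read_csv(path: Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def ground_truth_bins(sim: SimConfig,
                      start_time=np.datetime64("2023-05-15T00:00:00"),
                      ) -> pd.DataFrame:
    """Oracle-label path: simulate every animal's behaviour sequence and run
    the ground-truth per-second labels through smoothing, regrouping and
    20 s binning — no signal synthesis or classification involved. Used for
    parameter-recovery checks of the post-processing chain."""
    total_s = int(sim.days_per_individual * 86_400)
    classes = tuple(sorted(sim.spec_by_name()))
    lut = np.array(classes, dtype=object)
    frames = []
    for i in range(sim.n_individuals):
        seq = simulate_behaviour_sequence(sim, i)
        labels = lut[sequence_labels_per_second(seq, total_s, classes)]
        regrouped = postprocess.regroup(postprocess.smooth_labels(labels))
        frames.append(
            postprocess.bin_20s(regrouped, start_time=start_time,
                                meta=individual_meta(sim, i))
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for role, sim in (("captive", cfg.captive_sim()), ("wild", cfg.wild_sim())):
        io.write_config_json(sim, out / f"sim_{role}.json")
        for i in range(sim.n_individuals):
            stream = simulate_stream(sim, i)
            stream.individual_id = f"{role[0]}{i + 1:02d}"
            io.write_stream(stream, out / f"stream_{role}_{i + 1:02d}.csv")
            log.info("simulated %s stream %d (%.2f days)", role, i + 1,
                     stream.duration_s / 86400)


def stage_features(cfg: RunConfig, out: Path) -> None:
    for role, overlap in (("captive", cfg.overlap), ("wild", 0.0)):
        tables = []
        for path in sorted(out.glob(f"stream_{role}_*.csv")):
            stream = io.read_stream(path)
            tables.append(
                extract_feature_table(stream, cfg.window_s, overlap,
                                      cfg.smooth_s)
            )
            if role == "wild":
                sec = vedba_seconds(stream, cfg.smooth_s)
                sec["individual_id"] = stream.individual_id
                sec["true_label"] = stream.labels[
                    :: int(stream.sample_rate)][: len(sec)]
                _write_csv(sec, out / f"vedba_{path.stem}.csv", cfg)
        frame = pd.concat(tables, ignore_index=True)
        _write_csv(frame, out / f"features_{role}.csv", cfg)
        log.info("extracted %d %s windows", len(frame), role)


def stage_train(cfg: RunConfig, out: Path) -> None:
    table = classify.training_table(
        _read_csv(out / "features_captive.csv"), cfg.purity_threshold)
    train, val, test = classify.chronological_split(table)
    best = classify.tune(train, val, search_budget=cfg.search_budget,
                         seed=cfg.seed, search=cfg.search)
    model = classify.train_forest(train, best)
    preds = classify.predict(model, test)
    cm = classify.ConfusionMatrix.from_labels(test["label"], preds)
    metrics = classify.classification_metrics(cm)
    table_out = metrics.summary().rename(
        columns={"precision": "Precision", "recall": "Recall", "f1": "F1",
                 "balanced_accuracy": "Accuracy", "prevalence": "Prevalence"}
    )
    _write_csv(table_out, out / "metrics.csv", cfg, index=True)
    # final model: retrain on all labelled data with the chosen config
    final = classify.train_forest(table, best)
    with open(out / "model.pkl", "wb") as fh:
        pickle.dump({"model": final, "config_hash": cfg.config_hash}, fh)
    log.info("tuned %s; test macro-F1 %.3f", best, metrics.macro["f1"])


def stage_classify(cfg: RunConfig, out: Path) -> None:
    with open(out / "model.pkl", "rb") as fh:
        model = pickle.load(fh)["model"]
    wild = _read_csv(out / "features_wild.csv")
    labels = classify.predict_per_second(model, wild)
    _write_csv(labels, out / "labels_per_second.csv", cfg)
    log.info("predicted %d seconds", len(labels))


def stage_post(cfg: RunConfig, out: Path) -> None:
    labels = _read_csv(out / "labels_per_second.csv")
    all_bins = []
    for path in sorted(out.glob("vedba_stream_wild_*.csv")):
        sec = _read_csv(path)
        ind = sec["individual_id"].iloc[0]
        lab = labels.loc[labels["individual_id"] == ind].sort_values("second")
        merged = sec.merge(lab[["second", "label"]], on="second", how="left")
        smoothed = postprocess.smooth_labels(
            merged["label"].to_numpy(), cfg.modal_half_width, cfg.min_run_s)
        regrouped = postprocess.regroup(smoothed)
        sim = cfg.wild_sim()
        idx = int(str(ind).lstrip("w")) - 1
        bins = postprocess.bin_20s(
            regrouped, merged, bin_s=cfg.bin_s,
            start_time=np.datetime64("2023-05-15T00:00:00"),
            meta={"individual_id": ind, **{k: v for k, v in
                  individual_meta(sim, idx).items() if k != "individual_id"}},
        )
        all_bins.append(bins)
    bins = pd.concat(all_bins, ignore_index=True)
    bins = postprocess.exclude_other(bins)
    _write_csv(bins, out / "bins.csv", cfg)
    log.info("built %d bins (Other fraction %.4f)", len(bins),
             bins.attrs.get("other_fraction", 0.0))


def stage_visits(cfg: RunConfig, out: Path) -> None:
    bins = _read_csv(out / "bins.csv")
    v = visits_mod.detect_visits(bins, cfg.max_gap_s, cfg.bin_s)
    _write_csv(v, out / "visits.csv", cfg)
    budgets = visits_mod.daily_budget(bins, cfg.bin_s)
    _write_csv(budgets, out / "budgets.csv", cfg)
    summary = visits_mod.summarise_budgets(budgets)
    rates = visits_mod.visit_rates(v, bins, cfg.bin_s)
    walk = summary["category"] == "Walking"
    summary.loc[walk, "visits_per_day_mean"] = rates["visits_per_day"].mean()
    summary.loc[walk, "minutes_per_visit_mean"] = rates["minutes_per_visit"].mean()
    _write_csv(summary, out / "budget_summary.csv", cfg)
    log.info("detected %d visits across %d budget days", len(v),
             budgets["date"].nunique() if len(budgets) else 0)


def stage_model(cfg: RunConfig, out: Path) -> None:
    bins = _read_csv(out / "bins.csv")
    act = fit_cyclic_activity(bins, n_harmonics=cfg.n_harmonics)
    _write_csv(act.hourly_table(), out / "hourly_activity.csv", cfg)
    summaries = {"activity": act.summary()}
    try:
        walk = fit_walking_curve(bins)
        _write_csv(walk.hourly_table(), out / "hourly_walking.csv", cfg)
        summaries["walking"] = walk.summary()
    except ValueError as exc:
        log.warning("walking curve skipped: %s", exc)
    try:
        ranks = compare_vedba(bins)
        _write_csv(ranks.pairwise, out / "vedba_pairwise.csv", cfg)
        summaries["vedba_ranks"] = ranks.summary()
    except ValueError as exc:
        log.warning("VeDBA comparison skipped: %s", exc)
    (out / "model_summaries.json").write_text(
        json.dumps({"config_hash": cfg.config_hash, **summaries}, indent=1))


def stage_report(cfg: RunConfig, out: Path) -> pd.DataFrame:
    metrics_path = out / "metrics.csv"
    metrics = (
        _read_csv(metrics_path, index_col=0).rename(
            columns={"Precision": "precision", "Recall": "recall", "F1": "f1",
                     "Accuracy": "accuracy", "Prevalence": "prevalence"})
        if metrics_path.exists() else None
    )
    budget_path = out / "budget_summary.csv"
    budgets = _read_csv(budget_path) if budget_path.exists() else None
    checklist = validate_report(metrics, budgets)
    _write_csv(checklist, out / "validation.csv", cfg)
    return checklist


STAGES = {
    "simulate": stage_simulate,
    "features": stage_features,
    "train": stage_train,
    "classify": stage_classify,
    "post": stage_post,
    "visits": stage_visits,
    "model": stage_model,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, out_dir) -> Path:
    """Execute every stage in order; halts with a stage-tagged error while
    preserving partial outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps({"hash": cfg.config_hash, **cfg.to_dict()}, indent=1))
    for name, fn in STAGES.items():
        log.info("=== stage %s ===", name)
        try:
            fn(cfg, out)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    return out
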