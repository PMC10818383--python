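"""Reproducible study orchestration: generate -> preprocess -> label ->
featurize -> classify -> identify parameters -> report.

Every run is a pure function of its :class:`RunConfig` and seed: all
randomness flows through one root seed, stage outputs are written with
deterministic serialization (sorted JSON keys, plain CSV), and each output
carries the run's config hash, so reruns with the same configuration are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf_mod
from . import cohort as cohort_mod
from . import features as feat_mod
from . import labeling as label_mod
from . import preprocess as prep_mod
from .preprocess import AveragedEvent
from .therapy import (aggregate_agreement, compare_to_ground_truth,
                      extract_therapy_params)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full study run."""

    out_dir: str = "run_out"
    seed: int = 0
    # cohort
    use_study_cohort: bool = False
    n_healthy: int = 4
    n_patients: int = 0
    positions: tuple[float, ...] = (-4.0, 0.0)
    max_current: float | None = 25.0
    noise_scale: float = 1.0
    # experiment grid
    datasets: tuple[str, ...] = ("ALL",)
    feature_sets: tuple[str, ...] = ("SET-OBSERVE", "SET-PREDICT")
    class_counts: tuple[int, ...] = (2, 3)
    models: tuple[str, ...] = ("RF",)
    search_iterations: int = 50

    @property
    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # identical studies hash equal anywhere
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:10]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("positions", "datasets", "feature_sets", "class_counts",
                    "models"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _write_json(path: Path, obj: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def cohort_spec_for(config: RunConfig) -> cohort_mod.CohortSpec:
    if config.use_study_cohort:
        return cohort_mod.study_cohort_spec()
    return cohort_mod.demo_cohort_spec(
        n_healthy=config.n_healthy, n_patients=config.n_patients,
        positions=config.positions, max_current=config.max_current,
        noise_scale=config.noise_scale)


# ---------------------------------------------------------------------------
# event container on disk (intermediate artifact between stages)
# ---------------------------------------------------------------------------

def save_events(events: list[AveragedEvent], path: str | Path) -> None:
    """Persist averaged events (arrays in .npz, keys/metas in .json)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n_e, n_a = prep_mod.N_EMG_CROP, prep_mod.N_ACC_CROP
    zeros_e, zeros_a = np.zeros(n_e), np.zeros(n_a)
    arrays = {
        "emg_double": np.stack([
            ev.emg_double_avg if ev.emg_double_avg is not None else zeros_e
            for ev in events]),
        "acc_single": np.stack([
            ev.acc_single_avg if ev.acc_single_avg is not None else zeros_a
            for ev in events]),
        "acc_double": np.stack([
            ev.acc_double_avg if ev.acc_double_avg is not None else zeros_a
            for ev in events]),
        "acc_diff": np.stack([
            ev.acc_diff if ev.acc_diff is not None else zeros_a
            for ev in events]),
        "valid": np.array([ev.valid for ev in events]),
    }
    np.savez(path.with_suffix(".npz"), **arrays)
    keys = [{
        "subject_id": ev.subject_id, "group": ev.group,
        "position": ev.position, "day": ev.day, "current": ev.current,
        "muscle": ev.muscle, "invalid_reason": ev.invalid_reason,
        "meta": dataclasses.asdict(ev.meta) if ev.meta else None,
    } for ev in events]
    _write_json(path.with_suffix(".json"), {"events": keys})


def load_events(path: str | Path) -> list[AveragedEvent]:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    keys = json.loads(path.with_suffix(".json").read_text())["events"]
    events = []
    for i, k in enumerate(keys):
        valid = bool(arrays["valid"][i])
        meta = (cohort_mod.SubjectMeta(**k["meta"]) if k["meta"] else None)
        events.append(AveragedEvent(
            subject_id=k["subject_id"], group=k["group"],
            position=k["position"], day=k["day"], current=k["current"],
            muscle=k["muscle"], meta=meta,
            emg_double_avg=arrays["emg_double"][i] if valid else None,
            acc_single_avg=arrays["acc_single"][i] if valid else None,
            acc_double_avg=arrays["acc_double"][i] if valid else None,
            acc_diff=arrays["acc_diff"][i] if valid else None,
            valid=valid, invalid_reason=k["invalid_reason"],
        ))
    return events


# ---------------------------------------------------------------------------
# therapy-parameter comparison for one experiment
# ---------------------------------------------------------------------------

def _measurement_grids(labels: pd.DataFrame, scheme: int):
    """Yield (measurement_id, subject_id, grid) per (subject, day)."""
    col = f"label_{scheme}"
    for (subj, day), sub in labels.groupby(["subject_id", "day"]):
        grid = sub.rename(columns={col: "label"})[
            ["position", "current_ma", "muscle", "label", "valid"]]
        yield f"{subj}_day{day}", str(subj), grid


def therapy_agreement(labels: pd.DataFrame, table: pd.DataFrame,
                      folds: list[clf_mod.FoldResult], scheme: int,
                      margin: float = 5.0) -> tuple[list[dict], dict]:
    """Compare EMG-derived and ML-derived therapy parameters.

    Ground-truth grids come from the EMG labels; predicted grids replace
    each valid event's label with the LOSO prediction of the experiment.
    Returns the per-measurement rows and the aggregate proportions.
    """
    pred = pd.concat([f.predictions for f in folds]).sort_index()
    pred_table = table.loc[pred.index].copy()
    pred_table["label"] = pred.astype(int)
    covered = set(pred_table.subject_id)
    rows = []
    for meas_id, subj, gt_grid in _measurement_grids(labels, scheme):
        if subj not in covered:
            continue  # subject outside this experiment's dataset
        day = int(meas_id.rsplit("day", 1)[1])
        sub = pred_table[(pred_table.subject_id == subj)
                         & (pred_table.day == day)]
        ml_grid = sub[["position", "current_ma", "muscle", "label"]].assign(
            valid=True)
        if ml_grid.empty:
            continue
        single_pos = gt_grid.position.nunique() == 1
        gt = extract_therapy_params(gt_grid, meas_id,
                                    single_position=single_pos)
        ml = extract_therapy_params(ml_grid, meas_id,
                                    single_position=single_pos)
        rows.append(compare_to_ground_truth(gt, ml, margin=margin))
    return rows, aggregate_agreement(rows)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def run_full_study(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``out_dir``.

    Produces: sessions' exclusion report, labels.csv, features.csv, one
    result directory per experiment config (folds.csv, summary.json,
    confusion.csv, predictions.csv), therapy_params agreement.json and a
    top-level report.json. Idempotent for a fixed config and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    _write_json(out / "run.json",
                {"config": dataclasses.asdict(config), "config_hash": chash})

    spec = cohort_spec_for(config)
    sessions, _registry = cohort_mod.generate_cohort(spec, config.seed)
    events, exclusions = prep_mod.preprocess_cohort(sessions)
    _write_json(out / "exclusions.json",
                {**exclusions, "config_hash": chash})

    labels = label_mod.label_events(events)
    labels.to_csv(out / "labels.csv", index=False)
    table = feat_mod.assemble_feature_table(events, labels)
    table.to_csv(out / "features.csv", index=False)
    _write_json(out / "feature_registry.json", feat_mod.feature_registry())

    grid = clf_mod.experiment_grid(
        datasets=config.datasets, feature_sets=config.feature_sets,
        class_counts=config.class_counts, models=config.models,
        search_iterations=config.search_iterations, seed=config.seed)

    report: dict = {"config_hash": chash, "n_events": int(len(table)),
                    "exclusions": exclusions, "experiments": {}}
    for exp in grid:
        folds, summary = clf_mod.run_experiment(table, exp)
        exp_dir = out / "results" / exp.config_id
        exp_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([{
            "test_subject": f.test_subject,
            "balanced_accuracy": f.balanced_accuracy,
            "best_params": json.dumps(f.best_params, sort_keys=True),
        } for f in folds]).to_csv(exp_dir / "folds.csv", index=False)
        pd.DataFrame(summary.confusion_sum,
                     index=summary.classes, columns=summary.classes
                     ).to_csv(exp_dir / "confusion.csv")
        pred = pd.concat([f.predictions for f in folds]).sort_index()
        pred_df = table.loc[pred.index, feat_mod.KEY_COLUMNS].copy()
        pred_df["y_true"] = table.loc[pred.index, f"label_{exp.n_classes}"]
        pred_df["y_pred"] = pred.astype(int)
        pred_df.to_csv(exp_dir / "predictions.csv", index=False)

        rows, agg = therapy_agreement(labels, table, folds, exp.n_classes)
        pd.DataFrame(rows).to_csv(exp_dir / "therapy_params.csv", index=False)
        _write_json(exp_dir / "summary.json", {
            "config": dataclasses.asdict(exp),
            "config_hash": chash,
            "summary": summary.to_dict(),
            "therapy_agreement": agg,
        })
        report["experiments"][exp.config_id] = {
            "mean_balanced_accuracy": summary.mean_balanced_accuracy,
            "std_balanced_accuracy": summary.std_balanced_accuracy,
            "therapy_agreement": agg,
        }
    _write_json(out / "report.json", report)
    return report
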