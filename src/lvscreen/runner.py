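"""Pipeline orchestration: simulate -> delineate -> extract -> train -> evaluate.

Each stage reads its inputs from, and writes its artifacts to, the run
directory, so any stage can be skipped when its input artifacts already
exist. Every artifact carries the configuration hash for provenance.
"""

from __future__ import annotations

import dataclasses
import logging
import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import features as ft
from . import pipeline as ml
from .delineate import delineate_record
from .errors import LVScreenError, StageError
from .io import (RunConfig, read_cohort_csv, read_record_csv, write_cohort_csv,
                 write_json, write_record_csv)
from .synth import generate_study

log = logging.getLogger("lvscreen")


def _records_dir(out: Path) -> Path:
    return out / "records"


def _load_records(out: Path) -> list:
    rdir = _records_dir(out)
    if not rdir.is_dir():
        raise StageError(f"missing records directory {rdir}; "
                         "run or un-skip the simulate stage")
    paths = sorted(rdir.glob("*.csv"))
    if not paths:
        raise StageError(f"no record CSVs in {rdir}")
    return [read_record_csv(p) for p in paths]


def stage_simulate(config: RunConfig, out: Path) -> None:
    cohort_cfg = config.cohort_config()
    profiles, records = generate_study(cohort_cfg)
    write_cohort_csv(profiles, out / "cohort.csv")
    rdir = _records_dir(out)
    rdir.mkdir(exist_ok=True)
    truth = {}
    for rec in records:
        write_record_csv(rec, rdir / f"{rec.subject_id}.csv")
        truth[rec.subject_id] = rec.ground_truth
    write_json({"config_hash": config.hash(), "truth": truth},
               out / "ground_truth.json")
    log.info("simulate: %d subjects, %d records", len(profiles), len(records))


def stage_delineate(config: RunConfig, out: Path) -> None:
    records = _load_records(out)
    fiducials = {}
    for rec in records:
        try:
            _, fid = delineate_record(rec)
        except LVScreenError as exc:
            fiducials[rec.subject_id] = {"error": str(exc)}
            continue
        d = {k: v for k, v in dataclasses.asdict(fid).items()
             if k not in ("r_indices", "rr_ms")}
        d["n_beats"] = int(len(fid.r_indices))
        d["window_ms"] = list(fid.window_ms)
        fiducials[rec.subject_id] = d
    write_json({"config_hash": config.hash(), "fiducials": fiducials},
               out / "fiducials.json")
    log.info("delineate: %d records", len(fiducials))


def stage_extract(config: RunConfig, out: Path) -> None:
    cohort_path = out / "cohort.csv"
    if not cohort_path.exists():
        raise StageError(f"missing cohort table {cohort_path}")
    records = _load_records(out)
    covariates = read_cohort_csv(cohort_path)
    table = ft.extract_cohort(records, covariates, seed=config.seed)
    table.df.to_csv(out / "features.csv", index=False)
    meta = dict(table.metadata)
    meta["config_hash"] = config.hash()
    meta["columns"] = list(table.df.columns)
    write_json(meta, out / "features.schema.json")
    log.info("extract: %d rows, %d excluded", len(table.df), table.n_excluded)


def stage_train(config: RunConfig, out: Path) -> None:
    fpath = out / "features.csv"
    if not fpath.exists():
        raise StageError(f"missing feature table {fpath}; "
                         "run or un-skip the extract stage")
    table = pd.read_csv(fpath)
    endpoint = ml.EndpointRule.from_id(
        config.train.get("endpoint", "below_40"))
    archs = config.train.get("architectures", ml.ARCHITECTURES)
    split_seed = config.train.get("split_seed", ml.DEFAULT_SPLIT_SEED)
    run = ml.run_training(table, endpoint, architectures=archs,
                          seed=config.seed, split_seed=split_seed)
    mdir = out / "models"
    mdir.mkdir(exist_ok=True)
    with open(mdir / "bundle.pkl", "wb") as fh:
        pickle.dump(run, fh)
    write_json({
        "config_hash": config.hash(),
        "endpoint": endpoint.endpoint_id,
        "seed": config.seed,
        "split_seed": split_seed,
        "selection": {"by_lasso": run.selection.by_lasso,
                      "by_gain": run.selection.by_gain,
                      "by_shap": run.selection.by_shap,
                      "union": run.selection.union},
        "models": {a: {"threshold": m.threshold, **m.metadata}
                   for a, m in run.models.items()},
        "ensemble_threshold": run.ensemble.threshold,
        "n_train": len(run.train), "n_test": len(run.test),
    }, mdir / "metadata.json")
    # per-subject test-set predictions for the evaluate stage
    preds = pd.DataFrame({"subject_id": run.test["subject_id"],
                          "label": run.test["label"]})
    for arch, model in run.models.items():
        preds[f"prob_{arch}"] = model.predict_proba(run.test)
        preds[f"call_{arch}"] = model.predict(run.test)
    preds["prob_ensemble"] = run.ensemble.predict_proba(run.test)
    preds["call_ensemble"] = run.ensemble.predict(run.test)
    preds.to_csv(out / "test_predictions.csv", index=False)
    log.info("train: %d models, endpoint %s", len(run.models),
             endpoint.endpoint_id)


def stage_evaluate(config: RunConfig, out: Path) -> None:
    ppath = out / "test_predictions.csv"
    if not ppath.exists():
        raise StageError(f"missing predictions {ppath}; "
                         "run or un-skip the train stage")
    preds = pd.read_csv(ppath)
    y = preds["label"].to_numpy()
    report: dict = {"config_hash": config.hash(), "models": {}}
    arch_cols = [c[5:] for c in preds.columns if c.startswith("prob_")]
    for arch in arch_cols:
        calls = preds[f"call_{arch}"].to_numpy()
        scores = preds[f"prob_{arch}"].to_numpy()
        rep = ev.external_style_report(y, calls, extra={"seed": config.seed})
        try:
            roc = ev.roc_auc(y, scores, n_boot=500, seed=config.seed)
            rep["auc"] = roc.auc
            rep["auc_ci"] = [roc.ci_low, roc.ci_high]
        except LVScreenError:
            rep["auc"] = None
        report["models"][arch] = rep
    write_json(report, out / "report.json")
    log.info("evaluate: %d models reported", len(arch_cols))


_STAGE_FNS = {
    "simulate": stage_simulate,
    "delineate": stage_delineate,
    "extract": stage_extract,
    "train": stage_train,
    "evaluate": stage_evaluate,
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    for stage in _STAGE_FNS:
        if stage in config.stages:
            log.info("running stage %s", stage)
            _STAGE_FNS[stage](config, out)
    return out
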