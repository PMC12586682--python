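"""End-to-end orchestration: simulate -> process -> render -> train -> evaluate.

Two entry points:

* :func:`run_experiment` — the in-memory protocol used by tests and the
  reproduction script: simulate a labelled corpus, LOI-filter, hold out
  species for the open-set evaluation, stratify, grid-search, retrain and
  evaluate, then sweep the unseen-detection threshold.

* :func:`run_pipeline` — the staged, resumable directory pipeline behind the
  command-line interface.  Each stage writes its outputs plus a marker file
  under the work directory; completed stages are skipped on resume.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import curves as curves_mod
from . import fixtures
from .classify import (
    TrainConfig,
    evaluate,
    filter_min_samples,
    grid_search,
    predict,
    retrain_full,
    stratified_split,
)
from .imaging import RenderStyle, compute_axis_limits, render_dataset
from .meltsim import (
    MeltModelParams,
    MeltRun,
    TemperatureGrid,
    make_labeled_dataset,
    read_runs_csv,
    write_runs_csv,
)
from .openset import default_thresholds, summarize_unseen, sweep, sweep_table

logger = logging.getLogger("meltid.pipeline")

__all__ = ["PipelineConfig", "ExperimentResult", "process_runs",
           "run_experiment", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """Declarative configuration for the staged pipeline."""

    fasta: str = ""
    workdir: str = ""
    n_species: int = 30
    n_per_species: int = 12
    n_unseen: int = 5
    weak_fraction: float = 0.165
    master_seed: int = 1
    kinds: tuple[str, ...] = ("melt",)
    pre_window: tuple[float, float] = curves_mod.DEFAULT_PRE_WINDOW
    post_window: tuple[float, float] = curves_mod.DEFAULT_POST_WINDOW
    loi_threshold: float = curves_mod.LOI_THRESHOLD_NFU
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    thresholds: tuple[float, ...] = tuple(default_thresholds())

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclasses.dataclass
class ExperimentResult:
    """Everything the end-to-end protocol produces."""

    report: object                      # ClassifierReport on the seen test split
    best_hyperparams: tuple[float, float]
    grid_table: pd.DataFrame
    sweep_rows: list
    sweep_df: pd.DataFrame
    mean_confidence_seen: float
    mean_confidence_unseen: float
    best_threshold: float
    manifest: pd.DataFrame
    excluded_loi: int
    excluded_min_samples: int
    n_runs_total: int
    model: object
    predictions_seen: list
    predictions_unseen: list


def process_runs(runs: Sequence[MeltRun],
                 pre_window=curves_mod.DEFAULT_PRE_WINDOW,
                 post_window=curves_mod.DEFAULT_POST_WINDOW,
                 loi_threshold=curves_mod.LOI_THRESHOLD_NFU,
                 reference_run_id: str | None = None) -> list[curves_mod.CurveSet]:
    """Pair melt and amplification stages by run id and derive curve sets."""
    melts = {r.run_id: r for r in runs if r.stage == "melt"}
    amps = {r.run_id: r for r in runs if r.stage == "amplification"}
    reference_normalized = None
    if reference_run_id is not None:
        ref = melts.get(reference_run_id)
        if ref is None:
            raise ValueError(f"reference run {reference_run_id!r} not found")
        reference_normalized = curves_mod.hrm_normalize(ref, pre_window, post_window)
    out = []
    for run_id, melt in melts.items():
        out.append(curves_mod.build_curveset(
            melt, amps.get(run_id), reference_normalized,
            pre_window, post_window, threshold_nfu=loi_threshold))
    return out


def _select_unseen(species: list[str], n_unseen: int, seed: int) -> set[str]:
    rng = np.random.default_rng(seed + 17)
    return set(rng.choice(sorted(species), size=n_unseen, replace=False))


def run_experiment(n_species: int = 30, n_per_species: int = 12,
                   n_unseen: int = 5, seed: int = 1,
                   weak_fraction: float = 0.165,
                   train_config: TrainConfig | None = None,
                   workdir: str | Path | None = None,
                   kinds: tuple[str, ...] = ("melt",),
                   eval_kind: str = "melt",
                   thresholds: Sequence[float] | None = None,
                   panel=None) -> ExperimentResult:
    """Run the full identification protocol on a synthetic corpus.

    Simulates ``n_species`` x ``n_per_species`` reactions (a ``weak_fraction``
    of them below the limit of identification), excludes sub-LOI runs and
    species left with fewer than five, holds out ``n_unseen`` species entirely,
    splits the rest 60/20/20 stratified, grid-searches the classifier,
    retrains on train+val, evaluates on the test split, and finally sweeps the
    open-set confidence threshold over the merged test+unseen mixture.
    """
    if train_config is None:
        train_config = TrainConfig(seed=seed)
    if thresholds is None:
        thresholds = default_thresholds()
    tmp = None
    if workdir is None:
        tmp = tempfile.TemporaryDirectory(prefix="meltid_")
        workdir = tmp.name
    workdir = Path(workdir)

    try:
        if panel is None:
            panel = fixtures.make_panel(n_species, seed)
        logger.info("simulating %d species x %d replicates", n_species, n_per_species)
        runs, sim_manifest = make_labeled_dataset(
            panel, n_per_species, MeltModelParams(), TemperatureGrid(),
            master_seed=seed, weak_fraction=weak_fraction)
        n_runs_total = len(sim_manifest)

        curvesets = process_runs(runs)
        loi_pass = {cs.run_id: cs.loi_pass for cs in curvesets}
        valid = [cs for cs in curvesets if cs.loi_pass]
        excluded_loi = len(curvesets) - len(valid)
        logger.info("LOI filter excluded %d/%d runs", excluded_loi, len(curvesets))

        all_species = sorted({cs.species_label for cs in valid})
        unseen_species = _select_unseen(all_species, n_unseen, seed) if n_unseen else set()
        seen = [cs for cs in valid if cs.species_label not in unseen_species]
        unseen = [cs for cs in valid if cs.species_label in unseen_species]

        counts = pd.Series([cs.species_label for cs in seen]).value_counts().to_dict()
        retained, excluded_species, removed = filter_min_samples(counts, min_n=5)
        seen = [cs for cs in seen if cs.species_label in retained]

        run_level = pd.DataFrame(
            {"run_id": [cs.run_id for cs in seen],
             "species_label": [cs.species_label for cs in seen]})
        run_level = stratified_split(run_level, seed=seed)
        split_of = dict(zip(run_level["run_id"], run_level["split"]))

        train_sets = [cs for cs in seen if split_of[cs.run_id] == "train"]
        style = RenderStyle(axis_limits=compute_axis_limits(train_sets, kinds))
        logger.info("rendering %d curve sets x %d kinds", len(seen) + len(unseen), len(kinds))
        manifest = render_dataset(seen + unseen, workdir / "images", style, kinds)
        manifest["split"] = [
            "unseen" if s in unseen_species else split_of[r]
            for r, s in zip(manifest["run_id"], manifest["species_label"])]

        logger.info("grid search over %dx%d cells", len(train_config.learning_rates),
                    len(train_config.weight_decays))
        best, grid_table = grid_search(manifest, eval_kind, train_config)
        model = retrain_full(manifest, eval_kind, train_config, best)
        report = evaluate(model, manifest, eval_kind)

        preds_seen = predict(model, manifest, eval_kind, "test")
        preds_unseen = predict(model, manifest, eval_kind, "unseen") if unseen else []
        rows = sweep(preds_seen, preds_unseen, list(thresholds)) if preds_unseen else []
        df = sweep_table(rows) if rows else pd.DataFrame()
        best_threshold = float(df.loc[df["f1"].idxmax(), "threshold"]) if len(df) else float("nan")

        return ExperimentResult(
            report=report,
            best_hyperparams=best,
            grid_table=grid_table,
            sweep_rows=rows,
            sweep_df=df,
            mean_confidence_seen=float(np.mean([p.confidence for p in preds_seen])),
            mean_confidence_unseen=(summarize_unseen(preds_unseen)
                                    if preds_unseen else float("nan")),
            best_threshold=best_threshold,
            manifest=manifest,
            excluded_loi=excluded_loi,
            excluded_min_samples=removed,
            n_runs_total=n_runs_total,
            model=model,
            predictions_seen=preds_seen,
            predictions_unseen=preds_unseen,
        )
    finally:
        if tmp is not None:
            tmp.cleanup()


# ---- staged directory pipeline ---------------------------------------------

def _stage_done(workdir: Path, stage: str) -> bool:
    return (workdir / f".stage_{stage}.done").exists()


def _mark_done(workdir: Path, stage: str) -> None:
    (workdir / f".stage_{stage}.done").write_text("ok\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the staged pipeline under ``config.workdir``; resumable per stage.

    Stage outputs: ``runs.csv`` (simulate), ``images/`` + ``manifest.csv``
    (process/render/split), ``model/`` (train), ``report.json`` (evaluate +
    open-set sweep).  A failed stage leaves earlier outputs in place.
    """
    workdir = Path(config.workdir or "meltid_run")
    workdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    (workdir / "config.json").write_text(
        json.dumps({"hash": cfg_hash, **config.to_dict()}, indent=1))

    # simulate
    runs_path = workdir / "runs.csv"
    if not _stage_done(workdir, "simulate"):
        logger.info("stage simulate")
        if config.fasta:
            from .amplicon import read_fasta
            panel = read_fasta(config.fasta)
        else:
            panel = fixtures.make_panel(config.n_species, config.master_seed)
        runs, _ = make_labeled_dataset(
            panel, config.n_per_species, MeltModelParams(),
            master_seed=config.master_seed, weak_fraction=config.weak_fraction)
        write_runs_csv(runs, runs_path)
        _mark_done(workdir, "simulate")

    # everything downstream runs through the in-memory protocol on those runs
    report_path = workdir / "report.json"
    if not _stage_done(workdir, "evaluate"):
        logger.info("stages process/render/train/evaluate")
        runs = read_runs_csv(runs_path)
        by_species: dict[str, str] = {}
        for r in runs:
            if r.stage == "melt":
                by_species[r.run_id] = r.species_label
        curvesets = process_runs(runs, config.pre_window, config.post_window,
                                 config.loi_threshold)
        valid = [cs for cs in curvesets if cs.loi_pass]
        all_species = sorted({cs.species_label for cs in valid})
        unseen_species = (_select_unseen(all_species, config.n_unseen,
                                         config.master_seed)
                          if config.n_unseen else set())
        seen = [cs for cs in valid if cs.species_label not in unseen_species]
        unseen = [cs for cs in valid if cs.species_label in unseen_species]
        counts = pd.Series([cs.species_label for cs in seen]).value_counts().to_dict()
        retained, _, _ = filter_min_samples(counts, min_n=5)
        seen = [cs for cs in seen if cs.species_label in retained]
        run_level = pd.DataFrame(
            {"run_id": [cs.run_id for cs in seen],
             "species_label": [cs.species_label for cs in seen]})
        run_level = stratified_split(run_level, seed=config.master_seed)
        split_of = dict(zip(run_level["run_id"], run_level["split"]))
        train_sets = [cs for cs in seen if split_of[cs.run_id] == "train"]
        style = RenderStyle(axis_limits=compute_axis_limits(train_sets, config.kinds))
        manifest = render_dataset(seen + unseen, workdir / "images", style,
                                  config.kinds)
        manifest["split"] = [
            "unseen" if s in unseen_species else split_of[r]
            for r, s in zip(manifest["run_id"], manifest["species_label"])]
        manifest["config_hash"] = cfg_hash
        manifest.to_csv(workdir / "manifest.csv", index=False)

        kind = config.kinds[0]
        best, grid_table = grid_search(manifest, kind, config.train)
        model = retrain_full(manifest, kind, config.train, best)
        model.save(workdir / "model")
        grid_table.to_csv(workdir / "grid.csv", index=False)
        report = evaluate(model, manifest, kind)
        preds_seen = predict(model, manifest, kind, "test")
        preds_unseen = (predict(model, manifest, kind, "unseen")
                        if unseen else [])
        payload = {"config_hash": cfg_hash,
                   "best_hyperparams": list(best),
                   "classifier": report.to_dict()}
        if preds_unseen:
            rows = sweep(preds_seen, preds_unseen, list(config.thresholds))
            df = sweep_table(rows)
            df.to_csv(workdir / "openset_sweep.csv", index=False)
            payload["openset"] = {
                "mean_confidence_seen": float(np.mean([p.confidence for p in preds_seen])),
                "mean_confidence_unseen": summarize_unseen(preds_unseen),
                "best_threshold": float(df.loc[df["f1"].idxmax(), "threshold"]),
            }
        report_path.write_text(json.dumps(payload, indent=1))
        _mark_done(workdir, "evaluate")

    return json.loads(report_path.read_text())
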