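"""End-to-end orchestration: config, seed derivation, staged execution.

The whole chain — simulate (or ingest) -> preprocess -> segment -> extract
-> select -> LOSO classify -> evaluate — runs off a single
:class:`RunConfig`.  All randomness derives from the one top-level seed via
``numpy.random.SeedSequence`` spawning, so a rerun with the same config is
bit-identical; every written artifact carries the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .classify import CLASSIFIER_NAMES, ClassifierSpec, default_bank
from .evaluate import (EvaluationResult, correctness_matrix, posthoc_pairwise,
                       run_loso, summarize)
from .features import FeatureMatrix, FeatureRegistry, build_matrix, default_registry
from .preprocess import Recording, preprocess
from .segment import StepSegment, segment_recording
from .select import SelectionResult, mrmr_rank, rf_importance_top, sequential_select

logger = logging.getLogger(__name__)

SELECTION_METHODS = ("mrmr", "sfs", "sbs", "rf_importance", "none")


class StageError(RuntimeError):
    """An error raised by a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, serializable round-trip."""

    seed: int = 0
    # cohort
    n_per_group: int = 29
    recordings_per_subject: int = 2
    # sampling / filtering
    fs: float = 100.0
    cutoff: float = 20.0
    order: int = 4
    causal: bool = False
    # segmentation
    pos_k: float = 0.5
    neg_k: float = 0.5
    # selection
    selection_method: str = "mrmr"
    n_features: int = 15
    nested_selection: bool = False
    # classification
    classifiers: Tuple[str, ...] = CLASSIFIER_NAMES
    knn_k: int = 49
    rf_trees: int = 100
    rf_repeats: int = 11
    # evaluation
    vote_tie: str = "PD"
    alpha: float = 0.01
    posthoc_method: str = "dunn"

    def __post_init__(self) -> None:
        self.classifiers = tuple(self.classifiers)
        unknown = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ValueError(f"unknown classifier(s): {sorted(unknown)}")
        if self.selection_method not in SELECTION_METHODS:
            raise ValueError(f"unknown selection method {self.selection_method!r}")
        if self.vote_tie not in ("PD", "control"):
            raise ValueError("vote_tie must be 'PD' or 'control'")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["classifiers"] = list(d["classifiers"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        d = asdict(self)
        d["classifiers"] = list(d["classifiers"])
        return hashlib.sha1(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def derive_seeds(seed: int, n: int) -> List[int]:
    """Child seeds (each < 2**31) derived from one top-level seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def _bank(config: RunConfig) -> List[ClassifierSpec]:
    bank_seed = derive_seeds(config.seed, 3)[2]
    all_specs = {s.name: s for s in default_bank(
        seed=bank_seed, knn_k=config.knn_k,
        rf_trees=config.rf_trees, rf_repeats=config.rf_repeats)}
    return [all_specs[name] for name in config.classifiers]


def select_features(fm: FeatureMatrix, config: RunConfig,
                    spec: Optional[ClassifierSpec] = None) -> SelectionResult:
    """Dispatch to the configured selection method."""
    sel_seed = derive_seeds(config.seed, 3)[1]
    method = config.selection_method
    if method == "none":
        return SelectionResult(method="mRMR", selected=list(fm.feature_names),
                               criterion_trace=[])
    if method == "mrmr":
        return mrmr_rank(fm, config.n_features)
    if method == "rf_importance":
        return rf_importance_top(fm, n=config.n_features, seed=sel_seed)
    if spec is None:
        spec = ClassifierSpec("lda")
    direction = "forward" if method == "sfs" else "backward"
    return sequential_select(fm, spec, direction=direction, seed=sel_seed,
                             max_features=config.n_features if method == "sfs" else None)


def segment_cohort(recordings: Sequence[object], config: RunConfig) -> List[StepSegment]:
    """Preprocess + segment a list of recordings (raw or simulated)."""
    steps: List[StepSegment] = []
    for item in recordings:
        rec: Recording = item.recording if isinstance(item, synthetic.SimulatedRecording) else item
        uni = preprocess(rec, fs=config.fs, cutoff=config.cutoff,
                         order=config.order, causal=config.causal)
        steps.extend(segment_recording(uni, pos_k=config.pos_k, neg_k=config.neg_k))
    return steps


def run_pipeline(config: RunConfig,
                 recordings: Optional[Sequence[object]] = None,
                 outdir: Optional[Path] = None,
                 profiles=None,
                 registry: Optional[FeatureRegistry] = None) -> Dict[str, object]:
    """Execute the full chain and return a report bundle.

    ``recordings=None`` simulates a cohort per the config; otherwise pass
    Recording or SimulatedRecording objects.  With ``outdir`` set, the
    feature matrix, selection, predictions, per-classifier metrics and the
    comparison are written as CSV/JSON, each stamped with the config hash.

    The report dict holds: ``feature_matrix``, ``selection``,
    ``predictions``, ``evaluations`` (classifier -> EvaluationResult),
    ``comparison`` and provenance (``config_hash``, stage wall times).
    """
    t_start = time.time()
    timing: Dict[str, float] = {}
    chash = config.hash()

    def stage(name, fn):
        t0 = time.time()
        try:
            out = fn()
        except Exception as exc:
            raise StageError(name, exc) from exc
        timing[name] = time.time() - t0
        logger.info("stage %-10s %6.2f s", name, timing[name])
        return out

    if recordings is None:
        def _simulate():
            sim_seed = derive_seeds(config.seed, 3)[0]
            recs, meta = synthetic.simulate_cohort(
                n_per_group=config.n_per_group, profiles=profiles,
                recordings_per_subject=config.recordings_per_subject,
                seed=sim_seed)
            return recs
        recordings = stage("simulate", _simulate)

    steps = stage("segment", lambda: segment_cohort(recordings, config))
    fm = stage("extract", lambda: build_matrix(steps, registry))

    bank = _bank(config)
    if config.nested_selection:
        # per-fold re-selection: leakage-free variant
        from .evaluate import loso_folds
        selection = None

        def _nested():
            frames = []
            for fold_id, (tr, te) in enumerate(loso_folds(fm)):
                train = fm.rows(tr)
                sel = select_features(train, config)
                names = sel.selected
                from .classify import fit_predict, rf_repeated
                for spec in bank:
                    tr_s, te_s = train.subset(names), fm.rows(te).subset(names)
                    if spec.name == "random_forest" and spec.params.get("n_repeats", 1) > 1:
                        frames.append(rf_repeated(spec, tr_s, te_s, fold=fold_id))
                    else:
                        frames.append(fit_predict(spec, tr_s, te_s, fold=fold_id))
            return pd.concat(frames, ignore_index=True)
        preds = stage("classify", _nested)
    else:
        selection = stage("select", lambda: select_features(fm, config))
        preds = stage("classify",
                      lambda: run_loso(fm.subset(selection.selected), bank))

    evaluations = stage("evaluate", lambda: {
        clf: summarize(g, tie=config.vote_tie)
        for clf, g in preds.groupby("classifier")})
    comparison = stage("compare", lambda: posthoc_pairwise(
        correctness_matrix(preds, level="step"),
        alpha=config.alpha, method=config.posthoc_method)
        if len(config.classifiers) >= 2 else None)

    report = {
        "config_hash": chash,
        "seed": config.seed,
        "n_steps": fm.n_steps,
        "n_subjects": int(np.unique(fm.subject_ids).size),
        "feature_matrix": fm,
        "selection": selection,
        "predictions": preds,
        "evaluations": evaluations,
        "comparison": comparison,
        "stage_seconds": timing,
        "total_seconds": time.time() - t_start,
    }
    if outdir is not None:
        _write_report(report, config, Path(outdir))
    return report


def _write_report(report: Dict[str, object], config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    chash = report["config_hash"]
    config.to_yaml(outdir / "config.yaml")
    report["feature_matrix"].to_csv(outdir / "feature_matrix.csv")
    if report["selection"] is not None:
        report["selection"].to_json(outdir / "selection.json")
    report["predictions"].assign(config_hash=chash).to_csv(
        outdir / "step_predictions.csv", index=False)
    metrics = pd.DataFrame([ev.to_dict() for ev in report["evaluations"].values()])
    metrics["config_hash"] = chash
    metrics.to_csv(outdir / "metrics.csv", index=False)
    summary = {
        "config_hash": chash,
        "seed": report["seed"],
        "n_steps": report["n_steps"],
        "n_subjects": report["n_subjects"],
        "stage_seconds": report["stage_seconds"],
    }
    comp = report["comparison"]
    if comp is not None:
        summary["cochran_Q"] = comp.cochran_Q
        summary["cochran_p"] = comp.cochran_p
        comp.pairwise.to_csv(outdir / "posthoc_pairwise.csv")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
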