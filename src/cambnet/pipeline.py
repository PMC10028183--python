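"""End-to-end orchestration: simulate -> preprocess -> train -> evaluate
-> explain, with provenance (config hash) beside the artifacts."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, explainability, preprocessing, synthetic, training
from .config import RunConfig, config_hash, dump_config
from .model import build_cambnet, predict_proba


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as err:
                raise PipelineStageError(name, err) from err
        return wrapped
    return deco


@_stage("simulate")
def _simulate(config: RunConfig, outdir: Path):
    spec = config.phantom_spec()
    cases, meta = synthetic.generate_cohort(
        n_cases=config.phantom.n_cases, class_balance=config.phantom.class_balance,
        spec=spec, seed=config.seed,
    )
    synthetic.save_cohort(cases, meta, outdir / "cohort")
    return cases, meta


@_stage("preprocess")
def _preprocess(config: RunConfig, cases):
    pp = config.preprocess
    return preprocessing.preprocess_cohort(
        cases, margin=pp.margin, side=pp.side, mean=pp.mean, std=pp.std
    )


@_stage("train")
def _train(config: RunConfig, cases, patches, outdir: Path):
    tcfg = config.train_config()
    plan = training.patient_split(
        cases, test_fraction=tcfg.test_fraction, seed=tcfg.seed,
        val_fraction=tcfg.val_fraction,
    )
    model = build_cambnet(config.cambnet_config(), seed=config.seed)
    model, history = training.train(model, patches, plan, tcfg)
    model.save(outdir / "checkpoint.npz")
    with open(outdir / "history.jsonl", "w") as fh:
        for row in history:
            fh.write(json.dumps(row) + "\n")
    return model, history, plan


@_stage("evaluate")
def _evaluate(config: RunConfig, model, cases, patches, plan, outdir: Path):
    test_ids = set(plan.test_ids)
    test_patches = [p for p in patches if p.patient_id in test_ids]
    report = evaluation.evaluate(model, test_patches)
    pd.DataFrame([{"dataset": "test", **report.as_percent_row()}]).to_csv(
        outdir / "metrics.csv", index=False
    )
    # subgroup tables on the test set, scored with the model's
    # non-luminal probability
    test_cases = [c for c in cases if c.patient_id in test_ids]
    x = np.stack([p.data for p in test_patches])
    scores = predict_proba(model, x)[:, evaluation.POSITIVE_CLASS]
    by_id = {c.patient_id: c for c in test_cases}
    ordered = [by_id[p.patient_id] for p in test_patches]
    subgroups = evaluation.subgroup_eval(
        labels4=[c.subtype_label4 for c in ordered],
        covariate_values={
            "menarche_age": [c.menarche_age for c in ordered],
            "tumor_size": [c.tumor_size for c in ordered],
        },
        scores=scores,
        schemes=[
            evaluation.StratumScheme(
                "menarche_age", threshold=config.strata.menarche_threshold_years
            ),
            evaluation.StratumScheme(
                "tumor_size", threshold=config.strata.tumor_size_threshold_mm
            ),
        ],
    )
    subgroups.to_csv(outdir / "subgroups.csv", index=False)
    labels = np.array(
        [evaluation.relabel(c.subtype_label4, "luminal_vs_nonluminal")
         for c in ordered]
    )
    if len(np.unique(labels)) == 2:
        evaluation.plot_roc(labels, scores, outdir / "roc.png")
    return report, subgroups


@_stage("explain")
def _explain(config: RunConfig, model, cases, patches, plan, outdir: Path,
             n_examples: int = 4):
    test_ids = sorted(plan.test_ids)[:n_examples]
    by_id = {c.patient_id: c for c in cases}
    patch_by_id = {p.patient_id: p for p in patches}
    scores = []
    exdir = outdir / "explain"
    exdir.mkdir(exist_ok=True)
    for pid in test_ids:
        case, patch = by_id[pid], patch_by_id[pid]
        probs = predict_proba(model, patch.data[None])
        target = int(probs[0].argmax())
        sal = explainability.gradcam(model, patch, target)
        box = preprocessing.extract_bounding_box(case.mask,
                                                 margin=config.preprocess.margin)
        mask64 = preprocessing.resize_mask(case.mask, box,
                                           side=config.preprocess.side)
        scores.append(explainability.localization_score(sal, mask64))
        np.save(exdir / f"{pid}_saliency.npy", sal.data)
        explainability.save_overlay(patch, sal, exdir / f"{pid}_overlay.png")
    return float(np.mean(scores)) if scores else float("nan")


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the whole pipeline; returns a result bundle of paths and metrics."""
    outdir = Path(outdir or config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(dump_config(config))

    cases, meta = _simulate(config, outdir)
    patches = _preprocess(config, cases)
    model, history, plan = _train(config, cases, patches, outdir)
    report, subgroups = _evaluate(config, model, cases, patches, plan, outdir)
    mean_localization = _explain(config, model, cases, patches, plan, outdir)

    manifest = {
        "config_hash": config_hash(config),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "n_cases": len(cases),
        "n_train": len(plan.train_ids),
        "n_val": len(plan.val_ids),
        "n_test": len(plan.test_ids),
        "test_metrics": report.as_percent_row(),
        "mean_gradcam_localization": mean_localization,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "outdir": outdir,
        "checkpoint": outdir / "checkpoint.npz",
        "metrics_csv": outdir / "metrics.csv",
        "subgroups_csv": outdir / "subgroups.csv",
        "manifest": manifest,
        "model": model,
        "plan": plan,
        "history": history,
        "report": report,
    }


__all__ = ["run_pipeline", "PipelineStageError"]
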