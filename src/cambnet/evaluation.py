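"""Classification metrics, ROC/AUC and subgroup analyses.

Accuracy, precision, recall and F1 follow the standard confusion-count
formulas; metrics are stored as fractions in [0, 1] and rendered as
percentages with two decimals in tables.  AUC uses the rank (midrank on
ties) convention, i.e. it equals the Mann-Whitney U statistic normalised
by n1*n0.  Headline numbers are macro-averaged over the two classes (the
only convention under which recall can exceed accuracy on an imbalanced
test set); per-class values are also reported.

Subgroup machinery: cohorts are stratified by age at menarche (threshold
14 years) or tumor size (threshold 20 mm) and relabeled under one of three
binary schemes — luminal vs non-luminal, triple-negative vs rest, or
luminal A vs rest — then scored per stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

MENARCHE_THRESHOLD_YEARS = 14
TUMOR_SIZE_THRESHOLD_MM = 20.0

#: positive class index convention: non_luminal = 1
POSITIVE_CLASS = 1

LABEL_SCHEMES = ("luminal_vs_nonluminal", "TN_vs_rest", "luminalA_vs_rest")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None
    averaging_mode: str = "macro"  # or "per-class"
    n: int = 0
    per_class: dict = field(default_factory=dict)

    def as_percent_row(self) -> dict[str, float]:
        row = {
            "Acc (%)": round(100 * self.accuracy, 2),
            "Pre (%)": round(100 * self.precision, 2),
            "Rec (%)": round(100 * self.recall, 2),
            "F1 (%)": round(100 * self.f1, 2),
        }
        if self.auc is not None:
            row["AUC (%)"] = round(100 * self.auc, 2)
        return row


@dataclass(frozen=True)
class StratumScheme:
    """One subgroup analysis: a covariate threshold plus a label scheme."""

    covariate: str  # "menarche_age" | "tumor_size"
    label_scheme: str = "luminal_vs_nonluminal"
    threshold: float | None = None

    def __post_init__(self):
        if self.covariate not in ("menarche_age", "tumor_size"):
            raise ValueError(f"unknown covariate {self.covariate!r}")
        if self.label_scheme not in LABEL_SCHEMES:
            raise ValueError(f"unknown label scheme {self.label_scheme!r}")
        if self.threshold is None:
            object.__setattr__(
                self, "threshold",
                MENARCHE_THRESHOLD_YEARS if self.covariate == "menarche_age"
                else TUMOR_SIZE_THRESHOLD_MM,
            )


def confusion(labels, predictions) -> ConfusionCounts:
    """Confusion counts of binary predictions against binary labels."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError(
            f"length mismatch: {labels.shape} labels vs {predictions.shape} predictions"
        )
    if not np.isin(labels, (0, 1)).all() or not np.isin(predictions, (0, 1)).all():
        raise ValueError("labels and predictions must be binary (0/1)")
    return ConfusionCounts(
        tp=int(((labels == 1) & (predictions == 1)).sum()),
        fp=int(((labels == 0) & (predictions == 1)).sum()),
        tn=int(((labels == 0) & (predictions == 0)).sum()),
        fn=int(((labels == 1) & (predictions == 0)).sum()),
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reporting 0.0", stacklevel=3)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, F1 from confusion counts.

    Zero denominators yield 0.0 with a warning.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics of zero samples")
    acc = (counts.tp + counts.tn) / counts.total
    pre = _safe_div(counts.tp, counts.tp + counts.fp, "precision")
    rec = _safe_div(counts.tp, counts.tp + counts.fn, "recall")
    f1 = _safe_div(2 * pre * rec, pre + rec, "f1")
    return {"accuracy": acc, "precision": pre, "recall": rec, "f1": f1}


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (midrank/Mann-Whitney convention)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores)))


def report_from_scores(labels: np.ndarray, scores: np.ndarray,
                       averaging_mode: str = "macro") -> MetricsReport:
    """Score a binary problem from positive-class probabilities.

    Predictions are thresholded at 0.5 (equivalently argmax of the 2-class
    softmax).  Per-class precision/recall/F1 are computed by swapping the
    positive class; the macro report averages them.  Accuracy and AUC are
    class-symmetric.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if labels.size == 0:
        raise ValueError("empty evaluation set")
    preds = (scores >= 0.5).astype(int)
    per_class = {}
    for positive in (1, 0):
        lab = labels if positive == 1 else 1 - labels
        prd = preds if positive == 1 else 1 - preds
        per_class[positive] = metrics(confusion(lab, prd))
    acc = per_class[1]["accuracy"]
    auc = roc_auc(scores, labels) if len(np.unique(labels)) == 2 else None
    if averaging_mode == "macro":
        mean = {k: 0.5 * (per_class[1][k] + per_class[0][k])
                for k in ("precision", "recall", "f1")}
    elif averaging_mode == "per-class":
        mean = {k: per_class[POSITIVE_CLASS][k] for k in ("precision", "recall", "f1")}
    else:
        raise ValueError(f"unknown averaging mode {averaging_mode!r}")
    return MetricsReport(
        accuracy=acc, precision=mean["precision"], recall=mean["recall"],
        f1=mean["f1"], auc=auc, averaging_mode=averaging_mode,
        n=int(labels.size), per_class=per_class,
    )


def evaluate(model, patches, averaging_mode: str = "macro",
             label_map=None) -> MetricsReport:
    """Evaluate a model on ROI patches (softmax scores, argmax predictions)."""
    from .model import predict_proba
    from .training import LABEL_TO_INDEX, patches_to_arrays

    if not patches:
        raise ValueError("empty evaluation set")
    label_map = label_map or LABEL_TO_INDEX
    x, y, _ = patches_to_arrays(patches, label_map)
    probs = predict_proba(model, np.transpose(x, (0, 2, 3, 1)))
    return report_from_scores(y, probs[:, POSITIVE_CLASS],
                              averaging_mode=averaging_mode)


# -- subgroup machinery ----------------------------------------------------

def relabel(label4: str, scheme: str) -> int:
    """Map a 4-way subtype to the binary positive/negative of a scheme.

    Positive (1) is the non-luminal side for luminal_vs_nonluminal, the
    triple-negative class for TN_vs_rest, and luminal A for
    luminalA_vs_rest.
    """
    if scheme == "luminal_vs_nonluminal":
        return 1 if label4 in ("HER2", "TN") else 0
    if scheme == "TN_vs_rest":
        return 1 if label4 == "TN" else 0
    if scheme == "luminalA_vs_rest":
        return 1 if label4 == "luminalA" else 0
    raise ValueError(f"unknown label scheme {scheme!r}")


def stratify(values: np.ndarray, threshold: float) -> dict[str, np.ndarray]:
    """Boolean masks of the two strata (<= threshold, > threshold)."""
    values = np.asarray(values)
    return {"le": values <= threshold, "gt": values > threshold}


def subgroup_eval(labels4, covariate_values, scores,
                  schemes: list[StratumScheme],
                  averaging_mode: str = "macro") -> pd.DataFrame:
    """Per-stratum metrics tables.

    ``labels4`` are 4-way subtype labels, ``covariate_values`` maps
    covariate name -> per-case values, ``scores`` are positive-class
    probabilities of a model matched to each scheme's positive class.
    Strata partition the cohort at the scheme threshold; an empty stratum
    is reported as a row of NaNs, never silently dropped.
    """
    labels4 = np.asarray(labels4)
    scores = np.asarray(scores)
    rows = []
    for scheme in schemes:
        values = np.asarray(covariate_values[scheme.covariate])
        y = np.array([relabel(l, scheme.label_scheme) for l in labels4])
        for side, mask in stratify(values, scheme.threshold).items():
            name = (
                f"{scheme.covariate}_{side}{scheme.threshold:g}"
                f"_{scheme.label_scheme}"
            )
            base = {
                "stratum": name, "covariate": scheme.covariate,
                "side": side, "threshold": scheme.threshold,
                "label_scheme": scheme.label_scheme, "n": int(mask.sum()),
            }
            if mask.sum() == 0 or len(np.unique(y[mask])) < 1:
                rows.append({**base, "missing": True})
                continue
            rep = report_from_scores(y[mask], scores[mask],
                                     averaging_mode=averaging_mode)
            rows.append({**base, "missing": False, **rep.as_percent_row()})
    return pd.DataFrame(rows)


def default_strata() -> list[StratumScheme]:
    """The four analyses of the published subgroup tables."""
    return [
        StratumScheme("menarche_age", "luminal_vs_nonluminal"),
        StratumScheme("menarche_age", "luminalA_vs_rest"),
        StratumScheme("tumor_size", "luminal_vs_nonluminal"),
        StratumScheme("tumor_size", "TN_vs_rest"),
    ]


def plot_roc(labels, scores, path) -> None:
    """Write a ROC-curve figure for the positive-class scores."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr, tpr, _ = roc_curve(np.asarray(labels), np.asarray(scores))
    auc = roc_auc(scores, labels)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(fpr, tpr, label=f"CAMBNet (AUC = {100 * auc:.2f}%)")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


__all__ = [
    "MENARCHE_THRESHOLD_YEARS",
    "TUMOR_SIZE_THRESHOLD_MM",
    "POSITIVE_CLASS",
    "LABEL_SCHEMES",
    "ConfusionCounts",
    "MetricsReport",
    "StratumScheme",
    "confusion",
    "metrics",
    "roc_auc",
    "report_from_scores",
    "evaluate",
    "relabel",
    "stratify",
    "subgroup_eval",
    "default_strata",
    "plot_roc",
]
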