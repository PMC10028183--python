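"""Metrics against counting/pairwise oracles; subgroup machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cambnet.evaluation import (
    ConfusionCounts,
    StratumScheme,
    confusion,
    default_strata,
    metrics,
    relabel,
    report_from_scores,
    roc_auc,
    stratify,
    subgroup_eval,
)


def counting_oracle(labels, preds):
    """From-scratch confusion counting by explicit iteration."""
    tp = fp = tn = fn = 0
    for y, p in zip(labels, preds):
        if y == 1 and p == 1:
            tp += 1
        elif y == 0 and p == 1:
            fp += 1
        elif y == 0 and p == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def pairwise_auc_oracle(scores, labels):
    """Mann-Whitney: mean over all (pos, neg) pairs of 1/0.5/0."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_confusion_enumeration_oracle():
    counts = confusion([1, 1, 0, 0], [1, 0, 0, 1])
    assert (counts.tp, counts.fn, counts.tn, counts.fp) == (1, 1, 1, 1)


def test_confusion_perfect_and_inverted():
    y = np.array([1, 0, 1, 1, 0])
    assert confusion(y, y).fp == 0 and confusion(y, y).fn == 0
    inv = confusion(y, 1 - y)
    assert inv.tp == 0 and inv.tn == 0


def test_confusion_rejects_length_mismatch_and_nonbinary():
    with pytest.raises(ValueError):
        confusion([1, 0], [1])
    with pytest.raises(ValueError):
        confusion([1, 2], [1, 0])


def test_metrics_formula_oracle():
    m = metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
    assert m["accuracy"] == pytest.approx(0.7)
    assert m["precision"] == pytest.approx(0.75)
    assert m["recall"] == pytest.approx(0.6)
    assert m["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)


def test_metrics_all_correct_is_all_ones():
    m = metrics(ConfusionCounts(tp=1, fp=0, tn=1, fn=0))
    assert all(v == 1.0 for v in m.values())


def test_zero_denominator_policy_warns_and_returns_zero():
    with pytest.warns(UserWarning, match="precision"):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=3, fn=2))
    assert m["precision"] == 0.0


def test_metrics_match_counting_oracle_on_random_tables(rng):
    for _ in range(1000):
        n = int(rng.integers(2, 30))
        y = rng.integers(0, 2, n)
        p = rng.integers(0, 2, n)
        tp, fp, tn, fn = counting_oracle(y, p)
        c = confusion(y, p)
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
        if tp + fp == 0 or tp + fn == 0:
            continue  # degenerate policy covered above
        m = metrics(c)
        assert m["accuracy"] == pytest.approx((tp + tn) / n)
        assert m["precision"] == pytest.approx(tp / (tp + fp))
        assert m["recall"] == pytest.approx(tp / (tp + fn))


def test_auc_perfect_and_reversed():
    y = [0, 0, 1, 1]
    assert roc_auc([0.1, 0.2, 0.8, 0.9], y) == 1.0
    assert roc_auc([0.9, 0.8, 0.2, 0.1], y) == 0.0


def test_auc_tie_fixture_matches_midrank_oracle():
    scores = [0.1, 0.4, 0.4, 0.6, 0.6, 0.6, 0.8, 0.9]
    labels = [0, 0, 1, 0, 1, 1, 0, 1]
    assert roc_auc(scores, labels) == pytest.approx(
        pairwise_auc_oracle(scores, labels)
    )


def test_auc_matches_pairwise_oracle_on_random_vectors(rng):
    for _ in range(100):
        n = int(rng.integers(4, 20))
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            continue
        scores = rng.choice([0.1, 0.25, 0.5, 0.5, 0.75, 0.9], size=n)  # ties
        assert roc_auc(scores, labels) == pytest.approx(
            pairwise_auc_oracle(scores, labels)
        )


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.9], [1, 1])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(0.01, 0.99), min_size=4, max_size=20))
def test_auc_invariant_under_increasing_transform(scores):
    labels = [i % 2 for i in range(len(scores))]
    a = roc_auc(scores, labels)
    b = roc_auc([np.exp(3 * s) for s in scores], labels)
    assert a == pytest.approx(b)


def test_macro_recall_is_mean_of_per_class_recalls(rng):
    y = rng.integers(0, 2, 40)
    s = rng.random(40)
    rep = report_from_scores(y, s, averaging_mode="macro")
    assert rep.recall == pytest.approx(
        0.5 * (rep.per_class[1]["recall"] + rep.per_class[0]["recall"])
    )


def test_majority_model_accuracy_equals_majority_fraction():
    y = np.array([1] * 7 + [0] * 3)
    scores = np.full(10, 0.9)  # always predicts the majority class
    rep = report_from_scores(y, scores)
    assert rep.accuracy == pytest.approx(0.7)


def test_report_on_fixed_fixture_matches_hand_values():
    """20 scored samples, hand-assembled oracle for every field."""
    y = np.array([1] * 10 + [0] * 10)
    s = np.concatenate([np.linspace(0.55, 0.95, 8), [0.3, 0.2],     # 8 TP, 2 FN
                        np.linspace(0.05, 0.45, 7), [0.6, 0.7, 0.8]])  # 7 TN, 3 FP
    rep = report_from_scores(y, s, averaging_mode="per-class")
    assert rep.accuracy == pytest.approx(15 / 20)
    assert rep.precision == pytest.approx(8 / 11)
    assert rep.recall == pytest.approx(8 / 10)
    f1 = 2 * (8 / 11) * 0.8 / (8 / 11 + 0.8)
    assert rep.f1 == pytest.approx(f1)
    assert rep.auc == pytest.approx(pairwise_auc_oracle(s, y))


def test_relabel_schemes():
    assert [relabel(l, "TN_vs_rest") for l in ("TN", "luminalA", "luminalB", "HER2")] \
        == [1, 0, 0, 0]
    assert [relabel(l, "luminalA_vs_rest") for l in ("luminalA", "luminalB")] == [1, 0]
    assert [relabel(l, "luminal_vs_nonluminal") for l in ("luminalA", "HER2")] == [0, 1]


def test_strata_partition_cohort():
    ages = np.array([11, 14, 15, 17, 12])
    masks = stratify(ages, 14)
    assert (masks["le"] | masks["gt"]).all()
    assert not (masks["le"] & masks["gt"]).any()


def test_subgroup_eval_equals_filter_then_score_oracle(rng):
    n = 120
    labels4 = rng.choice(["luminalA", "luminalB", "HER2", "TN"], size=n)
    ages = rng.integers(11, 18, n)
    sizes = rng.uniform(8, 35, n)
    scores = rng.random(n)
    covs = {"menarche_age": ages, "tumor_size": sizes}
    table = subgroup_eval(labels4, covs, scores, default_strata())
    assert len(table) == 8  # 4 schemes x 2 strata, none dropped
    for _, row in table.iterrows():
        values = covs[row["covariate"]]
        mask = (values <= row["threshold"]) if row["side"] == "le" \
            else (values > row["threshold"])
        y = np.array([relabel(l, row["label_scheme"]) for l in labels4[mask]])
        oracle = report_from_scores(y, scores[mask])
        assert row["n"] == mask.sum()
        assert row["Acc (%)"] == pytest.approx(oracle.as_percent_row()["Acc (%)"])
        assert row["F1 (%)"] == pytest.approx(oracle.as_percent_row()["F1 (%)"])


def test_subgroup_empty_stratum_reported_missing():
    labels4 = np.array(["TN", "HER2", "luminalA"])
    covs = {"menarche_age": np.array([11, 12, 13])}  # nobody > 14
    table = subgroup_eval(labels4, covs, np.array([0.2, 0.8, 0.4]),
                          [StratumScheme("menarche_age", "TN_vs_rest")])
    gt_row = table[table.side == "gt"].iloc[0]
    assert bool(gt_row["missing"]) and gt_row["n"] == 0


def test_stratum_scheme_validation():
    with pytest.raises(ValueError):
        StratumScheme("height", "TN_vs_rest")
    with pytest.raises(ValueError):
        StratumScheme("tumor_size", "grade_vs_rest")
    assert StratumScheme("tumor_size").threshold == 20.0
    assert StratumScheme("menarche_age").threshold == 14
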