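"""Splitting, scheduling, augmentation and the training loop."""

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pytest

from cambnet.preprocessing import ROIPatch
from cambnet.training import (
    SplitPlan,
    TrainConfig,
    augment,
    dihedral_transform,
    kfold_plan,
    lr_at,
    patient_split,
    train,
    train_on_cohort,
)


@dataclass
class _Case:
    patient_id: str
    subtype_label: str


def _dummy_cases(n_luminal, n_non):
    return [_Case(f"L{i}", "luminal") for i in range(n_luminal)] + [
        _Case(f"N{i}", "non_luminal") for i in range(n_non)
    ]


def test_160_patients_fraction_02_gives_32_test():
    plan = patient_split(_dummy_cases(84, 76), test_fraction=0.2, seed=0)
    assert len(plan.test_ids) == 32
    # stratified: 17 luminal (round of 16.8), 15 non-luminal
    labels = Counter(i[0] for i in plan.test_ids)
    assert labels == Counter({"L": 17, "N": 15})


def test_split_is_deterministic_and_partitions():
    cases = _dummy_cases(30, 25)
    a = patient_split(cases, test_fraction=0.2, seed=5)
    b = patient_split(cases, test_fraction=0.2, seed=5)
    assert (a.train_ids, a.val_ids, a.test_ids) == (b.train_ids, b.val_ids, b.test_ids)
    union = set(a.train_ids) | set(a.val_ids) | set(a.test_ids)
    assert union == {c.patient_id for c in cases}
    assert len(a.train_ids) + len(a.val_ids) + len(a.test_ids) == len(cases)


def test_split_requires_two_patients_per_class():
    with pytest.raises(ValueError):
        patient_split(_dummy_cases(1, 10), test_fraction=0.2, seed=0)


def test_split_plan_rejects_overlap():
    with pytest.raises(ValueError):
        SplitPlan(train_ids=["a", "b"], val_ids=["b"], test_ids=["c"])


def test_kfold_10_patients_5_folds_all_size_2():
    ids = [f"P{i}" for i in range(10)]
    labels = ["luminal"] * 5 + ["non_luminal"] * 5
    assignment = kfold_plan(ids, labels, n_folds=5, seed=0)
    sizes = Counter(assignment.values())
    assert set(assignment) == set(ids)  # every patient in exactly one fold
    assert all(s == 2 for s in sizes.values())


def test_kfold_class_ratio_within_one_patient_of_global():
    ids = [f"P{i}" for i in range(20)]
    labels = ["luminal"] * 12 + ["non_luminal"] * 8
    assignment = kfold_plan(ids, labels, n_folds=5, seed=3)
    for fold in range(5):
        members = [i for i in ids if assignment[i] == fold]
        n_lum = sum(labels[ids.index(i)] == "luminal" for i in members)
        expected = 12 / 20 * len(members)
        assert abs(n_lum - expected) <= 1


def test_kfold_rejects_more_folds_than_patients():
    with pytest.raises(ValueError):
        kfold_plan(["a", "b"], ["luminal", "non_luminal"], n_folds=3, seed=0)


@pytest.mark.parametrize(
    "epoch,expected",
    [(0, 0.002), (9, 0.002), (10, 0.0019), (25, 0.002 * 0.95**2)],
)
def test_lr_schedule_closed_form(epoch, expected):
    assert lr_at(epoch, TrainConfig()) == pytest.approx(expected, rel=1e-12)


def test_augment_group_properties(rng):
    data = rng.random((64, 64, 3)).astype(np.float32)
    # identity draw
    assert np.array_equal(dihedral_transform(data, 0, False), data)
    # transpose is an involution
    t = dihedral_transform(data, 0, True)
    assert np.array_equal(dihedral_transform(t, 0, True), data)
    # four quarter-turns close the rotation subgroup
    r = data
    for _ in range(4):
        r = dihedral_transform(r, 1, False)
    assert np.array_equal(r, data)
    patch = ROIPatch(data=data, label="luminal", patient_id="P1")
    out = augment(patch, np.random.default_rng(0))
    assert out.data.shape == patch.data.shape
    assert out.label == patch.label


def test_augment_rejects_non_square():
    patch = ROIPatch(data=np.zeros((64, 32, 3), np.float32), label="luminal",
                     patient_id="P1")
    with pytest.raises(ValueError):
        augment(patch, np.random.default_rng(0))


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(test_fraction=1.5)
    with pytest.raises(ValueError):
        TrainConfig(optimizer_name="sgd")


@pytest.fixture(scope="module")
def short_training(small_cohort):
    cases, _ = small_cohort
    cfg = TrainConfig(max_epochs=3, seed=7)
    model, history, plan, patches = train_on_cohort(cases, cfg)
    return model, history, plan, patches, cfg


def test_history_lr_column_follows_schedule(short_training):
    _, history, _, _, cfg = short_training
    for row in history:
        assert row["lr"] == pytest.approx(lr_at(row["epoch"], cfg))


def test_restored_checkpoint_has_best_validation_accuracy(short_training):
    from cambnet.training import _accuracy, patches_to_arrays

    model, history, plan, patches, cfg = short_training
    val = [p for p in patches if p.patient_id in set(plan.val_ids)]
    x, y, _ = patches_to_arrays(val)
    acc = _accuracy(model, x, y, cfg.batch_size_eval)
    assert acc == pytest.approx(max(h["val_accuracy"] for h in history))


def test_training_rejects_leaky_plan(short_training, small_cohort):
    model, _, plan, patches, cfg = short_training
    leaky = SplitPlan(train_ids=plan.train_ids, val_ids=plan.val_ids,
                      test_ids=plan.test_ids)
    leaky.test_ids = list(leaky.test_ids) + [leaky.train_ids[0]]
    with pytest.raises(ValueError, match="disjoint"):
        train(model, patches, leaky, cfg)


def test_training_rejects_empty_validation(short_training):
    model, _, plan, patches, cfg = short_training
    no_val = SplitPlan(train_ids=plan.train_ids, val_ids=[], test_ids=plan.test_ids)
    with pytest.raises(ValueError, match="validation"):
        train(model, patches, no_val, cfg)


def test_first_step_decreases_first_batch_loss(small_cohort):
    """Smoke property: one RMSprop step at lr 0.002 reduces the loss of the
    batch it was taken on."""
    from cambnet.model import CambnetConfig, build_cambnet
    from cambnet.nn import tensor as T
    from cambnet.nn.optim import RMSprop
    from cambnet.preprocessing import preprocess_cohort
    from cambnet.training import patches_to_arrays

    cases, _ = small_cohort
    x, y, _ = patches_to_arrays(preprocess_cohort(cases[:8]))
    # dropout off so the two loss evaluations see the same network
    model = build_cambnet(CambnetConfig(dropout_rate=0.0), seed=1)
    model.train()
    opt = RMSprop(model.parameters(), lr=0.002)
    loss0 = T.cross_entropy(model(x), y)
    model.zero_grad()
    loss0.backward()
    opt.step()
    with T.no_grad():
        loss1 = T.cross_entropy(model(x), y)
    assert loss1.item() < loss0.item()


def test_training_history_is_reproducible(small_cohort):
    cases, _ = small_cohort
    cfg = TrainConfig(max_epochs=2, seed=3)
    _, h1, _, _ = train_on_cohort(cases, cfg)
    _, h2, _, _ = train_on_cohort(cases, cfg)
    assert h1 == h2
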