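"""Patient-wise splitting, augmentation and the training loop.

Splits are made at the patient level so no patient contributes images to
more than one of train/validation/test.  Training follows the recipe the
architecture was designed with: RMSprop, base learning rate 0.002 decayed
by 0.95 every 10 epochs, batch size 8 for training and 1 for evaluation,
cross-entropy loss, L2 regularisation, a per-kernel max-norm clamp after
every step, and checkpointing of the weights that score best on the
validation set.  A validation set is carved from the training patients
(15% by default) so checkpoint selection never touches the test set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .model import CAMBNet, CambnetConfig, build_cambnet
from .nn import tensor as T
from .nn.optim import RMSprop, apply_max_norm
from .preprocessing import ROIPatch


@dataclass(frozen=True)
class TrainConfig:
    batch_size_train: int = 8
    batch_size_eval: int = 1
    max_epochs: int = 200
    base_lr: float = 0.002
    lr_decay_factor: float = 0.95
    lr_decay_interval_epochs: int = 10
    optimizer_name: str = "rmsprop"
    l2_weight: float = 1e-4
    kernel_maxnorm: float = 2.0
    rmsprop_alpha: float = 0.99
    rmsprop_eps: float = 1e-8
    seed: int = 0
    n_folds: int = 5
    test_fraction: float = 0.2
    val_fraction: float = 0.15  # of the training patients
    augment: bool = True

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if not 0 < self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must lie in (0, 1]")
        if self.batch_size_train < 1 or self.batch_size_eval < 1:
            raise ValueError("batch sizes must be >= 1")
        if self.optimizer_name.lower() != "rmsprop":
            raise ValueError(f"unsupported optimizer {self.optimizer_name!r}")


@dataclass
class SplitPlan:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    fold_assignments: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        groups = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = groups[i] & groups[j]
                if overlap:
                    raise ValueError(f"patient ids in two split groups: {overlap}")


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Stepped schedule: base_lr * factor ** floor(epoch / interval)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.base_lr * config.lr_decay_factor ** (
        epoch // config.lr_decay_interval_epochs
    )


def _stratified_take(ids_by_class: dict[str, list[str]], n_take: int,
                     rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Take ``n_take`` ids stratified by class; returns (taken, rest).

    Per-class quotas are proportional with largest-remainder rounding so the
    total is exactly ``n_take``.
    """
    classes = sorted(ids_by_class)
    total = sum(len(v) for v in ids_by_class.values())
    exact = {c: n_take * len(ids_by_class[c]) / total for c in classes}
    quota = {c: int(math.floor(exact[c])) for c in classes}
    remainder = sorted(classes, key=lambda c: exact[c] - quota[c], reverse=True)
    for c in remainder:
        if sum(quota.values()) >= n_take:
            break
        quota[c] += 1
    taken, rest = [], []
    for c in classes:
        ids = list(ids_by_class[c])
        rng.shuffle(ids)
        taken.extend(ids[: quota[c]])
        rest.extend(ids[quota[c] :])
    return sorted(taken), sorted(rest)


def patient_split(cases, test_fraction: float = 0.2, seed: int = 0,
                  val_fraction: float = 0.15) -> SplitPlan:
    """Class-stratified patient-level train/val/test split.

    The test set holds ``round(test_fraction * n_patients)`` patients; the
    validation set is carved from the remaining training patients.
    """
    by_class: dict[str, list[str]] = {}
    for c in cases:
        by_class.setdefault(c.subtype_label, []).append(c.patient_id)
    if len(cases) < 2:
        raise ValueError("need at least 2 patients")
    for lab, ids in by_class.items():
        if len(ids) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 patients")
    rng = np.random.default_rng(seed)
    n = sum(len(v) for v in by_class.values())
    n_test = int(round(test_fraction * n))
    test_ids, rest = _stratified_take(by_class, n_test, rng)
    rest_by_class = {
        lab: [i for i in ids if i in set(rest)] for lab, ids in by_class.items()
    }
    n_val = int(round(val_fraction * len(rest)))
    val_ids, train_ids = _stratified_take(rest_by_class, n_val, rng)
    return SplitPlan(train_ids=train_ids, val_ids=val_ids, test_ids=test_ids)


def kfold_plan(ids: list[str], labels: list[str], n_folds: int = 5,
               seed: int = 0) -> dict[str, int]:
    """Class-stratified patient-level fold assignment (fold sizes differ
    by at most one)."""
    if n_folds > len(ids):
        raise ValueError(f"n_folds={n_folds} exceeds {len(ids)} patients")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    ids_arr = np.asarray(ids)
    for fold, (_, test_idx) in enumerate(skf.split(ids_arr, np.asarray(labels))):
        for i in test_idx:
            assignment[str(ids_arr[i])] = fold
    return assignment


# -- augmentation ----------------------------------------------------------

def dihedral_transform(data: np.ndarray, k_rot: int, transpose: bool) -> np.ndarray:
    """Rotate an (H, W, C) patch by k*90 degrees and optionally flip about
    the main diagonal (transpose)."""
    out = np.rot90(data, k=k_rot, axes=(0, 1))
    if transpose:
        out = np.swapaxes(out, 0, 1)
    return np.ascontiguousarray(out)


def augment(patch: ROIPatch, rng: np.random.Generator) -> ROIPatch:
    """Random 90-degree rotation and/or main-diagonal flip; label kept."""
    if patch.data.shape[0] != patch.data.shape[1]:
        raise ValueError("augmentation requires a square patch")
    k_rot = int(rng.integers(0, 4))
    transpose = bool(rng.integers(0, 2))
    return ROIPatch(
        data=dihedral_transform(patch.data, k_rot, transpose),
        label=patch.label,
        patient_id=patch.patient_id,
        label4=patch.label4,
    )


# -- the loop --------------------------------------------------------------

LABEL_TO_INDEX = {"luminal": 0, "non_luminal": 1}


def patches_to_arrays(patches: list[ROIPatch],
                      label_map: dict[str, int] = LABEL_TO_INDEX
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack patches into (X NCHW, y, patient_ids)."""
    x = np.stack([np.transpose(p.data, (2, 0, 1)) for p in patches]).astype(np.float32)
    y = np.array([label_map[p.label] for p in patches], dtype=np.int64)
    pids = np.array([p.patient_id for p in patches])
    return x, y, pids


def _accuracy(model: CAMBNet, x: np.ndarray, y: np.ndarray,
              batch_size: int) -> float:
    model.eval()
    correct = 0
    with T.no_grad():
        for i in range(0, len(x), batch_size):
            logits = model(x[i : i + batch_size]).data
            correct += int((logits.argmax(axis=1) == y[i : i + batch_size]).sum())
    return correct / len(x)


def train(model: CAMBNet, patches: list[ROIPatch], plan: SplitPlan,
          config: TrainConfig) -> tuple[CAMBNet, list[dict]]:
    """Train on the plan's train patients, checkpoint on validation accuracy.

    Returns the model restored to its best-on-validation weights and the
    per-epoch history (train loss, validation accuracy, learning rate).
    """
    train_set, val_set, test_set = (
        set(plan.train_ids), set(plan.val_ids), set(plan.test_ids)
    )
    # leakage guard at the training entry point, not only in the splitter
    if (train_set & test_set) or (val_set & test_set) or (train_set & val_set):
        raise ValueError("split plan groups are not disjoint")
    train_patches = [p for p in patches if p.patient_id in train_set]
    val_patches = [p for p in patches if p.patient_id in val_set]
    if not train_patches:
        raise ValueError("empty training set")
    if not val_patches:
        raise ValueError("empty validation set")

    x_tr, y_tr, _ = patches_to_arrays(train_patches)
    x_val, y_val, _ = patches_to_arrays(val_patches)

    rng = np.random.default_rng(config.seed)
    opt = RMSprop(model.parameters(), lr=config.base_lr,
                  alpha=config.rmsprop_alpha, eps=config.rmsprop_eps,
                  weight_decay=config.l2_weight)
    kernel_weights = [
        p for name, p in model.named_parameters()
        if name.endswith("weight") and p.data.ndim >= 2
    ]

    history: list[dict] = []
    best_acc, best_state = -1.0, None
    n = len(x_tr)
    for epoch in range(config.max_epochs):
        lr = lr_at(epoch, config)
        opt.lr = lr
        model.train()
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size_train):
            idx = order[i : i + config.batch_size_train]
            xb = x_tr[idx]
            if config.augment:
                xb = np.stack([
                    np.transpose(
                        dihedral_transform(
                            np.transpose(s, (1, 2, 0)),
                            int(rng.integers(0, 4)), bool(rng.integers(0, 2)),
                        ),
                        (2, 0, 1),
                    )
                    for s in xb
                ])
            logits = model(xb)
            loss = T.cross_entropy(logits, y_tr[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            apply_max_norm(kernel_weights, config.kernel_maxnorm)
            losses.append(loss.item())
        val_acc = _accuracy(model, x_val, y_val, config.batch_size_eval)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_accuracy": val_acc, "lr": lr}
        )
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def train_on_cohort(cases, config: TrainConfig | None = None,
                    model_config: CambnetConfig | None = None,
                    plan: SplitPlan | None = None):
    """Convenience wrapper: preprocess, split, build, train.

    Returns (model, history, plan, patches).
    """
    from .preprocessing import preprocess_cohort

    config = config or TrainConfig()
    patches = preprocess_cohort(cases)
    if plan is None:
        plan = patient_split(cases, test_fraction=config.test_fraction,
                             seed=config.seed, val_fraction=config.val_fraction)
    model = build_cambnet(model_config, seed=config.seed)
    model, history = train(model, patches, plan, config)
    return model, history, plan, patches


__all__ = [
    "TrainConfig",
    "SplitPlan",
    "lr_at",
    "patient_split",
    "kfold_plan",
    "augment",
    "dihedral_transform",
    "train",
    "train_on_cohort",
    "patches_to_arrays",
    "LABEL_TO_INDEX",
]
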