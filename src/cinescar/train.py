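"""Patient-wise stratified splitting, training loop, slice/patient evaluation.

Splits are always patient-wise — no patient's slices may straddle
partitions — and stratified on the patient's global label.  Training is
mini-batch SGD (lr 0.001) on binary cross-entropy with on-the-fly
augmentation of training samples only, early stopping on a validation-loss
plateau (16 epochs without strict improvement), and restoration of the
best-validation-epoch weights.  Evaluation reports the confusion matrix and
accuracy, F1, sensitivity, specificity, PPV, NPV (and, at slice level, the
ROC AUC) at slice level, then aggregates to patient level with the
"any positive slice makes the patient positive" rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import ScarResNet
from .nn import SGD, bce_with_logits
from .preprocess import augment
from .protocols import ProtocolSample

SCAR = "SCAR"
NL = "NL"


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def assert_disjoint(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise AssertionError("patient leakage: split partitions overlap")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_patients(
    patients: list[tuple[str, str]],
    seed: int = 0,
    test_frac: float = 0.2,
    val_frac: float = 0.15,
) -> SplitPlan:
    """Stratified patient-wise split into train / validation / test.

    Per stratum (SCAR and NL patient groups): shuffle with a seeded RNG,
    take round(test_frac * stratum) patients for test (nearest integer, ties
    up), then round(val_frac * remainder) of the remainder for validation.
    """
    ids = [p for p, _ in patients]
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    strata: dict[str, list[str]] = {}
    for pid, group in patients:
        if group not in (SCAR, NL):
            raise ValueError(f"patient {pid}: group must be SCAR or NL")
        strata.setdefault(group, []).append(pid)
    rng = np.random.default_rng(seed)
    train: list[str] = []
    val: list[str] = []
    test: list[str] = []
    for group in sorted(strata):
        members = sorted(strata[group])
        if len(members) < 2:
            raise ValueError(f"stratum {group} has fewer than 2 patients")
        order = rng.permutation(len(members))
        shuffled = [members[i] for i in order]
        n_test = _round_half_up(test_frac * len(shuffled))
        test.extend(shuffled[:n_test])
        remainder = shuffled[n_test:]
        n_val = _round_half_up(val_frac * len(remainder))
        val.extend(remainder[:n_val])
        train.extend(remainder[n_val:])
    plan = SplitPlan(tuple(train), tuple(val), tuple(test), seed)
    plan.assert_disjoint()
    return plan


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    max_epochs: int = 200
    patience: int = 16
    batch_size: int = 32
    threshold: float = 0.5
    seed: int = 0
    augment: bool = True
    shift_frac: float = 0.2
    rot_deg: float = 20.0
    restore_best: bool = True
    verbose: bool = False

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.max_epochs <= 0 or self.patience <= 0:
            raise ValueError("learning_rate, max_epochs and patience must be positive")
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


def _stack(samples: list[ProtocolSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.tensor for s in samples]).astype(np.float32)
    y = np.array([s.label for s in samples], dtype=np.float32)
    return X, y


def train(
    model: ScarResNet,
    train_samples: list[ProtocolSample],
    val_samples: list[ProtocolSample],
    config: TrainConfig,
) -> tuple[ScarResNet, dict[str, list[float]]]:
    """Fit the model with early stopping; returns it with the best weights.

    Augmentation is redrawn per sample per epoch on the training set only;
    validation loss is computed augmentation-free in evaluation mode.
    """
    config.validate()
    if not train_samples or not val_samples:
        raise ValueError("training and validation sets must be non-empty")
    X_train, y_train = _stack(train_samples)
    X_val, y_val = _stack(val_samples)
    rng = np.random.default_rng(config.seed)
    optimizer = SGD(model.parameters(), lr=config.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = math.inf
    best_state = model.get_state()
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(X_train))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = X_train[idx]
            if config.augment:
                batch = np.stack(
                    [
                        augment(x, rng, config.shift_frac, config.rot_deg)
                        for x in batch
                    ]
                ).astype(np.float32)
            optimizer.zero_grad()
            logits = model.forward_logits(batch, training=True)
            loss, dlogits = bce_with_logits(logits, y_train[idx])
            model.backward(dlogits)
            optimizer.step()
            epoch_loss += loss * len(idx)
        epoch_loss /= len(X_train)
        val_logits = model.forward_logits(X_val, training=False)
        val_loss, _ = bce_with_logits(val_logits, y_val)
        history["train_loss"].append(epoch_loss)
        history["val_loss"].append(val_loss)
        if config.verbose:
            print(f"epoch {epoch:3d}  train_loss {epoch_loss:.4f}  val_loss {val_loss:.4f}")
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.get_state()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if config.restore_best:
        model.set_state(best_state)
    return model, history


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Confusion matrix and derived classification metrics at one level."""

    tp: int
    fp: int
    tn: int
    fn: int
    level: str  # "slice" or "patient"
    auc: float | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.total)

    @property
    def f1(self) -> float:
        return self._ratio(2 * self.tp, 2 * self.tp + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    def as_dict(self) -> dict:
        return {
            "level": self.level,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "auc": self.auc,
        }


def report_from_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    probs: np.ndarray | None = None,
    level: str = "slice",
) -> EvalReport:
    """Build an EvalReport from binary ground truth and hard predictions.

    When probabilities are supplied and both classes are present, the ROC
    AUC (trapezoidal, all distinct cut-points) is included.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    report = EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, level=level)
    if probs is not None:
        if len(np.unique(y_true)) < 2:
            msg = "AUC undefined: test set contains a single class"
            warnings.warn(msg)
            report.warnings.append(msg)
        else:
            from sklearn.metrics import roc_auc_score

            report.auc = float(roc_auc_score(y_true, probs))
    return report


def evaluate_slices(
    model: ScarResNet,
    test_samples: list[ProtocolSample],
    threshold: float = 0.5,
) -> tuple[EvalReport, np.ndarray]:
    """Slice-level evaluation; probabilities >= threshold count positive.

    Returns the report and the per-slice probabilities (in sample order).
    """
    if not test_samples:
        raise ValueError("test set must be non-empty")
    X, y = _stack(test_samples)
    probs = model.predict_proba(X)
    preds = (probs >= threshold).astype(int)
    return report_from_predictions(y, preds, probs, level="slice"), probs


def evaluate_patients(
    slice_probs: np.ndarray,
    samples: list[ProtocolSample],
    patient_labels: dict[str, str],
    threshold: float = 0.5,
) -> EvalReport:
    """Patient-level evaluation: a patient is SCAR iff any slice is positive."""
    by_patient: dict[str, list[float]] = {}
    for prob, sample in zip(slice_probs, samples):
        by_patient.setdefault(sample.patient_id, []).append(float(prob))
    for pid in patient_labels:
        if pid not in by_patient:
            raise ValueError(f"patient {pid} has no slice predictions")
    y_true = []
    y_pred = []
    for pid, probs in sorted(by_patient.items()):
        if pid not in patient_labels:
            raise ValueError(f"patient {pid} has predictions but no ground truth")
        y_true.append(1 if patient_labels[pid] == SCAR else 0)
        y_pred.append(1 if any(p >= threshold for p in probs) else 0)
    return report_from_predictions(np.array(y_true), np.array(y_pred), level="patient")
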