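"""Splitting arithmetic, training-loop behaviour, evaluation metrics."""

import numpy as np
import pytest

from cinescar import (
    ModelConfig,
    ProtocolSample,
    TrainConfig,
    build_model,
    evaluate_patients,
    evaluate_slices,
    report_from_predictions,
    split_patients,
    train,
)


def roster(n_scar, n_nl):
    return [(f"S{i}", "SCAR") for i in range(n_scar)] + [
        (f"N{i}", "NL") for i in range(n_nl)
    ]


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------

def test_clinical_roster_partition_sizes():
    plan = split_patients(roster(158, 48), seed=0)
    assert len(plan.test_ids) == 42
    assert len(plan.train_ids) + len(plan.val_ids) == 164
    assert len(plan.val_ids) == 25
    assert len(plan.train_ids) == 139


def test_small_balanced_roster_strata():
    plan = split_patients(roster(5, 5), seed=1)
    assert len(plan.test_ids) == 2
    scar_test = [p for p in plan.test_ids if p.startswith("S")]
    assert len(scar_test) == 1  # one per stratum
    all_ids = set(plan.train_ids) | set(plan.val_ids) | set(plan.test_ids)
    assert all_ids == {pid for pid, _ in roster(5, 5)}
    plan.assert_disjoint()


def test_split_is_seed_deterministic_and_seed_sensitive():
    a = split_patients(roster(20, 10), seed=5)
    b = split_patients(roster(20, 10), seed=5)
    c = split_patients(roster(20, 10), seed=6)
    assert a == b
    assert a.test_ids != c.test_ids


def test_tiny_stratum_rejected():
    with pytest.raises(ValueError, match="stratum"):
        split_patients([("A", "SCAR"), ("B", "NL"), ("C", "NL")], seed=0)


def test_duplicate_patient_ids_rejected():
    with pytest.raises(ValueError, match="unique"):
        split_patients([("A", "SCAR"), ("A", "NL"), ("B", "NL")], seed=0)


# --------------------------------------------------------------------------
# training loop (patience arithmetic probed with a stub model)
# --------------------------------------------------------------------------

class _StubModel:
    """Minimal model interface with a scripted validation-loss trajectory."""

    def __init__(self, logits_per_epoch):
        self.logits_per_epoch = logits_per_epoch
        self.calls = 0

    def forward_logits(self, x, training=False):
        if training:
            return np.zeros((len(x), 1))
        self.calls += 1
        return np.full((len(x), 1), self.logits_per_epoch(self.calls))

    def backward(self, grad):
        return grad

    def parameters(self):
        return []

    def get_state(self):
        return []

    def set_state(self, state):
        pass


def _samples(n, side=8, channels=1, label_fn=lambda i: i % 2):
    rng = np.random.default_rng(0)
    return [
        ProtocolSample(rng.normal(size=(channels, side, side)), label_fn(i), f"P{i}", 0)
        for i in range(n)
    ]


def _run_stub(logits_per_epoch, max_epochs=30):
    cfg = TrainConfig(max_epochs=max_epochs, patience=16, batch_size=4,
                      augment=False, seed=0)
    model = _StubModel(logits_per_epoch)
    # validation labels all positive: a rising logit means falling loss
    _, history = train(model, _samples(8), _samples(4, label_fn=lambda i: 1), cfg)
    return history


def test_constant_validation_loss_stops_after_one_plus_patience_epochs():
    history = _run_stub(lambda epoch: 0.3)
    assert len(history["val_loss"]) == 17  # 1 improving + 16 stale


def test_improving_validation_loss_runs_to_max_epochs():
    history = _run_stub(lambda epoch: 0.01 * epoch, max_epochs=25)
    assert len(history["val_loss"]) == 25


def test_real_training_reduces_loss_on_separable_data():
    """A linearly separable two-class toy (channel mean encodes the label)
    must show a decreasing loss trend with the real CNN."""
    rng = np.random.default_rng(1)
    samples = []
    for i in range(24):
        label = i % 2
        tensor = rng.normal(loc=2.0 * label - 1.0, scale=0.5, size=(1, 16, 16))
        samples.append(ProtocolSample(tensor, label, f"P{i}", 0))
    model = build_model(ModelConfig(
        in_channels=1, input_side=16, base_filters=4, residual_filters=(4, 4, 8),
        fc_units=(8, 4), seed=0,
    ))
    cfg = TrainConfig(learning_rate=0.05, max_epochs=12, patience=16,
                      batch_size=8, augment=False, seed=0)
    _, history = train(model, samples[:16], samples[16:], cfg)
    assert history["train_loss"][-1] < history["train_loss"][0]


def test_empty_sets_rejected():
    with pytest.raises(ValueError):
        train(_StubModel(lambda e: 0.0), [], _samples(2), TrainConfig())


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

class _FixedProbModel:
    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_proba(self, x, batch_size=32):
        return self.probs[: len(x)]


def test_perfect_separation_scores_unity():
    samples = _samples(6, label_fn=lambda i: 1 if i < 3 else 0)
    model = _FixedProbModel([0.9, 0.9, 0.9, 0.1, 0.1, 0.1])
    report, probs = evaluate_slices(model, samples, threshold=0.5)
    assert report.accuracy == 1.0
    assert report.auc == 1.0
    assert report.f1 == 1.0


def test_threshold_tie_rule_counts_half_as_positive():
    samples = _samples(6, label_fn=lambda i: 1 if i < 3 else 0)
    model = _FixedProbModel([0.5] * 6)
    report, _ = evaluate_slices(model, samples, threshold=0.5)
    assert report.sensitivity == 1.0
    assert report.specificity == 0.0


def test_auc_equals_mann_whitney_pairwise_oracle():
    rng = np.random.default_rng(7)
    y = np.array([1] * 8 + [0] * 12)
    probs = rng.random(20)
    report = report_from_predictions(y, (probs >= 0.5).astype(int), probs)
    pos = probs[y == 1]
    neg = probs[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    assert report.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


def test_single_class_test_set_reports_missing_auc_with_warning():
    with pytest.warns(UserWarning, match="single class"):
        report = report_from_predictions(
            np.ones(5), np.ones(5), probs=np.full(5, 0.8)
        )
    assert report.auc is None


def test_metric_identities_recomputed_from_confusion():
    rng = np.random.default_rng(11)
    for _ in range(20):
        y = (rng.random(30) < 0.5).astype(int)
        pred = (rng.random(30) < 0.5).astype(int)
        r = report_from_predictions(y, pred)
        tp, fp, tn, fn = r.tp, r.fp, r.tn, r.fn
        assert tp + fp + tn + fn == 30
        assert r.accuracy == pytest.approx((tp + tn) / 30)
        if 2 * tp + fp + fn:
            assert r.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))
        if tp + fn:
            assert r.sensitivity == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert r.specificity == pytest.approx(tn / (tn + fp))
        if tp + fp:
            assert r.ppv == pytest.approx(tp / (tp + fp))
        if tn + fn:
            assert r.npv == pytest.approx(tn / (tn + fn))


def test_patient_any_positive_slice_rule():
    samples = [
        ProtocolSample(np.zeros((1, 8, 8)), 1, "A", i) for i in range(3)
    ] + [ProtocolSample(np.zeros((1, 8, 8)), 0, "B", i) for i in range(2)]
    probs = np.array([0.2, 0.7, 0.4, 0.1, 0.2])
    report = evaluate_patients(
        probs, samples, {"A": "SCAR", "B": "NL"}, threshold=0.5
    )
    assert report.tp == 1 and report.tn == 1
    assert report.accuracy == 1.0


def test_patient_accuracy_forty_one_of_forty_two():
    samples = [ProtocolSample(np.zeros((1, 8, 8)), 0, f"P{i}", 0) for i in range(42)]
    labels = {f"P{i}": ("SCAR" if i < 30 else "NL") for i in range(42)}
    # all scar patients detected; one control (P30) falsely positive
    probs = np.array([0.9] * 30 + [0.9] + [0.1] * 11)
    report = evaluate_patients(probs, samples, labels, threshold=0.5)
    assert report.fp == 1 and report.fn == 0
    assert report.accuracy == pytest.approx(41 / 42)


def test_all_negative_predictions_on_mixed_cohort():
    samples = [ProtocolSample(np.zeros((1, 8, 8)), 0, f"P{i}", 0) for i in range(6)]
    labels = {f"P{i}": ("SCAR" if i < 3 else "NL") for i in range(6)}
    report = evaluate_patients(np.full(6, 0.2), samples, labels)
    assert report.specificity == 1.0
    assert report.sensitivity == 0.0


def test_patient_without_predictions_rejected():
    samples = [ProtocolSample(np.zeros((1, 8, 8)), 0, "A", 0)]
    with pytest.raises(ValueError, match="no slice predictions"):
        evaluate_patients(np.array([0.5]), samples, {"A": "SCAR", "B": "NL"})
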