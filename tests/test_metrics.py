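"""Closed-form metric checks, an AUC pair-counting oracle, and the
ablation-improvement arithmetic over the packaged results table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from timnet.exceptions import ValidationError
from timnet.metrics import (
    ConfusionCounts,
    ablation_improvement,
    compute_metrics,
    confusion_counts,
    default_ablation_table,
    dice,
    evaluate,
    load_ablation_table,
    roc_auc,
)


def counts_from(tp, fn, tn, fp):
    pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp, dtype=np.uint8)
    gt = np.array([1] * (tp + fn) + [0] * (tn + fp), dtype=np.uint8)
    return confusion_counts(pred, gt)


# ---------------------------------------------------------------- counts
def test_perfect_prediction_has_no_errors(rng):
    gt = (rng.random((10, 10)) > 0.6).astype(np.uint8)
    c = confusion_counts(gt, gt)
    assert c.fp == 0 and c.fn == 0
    assert c.tp == int(gt.sum()) and c.total == gt.size


def test_inverted_prediction_has_no_hits(rng):
    gt = (rng.random((10, 10)) > 0.6).astype(np.uint8)
    c = confusion_counts(1 - gt, gt)
    assert c.tp == 0 and c.tn == 0


def test_enumerated_counts_returned_exactly():
    c = counts_from(tp=3, fn=1, tn=5, fp=1)
    assert (c.tp, c.fn, c.tn, c.fp) == (3, 1, 5, 1)


def test_fov_restricts_the_counted_region():
    pred = np.array([[1, 1], [0, 0]], dtype=np.uint8)
    gt = np.array([[1, 0], [0, 1]], dtype=np.uint8)
    fov = np.array([[1, 0], [1, 0]], dtype=np.uint8)
    c = confusion_counts(pred, gt, fov)
    assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)


def test_shape_and_binarity_validation(rng):
    with pytest.raises(ValidationError):
        confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))
    with pytest.raises(ValidationError):
        confusion_counts(np.full((2, 2), 0.5), np.zeros((2, 2)))


# ---------------------------------------------------------------- Acc/Se/Sp
def test_perfect_counts_score_one():
    r = compute_metrics(ConfusionCounts(tp=7, tn=13, fp=0, fn=0))
    assert r.acc == r.se == r.sp == 1.0


def test_closed_form_example():
    r = compute_metrics(counts_from(tp=3, fn=1, tn=5, fp=1))
    assert r.se == pytest.approx(0.75)
    assert r.sp == pytest.approx(5 / 6)
    assert r.acc == pytest.approx(0.8)


def test_all_background_truth_leaves_sensitivity_undefined():
    r = compute_metrics(ConfusionCounts(tp=0, tn=8, fp=2, fn=0))
    assert r.se is None
    assert r.sp == pytest.approx(0.8)
    assert r.acc == pytest.approx(0.8)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    tp=st.integers(0, 50),
    fn=st.integers(0, 50),
    tn=st.integers(0, 50),
    fp=st.integers(0, 50),
)
def test_accuracy_is_prevalence_weighted_mix_of_se_and_sp(tp, fn, tn, fp):
    c = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    r = compute_metrics(c)
    pos, neg = tp + fn, tn + fp
    if pos and neg:
        assert r.acc == pytest.approx((pos * r.se + neg * r.sp) / (pos + neg))


# ---------------------------------------------------------------- AUC
def pair_counting_auc(scores, labels):
    """Mann-Whitney oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def test_separating_scores_give_auc_one():
    gt = np.array([0, 0, 1, 1], dtype=np.uint8)
    assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), gt) == pytest.approx(1.0)


def test_constant_scores_give_auc_half():
    gt = np.array([0, 1, 0, 1], dtype=np.uint8)
    assert roc_auc(np.full(4, 0.5), gt) == pytest.approx(0.5)


def test_auc_matches_pair_counting_oracle():
    scores = np.array([0.9, 0.4, 0.4, 0.7, 0.2, 0.1])
    labels = np.array([1, 1, 0, 0, 0, 1], dtype=np.uint8)
    assert roc_auc(scores, labels) == pytest.approx(pair_counting_auc(scores, labels))


def test_auc_random_instances_match_oracle():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(30), 2)  # coarse grid forces ties
        labels = (rng.random(30) > 0.5).astype(np.uint8)
        if labels.all() or not labels.any():
            continue
        assert roc_auc(scores, labels) == pytest.approx(pair_counting_auc(scores, labels))


def test_auc_single_class_is_undefined():
    assert roc_auc(np.array([0.2, 0.4]), np.array([1, 1], dtype=np.uint8)) is None


def test_auc_complement_symmetry(rng):
    scores = rng.random(40)  # continuous, tie-free
    labels = (rng.random(40) > 0.4).astype(np.uint8)
    assert roc_auc(1 - scores, labels) == pytest.approx(1 - roc_auc(scores, labels))


def test_metrics_invariant_to_pixel_ordering(rng):
    scores = rng.random(50)
    labels = (rng.random(50) > 0.5).astype(np.uint8)
    perm = rng.permutation(50)
    assert roc_auc(scores[perm], labels[perm]) == pytest.approx(roc_auc(scores, labels))
    pred = (scores > 0.5).astype(np.uint8)
    a, b = confusion_counts(pred, labels), confusion_counts(pred[perm], labels[perm])
    assert (a.tp, a.tn, a.fp, a.fn) == (b.tp, b.tn, b.fp, b.fn)


def test_evaluate_combines_threshold_metrics_and_auc(rng):
    gt = (rng.random((16, 16)) > 0.7).astype(np.uint8)
    prob = np.where(gt == 1, 0.9, 0.1)
    r = evaluate(prob, gt)
    assert r.acc == r.se == r.sp == 1.0 and r.auc == pytest.approx(1.0)


def test_dice_overlap():
    a = np.array([1, 1, 0, 0], dtype=np.uint8)
    b = np.array([1, 0, 1, 0], dtype=np.uint8)
    assert dice(a, b) == pytest.approx(0.5)
    assert dice(np.zeros(4, dtype=np.uint8), np.zeros(4, dtype=np.uint8)) == 1.0


# ---------------------------------------------------------------- ablation
def test_mean_se_gain_of_dual_attention_over_unet():
    """Mean Se gain of Backbone1+DA over Backbone1 across the three
    datasets, recomputed from the packaged table."""
    table = default_ablation_table()
    value = ablation_improvement(table, "Se", "Backbone1", "Backbone1+DA", ["DRIVE", "CHASEDB1", "STARE"])
    hand = ((0.7787 - 0.7042) + (0.7303 - 0.7430) + (0.8132 - 0.7371)) / 3
    assert value == pytest.approx(hand, abs=1e-12)


def test_single_dataset_improvement_is_plain_difference():
    table = default_ablation_table()
    value = ablation_improvement(table, "Se", "Backbone1", "Backbone2", ["DRIVE"])
    assert value == pytest.approx(0.7514 - 0.7042, abs=1e-12)


def test_identical_configs_give_zero_improvement():
    table = default_ablation_table()
    assert ablation_improvement(table, "Acc", "Backbone2", "Backbone2", ["DRIVE", "STARE"]) == 0.0


def test_improvement_is_antisymmetric():
    table = default_ablation_table()
    fwd = ablation_improvement(table, "AUC", "Backbone1", "Backbone2+DA", ["CHASEDB1", "STARE"])
    rev = ablation_improvement(table, "AUC", "Backbone2+DA", "Backbone1", ["CHASEDB1", "STARE"])
    assert fwd == pytest.approx(-rev, abs=1e-12)


def test_missing_row_names_the_offender():
    table = default_ablation_table()
    with pytest.raises(KeyError, match="HRF"):
        ablation_improvement(table, "Se", "Backbone1", "Backbone2", ["HRF"])


def test_table_roundtrips_through_csv(tmp_path):
    table = default_ablation_table()
    path = tmp_path / "results.csv"
    table.reset_index().to_csv(path, index=False)
    reloaded = load_ablation_table(path)
    assert reloaded.equals(table)
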