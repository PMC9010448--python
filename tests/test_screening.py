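"""Ground truth, confusion metrics, bootstrap CIs and the random baseline."""

import numpy as np
import pytest

from fragchal import (SubmissionRecordS1, bootstrap_ci, build_ground_truth,
                      evaluate_stage1, hit_rate, make_submission_with_accuracy,
                      random_null_submission, read_ground_truth_csv,
                      summarize_balanced_accuracies, write_ground_truth_csv)
from fragchal.errors import DegenerateDataError, ValidationError
from fragchal.screening import Label, metrics_from_confusion


def _constant_submission(gt, value):
    return [SubmissionRecordS1(fid, value) for fid in gt.non_excluded_ids]


def _perfect_submission(gt):
    return [SubmissionRecordS1(fid, gt.labels[fid] is Label.POSITIVE)
            for fid in gt.non_excluded_ids]


def test_ground_truth_bookkeeping(all_sites_ground_truth, kac_ground_truth):
    """52 hits + 40 exclusions in a 799 library leave 707 negatives;
    47 hits leave 712."""
    gt_all, gt_kac = all_sites_ground_truth, kac_ground_truth
    assert (gt_all.n_positive, gt_all.n_negative, gt_all.n_excluded) == (52, 707, 40)
    assert (gt_kac.n_positive, gt_kac.n_negative, gt_kac.n_excluded) == (47, 712, 40)
    assert gt_all.n_positive + gt_all.n_negative + gt_all.n_excluded == 799


def test_ground_truth_validation():
    with pytest.raises(ValidationError, match="not in library"):
        build_ground_truth(["F1"], ["F2"], [])
    with pytest.raises(ValidationError, match="both hit and excluded"):
        build_ground_truth(["F1", "F2"], ["F1"], ["F1"])
    gt = build_ground_truth(["F1", "F2"], [], [])
    assert gt.n_negative == 2


def test_ground_truth_csv_round_trip(tmp_path, kac_ground_truth):
    path = tmp_path / "gt.csv"
    write_ground_truth_csv(kac_ground_truth, path)
    back = read_ground_truth_csv(path)
    assert back.labels == kac_ground_truth.labels


@pytest.mark.parametrize("n_hits, n_library, expected", [
    (52, 799, 6.51), (47, 799, 5.88), (0, 799, 0.0), (799, 799, 100.0),
])
def test_hit_rate(n_hits, n_library, expected):
    assert hit_rate(n_hits, n_library) == expected


def test_hit_rate_domain_errors():
    with pytest.raises(ValidationError):
        hit_rate(1, 0)
    with pytest.raises(ValidationError):
        hit_rate(5, 3)


def test_perfect_and_all_positive_predictors(kac_ground_truth):
    gt = kac_ground_truth
    perfect = evaluate_stage1(_perfect_submission(gt), gt)
    assert (perfect.sensitivity, perfect.specificity,
            perfect.balanced_accuracy) == (1.0, 1.0, 1.0)
    allpos = evaluate_stage1(_constant_submission(gt, True), gt)
    assert allpos.sensitivity == 1.0
    assert allpos.specificity == 0.0
    assert allpos.balanced_accuracy == 0.5


def test_confusion_arithmetic_example():
    m = metrics_from_confusion(tp=5, fp=7, tn=700, fn=42)
    assert m.sensitivity == pytest.approx(5 / 47)
    assert m.specificity == pytest.approx(700 / 707)
    assert m.balanced_accuracy == pytest.approx((5 / 47 + 700 / 707) / 2)


def test_metrics_match_sklearn_on_simulated_submission(kac_ground_truth):
    """Independent cross-check against scikit-learn's implementation."""
    from sklearn.metrics import balanced_accuracy_score, recall_score

    gt = kac_ground_truth
    sub = make_submission_with_accuracy(gt, 0.6, 0.9, seed=11)
    m = evaluate_stage1(sub, gt)
    preds = {r.fragment_id: r.predicted_binder for r in sub}
    y_true = [gt.labels[f] is Label.POSITIVE for f in gt.non_excluded_ids]
    y_pred = [preds[f] for f in gt.non_excluded_ids]
    assert m.balanced_accuracy == pytest.approx(
        balanced_accuracy_score(y_true, y_pred), abs=1e-12)
    assert m.sensitivity == pytest.approx(recall_score(y_true, y_pred), abs=1e-12)


def test_excluded_fragments_never_influence_metrics(kac_ground_truth):
    gt = kac_ground_truth
    sub = make_submission_with_accuracy(gt, 0.7, 0.8, seed=2)
    base = evaluate_stage1(sub, gt)
    excluded_ids = [f for f, lab in gt.labels.items() if lab is Label.EXCLUDED]
    extended = sub + [SubmissionRecordS1(f, True) for f in excluded_ids]
    assert evaluate_stage1(extended, gt) == base


def test_missing_predictions_are_reported(kac_ground_truth):
    gt = kac_ground_truth
    sub = _perfect_submission(gt)[:-3]
    with pytest.raises(ValidationError, match="missing predictions"):
        evaluate_stage1(sub, gt)


def test_label_swap_maps_sensitivity_to_specificity(kac_ground_truth):
    """Swapping the positive/negative meaning swaps the two rates."""
    gt = kac_ground_truth
    lib = sorted(gt.labels)
    swapped = build_ground_truth(
        lib,
        [f for f, lab in gt.labels.items() if lab is Label.NEGATIVE],
        [f for f, lab in gt.labels.items() if lab is Label.EXCLUDED],
    )
    sub = make_submission_with_accuracy(gt, 0.6, 0.9, seed=3)
    inverted = [SubmissionRecordS1(r.fragment_id, not r.predicted_binder)
                for r in sub]
    m = evaluate_stage1(sub, gt)
    ms = evaluate_stage1(inverted, swapped)
    assert ms.sensitivity == pytest.approx(m.specificity)
    assert ms.specificity == pytest.approx(m.sensitivity)


def test_bootstrap_is_deterministic_and_degenerate_on_perfect(kac_ground_truth):
    gt = kac_ground_truth
    sub = make_submission_with_accuracy(gt, 0.6, 0.9, seed=7)
    ci1 = bootstrap_ci(sub, gt, "balanced_accuracy", seed=42)
    ci2 = bootstrap_ci(sub, gt, "balanced_accuracy", seed=42)
    assert ci1 == ci2  # bit-identical under a fixed seed
    assert ci1.lower <= ci1.point <= ci1.upper
    perfect = bootstrap_ci(_perfect_submission(gt), gt, "balanced_accuracy", seed=0)
    assert perfect.lower == perfect.upper == 1.0


def test_bootstrap_discards_undefined_resamples():
    """With a single positive, many resamples draw no positives; those are
    discarded and counted, not imputed."""
    gt = build_ground_truth([f"F{i}" for i in range(1, 41)], ["F1"], [])
    sub = _perfect_submission(gt)
    ci = bootstrap_ci(sub, gt, "sensitivity", n_resamples=2000, seed=1)
    assert ci.n_discarded > 0
    assert ci.lower == ci.upper == 1.0


def test_random_null_submission_extremes(kac_ground_truth):
    gt = kac_ground_truth
    all_neg = random_null_submission(gt, 0.0, seed=0)
    assert not any(r.predicted_binder for r in all_neg)
    all_pos = random_null_submission(gt, 1.0, seed=0)
    assert all(r.predicted_binder for r in all_pos)
    m = evaluate_stage1(all_pos, gt)
    assert m.balanced_accuracy == 0.5


def test_label_independent_predictor_averages_to_half(kac_ground_truth):
    """A random predictor's balanced accuracy converges to 0.5 regardless of
    its binder probability (reduced replicate count here; the full study runs
    in the acceptance suite)."""
    gt = kac_ground_truth
    bas = [evaluate_stage1(random_null_submission(gt, 0.1, seed=s), gt)
           .balanced_accuracy for s in range(200)]
    assert np.mean(bas) == pytest.approx(0.5, abs=0.03)


def test_simulated_submission_hits_target_rates(kac_ground_truth):
    """Empirical sensitivity/specificity of the generator match its targets
    to binomial error when averaged across seeds."""
    gt = kac_ground_truth
    sens, spec = [], []
    for s in range(300):
        m = evaluate_stage1(make_submission_with_accuracy(gt, 0.6, 0.9, seed=s), gt)
        sens.append(m.sensitivity)
        spec.append(m.specificity)
    assert np.mean(sens) == pytest.approx(0.6, abs=0.02)
    assert np.mean(spec) == pytest.approx(0.9, abs=0.005)


def test_balanced_accuracy_summary_labels_spreads():
    s = summarize_balanced_accuracies([0.49, 0.50, 0.51])
    assert s["mean"] == pytest.approx(0.5)
    assert s["sd"] == pytest.approx(0.01)
    assert s["sem"] == pytest.approx(0.01 / np.sqrt(3))
    assert s["n"] == 3


def test_all_undefined_resamples_raise():
    gt = build_ground_truth(["F1", "F2"], [], [])
    sub = _constant_submission(gt, False)
    with pytest.raises(DegenerateDataError):
        bootstrap_ci(sub, gt, "sensitivity", n_resamples=10, seed=0)
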