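import numpy as np
import pytest

from posturekit.annotation import AlignmentError, AnnotationTrack
from posturekit.labels import LABELS
from posturekit.metrics import (
    accuracy,
    auroc,
    cohens_kappa,
    confusion,
    interpret_kappa,
    iou_score,
)


def track(labels, unlabelled=None):
    labels = np.asarray(labels, dtype=np.uint8)
    if unlabelled is None:
        unlabelled = np.zeros(len(labels), dtype=bool)
    return AnnotationTrack(labels, np.asarray(unlabelled, dtype=bool))


def random_tracks(seed, max_len=200):
    rng = np.random.default_rng(seed)
    n = rng.integers(5, max_len + 1)
    return (
        track(rng.integers(0, 2, size=(n, 8))),
        track(rng.integers(0, 2, size=(n, 8))),
        rng,
    )


# ---------------------------------------------------------------- accuracy


class TestAccuracy:
    def test_identical_tracks_score_one(self):
        t = track(np.random.default_rng(0).integers(0, 2, size=(30, 8)))
        assert accuracy(t, t).micro == 1.0
        assert accuracy(t, t).macro == 1.0

    def test_complementary_tracks_score_zero(self):
        a = track(np.ones((20, 8)))
        b = track(np.zeros((20, 8)))
        assert accuracy(a, b).micro == 0.0

    def test_pooled_count_arithmetic(self):
        # one second, 8 label decisions: TP=3, FP=1, FN=1, TN=3 -> 6/8
        pred = track([[1, 1, 1, 1, 0, 0, 0, 0]])
        truth = track([[1, 1, 1, 0, 1, 0, 0, 0]])
        assert accuracy(pred, truth).micro == pytest.approx(0.75)

    def test_length_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            accuracy(track(np.zeros((3, 8))), track(np.zeros((4, 8))))

    def test_unlabelled_seconds_dropped_pairwise(self):
        pred = track([[1] * 8, [0] * 8], unlabelled=[False, True])
        truth = track([[1] * 8, [1] * 8])
        assert accuracy(pred, truth).micro == 1.0


# ---------------------------------------------------------------- IoU


class TestIoU:
    def test_perfect_prediction_is_one(self):
        t = track(np.random.default_rng(1).integers(0, 2, size=(40, 8)))
        assert iou_score(t, t).mean == pytest.approx(1.0)

    def test_direct_formula(self):
        # label 0: TP=2, FP=1, FN=1 -> IoU = 2/4; other labels all-negative
        pred = track([[1, 0, 0, 0, 0, 0, 0, 0]] * 2 + [[0] * 8] + [[1, 0, 0, 0, 0, 0, 0, 0]])
        truth = track([[1, 0, 0, 0, 0, 0, 0, 0]] * 3 + [[0] * 8])
        with pytest.warns(UserWarning, match="undefined"):
            result = iou_score(pred, truth)
        assert result.per_label["LY"] == pytest.approx(0.5)
        assert result.mean == pytest.approx(0.5)

    def test_all_negative_prediction_scores_zero(self):
        pred = track(np.zeros((10, 8)))
        labels = np.zeros((10, 8))
        labels[:, 2] = 1
        assert iou_score(pred, track(labels)).per_label["ST"] == 0.0


# ---------------------------------------------------------------- confusion


class TestConfusion:
    def test_identical_tracks_have_zero_error_rates(self):
        labels = np.random.default_rng(2).integers(0, 2, size=(50, 8))
        labels[0] = 1  # ensure both classes somewhere
        labels[1] = 0
        t = track(labels)
        table = confusion(t, t)
        for name in LABELS:
            assert table.rates[name]["FP"] in (0.0,) or np.isnan(table.rates[name]["FP"])
            assert table.rates[name]["FN"] in (0.0,) or np.isnan(table.rates[name]["FN"])

    def test_fn_rate_counts_missed_positives(self):
        # truth has 10 positives on LY; prediction misses 4 -> FN rate 0.4
        truth_labels = np.zeros((12, 8))
        truth_labels[:10, 0] = 1
        pred_labels = truth_labels.copy()
        pred_labels[:4, 0] = 0
        table = confusion(track(pred_labels), track(truth_labels))
        assert table.rates["LY"]["FN"] == pytest.approx(0.4)
        assert table.rates["LY"]["TP"] == pytest.approx(0.6)

    def test_rates_complement_within_truth_classes(self):
        pred, truth, _ = random_tracks(3)
        table = confusion(pred, truth)
        for name in LABELS:
            r = table.rates[name]
            if not np.isnan(r["TP"]):
                assert r["TP"] + r["FN"] == pytest.approx(1.0)
            if not np.isnan(r["TN"]):
                assert r["TN"] + r["FP"] == pytest.approx(1.0)


# ---------------------------------------------------------------- AUROC


def make_scores_truth(pos_scores, neg_scores):
    n = len(pos_scores) + len(neg_scores)
    scores = np.zeros((n, 8))
    labels = np.zeros((n, 8), dtype=np.uint8)
    scores[:, 0] = list(pos_scores) + list(neg_scores)
    labels[: len(pos_scores), 0] = 1
    labels[:, 1] = 1  # keep another label two-class free of warnings? no: constant
    return scores, track(labels)


class TestAuroc:
    def test_perfect_separation_is_one(self):
        scores, truth = make_scores_truth([0.9, 0.8], [0.2, 0.1])
        with pytest.warns(UserWarning):
            assert auroc(scores, truth)["LY"] == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        scores, truth = make_scores_truth([0.5, 0.5], [0.5, 0.5])
        with pytest.warns(UserWarning):
            assert auroc(scores, truth)["LY"] == pytest.approx(0.5)

    def test_pairwise_concordance_example(self):
        # pairs: (.9,.6)+, (.9,.1)+, (.4,.6)-, (.4,.1)+ -> 3/4
        scores, truth = make_scores_truth([0.9, 0.4], [0.6, 0.1])
        with pytest.warns(UserWarning):
            assert auroc(scores, truth)["LY"] == pytest.approx(0.75)

    def test_single_class_label_reported_nan_with_warning(self):
        scores, truth = make_scores_truth([0.9], [0.1])
        with pytest.warns(UserWarning, match="single-class"):
            out = auroc(scores, truth)
        assert np.isnan(out["SI"])


# ---------------------------------------------------------------- kappa


class TestKappa:
    def test_identical_tracks_with_both_classes(self):
        labels = np.zeros((20, 8), dtype=np.uint8)
        labels[:10] = 1
        t = track(labels)
        assert cohens_kappa(t, t).overall == pytest.approx(1.0)

    def test_closed_form_contingency_table(self):
        # a=40 both-positive, b=10, c=10, d=40 -> p_o=0.8, p_e=0.5, kappa=0.6
        a_col = np.array([1] * 40 + [1] * 10 + [0] * 10 + [0] * 40, dtype=np.uint8)
        b_col = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40, dtype=np.uint8)
        la = np.zeros((100, 8), dtype=np.uint8)
        lb = np.zeros((100, 8), dtype=np.uint8)
        la[:, 0], lb[:, 0] = a_col, b_col
        result = cohens_kappa(track(la), track(lb))
        assert result.per_label["LY"] == pytest.approx(0.6)
        assert result.overall == pytest.approx(0.6)  # only LY is defined

    def test_independent_tracks_have_near_zero_kappa(self):
        rng = np.random.default_rng(123)
        a = track(rng.integers(0, 2, size=(10_000, 8)))
        b = track(rng.integers(0, 2, size=(10_000, 8)))
        assert abs(cohens_kappa(a, b).overall) < 0.05

    def test_both_constant_is_undefined(self):
        t = track(np.zeros((10, 8)))
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(cohens_kappa(t, t).overall)


class TestInterpretKappa:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.89, "strong"),
            (0.10, "none"),
            (0.95, "almost perfect"),
            (-0.3, "none"),
            (0.30, "minimal"),
            (0.50, "weak"),
            (0.70, "moderate"),
            (0.20, "none"),
            (0.90, "strong"),
        ],
    )
    def test_bands(self, value, band):
        assert interpret_kappa(value) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.5)


# ------------------------------------------------- brute-force equivalence


def oracle_counts(pred, truth):
    """Exhaustive per-label counting, one comparison at a time."""
    counts = {}
    for j, name in enumerate(LABELS):
        tp = fp = tn = fn = 0
        for p, t in zip(pred[:, j], truth[:, j]):
            if p == 1 and t == 1:
                tp += 1
            elif p == 1 and t == 0:
                fp += 1
            elif p == 0 and t == 0:
                tn += 1
            else:
                fn += 1
        counts[name] = (tp, fp, tn, fn)
    return counts


def oracle_auroc(scores, truth):
    """All-pairs positive-vs-negative concordance, ties at one half."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


def oracle_kappa(a, b):
    n = len(a)
    p_o = float((a == b).mean())
    p_e = (a.mean() * b.mean()) + ((1 - a.mean()) * (1 - b.mean()))
    if p_e >= 1.0:
        return float("nan")
    return (p_o - p_e) / (1 - p_e)


@pytest.mark.parametrize("seed", range(100))
def test_metrics_match_brute_force_oracles(seed):
    pred, truth, rng = random_tracks(seed)
    counts = oracle_counts(pred.labels, truth.labels)

    total_correct = sum(tp + tn for tp, fp, tn, fn in counts.values())
    total = sum(sum(c) for c in counts.values())
    assert accuracy(pred, truth).micro == pytest.approx(total_correct / total, abs=1e-9)

    ious = [tp / (tp + fp + fn) for tp, fp, tn, fn in counts.values() if tp + fp + fn > 0]
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        got = iou_score(pred, truth)
        table = confusion(pred, truth)
        kappas = cohens_kappa(pred, truth)
        scores = rng.random((len(truth), 8))
        aucs = auroc(scores, truth)

    assert got.mean == pytest.approx(float(np.mean(ious)), abs=1e-9)
    for name, (tp, fp, tn, fn) in counts.items():
        assert table.counts[name] == {"TP": tp, "FP": fp, "TN": tn, "FN": fn}
        expected_kappa = oracle_kappa(pred.labels[:, LABELS.index(name)].astype(float),
                                      truth.labels[:, LABELS.index(name)].astype(float))
        if np.isnan(expected_kappa):
            assert np.isnan(kappas.per_label[name])
        else:
            assert kappas.per_label[name] == pytest.approx(expected_kappa, abs=1e-9)
        expected_auc = oracle_auroc(scores[:, LABELS.index(name)],
                                    truth.labels[:, LABELS.index(name)])
        if np.isnan(expected_auc):
            assert np.isnan(aucs[name])
        else:
            assert aucs[name] == pytest.approx(expected_auc, abs=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_metrics_invariant_under_joint_permutation(seed):
    pred, truth, rng = random_tracks(seed, max_len=80)
    perm = rng.permutation(len(pred))
    pred_p = track(pred.labels[perm])
    truth_p = track(truth.labels[perm])
    assert accuracy(pred, truth).micro == accuracy(pred_p, truth_p).micro
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        assert iou_score(pred, truth).mean == pytest.approx(iou_score(pred_p, truth_p).mean)


@pytest.mark.parametrize("seed", range(10))
def test_iou_never_exceeds_tp_rate(seed):
    pred, truth, _ = random_tracks(seed, max_len=80)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        iou = iou_score(pred, truth)
        table = confusion(pred, truth)
    for name in LABELS:
        if not np.isnan(iou.per_label[name]) and not np.isnan(table.rates[name]["TP"]):
            assert iou.per_label[name] <= table.rates[name]["TP"] + 1e-12
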