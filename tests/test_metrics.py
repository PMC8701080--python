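"""Recovery and clustering metrics, checked against from-scratch oracles."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rdaclone import (
    clustering_scores,
    confusion_counts,
    fpnr,
    fpnr_ratio,
    missing_accuracy,
    recovery_error,
    recovery_report,
)


def ari_oracle(a, b):
    """Adjusted Rand index from the contingency table, written from scratch."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ua, ub = np.unique(a), np.unique(b)
    table = np.array(
        [[(np.sum((a == x) & (b == y))) for y in ub] for x in ua]
    )
    sum_ij = sum(comb(int(v), 2) for v in table.ravel())
    sum_a = sum(comb(int(v), 2) for v in table.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in table.sum(axis=0))
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    maximum = (sum_a + sum_b) / 2
    if maximum == expected:
        return 1.0
    return (sum_ij - expected) / (maximum - expected)


# -- confusion / FPNR --------------------------------------------------------

def test_confusion_example():
    truth = np.array([[1, 0, 1, 0]])
    rec = np.array([[1, 1, 0, 0]])
    tp, fp, tn, fn = confusion_counts(rec, truth)
    assert (tp, fp, tn, fn) == (1, 1, 1, 1)
    assert fpnr(rec, truth) == pytest.approx(1.0)


def test_confusion_identity_and_partition(rng):
    truth = rng.integers(0, 2, size=(6, 8))
    assert confusion_counts(truth, truth)[1] == 0  # FP
    assert confusion_counts(truth, truth)[3] == 0  # FN
    rec = rng.integers(0, 2, size=(6, 8))
    scope = rng.random((6, 8)) > 0.4
    counts = confusion_counts(rec, truth, scope)
    assert sum(counts) == int(scope.sum())


def test_confusion_empty_scope():
    with pytest.raises(ValueError, match="empty"):
        confusion_counts(np.ones((2, 2)), np.ones((2, 2)), np.zeros((2, 2), bool))


def test_fpnr_extremes():
    truth = np.array([[1, 0], [0, 1]])
    assert fpnr(truth, truth) == 0.0
    assert fpnr(1 - truth, truth) == pytest.approx(2.0)


def test_fpnr_degenerate_class_warns():
    truth = np.ones((2, 2), dtype=int)
    with pytest.warns(UserWarning, match="FPR taken as 0"):
        v = fpnr(truth, truth)
    assert v == 0.0


# -- FPNR ratio --------------------------------------------------------------

def test_fpnr_ratio_perfect_recovery(rng):
    truth = rng.integers(0, 2, size=(5, 6))
    observed = truth.copy()
    observed[0, 0] = 1 - observed[0, 0]  # one flip of noise
    assert fpnr_ratio(truth, observed, truth) == 0.0


def test_fpnr_ratio_self_is_one(rng):
    truth = rng.integers(0, 2, size=(5, 6))
    noisy = np.abs(truth - (rng.random((5, 6)) < 0.2).astype(int))
    assert fpnr_ratio(noisy, noisy, truth) == pytest.approx(1.0)


def test_fpnr_ratio_undefined_for_clean_input(rng):
    truth = rng.integers(0, 2, size=(4, 4))
    assert fpnr_ratio(truth, truth, truth) is None


# -- imputation accuracy and error ------------------------------------------

def test_missing_accuracy_counts():
    truth = np.array([[1, 1], [0, 0]])
    rec = np.array([[1, 0], [0, 0]])
    oc = np.ones((2, 2), dtype=bool)
    assert missing_accuracy(rec, truth, oc) == pytest.approx(0.75)
    assert missing_accuracy(truth, truth, oc) == 1.0
    assert missing_accuracy(1 - truth, truth, oc) == 0.0
    assert missing_accuracy(rec, truth, np.empty((0, 2), dtype=int)) is None


def test_missing_accuracy_complements_error_rate(rng):
    truth = rng.integers(0, 2, size=(10, 10))
    rec = rng.integers(0, 2, size=(10, 10))
    oc = rng.random((10, 10)) > 0.5
    acc = missing_accuracy(rec, truth, oc)
    err = np.mean(rec[oc] != truth[oc])
    assert acc + err == pytest.approx(1.0)


def test_recovery_error_examples(rng):
    truth = rng.integers(0, 2, size=(2, 2))
    assert recovery_error(truth, truth) == 0.0
    assert recovery_error(1 - truth, truth) == 1.0
    one_off = truth.copy()
    one_off[0, 0] = 1 - one_off[0, 0]
    assert recovery_error(one_off, truth) == 0.25


def test_metrics_invariant_to_joint_permutation(rng):
    truth = rng.integers(0, 2, size=(8, 9))
    rec = rng.integers(0, 2, size=(8, 9))
    pr, pc = rng.permutation(8), rng.permutation(9)
    assert recovery_error(rec, truth) == recovery_error(
        rec[np.ix_(pr, pc)], truth[np.ix_(pr, pc)]
    )
    assert fpnr(rec, truth) == pytest.approx(
        fpnr(rec[np.ix_(pr, pc)], truth[np.ix_(pr, pc)])
    )


def test_recovery_report_f1_consistency(rng):
    truth = rng.integers(0, 2, size=(12, 12))
    rec = rng.integers(0, 2, size=(12, 12))
    mask = (rng.random((12, 12)) > 0.3).astype(float)
    rep = recovery_report(rec, truth, np.where(mask > 0, truth, 0), mask)
    if rep.precision + rep.recall > 0:
        assert rep.f1 == pytest.approx(
            2 * rep.precision * rep.recall / (rep.precision + rep.recall)
        )
    assert rep.error == pytest.approx((rep.fp + rep.fn) / truth.size)


# -- clustering scores -------------------------------------------------------

def test_identical_partitions_score_one():
    rep = clustering_scores([0, 0, 1, 1, 2], [0, 0, 1, 1, 2])
    assert rep.ari == rep.nmi == rep.v_measure == 1.0


def test_label_permutation_invariance():
    assert clustering_scores([0, 0, 1, 1], [1, 1, 0, 0]).ari == 1.0


def test_ari_matches_contingency_oracle(rng):
    for _ in range(50):
        a = rng.integers(0, 4, size=12)
        b = rng.integers(0, 4, size=12)
        assert clustering_scores(a, b).ari == pytest.approx(
            ari_oracle(a, b), abs=1e-12
        )


@given(st.lists(st.integers(0, 3), min_size=4, max_size=12))
def test_ari_bounded_and_relabel_invariant(labels):
    labels = np.array(labels)
    rng = np.random.default_rng(0)
    other = rng.integers(0, 3, size=len(labels))
    score = clustering_scores(labels, other).ari
    assert score <= 1.0 + 1e-12
    remap = {v: i for i, v in enumerate(dict.fromkeys(labels.tolist()))}
    relabeled = np.array([remap[v] for v in labels.tolist()])
    assert clustering_scores(relabeled, other).ari == pytest.approx(score)


def test_clustering_scores_length_mismatch():
    with pytest.raises(ValueError):
        clustering_scores([0, 1], [0, 1, 2])
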