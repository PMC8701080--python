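"""Recovery and clustering accuracy metrics.

Genotype recovery is scored against the simulated ground truth by
  * FPNR = FPR + FNR = FP/(FP+TN) + FN/(FN+TP), where "positive" means a
    mutation call of 1;
  * the FPNR ratio (recovered matrix over raw input matrix — values below 1
    mean the decomposition removed noise);
  * missing-imputation accuracy: the fraction of entries in Ω̄ (the missing
    set) whose recovered call equals the truth;
  * overall error: the fraction of all n·m entries recovered incorrectly.

Clustering is scored by the adjusted Rand index, plus NMI (arithmetic-mean
normalisation) and V-measure as auxiliary views of partition agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    v_measure_score,
)


@dataclass
class RecoveryReport:
    fpnr_recovered: float
    fpnr_input: float
    fpnr_ratio: float | None
    missing_accuracy: float | None
    error: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ClusterReport:
    ari: float
    nmi: float
    v_measure: float

    def to_dict(self) -> dict:
        return asdict(self)


def _as_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary")
    return a


def confusion_counts(
    recovered: np.ndarray,
    truth: np.ndarray,
    scope: np.ndarray | None = None,
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) over ``scope`` (boolean mask or index pair array).

    Positive = mutation present (1).  scope=None means every entry.
    """
    recovered = _as_binary(recovered, "recovered")
    truth = _as_binary(truth, "truth")
    if recovered.shape != truth.shape:
        raise ValueError("recovered and truth shapes differ")
    if scope is None:
        r, t = recovered.ravel(), truth.ravel()
    elif isinstance(scope, np.ndarray) and scope.dtype == bool:
        r, t = recovered[scope], truth[scope]
    else:
        scope = np.asarray(scope)
        r = recovered[scope[:, 0], scope[:, 1]]
        t = truth[scope[:, 0], scope[:, 1]]
    if r.size == 0:
        raise ValueError("empty evaluation scope")
    tp = int(np.sum((r == 1) & (t == 1)))
    fp = int(np.sum((r == 1) & (t == 0)))
    tn = int(np.sum((r == 0) & (t == 0)))
    fn = int(np.sum((r == 0) & (t == 1)))
    return tp, fp, tn, fn


def fpnr(
    recovered: np.ndarray,
    truth: np.ndarray,
    scope: np.ndarray | None = None,
) -> float:
    """False-positive rate + false-negative rate over the scope.

    If the truth has no negatives (or no positives) in scope, the undefined
    rate is taken as 0 with a warning.
    """
    tp, fp, tn, fn = confusion_counts(recovered, truth, scope)
    if fp + tn == 0:
        warnings.warn("no true negatives in scope; FPR taken as 0", stacklevel=2)
        fpr = 0.0
    else:
        fpr = fp / (fp + tn)
    if fn + tp == 0:
        warnings.warn("no true positives in scope; FNR taken as 0", stacklevel=2)
        fnr = 0.0
    else:
        fnr = fn / (fn + tp)
    return fpr + fnr


def fpnr_ratio(
    recovered: np.ndarray,
    observed: np.ndarray,
    truth: np.ndarray,
    omega_mask: np.ndarray | None = None,
) -> float | None:
    """FPNR of the recovered matrix (all entries) over FPNR of the input.

    The input-side FPNR is computed on observed entries only — a missing
    entry carries no call that could be wrong.  Returns None when the input
    FPNR is zero (noise-free input: the ratio is undefined).
    """
    scope = None
    if omega_mask is not None:
        scope = np.asarray(omega_mask, dtype=bool)
    denom = fpnr(observed, truth, scope)
    if denom == 0:
        return None
    return fpnr(recovered, truth, None) / denom


def missing_accuracy(
    recovered: np.ndarray,
    truth: np.ndarray,
    omega_complement: np.ndarray,
) -> float | None:
    """Fraction of missing entries whose recovered call matches the truth.

    ``omega_complement``: boolean mask or (row, col) index array of Ω̄.  The
    denominator is the exact |Ω̄| (identical to n·m·MR when MR is exact).
    Returns None when Ω̄ is empty.
    """
    recovered = _as_binary(recovered, "recovered")
    truth = _as_binary(truth, "truth")
    oc = np.asarray(omega_complement)
    if oc.dtype == bool:
        r, t = recovered[oc], truth[oc]
    else:
        if oc.size == 0:
            return None
        r = recovered[oc[:, 0], oc[:, 1]]
        t = truth[oc[:, 0], oc[:, 1]]
    if r.size == 0:
        return None
    return float(np.mean(r == t))


def recovery_error(recovered: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of all entries recovered incorrectly."""
    recovered = _as_binary(recovered, "recovered")
    truth = _as_binary(truth, "truth")
    if recovered.shape != truth.shape:
        raise ValueError("recovered and truth shapes differ")
    return float(np.mean(recovered != truth))


def recovery_report(
    recovered: np.ndarray,
    truth: np.ndarray,
    observed: np.ndarray,
    omega_mask: np.ndarray,
) -> RecoveryReport:
    """All recovery metrics in one bundle.

    ``observed`` is the raw input with missing entries encoded arbitrarily;
    only its values on Ω (per ``omega_mask``) are consulted.
    """
    omega_mask = np.asarray(omega_mask, dtype=bool)
    tp, fp, tn, fn = confusion_counts(recovered, truth, None)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    obs_clean = np.where(omega_mask, observed, 0).astype(np.int8)
    fpnr_in = fpnr(obs_clean, truth, omega_mask)
    fpnr_rec = fpnr(recovered, truth, None)
    ratio = fpnr_rec / fpnr_in if fpnr_in > 0 else None
    oc = ~omega_mask
    macc = missing_accuracy(recovered, truth, oc) if oc.any() else None
    return RecoveryReport(
        fpnr_recovered=fpnr_rec,
        fpnr_input=fpnr_in,
        fpnr_ratio=ratio,
        missing_accuracy=macc,
        error=recovery_error(recovered, truth),
        precision=precision,
        recall=recall,
        f1=f1,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def clustering_scores(
    pred_labels: np.ndarray, true_labels: np.ndarray
) -> ClusterReport:
    """ARI / NMI / V-measure between a predicted and a reference partition."""
    pred = np.asarray(pred_labels).ravel()
    true = np.asarray(true_labels).ravel()
    if pred.shape != true.shape:
        raise ValueError("label vectors have different lengths")
    if pred.size == 0:
        raise ValueError("empty label vectors")
    return ClusterReport(
        ari=float(adjusted_rand_score(true, pred)),
        nmi=float(
            normalized_mutual_info_score(true, pred, average_method="arithmetic")
        ),
        v_measure=float(v_measure_score(true, pred)),
    )
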