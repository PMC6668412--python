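"""Comparison machinery: LOOCV classification, AUC/mAUC, overlap, correlation.

Population classification uses a multinomial logit on the top-ranked
genotype codes, evaluated by leave-one-out cross-validation.  Because top
ancestry-informative markers typically separate populations perfectly, the
unpenalized maximum-likelihood fit diverges; a small L2 ridge keeps the
coefficients finite without changing the argmax predictions.

Per-class AUC follows the confusion-count formula
AUC = 1 - 0.5 (x/n + (e - x)/m) with n true negatives, m true positives,
e total binarized errors and x false positives; the multiclass summary
mAUC is the class-proportion-weighted sum of one-vs-rest AUCs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.proportion import proportion_confint

from .containers import ContractError, GenotypeMatrix, LeikitError, MarkerScoreVector
from .estimate import QMatrix
from .rankers import _imputed_codes, _require_labels


class UndefinedClassError(LeikitError):
    """AUC is undefined when a class has no positives or no negatives."""


@dataclass
class ClassificationResult:
    """LOOCV classification summary for one marker subset."""

    n_markers_used: int
    class_names: list[str]
    confusion: np.ndarray  # k x k, rows = truth, columns = prediction
    accuracy: float
    accuracy_ci95: tuple[float, float]
    per_class_auc: np.ndarray
    mauc: float

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=np.int64)
        if not (0 <= self.accuracy <= 1):
            raise ContractError("accuracy outside [0, 1]")
        lo, hi = self.accuracy_ci95
        if not (lo - 1e-12 <= self.accuracy <= hi + 1e-12):
            raise ContractError("confidence interval does not contain accuracy")


def loocv_classify(G: GenotypeMatrix, ridge: float = 1e-4) -> ClassificationResult:
    """Leave-one-out multinomial-logit classification of population labels.

    For each sample, the model log(p_i/p_k) = beta_0i + sum_j beta_ji x_j is
    fitted on the remaining samples (L2 penalty strength ``ridge``) and the
    left-out sample is assigned to the class with maximal predicted
    probability.  Returns the confusion matrix, accuracy with an exact
    Clopper-Pearson 95% CI, per-class one-vs-rest AUCs and mAUC.
    """
    labels = _require_labels(G)
    classes = sorted(set(labels.tolist()))
    k = len(classes)
    counts = {cls: int((labels == cls).sum()) for cls in classes}
    if min(counts.values()) < 2:
        raise ContractError("every population needs >= 2 samples for LOOCV")
    X = _imputed_codes(G)
    y = labels.astype(str)
    n = len(y)
    preds = np.empty(n, dtype=object)
    model = LogisticRegression(C=1.0 / ridge, max_iter=5000, solver="lbfgs")
    for i in range(n):
        keep = np.arange(n) != i
        model.fit(X[keep], y[keep])
        preds[i] = model.predict(X[i : i + 1])[0]
    index = {cls: j for j, cls in enumerate(classes)}
    confusion = np.zeros((k, k), dtype=np.int64)
    for truth, pred in zip(y, preds):
        confusion[index[truth], index[pred]] += 1
    correct = int(np.trace(confusion))
    accuracy = correct / n
    lo, hi = proportion_confint(correct, n, alpha=0.05, method="beta")
    per_class = per_class_auc_from_confusion(confusion)
    proportions = confusion.sum(axis=1) / n
    return ClassificationResult(
        n_markers_used=G.n_markers,
        class_names=classes,
        confusion=confusion,
        accuracy=accuracy,
        accuracy_ci95=(float(lo), float(hi)),
        per_class_auc=per_class,
        mauc=mauc(per_class, proportions),
    )


def binary_auc(
    n_true_negative: int, m_true_positive: int, e_errors: int, x_false_positives: int
) -> float:
    """Confusion-count AUC: 1 - 0.5 (x/n + (e - x)/m)."""
    n, m, e, x = n_true_negative, m_true_positive, e_errors, x_false_positives
    if n <= 0 or m <= 0:
        raise UndefinedClassError("AUC undefined without both positives and negatives")
    if not (0 <= x <= e and x <= n and e - x <= m):
        raise ContractError("inconsistent error counts")
    return 1.0 - 0.5 * (x / n + (e - x) / m)


def per_class_auc_from_confusion(confusion: np.ndarray) -> np.ndarray:
    """One-vs-rest AUC per class from hard confusion counts."""
    confusion = np.asarray(confusion, dtype=np.int64)
    k = confusion.shape[0]
    total = confusion.sum()
    aucs = np.empty(k)
    for i in range(k):
        m = int(confusion[i].sum())  # actual positives
        n = int(total - m)  # actual negatives
        x = int(confusion[:, i].sum() - confusion[i, i])  # false positives
        fn = int(confusion[i].sum() - confusion[i, i])  # false negatives
        aucs[i] = binary_auc(n, m, x + fn, x)
    return aucs


def mauc(per_class_auc: np.ndarray, class_proportions: np.ndarray) -> float:
    """Weighted multiclass AUC: sum_i AUC_i * p_i with p on the simplex."""
    p = np.asarray(class_proportions, dtype=float)
    a = np.asarray(per_class_auc, dtype=float)
    if a.shape != p.shape:
        raise ContractError("per-class AUCs and proportions differ in length")
    if np.any(p < 0) or abs(p.sum() - 1) > 1e-8:
        raise ContractError("class proportions must lie on the simplex")
    return float(a @ p)


def topn_overlap(rankings: list[MarkerScoreVector], N: int) -> dict:
    """Membership analysis of top-N sets across ranking methods.

    Each marker in the union of the top-N sets receives a bit-vector over
    methods (1 = selected by that method).  Returns per-marker patterns,
    counts per pattern, and pairwise intersection counts.
    """
    universe = set(rankings[0].marker_ids)
    for r in rankings[1:]:
        if set(r.marker_ids) != universe:
            raise ContractError("rankings do not share a marker universe")
    if N > len(universe):
        raise ContractError("N exceeds the number of markers")
    methods = [r.method_name for r in rankings]
    tops = [set(r.top(N)) for r in rankings]
    union = sorted(set().union(*tops))
    patterns = {
        mid: "".join("1" if mid in t else "0" for t in tops) for mid in union
    }
    pattern_counts: dict[str, int] = {}
    for pat in patterns.values():
        pattern_counts[pat] = pattern_counts.get(pat, 0) + 1
    pairwise = {
        (methods[a], methods[b]): len(tops[a] & tops[b])
        for a, b in itertools.combinations(range(len(rankings)), 2)
    }
    return {
        "methods": methods,
        "patterns": patterns,
        "pattern_counts": pattern_counts,
        "pairwise_intersections": pairwise,
    }


def q_correlations(
    estimates: list[QMatrix], ancestry_column: str
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson correlation of one ancestry column across estimates.

    Returns (correlation matrix, undefined flags); a pair is flagged and its
    correlation set to NaN when either column has zero variance.
    """
    n = len(estimates[0].individual_ids)
    for est in estimates[1:]:
        if len(est.individual_ids) != n:
            raise ContractError("estimates cover different individuals")
    cols = [est.column(ancestry_column) for est in estimates]
    m = len(cols)
    corr = np.eye(m)
    undefined = np.zeros((m, m), dtype=bool)
    for a, b in itertools.combinations(range(m), 2):
        if np.std(cols[a]) == 0 or np.std(cols[b]) == 0:
            corr[a, b] = corr[b, a] = np.nan
            undefined[a, b] = undefined[b, a] = True
        else:
            r = float(np.corrcoef(cols[a], cols[b])[0, 1])
            corr[a, b] = corr[b, a] = r
    return corr, undefined
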