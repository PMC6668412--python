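"""Machine-learning baseline marker rankers: PCA, random forest, linear SVM.

Each scorer consumes a labeled (RF/SVM) or unlabeled (PCA) genotype matrix
and emits a :class:`~leikit.containers.MarkerScoreVector` directly
comparable with the LEI and F_ST rankings:

* PCA: b_j = max(|a_1j|, |a_2j|), the larger absolute loading of marker j
  on the first two principal components of the column-centered code matrix.
* RF: mean decrease in Gini impurity over an ensemble of 500 classification
  trees, normalized to sum to 1.
* SVM: omega_j = (1/k) sum_i |w_ij| over the k one-vs-rest linear
  maximum-margin classifiers (squared-hinge loss, C = 1).
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import LinearSVC

from .containers import MISSING, ContractError, GenotypeMatrix, MarkerScoreVector
from .lei import rank_markers


class RankDeficiencyError(ContractError):
    """Fewer than two nonzero principal components exist."""


def _imputed_codes(G: GenotypeMatrix) -> np.ndarray:
    """Codes as float with missing entries imputed to the marker mean."""
    X = G.codes.astype(float)
    mask = G.codes == MISSING
    if mask.any():
        X[mask] = np.nan
        col_mean = np.nanmean(X, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        X[mask] = np.take(col_mean, np.nonzero(mask)[1])
    return X


def _require_labels(G: GenotypeMatrix) -> np.ndarray:
    if G.population_labels is None:
        raise ContractError("this scorer requires population labels")
    labels = np.asarray(G.population_labels, dtype=object)
    if len(set(labels.tolist())) < 2:
        raise ContractError("labels contain a single class")
    return labels


def pca_scores(G: GenotypeMatrix) -> MarkerScoreVector:
    """Score markers by their largest absolute loading on PC1/PC2.

    The code matrix is column mean-centered (no variance scaling) before the
    decomposition; exactly the first two components are used.  Eigenvector
    signs are canonicalized (largest-magnitude loading positive) for stable
    serialized output, though scores only use absolute values.
    """
    if G.n_samples < 3 or G.n_markers < 2:
        raise ContractError("PCA scoring needs >= 3 samples and >= 2 markers")
    X = _imputed_codes(G)
    X = X - X.mean(axis=0)
    pca = PCA(n_components=2, svd_solver="auto", random_state=0)
    pca.fit(X)
    if np.count_nonzero(pca.singular_values_ > 1e-10) < 2:
        raise RankDeficiencyError("genotype matrix has fewer than 2 nonzero components")
    loadings = pca.components_  # 2 x L, unit-norm rows
    flip = np.sign(loadings[np.arange(2), np.abs(loadings).argmax(axis=1)])
    loadings = loadings * flip[:, None]
    scores = np.abs(loadings).max(axis=0)
    return rank_markers(
        MarkerScoreVector(
            method_name="pca",
            marker_ids=list(G.marker_ids),
            scores=scores,
            chrom=G.chrom,
            bp=G.bp,
        )
    )


def rf_scores(
    G: GenotypeMatrix, n_trees: int = 500, seed: int = 0
) -> MarkerScoreVector:
    """Score markers by random-forest Gini importance (labels required).

    ``n_trees`` classification trees are grown on codes -> population with
    scikit-learn defaults otherwise; importances are normalized to sum to 1
    and are bit-reproducible given ``seed``.
    """
    labels = _require_labels(G)
    rf = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", random_state=seed, n_jobs=1
    )
    rf.fit(_imputed_codes(G), labels.astype(str))
    importances = rf.feature_importances_
    total = importances.sum()
    if total > 0:
        importances = importances / total
    return rank_markers(
        MarkerScoreVector(
            method_name="rf",
            marker_ids=list(G.marker_ids),
            scores=importances,
            chrom=G.chrom,
            bp=G.bp,
        )
    )


def svm_scores(G: GenotypeMatrix, regularization: float = 1.0) -> MarkerScoreVector:
    """Score markers by mean absolute one-vs-rest linear-SVM weight.

    Fits k one-vs-rest linear classifiers (squared-hinge loss,
    C = ``regularization``) and scores marker j as the average of |w_ij|
    over classes.  With k = 2 the two implicit weight vectors are sign
    flips, so the score equals |w_j| of the single fitted separator.
    """
    labels = _require_labels(G)
    svc = LinearSVC(
        C=regularization,
        loss="squared_hinge",
        multi_class="ovr",
        max_iter=20000,
        random_state=0,
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            svc.fit(_imputed_codes(G), labels.astype(str))
        except ConvergenceWarning as exc:
            raise ContractError(
                "linear SVM failed to converge within the iteration cap"
            ) from exc
    scores = np.abs(svc.coef_).mean(axis=0)
    return rank_markers(
        MarkerScoreVector(
            method_name="svm",
            marker_ids=list(G.marker_ids),
            scores=scores,
            chrom=G.chrom,
            bp=G.bp,
        )
    )
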