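"""Supervised maximum-likelihood estimation of global ancestry proportions.

Given reference allele frequencies ``f_kl`` for K source populations at L
selected markers and an individual's genotype dosages ``g_l`` (reference
allele counts, 0/1/2), the admixture log-likelihood is

    ell(q) = sum_l [ g_l log(sum_k q_k f_kl) + (2 - g_l) log(sum_k q_k (1 - f_kl)) ]

maximized over the K-simplex by the standard multiplicative EM update

    q_k <- q_k / (2 L') * sum_l [ g_l f_kl / p_l + (2 - g_l)(1 - f_kl) / (1 - p_l') ]

with p_l = sum_m q_m f_ml and L' the individual's non-missing marker count.
The update is monotone in ell and keeps q on the simplex.  This plays the
role of a supervised ("projection") run of an admixture-clustering program:
the reference panel frequencies are treated as known, which removes
label-switching and any dependence on an external binary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import ContractError, GenotypeMatrix, LeikitError, PopAlleleFreqTable

_FREQ_EPS = 1e-6


class EstimationError(LeikitError):
    """The likelihood is non-finite or the inputs are unusable."""


class FlatLikelihoodWarning(UserWarning):
    """All populations have identical frequencies: q is unidentifiable."""


@dataclass
class QMatrix:
    """n x K ancestry-proportion estimates, rows on the simplex."""

    individual_ids: list[str]
    population_names: list[str]
    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.individual_ids), len(self.population_names)):
            raise ContractError("q shape does not match ids x populations")
        if np.any(self.q < -1e-8) or np.max(np.abs(self.q.sum(axis=1) - 1)) > 1e-8:
            raise ContractError("q rows must lie on the simplex")

    def column(self, population: str | int) -> np.ndarray:
        if isinstance(population, str):
            population = self.population_names.index(population)
        return self.q[:, population]


def estimate_q(
    G: GenotypeMatrix,
    F: PopAlleleFreqTable,
    tol: float = 1e-6,
    max_iter: int = 1000,
    return_history: bool = False,
) -> QMatrix | tuple[QMatrix, np.ndarray]:
    """EM estimate of each individual's ancestry proportions.

    ``G`` and ``F`` must cover the same markers in the same order.
    Frequencies are clamped to [1e-6, 1 - 1e-6] to keep fixed alleles from
    producing log(0).  Missing genotypes are skipped per individual.  The
    log-likelihood is non-decreasing across iterations; iteration stops when
    every individual's gain falls below ``tol`` or after ``max_iter``.

    With ``return_history=True`` also returns the iterations x n
    per-individual log-likelihood trajectory.
    """
    if G.n_markers == 0:
        raise EstimationError("empty marker subset")
    if G.marker_ids != F.marker_ids:
        raise EstimationError("marker sets of genotypes and frequencies differ")
    K = F.n_populations
    if K < 2:
        raise EstimationError("need at least two reference populations")

    f = np.clip(F.f, _FREQ_EPS, 1 - _FREQ_EPS)  # L x K
    if np.max(f.max(axis=1) - f.min(axis=1)) < 1e-12:
        warnings.warn(
            "reference frequencies identical across populations; "
            "ancestry proportions are unidentifiable, returning uniform q",
            FlatLikelihoodWarning,
            stacklevel=2,
        )
        q = np.full((G.n_samples, K), 1.0 / K)
        result = QMatrix(list(G.sample_ids), list(F.population_names), q)
        return (result, np.empty((0, G.n_samples))) if return_history else result

    codes = G.codes.astype(float)  # n x L
    observed = codes >= 0
    g = np.where(observed, codes, 0.0)
    g2 = np.where(observed, 2.0 - codes, 0.0)
    L_prime = observed.sum(axis=1).astype(float)
    if np.any(L_prime == 0):
        raise EstimationError("an individual has no non-missing genotype")

    q = np.full((G.n_samples, K), 1.0 / K)
    prev_ll = _loglik(q, f, g, g2)
    history = [prev_ll]
    for _ in range(max_iter):
        p_ref = q @ f.T  # n x L: P(reference allele)
        p_alt = q @ (1 - f).T
        # E-step responsibilities folded into the multiplicative update
        num = (g / p_ref) @ f + (g2 / p_alt) @ (1 - f)  # n x K
        q = q * num / (2.0 * L_prime)[:, None]
        q /= q.sum(axis=1, keepdims=True)  # guard drift; sums are 1 analytically
        ll = _loglik(q, f, g, g2)
        if not np.all(np.isfinite(ll)):
            bad = int(np.argmax(~np.isfinite(ll)))
            raise EstimationError(
                f"non-finite likelihood for individual {G.sample_ids[bad]!r}"
            )
        history.append(ll)
        if np.max(ll - prev_ll) < tol:
            prev_ll = ll
            break
        prev_ll = ll
    result = QMatrix(list(G.sample_ids), list(F.population_names), q)
    return (result, np.asarray(history)) if return_history else result


def _loglik(q: np.ndarray, f: np.ndarray, g: np.ndarray, g2: np.ndarray) -> np.ndarray:
    p_ref = q @ f.T
    p_alt = q @ (1 - f).T
    return (g * np.log(p_ref) + g2 * np.log(p_alt)).sum(axis=1)


def rmse_two_way(
    qhat: QMatrix, qtrue: QMatrix, population: str | int = 1
) -> float:
    """Two-way RMSE on the designated ancestry column.

    sqrt( (1/n) sum_i (qhat_i - q_i)^2 ).  By default the second population
    column is compared (the convention here: the minority/second panel).
    """
    if len(qhat.individual_ids) != len(qtrue.individual_ids):
        raise ContractError("Q matrices cover different individuals")
    a = qhat.column(population)
    b = qtrue.column(population)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def rmse_three_way(qhat: QMatrix, qtrue: QMatrix) -> float:
    """Multi-way RMSE: sqrt( (1/(nK)) sum_i sum_k (qhat_ik - q_ik)^2 )."""
    if qhat.q.shape != qtrue.q.shape:
        raise ContractError("Q matrices have different shapes")
    return float(np.sqrt(np.mean((qhat.q - qtrue.q) ** 2)))
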