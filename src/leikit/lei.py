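"""Lancaster estimator of independence and global F_ST marker scores.

For one biallelic marker, cross-classify genotype (0/1/2 reference-allele
copies) against population membership into a 3 x k table of joint
probabilities ``p_ij``.  The Lancaster estimator of independence is

    theta^2 = sum_ij p_ij^2 / (p_i+ p_+j) - 1

with marginals ``p_i+`` (genotype) and ``p_+j`` (population).  theta^2 = 0
when genotype and population are independent and is bounded above by
min(m, k) - 1 where m is the number of genotype categories (here 3).  Larger
values mean the marker is more informative about ancestry.

The table can be built two ways:

* from genotypes: p_ij = n_ij / n (``build_genotype_contingency``);
* from per-population allele frequencies under Hardy-Weinberg equilibrium:
  expected counts c_j (1-f_j)^2, 2 c_j f_j (1-f_j), c_j f_j^2
  (``expected_contingency_from_freq``).

The frequency route needs only summary statistics, never individual
genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    MISSING,
    ContractError,
    GenotypeMatrix,
    LeikitError,
    MarkerScoreVector,
    PopAlleleFreqTable,
)

_MARGINAL_TOL = 1e-12
_INDEPENDENCE_SNAP = 1e-12


class DegeneratePopulationError(LeikitError):
    """A population contributes no non-missing genotype at a marker."""


@dataclass
class ContingencyTable3xK:
    """Joint genotype x population probability estimates for one marker."""

    population_names: list[str]
    p: np.ndarray  # 3 x k
    row_marginals: np.ndarray  # 3
    col_marginals: np.ndarray  # k

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.row_marginals = np.asarray(self.row_marginals, dtype=float)
        self.col_marginals = np.asarray(self.col_marginals, dtype=float)
        k = len(self.population_names)
        if self.p.shape != (3, k):
            raise ContractError(f"table must be 3 x {k}, got {self.p.shape}")
        if np.any(self.p < 0):
            raise ContractError("joint probabilities must be non-negative")
        if abs(self.p.sum() - 1.0) > _MARGINAL_TOL:
            raise ContractError("joint probabilities must sum to 1")
        if np.max(np.abs(self.p.sum(axis=1) - self.row_marginals)) > _MARGINAL_TOL:
            raise ContractError("row marginals inconsistent with table")
        if np.max(np.abs(self.p.sum(axis=0) - self.col_marginals)) > _MARGINAL_TOL:
            raise ContractError("column marginals inconsistent with table")

    @property
    def k(self) -> int:
        return len(self.population_names)


@dataclass
class LEIScore:
    """A theta^2 value with its attainable upper bound context."""

    value: float
    m_effective: int  # genotype categories with positive marginal
    k: int

    def __post_init__(self) -> None:
        bound = min(3, self.k) - 1
        if not (-1e-9 <= self.value <= bound + 1e-9):
            raise ContractError(
                f"theta^2 = {self.value} outside [0, {bound}] for k={self.k}"
            )


def build_genotype_contingency(
    codes: np.ndarray, labels: list[str] | np.ndarray
) -> ContingencyTable3xK:
    """Estimate the 3 x k joint table from one marker's genotype codes.

    Missing genotypes are dropped (complete-case counting): p_ij = n_ij / n
    over non-missing entries.  Every population must retain at least one
    non-missing genotype, otherwise its frequency column is undefined.
    """
    codes = np.asarray(codes)
    labels = np.asarray(labels, dtype=object)
    if codes.shape != labels.shape:
        raise ContractError("codes and labels must have equal length")
    pops = sorted(set(labels.tolist()))
    counts = np.zeros((3, len(pops)), dtype=float)
    keep = codes != MISSING
    for j, pop in enumerate(pops):
        in_pop = (labels == pop) & keep
        if not in_pop.any():
            raise DegeneratePopulationError(
                f"population {pop!r} has no non-missing genotype"
            )
        counts[:, j] = np.bincount(codes[in_pop].astype(np.intp), minlength=3)[:3]
    p = counts / counts.sum()
    return ContingencyTable3xK(
        population_names=pops,
        p=p,
        row_marginals=p.sum(axis=1),
        col_marginals=p.sum(axis=0),
    )


def expected_contingency_from_freq(
    f: np.ndarray, c: np.ndarray, population_names: list[str] | None = None
) -> ContingencyTable3xK:
    """HWE-expected 3 x k table from allele frequencies and sample counts.

    Expected genotype counts in population j are c_j(1-f_j)^2,
    2 c_j f_j (1-f_j) and c_j f_j^2; fractional counts are retained.
    """
    f = np.asarray(f, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ContractError("frequencies must lie in [0, 1]")
    if np.any(c <= 0):
        raise ContractError("population counts must be positive")
    if population_names is None:
        population_names = [f"pop{j + 1}" for j in range(len(f))]
    counts = np.vstack([c * (1 - f) ** 2, 2 * c * f * (1 - f), c * f**2])
    p = counts / counts.sum()
    return ContingencyTable3xK(
        population_names=list(population_names),
        p=p,
        row_marginals=p.sum(axis=1),
        col_marginals=p.sum(axis=0),
    )


def theta_squared(table: ContingencyTable3xK) -> LEIScore:
    """Evaluate theta^2 on a 3 x k table.

    Terms whose row or column marginal is zero contribute 0: their joint
    probability is necessarily zero and the limit of p^2/(p_r p_c) is 0.
    """
    value = _theta_squared_raw(table.p, table.row_marginals, table.col_marginals)
    m_eff = int(np.count_nonzero(table.row_marginals > 0))
    return LEIScore(value=value, m_effective=m_eff, k=table.k)


def _theta_squared_raw(
    p: np.ndarray, row: np.ndarray, col: np.ndarray
) -> float:
    denom = np.outer(row, col)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(denom > 0, p**2 / np.where(denom > 0, denom, 1.0), 0.0)
    value = float(terms.sum() - 1.0)
    # rounding leaves O(eps) residue at exact independence; snap to 0
    return value if value > _INDEPENDENCE_SNAP else 0.0


def _theta_squared_freq_batch(f: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorized theta^2 over markers from HWE-expected tables.

    ``f`` is markers x k, ``c`` length k.  Equivalent to calling
    ``expected_contingency_from_freq`` + ``theta_squared`` per marker.
    """
    c = np.asarray(c, dtype=float)
    n = c.sum()
    counts = np.stack(
        [c * (1 - f) ** 2, 2 * c * f * (1 - f), c * f**2], axis=1
    )  # markers x 3 x k
    p = counts / n
    row = p.sum(axis=2)  # markers x 3
    col = p.sum(axis=1)  # markers x k
    denom = row[:, :, None] * col[:, None, :]
    terms = np.where(denom > 0, p**2 / np.where(denom > 0, denom, 1.0), 0.0)
    values = terms.sum(axis=(1, 2)) - 1.0
    return np.where(values > _INDEPENDENCE_SNAP, values, 0.0)


def lei_geno_scores(G: GenotypeMatrix) -> MarkerScoreVector:
    """LEI_Geno: one theta^2 estimate per marker from genotype counts."""
    if G.population_labels is None:
        raise ContractError("LEI_Geno requires population labels")
    pops = G.populations()
    if len(pops) < 2:
        raise ContractError("LEI_Geno requires at least two populations")
    labels = np.asarray(G.population_labels, dtype=object)
    pop_masks = [(labels == pop) for pop in pops]
    scores = np.empty(G.n_markers)
    for j in range(G.n_markers):
        col = G.codes[:, j]
        keep = col != MISSING
        counts = np.zeros((3, len(pops)))
        for q, mask in enumerate(pop_masks):
            use = mask & keep
            if not use.any():
                raise DegeneratePopulationError(
                    f"marker {G.marker_ids[j]!r}: population {pops[q]!r} "
                    "has no non-missing genotype"
                )
            counts[:, q] = np.bincount(col[use].astype(np.intp), minlength=3)[:3]
        p = counts / counts.sum()
        scores[j] = _theta_squared_raw(p, p.sum(axis=1), p.sum(axis=0))
    return rank_markers(
        MarkerScoreVector(
            method_name="lei_geno",
            marker_ids=list(G.marker_ids),
            scores=scores,
            chrom=G.chrom,
            bp=G.bp,
        )
    )


def lei_freq_scores(F: PopAlleleFreqTable) -> MarkerScoreVector:
    """LEI_Freq: theta^2 per marker from HWE-expected genotype counts."""
    scores = _theta_squared_freq_batch(F.f, F.c)
    return rank_markers(
        MarkerScoreVector(
            method_name="lei_freq",
            marker_ids=list(F.marker_ids),
            scores=scores,
            chrom=F.chrom,
            bp=F.bp,
        )
    )


def global_fst_scores(F: PopAlleleFreqTable) -> MarkerScoreVector:
    """Global F_ST = (H_T - H_S) / H_T per marker across all k populations.

    H_S is the sample-size-weighted mean within-population heterozygosity
    2 f_j (1 - f_j); H_T = 2 fbar (1 - fbar) with fbar the weighted mean
    frequency.  Markers monomorphic overall (H_T = 0) score 0.
    """
    if F.n_populations < 2:
        raise ContractError("global F_ST requires at least two populations")
    w = F.c / F.c.sum()
    fbar = F.f @ w
    h_s = (2 * F.f * (1 - F.f)) @ w
    h_t = 2 * fbar * (1 - fbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(h_t > 0, (h_t - h_s) / np.where(h_t > 0, h_t, 1.0), 0.0)
    return rank_markers(
        MarkerScoreVector(
            method_name="fst",
            marker_ids=list(F.marker_ids),
            scores=scores,
            chrom=F.chrom,
            bp=F.bp,
        )
    )


def rank_markers(scores: MarkerScoreVector) -> MarkerScoreVector:
    """Attach ranks: descending score, ties by (chrom, bp) then marker id."""
    if not np.all(np.isfinite(scores.scores)):
        raise ContractError("scores must be finite to rank")
    L = scores.n_markers
    if scores.chrom is not None and scores.bp is not None:
        keys = list(
            zip(
                -scores.scores,
                scores.chrom.tolist(),
                scores.bp.tolist(),
                scores.marker_ids,
            )
        )
    else:
        keys = list(zip(-scores.scores, scores.marker_ids))
    order = sorted(range(L), key=lambda i: keys[i])
    rank = np.empty(L, dtype=np.int64)
    rank[order] = np.arange(1, L + 1)
    scores.rank = rank
    return scores
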