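"""Lancaster estimator of independence: tables, theta^2, F_ST, ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_genotype_matrix
from leikit.containers import MISSING, ContractError, PopAlleleFreqTable
from leikit.lei import (
    ContingencyTable3xK,
    DegeneratePopulationError,
    build_genotype_contingency,
    expected_contingency_from_freq,
    global_fst_scores,
    lei_freq_scores,
    lei_geno_scores,
    rank_markers,
    theta_squared,
)
from leikit.containers import MarkerScoreVector


def naive_theta_squared(p: np.ndarray) -> float:
    """Independent oracle: scalar double loop over the joint table."""
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if row[i] > 0 and col[j] > 0:
                total += p[i, j] ** 2 / (row[i] * col[j])
    return total - 1.0


def table_from_p(p: np.ndarray) -> ContingencyTable3xK:
    return ContingencyTable3xK(
        population_names=[f"p{j}" for j in range(p.shape[1])],
        p=p,
        row_marginals=p.sum(axis=1),
        col_marginals=p.sum(axis=0),
    )


def freq_table(f, c, **kw):
    f = np.atleast_2d(np.asarray(f, dtype=float))
    return PopAlleleFreqTable(
        marker_ids=kw.get("marker_ids", [f"m{j + 1}" for j in range(f.shape[0])]),
        population_names=[f"p{j + 1}" for j in range(f.shape[1])],
        f=f,
        c=np.asarray(c),
    )


class TestGenotypeContingency:
    def test_direct_counting(self):
        t = build_genotype_contingency(
            np.array([0, 0, 2, 2]), ["A", "A", "B", "B"]
        )
        assert np.allclose(t.p, [[0.5, 0], [0, 0], [0, 0.5]])

    def test_identical_distributions_give_zero_theta(self):
        t = build_genotype_contingency(
            np.array([1, 1, 1, 1]), ["A", "A", "B", "B"]
        )
        assert t.row_marginals[1] == 1.0
        assert theta_squared(t).value == 0.0

    def test_missing_dropped_complete_case(self):
        t = build_genotype_contingency(
            np.array([0, MISSING, 2, 2]), ["A", "A", "B", "B"]
        )
        assert np.allclose(t.p, [[1 / 3, 0], [0, 0], [0, 2 / 3]])

    def test_fully_missing_population_raises(self):
        with pytest.raises(DegeneratePopulationError):
            build_genotype_contingency(
                np.array([MISSING, MISSING, 2, 2]), ["A", "A", "B", "B"]
            )


class TestExpectedContingency:
    def test_fixed_alleles(self):
        t = expected_contingency_from_freq(np.array([0.0, 1.0]), np.array([50, 50]))
        assert np.allclose(t.p, [[0.5, 0], [0, 0], [0, 0.5]])

    def test_hwe_at_half(self):
        t = expected_contingency_from_freq(np.array([0.5]), np.array([100]))
        assert np.allclose(t.p[:, 0], [0.25, 0.5, 0.25])

    def test_fractional_counts_retained(self):
        # HWE products by hand: pop1 (0.5, 9, 40.5), pop2 (40.5, 9, 0.5)
        t = expected_contingency_from_freq(np.array([0.9, 0.1]), np.array([50, 50]))
        counts = t.p * 100
        assert np.allclose(counts[:, 0], [0.5, 9, 40.5])
        assert np.allclose(counts[:, 1], [40.5, 9, 0.5])


class TestThetaSquared:
    def test_maximal_three_population_exclusivity(self):
        p = np.eye(3) / 3
        assert theta_squared(table_from_p(p)).value == pytest.approx(2.0, abs=1e-12)

    def test_independence_is_zero(self):
        p = np.outer([0.2, 0.5, 0.3], [0.4, 0.6])
        assert theta_squared(table_from_p(p)).value == pytest.approx(0.0, abs=1e-12)

    def test_hwe_table_hand_value(self):
        # brute-force double sum over the 3x2 HWE table for f=(0.9,0.1)
        t = expected_contingency_from_freq(np.array([0.9, 0.1]), np.array([50, 50]))
        assert theta_squared(t).value == pytest.approx(0.780488, abs=1e-6)
        assert theta_squared(t).value == pytest.approx(naive_theta_squared(t.p))

    def test_oracle_equivalence_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            k = int(rng.integers(2, 6))
            p = rng.random((3, k))
            # random zeros exercise the zero-marginal convention
            p[rng.random((3, k)) < 0.2] = 0.0
            if p.sum() == 0:
                continue
            p /= p.sum()
            t = table_from_p(p)
            assert theta_squared(t).value == pytest.approx(
                max(naive_theta_squared(p), 0.0), abs=1e-12
            )

    @given(
        st.integers(min_value=2, max_value=6),
        st.integers(min_value=0, max_value=2**32 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_bound_property(self, k, seed):
        """0 <= theta^2 <= min(3, k) - 1 for any joint table."""
        rng = np.random.default_rng(seed)
        p = rng.random((3, k))
        p /= p.sum()
        val = theta_squared(table_from_p(p)).value
        assert -1e-9 <= val <= min(3, k) - 1 + 1e-9

    def test_invariance_population_permutation_and_allele_flip(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.random((3, 4))
            p /= p.sum()
            base = theta_squared(table_from_p(p)).value
            perm = p[:, rng.permutation(4)]
            flipped = p[::-1, :]  # relabel genotype 0 <-> 2
            assert theta_squared(table_from_p(perm)).value == pytest.approx(base, abs=1e-12)
            assert theta_squared(table_from_p(flipped)).value == pytest.approx(base, abs=1e-12)


class TestLeiScores:
    def test_monomorphic_marker_scores_zero(self):
        G = make_genotype_matrix([[2], [2], [2], [2]], labels=["A", "A", "B", "B"])
        assert lei_geno_scores(G).scores[0] == 0.0

    def test_exclusive_homozygotes_score_one(self):
        G = make_genotype_matrix(
            [[0], [0], [2], [2]], labels=["A", "A", "B", "B"]
        )
        assert lei_geno_scores(G).scores[0] == pytest.approx(1.0, abs=1e-12)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 3, size=(30, 8))
        labels = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        G = make_genotype_matrix(codes, labels=labels)
        perm = rng.permutation(30)
        Gp = make_genotype_matrix(codes[perm], labels=[labels[i] for i in perm])
        assert np.allclose(lei_geno_scores(G).scores, lei_geno_scores(Gp).scores)

    def test_freq_identical_scores_zero(self):
        F = freq_table([[0.3, 0.3, 0.3]], [40, 40, 40])
        assert lei_freq_scores(F).scores[0] == 0.0

    def test_freq_fixed_difference_scores_one(self):
        F = freq_table([[1.0, 0.0]], [50, 50])
        assert lei_freq_scores(F).scores[0] == pytest.approx(1.0, abs=1e-12)

    def test_freq_hand_value(self):
        F = freq_table([[0.9, 0.1]], [50, 50])
        assert lei_freq_scores(F).scores[0] == pytest.approx(0.780488, abs=1e-6)

    def test_geno_equals_freq_on_exact_hwe_counts(self):
        """When genotype counts equal HWE expectations, the two routes agree."""
        # f=(0.8, 0.2), c=(25, 25): counts pop1 (1,8,16), pop2 (16,8,1)
        codes_a = [0] * 1 + [1] * 8 + [2] * 16
        codes_b = [0] * 16 + [1] * 8 + [2] * 1
        G = make_genotype_matrix(
            np.asarray(codes_a + codes_b).reshape(-1, 1),
            labels=["A"] * 25 + ["B"] * 25,
        )
        F = freq_table([[0.8, 0.2]], [25, 25])
        assert lei_geno_scores(G).scores[0] == pytest.approx(
            lei_freq_scores(F).scores[0], abs=1e-12
        )

    def test_geno_freq_correlation_on_balding_nichols_panel(self):
        """LEI_Geno and LEI_Freq track each other on differentiated data."""
        rng = np.random.default_rng(21)
        L, n_per = 2000, 100
        anc = rng.uniform(0.05, 0.95, size=L)
        shape = (1 - 0.15) / 0.15
        f = rng.beta(anc * shape, (1 - anc) * shape, size=(2, L))
        codes = np.vstack(
            [rng.binomial(2, f[k], size=(n_per, L)) for k in range(2)]
        )
        G = make_genotype_matrix(codes, labels=["A"] * n_per + ["B"] * n_per)
        F = freq_table(f.T, [n_per, n_per])
        r = np.corrcoef(lei_geno_scores(G).scores, lei_freq_scores(F).scores)[0, 1]
        assert r >= 0.95


class TestGlobalFst:
    def test_identical_frequencies_zero(self):
        assert global_fst_scores(freq_table([[0.4, 0.4]], [30, 30])).scores[0] == 0.0

    def test_complete_fixation_one(self):
        assert global_fst_scores(freq_table([[1.0, 0.0]], [30, 30])).scores[0] == pytest.approx(1.0)

    def test_hand_value(self):
        # H_S = 0.18, H_T = 0.5 -> (0.5 - 0.18) / 0.5 = 0.64
        F = freq_table([[0.9, 0.1]], [50, 50])
        assert global_fst_scores(F).scores[0] == pytest.approx(0.64, abs=1e-12)

    def test_monomorphic_overall_scores_zero(self):
        assert global_fst_scores(freq_table([[0.0, 0.0]], [30, 30])).scores[0] == 0.0


class TestRanking:
    def _vec(self, scores, bp=None):
        L = len(scores)
        return MarkerScoreVector(
            method_name="x",
            marker_ids=[f"m{j}" for j in range(L)],
            scores=np.asarray(scores, dtype=float),
            chrom=np.asarray(["1"] * L, dtype=object),
            bp=np.asarray(bp if bp is not None else np.arange(1, L + 1)),
        )

    def test_descending_rank(self):
        v = rank_markers(self._vec([0.2, 0.9, 0.5]))
        assert v.rank.tolist() == [3, 1, 2]

    def test_tie_broken_by_position(self):
        v = rank_markers(self._vec([0.5, 0.5], bp=[2000, 1000]))
        assert v.rank.tolist() == [2, 1]

    def test_idempotent(self):
        v = rank_markers(self._vec([0.1, 0.3, 0.3, 0.0]))
        again = rank_markers(v)
        assert v.rank.tolist() == again.rank.tolist()

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ContractError):
            rank_markers(self._vec([0.1, np.nan]))
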