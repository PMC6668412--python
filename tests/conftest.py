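import numpy as np
import pytest

from leikit.containers import GenotypeMatrix


def make_genotype_matrix(codes, labels=None, bp=None, chrom=None, marker_ids=None):
    """Build a small GenotypeMatrix from a codes array with sane defaults."""
    codes = np.asarray(codes, dtype=np.int8)
    n, L = codes.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i + 1}" for i in range(n)],
        marker_ids=marker_ids or [f"m{j + 1}" for j in range(L)],
        chrom=np.asarray(chrom or ["1"] * L, dtype=object),
        bp=np.asarray(bp if bp is not None else np.arange(1, L + 1) * 1000),
        ref_allele=np.asarray(["A"] * L, dtype=object),
        alt_allele=np.asarray(["C"] * L, dtype=object),
        codes=codes,
        population_labels=list(labels) if labels is not None else None,
    )


@pytest.fixture(scope="session")
def small_panels():
    """Two Balding-Nichols panels sharing a map (session-cached)."""
    from leikit.simulate import generate_reference_panels

    panels, freqs = generate_reference_panels(2, 500, 100, 0.15, seed=11)
    return panels, freqs


@pytest.fixture(scope="session")
def three_pop_cohort_matrix():
    """Labeled three-population reference genotype matrix (n=60, L=40).

    The first 10 markers are planted with maximal frequency differentiation
    (each population near-fixed for a different allele pattern); the rest are
    weakly differentiated Balding-Nichols draws.
    """
    rng = np.random.default_rng(7)
    n_per, L = 20, 40
    labels = ["A"] * n_per + ["B"] * n_per + ["C"] * n_per
    freqs = np.empty((3, L))
    freqs[:, :10] = np.array([[0.98], [0.5], [0.02]])  # strong AIMs
    anc = rng.uniform(0.2, 0.8, size=L - 10)
    shape = (1 - 0.05) / 0.05
    freqs[:, 10:] = rng.beta(anc * shape, (1 - anc) * shape, size=(3, L - 10))
    codes = np.vstack(
        [rng.binomial(2, freqs[k], size=(n_per, L)) for k in range(3)]
    )
    return make_genotype_matrix(codes, labels=labels)
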