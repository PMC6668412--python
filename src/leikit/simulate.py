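"""Synthetic reference panels and mosaic admixture simulators.

Reference panels stand in for real haplotype panels (HapMap/1000 Genomes
style): per-population allele frequencies are drawn from the
Balding-Nichols model around a shared ancestral frequency at a chosen
differentiation F_ST, and haplotype alleles are Bernoulli draws from the
population frequency.

Two admixture scenarios are simulated on those panels, both returning the
full local-ancestry truth:

* two-way: a Poisson-switch mosaic.  Each admixed chromosome draws its own
  ancestry weight theta1 ~ Beta(alpha, beta) (the probability of carrying
  second-panel ancestry), starts from one ancestry with probability theta1,
  and between adjacent markers resamples its ancestry with probability
  1 - exp(-g * l), where g is generations since admixture and
  l = bp gap / 1e8 approximates genetic distance.  Beta(12, 3) with g = 8
  gives a cohort averaging 80% second-panel ancestry.
* three-way: fixed 100-kb blocks.  The chromosome is cut into consecutive
  windows of ``block_bp`` base pairs anchored at the first marker; each
  window's ancestry is an independent draw from the mixing proportions
  (default 0.6 / 0.3 / 0.1).

Chromosomes are paired sequentially after a seeded shuffle into diploid
individuals.  The recorded "true" ancestry proportion of an individual is
the realized marker fraction of each ancestry averaged over its two
chromosome copies (the mosaic the genotypes actually carry), not the drawn
theta1; theta1 is kept in the provenance record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .containers import ContractError, GenotypeMatrix, LeikitError


class MapMismatchError(LeikitError):
    """Panels passed to a simulator do not share an identical marker map."""


@dataclass
class HaplotypePanel:
    """Phased reference haplotypes for one population (1 = reference allele)."""

    population_name: str
    marker_ids: list[str]
    chrom: np.ndarray
    bp: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    haplotypes: np.ndarray  # H x L, values in {0, 1}

    def __post_init__(self) -> None:
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] < 2:
            raise ContractError("panel needs at least 2 haplotypes")
        if self.haplotypes.shape[1] != len(self.marker_ids):
            raise ContractError("haplotype width does not match marker map")
        if np.any(np.diff(self.bp) <= 0):
            raise ContractError("bp must be strictly increasing")
        if not np.all((self.haplotypes == 0) | (self.haplotypes == 1)):
            raise ContractError("haplotype alleles must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Realized reference-allele frequency per marker."""
        return self.haplotypes.mean(axis=0)


@dataclass
class AdmixedCohort:
    """Simulated admixed individuals with complete truth bookkeeping."""

    genotypes: GenotypeMatrix
    local_ancestry: np.ndarray  # 2 x n x L population indices
    true_q: np.ndarray  # n x K realized ancestry fractions
    population_names: list[str]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.true_q = np.asarray(self.true_q, dtype=float)
        n, L = self.genotypes.codes.shape
        if self.local_ancestry.shape != (2, n, L):
            raise ContractError("local_ancestry must be 2 x n x L")
        if np.max(np.abs(self.true_q.sum(axis=1) - 1)) > 1e-12:
            raise ContractError("true_q rows must lie on the simplex")
        K = self.true_q.shape[1]
        frac = np.stack(
            [(self.local_ancestry == k).mean(axis=(0, 2)) for k in range(K)], axis=1
        )
        if np.max(np.abs(frac - self.true_q)) > 1e-12:
            raise ContractError("true_q inconsistent with local_ancestry")


@dataclass
class TwoWayParams:
    """Two-way Poisson-switch mosaic parameters."""

    g: float = 8.0  # generations since admixture
    alpha: float = 12.0
    beta: float = 3.0
    n_chromosomes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g < 0 or self.alpha <= 0 or self.beta <= 0:
            raise ContractError("g must be >= 0 and Beta shapes positive")
        if self.n_chromosomes % 2:
            raise ContractError("n_chromosomes must be even (paired into diploids)")


@dataclass
class ThreeWayParams:
    """Three-way block-mosaic parameters."""

    proportions: tuple[float, ...] = (0.6, 0.3, 0.1)
    block_bp: int = 100_000
    n_chromosomes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1) > 1e-9 or min(self.proportions) < 0:
            raise ContractError("proportions must lie on the simplex")
        if self.block_bp <= 0:
            raise ContractError("block_bp must be positive")
        if self.n_chromosomes % 2:
            raise ContractError("n_chromosomes must be even (paired into diploids)")


def generate_reference_panels(
    K: int,
    L: int,
    n_haplotypes: int,
    fst: float,
    seed: int = 0,
    chrom: str = "1",
) -> tuple[list[HaplotypePanel], np.ndarray]:
    """Balding-Nichols reference panels for K populations.

    Ancestral frequencies are uniform on [0.05, 0.95]; each population's
    frequency is Beta(p(1-F)/F, (1-p)(1-F)/F); haplotype alleles are
    Bernoulli(f).  Positions are strictly increasing with uniform random
    gaps in [500, 5000] bp.  Returns the panels and the true K-population
    frequency matrix (L x K).
    """
    if not (0 < fst < 1):
        raise ContractError("fst must lie strictly between 0 and 1")
    if min(K, L, n_haplotypes) <= 0:
        raise ContractError("K, L and n_haplotypes must be positive")
    rng = np.random.default_rng(seed)
    ancestral = rng.uniform(0.05, 0.95, size=L)
    shape = (1 - fst) / fst
    freqs = rng.beta(ancestral * shape, (1 - ancestral) * shape, size=(K, L)).T
    bp = np.cumsum(rng.integers(500, 5001, size=L)).astype(np.int64)
    marker_ids = [f"snp{j + 1}" for j in range(L)]
    ref = np.asarray(["A"] * L, dtype=object)
    alt = np.asarray(["C"] * L, dtype=object)
    panels = []
    for k in range(K):
        haps = (rng.random((n_haplotypes, L)) < freqs[:, k]).astype(np.int8)
        panels.append(
            HaplotypePanel(
                population_name=f"POP{k + 1}",
                marker_ids=list(marker_ids),
                chrom=np.asarray([chrom] * L, dtype=object),
                bp=bp,
                ref_allele=ref,
                alt_allele=alt,
                haplotypes=haps,
            )
        )
    return panels, freqs


def panel_freq_table(panels: list[HaplotypePanel]):
    """Realized-frequency table of a panel list (diploid counts = H/2)."""
    from .containers import PopAlleleFreqTable

    _check_shared_map(panels)
    f = np.stack([p.allele_frequencies() for p in panels], axis=1)
    c = np.asarray([max(p.n_haplotypes // 2, 1) for p in panels], dtype=np.int64)
    return PopAlleleFreqTable(
        marker_ids=list(panels[0].marker_ids),
        population_names=[p.population_name for p in panels],
        f=f,
        c=c,
        chrom=panels[0].chrom,
        bp=panels[0].bp,
    )


def _check_shared_map(panels: list[HaplotypePanel]) -> None:
    first = panels[0]
    for p in panels[1:]:
        if (
            p.marker_ids != first.marker_ids
            or not np.array_equal(p.bp, first.bp)
            or not np.array_equal(p.chrom, first.chrom)
        ):
            raise MapMismatchError(
                f"panels {first.population_name} and {p.population_name} "
                "do not share a marker map"
            )


def simulate_two_way(
    panelA: HaplotypePanel, panelB: HaplotypePanel, params: TwoWayParams
) -> AdmixedCohort:
    """Simulate a two-way admixed cohort by the Poisson-switch mosaic.

    Ancestry is *resampled* (not forcibly switched) at each event: with
    probability 1 - exp(-g*l) the ancestry of the next marker is redrawn as
    panelB with probability theta1, and may land on the current ancestry.
    """
    _check_shared_map([panelA, panelB])
    rng = np.random.default_rng(params.seed)
    L = panelA.n_markers
    gaps_l = np.diff(panelA.bp) / 1e8  # genetic-distance proxy per gap
    p_resample = 1.0 - np.exp(-params.g * gaps_l)

    n_chrom = params.n_chromosomes
    thetas = rng.beta(params.alpha, params.beta, size=n_chrom)
    chrom_anc = np.empty((n_chrom, L), dtype=np.int8)
    chrom_alleles = np.empty((n_chrom, L), dtype=np.int8)
    hapA_idx = np.empty(n_chrom, dtype=np.int64)
    hapB_idx = np.empty(n_chrom, dtype=np.int64)
    for c in range(n_chrom):
        theta1 = thetas[c]
        hapA_idx[c] = rng.integers(panelA.n_haplotypes)
        hapB_idx[c] = rng.integers(panelB.n_haplotypes)
        # resample events: marker 0 always draws; after that Bernoulli per gap
        resample = np.empty(L, dtype=bool)
        resample[0] = True
        resample[1:] = rng.random(L - 1) < p_resample
        draws = (rng.random(L) < theta1).astype(np.int8)  # 1 = panelB ancestry
        # ancestry at marker j = draw at the latest resample point <= j
        last_event = np.maximum.accumulate(
            np.where(resample, np.arange(L), -1)
        )
        anc = draws[last_event]
        chrom_anc[c] = anc
        srcA = panelA.haplotypes[hapA_idx[c]]
        srcB = panelB.haplotypes[hapB_idx[c]]
        chrom_alleles[c] = np.where(anc == 1, srcB, srcA)

    return _pair_into_cohort(
        panels=[panelA, panelB],
        chrom_anc=chrom_anc,
        chrom_alleles=chrom_alleles,
        rng=rng,
        provenance={
            "scenario": "two_way",
            "g": params.g,
            "alpha": params.alpha,
            "beta": params.beta,
            "n_chromosomes": n_chrom,
            "seed": params.seed,
            "theta1": thetas.tolist(),
            "hap_indices": {
                panelA.population_name: hapA_idx.tolist(),
                panelB.population_name: hapB_idx.tolist(),
            },
        },
    )


def simulate_three_way(
    panels: list[HaplotypePanel], params: ThreeWayParams
) -> AdmixedCohort:
    """Simulate a three-way admixed cohort with independent fixed-bp blocks."""
    if len(panels) != len(params.proportions):
        raise ContractError("need one mixing proportion per panel")
    _check_shared_map(panels)
    rng = np.random.default_rng(params.seed)
    L = panels[0].n_markers
    bp = panels[0].bp
    window = ((bp - bp[0]) // params.block_bp).astype(np.int64)
    n_windows = int(window[-1]) + 1
    props = np.asarray(params.proportions, dtype=float)

    n_chrom = params.n_chromosomes
    K = len(panels)
    chrom_anc = np.empty((n_chrom, L), dtype=np.int8)
    chrom_alleles = np.empty((n_chrom, L), dtype=np.int8)
    hap_idx = np.empty((n_chrom, K), dtype=np.int64)
    for c in range(n_chrom):
        for k in range(K):
            hap_idx[c, k] = rng.integers(panels[k].n_haplotypes)
        win_anc = rng.choice(K, size=n_windows, p=props).astype(np.int8)
        anc = win_anc[window]
        chrom_anc[c] = anc
        sources = np.stack(
            [panels[k].haplotypes[hap_idx[c, k]] for k in range(K)], axis=0
        )
        chrom_alleles[c] = sources[anc, np.arange(L)]

    return _pair_into_cohort(
        panels=panels,
        chrom_anc=chrom_anc,
        chrom_alleles=chrom_alleles,
        rng=rng,
        provenance={
            "scenario": "three_way",
            "proportions": props.tolist(),
            "block_bp": params.block_bp,
            "n_chromosomes": n_chrom,
            "seed": params.seed,
            "hap_indices": hap_idx.tolist(),
        },
    )


def _pair_into_cohort(
    panels: list[HaplotypePanel],
    chrom_anc: np.ndarray,
    chrom_alleles: np.ndarray,
    rng: np.random.Generator,
    provenance: dict[str, Any],
) -> AdmixedCohort:
    """Randomly pair simulated chromosomes into diploid individuals."""
    n_chrom, L = chrom_anc.shape
    K = len(panels)
    order = rng.permutation(n_chrom)
    first, second = order[0::2], order[1::2]
    n_ind = n_chrom // 2
    codes = (chrom_alleles[first] + chrom_alleles[second]).astype(np.int8)
    local = np.stack([chrom_anc[first], chrom_anc[second]], axis=0)
    true_q = np.stack(
        [(local == k).mean(axis=(0, 2)) for k in range(K)], axis=1
    )
    ref_panel = panels[0]
    G = GenotypeMatrix(
        sample_ids=[f"admixed{i + 1}" for i in range(n_ind)],
        marker_ids=list(ref_panel.marker_ids),
        chrom=ref_panel.chrom,
        bp=ref_panel.bp,
        ref_allele=ref_panel.ref_allele,
        alt_allele=ref_panel.alt_allele,
        codes=codes,
    )
    provenance["chromosome_pairing"] = np.stack([first, second], axis=1).tolist()
    return AdmixedCohort(
        genotypes=G,
        local_ancestry=local,
        true_q=true_q,
        population_names=[p.population_name for p in panels],
        provenance=provenance,
    )
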