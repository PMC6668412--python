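"""End-to-end simulation experiments used by the docs and reporting script.

Each experiment regenerates its inputs from a seed: Balding-Nichols
reference panels (the synthetic stand-in for real haplotype panels), a
mosaic admixed cohort, an LEI_Freq marker ranking on the realized panel
frequencies, supervised EM ancestry estimates from the top-ranked subset,
and the RMSE against the realized simulated truth.

Default problem sizes follow the simulation study design: 20,000 markers on
one chromosome, 200 reference haplotypes per population, F_ST = 0.15,
200 admixed chromosomes paired into 100 individuals, top-85 markers for the
two-way scenario and top-1000 for the three-way scenario.
"""

from __future__ import annotations

import numpy as np

from ._random import stage_rng
from .estimate import QMatrix, estimate_q, rmse_three_way, rmse_two_way
from .lei import lei_freq_scores
from .simulate import (
    AdmixedCohort,
    ThreeWayParams,
    TwoWayParams,
    generate_reference_panels,
    panel_freq_table,
    simulate_three_way,
    simulate_two_way,
)

DEFAULT_L = 20_000
DEFAULT_HAPLOTYPES = 200
DEFAULT_FST = 0.15


def _seed(master: int, stage: str) -> int:
    return int(stage_rng(master, stage).integers(2**31))


def simulate_two_way_cohort(
    seed: int,
    L: int = DEFAULT_L,
    n_haplotypes: int = DEFAULT_HAPLOTYPES,
    fst: float = DEFAULT_FST,
    n_chromosomes: int = 200,
) -> tuple[AdmixedCohort, list]:
    """Fresh panels plus a default-parameter two-way admixed cohort."""
    panels, _ = generate_reference_panels(
        2, L, n_haplotypes, fst, seed=_seed(seed, "panels-2way")
    )
    cohort = simulate_two_way(
        panels[0],
        panels[1],
        TwoWayParams(n_chromosomes=n_chromosomes, seed=_seed(seed, "sim-2way")),
    )
    return cohort, panels


def simulate_three_way_cohort(
    seed: int,
    L: int = DEFAULT_L,
    n_haplotypes: int = DEFAULT_HAPLOTYPES,
    fst: float = DEFAULT_FST,
    n_chromosomes: int = 200,
) -> tuple[AdmixedCohort, list]:
    """Fresh panels plus a default-parameter three-way admixed cohort."""
    panels, _ = generate_reference_panels(
        3, L, n_haplotypes, fst, seed=_seed(seed, "panels-3way")
    )
    cohort = simulate_three_way(
        panels,
        ThreeWayParams(n_chromosomes=n_chromosomes, seed=_seed(seed, "sim-3way")),
    )
    return cohort, panels


def mean_two_way_ancestry(seed: int, L: int = DEFAULT_L, n_chromosomes: int = 200) -> float:
    """Mean realized second-panel ancestry fraction over simulated chromosomes."""
    cohort, _ = simulate_two_way_cohort(seed, L=L, n_chromosomes=n_chromosomes)
    return float((cohort.local_ancestry == 1).mean())


def mean_three_way_ancestry(
    seed: int, L: int = DEFAULT_L, n_chromosomes: int = 200
) -> np.ndarray:
    """Mean realized ancestry fractions (K,) over simulated individuals."""
    cohort, _ = simulate_three_way_cohort(seed, L=L, n_chromosomes=n_chromosomes)
    return cohort.true_q.mean(axis=0)


def _rmse_from_cohort(cohort: AdmixedCohort, panels, top_n: int, two_way: bool) -> float:
    F = panel_freq_table(panels)
    ranking = lei_freq_scores(F)
    idx = ranking.top_indices(top_n)
    qhat = estimate_q(cohort.genotypes.subset_markers(idx), F.subset_markers(idx))
    truth = QMatrix(
        list(cohort.genotypes.sample_ids), cohort.population_names, cohort.true_q
    )
    return rmse_two_way(qhat, truth) if two_way else rmse_three_way(qhat, truth)


def two_way_rmse_experiment(seed: int, L: int = DEFAULT_L, top_n: int = 85) -> float:
    """Two-way RMSE of supervised q-hat from the top-N LEI_Freq markers."""
    cohort, panels = simulate_two_way_cohort(seed, L=L)
    return _rmse_from_cohort(cohort, panels, top_n, two_way=True)


def three_way_rmse_experiment(seed: int, L: int = DEFAULT_L, top_n: int = 1000) -> float:
    """Three-way RMSE of supervised q-hat from the top-N LEI_Freq markers."""
    cohort, panels = simulate_three_way_cohort(seed, L=L)
    return _rmse_from_cohort(cohort, panels, top_n, two_way=False)
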