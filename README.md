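# leikit

Selecting ancestry-informative markers (AIMs) — SNPs whose allele
frequencies differ strongly among reference populations — is a routine step
in admixture mapping and population-structure analysis. Most feature
selection approaches (PCA loadings, random-forest importance, SVM weights)
need individual-level genotypes, which are expensive to compute on and often
restricted. `leikit` implements a likelihood-based score, the **Lancaster
estimator of independence (LEI)**, that ranks markers for multi-way admixed
settings from nothing more than per-population allele frequencies, together
with the genotype-based baselines, mosaic admixture simulators, a supervised
ancestry-proportion estimator, and the evaluation machinery to compare them.

## The statistic

For one biallelic marker, cross-classify genotype X ∈ {0, 1, 2} (reference
allele copies) against population membership Y ∈ {1, …, k} into a 3 × k
joint table p<sub>ij</sub>. The LEI is

θ² = Σ<sub>ij</sub> p<sub>ij</sub>² / (p<sub>i+</sub> p<sub>+j</sub>) − 1,

where p<sub>i+</sub> and p<sub>+j</sub> are the marginals. θ² = 0 when
genotype and population are independent (the marker carries no ancestry
information) and θ² ≤ min(3, k) − 1, attained when genotype classes are
exclusive to populations. Two estimators are provided:

- **LEI_Geno** — p̂<sub>ij</sub> = n<sub>ij</sub>/n from observed genotype
  counts;
- **LEI_Freq** — expected genotype counts under Hardy–Weinberg equilibrium,
  n̂<sub>0j</sub> = c<sub>j</sub>(1−f<sub>j</sub>)², n̂<sub>1j</sub> =
  2c<sub>j</sub>f<sub>j</sub>(1−f<sub>j</sub>), n̂<sub>2j</sub> =
  c<sub>j</sub>f<sub>j</sub>², so only summary frequencies f<sub>j</sub> and
  sample counts c<sub>j</sub> are needed.

Baselines (`leikit.rankers`): PCA score max(|a₁ⱼ|, |a₂ⱼ|) over the first two
eigenvectors, random-forest Gini importance (500 trees), and mean absolute
one-vs-rest linear-SVM weight. A Nei-style global F<sub>ST</sub> =
(H_T − H_S)/H_T is included as the classical frequency-only comparator.

## Worked example

```python
import numpy as np
from leikit import (
    generate_reference_panels, simulate_two_way, TwoWayParams,
    lei_freq_scores, estimate_q, rmse_two_way, QMatrix,
)
from leikit.simulate import panel_freq_table

# two Balding-Nichols reference panels (F_ST 0.15, 20,000 markers)
panels, _ = generate_reference_panels(K=2, L=20_000, n_haplotypes=200,
                                      fst=0.15, seed=1)
# 200 mosaic chromosomes -> 100 admixed individuals (g=8, Beta(12,3))
cohort = simulate_two_way(panels[0], panels[1], TwoWayParams(seed=2))
print(f"mean second-panel ancestry: {cohort.true_q[:, 1].mean():.3f}")

# rank markers from summary frequencies alone, keep the top 85
F = panel_freq_table(panels)
ranking = lei_freq_scores(F)
idx = ranking.top_indices(85)

# supervised EM ancestry estimates and their error vs. simulated truth
qhat = estimate_q(cohort.genotypes.subset_markers(idx), F.subset_markers(idx))
truth = QMatrix(cohort.genotypes.sample_ids, cohort.population_names,
                cohort.true_q)
print(f"RMSE with top-85 LEI_Freq markers: {rmse_two_way(qhat, truth):.4f}")
```

Output:

```
mean second-panel ancestry: 0.800
RMSE with top-85 LEI_Freq markers: 0.0328
```

The cohort averages ~80% second-panel ancestry (the Beta(12, 3) mean is
0.8), and 85 well-chosen markers already estimate each individual's
admixture proportion to within a few percent.

The same pipeline is available from the shell:

```sh
leikit demo --seed 7          # panels -> cohort -> ranking -> q-hat -> RMSE
leikit --help                 # all subcommands
```

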