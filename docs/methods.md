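# Methods

## The Lancaster estimator of independence

For a biallelic marker, genotype X (0/1/2 copies of the reference allele)
and population membership Y (k populations) form a 3 × k joint distribution
p_ij. The statistic

    theta^2 = sum_ij p_ij^2 / (p_i+ p_+j) - 1

measures departure from independence: it is 0 when the genotype
distribution is identical in every population and bounded by min(3, k) − 1,
the bound being attained when each genotype class is exclusive to one
population. For k ≥ 3 the maximum is 2. The score is invariant to
permuting population columns and to swapping the allele labels (reversing
the genotype rows), so marker orientation does not affect rankings.

Two plug-in estimators are provided. `lei_geno_scores` uses observed
genotype counts, p̂_ij = n_ij/n, with per-marker complete-case handling of
missing calls (a missing genotype is dropped from that marker's table; the
probability interpretation of the remaining cells is unchanged; whether one
should instead impute is an open modelling choice — complete-case is the
least committal). `lei_freq_scores` assumes Hardy–Weinberg equilibrium
within each population and replaces counts by their expectations
c_j(1−f_j)², 2c_j f_j(1−f_j), c_j f_j² from the population reference-allele
frequency f_j and diploid sample count c_j. Fractional expected counts are
kept as-is. Under exact HWE counts the two estimators coincide (tested to
1e-12), and on differentiated synthetic panels they correlate above 0.95.

Terms with a zero row or column marginal contribute 0 to the double sum —
the corresponding joint probability is necessarily 0 and p²/(p_r p_c) → 0
in the limit. Values within 1e-12 of zero are snapped to exactly 0 so that
"identical distributions score 0" holds as an identity, not approximately.

## Global F_ST

As the classical frequency-only comparator, each marker gets the Nei-style
global fixation index (H_T − H_S)/H_T, with H_S the c_j-weighted average of
within-population heterozygosities 2f_j(1−f_j) and H_T = 2f̄(1−f̄) at the
c_j-weighted mean frequency f̄. Markers monomorphic overall score 0. This
is the simplest global estimator built from population allele frequencies
alone; variance-component (Weir–Cockerham) estimators are out of scope.
Note this per-marker score, used for *ranking*, is downward-biased as an
estimate of the drift parameter when k is small; the test suite's recovery
check for the simulator therefore uses the ddof-corrected multi-locus
ratio-of-sums version, which is consistent for the Balding–Nichols F.

## Baseline rankers

* **PCA** — codes are imputed to the marker mean (missing only), column
  mean-centered (no variance scaling: the minimal standard, and 0/1/2 codes
  are already on one scale), and decomposed; the score is
  b_j = max(|a_1j|, |a_2j|) over exactly the first two unit-norm
  eigenvectors. Eigenvector signs are canonicalized (largest-magnitude
  loading positive) so serialized loadings are stable; scores are
  sign-free anyway.
* **Random forest** — mean decrease in Gini impurity from 500
  classification trees (scikit-learn defaults otherwise), importances
  normalized to sum to 1, seed exposed for bit-reproducibility. Because
  bootstrap draws are indexed by row, RF scores are only statistically (not
  bitwise) invariant to sample reordering; the tests check rank stability
  rather than exact equality for this scorer.
* **Linear SVM** — k one-vs-rest maximum-margin classifiers with squared
  hinge loss and C = 1 (fixed for reproducibility); the score is the mean
  absolute weight (1/k)Σ|w_ij|. For k = 2 the implicit one-vs-rest weight
  vectors are sign flips, so the score reduces to |w| of the single fitted
  separator.

Rankings are deterministic: descending score, ties broken by (chrom, bp)
ascending, then marker id.

## Synthetic reference panels

Real haplotype reference panels are emulated with the Balding–Nichols
model: an ancestral frequency p ~ Uniform(0.05, 0.95) per marker, each
population's frequency drawn Beta(p(1−F)/F, (1−p)(1−F)/F) at drift
parameter F (default 0.15, a typical continental-scale differentiation),
haplotype alleles Bernoulli(f). Positions have uniform random gaps in
[500, 5000] bp, so 20,000 markers span ≈ 55 Mb — one chromosome's worth of
SNP-array-density data. What this emulates: exchangeable drift around a
shared ancestral pool, dense biallelic SNPs, realistic per-marker
differentiation spread. What it does not: linkage disequilibrium within
panels (alleles are drawn independently given frequencies), mutation-rate
heterogeneity, ascertainment bias, or non-equilibrium demography. Passing
tests therefore demonstrate correctness of the statistics and estimators
under the stated model, not performance on any particular human cohort.

## Admixture simulators

**Two-way Poisson-switch mosaic.** Each admixed chromosome draws its
ancestry weight θ₁ ~ Beta(α=12, β=3) (mean 0.8 — the second panel plays
the role of the majority ancestry), picks one haplotype from each panel,
and walks the marker map: the first marker's ancestry is panel B with
probability θ₁; at each gap the ancestry is *resampled* with probability
1 − e^(−g·l), l = bp gap / 10⁸ (a genetic-distance proxy of 1 cM/Mb), and a
resample draws panel B again with probability θ₁ — so it may land on the
current ancestry and produce no visible switch. g = 8 generations matches
African-American-style admixture timing. 200 chromosomes are shuffled
(seeded) and paired sequentially into 100 diploid individuals.

**Three-way block mosaic.** The chromosome is cut into consecutive windows
of 100,000 bp anchored at the first marker; each window's ancestry is an
independent draw from the mixing proportions (default 0.6/0.3/0.1); one
haplotype per panel per chromosome supplies the alleles.

The recorded truth q_i is the *realized* marker fraction of each ancestry
averaged over the two chromosome copies — the mosaic the genotypes actually
carry — not the drawn θ₁ (which is kept in the provenance record). With
few expected switch events per chromosome the two differ noticeably per
individual; the realized fraction is the quantity an ancestry estimator
can hope to recover. Truth is a marker fraction, not a bp fraction,
because estimation operates on markers. Haplotypes are drawn with
replacement across chromosomes; a chromosome never copies from the same
source haplotype twice at once.

## Supervised ancestry estimation

Ancestry proportions are estimated by maximizing the binomial admixture
likelihood with *known* reference frequencies (supervised projection),
rather than the unsupervised joint (Q, F) problem: every experiment here
anchors clusters with reference panels, and supervision removes
label-switching and external-binary dependencies. The EM update

    q_k <- q_k/(2L') * sum_l [ g_l f_kl / sum_m q_m f_ml
                               + (2-g_l)(1-f_kl) / sum_m q_m (1-f_ml) ]

is monotone in the log-likelihood and preserves the simplex; iteration
starts from uniform q and stops when every individual's log-likelihood
gain drops below `tol` (default 1e-6) or at `max_iter` (default 1000).
Frequencies are clamped to [1e-6, 1 − 1e-6] to avoid log(0) at fixed
alleles. Boundary optima (nearly pure individuals) are approached
sublinearly; tighten `tol` when exact boundary recovery matters. If all
populations share identical frequencies the likelihood is flat: uniform q
is returned with a warning rather than an arbitrary vertex.

RMSE metrics: the two-way form compares one designated ancestry column,
sqrt(mean (q̂_i − q_i)²) (default: the second panel's column); the
multi-way form averages over all nK entries, sqrt(Σ_ik (q̂_ik − q_ik)²/nK).

## Classification evaluation

LOOCV multinomial logistic regression on the top-r marker codes: for each
sample the model is refitted without it and the sample is assigned by
argmax predicted probability. Top AIMs separate populations perfectly,
which makes the unpenalized MLE diverge, so a small L2 ridge (1e-4) is
always applied; it leaves argmax predictions unchanged while keeping
coefficients finite. Accuracy CIs are exact Clopper–Pearson (conservative
and method-unambiguous). Per-class AUC uses the confusion-count formula
AUC = 1 − 0.5(x/n + (e−x)/m) on the hard LOOCV confusion matrix (not the
rank-based construction), and mAUC is the class-proportion-weighted sum.
The reference category of the logit is the last population in sorted label
order (determinism only; the fit is invariant to the choice).

## Problem sizes and numerical choices

The end-to-end experiments run at the study design's scale — 20,000
markers, 200 reference haplotypes per population, F_ST 0.15, 200 admixed
chromosomes paired into 100 individuals, top-85 markers (two-way) and
top-1000 (three-way) — which completes in seconds with the vectorized
implementations. Property tests use smaller panels (500–2,000 markers)
where scale adds nothing to the property being checked. All stochastic
stages consume numpy Generator streams derived from a master seed keyed by
stage name, so adding or reordering stages never silently shifts another
stage's stream, and identical seeds give bit-identical cohorts, rankings
and estimates (RF included).

## Known limitations

* LEI is defined here for biallelic SNPs (3 genotype categories); the
  multi-allelic generalization is not implemented.
* No LD handling: markers are scored independently and top-N sets may be
  locally redundant on real (linked) data; the synthetic panels carry no
  LD, so this cost is invisible to the test suite.
* The supervised estimator treats reference frequencies as known constants;
  with small reference panels their sampling noise propagates into q̂
  without being reflected in any reported uncertainty (no standard errors).
* The per-marker Nei F_ST score is a ranking device, not an unbiased drift
  estimate, for small k (see above).
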