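# Methods

## The model

`famvc` partitions the phenotypic variance of a quantitative trait measured
in a family-structured cohort into additive-genetic and shared-environment
components with a linear mixed model fitted by restricted maximum
likelihood (REML):

    y = X beta + g_g + g_kin + e_f + e_s + e_c + eps
    V = GRM_g sigma2_g + GRM_kin sigma2_kin + ERM_F sigma2_f
        + ERM_S sigma2_s + ERM_C sigma2_c + I sigma2_e

Each random effect is a zero-mean Gaussian vector whose covariance is a
known n x n design matrix scaled by an unknown variance:

* **GRM_g** — realized genomic relatedness estimated from common-SNP
  dosages.  Off-diagonals average `(x_j - 2p)(x_k - 2p) / (2p(1-p))` over
  SNPs non-missing in both individuals; diagonals are one plus the
  analogous inbreeding estimate.  Captures variance tagged by genotyped
  SNPs (`h2_g`).
* **GRM_kin** — GRM_g with entries below a close-relative threshold set to
  zero.  Captures additional genetic variance shared by close relatives
  but untagged by the SNP panel (`h2_kin`); `h2_g + h2_kin` is the total
  (pedigree-comparable) heritability.
* **ERM_Family / ERM_Sib / ERM_Couple** — 0/1 indicators with unit
  diagonal of shared nuclear-family, full-sibling and couple ("pair with a
  common offspring in the data") environments (`e2_f`, `e2_s`, `e2_c`).

Any non-empty subset of {G, K, F, S, C} (31 models) can be fitted; the
residual is always present.  Ratios `sigma2_c / sum(sigma2)` are the
reported variance shares.

Fixed effects default, for real data, to sex, age, age^2, sex-by-age,
clinic, standardized deprivation index and its square, and the leading 20
eigenvectors of GRM_g; synthetic runs use an intercept plus 20
eigenvectors.  Collinear columns are dropped (pivoted QR, relative
tolerance 1e-10).

## REML algorithm and numerics

Fixed effects are removed once per dataset by projecting onto an
orthonormal basis of the null space of X' (thin-QR); kernels are projected
with it.  The restricted likelihood is then an ordinary Gaussian
log-likelihood in n - p dimensions; the reported value includes the
`log|X'X|` constant so it equals the textbook form
`-1/2 [log|V| + log|X'V^-1 X| + y'Py + (n-p) log 2pi]` (verified in tests
against a direct implementation).

Updates are average-information (AI) Newton steps preceded by three
expectation-maximisation warm-up iterations (one when warm-started).
Per-iteration quantities come from an explicit inverse of the projected V
(Cholesky + `dpotri`), which makes the cost essentially independent of the
number of components; single-kernel models instead use a one-off
eigendecomposition of the projected kernel, after which every iteration is
O(n).  Steps are halved when V leaves the positive-definite cone or the
likelihood drops by more than `1e-6 (1 + |logL|)`; strict monotone
acceptance is deliberately not enforced (AI steps are not monotone far
from the optimum, and rejecting noise-level dips caused premature
convergence).  Steps larger than five times the parameter scale (a symptom
of a near-singular AI matrix) are rescaled, and the AI system falls back
to a ridge solve if singular.

Convergence requires a relative likelihood change below 1e-8 *and* a
maximum relative parameter change below 1e-6, with a 100-iteration cap
(`converged=False` and a warning otherwise).

Constrained fitting (default, matching common GREML practice) pins
parameters that cross zero at a small positive floor (1e-6 of the
phenotypic variance), takes active-set AI steps in the free coordinates
while a pinned parameter's gradient points outward, uses the monotone EM
update as a fallback when a projected step fails, and finally projects
floored components to exactly zero and refits the remainder.  The
unconstrained mode allows negative components (including, if the
likelihood demands it, the residual) so long as V stays positive definite;
simulation means are computed in this mode so they remain unbiased.

Standard errors of variances come from the inverse AI matrix at
convergence; ratio standard errors by the delta method with the full
sampling covariance (checked against a delete-a-group jackknife).  The
Wald statistic `(sigma2/se)^2` is referred to chi-square(1).  The LRT for
one component uses the boundary mixture `0.5 chi2_0 + 0.5 chi2_1`, so
`p = 0.5 P(chi2_1 >= LR)` and LR = 0 gives exactly 0.5.

## Stepwise backward selection

Starting from the full model GKFSC: fit, compute per-component Wald
p-values and drop-one LRT p-values, and remove the component that is
non-significant for *both* tests at alpha = 0.05 and has the highest Wald
p-value (ties broken toward the later component in the canonical order
G, K, F, S, C); repeat until every remaining component is significant for
at least one test.  A reduced model that fails to fit or converge records
an LRT of `NA`, and the Wald test alone governs that component.  By
default the reduced model is only fitted for components whose Wald test is
already non-significant — a component with Wald p <= alpha survives
whatever the LRT says, so the selection path is identical while roughly
halving the fits per step; `lrt_mode="all"` fills the complete LRT table.
No multiple-testing correction is applied, so error rates are per trait.

## Synthetic cohorts

The generator emulates a population-based family cohort:

* **Pedigree** — `n_families` nuclear families (two founder parents,
  `n_offspring` children, default 2) plus `n_singletons` unrelated
  individuals.  `extended_fraction` links that fraction of families
  pairwise through a shared genotyped grandparental couple (the two
  fathers become full siblings), creating 2nd-degree (grandparent-
  grandchild, avuncular) and 3rd-degree (cousin) pairs.
* **Genotypes** — founder dosages binomial under Hardy-Weinberg
  equilibrium at per-SNP frequencies uniform on (0.05, 0.5]; offspring by
  Mendelian gene dropping at independent loci; chromosome labels assigned
  round-robin over autosomes 1-22.
* **Phenotypes** — causal SNPs are drawn at density 1/500 separately from
  even chromosomes (the "tagged" causal variation; only even chromosomes
  enter GRM_g/GRM_kin) and odd chromosomes (untagged, pedigree-associated
  variation).  Per-locus effects are Exponential(1) magnitudes with random
  signs on standardized dosages — the scale is irrelevant because each
  component is rescaled, and symmetric signs follow from exchangeability.
  Shared environments are one standard-normal draw per couple, per
  full-sib group, and per nuclear-family *unit* (a parent couple plus its
  offspring; an individual can carry a natal and an own unit, normalized
  to unit variance).  Unit-based sharing realizes exactly the ERM
  covariance pattern — cousins in extended pedigrees share no draw — and
  corresponds to the youth/adulthood family-environment framing; an
  optional mode splits the family effect into two equal-variance draws
  with the same covariance.  Individuals outside any group draw
  independently, so every individual carries each component's full
  marginal variance, as the unit-diagonal ERMs assume.
* **Closure** — every constructed part is rescaled so its realized sample
  variance equals its target share exactly (a flag restores
  expectation-scaling); the residual takes `1 - sum(shares)`.  The truth
  record is therefore exact per replicate, and the covariance
  decomposition `sum_c cov(part_c, y) = var(y)` holds to machine
  precision.

### Desk-scale study conditions

The standard recovery cohort is 300 two-parent/two-offspring families plus
300 singletons (n = 1,500) with 4,000 SNPs; recovery studies use 50
replicates per scenario with unconstrained fits, and recovery is judged by
a Z-test of the mean estimate against the simulated value.  Two choices
deserve comment because naive downscaling breaks the design:

* **Close-relative threshold.**  Realized relatedness between unrelated
  pairs has sampling SD `1/sqrt(m)`.  With hundreds of thousands of SNPs a
  fixed cutoff of 0.025 sits far outside this noise and GRM_kin contains
  only relatives; with ~2,000 even-chromosome SNPs it sits at one SD and
  ~13% of unrelated pairs leak in, destroying the pedigree-genetic
  component (its recovery drops from ~0.20 to ~0.13).  `build_cohort`
  therefore defaults the threshold to `max(0.025, 4/sqrt(m))`, which is
  the conventional 0.025 whenever m exceeds ~25k and otherwise keeps the
  cutoff four noise-SDs out.
* **Identifiability in the selection study.**  In a cohort consisting
  solely of two-parent/two-offspring families,
  `GRM_kin = 0.5 ERM_Family - 0.5 ERM_Couple + I` holds exactly in
  expectation (parent-offspring and sibling entries 0.5, couple entries 0,
  unit diagonal), so the full model is rank-deficient and the choice
  between K and F/C is arbitrary at any sample size.  Real cohorts are not
  degenerate this way because they contain 2nd/3rd-degree relatives, which
  appear in GRM_kin but in no ERM.  The selection-effectiveness study
  therefore uses `extended_fraction = 0.4` (n = 1,620), restoring those
  pairs at roughly the 1st:2nd/3rd-degree ratio seen in population family
  cohorts.  Selection scenarios use a moderate SNP effect of 0.3, moderate
  familial effects of 0.2 and low effects of 0.05, with 10 replicates per
  scenario and constrained fits.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `maf_min`, `hwe_alpha`, `snp_miss_max`, `ind_miss_max` | 0.05, 1e-6, 0.02, 0.05 | QC thresholds (exact Hardy-Weinberg test; by default over all samples — family structure barely perturbs genotype frequencies at these alphas — with `hwe_sample_mask` to restrict to founders) |
| `sd_limit` | 4 | outlier masking, in adjusted-residual SDs |
| `threshold_grm` t | 0.025 | close-relative cutoff on GRM_g entries |
| `build_cohort` kin threshold | `max(0.025, 4/sqrt(m))` | scale-aware version of the same cutoff |
| `n_pcs` | 20 | GRM eigenvector covariates |
| `alpha` | 0.05 | selection significance level |
| `causal_fraction` | 1/500 | causal SNP density per chromosome parity |
| `tol_logl`, `tol_param`, `max_iter` | 1e-8, 1e-6, 100 | REML convergence |

## What the synthetic studies do and do not show

The generator reproduces the covariance *structure* the model assumes:
independent common-frequency loci, exact Mendelian transmission,
group-constant environmental draws, Gaussian residuals, and variance
shares that close to one.  It does not emulate linkage disequilibrium,
assortative mating, rare variants, genotyping error, age/sex effects on
the trait (beyond optional covariates), or environmental sharing that
decays with time or distance.  Passing recovery tests therefore show that
the estimator and selection machinery are correct and calibrated under the
model's own assumptions at desk scale — not that the model is adequate
for any particular real trait.  Estimates on real cohorts also inherit
whatever confounding (e.g. population stratification beyond 20
eigenvectors) the design matrices cannot absorb.

## Known limitations

* Dense linear algebra throughout: memory O(n^2), time O(n^3) per
  iteration; comfortable to n ~ 20k, not beyond.
* Univariate traits only; no GxE, dominance, or BLUP prediction.
* The exact-test HWE filter assumes autosomal biallelic SNPs; X-chromosome
  and multi-allelic variants are out of scope.
* ERM_Family in multi-generation pedigrees is indefinite (overlapping
  cliques); fits remain well-defined while V is positive definite, but the
  matrix is then an approximation to any realizable shared-environment
  process.
* Separating the pedigree-genetic component from family/couple environment
  in the stepwise selection is information-limited: when
  `(h2_kin, e2_c) = (0.2, 0.2)`, the model GFC with
  `(e2_f, e2_c) = (0.1, 0.1)` reproduces the first-degree covariance
  structure exactly, and only 2nd/3rd-degree pairs discriminate.  At the
  desk-scale cohort size their total likelihood contribution is of order
  one unit, so the selection recovers all major components well below the
  ~80% rate achievable on cohorts several times larger; this confounding
  of pedigree-genetic with family/couple environmental structure is the
  known hard part of this class of analysis at any scale.  The recovery of
  variance-component *estimates* under matched models is unaffected.
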