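# Methods

This note records the statistical models implemented in `namgei`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter to anyone
auditing or extending the package.

## Genotype representation and recoding

Genotypes are integer codes oriented toward the common parent of the NAM
design: 2 = homozygous for the common-parent allele, 0 = homozygous for
the family founder's allele, 1 = heterozygous. Founder-allele dosage is
`2 - code`. The marker-by-family recoding places that dosage in the RIL's
own family column of an incidence matrix `Z_k`, zeroing columns of
families in which the marker does not segregate (a family segregates when
a heterozygote is observed or both homozygote classes appear). This lets
one SNP carry a distinct allele effect per family — the natural model
when linkage phase between SNP and QTL differs across families.

Missing calls are imputed deterministically with the within-family modal
code at each marker (ties toward the lower code; a fully missing
family-marker cell falls back to the family's overall mode). A stochastic
machine-learning imputer would add an external model and nondeterminism
for no benefit here: imputation accuracy is not an outcome of interest,
and the modal fill is exact in the dominant case of low missingness in
near-homozygous families.

The genomic relationship matrix is the additive linear kernel
`K = alpha M M'` with `M` the marker-mean-centered code matrix and
`alpha = 1 / mean(diag(M M'))`, so `mean(diag K) = 1` and the polygenic
variance is on the phenotypic scale. Centering is by marker mean over all
RILs; raw codes (not the parental-origin recoding) enter `M`.

## Field adjustment

Trials follow a modified augmented design: unreplicated test plots plus
repeated check entries in every block. Each non-check yield is adjusted by
(block check mean - environment check mean), after which check records are
dropped. Blocks without checks are a hard error naming the block. Where a
RIL has several plots in one environment they are averaged before model
fitting, which also makes the fits exactly invariant to record
duplication.

## Per-environment mixed model and boundary LRT

The association model per environment is

    y = X b + Z_k a + psi + e,
    a ~ N(0, I s2a), psi ~ N(0, K s2psi), e ~ N(0, I s2e),

fitted by REML with the fixed part reduced to an intercept after check
adjustment. The null model (no marker) is profiled over the single ratio
`s2psi / s2e` using the eigendecomposition of `K`: a coarse 17-point log
grid on [1e-6, 1e6] followed by bounded Brent refinement (absolute
tolerance 1e-8 on the log-ratio). Restricted likelihoods include the
`log|X' V^-1 X| - log|X'X|` terms so models with the same fixed effects
are comparable.

Each marker is tested by `LRT = -2 (L0 - L1)`, clipped at zero. Two
fitting strategies are provided:

* **full** (reference): joint re-optimization of both variance ratios by
  coordinate descent (up to three sweeps of the two 1-D searches), each
  likelihood evaluated through a Cholesky factorization of
  `lam_a Z Z' + lam_psi K + I`.
* **fast** (scan default): the polygenic ratio is frozen at its null
  optimum and only the marker variance is profiled. After whitening by
  `(lam_psi K + I)^(-1/2)`, a thin SVD of the whitened `Z` reduces every
  likelihood evaluation to O(n x rank) via the Woodbury identity.

The fast mode is the standard two-stage approximation used by
genome-scan software; on simulated data the two modes agree to a fraction
of an LRT unit, and a cross-check test enforces that agreement. `test_marker`
defaults to full; `genome_scan` defaults to fast so thousand-marker scans
and the per-environment GEI collection stay interactive.

Because `s2a = 0` sits on the boundary of the parameter space, the null
law of the LRT is not chi-square(1). The package's operative law is the
chi-square with 0.5 degrees of freedom (the gamma(1/4, 2) distribution),
with the 50:50 `{chi2_0, chi2_1}` mixture as a configurable alternative;
the two cross near LRT = 1 (the half-df law is heavier near zero, lighter
in the tail). Under null simulations with a polygenic background the
half-df law rejects ~3-4% of markers at nominal 5% — calibrated to
slightly conservative, as the boundary mass P(LRT = 0) exceeds 1/2 in
finite samples. Family allele effects are reported as BLUPs
`a_hat = lam_a Z' V^(-1) (y - X b_hat)` in kg/ha per founder-allele
dosage. Multiple testing uses the Bonferroni cut `-log10(alpha / m)`,
about 4.94 for alpha = 0.05 and m = 4312.

## Finlay-Wilkinson stability

The environmental index is the mean non-check yield per environment,
centered. Each RIL is regressed by OLS on the centered index over the
environments where it was observed; the slope is the FW index (1 =
dynamic stability), the intercept is the fitted yield at the average
environment, and the deviation mean square (residual MS on n-2 df)
measures consistency. A two-step fit (index, then per-RIL regressions) is
used rather than the alternating variant: with hundreds to thousands of
RILs the index is essentially design-driven. Slopes require at least 3
observed environments — two points fit perfectly and carry no deviation
information. On balanced data the slopes average exactly 1 when the index
comes from the same records. The stability GWAS feeds the slopes (one
record per RIL, no blocks) back through the same mixed-model scan, and
additionally reports each marker's adjusted R^2 from a fixed-effects
regression of the slope on founder dosage as a descriptive
variance-explained measure. No adjustment for maturity or other cofactors
is applied to the slopes; users with real data may wish to pre-adjust.

## GEI meta-analysis

For one marker, per-environment analyses yield a family x environment
effect panel `A` with weights `N` (plot records per family-environment
cell; zero marks cells where the family is absent or the marker is
monomorphic, and such cells are excluded from every sum). The additive
null `alpha = W delta + e` is fitted by N-weighted least squares; with
the one-parent-per-family incidence `W` the normal equations decouple
into per-parent weighted means. The alternative adds the first singular
component of the residual matrix (unobserved cells zero-filled), with the
sign convention that the first non-negligible entry of `u` is positive; a
masked alternating-least-squares variant that ignores unobserved cells is
available behind a flag. `pc_load = d1^2 / sum(d_i^2)` reports the
captured fraction of residual variation.

The test statistic is the Gaussian profiled-variance likelihood ratio
`LRT = n_cells * ln(RSS0 / RSS1)` on weighted residual sums of squares,
referred to chi-square with `(n_parents - 1) + (n_env - 1) + 1` degrees
of freedom — the free-parameter count of a rank-1 bilinear term, exposed
as an override. Counting parameters does **not** calibrate the maximized
first singular value: direct null simulation (Gaussian panels, no
interaction) rejects 78-100% at nominal 5% depending on panel shape, with
null LRTs far below the level needed to reach `-log10 p = 50`. The
empirical threshold of 50 is therefore the operative genome-wide flag,
and the naive p-values should be read as ranking scores, not error rates.
If `RSS1` underflows to zero with `RSS0 > 0` (an exactly rank-1 residual)
the p-value is reported as an underflow with `-log10 p` capped at 320.

**Effect estimator entering the panel.** The default is the unshrunk
within-family OLS slope of the adjusted phenotype on founder dosage. The
shrinkage (BLUP) estimates remain available (`effects="blup"`), but they
are not the default for a structural reason: per-environment REML
shrinkage is inconsistent across environments — a marker estimated on the
boundary (`s2a = 0`) in one environment contributes an exactly-zero effect
column there — and a marker with a small constant effect can then present
one dominant nonzero column, i.e. a near-exact rank-1 residual and an
arbitrarily large LRT. OLS effects have comparable scale across
environments and sampling variance proportional to 1/N, matching the
weighted meta-model's homoscedasticity-per-weight assumption.

**Saturation guard.** The profiled-likelihood test is undefined when the
rank-1 alternative can fit the residuals exactly. With fewer than three
environments carrying a nonzero effect contrast the weighted row-centered
residual matrix is (generically) exactly rank 1, so `gei_scan` skips such
markers, as it skips markers segregating in fewer than two families.

## Environment clustering

Environments are profiled by per-family mean yields (families absent from
an environment are imputed with that environment's overall mean), and
clustered with the classical Ward-D criterion applied to unsquared
Euclidean distances. SciPy ships only the squared-distance Ward variant,
so Ward-D is obtained exactly by passing the square roots of the
distances and squaring the output heights — the Lance-Williams
recurrences coincide under that substitution (verified against R's
`hclust(method = "ward.D")`). Ward-D's recurrence coefficients satisfy
the monotonicity condition, so merge heights never decrease. Ties break
deterministically by cluster-index order. The dendrogram exports to
newick with branch lengths from merge-height differences.

A caution on the preset-environment check: the 18 preset mean yields
contain merge margins as small as ~8 kg/ha, so the expected grouping of
the three >4700 kg/ha site-years is identifiable from main-effect
profiles only when plot noise is negligible; at realistic noise the
marginal merges flip for a large fraction of seeds. The packaged
clustering study therefore runs in the noise-free limit. Real trials
recover such structure through correlated family-by-environment
deviations (e.g. shared location effects across years) that a
main-effects generator does not produce.

## The synthetic-data generator

`simdata` emulates the *statistical structure* the analyses assume, not
the biology of a real population:

* **Genotypes.** F5-derived RILs: P(het) = 1/16, P(either homozygote) =
  15/32 at segregating markers; a marker segregates in a given family
  with probability 0.7 (NAM SNP panels are chosen to maximize segregating
  families). Markers are independent within family — no linkage or LD —
  and are assigned to chromosomes contiguously. Tests that pass here say
  nothing about LD decay, haplotype structure or mapping resolution on
  real data; they validate the estimators marker by marker, which is how
  the analysis operates.
* **Phenotypes.** `y_ij = mu + x_j b_i + sum_q dos_iq (beta_qf + s_q
  l_qj) + psi_i + block + e`, with `x_j` the centered environment effect,
  `b_i ~ N(1, 0.2^2)` the true FW slope (optionally shifted by slope
  QTL), rank-1 multiplicative QTL interaction via `s_q l_qj`, an optional
  polygenic term drawn with covariance proportional to the marker kinship
  (so the association null model is exactly correct), Gaussian block
  effects and residuals. Checks are three genotype-free entries at fixed
  offsets (+150/0/-150 kg/ha), replicated once per block.
* **Defaults.** slope_sd 0.2 (a realistic spread for yield MET slope
  distributions, centered at 1 as observed in large trials), residual_sd
  450 kg/ha, block_sd 100 kg/ha, 4 blocks per environment. The
  "soynam-like" preset uses the 18 published environment mean yields
  (2364-5057 kg/ha) and an unbalanced family-presence pattern matching
  the published per-environment RIL fractions, with partial environments
  hosting rotating subsets of families.
* All randomness flows through explicit integer seeds; equal seeds give
  byte-identical outputs.

## Validation studies and problem sizes

The `studies` module runs the whole chain at a scaled-down design chosen
to keep the complete battery within minutes on one core: 10 families x 50
RILs x 150 markers (the full design is 39 x 140 x 4312), residual 400
kg/ha, polygenic 300 kg/ha. Injected effects follow the scaled design:
additive family effects ~ N(0, 200) kg/ha (about half a residual SD),
multiplicative GEI of scale 150 kg/ha on standardized loadings over 8
environments, slope QTL of 0.2 per allele over 15 environments spanning
the preset yield range. The slope-recovery study uses residual 250 kg/ha,
inside its stated <= 300 band: at 15 environments the slope standard
error is sigma / sqrt(sum x^2) ~ 0.08-0.09 at 250-300 kg/ha against a
true slope SD of 0.2, putting the expected recovery correlation at ~0.93
(resp. ~0.91 at the 300 boundary), so 250 leaves honest headroom without
leaving the band. Power is reported as the fraction of 20 seeded
replicates in which the causal marker tops the scan (additive, GEI) or
exceeds the Bonferroni line (stability).

## Known limitations

* No linkage simulation: resolution/LD questions are out of scope.
* The GEI meta-LRT's naive degrees of freedom are anticonservative by
  construction (documented above); cross-marker comparison by `-log10 p`
  and the empirical threshold are the supported uses.
* The mixed model absorbs part of a marker's own signal into the
  polygenic term (no leave-one-chromosome-out kinship), which mostly
  affects markers whose effects are uniform across families.
* Heterozygotes enter additively (dosage coding); no dominance term.
* FW slopes are not adjusted for maturity or other cofactors.
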