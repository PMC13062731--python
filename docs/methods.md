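# Methods

This note documents the models, the numerical decisions, and what the
synthetic data do and do not emulate. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Per-trait domestication-syndrome calls

Quantitative traits in replicated designs are fitted with the
randomized-block mixed model `X_ijk = mu + B_i + F_j + A_k + (AxF)_jk +
eps_ijk`: fixed block (replicate) and form effects, a random intercept per
accession with variance `sigma2_k`, a form-specific accession variance
`sigma2_j` (one value per form), and i.i.d. residuals.

*Identifiability.* Accessions are nested within forms (a wild population
and a landrace are never the same accession), so `sigma2_k` and `sigma2_j`
enter the marginal covariance only through their per-form sum. The REML
fitter therefore works internally with the per-form total accession
variance `tau2_f = sigma2_k + sigma2_{j,f}` plus the residual variance —
a fully identifiable compound-symmetry-per-accession model solved in closed
form per block. Reported components use the boundary convention
`sigma2_k = min(tau2_wild, tau2_dom)`; this affects labels only, never the
form test.

*Inference.* The form contrast (domestic − wild; wild is the reference, so
positive = higher in domesticates) is tested with a t statistic whose
denominator degrees of freedom come from the Satterthwaite approximation,
computed from the numeric gradient of the contrast variance and the numeric
Hessian of the REML criterion; variance parameters estimated at the zero
boundary are excluded from that computation, and when both accession
variances hit zero the fit collapses exactly onto the OLS block+form model
(verified to 1e-6 in the tests). Degrees of freedom are clamped to
[1, N − p]. Calibration at study scale (≈40 accessions × 3 replicates):
empirical type-I error 0.050 at the 5% level over 1000 null simulations, and
95% CIs for a 2-residual-SD effect cover the truth ≥90% of the time.
Non-convergent fits (rare) fall back to OLS on accession means and are
flagged `model_used='linear'`.

Discrete counts are modelled as Gaussian like all other quantitative traits
— one shared pipeline rather than trait-specific GLMs — and no trait
transformations are applied.

Qualitative traits use Fisher's exact test on the level-by-form table:
2×2 through `scipy.stats.fisher_exact`; larger tables by full enumeration of
fixed-margin tables (probability mass summed over tables no more probable
than the observed one) when the enumeration stays below ~5·10^5 tables, and
otherwise by a seeded permutation Monte Carlo with ≥10^5 draws (the
permutation null is exactly the conditional hypergeometric distribution),
flagged as approximate. A constant trait returns p = 1 with a warning.

BH q-values are computed within species (species-specific FDR), with traits
flagged DA at q ≤ 0.05 by default.

## NIRS preprocessing and control traits

*Replicate QC.* The intended rule — discard a technical replicate whose
deviation from the individual's mean exceeds twice the SD on ≥30% of the
spectrum — is ill-posed when the per-wavelength SD is estimated from the 3–4
replicates including the candidate: the maximum attainable deviation/SD
ratio is (n−1)/√n < 2 for n ≤ 5, so the rule could never fire. The package's
reading keeps the rule's structure (2 × SD threshold, 30% coverage) but
measures deviation as the distance to the *nearest sibling replicate*, with
the SD a robust scale of replicate differences calibrated from the 25th
percentile of nearest-sibling distances via half-normal order statistics.
The nearest-sibling reference cannot be contaminated by the candidate
outlier, the low quantile tolerates one gross outlier among 3–4 replicates,
and the rule is idempotent. It discards a full-spectrum 10-SD deviant,
retains a deviant confined to 20% of wavelengths, and flags ~5% of clean
replicates under the generator's multiplicative/additive replicate
artifacts. Individuals with fewer than 3 replicates are never touched; an
individual losing all replicates is excluded from the species' analysis with
a logged warning.

*Preprocessing.* Standard-normal-variate normalization per spectrum
(mean 0, sample SD 1 — the standard chemometric control for additive and
multiplicative wavelength effects), then a Savitzky–Golay first derivative,
window 37 points, polynomial order 2, computed on interior points only (the
grid shrinks by 36 points; no edge padding). Order-2 SG reproduces
polynomials of degree ≤2 exactly, so linear spectra differentiate exactly —
a test identity.

*Ordination.* PCoA on Euclidean distances between preprocessed spectra
(classical metric MDS via scikit-bio), which for Euclidean input equals PCA
up to sign and guarantees non-negative eigenvalues. Technical replicates are
projected individually and averaged per individual; the first two axes
become two new traits (LNIRS1/2 for leaves, SNIRS1/2 for seeds). Replicate
coherence is validated by Ward hierarchical clustering cut at g = number of
individuals and scored with the (unadjusted, pair-counting) Rand index.

Leaf axes are the *control* traits: they enter Pillai_control only. Seed
axes are ordinary traits but are excluded from the convergence analysis
because PCoA axes are not homologous across species.

## Convergence test

Trait identities shared across species are counted by the number of species
in which they are DA; the classes are exactly {1, 2, ≥3}. The null preserves
the measured design: each iteration draws n species-trait slots uniformly
without replacement from the t measured slots (species-specific traits
participate and can only fall in the unique class) and recounts the classes.
Empirical p-values are reported both add-one-smoothed, (1 + #extreme)/(1 +
iterations), and raw; the smoothed version is primary because it cannot
return p = 0 from finite resampling. The slot list is canonically ordered,
making the null invariant to species ordering. Because every iteration
assigns exactly n DA slots, total DA multiplicity is conserved — enrichment
in one sharing class forces a deficit elsewhere, which is why the ≥3-class
excess is mirrored by a two-class deficit. A family-sensitivity helper
re-runs the analysis keeping one member of a named family (e.g. Poaceae) at
a time. Calibration: with DA slots assigned at random over the 13-species
design, the ≥3-class enrichment test at nominal 5% rejects at ≈3% over 500
simulations (slightly conservative, as expected for a discrete statistic
with add-one smoothing).

## Hypervolume

Quantitative traits are z-scored across all individuals (both forms pooled,
sample SD); qualitative traits expand into all-level 0/1 indicators, kept
unscaled. Linearly dependent columns are removed separately per form by a
greedy, order-stable Gram–Schmidt sweep on centered columns (threshold 1e-8
× the largest centered column norm; a k-level one-hot block loses exactly
one column). Log-determinants come from `slogdet` of the sample (N−1)
covariance; a non-positive determinant is fatal with the offending form
named. Sizes are `exp(logdet/r)` with r the larger of the two reduced
dimensions, and the reported statistic is the natural-log ratio
domestic/wild (the base only rescales; the sign is the finding). Closed-form
anchor: scaling one form's traits by c with equal dimensions shifts the log
ratio by exactly 2·ln c.

## FAMD, Pillai trace, mPDI

FAMD is computed directly by SVD: quantitative columns standardized with the
population SD; each qualitative level indicator scaled by 1/√(level
proportion) and centered; row scores are projections on the right singular
vectors of Z/√n and eigenvalues the squared singular values over n. On
all-quantitative input this reduces to PCA of standardized data, on
all-qualitative input to MCA, both verified against brute-force oracles.
Levels absent from the complete-case rows are dropped.

Pillai's trace is `trace(H(H+E)^{-1})` with H and E the between/within-form
cross-product matrices of the FAMD scores. Using *all* FAMD axes makes H+E
singular once the axis count approaches the sample size, so axes (ordered by
eigenvalue) are capped at N−2 and further truncated from the tail if the
total scatter is numerically singular (condition number > 1e12); truncation
is logged and flagged in the output. Pillai is invariant to invertible
linear maps of the responses, so this cap is the only place dimensionality
enters.

mPDI = Pillai_all − Pillai_control, with Pillai_control from exactly the two
leaf PCoA axis traits on the same individuals; mPDI/Pillai_control is also
reported, flagged undefined when the baseline is zero. Replicates enter the
multivariate stages as separate individuals; multivariate stages use
complete-case individuals by default (per-form mean imputation is opt-in).
Missing quantitative cells elsewhere are handled per trait (complete cases
per univariate test).

The control premise is itself checked: on 50 synthetic studies at full scale
where leaf spectra carry no form signal, mean Pillai_control < 0.1 while
Pillai_all on diverged traits > 0.7, and mPDI tracks Pillai_all within 0.1.
The boundary case is also covered: when the "traits" are the control axes
themselves (divergence entirely attributable to baseline drift — the
apple-like sampling artifact), mPDI collapses to ~0.

## Correlation-structure comparison

Traits are averaged across replicates to one value per accession
(quantitative traits only — rank correlations and Lande responses need
ordered numeric values); Spearman matrices use mid-ranks and
pairwise-complete observations, with constant traits masked. The mean-|r|
comparison is a Welch t-test on the upper-triangle absolute correlations
(the equal-variance Student variant is a flag away). Random skewers draws
unit-norm Gaussian gradients beta, computes responses C·beta for each form's
accession-mean covariance matrix, and averages the cosine between the
response vectors (the Pearson-after-centering variant is a flag away);
draws annihilated by a singular matrix are skipped and counted. The
similarity is exactly 1 for proportional matrices and invariant to positive
scaling of either argument.

## Cross-species statistics

Rank-based tests are primary at species-level n: Spearman and Kendall
(tie-corrected, two-sided) against domestication timing in generations;
Wilcoxon–Mann–Whitney for binary groupings (exact when combined n ≤ 12 and
untied, normal approximation with tie correction otherwise), with the
Student t reported alongside because both appear in comparative practice.
The drift-control validation correlates the leaf-spectra space log ratio
(per-individual mean PCoA coordinates, axes capped at 95% cumulative
variance and min-form-size − 2) with user-supplied domestic/wild genomic
diversity ratios; fewer than 4 complete species pairs flags the check
underpowered rather than testing.

## What the generator emulates — and what it does not

Defaults are the study design the pipeline targets: 13 species, 18 wild + 19
domestic accessions × 3 replicates; 20 quantitative + 6 qualitative traits
per species (338 species-trait slots); 40 shared trait identities whose
breadth is skewed (mostly 2–4 species, occasionally most); leaf spectra with
2150 wavelengths × 3 technical replicates, seed spectra 1300 × 4. Block
effects are drawn once per replicate index (randomized complete block);
qualitative traits are drawn once per accession (accession-level genetic
determination); all randomness flows through per-species substreams keyed by
species id, so outputs are invariant to species order.

Domestication enters four ways, each a deliberate modelling choice:
form effects delta ∈ [0.5, 3] residual SD on a ~50% subset of traits (no
effect sizes are published for most traits; this range makes single-trait
power realistic rather than saturated); domestic accession-level variance
below wild (0.25 vs 0.75 on top of sigma2_k = 1) to emulate the
domestication bottleneck's loss of standing variance, which is what makes
domestic spaces tend to shrink; the most broadly shared identities are
convergence-prone (DA with probability 0.9 wherever measured, with effect
sizes from the upper half of the range) — mirroring the fact that widely
measurable homologous traits such as organ size are also the repeated
targets of selection; and seed spectra shift by a smooth unit-RMS signature
in domesticates while leaf spectra never carry a form signal, which is the
control-trait premise by construction.

Not emulated: spectroscopy physics (water bands, scattering), phylogenetic
signal among species, genetic linkage or pleiotropy behind trait
correlations (traits are conditionally independent given accession), gene
flow, and missing-data mechanisms. Passing tests therefore demonstrate that
the statistical machinery is correct and calibrated under the assumed
generative structure — not that real spectra or real trait architectures
satisfy those assumptions.

## Problem sizes used in the checks

The test suite runs the mixed-model calibration at 1000 null fits plus 200
coverage fits, the convergence calibration at 500 simulations × 2000
iterations, and the control-premise check at 50 full-scale single-species
studies; `scripts/acceptance.py` runs the complete 13-species study with
10 000 resampling iterations and 10 000 skewers. These sizes give Monte
Carlo standard errors well inside every asserted band while keeping a full
run in minutes on a single CPU.

## Known limitations

- The Satterthwaite machinery uses numeric differentiation; pathological
  likelihood surfaces could degrade the df estimate (it is clamped, and the
  boundary/OLS limit is exact).
- Exact r×c Fisher enumeration is exponential in table size; large sparse
  qualitative tables fall back to Monte Carlo (flagged).
- The mPDI inherits Pillai's dependence on retained dimensionality when the
  axis cap binds; the cap and any truncation are reported in the output.
- Hypervolume determinants on nearly collinear trait sets are sensitive to
  the rank tolerance; the default (1e-8, relative) is shared with the FAMD
  axis cutoff so both stages agree on effective dimensionality.
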