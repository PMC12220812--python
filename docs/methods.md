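# Methods

## Scope and data model

`sexcov` analyses subject-by-region grey-matter volume tables. Volumes
arrive pre-extracted (mm³); image acquisition, registration and
segmentation are out of scope. A cohort carries, per subject: sex
(exactly two observed levels, `female`/`male`), age (days or years),
a batch label (e.g. background strain or scan cohort), an optional
numeric QC covariate (e.g. a FreeSurfer-style Euler number), and total
tissue volume (TTV). TTV may be supplied as a column; when absent it is
computed as the row-sum of the region volumes. Region metadata records
hemisphere and homotopic (left/right counterpart) pairing; the partner
mapping must be symmetric and midline regions have no partner.

Edges — unordered region pairs — are stored once each in a canonical
lexicographic order; all modules index edges this way, which is valid
because every edge statistic here is symmetric in the pair.

At the I/O and QC boundaries a cohort must contain at least 5 subjects
per sex (the wild-type inclusion rule). Directly constructed or
simulated cohorts may be smaller (≥ 3 per sex) so that enumeration
oracles on tiny cohorts remain expressible.

## Quality control

**Threshold filter.** Subjects whose QC covariate falls strictly below
(`direction="min"`, the Euler-number convention) or above
(`direction="max"`) a cutoff are excluded, with the exclusion list
returned and the remaining cohort re-validated.

**Influence screen.** For every ordered region pair (y, x) a simple
least-squares line is fitted on the mixed-sex cohort and each subject's
Cook's distance D_i = e_i² h_ii / (k s² (1 − h_ii)²), k = 2, is
computed; the subject's maximum over all models is recorded, z-scored
across subjects, and z > 3 flags the subject. Ordered (not unordered)
pairs are used because Cook's distance is not symmetric in the
response/predictor roles; using both orientations removes dependence on
an arbitrary pair orientation. Exactly collinear pairs carry no
influence information (the statistic is 0/0) and contribute zero.
Flagging is the reproducible part of an outlier review; removal is
opt-in (`remove_flagged_outliers`), since the confirmatory visual
review it stands in for cannot be automated.

**Batch adjustment.** A moment-matching location(-scale) adjustment per
region: `center` subtracts the batch mean and restores the grand mean
(removing additive offsets exactly and preserving each region's grand
mean); `location_scale` additionally rescales each batch's SD to the
pooled SD of the batch-centered values. This is a deliberate
simplification of empirical-Bayes harmonization: there is no shrinkage
across regions and no covariate protection, so in small batches the
adjustment can absorb some true covariate signal. TTV is recomputed as
the row-sum of the adjusted volumes. Batch adjustment runs before sex
splitting and residualization.

**Age residualization.** Within each sex separately, every region is
regressed on intercept + age and the residuals feed all correlation
analyses. The operation is idempotent and its residuals are orthogonal
to age within sex by construction. Constant age within a sex is an
error rather than a silent skip.

## Edge-wise covariance sex differences

Per-sex Pearson correlation matrices of the residuals give the edge
statistic D under a configurable sign convention. The primary report
convention is `male_minus_female` (positive D = male-biased
covariance), chosen so the sign matches the volumetric coefficient
convention (positive β₁ = male-biased volume); `female_minus_male` is
available and every output records the convention in use.

The null permutes sex labels across subjects and, by default
(`mode="full"`), re-runs the within-group age residualization on the
permuted groups before recomputing both correlation matrices — a
literal re-run of the whole process per iteration. A `fast` mode
residualizes once within the observed groups and permutes only the
residual labels; on cohorts where age effects are identical across
sexes the two modes agree closely, and the generator plants age slopes
identically in both sexes precisely so this equivalence is testable.
One master seed spawns per-iteration substreams, so results are
independent of any parallelization granularity.

Empirical p-values are two-sided on |D| with add-one smoothing,
bounding p ≥ 1/(n_perm + 1) and avoiding zero p-values; both
female- and male-biased edges are therefore detectable. BH-FDR across
edges at q < 0.05 defines the significant set. n_perm defaults to 1000.

Mean per-edge correlations are compared between sexes with a paired
t-test across edges (edges are matched between sexes; raw correlations,
no Fisher z-transform, though a transform option exists). Constant
differences yield a degenerate-flagged result with a zero-width
interval rather than an undefined test.

The strength-vs-difference analysis correlates mean within-sex strength
(r_f + r_m)/2 with |D| on edges passing a series of p-value thresholds;
thresholds retaining fewer than 3 edges report NaN rather than erroring.
The companion `simulate_bounded_pairs` Monte-Carlo study documents the
mechanism: the sampling variance of a sample correlation is
approximately (1 − ρ²)²/n, so a fixed planted difference is estimated
with more spread — and observed differences are larger in magnitude —
where the baseline correlation is weak. This is a minimal emulation of
that qualitative claim, not a reconstruction of any particular study's
simulation design.

## Volumetric sex effects

Region volumes and TTV are z-scored across all subjects pooled (sample
SD, n − 1). Each region is fitted by OLS on intercept, sex (female = 0,
male = 1), and the profile's covariates: age + TTV + batch indicators
for mouse-like cohorts, age + TTV + QC covariate for human-like ones.
Age and the QC covariate enter centered (affecting only the intercept);
batch enters as unscaled indicators with the lexicographically first
level as reference. All regions share one design matrix, so the fit is
a single multi-response least squares with per-region residual
variances; results match a per-region statsmodels OLS to rounding.
β₁ p-values are BH-corrected across regions (the FDR family is the
region set of one cohort).

Note on scale: the generator plants effects in units of the region's
*within-sex* SD, while the model standardizes by the *pooled* SD (which
includes the between-sex shift), and TTV conditioning absorbs a further
small share. A planted 0.8 SD shift therefore has a population β₁ of
about 0.72 under the default simulation conditions — inside the ±0.1
recovery band the tests check, and the reason recovery is asserted on
the mean over replicates.

## Regional summaries, coupling, symmetry, networks

Each region's covariance bias is the mean of D over its p − 1 incident
edges — signed and absolute, over all edges and over the
FDR-significant subset (absent when the region has no significant
incident edge, and such regions are dropped pairwise from analyses of
those columns).

The coupling test Pearson-correlates regional bias with β₁ across
regions: signed mode pairs the signed mean with β₁, absolute mode pairs
the absolute mean with |β₁|. Significance comes from sex-label
permutations in which both arms — residualization → D → all-pairs
regional means, and the per-region sex-effect refit — are recomputed
per iteration; p uses the same two-sided add-one estimator. All-pairs
(not significant-only) means are used inside the null because the
significant set is undefined within a null iteration without nesting
the full edge-wise permutation inside each coupling permutation, a
quadratic-cost construction with no inferential gain here. Degenerate
arms (constant up to rounding) are flagged NaN, never reported as 0.

Hemispheric symmetry is the Pearson correlation of a chosen regional
bias column between left regions and their homotopic right partners
(midline and unpaired regions excluded; at least 3 usable pairs
required).

The significant-edge graph has regions as nodes (only regions incident
to a significant edge enter) and significant edges labelled by bias
direction; nodes carry the volumetric bias status. Connected components
are ranked by node count, then edge count, then smallest member id —
deterministic and invariant to input edge order. A component's
"centers" are its maximum-degree nodes (ties reported jointly), and its
summary cross-tabulates edges by how many endpoints are volumetrically
sex-biased.

The targeted test restricts the same permutation machinery to the
C(k,2) pairs among k user-named regions (classically, volumetrically
male-biased structures such as the BNST, medial amygdala and olfactory
bulb in rodents) and applies Bonferroni with factor C(k,2). Because
label draws depend only on the subject count and correlations depend
only on the pair's columns, restricted p-values equal the full-matrix
pipeline's for the same seed and mode. The convention of adding
sex-specific means back onto residuals for display purposes provably
leaves within-sex correlations unchanged and is provided only as an
export transform.

## Synthetic cohorts

The generator draws each sex from a multivariate normal whose
correlation matrix is an exchangeable (or per-block) base perturbed on
planted edges by ±δ/2 (female +, male −), keeping the pooled
correlation at the base value and making δ the exact population
analogue of the edge statistic. Implied non-positive-definite matrices
abort generation (no silent projection to the nearest valid matrix,
which would break the planted-truth contract); all correlations are
bounded at |ρ| ≤ 0.999 for Cholesky stability. Volumetric effects are
mean shifts in within-sex SD units, split symmetrically about the
common mean. Age is uniform over a configurable range (default 56–90,
a mouse-like age window in days) with per-region slopes identical in
both sexes; batches add constant offsets; volumes are shifted per
region if needed to stay strictly positive (an additive constant,
correlation-invariant); TTV is the row-sum. Region names alternate
left/right homotopic pairs with a midline remainder. The same config
and seed give byte-identical output.

Defaults emulate study-shaped cohorts: roughly balanced sexes at
tens-to-hundreds of subjects per sex, tens of regions, baseline
inter-regional correlation 0.2–0.3 (between the human-like ~0.2 and
mouse-like ~0.3 regimes). What the generator does **not** emulate:
empirical covariance spectra or atlas-specific region profiles,
non-Gaussian volume distributions, heteroscedastic or spatially
structured noise, family/relatedness structure, and batch-by-covariate
interactions. Passing tests therefore demonstrate the statistical
machinery's calibration and recovery under a Gaussian
planted-truth model, not performance guarantees on any particular
empirical dataset.

`make_coupled_config` plants an inverse covariance–volume coupling:
a block of regions receives male-biased volumes and female-biased
within-block covariance. The block's base correlation is raised by
|δ|/2 so the weaker sex lands exactly at the background correlation;
a block whose within correlation dropped below the between-block
background would not be positive definite.

## Numerical choices and problem sizes

- Empirical p-values and permutation counts: add-one smoothing
  everywhere; the smallest attainable p is 1/(n_perm + 1).
- Degeneracy guards: zero-variance regions and rank-deficient designs
  are errors naming the offending columns; constant-up-to-rounding
  coupling arms return flagged NaN.
- Collinear pairs in the influence screen contribute zero (see above).
- Test and acceptance runs use 10–40 replicates at 20–30 regions and
  60–200 subjects per sex with 500–1000 permutations — sizes at which
  the asymptotics the checks rely on (correlation sampling variance,
  BH behaviour) are already accurate while a full run stays in seconds.
  With eight planted edges among 20 regions, the BH floor
  p = 1/1001 gives q ≈ 0.024 for a jointly recovered set; a single
  planted edge could never reach q < 0.05 at n_perm = 1000 with
  190 edges in the family, which is why recovery conditions plant
  several edges.
- Full-run determinism: one config (including seed) reproduces every
  CSV byte-for-byte; the summary carries a provenance block with the
  seed, permutation count, sign convention and a config hash that
  excludes only the output location.

## Known limitations

- The batch adjustment is location-scale only; cohorts needing
  empirical-Bayes shrinkage or covariate protection should harmonize
  upstream.
- No partial correlations, covariance (as opposed to correlation)
  analyses, or age-resolved covariance; the design is cross-sectional.
- No mixed-effects or relatedness modelling; family structure must be
  handled by subject selection upstream.
- The paired t-test on mean correlations treats edges as independent
  observations, which they are not; it is reported descriptively, with
  inference on specific edges and on the coupling carried by the
  permutation machinery.
- Hemispheric symmetry requires a homotopic-partner mapping; the
  package does not infer left/right pairings from names in user data.
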