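# Methods

This note documents the statistical procedures shapecat implements, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Dissimilarity and comparison

**RDM construction.** Dissimilarity between two condition patterns is
1 − Pearson correlation across units, the RSA convention; values lie in
[0, 2] with 0 on the diagonal. A Spearman-based dissimilarity is available
(`RDMTransformer(dissimilarity="spearman")`) but off by default. A
zero-variance pattern row makes the correlation undefined and is a hard
error naming the offending condition — rows are never dropped silently,
because row order must stay aligned with the design. Matrices read from
disk are symmetrised as (M + Mᵀ)/2 when the asymmetry is within 1e−9 and
rejected otherwise.

**Vectorisation.** All comparisons operate on the strict upper triangle in
row-major pair order, length N(N−1)/2; `vectorize`/`devectorize` round-trip.

**Spearman and partial Spearman.** RDM vectors are rank-transformed with
average ranks for ties, then Pearson-correlated. The partial statistic
ranks first, then residualises both sides on the controls plus an intercept
by least squares, and correlates the residuals (rank-then-partial, the
common RSA order). A control whose residualisation leaves less than 1e−12
of either side's variance is reported as degenerate rather than returning a
meaningless ratio.

**Permutation test.** The null relabels the second RDM's conditions (rows
and columns jointly) uniformly at random and recomputes the (partial)
statistic; default 1000 permutations. The test is one-sided for positive
correspondence — positive correspondence is the hypothesis throughout this
kind of analysis — with +1 smoothing: p = (1 + #{ρ_null ≥ ρ_obs})/(1 + n).
The significance threshold reported alongside each comparison is the
empirical (1 − α) quantile of the null, computed per comparison. Sidedness
and tie handling are recorded package choices, not inferences about any
particular prior study. Permuting either side is distributionally
equivalent under exchangeability; the second argument is permuted.

**Partialling trigger.** `layer_profile` partials each model comparison by
the other model exactly when the two models are significantly correlated by
the permutation test at α (default 0.05). This mirrors the situation where
behavioural shape and category models are dependent in one stimulus set but
not another; with the trigger, the same code path handles both regimes.

## ANOVAs

**Layer × Condition (2 × 2, layers as units).** The shape and category
correlation series are stacked and fitted by fixed-effects least squares:
ρ ~ 1 + layer + condition + layer:condition, with the layer index centred
and condition effect-coded ±1/2. There are no subjects at this level, so
the error term is the regression residual on 2L − 4 df. Each effect's F is
the nested residual-sum-of-squares comparison of the full model against the
model with that column removed. (Reports of this design elsewhere sometimes
print F with (1, 1) df regardless of layer count; that is not a standard
partition and shapecat uses the regression df.)

**Condition × ROI (fully within-subject).** Classical repeated-measures
partition from cell and marginal means; each effect is tested against its
own subject-by-effect interaction mean square — Condition on
(p−1, (p−1)(n−1)) df, ROI on (q−1, (q−1)(n−1)), interaction on
((p−1)(q−1), (p−1)(q−1)(n−1)). Requires a complete subject × ROI ×
condition grid and n ≥ 3. The implementation is the explicit partition;
tests cross-check it against statsmodels' `AnovaRM` on random instances.

**Layer-trend × ROI (brain–layer profiles).** "Layer modelled linearly" is
implemented as a within-subject trend contrast: each subject × ROI series
is reduced to its least-squares slope over the centred layer index. The
Layer main effect is the one-sample F (= t²) of the ROI-averaged subject
slopes on (1, n−1) df; the ROI effect is a one-way repeated-measures ANOVA
of the layer-averaged means; the interaction is the same ANOVA of the
per-ROI slopes, both on ((q−1), (q−1)(n−1)) df. With a single subject the
SEM is undefined and the ANOVA is refused (returned as `None` with a
warning) rather than fabricated.

**Degenerate inputs.** Sums of squares below 1e−12 of the response's total
sum of squares are rounding residue of a constant effect and give F = 0,
p = 1; a zero error term under a real effect gives F = ∞ with the smallest
representable p. F statistics are invariant to shifting and rescaling the
response, which the tests assert.

**Post-hocs.** Paired and one-sample t use the textbook formulas with
two-sided p; identical paired samples give t = 0, p = 1 rather than 0/0.
Tukey HSD over ROI means uses the repeated-measures subject × ROI error
mean square, q = |m_i − m_j| / √(MS_err/n), with p from the studentized
range distribution on (k, (k−1)(n−1)). No multiple-testing correction is
applied beyond what each named test defines.

## GIST + LDA stimulus audit

**Descriptor.** The filter bank is built in the frequency domain: each of
the 8 scales × 8 orientations is the product of a log-Gaussian radial
profile (σ = 0.55 log-frequency units, centre frequencies descending from
0.32 cycles/pixel by √2 per scale) and a Gaussian angular profile
(σ = π/8), restricted to a half-plane so the complex modulus of the
filtered image is a quadrature local-energy measure. DC and the unpaired
Nyquist row/column are zeroed — the former makes constant images map to the
zero descriptor, the latter makes the bank exactly covariant under 90°
image rotation (orientation channels shift by 4 positions; the tests assert
this). Energies are averaged on a 4 × 4 grid; descriptor length
8·8·16 = 1024. Images are resized to 256 × 256. Optional Oliva–Torralba
style local contrast normalisation is available (`prefilter=True`) but off
by default. Grid 4 × 4 and side 256 are the standard GIST convention.

**Cross-decoding.** Leave-one-level-out: to decode category, entire shape
levels are held out (and vice versa), so above-chance accuracy requires
generalisation across the nuisance factor. The two-way scheme (2-level
generalisation factor) has one fold per held-out level. The six-way scheme
on a 9-shape × 6-category design enumerates every 6-subset of shape levels
crossed with each choice of held-out member: C(9,6) × 6 = 504 folds, each
training on 5 × 6 = 30 conditions and testing on 6; for shape decoding the
6-subset defines the classes and one category level is held out instead.
With 1024-dimensional descriptors and 30 training rows the within-class
scatter is singular, so LDA uses Ledoit–Wolf shrinkage (`solver="lsqr",
shrinkage="auto"`): deterministic, no tuning fold. Accuracy is the
unweighted mean over folds; a pooled binomial test against 1/k chance is
reported as a descriptive criterion ("at chance" has no canonical
definition here, so the audit reports the p-value rather than asserting a
verdict).

## Classical MDS

Torgerson's method: double-centre the squared dissimilarities,
eigendecompose, scale the top-d eigenvectors by √λ. Chosen over
stress-majorisation because it is deterministic and is what typical RSA
geometry figures use. Negative eigenvalues (non-Euclidean inputs) are
truncated to zero with a warning and their share of spectral mass reported
as a diagnostic. The `stress` field is the strain-type spectral residual of
the rank-d Gram approximation (in [0, 1], provably non-increasing in d);
Euclidean inputs embed exactly (Procrustes residual at float precision).

## Synthetic generator

The generator produces the regimes the analyses assume, with planted,
recoverable parameters:

* **Designs** — fully crossed balanced shape × category factorials; the two
  bundled sizes are 2 × 2 with 8 per cell (32 conditions) and 9 × 6 with 1
  per cell (54 conditions).
* **Activations** — each shape level and category level is embedded once as
  a fixed standard-normal vector over units; layer l's pattern for a
  condition is shape_schedule[l]·S + category_schedule[l]·C + 1.0·E +
  noise, where E is a fixed exemplar-unique embedding and noise is i.i.d.
  Gaussian. Depth changes only the mixture weights — the minimal structure
  under which a layer profile is interpretable. The exemplar component is
  held at the same scale as the level signal: without it, a fully separated
  level split pins Spearman-vs-binary-model correlations at their ceiling
  and profiles become uninformative plateaus; real measured RDMs are never
  perfectly separated.
* **Defaults (the "paper-like" preset)** — 8 layers; shape schedule
  linearly decaying 1.0 → 0.35; category schedule geometrically rising
  0.05 → 1.0 (peak at the final layer); unit noise σ = 0.3; 60 units;
  16 subjects with noise σ = 0.4; three ROIs with (shape, category) weights
  V1 (1.0, 0.05), VTC_post (0.55, 0.45), VTC_ant (0.08, 1.0), giving the
  early-shape → late-category gradient; behavioural model dependency 0.48,
  the Set-A-like regime in which partialling engages.
* **Images** — smooth textured ellipses on a light background: the first
  shape level renders elongated (bounding-box aspect ratio > 2.5), the
  second compact (< 1.5); position/size/orientation jitter and interior
  texture are drawn independently of category, so category is unpredictable
  from low-level statistics by construction.
* **Behavioural-style model RDMs** — binary factor model + w·(other-factor
  model) + symmetric noise, rescaled to [0, 2]; w is calibrated by
  bisection plus a candidate grid so the achieved rank correlation with the
  other factor's model lands within ±0.1 of the requested dependency
  (rank-based targets are piecewise constant in w at low noise, hence the
  grid refinement). Unreachable targets produce a warning with the achieved
  value.

Everything is bit-reproducible given (spec, seed); per-stage generators
draw from seed-sequence-spawned streams.

**What the generator does not emulate** — and hence what green tests do not
establish about real data: no spatial voxel correlation or hemodynamics, no
GLM beta estimation, no photorealistic stimuli, no retinotopy, no
between-subject signal heterogeneity (subjects share the ROI mixtures and
differ only in noise), and no nonlinear layer transforms — depth is a pure
mixture schedule. Passing tests certify the *estimators and tests*, and
that the pipeline recovers planted structure of the assumed form; they are
not evidence about any particular network or cortex.

## Problem sizes in the test and acceptance runs

Oracle-equivalence checks use 100 seeded instances of 4–8 conditions;
permutation calibration uses 500 null replicates at 200 permutations with
8 conditions; the ROI-interaction rate uses 200 simulated 16-subject
studies; the image audit uses the 32-image 2 × 2 set at 256 × 256. These
sizes make the full suite run in about a minute while leaving Monte-Carlo
error well inside the asserted bands.

## Known limitations

* Partial Spearman with a binary control removes the factor's linear rank
  component only; graded structure aligned with a factor but not captured
  by the binary regressor can leave small residual correlations (the tests
  average over generator draws for this reason).
* The permutation threshold is computed per comparison; with many layers
  this is a per-comparison α, not a family-wise criterion.
* The layer × condition ANOVA treats per-layer correlations as independent
  observations; adjacent CNN layers are in fact dependent, so its p-values
  are descriptive, as in the literature this battery follows.
* Binomial p-values in the audit pool test items that recur across folds
  and are therefore correlated; they are reported as descriptive evidence,
  not exact tests.
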