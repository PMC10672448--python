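# Methods

`lichenmonitor` implements a two-track analysis of long-term epiphytic-lichen
biomonitoring data: community/damage index statistics on field survey tables,
and chemometric classification of Vis-NIR thallus spectra. Every stage is
exercised end-to-end on synthetic data with known ground truth; this note
records the models, the defaults and why, and what the synthetic conditions
do and do not establish about real field data.

## Indices

**Index of Atmospheric Purity (IAP).** A tree's community is scored by the
frequency of each epiphytic species over a 20 × 50 cm quadrat subdivided into
ten 10 × 10 cm squares, so each species contributes f ∈ {1..10}. The tree
index is IAP_tree = Σᵢ fᵢ and the station index is the arithmetic mean over
its m sampled trees, IAP_station = (Σ IAP_tree)/m. Absence is encoded by the
row being absent; frequency-0 rows are accepted on read and normalized away.
Campaign change is tested per locality with a two-sided pooled-variance
Student's t over per-tree values (df = n₁ + n₂ − 2); a Welch variant sits
behind a flag, and no multiple-testing correction is applied across
localities by default (raw per-locality p values are the primary output; a
Holm-adjusted column is available).

**Damage Index (DI).** Each thallus of the nine target macrolichens is
scored on an ordinal 1–5 scale (1 = no visible damage, 5 = necrosis over
≥ 90 % of the thallus / dead). A thallus with several symptoms takes the
maximum category — the max rule — and a symptom-free thallus scores 1, which
also means a thallus whose symptoms are all category 1 shares the category
floor. Field range tables mapping affected-surface extent to categories are
survey-specific; the package exposes a configurable breakpoint table
defaulting to fractions (0, 0.1, 0.25, 0.5, 0.9) with left-closed intervals,
so exactly 90 % affected surface is category 5. Per-locality campaign
comparisons pool thalli across species and trees (one test per locality,
matching how such networks report damage change); per-species breakdowns are
additionally emitted. The species-by-station change matrix orders species by
decreasing mean absolute change.

**Trait models.** Per-species abundance change (mean quadrat frequency in
the second campaign minus the first, averaged over a station's trees with
absent-on-tree counted as 0) is regressed on numeric ecological indicators
(substratum pH, eutrophication tolerance; ordinary least squares with
Pearson r and its two-sided p) and compared across categorical traits
(growth form, reproductive structure) with one-way fixed-effects ANOVA.
Constant responses return a flagged degenerate result rather than raising.

**Ordination.** Community composition per tree is embedded by nonmetric
multidimensional scaling of Bray–Curtis dissimilarities (Euclidean is
selectable; the dissimilarity underlying such published ordinations is
frequently unstated, so the default is the field's standard for abundance
data). The embedding uses SMACOF with nonmetric (isotonic) disparity
updates, 20 random restarts by default, k = 2, max 500 iterations, and
reports the best restart's Kruskal stress-1 computed from an isotonic fit of
embedding distances against the dissimilarity order.

## Chemometrics

The spectral pipeline follows the aquaphotomics convention of treating the
water spectral pattern as the information source: from the full 350–2500 nm,
1-nm reflectance grid (2151 variables), the first overtone of the OH
stretching vibrations, 1300–1600 nm inclusive (301 variables), is retained.

**Preprocessing.** Multiplicative scatter correction regresses each spectrum
on a reference over wavelengths, x = a + b·ref, and inverts the affine
distortion, (x − a)/b. The reference is the mean training spectrum, and test
spectra are corrected against the training reference — the reference and the
subsequent column-centring means are training-set statistics, never refit on
test data. Slopes below 1e−12 abort with the offending sample named. MSC is
exactly affine-invariant: msc(b·x + a) = msc(x) for any b ≠ 0, which the
property suite checks to 1e−10. An optional log10(1/R) absorbance transform
exists but is off by default (reflectance is analyzed as read).

**PCA** is a display step: SVD of the pretreated matrix, scores = U·s,
orthonormal loadings, explained fractions from squared singular values.
Components are oriented so each loading's largest-magnitude entry is
positive, making score plots reproducible.

**PLS-DA.** Class membership is encoded one column per class (0/1, then
centred), and latent variables are extracted sequentially by NIPALS: each
component's weight vector maximizes residual X–Y covariance, X-scores are
mutually orthogonal through deflation, and regression coefficients are
recovered as B = W(PᵀW)⁻¹Cᵀ. Samples are assigned to the class of maximal
predicted score; exact ties go to the lexicographically first class label.
With all feasible components on full-rank data the fitted values coincide
with the least-squares fit, a limit the tests verify, and the implementation
is cross-checked against an independent PLS regression implementation.

**Latent-variable selection.** The LV count is chosen by stratified 10-fold
cross-validation (venetian blinds selectable) over a 1–15 grid: per fold a
single maximal-rank NIPALS fit provides truncated coefficient forms for all
candidate counts; the count minimizing the mean per-class balanced error,
averaged over folds, wins, with ties broken toward the smaller count.
Cross-validation operates on the pretreated training block with per-fold
re-centring; the MSC reference is not refit per fold, since it is a mean
spectrum whose leave-fold-out perturbation is negligible and the pipeline
fixes preprocessing before model selection. A fold losing a class aborts
with advice to stratify.

**Figures of merit.** Per class, sensitivity Sn = TP/(TP+FN), specificity
Sp = TN/(TN+FP) with all other classes pooled as negative, and the balanced
classification error Er = 1 − (Sn + Sp)/2 — the convention under which every
published binary-model error row this package checks reproduces from its own
printed Sn/Sp within ±0.002 (published tables round unprinted intermediates,
e.g. an Er printed 0.1398 where the printed Sn/Sp give 0.1395; the package
documents rather than resolves such slack and rounds its own report output
to 3 decimals). Metrics are reported for two phases: pooled held-out CV
predictions at the chosen LV count, and the single external test-set
prediction (58 of 195 samples held out at random by default).

## Synthetic data

The generators define the conditions every recovery test runs under.

*Surveys.* Per species, station, tree, year, presence is drawn independently
per square, so frequency ~ Binomial(10, p) with
logit p = logit(base occupancy) + [second campaign]·year_effect. The default
pool couples year_effect to centred eutrophication tolerance
(−0.4 logit/unit), imposing the trait-linked community change the trait
regression must recover.

*Damage.* Symptom counts are Poisson (rate 1 by default, ≤ 10 thalli per
species per tree per the field protocol); each symptom's category is an
ordered five-class draw, 1 + #{cutpoints (0.5, 1.5, 2.5, 3.5) below
μ + size_effect·(size − median) + N(0,1)}, where μ is the per-(station, year)
latent stress. Sizes are log-normal (median ≈ 6 cm); size_effect defaults to
0 so the no-size-effect null is exact. An exact-count mode allocates a
requested number of thalli per campaign over (station, tree, species) cells
under the 10-per-cell cap.

*Spectra.* Clean spectra are a smooth reflectance baseline (gentle slope plus
broad 1930/2450 nm troughs) minus Gaussian absorption peaks at canonical
first-overtone OH coordinates (1342, 1364, 1382, 1412, 1440, 1462, 1476,
1494 nm; width 16 nm, base depth 0.10). Class effects are additive depth
shifts (0.025–0.045) on designated peaks per label field; five label fields
are drawn with configurable proportions (defaults mirror a 195-sample
campaign with a 32-sample excessive-reproductive-structures minority), and
reproduction strategy can be drawn conditionally on growth form to mimic
trait confounding. The recorded spectrum is b·clean + a + white noise with
b log-normal (σ = 0.10) and a normal (σ = 0.02) — exactly the affine model
MSC inverts, which makes the MSC test analytic. Air-quality series are
exponentially declining SO₂, flat O₃, and linearly warming temperature with
optional noise, gases clipped at zero.

What the synthetic conditions do **not** establish: real thallus spectra have
correlated, structured noise, instrument drift, and chemistry outside the
water band; real communities have spatial structure among stations and
tree-level heterogeneity; real damage scoring carries observer subjectivity.
Passing recovery tests shows the estimators are correct under their stated
models, not that field data meet those models.

## Numerical choices and degenerate inputs

- Zero pooled variance with equal means returns t = 0, p = 1; with unequal
  means it is an error.
- All-zero dissimilarity profiles, single-class PLS-DA, zero-variance traits
  or sizes, empty station tree-sets, and MSC slopes near zero raise
  validation errors naming the offending entity; constant responses in
  regressions are flagged degenerate instead.
- NIPALS inner iterations converge at 1e−12 relative change (max 1000); a
  rank-exhausted residual truncates the component sequence during CV (later
  LV counts inherit the achieved fit) but is an error when a user requests
  more components than the data support.
- Problem sizes used by the test and acceptance suites — 195-sample spectra,
  20 null seeds, 2000 permutation replicates, 200 recovery simulations —
  were chosen to put Monte-Carlo standard errors well inside the asserted
  tolerances.

## Known limitations

- The DI breakpoint table is a configurable stand-in for survey-specific
  range tables, flagged as such.
- NMDS stress below 0.01 on exactly embeddable configurations depends on
  restarts; pathological dissimilarity matrices may need more than the
  default 20.
- The CLI's `report` subcommand is an alias of `run-all`; no figure rendering
  is provided beyond heatmap-ready CSV matrices and score coordinates.
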