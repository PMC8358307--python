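# Methods

This note documents the models, estimators and numerical choices behind
`nptnet`, what the synthetic data generator does and does not emulate, and
the limitations a user should know before applying the pipeline to real
recordings.

## Spectral estimation

The per-epoch spectrum is a Blackman–Tukey estimate: the biased sample
autocorrelation up to a maximum lag of one fifth of the epoch length is
tapered with a Blackman lag window and Fourier transformed with an FFT of
length `2·max_lag`, giving a frequency resolution of
`sampling_rate / (2·max_lag)` (0.5 Hz for 5-s epochs at 1 kHz). The
spectrum is restricted to 1–70 Hz, small negative values from the finite
lag truncation are clipped to zero, and the result is renormalized to unit
sum (the PSDn). The lag fraction is exposed in `blackman_tukey_psd` /
`FeatureConfig`.

A measured property worth knowing: for a pure on-bin sinusoid at n = 5000,
about 2% of the PSDn mass lies outside ±1 Hz of the tone. This is the
O(1/n) edge term of the finite-sample autocorrelation — a broadband floor,
not window sidelobes — and it does not shrink with a longer lag window. It
does not displace the quantile-type parameters (MF, IAF, SEF return the
left edge of the first bin reaching the cumulative threshold, smallest such
frequency on ties), but relative powers of a narrowband signal saturate
near 0.98 rather than 1.0.

Band conventions: the six canonical bands are half-open `[f_low, f_high)`
and tile [1, 70); the final band is right-closed so the 70 Hz bin is
counted and the six relative powers sum to one exactly. The IAF restricts
and renormalizes the PSDn to 4–15 Hz; an epoch with no power there raises a
degenerate-band error rather than returning a boundary value.

## Non-linear parameters

* **LZC**: binarization at the epoch median (strictly-greater comparison,
  so a pre-binarized 0/1 sequence parses as itself), LZ76 exhaustive
  parsing, normalization `c(n)·log2(n)/n`. The threshold rule is
  configurable (`median`/`mean`).
* **SampEn(m, r)**: Chebyshev distance, tolerance `r = 0.25·σ` with σ the
  *per-epoch* standard deviation (the alternative, a per-recording σ, is a
  known sensitivity; the per-epoch choice keeps epochs self-contained and
  the statistic scale-free). Template pairs are counted over the first
  `n − m` positions for both lengths, self-matches excluded. When no
  (m+1)-template pair matches, the entropy is undefined: the function
  returns NaN with a logged warning and the feature pipeline excludes such
  epochs from that parameter's average instead of clipping to a large
  value.
* **CTM**: the epoch is divided by its standard deviation before second
  order differencing, so the 0.025 radius is scale-free; a constant epoch
  (σ = 0) has every difference point at the origin and returns 1 by the
  delta-limit convention.

All three are invariant to amplitude scaling by construction; this is
property-tested.

## Spatial Shannon entropy

For each parameter, its 68 ROI values are histogrammed into `n_bins`
equal-width bins over the per-map min–max range (right-closed final bin)
and the normalized entropy `−Σ p log p / log n_bins` is returned. The
default `n_bins = 8` is approximately √68 rounded to a power of two; the
bin count materially affects SSE values and should be reported with them.
Equal-width bins over the map's own range make the SSE invariant to affine
transforms of the map, and a degenerate map (max = min) returns 0, the
delta-distribution limit.

## Preprocessing and aggregation

Epochs are zero-phase FIR filtered (Hamming-window designs applied
forward-backward): a 1–70 Hz band-pass and a 49–51 Hz band-stop against
line noise. Two numerical details:

* the band-stop design edges are widened by the filter's transition width
  so the requested 2-Hz band sits inside the realized stopband rather than
  in its skirts;
* half a filter length is trimmed from each end of every epoch after
  filtering. A narrowband FIR rings for roughly its own length around the
  epoch boundaries and no padding strategy removes that transient; trimming
  is the standard remedy. With the default 1001-tap filter at 1 kHz this
  keeps the central 4 s of a 5-s epoch. Under this scheme a unit-amplitude
  50 Hz probe injected into synthetic signals changes every parameter by
  less than 1% (worst case ≈ 0.6% across boundary phases, covered by a
  test).

Aggregation order: each of the 13 parameters is computed per epoch per ROI,
averaged over epochs within the ROI, and only then collapsed across ROIs —
the subject-level value is the 68-ROI mean, and the subject-level SSE is
computed from the same 68 epoch-averaged values. Parameters are epoch
statistics, so parameter values (not spectra) are averaged. Degenerate
epochs are skipped and counted in the log, never imputed; an ROI with no
valid epoch raises naming the subject and ROI.

## Association networks

The partial Spearman correlation of two variables given age and gender is
computed by rank-transforming all columns (average ranks on ties),
residualizing the two variable rank vectors on the covariate ranks by least
squares, and correlating the residuals; the p-value uses the t statistic
with `n − 2 − k` degrees of freedom. This equals the inverse-correlation
definition used by standard partial-correlation routines (cross-checked
against an independent implementation in the tests). An exact/Monte-Carlo
permutation p-value is available as an option (full enumeration up to
n = 8, seeded Monte Carlo beyond). Edges with p > 0.05 are removed,
negative correlations are folded to |ρ| (the signed value is kept as edge
metadata), and no multiplicity correction is applied — the deliberate
choice to retain weak clinical edges.

Rank-based partialling removes monotone covariate effects only
approximately: under strong confounding the type-I rate of the adjusted
test is mildly inflated (a property of partial Spearman itself, shared by
the standard implementations). The null-calibration tests quantify this:
with independent columns the edge-retention rate matches the nominal 5%.

**Bootstrap.** Each of the (default 2,000) iterations draws `n_subjects`
subjects with replacement and recomputes all pairwise adjusted |ρ| *without*
the significance threshold, so percentile confidence intervals are not
truncated; the p < 0.05 pruning applies to point-estimate networks only.
Iterations in which a variable is constant record NaN for its edges rather
than 0. The resample matrix is a function of the seed alone, so the pre and
post ensembles built with one seed share it.

**Variability network.** Per edge, the pre and post bootstrapped weights
are compared with a Wilcoxon signed-rank test paired by iteration index —
well-posed only because both ensembles resample the same subjects in each
iteration. The edge weight is |z|, the magnitude of the standardized
statistic, and exactly `⌈0.05 · 378⌉ = 19` strongest edges are retained
(ties broken by smaller p, then lexicographic node pair). If every paired
difference is zero (cloned ensembles) the retained set is flagged
degenerate. Note that |z| grows with the iteration count for *any* fixed
pre/post difference; with very small cohorts many null edges saturate the
statistic and the top-5% ranking becomes noisy — see the simulation sizes
below.

## Outcome statistics

The Wilcoxon signed-rank test drops zero differences (Wilcoxon's original
rule), assigns average ranks to tied absolute differences, and uses the
statistic W⁺. Up to 25 non-zero pairs the p-value is exact: the null
distribution of W⁺ over all 2ⁿ sign assignments is built by dynamic
programming on the doubled (integer-lattice) rank values, which handles
ties correctly — the reason the test is implemented here rather than taken
from a library whose exact path assumes distinct ranks. Above 25 pairs a
normal approximation with tie-corrected variance and a 0.5 continuity
correction is used; outcome summaries report both p-values so the switch is
transparent. MMSE is tested one-tailed for increase, DBD-13 one-tailed for
decrease.

## Synthetic cohorts

A single latent severity scalar per subject and session drives every
variable. Scores are monotone affine transforms of severity plus Gaussian
noise, rounded and clipped to their ranges (0–30, 0–52); rounding
deliberately produces ties to exercise the rank-tie handling. DBD-13
carries an additional stable per-subject trait so its cross-sectional
spread (σ ≈ 10) exceeds its treatment-related change (≈ −1), as in
realistic behavioral data. Treatment reduces severity by a draw (mean 0.35,
SD 0.30 severity-SDs) whose correlation with baseline severity is −0.5:
milder baseline alteration responds better. Default cohort conditions are
19 subjects, 68 ROIs, 1 kHz sampling, 5-s epochs; the epoch count per
session (12) is a free choice, as recording protocols do not fix it.

The signal path synthesizes each ROI trace as six band-limited sinusoids
(frequency drawn within the band) on unit-variance 1/f^χ noise; severity
raises δ/θ amplitudes, lowers β amplitudes and steepens χ (slower, more
regular activity). ROI-to-ROI amplitude dispersion is a log-normal factor
scaled by `spatial_heterogeneity ∈ [0, 1]`; at 0 all ROIs share identical
amplitudes. Per-entity seeds are derived by hashing
`(seed, subject_id, session)`, so any subject's signals are reproducible
independently of generation order.

The fast table path draws the 26 subject-level variables directly from the
same severity couplings (fixed baselines and noise SDs per variable),
skipping signal synthesis. Two deliberate simplifications: the six relative
power columns are drawn independently rather than renormalized to unit sum
— this keeps zero-coupling tables exactly column-independent, which the
null-calibration simulations require — and no residual correlation beyond
the latent severity is modelled. The generator therefore emulates the
*statistical structure* the network analysis assumes (monotone
severity couplings, covariates, score discreteness), not the physics of MEG:
no sensor noise, volume conduction, artifacts, nonstationarity, or
between-parameter dependence beyond one latent factor. Passing tests
demonstrate that the pipeline recovers structure that is present and stays
calibrated when it is absent; they do not certify performance on real
recordings.

Planted-structure helpers create ground truth for power studies: a Gaussian
copula with Pearson `r = 2 sin(πρ/6)` realizes a target Spearman ρ between
one chosen pair of columns (score rounding attenuates it by ≲ 0.02), either
as a pre-treatment predictor of the MMSE change or as a single association
that changes between sessions.

## Simulation sizes

The statistical acceptance checks run at these sizes, chosen to make the
quantities they estimate stable: null calibration with 200 independent
tables of n = 500 (the per-edge binomial 95% interval over 200 draws is the
tolerance); planted-edge recovery with ρ = 0.6 at n = 100 over 100
simulations; variability-network detection of a 0.0 → 0.8 change at n = 50
with 500 bootstrap iterations over 50 seeds. The n = 50 table size for the
detection study avoids the small-cohort saturation regime described above,
where top-5% membership is dominated by sampling noise rather than the
planted change; the saturation behaviour itself is exercised by the
cloned-ensemble degenerate test.

## Known limitations

* The pipeline starts from ROI time courses; sensor-space preprocessing
  (artifact removal, source inversion, atlas projection) is out of scope.
* ROI-resolved analyses are deliberately absent: the spatial dimension
  enters only through the SSE.
* The t-approximation p-value for the partial Spearman is approximate at
  n ≈ 19; the permutation option is the conservative alternative for very
  small cohorts.
* GEXF export carries node classes and edge weights; layout and styling are
  left to external graph tools.
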