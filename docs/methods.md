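# Methods

This note documents the models, conventions and numerical choices behind
`megabn`, and what the synthetic validation does and does not establish.

## Spectral estimation and band definitions

Regional power spectral densities use Welch's method with 2 s sliding
windows at 50% overlap (defaults; both configurable). The window taper and
detrending are not dictated by the underlying method description, so we use
the field defaults: a Hann taper with constant (mean) detrending per
window. A trailing segment shorter than one full window is dropped, the
standard Welch convention, which also makes results deterministic for any
epoch length. Frequency resolution is 1/window_s Hz (0.5 Hz at defaults).

Bands are half-open intervals [low, high): delta [1, 4), theta [4, 8),
alpha [8, 13), beta [13, 30), gamma [30, 80) with the 47.5–52.5 Hz
sub-range excluded from gamma to avoid UK powerline (50 Hz) residue.
Half-open edges guarantee no frequency bin is counted in two bands, so the
five relative powers sum to exactly 1. Band power is the sum of PSD bins
whose centre lies in the included set, times the bin width — a rule that is
exactly invertible for flat spectra (the effective bandwidth ratio
3 : 4 : 5 : 17 : 45 is a test anchor).

"Total power" for the relative normalisation is the sum of the five band
powers, not the full 1–100 Hz integral. This keeps the gamma notch out of
numerator and denominator alike and makes the five reported fractions a
true composition; residual 80–100 Hz power is deliberately excluded on both
sides.

## Normative and abnormality maps

The normative map stores the per-cell mean and **sample** standard
deviation (ddof = 1) over controls — controls are a sample of the healthy
population, and with 70 controls the distinction from the population
convention is below 1%.

Patient abnormality is |z| = |x − μ| / σ per cell, reduced per region to
the maximum across bands, recording the attaining band (ties resolve to the
lowest band index, delta first; the score is unaffected). Degenerate cells
(σ = 0) score 0 when the patient equals the control mean and raise an error
otherwise: a silent infinity would dominate every downstream rank
statistic. Regions labelled "unknown" by the resection rule stay in the
abnormality map and are excluded only when markers are computed.

Under the null (a patient drawn from the normative law itself), the
per-region max-|z| follows the maximum of five absolute standard normals,
with CDF (2Φ(t) − 1)⁵. Its 95th percentile, t ≈ 2.5695, is the significance
threshold for calling a region abnormal; the package derives it both in
closed form and by Monte-Carlo (100,000 iterations, seeded), the latter
matching to within ±0.02.

## Resection labelling and markers

Percent volume change is 100·(pre − post)/pre, relative to the
pre-operative volume. Change > 10% labels a region resected, change in
(1, 10] unknown, change ≤ 1 spared; the boundaries follow the literal
reading of "exceeded 10%" (so exactly 10% is unknown) and "between 1% and
10%" (so exactly 1% is spared). Volume increases are treated as
registration noise and clamped to 0% with a warning.

The three markers, computed over resected/spared regions only:

- **MA_R**: arithmetic mean of max-|z| over resected regions.
- **D_RS**: fraction of (resected, spared) pairs in which the spared region
  is more abnormal, ties counting ½ — the Mann–Whitney AUC with spared as
  the positive class, computed via midranks in O(n log n). Strictly
  monotone transforms of the abnormality scores leave it unchanged.
- **AC_R**: 100 × (Σ resected max-|z|) / (Σ resected + spared max-|z|).

## Cohort statistics

**Mann–Whitney AUC.** One-tailed, with the hypothesised direction stated
per marker (good outcome: higher MA_R, lower D_RS, higher AC_R). P-values
are exact for combined n ≤ 20 without ties and use the tie-corrected normal
approximation otherwise — study-sized cohorts (12 vs 20) straddle the exact
regime.

**One-sample Wilcoxon signed-rank.** Zero differences are dropped (the
standard signed-rank convention). For n ≤ 25 remaining differences the
p-value is an exact enumeration of the 2ⁿ sign patterns by subset-sum
convolution over doubled midranks, which is exact even with tied absolute
differences; above that, a tie-corrected, continuity-corrected normal
approximation (which matches the exact enumeration to < 0.01 just past the
cutoff). The reported statistic is W⁺, the positive-rank sum.

**ROC-optimal thresholds.** Candidate cuts are midpoints between adjacent
sorted unique marker values plus ±∞; a subject is flagged when its value is
strictly below (MA_R, AC_R) or above (D_RS) the cut. The default criterion
is Youden's J = TPR − FPR, the operational reading of "maximise the true
positive rate while minimising the false positive rate"; distance to the
ROC corner (0, 1) is exposed as `method="corner"` since the phrasing admits
both. Ties resolve to the lowest FPR, then to the most extreme cut in the
failure direction — so degenerate inputs flag nobody. Flag inequalities are
strict; boundary equality never flags.

**Unified analysis.** Thresholds are fit in-sample (as in the study design;
no cross-validation), each patient receives up to three mechanism flags,
and the flag count itself is scored as a discriminator of bad outcome.

## Synthetic cohort model

The generator is an *emulation* of the study's data shapes, not a claim
about MEG physics. Band-power compositions follow a logistic-normal model:
cohort-level regional mean log-fractions (base fractions 0.20 / 0.15 /
0.30 / 0.25 / 0.10 for delta…gamma, regional spread SD 0.15), per-subject
Gaussian latent noise (SD 0.10 per cell), softmax to the simplex. Rows are
therefore valid compositions by construction, and per-cell z-scores are
approximately Gaussian.

Abnormality is injected in latent space as `effect × noise_sd` added to one
randomly chosen band per abnormal region, so the effect size reads as an
approximate z-score while rows remain compositional (the softmax slightly
attenuates it; at effect 6 the realised max-|z| is ≈ 5.5–6.5). Defaults
mirror the study shape: 114 regions, 70 controls, 32 patients (12 good /
20 bad outcome).

Scenario designs (resection size 10 by default):

- **clean** (good outcome): 10 focal abnormal regions at full effect,
  resection covers exactly that set.
- **mislocalized**: same focal abnormality, resection drawn disjointly.
- **partial**: widespread graded abnormality (60 regions, effects ramping
  0.15–1 × effect), resection covers only the weakest tier. The wide
  gradient is what makes the spared tissue rank above the resected tissue
  (D_RS > 0.5), matching the widespread-abnormality archetype of a partial
  resection; a focal abnormal set cannot produce D_RS > 0.5 when most
  spared cortex is normal.
- **diffuse**: widespread abnormality (effects 0.5–1 × effect), resection
  covers the most abnormal few — MA_R and D_RS look excellent while AC_R
  stays low.

Outcome is determined by scenario (good only for clean) and then flipped
with probability 0.1 (label noise), mimicking imperfect real-world
separation; ground truth records both labels. Pre/post-operative volumes
are emitted consistently with the mask (30% loss for resected, 0.2% for
spared, 5% for unknown) so they round-trip through the labelling rule.

What passing synthetic tests show: the pipeline recovers injected
mechanisms, the statistics are calibrated under the null, and every
conservation law holds. What they do not show: performance on real MEG,
where spatial correlation of cortical noise, site effects, age structure
and source-reconstruction artifacts are all absent from this generator.

## Problem sizes and numerical choices

- Mechanism-recovery checks use 34 replicate cohorts at the default
  configuration (≥ 200 patient replicates per scenario); dose-response
  pools 8 cohorts per effect level at 0/2/4/6 σ. These sizes give
  Monte-Carlo standard errors comfortably below the asserted margins.
- The threshold simulation uses 100,000 iterations; the empirical 95th
  percentile has a standard error of ≈ 0.005 z-units.
- Tables are matched by region label, never row order; mismatches are
  errors, not silent reordering. Files are plain delimited text written at
  full float precision (shortest round-tripping representation) and parsed
  with round-trip float precision, so write → read is bit-exact.
- Constant cells across controls are snapped to exactly σ = 0 and μ = the
  common value, making the degenerate-cell contract float-exact.

## Known limitations

- Sensor-space processing (filtering, ICA, source reconstruction) is out of
  scope; inputs are parcellated region time series or precomputed
  band-power tables.
- Normative maps are not age- or site-harmonised.
- Thresholds are derived in-sample; generalisation requires external
  validation.
- The exact complement identity D_RS(swap) = 1 − D_RS holds at the
  pair-count level; as floating-point numbers the two sides can differ by
  one ulp.
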