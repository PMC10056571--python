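# Methods

## The triangle model of the r'-wave

The r'-wave — the terminal positive deflection of the QRS in right
precordial leads — is treated as a triangle in the paper-mm coordinate
frame (25 mm/s, 10 mm/mV by default, i.e. 1 mm = 40 ms = 0.1 mV). This
frame, not the raw time/voltage plane, is where the published angle
cut-offs are defined: an "angle" on an ECG is only meaningful at a fixed
aspect ratio, because rescaling either axis changes it. Both the
calibration and every derived angle therefore carry the frame explicitly,
and non-standard calibrations can be supplied per record.

With θ_up the upslope angle from vertical, α the downslope angle from
vertical, and h the apex height above the isoelectric line (mm), the five
criteria are exact functions of three quantities:

    β        = θ_up + α
    DBT-5mm  = ms_per_mm · 5 · (tan θ_up + tan α)
    DBT-iso  = ms_per_mm · h · (tan θ_up + tan α)
    ratio    = tan θ_up + tan α

`RPrimeGeometry` computes the derived quantities from the fitted tangents
at construction, so these identities hold to machine precision on every
emitted object — they are invariants, not approximations.

## Extraction pipeline

1. **Beat detection.** A smoothed-derivative energy detector (squared first
   difference, 30 ms moving average, peaks above 25 % of the maximum with a
   200 ms refractory period) marks QRS complexes; the R peak is refined to
   the raw-signal maximum within ±40 ms. The QRS analysis window defaults
   to R−80 ms … R+120 ms; strips whose r' extends later (wide triangles at
   low heart rates) should widen `post_ms`. This detector is deliberately
   simple — the package's subject is the r' geometry, not QRS detection on
   pathological clinical signals.
2. **Baseline.** Median of the 40 ms window ending 40 ms before QRS onset
   (PR segment). The median resists residual P-wave or noise excursions.
3. **r' location.** The last local maximum between the R peak and the end
   of the QRS window rising >0.05 mV above baseline. Extrema are detected
   on a 5-sample moving average and refined on the raw samples (±2), so
   noise wiggles on a limb cannot masquerade as the apex; a peak must also
   have ≥0.05 mV prominence. J-point elevation without a discrete peak
   yields no r'. The 0.05 mV candidate gate is intentionally looser than
   the 0.1 mV measurability rule so that sub-threshold r' waves are still
   counted as "present but unmeasurable".
4. **Measurability.** Apex >0.1 mV above baseline *and* descending limb
   >0.1 mV, both strict inequalities (0.1 mV exactly fails).
5. **Limb fitting.** Each limb is fitted by least squares of x on y
   (regressing time on voltage keeps near-vertical limbs finite) over the
   samples whose height lies in the 20–80 % vertical band between the
   adjacent trough and the apex. The band excludes apex rounding and foot
   curvature; its bounds are configurable. A fit needs ≥3 in-band samples;
   a limb whose whole descent spans ≤2 samples is treated as vertical (0°
   from vertical) with a warning, and any other failed fit voids the
   beat's geometry. When the downslope shows no discrete trough, the limb
   is taken to end where the signal returns to within max(10 % of the apex
   height, 0.02 mV) of baseline, preventing flat-segment noise from
   entering the fit.
6. **Triangle.** The apex is the *intersection of the fitted lines* (it can
   sit above the sampled maximum, as a caliper construction would), and h
   is measured from that intersection to the baseline. An apex at or below
   the isoelectric line is unmeasurable. A flag-selectable alternative
   (signal apex) is not provided because the intersection apex is the only
   construction consistent with the derived-quantity identities above.
7. **Aggregation.** Per (lead, intercostal level) placement: arithmetic
   mean of each criterion over measurable, successfully fitted beats. Per
   patient: the maximum of the placement means, independently per
   criterion ("major value"). Each physical lead at each intercostal level
   counts as a distinct placement. An intercostal level is measurable if
   any beat of V1 or V2 there is measurable.

## Scoring

One unweighted point per criterion at β ≥ 40°, α ≥ 24°, DBT-5mm ≥ 120 ms,
DBT-iso ≥ 80 ms (inclusive comparisons, matching the published "≥"
cut-offs); prediction positive at score ≥ 2. The base/height ratio is
deliberately not part of the score — its discrimination is reported to be
substantially weaker. Patients without a measurable r' score 0 and are
predicted negative: a missing terminal deflection is itself evidence
against the pattern. Both evaluation denominators are supported, because
published reports rarely state theirs: `measurable_only` (default for
single-criterion ROC) excludes such patients; `all_patients` keeps them,
ranking their criterion markers below every measured value.

## Diagnostic statistics

- **AUC** is the Mann–Whitney statistic with half credit for ties; its SE
  and the paired AUC comparison use DeLong placement values computed via
  midranks (the O(N log N) formulation). The 95 % CI is Wald, clipped to
  [0, 1]. The paired test uses a two-sided normal reference.
- **Youden's J** is maximised over thresholds at midpoints of adjacent
  unique marker values plus ±∞; ties in J (within 1e-12, absorbing
  floating-point noise between algebraically equal expressions) break
  toward the lowest threshold, i.e. toward sensitivity.
- **McNemar** uses the exact two-sided binomial test when the discordant
  count b+c < 25, otherwise the continuity-corrected χ²; b = c = 0 gives
  p = 1.
- **ICC** is ICC(A,1) — two-way model, absolute agreement, single
  measurement — from the ANOVA mean squares, with the Satterthwaite
  F-based CI. Zero between-subject variance is flagged as undefined
  rather than reported as 0.
- No multiplicity correction is applied; reports carry raw p-values.

## Synthetic data

**Waveform generator.** Each beat is a stylised qRS complex (1 mV R wave,
2 mm S trough 40 ms after R) followed by an exactly triangular r' with the
requested limb angles and apex height, then a flat segment; optional
Gaussian noise (σ default 0 for geometry tests; the CLI demo uses
0.01 mV, a typical clean-trace noise floor). Ground truth is closed-form.
The generator omits P/T waves, baseline wander and muscle artifact:
green extraction tests establish geometric correctness of the fitting
pipeline, not robustness on clinical recordings.

**Cohort generator.** Each patient draws three latent quantities from
truncated normals — θ_up ∈ (1°, 45°), α ∈ (1°, 70°), h ∈ (0.5, 8) mm,
ranges chosen for physical plausibility — and the five criteria are
derived through the exact identities, which induces the strong
inter-criterion correlation a composite score exploits. The two presets
calibrate the latent distributions to the published class-conditional
summaries (mean ± SD) of the test and validation cohorts: α is matched
directly; θ_up gets mean β−α and variance β−α by moment differencing
(floored at (0.25·SD_β)² when the reported β SD is smaller than the α SD);
h is scaled so the derived DBT-iso matches its reported mean ± SD at the
latent mean angles. Published summaries are conditional on a measurable
r', so calibration targets that conditional population; measurability per
intercostal level is drawn independently per class at the reported
frequencies, and patients with no measurable level carry no feature
values.

What this stated world does *not* reproduce: the published distributions
are strongly right-skewed (one cohort reports DBT-5mm 149 ± 144 ms in the
negative class), while the calibrated world is (truncated) normal.
Consequently single-criterion exceedance rates at the published cut-offs —
and hence the composite score's specificity among measurable patients —
differ from the clinical report, and the 0–4 score, being a coarsening of
smooth functions of three shared latents, cannot out-rank its best
continuous component criterion in AUC, as it did on the clinical data
where independent per-criterion measurement error favours a consensus
score. The replicate-average sensitivity/specificity of the score ≥ 2 rule
under the all-patients denominator does land close to the published
operating point, because unmeasurable-patient frequencies are calibrated
per class.

**Binormal AUC simulation.** Draws class samples from stated normals and
averages the empirical AUC over replicates; the mean converges to
Φ(Δμ/√(σ₊²+σ₋²)), which serves as the independent closed-form check.

## Numerical and interface choices

- Sampling floor 250 Hz (slope estimation needs ~5 samples per limb);
  default generator rate 500 Hz. Parameter-recovery tests of the smallest
  admissible r' (α = 10°, h = 1 mm: a ~7 ms downslope) run at 1000 Hz,
  where the ≥3-samples-per-limb rule is satisfiable.
- CSV time columns auto-detect seconds vs milliseconds by median step
  (<0.1 → seconds); non-uniform steps are rejected.
- Voltages are always mV internally; missing feature values are NaN in
  memory and empty fields on disk, never zeros.
- All simulation randomness flows through a single integer seed per call
  (`numpy.random.default_rng`); identical seeds give identical outputs.
- Exit codes of the `rwave` tool: 0 success, 2 partial (some inputs
  skipped), 1 fatal.

## Known limitations

- The beat detector and the fixed QRS window are not suitable for
  arrhythmic or heavily artifacted recordings; the package expects short,
  clean resting strips.
- QRS onset/offset are window conventions, not delineations; DBT values
  depend only on the fitted limbs, so this mainly affects which samples
  are searched.
- The WFDB path requires the optional `wfdb` dependency and is not
  exercised by the test suite; CSV is the reference format.
- Cohort calibration matches first and second moments only; skewness and
  outliers of real criterion distributions are not modelled.
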