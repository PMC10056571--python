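# rprime

Quantitative r'-wave morphometry for suspected Brugada syndrome.

Brugada syndrome is diagnosed from a type 1 ECG pattern, spontaneous or
unmasked by a sodium-channel-blocker provocation test (SCBPT, e.g.
intravenous flecainide). Because the provocation test requires admission and
carries arrhythmic risk, several geometric measurements of the r'-wave — the
terminal positive QRS deflection in leads V1/V2 — have been proposed to
estimate the pre-test probability of a positive result from the baseline
ECG. `rprime` implements that analysis end to end for people who study or
automate it: cardiology researchers evaluating ECG predictors, and engineers
building screening software around them.

## The measurements and the score

All geometry is defined on the *paper-mm* frame of a standard printed ECG
(25 mm/s, 10 mm/mV: 1 mm = 40 ms horizontally, 0.1 mV vertically). The
r'-wave is modelled as a triangle whose limbs are straight lines fitted to
its upslope and downslope; with θ_up and α the limb angles from vertical
and h the apex height (mm) above the isoelectric line:

- **β-angle** = θ_up + α — the apex angle between the limbs,
- **α-angle** — the angle between a vertical line and the downslope,
- **DBT-5mm** = 40·5·(tan θ_up + tan α) ms — triangle-base duration 5 mm
  below the apex,
- **DBT-iso** = 40·h·(tan θ_up + tan α) ms — base duration at the
  isoelectric line,
- **base/height ratio** = tan θ_up + tan α.

An r'-wave is *measurable* when its apex rises >0.1 mV above baseline and
its descending limb drops >0.1 mV. Per lead placement (V1/V2 at the second,
third or fourth intercostal space) beat measurements are averaged; per
patient, the **major value** (maximum across placements) of each criterion
is kept.

The **r'-wave score** awards one point per criterion at its published
cut-off — β ≥ 40°, α ≥ 24°, DBT-5mm ≥ 120 ms, DBT-iso ≥ 80 ms — and
predicts a positive provocation test at score ≥ 2. The `diagstats` module
supplies the companion statistics: empirical ROC/AUC with DeLong variance
and paired DeLong comparison, Youden-index cut-off selection,
sensitivity/specificity, McNemar's test against the provocation-test gold
standard, and ICC(A,1) for observer agreement.

## Worked example

Extract the geometry from a synthetic strip with known ground truth
(θ_up = 16°, α = 24°, h = 3 mm) and score it:

```python
from rprime.synth import WaveformParams, gen_waveform
from rprime.geometry import extract_channel
from rprime.scoring import score_patient

rec, truth = gen_waveform(WaveformParams(theta_up_deg=16, alpha_deg=24, h_mm=3))
g = extract_channel(rec, 0, post_ms=300)[0]
print(f"beta={g.beta_deg:.1f} deg  alpha={g.alpha_deg:.1f} deg  "
      f"DBT-5mm={g.dbt5_ms:.1f} ms  DBT-iso={g.dbtiso_ms:.1f} ms  ratio={g.ratio:.2f}")
```

prints

```
beta=40.0 deg  alpha=24.0 deg  DBT-5mm=146.4 ms  DBT-iso=87.8 ms  ratio=0.73
```

— the extracted triangle matches the generator's closed-form geometry
(β = 16 + 24 = 40°, DBT-5mm = 200·(tan 16° + tan 24°) = 146.4 ms). Scoring
these majors flags β (40 ≥ 40) and DBT-iso (87.8 ≥ 80): score 2, prediction
positive.

The same pipeline runs from the shell on a simulated validation-style
cohort (47 positive / 150 negative patients, class-conditional feature
distributions calibrated to published summaries):

```sh
rwave simulate cohort --preset table5 --seed 7 --out sim/
rwave score    --features sim/features.csv --out scores.csv
rwave evaluate --scores sim/features.csv --out report.json
```

`report.json` then contains, e.g. (seed 7, measurable patients only):

```
beta_deg   AUC 0.870 (95% CI 0.799-0.941)  Youden cut 41.9
alpha_deg  AUC 0.827 (95% CI 0.742-0.913)  Youden cut 31.3
score>=2   sens 0.932  spec 0.493          McNemar p 4.9e-07
```

AUCs near 0.8 for the angles and a Youden β cut near 40° mirror the
published behaviour of these criteria; the low specificity of the score on
*this* synthetic world is expected and discussed in `docs/methods.md`.

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch, the replication targets:
for each of four published single-criterion AUCs (β and α in the test
cohort, β and DBT-5mm in the validation cohort) it draws class-conditional
marker samples from the published mean ± SD at the published class sizes,
computes the empirical AUC with the package's ROC code, and averages 1000
replicates:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `rprime.io` — calibration, trace CSV/WFDB reading, feature tables
- `rprime.geometry` — beat detection, r' location, limb fitting, triangle
  geometry, per-patient aggregation
- `rprime.scoring` — the four-criterion composite score
- `rprime.diagstats` — ROC/DeLong/Youden/McNemar/ICC
- `rprime.synth` — waveform and cohort generators with exact ground truth
- `rprime.cli` — the `rwave` command (`extract`, `score`, `evaluate`,
  `simulate`)

WFDB input needs the optional `wfdb` package (`pip install rprime[wfdb]`);
CSV traces work out of the box. See `docs/methods.md` for the model,
numerical choices and limitations.
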