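# spleendce

Semi-quantitative spleen DCE-MRI perfusion analysis for liver-fibrosis
staging, with a fully calibrated synthetic-data generator.

## The problem

As liver fibrosis progresses, portal hypertension congests the spleen and
slows its microcirculation. Dynamic contrast-enhanced MRI (DCE-MRI) of the
spleen samples the first pass of a gadolinium bolus (here: 12 sections every
~2.7 s over 108 s, 480 images) and summarizes each region's
signal-intensity–time curve (STC) with four model-free parameters:

- **TTP** (s) — time from detectable enhancement onset to the signal maximum;
- **PEI** (a.u.) — positive enhancement integral, the baseline-subtracted
  area under the STC from onset to the end of the acquisition (a blood-volume
  surrogate);
- **MSI**, **MSD** (1/s) — maximum wash-in / wash-out slopes of the
  relative-enhancement curve `(SI − base)/(SImax − base)`, as magnitudes.

In a longitudinal CCl₄ piglet model, spleen TTP rises and PEI falls with
METAVIR stage (0–4); TTP best classifies stage ≥1/≥2 and PEI best classifies
stage ≥3/4. This package provides, for users who want to reproduce, stress
or extend that analysis without scanner data:

- `spleendce.synth` — a gamma-variate enhancement model
  `g(τ) = τ^α e^{α(1−τ)}` with a recirculation plateau, whose TTP/PEI/MSI/MSD
  are known analytically; per-stage calibration (truncated normals on TTP and
  PEI, amplitude solved by linear inversion); a digital spleen phantom with a
  hilar vessel; and the longitudinal cohort simulator (16 animals, weekends
  0/5/9/16/21, deaths, monotone stage progression, repeat-stage flags).
- `spleendce.stc` — curve preprocessing, onset detection
  (baseline mean + k·SD sustained m frames), the four parameter estimators,
  ROI extraction with margin erosion and vessel exclusion, three-section
  averaging, and voxelwise parametric maps (NIfTI in/out).
- `spleendce.stats` — Spearman stage correlation, Mann–Whitney tests
  (exact when tie-free and small, asymptotic otherwise) with Bonferroni
  correction over the four grouped-stage splits, rank-method ROC analysis
  with Youden-index cutoffs, ICC(A,1), Pearson, and Cohen's kappa with the
  Kundel bands.
- `spleendce.pipeline` / the `spleendce` CLI — reproducible
  simulate → extract → stats runs with YAML configs and a manifest.

## Worked example

```bash
spleendce run --seed 7 --out demo/
```

simulates the default 69-observation cohort through the full curve-estimation
path and writes `cohort.csv`, `report.json`, `group_stats.csv`, `roc.csv`
and `manifest.json`. From `report.json` of that run:

```
group sizes:  [16, 11, 13, 12, 10]
spearman ttp: rho = 0.584   (TTP rises with stage)
spearman pei: rho = -0.593  (PEI falls with stage)
roc ttp >=1:  AUC 0.798, cutoff 75.6 s, sens 73.9%, spec 75.0%
grouped ttp Bonferroni p: S0 vs S1-4 0.0016, S0-1 vs S2-4 0.00008,
                          S0-2 vs S3-4 0.0072, S0-3 vs S4 0.0010
```

Group sizes are the deduplicated per-stage counts (each animal counted once
per stage); a single replicate's rho and AUC scatter around their
simulation means (≈0.65 and ≈0.86 over 2000 replicates). Per-stage group
means in `group_stats.csv` track the calibration table (e.g. stage-4 TTP
87.2 ± 4.6 s against the calibrated 88.29 ± 4.9 s).

The same steps are available in the library:

```python
import numpy as np
from spleendce import (AcquisitionProtocol, calibrate_model, sample_curve,
                       SignalTimeCurve, extract_params)

rng = np.random.default_rng(0)
model = calibrate_model(stage=4, rng=rng)          # stage-calibrated kinetics
t, s = sample_curve(model, AcquisitionProtocol())  # noiseless 40-frame curve
print(extract_params(SignalTimeCurve(t, s)))       # TTP/PEI/MSI/MSD
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch each run: the group-mean TTP recovered by the full
noiseless extraction pipeline on stage-0 (n=16) and stage-4 (n=10) calibrated
cohorts; the stage-4 group-mean PEI; the mean empirical AUC of TTP for the
stage ≥1 split over 2000 calibrated normal replicates; and the mean Spearman
correlations of TTP and PEI with stage over 2000 replicates. All randomness
derives from `--seed`.

## Documentation

`docs/methods.md` describes the enhancement model, the calibration and
cohort-simulation rules, estimator conventions and tolerances, and known
limitations.
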