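# Methods

## Enhancement model

A spleen signal-time curve is modelled as a baseline plus a gamma-variate
first pass with a recirculation plateau:

```
S(t) = s_base                                        t ≤ t_onset
S(t) = s_base + A · g(τ)                             0 < τ ≤ 1
S(t) = s_base + A · ((1 − w) + w · g(τ))             τ > 1

g(τ) = τ^α · exp(α(1 − τ)),   τ = (t − t_onset) / t_peak_offset
```

`g` is normalized so the unique maximum `S = s_base + A` occurs exactly at
`t_onset + t_peak_offset`; `w` (washout_fraction) is the fraction of peak
enhancement that washes out, so the late plateau sits at `(1 − w)·A`.
The gamma-variate is the standard parametric form for bolus first passes;
it was chosen because its peak is closed-form and its enhancement area is
linear in `A`, which makes every semi-quantitative parameter analytically
recoverable (`analytic_params`, dense grid at `frame_interval/100`).

Parameter defaults: `s_base = 100` a.u., `α = 3`, `w = 0.6`,
`t_onset = 10` s. The contrast arrival time in the spleen is not part of
the published protocol; 10 s after injection start is a typical
splenic-artery arrival for a power-injected peripheral bolus and clears the
3-frame baseline window (frames at 2.7/5.4/8.1 s). Frames are timestamped
at acquisition completion, so the 40-frame grid runs 2.7…108 s and the last
frame closes the acquisition window.

## Vendor-unit scales

PEI and the slopes are reported by clinical workstations in arbitrary
units. Two config constants map the generator's native units onto the
published magnitudes and are applied symmetrically by the oracle and the
estimators:

- `pei_scale = 1e-3` (per a.u.·s): a stage-0 PEI of ≈6.8 then corresponds
  to an enhancement area of ≈6800 a.u.·s, i.e. amplitudes of ≈100–150 a.u.
  over a ≈50 s effective first pass.
- `slope_scale = 300` (dimensionless): the maximum normalized wash-in slope
  of an `α = 3`, TTP ≈ 64 s curve is ≈0.027 1/s; scaled, stage-0 MSI ≈ 8,
  matching the published magnitude.

Only TTP and PEI are *calibrated* per stage (below). MSI and MSD follow
from the fixed shape (`α`, `w`) and the drawn TTP; their stage trends are
qualitatively right (slopes flatten as TTP lengthens) but their group means
are not fitted to the published MSI/MSD cells, and no acceptance check
relies on them.

## Stage calibration

For each METAVIR stage 0–4 the calibration table stores the published group
mean ± SD of TTP (s) and PEI (a.u.) and the deduplicated group size
(16/11/13/13/10). `calibrate_model` draws

- `TTP ~ Normal(μ, σ)` truncated to `[2·frame_interval, duration − t_onset]`,
- `PEI ~ Normal(μ, σ)` truncated to positive values,

(the published tables give only means and SDs; a truncated normal is the
minimal distributional assumption) and solves the amplitude by linear
inversion `A = PEI / PEI_unit(TTP)`, exact up to the dense-grid integral.

## Cohort simulation

The longitudinal design reproduces the published follow-up: 16 animals
observed on weekends 0/5/9/16/21 with per-weekend stage counts
(16/0/0/0/0, 3/8/5/0/0, 0/3/7/5/0, 0/1/1/7/4, 0/1/1/1/6) and 1/2/4 deaths
in the last three intervals. Stages are non-decreasing per animal.

Two rules make the assignment reproducible:

- **Deaths highest-stage-first**, randomized within equal-stage ties. Purely
  random deaths cannot reproduce the published group sizes (a surviving
  week-16 cirrhotic animal would create a repeat stage-4 observation), and
  the study reports that the dead animals carried the most advanced disease
  (4 cirrhotic, 3 fibrotic of the 7 deaths).
- **Order-preserving stage matching**: survivors sorted by current stage are
  matched to the next weekend's stage multiset sorted ascending — the unique
  monotone assignment.

An observation is flagged `is_repeat_stage` when the same animal already had
the same stage at an earlier weekend; deduplicated group sizes count the
first observation per (animal, stage). Under these rules the default design
yields dedup counts **(16, 11, 13, 12, 10)**. The stage-3 count is 12, not
the published 13: for all ten final-weekend cirrhotic observations to be
first-time stage 4 (stage-4 dedup = 10), all four week-16 stage-4 animals
must die in the last interval, which leaves no never-stage-3 animal
available for the single week-21 stage-3 slot — that observation is
necessarily a repeat. The published group sizes are therefore mutually
inconsistent with strict monotone progression by one stage-3 observation;
the simulator errs on the side of monotonicity.

Body weights are drawn per weekend from the published mean ± SD and carried
along for realism only; nothing downstream uses them.

## Estimator conventions

- **Preprocessing**: centred moving average with shrinking endpoint windows.
  Default window 1 (off) for noiseless data; window 5 is recommended for
  noisy data — the gamma-variate is flat near its peak, so unsmoothed argmax
  jitter dominates the TTP error (with window 5, median |ΔTTP| at 2% noise
  is within one frame over 500 curves).
- **Onset**: first frame, at or after the end of the baseline window, whose
  intensity exceeds `baseline_mean + k·max(baseline_sd, ε)` for `m`
  consecutive frames (defaults `k = 3`, `m = 2`, 3 baseline frames).
  `ε = 1e-9` is an absolute guard so noise-free curves detect on the first
  truly enhanced frame; an absolute (not relative) guard keeps onset
  detection exactly invariant to intensity shifts and scales.
- **TTP**: global maximum of the (smoothed) curve, earliest frame on ties
  (minimizes TTP bias under plateaus), minus onset time.
- **PEI**: trapezoidal integral of `max(SI − baseline_mean, 0)` from the
  onset frame to the last frame, times `pei_scale`. Baseline-subtracted
  (not absolute) area: absolute area would be dominated by the arbitrary
  scanner offset and would break shift invariance.
- **MSI/MSD**: extreme finite-difference slopes (1-frame window by default)
  of the relative-enhancement curve `(SI − base)/(SImax − base)`, MSI over
  [onset, peak], MSD over [peak, end], clipped at zero, times `slope_scale`.
  Normalizing by peak enhancement (rather than by baseline) is what makes
  both slopes invariant to intensity shift *and* scale simultaneously. A
  peak on the final frame gives MSD = 0 with a warning.
- **ROI rule**: erode the mask by `erosion_margin_px` (margin/partial-volume
  guard), drop voxels whose peak enhancement exceeds
  `vessel_exclusion_factor` × ROI-median peak enhancement (hilar-vessel
  proxy), average the remaining voxels per frame. A spleen measurement uses
  three ROIs on the three largest consecutive sections and averages the
  *parameters* across sections, not the curves.
- Vendor preprocessing on clinical workstations is proprietary and not
  reproduced; the documented smoothing plus optional integer-shift frame
  registration (`register_frames`, correlation against frame 0) stand in
  for it.

## Discretization tolerances

On noiseless generated curves at the 2.7 s grid the estimators recover the
analytic oracle within: TTP ≤ one frame interval (onset lands on the first
frame after arrival; peak quantization ≤ half a frame), PEI ≤ 2% (in
practice ≪ 1%), slopes ≤ 5%. The slope bound presumes the slope extrema are
sampled: for late-peaking curves (stage 3–4, peak ≈ 90–100 s) the steepest
wash-out lies at or beyond the 108 s window edge and the discrete MSD
underestimates the window-limited analytic value by more than 5% — an
honest limit of a 108 s acquisition, mirrored in vivo by advanced-stage
spleens still enhancing at the end of the scan. No validation target uses
MSD.

## Statistics

- Spearman (average ranks, t approximation), Pearson, and Mann–Whitney U
  via scipy; the U test is exact (enumeration) when `n1·n2 ≤ 400` and the
  pooled sample is tie-free — which holds for every group pair at the
  published sizes — else normal approximation with tie and continuity
  corrections. All tests two-sided.
- Bonferroni families default to the four grouped-stage splits of one
  parameter (`family_size = 4`, configurable): the published analysis says
  only "corrected for multiple testing", so the family definition is a
  documented default, not an asserted reconstruction.
- ROC: empirical AUC by the rank method (ties ½), which makes
  `AUC = U/(n1·n2)` an exact identity (asserted in tests against scipy's
  independently computed U). Polarity is auto-oriented so AUC ≥ 0.5 and
  recorded; cutoffs maximize the Youden index over observed values with
  ties broken toward higher specificity; sensitivity/specificity are
  reported in percent and are exactly those attained by thresholding the
  data at the reported cutoff.
- ICC: two-way random effects, absolute agreement, single measure —
  ICC(A,1), the strictest common choice for method agreement — via
  pingouin, with F-distribution CI bounds.
- Cohen's kappa: unweighted, asymptotic 95% CI via statsmodels;
  interpretation bands partition [−1, 1] with closed upper bounds at
  0.41/0.60/0.80 (poor / moderate / good / excellent).

## What the synthetic world does and does not establish

The generator reproduces the acquisition geometry, the stage-wise TTP/PEI
distributions (as truncated normals), hilar-vessel contamination, additive
Gaussian noise, and integer-pixel inter-frame motion. It does not model
breathing-induced deformable motion, B1/coil shading, saturation
nonlinearity between contrast concentration and signal, within-animal
longitudinal correlation of perfusion parameters, or any real spleen
heterogeneity beyond the two-compartment phantom. A green estimator test
therefore establishes correctness of the curve analysis under the stated
kinetic model, not scanner-grade robustness; the statistical reproduction
targets establish that the published group-level statistics follow from
the published group summaries at the published sample sizes.
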