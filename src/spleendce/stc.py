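"""Signal-intensity–time curve (STC) analysis.

Extracts ROI curves from 4-D dynamic series and computes the four
semi-quantitative spleen perfusion parameters:

* TTP  — time to peak, from detectable enhancement onset to maximum signal.
* PEI  — positive enhancement integral, the baseline-subtracted area under
         the curve from onset to the end of the acquisition (a blood-volume
         surrogate).
* MSI  — maximum slope of increase of the relative-enhancement curve
         (steepest wash-in).
* MSD  — maximum slope of decrease after the peak (steepest wash-out),
         reported as a magnitude.

Slopes are computed on the baseline-subtracted, peak-normalized curve
(SI - base) / (SImax - base), which makes TTP/MSI/MSD invariant to both
additive intensity offsets and multiplicative rescaling, while PEI scales
linearly with intensity — the behaviour expected of these parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synth import DEFAULT_PEI_SCALE, DEFAULT_SLOPE_SCALE

__all__ = [
    "SignalTimeCurve",
    "RoiSpec",
    "PerfusionParams",
    "ExtractionConfig",
    "NoEnhancementError",
    "preprocess_curve",
    "detect_onset",
    "compute_ttp",
    "compute_pei",
    "compute_max_slopes",
    "extract_params",
    "roi_curve",
    "measure_spleen",
    "parametric_maps",
    "register_frames",
    "save_map_nifti",
]


class NoEnhancementError(ValueError):
    """Raised when no sustained enhancement above baseline is found."""


@dataclass(frozen=True)
class SignalTimeCurve:
    """A sampled signal-time series for one voxel or ROI."""

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("times and intensities must be equal-length 1-D")
        if len(t) < 4:
            raise ValueError("curve needs at least 4 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if np.max(np.abs(dt - dt.mean())) > 0.01 * dt.mean():
            raise ValueError("frame spacing must be uniform within 1%")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("curve values must be finite")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def frame_interval(self) -> float:
        return float(np.diff(self.times).mean())


@dataclass(frozen=True)
class RoiSpec:
    """One manual spleen ROI on one section.

    The mask is eroded by ``erosion_margin_px`` to stay clear of the organ
    margin (partial-volume guard), and voxels whose peak enhancement exceeds
    ``vessel_exclusion_factor`` times the ROI-median peak enhancement are
    dropped as hilar-vessel contamination.
    """

    section_index: int
    mask: np.ndarray
    erosion_margin_px: int = 1
    vessel_exclusion_factor: float = 2.0

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2 or not m.any():
            raise ValueError("mask must be a non-empty 2-D binary image")
        if self.erosion_margin_px < 0:
            raise ValueError("erosion_margin_px must be >= 0")
        if self.vessel_exclusion_factor <= 0:
            raise ValueError("vessel_exclusion_factor must be > 0")


@dataclass(frozen=True)
class PerfusionParams:
    """The four semi-quantitative parameters for one measurement."""

    ttp: float
    pei: float
    msi: float
    msd: float
    onset_time: float
    peak_time: float
    si_max: float


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable knobs of the curve-parameter estimators.

    The onset rule (baseline mean + ``k_sd`` standard deviations sustained
    for ``m_consecutive`` frames) is the conventional contrast-arrival
    criterion; ``eps`` guards the threshold on noise-free curves.
    ``pei_scale`` and ``slope_scale`` map areas and normalized slopes onto
    the arbitrary workstation units of the published values.
    """

    smooth_window: int = 1
    baseline_frames: int = 3
    k_sd: float = 3.0
    m_consecutive: int = 2
    eps: float = 1e-9
    slope_window: int = 1
    pei_scale: float = DEFAULT_PEI_SCALE
    slope_scale: float = DEFAULT_SLOPE_SCALE


def preprocess_curve(curve: SignalTimeCurve,
                     smooth_window: int = 1) -> SignalTimeCurve:
    """Centred moving-average smoothing; endpoints use a shrunken window."""
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    n = len(curve)
    if smooth_window > n:
        raise ValueError("smoothing window larger than the curve")
    if smooth_window == 1:
        return curve
    h = smooth_window // 2
    y = curve.intensities
    out = np.array([y[max(0, i - h): min(n, i + h + 1)].mean()
                    for i in range(n)])
    return SignalTimeCurve(curve.times, out)


def _baseline_stats(curve: SignalTimeCurve, baseline_frames: int
                    ) -> tuple[float, float]:
    if baseline_frames < 2:
        raise ValueError("need at least 2 baseline frames")
    if baseline_frames >= len(curve):
        raise ValueError("baseline window covers the whole curve")
    base = curve.intensities[:baseline_frames]
    return float(base.mean()), float(base.std(ddof=0))


def detect_onset(curve: SignalTimeCurve, baseline_frames: int = 3,
                 k_sd: float = 3.0, m_consecutive: int = 2,
                 eps: float = 1e-9) -> float:
    """Time of detectable contrast arrival.

    Returns the time of the first frame (at or after the end of the baseline
    window) whose intensity exceeds baseline mean + ``k_sd`` * max(baseline
    SD, ``eps``) for ``m_consecutive`` consecutive frames.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be > 0")
    if m_consecutive < 1:
        raise ValueError("m_consecutive must be >= 1")
    mean, sd = _baseline_stats(curve, baseline_frames)
    thr = mean + k_sd * max(sd, eps)
    above = curve.intensities > thr
    n = len(curve)
    for i in range(baseline_frames, n - m_consecutive + 1):
        if above[i: i + m_consecutive].all():
            return float(curve.times[i])
    raise NoEnhancementError("no enhancement detected above baseline")


def compute_ttp(curve: SignalTimeCurve, onset_time: float) -> float:
    """Time to peak: global-maximum time (earliest on ties) minus onset."""
    peak_idx = int(np.argmax(curve.intensities))  # argmax takes first tie
    peak_time = float(curve.times[peak_idx])
    if peak_time < onset_time:
        raise ValueError("peak occurs before the detected onset")
    return peak_time - onset_time


def compute_pei(curve: SignalTimeCurve, onset_time: float,
                pei_scale: float = DEFAULT_PEI_SCALE,
                baseline_frames: int = 3) -> float:
    """Positive enhancement integral from onset to end of acquisition.

    Trapezoidal integral of max(SI - baseline mean, 0) over frames at or
    after ``onset_time``, times ``pei_scale``.
    """
    mean, _ = _baseline_stats(curve, baseline_frames)
    sel = curve.times >= onset_time - 1e-12
    if sel.sum() < 2:
        return 0.0
    enh = np.clip(curve.intensities[sel] - mean, 0.0, None)
    return float(np.trapezoid(enh, curve.times[sel])) * pei_scale


def compute_max_slopes(curve: SignalTimeCurve, onset_time: float,
                       slope_scale: float = DEFAULT_SLOPE_SCALE,
                       baseline_frames: int = 3,
                       slope_window: int = 1) -> tuple[float, float]:
    """Maximum wash-in (MSI) and wash-out (MSD) slopes, as magnitudes.

    Slopes are finite differences over ``slope_window`` frames on the
    baseline-subtracted, peak-normalized curve: MSI over [onset, peak],
    MSD over [peak, end]; both clipped at zero and multiplied by
    ``slope_scale``.  A peak on the final frame yields MSD = 0 with a
    warning (no observable wash-out).
    """
    if slope_window < 1:
        raise ValueError("slope_window must be >= 1")
    mean, _ = _baseline_stats(curve, baseline_frames)
    t, y = curve.times, curve.intensities
    peak_idx = int(np.argmax(y))
    si_max = float(y[peak_idx])
    denom = si_max - mean
    if denom <= 0:
        return 0.0, 0.0
    norm = (y - mean) / denom
    onset_idx = int(np.searchsorted(t, onset_time - 1e-12))

    def max_rise(lo: int, hi: int) -> float:
        best = 0.0
        for i in range(lo, hi - slope_window + 1):
            j = i + slope_window
            best = max(best, (norm[j] - norm[i]) / (t[j] - t[i]))
        return best

    def max_fall(lo: int, hi: int) -> float:
        best = 0.0
        for i in range(lo, hi - slope_window + 1):
            j = i + slope_window
            best = max(best, (norm[i] - norm[j]) / (t[j] - t[i]))
        return best

    msi = max_rise(min(onset_idx, peak_idx), peak_idx) * slope_scale
    if peak_idx >= len(t) - 1:
        warnings.warn("peak at final frame: no wash-out, MSD set to 0",
                      stacklevel=2)
        msd = 0.0
    else:
        msd = max_fall(peak_idx, len(t) - 1) * slope_scale
    return msi, msd


def extract_params(curve: SignalTimeCurve,
                   config: ExtractionConfig | None = None
                   ) -> PerfusionParams:
    """Full per-curve pipeline: smooth, detect onset, compute all four."""
    cfg = config or ExtractionConfig()
    sm = preprocess_curve(curve, cfg.smooth_window)
    onset = detect_onset(sm, cfg.baseline_frames, cfg.k_sd,
                         cfg.m_consecutive, cfg.eps)
    ttp = compute_ttp(sm, onset)
    pei = compute_pei(sm, onset, cfg.pei_scale, cfg.baseline_frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        msi, msd = compute_max_slopes(sm, onset, cfg.slope_scale,
                                      cfg.baseline_frames, cfg.slope_window)
    peak_idx = int(np.argmax(sm.intensities))
    return PerfusionParams(
        ttp=ttp, pei=pei, msi=msi, msd=msd,
        onset_time=onset, peak_time=float(sm.times[peak_idx]),
        si_max=float(sm.intensities[peak_idx]))


# ---------------------------------------------------------------------------
# ROI and image-level operations

def _peak_enhancement(stack: np.ndarray, baseline_frames: int) -> np.ndarray:
    """Per-voxel peak enhancement over baseline; stack is (..., frames)."""
    base = stack[..., :baseline_frames].mean(axis=-1)
    return stack.max(axis=-1) - base


def roi_curve(series: np.ndarray, roi: RoiSpec,
              frame_interval: float,
              baseline_frames: int = 3) -> SignalTimeCurve:
    """Mean ROI curve after margin erosion and vessel exclusion.

    The ROI mask is eroded by ``roi.erosion_margin_px``; voxels whose peak
    enhancement exceeds ``roi.vessel_exclusion_factor`` times the ROI-median
    peak enhancement are excluded as vessel contamination; the remaining
    voxels are averaged per frame.
    """
    if series.ndim != 4:
        raise ValueError("series must be 4-D (x, y, section, frame)")
    z = roi.section_index
    if not 0 <= z < series.shape[2]:
        raise ValueError("section_index outside the series")
    mask = roi.mask
    if mask.shape != series.shape[:2]:
        raise ValueError("ROI mask shape does not match the series")
    if roi.erosion_margin_px > 0:
        mask = ndimage.binary_erosion(mask,
                                      iterations=roi.erosion_margin_px)
    if not mask.any():
        raise ValueError("ROI empty after margin erosion")
    stack = series[:, :, z, :][mask]  # (n_voxels, n_frames)
    peak_enh = _peak_enhancement(stack, baseline_frames)
    med = float(np.median(peak_enh))
    if med > 0:
        keep = peak_enh <= roi.vessel_exclusion_factor * med
    else:
        keep = np.ones(len(stack), dtype=bool)
    if not keep.any():
        raise ValueError("ROI empty after vessel exclusion")
    mean_curve = stack[keep].mean(axis=0)
    times = (np.arange(series.shape[3]) + 1) * frame_interval
    return SignalTimeCurve(times, mean_curve)


def measure_spleen(series: np.ndarray, rois: list[RoiSpec],
                   frame_interval: float,
                   config: ExtractionConfig | None = None
                   ) -> PerfusionParams:
    """Spleen measurement: three ROIs on consecutive largest sections.

    Parameters are computed per section from its ROI curve and then averaged
    arithmetically across the three measurements (parameters averaged, not
    curves pooled).
    """
    cfg = config or ExtractionConfig()
    if len(rois) != 3:
        raise ValueError("exactly three ROIs are required")
    idx = sorted(r.section_index for r in rois)
    if idx != list(range(idx[0], idx[0] + 3)):
        raise ValueError("ROI sections must be consecutive")
    per_section: list[PerfusionParams] = []
    for r in rois:
        curve = roi_curve(series, r, frame_interval, cfg.baseline_frames)
        try:
            per_section.append(extract_params(curve, cfg))
        except NoEnhancementError as e:
            raise NoEnhancementError(
                f"section {r.section_index}: {e}") from e
    fields = ("ttp", "pei", "msi", "msd", "onset_time", "peak_time",
              "si_max")
    means = {f: float(np.mean([getattr(p, f) for p in per_section]))
             for f in fields}
    return PerfusionParams(**means)


def parametric_maps(series: np.ndarray, mask: np.ndarray,
                    frame_interval: float,
                    config: ExtractionConfig | None = None
                    ) -> dict[str, np.ndarray]:
    """Voxelwise TTP/PEI/MSI/MSD maps over a 3-D mask.

    Voxels where onset detection fails (non-enhancing tissue) are set to
    NaN, the missing-value sentinel.
    """
    cfg = config or ExtractionConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.shape[:3]:
        raise ValueError("mask shape must match the series volume")
    if not mask.any():
        raise ValueError("mask is empty")
    times = (np.arange(series.shape[3]) + 1) * frame_interval
    maps = {k: np.full(series.shape[:3], np.nan)
            for k in ("ttp", "pei", "msi", "msd")}
    for ix, iy, iz in zip(*np.nonzero(mask)):
        curve = SignalTimeCurve(times, series[ix, iy, iz, :])
        try:
            p = extract_params(curve, cfg)
        except (NoEnhancementError, ValueError):
            continue
        maps["ttp"][ix, iy, iz] = p.ttp
        maps["pei"][ix, iy, iz] = p.pei
        maps["msi"][ix, iy, iz] = p.msi
        maps["msd"][ix, iy, iz] = p.msd
    return maps


def save_map_nifti(volume: np.ndarray, name: str, path) -> None:
    """Write one parameter map as NIfTI-1; NaN marks non-enhancing voxels."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), np.eye(4))
    img.header["descrip"] = f"{name} map; NaN = no enhancement".encode()[:79]
    nib.save(img, str(path))


def register_frames(series: np.ndarray, max_shift: int = 3) -> np.ndarray:
    """Integer-shift frame registration against the first frame.

    For each frame, the in-plane integer translation within ``max_shift``
    pixels that maximizes correlation with frame 0 (summed over sections)
    is undone with a circular shift.  Deformable correction is out of scope.
    """
    if series.ndim != 4:
        raise ValueError("series must be 4-D (x, y, section, frame)")
    ref = series[..., 0]
    out = series.copy()
    shifts = range(-max_shift, max_shift + 1)
    for k in range(1, series.shape[3]):
        frame = series[..., k]
        best, best_score = (0, 0), -np.inf
        for dx in shifts:
            for dy in shifts:
                shifted = np.roll(frame, (dx, dy), axis=(0, 1))
                score = float((shifted * ref).sum())
                if score > best_score:
                    best_score, best = score, (dx, dy)
        out[..., k] = np.roll(frame, best, axis=(0, 1))
    return out
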