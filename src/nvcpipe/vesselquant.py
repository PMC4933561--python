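"""Vessel-diameter extraction and biphasic response metrics.

The measurement chain for one arteriole location:

1. ``extract_diameter`` — per scan line, the lumen diameter is the full
   width at half maximum (FWHM) of the background-subtracted intensity
   profile, with sub-pixel linear interpolation at the half-maximum
   crossings.
2. ``percent_change`` — conversion to percent diameter change about the
   pre-stimulus baseline mean.
3. ``smooth`` — temporal Gaussian smoothing (FWHM 0.5 s).
4. Metric estimators on the smoothed percent-change trace:

   * peak dilation and its time (first maximum within the search window);
   * dilation onset: a straight line is fit to the rising limb between
     20% and 80% of the peak and extrapolated to its intercept with the
     pre-stimulus baseline (zero in percent units);
   * peak constriction: the (sign-flipped) minimum within 3-13 s after
     stimulus onset; a location "constricts" when this exceeds 1%;
   * constriction onset: the first downward zero crossing after the
     dilation peak, linearly interpolated between samples.

Undefined quantities (flat traces, profiles that never cross half
maximum, too few rising-limb samples) are flagged as NaN rather than
raised, so cohort-level code can drop them row-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import LineScanImage, Timecourse

log = logging.getLogger(__name__)

#: FWHM of a Gaussian = sigma * 2 sqrt(2 ln 2)
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class MetricsConfig:
    """Tunable analysis parameters with their defaults.

    ``baseline_window = None`` uses the entire pre-stimulus segment.
    ``peak_window`` bounds the dilation-peak search (s post-stimulus);
    ``constriction_window`` and ``constriction_threshold_pct`` define
    the constriction classifier.
    """

    baseline_window: tuple[float, float] | None = None
    smooth_fwhm_s: float = 0.5
    peak_window: tuple[float, float] = (0.0, 6.0)
    constriction_window: tuple[float, float] = (3.0, 13.0)
    constriction_threshold_pct: float = 1.0
    smooth_before_onset: bool = True


@dataclass
class ResponseMetrics:
    """Per-location summary of a biphasic response (NaN = undefined)."""

    onset_s: float
    time_to_peak_s: float
    peak_dilation_pct: float
    peak_constriction_pct: float
    constriction_onset_s: float
    has_constriction: bool


# ---------------------------------------------------------------------------
# diameter extraction
# ---------------------------------------------------------------------------

def _profile_fwhm(profile: np.ndarray, pixel_size: float,
                  smooth_px: float = 1.0) -> float:
    """FWHM of one background-subtracted line profile, in um (NaN if undefined).

    Background is the 5th percentile of the line; the profile is lightly
    smoothed (sigma = 1 px) before the peak search so single-pixel noise
    cannot split the lumen. Crossings are linearly interpolated, taking
    the crossing nearest the peak on each side.
    """
    p = profile - np.percentile(profile, 5.0)
    if smooth_px > 0:
        p = gaussian_filter1d(p, smooth_px, mode="nearest")
    i_pk = int(np.argmax(p))
    half = p[i_pk] / 2.0
    if p[i_pk] <= 0:
        return float("nan")
    below_left = np.nonzero(p[:i_pk + 1] < half)[0]
    below_right = np.nonzero(p[i_pk:] < half)[0]
    if below_left.size == 0 or below_right.size == 0:
        return float("nan")
    il = below_left[-1]                       # last sub-half sample left of peak
    ir = i_pk + below_right[0]                # first sub-half sample right of peak
    # linear interpolation of the two half-maximum crossings
    xl = il + (half - p[il]) / (p[il + 1] - p[il])
    xr = ir - 1 + (half - p[ir - 1]) / (p[ir] - p[ir - 1])
    return float((xr - xl) * pixel_size)


def extract_diameter(img: LineScanImage, method: str = "fwhm") -> Timecourse:
    """Per-line lumen diameter (um) from a vessel line-scan image.

    Lines whose profile never crosses half maximum (e.g. no vessel in
    the scan) are flagged NaN, not raised.
    """
    if method != "fwhm":
        raise ValueError(f"unknown diameter method {method!r}")
    diam = np.array([_profile_fwhm(line, img.pixel_size_um) for line in img.data])
    n_missing = int(np.isnan(diam).sum())
    if n_missing:
        log.info("extract_diameter: %d/%d lines flagged missing", n_missing, img.n_lines)
    return Timecourse(time=img.line_times(), value=diam, units="um")


# ---------------------------------------------------------------------------
# percent change and smoothing
# ---------------------------------------------------------------------------

def percent_change(tc: Timecourse, baseline_window: tuple[float, float] | None = None
                   ) -> Timecourse:
    """Convert to percent change about the pre-stimulus baseline mean.

    ``baseline_window`` must lie entirely before the stimulus; by default
    the whole pre-stimulus segment is used (>= 1 s required).
    """
    if baseline_window is None:
        mask = tc.pre_stimulus_mask()
        if tc.time[mask].size and tc.time[mask][-1] - tc.time[mask][0] < 1.0 - tc.dt:
            raise ValueError("need >= 1 s of pre-stimulus baseline")
    else:
        lo, hi = baseline_window
        if hi > 0:
            raise ValueError("baseline_window must be entirely pre-stimulus")
        mask = (tc.time >= lo) & (tc.time < hi)
    if mask.sum() < 10:
        raise ValueError("need >= 10 baseline samples")
    d0 = float(np.nanmean(tc.value[mask]))
    if not np.isfinite(d0) or d0 <= 0:
        raise ValueError("non-positive baseline diameter; cannot convert to percent change")
    return tc.with_value(100.0 * (tc.value - d0) / d0, units="pct")


def smooth(tc: Timecourse, kernel_fwhm: float = 0.5) -> Timecourse:
    """Temporal Gaussian smoothing (kernel specified by its FWHM in s).

    Implemented as convolution with a normalized Gaussian, reflection
    padding at the edges; a constant trace maps to itself.
    """
    dt = tc.dt
    if dt >= kernel_fwhm:
        raise ValueError("sampling interval must be smaller than the kernel FWHM")
    sigma_samples = kernel_fwhm / FWHM_TO_SIGMA / dt
    return tc.with_value(gaussian_filter1d(tc.value, sigma_samples, mode="reflect"))


# ---------------------------------------------------------------------------
# metric estimators (operate on smoothed percent-change traces)
# ---------------------------------------------------------------------------

def peak_constriction(tc_smoothed: Timecourse,
                      window: tuple[float, float] = (3.0, 13.0),
                      threshold: float = 1.0) -> tuple[float, bool]:
    """Peak constriction (positive magnitude, %) and the >threshold flag.

    The peak constriction is the minimum of the smoothed trace within
    ``window`` seconds after stimulus onset, sign-flipped and floored at
    zero; a trace "has constriction" when it exceeds ``threshold``.
    """
    lo, hi = window
    mask = (tc_smoothed.time >= lo) & (tc_smoothed.time <= hi)
    if not mask.any():
        raise ValueError("constriction window lies outside the trace")
    peak = max(0.0, -float(np.min(tc_smoothed.value[mask])))
    return peak, peak > threshold


def dilation_onset(tc_smoothed: Timecourse,
                   peak_window: tuple[float, float] = (0.0, 6.0)
                   ) -> tuple[float, float, float]:
    """(onset_s, time_to_peak_s, peak_dilation_pct); NaN onset when undefined.

    The peak is the first maximum of the trace within ``peak_window``.
    Rising-limb samples between 20% and 80% of the peak immediately
    preceding it (a contiguous run; any samples above 80% between the
    run and the peak are skipped) are fit by ordinary least squares, and
    the onset is the time where the fitted line crosses the zero
    baseline.  Fewer than two usable samples, a non-positive peak or a
    non-positive fitted slope leave the onset undefined.
    """
    lo, hi = peak_window
    t, v = tc_smoothed.time, tc_smoothed.value
    win = np.nonzero((t > lo) & (t <= hi))[0]
    if win.size == 0:
        raise ValueError("peak window lies outside the trace")
    rel = int(np.argmax(v[win]))             # ties -> earliest time
    i_pk = int(win[rel])
    peak = float(v[i_pk])
    if peak <= 0:
        return float("nan"), float("nan"), peak
    t_pk = float(t[i_pk])
    # walk back over the >80% shoulder, then collect the 20-80% rising limb
    i = i_pk
    while i > 0 and v[i - 1] > 0.8 * peak:
        i -= 1
    limb_end = i                             # exclusive
    while i > 0 and 0.2 * peak <= v[i - 1] <= 0.8 * peak:
        i -= 1
    limb = np.arange(i, limb_end)
    if limb.size < 2:
        return float("nan"), t_pk, peak
    slope, intercept = np.polyfit(t[limb], v[limb], 1)
    if slope <= 0:
        return float("nan"), t_pk, peak
    onset = float(-intercept / slope)
    return onset, t_pk, peak


def constriction_onset(tc_smoothed: Timecourse, time_to_peak_s: float,
                       window_end: float = 13.0) -> float:
    """First downward zero crossing after the dilation peak (NaN if none).

    Dips below baseline before the dilation peak are ignored; the
    crossing time is linearly interpolated between samples.  Crossings
    later than ``window_end`` (the end of the constriction search
    window) are treated as undefined.
    """
    t, v = tc_smoothed.time, tc_smoothed.value
    after = np.nonzero(t > time_to_peak_s)[0]
    for i in after[:-1] if after.size else []:
        if v[i] >= 0.0 > v[i + 1]:
            tc = t[i] + (t[i + 1] - t[i]) * v[i] / (v[i] - v[i + 1])
            return float(tc) if tc <= window_end else float("nan")
    return float("nan")


def compute_metrics(tc: Timecourse, config: MetricsConfig | None = None
                    ) -> ResponseMetrics:
    """Full per-location pipeline: percent change -> smooth -> estimators.

    ``tc`` may be a raw diameter trace (um) or already percent change.
    Undefined flags propagate: a location without constriction has NaN
    constriction onset.
    """
    cfg = config or MetricsConfig()
    if tc.units != "pct":
        tc = percent_change(tc, cfg.baseline_window)
    sm = smooth(tc, cfg.smooth_fwhm_s)
    onset_src = sm if cfg.smooth_before_onset else tc
    onset, t_pk, peak = dilation_onset(onset_src, cfg.peak_window)
    pc, has_c = peak_constriction(sm, cfg.constriction_window,
                                  cfg.constriction_threshold_pct)
    c_onset = float("nan")
    if has_c and np.isfinite(t_pk):
        c_onset = constriction_onset(sm, t_pk, cfg.constriction_window[1])
    return ResponseMetrics(
        onset_s=onset, time_to_peak_s=t_pk, peak_dilation_pct=peak,
        peak_constriction_pct=pc, constriction_onset_s=c_onset,
        has_constriction=has_c,
    )
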