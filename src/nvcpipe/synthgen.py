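"""Synthetic inputs with the statistical structure the analysis assumes.

Every downstream stage of the pipeline (diameter extraction, biphasic
response metrics, depth regression, MUA extraction, calcium ROI traces)
is exercised here against data whose ground truth is known exactly:

* single-vessel percent-diameter time-courses built from a smooth,
  causal dilation lobe optionally followed by a delayed constriction
  lobe (the biphasic shape seen after sensory or optogenetic stimuli);
* cohorts of such traces in which the dilation onset decreases linearly
  with cortical depth, emulating a response conducted upstream along the
  diving arteriole at a configurable velocity;
* line-scan images of a dye-filled vessel lumen and of neuronal somata;
* broadband extracellular voltage traces with embedded spikes;
* a synthetic bipolar-interneuron morphology (SWC) for the passive
  cable simulation.

All generators are deterministic given their seed.  The response
template is a difference of normalized rise-decay lobes; it is a
modelling convenience chosen for smoothness and analytic tractability,
not a measured kinetic model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import erf

from .core import LineScanImage, Timecourse

log = logging.getLogger(__name__)

#: Condition labels understood by the generators.  Pharmacological
#: conditions act purely as template-amplitude switches: TTX abolishes
#: both response phases; the NPY-Y1 antagonist (BIBP 3226) removes the
#: constriction phase; glutamatergic blockade (AP5+CNQX) delays it.
CONDITIONS = ("control", "TTX", "BIBP", "AP5+CNQX")


# ---------------------------------------------------------------------------
# biphasic template
# ---------------------------------------------------------------------------

@dataclass
class BiphasicParams:
    """Shape parameters of a single biphasic percent-change response.

    Amplitudes are in percent diameter change, times in seconds.  A zero
    ``constriction_amplitude`` gives a monophasic (dilation-only) trace.
    """

    onset_delay: float = 1.0
    dilation_amplitude: float = 10.0
    dilation_rise_tau: float = 0.6
    dilation_decay_tau: float = 2.0
    constriction_amplitude: float = 2.0
    constriction_delay: float = 5.0
    constriction_width_tau: float = 2.5
    secondary_dilation_amplitude: float = 0.0
    secondary_dilation_delay: float = 12.0

    def __post_init__(self) -> None:
        for name in ("dilation_rise_tau", "dilation_decay_tau", "constriction_width_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.onset_delay < 0:
            raise ValueError("onset_delay must be >= 0")
        if self.constriction_amplitude < 0:
            raise ValueError("constriction_amplitude must be >= 0")
        for name in ("dilation_amplitude", "constriction_amplitude",
                     "secondary_dilation_amplitude"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def with_condition(self, condition: str) -> "BiphasicParams":
        """Apply a pharmacological condition as an amplitude switch."""
        if condition == "control":
            return self
        if condition == "TTX":
            return replace(self, dilation_amplitude=0.0, constriction_amplitude=0.0,
                           secondary_dilation_amplitude=0.0)
        if condition == "BIBP":
            return replace(self, constriction_amplitude=0.0)
        if condition == "AP5+CNQX":
            return replace(self, constriction_delay=self.constriction_delay + 2.0)
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


def _lobe(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Causal rise-decay lobe, peak-normalized to 1.

    h(t) = (1 - exp(-t/rise)) * exp(-t/decay) for t > 0, which peaks at
    t* = rise * log(1 + decay/rise); dividing by h(t*) makes the
    configured amplitude exactly the lobe maximum.
    """
    h = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    h[pos] = (1.0 - np.exp(-tp / rise_tau)) * np.exp(-tp / decay_tau)
    t_star = rise_tau * np.log1p(decay_tau / rise_tau)
    h_max = (1.0 - np.exp(-t_star / rise_tau)) * np.exp(-t_star / decay_tau)
    return h / h_max


def lobe_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Time from lobe onset to its maximum (analytic)."""
    return rise_tau * np.log1p(decay_tau / rise_tau)


def biphasic_template(params: BiphasicParams, time: np.ndarray) -> np.ndarray:
    """Noiseless percent-change template on the given time axis."""
    t = np.asarray(time, dtype=float)
    v = params.dilation_amplitude * _lobe(t - params.onset_delay,
                                          params.dilation_rise_tau,
                                          params.dilation_decay_tau)
    if params.constriction_amplitude > 0:
        v = v - params.constriction_amplitude * _lobe(
            t - params.onset_delay - params.constriction_delay,
            params.constriction_width_tau, 2.0 * params.constriction_width_tau)
    if params.secondary_dilation_amplitude > 0:
        v = v + params.secondary_dilation_amplitude * _lobe(
            t - params.onset_delay - params.secondary_dilation_delay, 1.0, 2.0)
    return v


def gen_timecourse(params: BiphasicParams, duration: float = 35.0,
                   rate: float = 20.0, noise_sd: float = 0.0,
                   seed: int | None = None, pre_stimulus: float = 5.0,
                   **metadata) -> Timecourse:
    """Sample a biphasic percent-change trace with additive Gaussian noise.

    The trace runs from ``-pre_stimulus`` to ``duration - pre_stimulus``
    seconds around the stimulus at t = 0.  With ``noise_sd == 0`` the
    maximum of the trace equals ``dilation_amplitude`` up to sampling of
    the lobe peak (within 1% relative at rates >= 5 Hz).
    """
    if rate <= 0 or duration <= 0:
        raise ValueError("rate and duration must be positive")
    if rate < 5.0:
        raise ValueError("rate must be >= 5 Hz to resolve the response shape")
    if pre_stimulus < 2.0 or duration - pre_stimulus < 20.0:
        raise ValueError("need >= 2 s pre-stimulus baseline and >= 20 s post-stimulus")
    if seed is None:
        log.info("gen_timecourse called without a seed; defaulting to 0")
        seed = 0
    n = int(round(duration * rate))
    time = np.arange(n) / rate - pre_stimulus
    value = biphasic_template(params, time)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        value = value + rng.normal(0.0, noise_sd, size=n)
    return Timecourse(time=time, value=value, units="pct", **metadata)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Study-design parameters for a synthetic single-vessel cohort.

    The dilation onset at depth z is ``surface_onset - z/conduction_velocity``
    plus Gaussian jitter, truncated at zero: the response is conducted
    upstream along the diving arteriole, so deeper locations respond
    earlier.  Depths are drawn uniformly in ``depth_range``.
    """

    n_subjects: int = 10
    locations_per_subject: int = 10
    depth_range: tuple[float, float] = (50.0, 560.0)
    surface_onset: float = 1.2
    conduction_velocity: float = 900.0       # um/s
    onset_jitter_sd: float = 0.05            # s
    noise_sd: float = 1.0                    # percent
    constriction_fraction: float = 0.5
    dilation_amplitude_mean: float = 10.0
    dilation_amplitude_sd: float = 2.0
    condition: str = "control"
    rate: float = 20.0
    duration: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.depth_range
        if not (0.0 <= lo < hi <= 1000.0):
            raise ValueError("depth_range must be an increasing interval within [0, 1000] um")
        if self.conduction_velocity <= 0:
            raise ValueError("conduction_velocity must be > 0")
        if not 0.0 <= self.constriction_fraction <= 1.0:
            raise ValueError("constriction_fraction must be within [0, 1]")
        if self.n_subjects < 1 or self.locations_per_subject < 1:
            raise ValueError("need at least one subject and one location")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


def gen_cohort(spec: CohortSpec, with_truth: bool = False):
    """Generate one trace per measurement location across subjects.

    Each trace carries subject id, vessel id, depth and condition.  The
    ground-truth onset law is linear in depth with slope
    ``-1/conduction_velocity`` (before jitter and truncation at zero).
    With ``with_truth=True`` also returns a DataFrame of the generated
    ground truth (depth, onset, amplitude, constriction flag) per
    location.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    traces: list[Timecourse] = []
    truth_rows = []
    lo, hi = spec.depth_range
    for s in range(spec.n_subjects):
        subject = f"S{s + 1:02d}"
        for k in range(spec.locations_per_subject):
            depth = rng.uniform(lo, hi)
            jitter = rng.normal(0.0, spec.onset_jitter_sd) if spec.onset_jitter_sd > 0 else 0.0
            onset = max(0.0, spec.surface_onset - depth / spec.conduction_velocity + jitter)
            amp = max(3.0, rng.normal(spec.dilation_amplitude_mean,
                                      spec.dilation_amplitude_sd))
            constricting = rng.random() < spec.constriction_fraction
            params = BiphasicParams(
                onset_delay=onset,
                dilation_amplitude=amp,
                constriction_amplitude=2.0 if constricting else 0.0,
            ).with_condition(spec.condition)
            traces.append(gen_timecourse(
                params, duration=spec.duration, rate=spec.rate,
                noise_sd=spec.noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                depth_um=depth, subject_id=subject,
                vessel_id=f"{subject}-V{k + 1:02d}",
                condition=spec.condition,
            ))
            truth_rows.append({
                "subject_id": subject, "vessel_id": f"{subject}-V{k + 1:02d}",
                "depth_um": depth, "onset_s": params.onset_delay,
                "dilation_amplitude_pct": params.dilation_amplitude,
                "constricting": params.constriction_amplitude > 0,
            })
    if with_truth:
        return traces, pd.DataFrame(truth_rows)
    return traces


# ---------------------------------------------------------------------------
# vessel line-scan fixture
# ---------------------------------------------------------------------------

def gen_vessel_linescan(diameter_timecourse: Timecourse, baseline_diameter: float,
                        psf_sigma: float = 0.3, noise_sd: float = 0.0,
                        seed: int | None = None, pixel_size: float = 0.5,
                        scan_width: float | None = None,
                        intensity: float = 100.0) -> LineScanImage:
    """Render a dye-filled lumen as a line-scan image.

    Per line the lumen is a top-hat of width D(t) centred on the scan
    line, convolved with a Gaussian blur of ``psf_sigma`` (um); the
    convolution is evaluated analytically via the error function, so the
    noiseless profile's full width at half maximum equals D(t) whenever
    the blur is no wider than a pixel.  ``diameter_timecourse`` may be in
    percent change (converted around ``baseline_diameter``) or in um.
    """
    if seed is None:
        log.info("gen_vessel_linescan called without a seed; defaulting to 0")
        seed = 0
    if baseline_diameter < 4.0 * pixel_size:
        raise ValueError("baseline_diameter must span at least 4 pixels")
    tc = diameter_timecourse
    if tc.units == "pct":
        diam = baseline_diameter * (1.0 + tc.value / 100.0)
    else:
        diam = tc.value
    if scan_width is None:
        scan_width = 2.0 * baseline_diameter + 20.0 * pixel_size
    if np.max(diam) >= scan_width:
        raise ValueError("diameter exceeds the scan width")
    n_pix = int(round(scan_width / pixel_size))
    x = (np.arange(n_pix) - (n_pix - 1) / 2.0) * pixel_size    # um, centred
    sigma = max(psf_sigma, 1e-3)
    half = diam[:, None] / 2.0
    arg_hi = (x[None, :] + half) / (np.sqrt(2.0) * sigma)
    arg_lo = (x[None, :] - half) / (np.sqrt(2.0) * sigma)
    data = intensity * 0.5 * (erf(arg_hi) - erf(arg_lo))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    data = np.clip(data, 0.0, None)
    stim_onset_line = int(np.searchsorted(tc.time, 0.0))
    return LineScanImage(data=data, line_period_s=tc.dt, pixel_size_um=pixel_size,
                         stim_onset_line=stim_onset_line, channel_label="FITC lumen")


# ---------------------------------------------------------------------------
# cell-body line-scan fixture
# ---------------------------------------------------------------------------

def gen_cells_linescan(n_cells: int, transient_times: Sequence[Sequence[float]],
                       rate: float = 100.0, seed: int | None = None,
                       duration: float = 10.0, pixels_per_cell: int = 30,
                       gap_pixels: int = 15, pre_stimulus: float = 2.0,
                       background: float = 100.0, soma_brightness: float = 250.0,
                       transient_dff: float = 0.5, decay_tau: float = 1.0,
                       rise_tau: float = 0.005, noise_sd: float = 0.0,
                       segments: Sequence[tuple[int, int]] | None = None,
                       ) -> tuple[LineScanImage, list[tuple[int, int]]]:
    """Line scan across ``n_cells`` somata, with per-cell calcium transients.

    Somata are brighter than the neuropil background; each transient has
    a fast rise and a slow (~1 s time constant) exponential decay, the
    kinetics of action-potential-evoked somatic calcium signals.
    Returns the image and the ground-truth ``(start, stop)`` pixel
    segment per cell (stop exclusive).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if len(transient_times) != n_cells:
        raise ValueError("transient_times must have one entry per cell")
    if seed is None:
        log.info("gen_cells_linescan called without a seed; defaulting to 0")
        seed = 0
    if segments is None:
        segments = [(gap_pixels + i * (pixels_per_cell + gap_pixels),
                     gap_pixels + i * (pixels_per_cell + gap_pixels) + pixels_per_cell)
                    for i in range(n_cells)]
    segments = [(int(a), int(b)) for a, b in segments]
    for (a0, b0), (a1, b1) in zip(segments, segments[1:]):
        if b0 > a1:
            raise ValueError("cell segments overlap")
    n_pix = segments[-1][1] + gap_pixels
    n_lines = int(round(duration * rate))
    t = np.arange(n_lines) / rate - pre_stimulus
    data = np.full((n_lines, n_pix), background)
    for (a, b), times in zip(segments, transient_times):
        dff = np.zeros(n_lines)
        for t0 in times:
            tt = t - t0
            pos = tt > 0
            dff[pos] += transient_dff * (1.0 - np.exp(-tt[pos] / rise_tau)) \
                * np.exp(-tt[pos] / decay_tau)
        data[:, a:b] = soma_brightness * (1.0 + dff)[:, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    img = LineScanImage(data=np.clip(data, 0.0, None), line_period_s=1.0 / rate,
                        pixel_size_um=0.5, stim_onset_line=int(round(pre_stimulus * rate)),
                        channel_label="OGB1")
    return img, segments


# ---------------------------------------------------------------------------
# extracellular trace fixture
# ---------------------------------------------------------------------------

def gen_ephys_trace(spike_times: Sequence[float],
                    lfp_components: Sequence[tuple[float, float]] = (),
                    fs: float = 20000.0, noise_sd: float = 0.0,
                    seed: int | None = None, duration: float = 2.0,
                    spike_amplitude: float = 100.0) -> np.ndarray:
    """Broadband voltage trace: biphasic 1-ms spikes over sinusoidal LFP.

    Spike waveform is one sine cycle (negative-first, 1 ms), a standard
    stylized extracellular action potential.  ``lfp_components`` is a
    list of (frequency_hz, amplitude) sinusoids.
    """
    if fs < 20000.0:
        raise ValueError("fs must be >= 20 kHz")
    if seed is None:
        log.info("gen_ephys_trace called without a seed; defaulting to 0")
        seed = 0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    v = np.zeros(n)
    for f, a in lfp_components:
        v += a * np.sin(2.0 * np.pi * f * t)
    wf_n = int(round(1e-3 * fs))
    waveform = -spike_amplitude * np.sin(2.0 * np.pi * np.arange(wf_n) / wf_n)
    for ts in spike_times:
        i0 = int(round(ts * fs))
        if not 0 <= i0 <= n - wf_n:
            raise ValueError(f"spike time {ts} s outside the trace duration")
        v[i0:i0 + wf_n] += waveform
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=n)
    return v


# ---------------------------------------------------------------------------
# synthetic bipolar interneuron morphology (SWC)
# ---------------------------------------------------------------------------

def synthetic_bipolar_swc(seed: int = 0, soma_depth: float = 350.0,
                          tuft_top: float = 20.0) -> str:
    """SWC text for a synthetic VIP-like bipolar interneuron.

    This is a synthetic stand-in morphology, not a reconstruction.  It
    follows the classic bipolar plan of VIP-positive cells: a small
    soma at ``soma_depth`` um below the pia, a single ascending primary
    dendrite that bifurcates twice on its way up so that four thin
    branch tips reach layer I (``tuft_top``), one descending dendrite,
    and a thin descending axon.  Lengths and radii follow typical
    published morphometry for these cells (roughly 1.5-2 mm total
    dendrite, sub-micrometre dendritic radii tapering distally, soma
    about 10 um across).  The z-axis is cortical depth, increasing
    downward.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[int, int, float, float, float, float, int]] = []

    def add(stype, x, y, z, r, parent) -> int:
        rows.append((len(rows) + 1, stype, x, y, z, r, parent))
        return len(rows)

    soma = add(1, 0.0, 0.0, soma_depth, 5.0, -1)

    def grow(parent, x, y, z, dz_total, r0, r1, stype, n_seg=6, spread=12.0):
        """Straightish neurite from (x,y,z) spanning dz_total in depth."""
        pid, cx, cy, cz = parent, x, y, z
        for i in range(n_seg):
            cx += rng.normal(0.0, spread / n_seg)
            cy += rng.normal(0.0, spread / n_seg)
            cz += dz_total / n_seg
            r = r0 + (r1 - r0) * (i + 1) / n_seg
            pid = add(stype, cx, cy, cz, r, pid)
        return pid, cx, cy, cz

    # single ascending primary, bifurcating at ~55% and ~30% of soma depth
    trunk_end_z = soma_depth * 0.55
    pid, x, y, z = grow(soma, 0.0, 0.0, soma_depth - 5.0,
                        -(soma_depth - 5.0 - trunk_end_z), 0.45, 0.35, 3, n_seg=8)
    for dx in (-15.0, 15.0):
        mid_z = soma_depth * 0.30
        pid2, x2, y2, z2 = grow(pid, x + dx, y, z, -(z - mid_z), 0.3, 0.25, 3)
    # four tuft tips into layer I
        for dx2 in (-10.0, 10.0):
            grow(pid2, x2 + dx2, y2, z2, -(z2 - tuft_top), 0.25, 0.2, 3)
    # one descending dendrite
    grow(soma, 6.0, 0.0, soma_depth + 5.0, 250.0, 0.35, 0.25, 3, n_seg=5)
    # descending axon
    grow(soma, 0.0, 4.0, soma_depth + 5.0, 500.0, 0.15, 0.15, 2, n_seg=10)

    lines = ["# synthetic VIP-like bipolar interneuron (not a reconstruction)",
             "# columns: id type x y z radius parent; z = cortical depth (um)"]
    for nid, stype, x, y, z, r, parent in rows:
        lines.append(f"{nid} {stype} {x:.2f} {y:.2f} {z:.2f} {r:.3f} {parent}")
    return "\n".join(lines) + "\n"
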