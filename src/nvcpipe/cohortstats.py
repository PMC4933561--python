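"""Cohort-level statistics over per-location response metrics.

Conventions follow standard practice for multi-subject single-vessel
data: scatter data are presented as depth-binned means where, within
each 100-um bin, measurements are first averaged per subject and the
mean and standard error are then taken across subjects.  The
depth-onset regression, by contrast, is an ordinary least squares fit
to the individual measurements, with a two-sided t-test on the slope
against zero.  When the slope is negative (onset decreasing with
depth, i.e. the response is conducted upstream along the diving
arteriole), its reciprocal magnitude is the conduction velocity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .core import Timecourse
from .vesselquant import MetricsConfig, compute_metrics

log = logging.getLogger(__name__)

METRIC_COLUMNS = ["onset_s", "time_to_peak_s", "peak_dilation_pct",
                  "peak_constriction_pct", "constriction_onset_s"]


def metrics_table(traces: list[Timecourse], config: MetricsConfig | None = None
                  ) -> pd.DataFrame:
    """One row of response metrics per measurement location."""
    rows = []
    for tc in traces:
        m = compute_metrics(tc, config)
        rows.append({
            "subject_id": tc.subject_id, "vessel_id": tc.vessel_id,
            "depth_um": tc.depth_um, "branch": tc.branch,
            "condition": tc.condition,
            "onset_s": m.onset_s, "time_to_peak_s": m.time_to_peak_s,
            "peak_dilation_pct": m.peak_dilation_pct,
            "peak_constriction_pct": m.peak_constriction_pct,
            "constriction_onset_s": m.constriction_onset_s,
            "has_constriction": m.has_constriction,
        })
    return pd.DataFrame(rows)


def bin_by_depth(table: pd.DataFrame, metric: str, bin_width: float = 100.0
                 ) -> pd.DataFrame:
    """Depth-binned across-subject mean +- SE of one metric.

    Bins are half-open ``[k*w, (k+1)*w)``.  Within each bin, rows are
    first averaged per subject; the bin mean and SE are computed across
    those subject means.  Bins with a single subject get SE = NaN;
    empty bins are omitted (logged).
    """
    if table.empty:
        raise ValueError("empty cohort table")
    df = table.dropna(subset=[metric]).copy()
    df["bin_left"] = np.floor(df["depth_um"] / bin_width) * bin_width
    per_subject = (df.groupby(["bin_left", "subject_id"])[metric]
                     .mean().reset_index())
    out = (per_subject.groupby("bin_left")[metric]
           .agg(mean="mean", sd="std", n_subjects="count").reset_index())
    out["se"] = out["sd"] / np.sqrt(out["n_subjects"])
    out.loc[out["n_subjects"] < 2, "se"] = np.nan
    out["bin_center"] = out["bin_left"] + bin_width / 2.0
    n_bins_total = int(np.ceil(table["depth_um"].max() / bin_width))
    if len(out) < n_bins_total:
        log.info("bin_by_depth: %d of %d bins empty for %s",
                 n_bins_total - len(out), n_bins_total, metric)
    return out[["bin_left", "bin_center", "mean", "se", "n_subjects"]]


def subject_average_timecourses(traces: list[Timecourse], normalize: bool = True
                                ) -> pd.DataFrame:
    """Grand-average trace +- SE across subjects.

    All traces are resampled (linear interpolation) onto the time base
    of the first trace, averaged within each subject, optionally peak
    normalized per subject, then averaged across subjects.  Subjects
    whose average peaks at or below zero cannot be peak-normalized and
    are excluded (logged).
    """
    if not traces:
        raise ValueError("no traces given")
    base = traces[0].time
    by_subject: dict[str, list[np.ndarray]] = {}
    for tc in traces:
        v = np.interp(base, tc.time, tc.value)
        by_subject.setdefault(tc.subject_id, []).append(v)
    curves = []
    for subject, vs in by_subject.items():
        avg = np.mean(vs, axis=0)
        if normalize:
            peak = float(np.max(avg))
            if peak <= 0:
                log.warning("subject %s excluded: non-positive peak", subject)
                continue
            avg = avg / peak
        curves.append(avg)
    if not curves:
        raise ValueError("no subjects with a positive peak to average")
    arr = np.vstack(curves)
    mean = arr.mean(axis=0)
    se = (arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
          if arr.shape[0] > 1 else np.full_like(mean, np.nan))
    return pd.DataFrame({"time_s": base, "mean": mean, "se": se,
                         "n_subjects": arr.shape[0]})


@dataclass
class DepthRegressionResult:
    """OLS of a timing metric against depth over individual measurements."""

    slope: float            # s/um
    intercept: float        # s
    slope_p: float          # two-sided t-test against slope = 0
    conduction_velocity: float  # um/s; NaN when slope >= 0
    direction: str          # "upstream" (onset decreases with depth) | "downstream"
    n: int


def depth_regression(table: pd.DataFrame, metric: str = "onset_s"
                     ) -> DepthRegressionResult:
    """Fit metric ~ depth by OLS on individual measurements.

    The conduction velocity 1/|slope| is reported only for negative
    slopes (deeper locations responding earlier); a positive slope is
    annotated "downstream" with NaN velocity.
    """
    df = table.dropna(subset=[metric, "depth_um"])
    if len(df) < 3:
        raise ValueError("need >= 3 rows with a defined metric")
    depth = df["depth_um"].to_numpy(float)
    if np.ptp(depth) == 0:
        raise ValueError("degenerate depth variance")
    y = df[metric].to_numpy(float)
    model = sm.OLS(y, sm.add_constant(depth)).fit()
    intercept, slope = model.params
    slope_p = float(model.pvalues[1])
    if slope < 0:
        velocity, direction = 1.0 / abs(slope), "upstream"
    else:
        velocity, direction = float("nan"), "downstream"
    return DepthRegressionResult(slope=float(slope), intercept=float(intercept),
                                 slope_p=slope_p, conduction_velocity=velocity,
                                 direction=direction, n=len(df))


def coexpression_proportion(positive: int, total: int
                            ) -> tuple[int, tuple[float, float]]:
    """Display percent (nearest integer) and Wilson 95% CI for a count.

    Used for small immunostaining counts such as the fraction of
    GABAergic neurons co-expressing the optogenetic actuator.
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= positive <= total:
        raise ValueError("positive must lie within [0, total]")
    percent = int(round(100.0 * positive / total))
    lo, hi = proportion_confint(positive, total, alpha=0.05, method="wilson")
    return percent, (100.0 * float(lo), 100.0 * float(hi))
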