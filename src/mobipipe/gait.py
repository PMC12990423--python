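"""Gait-event detection and stride kinematics from heel-marker trajectories.

Heel strike is the most anterior excursion of the heel marker on the
anterior-posterior (AP) axis; heel lift is the most posterior excursion
within a stride (the interval between consecutive strikes of the same
foot).  Stride time is the interval between consecutive same-foot strikes;
stride length is the AP distance from a heel lift to the next heel strike;
step width is the mediolateral distance between the two heel markers at
right heel strike.  Per-block summaries report the mean and CV%
(100 * SD / mean, sample SD) of each metric.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InsufficientGaitError

__all__ = [
    "detect_heel_strikes",
    "detect_heel_lifts",
    "stride_metrics",
    "step_widths",
    "analyze_marker_stream",
    "summarize_gait",
    "gait_qc",
    "mph_to_mps",
    "cv_percent",
]

MPH_TO_MPS = 0.44704


def mph_to_mps(mph):
    """Convert miles per hour to metres per second (1 mph = 0.44704 m/s)."""
    return mph * MPH_TO_MPS


def cv_percent(values):
    """Coefficient of variation in percent: 100 * sample SD / mean."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return np.nan
    mean = values.mean()
    if mean == 0:
        return np.nan
    return 100.0 * values.std(ddof=1) / mean


def _smooth(trace, rate, smooth_ms):
    """Zero-phase moving average of the given width (stabilizes extrema)."""
    width = max(1, int(round(smooth_ms / 1000.0 * rate)))
    if width <= 1:
        return trace
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(trace, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + len(trace)]
    return out


def detect_heel_strikes(z_trace, rate, min_stride_time_ms=600.0,
                        min_prominence_mm=20.0, smooth_ms=0.0):
    """Heel-strike times (ms) from the AP heel trace.

    Strikes are local maxima of the (optionally smoothed) AP position
    separated by at least ``min_stride_time_ms`` with prominence of at
    least ``min_prominence_mm``; times are at sample resolution.
    """
    z = np.asarray(z_trace, dtype=float)
    min_samples = 2 * int(round(min_stride_time_ms / 1000.0 * rate))
    if len(z) < min_samples:
        raise InsufficientGaitError(
            f"trace of {len(z)} samples is shorter than two minimum strides"
        )
    if smooth_ms > 0:
        z = _smooth(z, rate, smooth_ms)
    distance = max(1, int(round(min_stride_time_ms / 1000.0 * rate)))
    peaks, _ = find_peaks(z, distance=distance, prominence=min_prominence_mm)
    if len(peaks) < 2:
        raise InsufficientGaitError(
            f"found {len(peaks)} heel strikes; need at least 2"
        )
    return peaks * 1000.0 / rate


def detect_heel_lifts(z_trace, rate, strike_times_ms):
    """One heel lift per inter-strike interval: the AP minimum within it.

    Ties at the minimum resolve to the earliest sample.
    """
    z = np.asarray(z_trace, dtype=float)
    strikes = np.asarray(strike_times_ms, dtype=float)
    if len(strikes) < 2:
        raise InsufficientGaitError("need at least 2 strikes to find lifts")
    idx = np.round(strikes / 1000.0 * rate).astype(int)
    lifts = []
    for i0, i1 in zip(idx[:-1], idx[1:]):
        interior = z[i0 + 1:i1]
        if len(interior) == 0:
            lifts.append(i0)
            continue
        lifts.append(i0 + 1 + int(np.argmin(interior)))
    return np.asarray(lifts) * 1000.0 / rate


def stride_metrics(z_trace, rate, strike_times_ms, lift_times_ms):
    """Per-stride time (ms) and length (mm).

    ``stride_time[i] = strike[i+1] - strike[i]``;
    ``stride_length[i] = z(strike[i+1]) - z(lift[i])``.  Strides with a
    negative length (backward excursion, a detection failure for forward
    walking) are excluded with a warning and flagged in the output.
    """
    z = np.asarray(z_trace, dtype=float)
    strikes = np.asarray(strike_times_ms, dtype=float)
    lifts = np.asarray(lift_times_ms, dtype=float)
    if len(lifts) != len(strikes) - 1:
        raise ValueError("expected one lift per inter-strike interval")
    s_idx = np.round(strikes / 1000.0 * rate).astype(int)
    l_idx = np.round(lifts / 1000.0 * rate).astype(int)
    times = np.diff(strikes)
    lengths = z[s_idx[1:]] - z[l_idx]
    valid = lengths >= 0
    if not valid.all():
        warnings.warn(
            f"excluded {int((~valid).sum())} stride(s) with negative length"
        )
    return pd.DataFrame({
        "stride_time_ms": times,
        "stride_length_mm": lengths,
        "valid": valid,
    })


def step_widths(x_left, x_right, rate, right_strike_times_ms):
    """Mediolateral |left - right| heel distance at each right heel strike."""
    x_left = np.asarray(x_left, dtype=float)
    x_right = np.asarray(x_right, dtype=float)
    idx = np.round(np.asarray(right_strike_times_ms, dtype=float)
                   / 1000.0 * rate).astype(int)
    if len(idx) and (idx.min() < 0 or idx.max() >= min(len(x_left), len(x_right))):
        raise ValueError("right heel strike outside marker trace coverage")
    return np.abs(x_left[idx] - x_right[idx])


def analyze_marker_stream(stream, min_stride_time_ms=600.0,
                          min_prominence_mm=20.0, smooth_ms=0.0):
    """Full gait-event extraction for one block's marker stream.

    Returns a dict with per-foot strike/lift times, per-foot stride metric
    tables, and the per-right-strike step widths.
    """
    stream.require_heels()
    rate = stream.rate
    result = {"rate": rate}
    for foot in ("left", "right"):
        z = stream.markers[f"{foot}_heel"][:, 2]
        strikes = detect_heel_strikes(z, rate, min_stride_time_ms,
                                      min_prominence_mm, smooth_ms)
        lifts = detect_heel_lifts(z, rate, strikes)
        result[foot] = {
            "strikes_ms": strikes,
            "lifts_ms": lifts,
            "strides": stride_metrics(z, rate, strikes, lifts),
        }
    result["step_widths_mm"] = step_widths(
        stream.markers["left_heel"][:, 0],
        stream.markers["right_heel"][:, 0],
        rate,
        result["right"]["strikes_ms"],
    )
    return result


def _block_row(events):
    strides = pd.concat(
        [events["left"]["strides"], events["right"]["strides"]],
        ignore_index=True,
    )
    strides = strides[strides["valid"]]
    widths = events["step_widths_mm"]
    return {
        "n_strides": len(strides),
        "stride_time_mean_ms": strides["stride_time_ms"].mean(),
        "stride_time_cv": cv_percent(strides["stride_time_ms"]),
        "stride_length_mean_mm": strides["stride_length_mm"].mean(),
        "stride_length_cv": cv_percent(strides["stride_length_mm"]),
        "step_width_mean_mm": float(np.mean(widths)),
        "step_width_cv": cv_percent(widths),
    }


GAIT_VARIABLES = (
    "stride_time_mean_ms", "stride_time_cv",
    "stride_length_mean_mm", "stride_length_cv",
    "step_width_mean_mm", "step_width_cv",
)


def summarize_gait(blocks):
    """Block summaries and per-condition means of the six gait variables.

    ``blocks`` is an iterable of ``(subject, condition, block_id, events)``
    with ``events`` from :func:`analyze_marker_stream`.  The condition-level
    value of each variable is the unweighted mean over that condition's
    blocks.  Blocks with fewer than 5 strides are kept but flagged.
    """
    rows = []
    for subject, condition, block_id, events in blocks:
        row = {"subject": subject, "condition": condition, "block": block_id}
        row.update(_block_row(events))
        row["short_block"] = row["n_strides"] < 5
        if row["short_block"]:
            warnings.warn(
                f"subject {subject} {condition} block {block_id}: only "
                f"{row['n_strides']} strides"
            )
        rows.append(row)
    block_table = pd.DataFrame(rows)
    if block_table.empty:
        return block_table, block_table
    condition_table = (
        block_table.groupby(["subject", "condition"], sort=True)[
            list(GAIT_VARIABLES)]
        .mean()
        .reset_index()
    )
    return block_table, condition_table


def gait_qc(events, mad_thresh=3.0):
    """QC report: stride-time histogram and outliers beyond 3 MAD.

    A reproducible surrogate for manual visual confirmation of detected
    peaks: flags strides whose time deviates from the median by more than
    ``mad_thresh`` scaled median absolute deviations.
    """
    strides = pd.concat(
        [events["left"]["strides"], events["right"]["strides"]],
        ignore_index=True,
    )
    st = strides["stride_time_ms"].to_numpy()
    med = np.median(st)
    mad = np.median(np.abs(st - med)) * 1.4826
    outliers = np.abs(st - med) > max(mad_thresh * mad, 1e-9)
    hist, edges = np.histogram(st, bins=20)
    return {
        "n_strides": int(len(st)),
        "stride_time_median_ms": float(med),
        "stride_time_mad_ms": float(mad),
        "n_outliers": int(outliers.sum()),
        "outlier_indices": np.nonzero(outliers)[0].tolist(),
        "histogram": {"counts": hist.tolist(), "edges_ms": edges.tolist()},
    }
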