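"""EEG preprocessing, epoching, ERP peak measures, and difference waves.

The preprocessing chain is zero-phase 0.25-40 Hz band-pass filtering,
average referencing, bad-channel detection with spherical-spline (Perrin)
interpolation, and stimulus-locked epoching over -100..800 ms with
pre-stimulus baseline correction.  Peak measurement is two-pass: canonical
component windows (P2 at FCz 200-280 ms, N2 at FCz 280-380 ms, P3 at CPz
350-500 ms) locate each group's grand-average peak, and per-subject peaks
are then measured inside that latency ± 25 ms (P2, N2) or ± 50 ms (P3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt
from scipy.special import eval_legendre

__all__ = [
    "EpochSet",
    "PeakMeasure",
    "bandpass",
    "average_reference",
    "detect_and_interpolate_bad",
    "spline_interpolation_matrix",
    "epoch",
    "grand_average",
    "two_pass_peak_windows",
    "find_peak",
    "difference_wave",
    "topo_segments",
]

CANONICAL_WINDOWS = {
    "P2": ("FCz", (200.0, 280.0), 1, 25.0),
    "N2": ("FCz", (280.0, 380.0), -1, 25.0),
    "P3": ("CPz", (350.0, 500.0), 1, 50.0),
}


# ---------------------------------------------------------------------------
# continuous preprocessing
# ---------------------------------------------------------------------------


def bandpass(recording, low_hz=0.25, high_hz=40.0, order=4):
    """Zero-phase (forward-backward) Butterworth band-pass; removes DC."""
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if recording.rate <= 2 * high_hz:
        raise ValueError("sampling rate must exceed twice the upper edge")
    sos = butter(order, [low_hz, high_hz], btype="bandpass",
                 fs=recording.rate, output="sos")
    out = recording.copy()
    out.samples = sosfiltfilt(sos, out.samples, axis=-1)
    return out


def average_reference(recording):
    """Re-reference to the per-sample mean across channels."""
    if recording.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = recording.copy()
    out.samples = out.samples - out.samples.mean(axis=0, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# bad channels and spherical-spline interpolation
# ---------------------------------------------------------------------------


def _spline_g(cosang, m=4, n_terms=7):
    """Perrin surface-spline kernel: Legendre series on the unit sphere."""
    cosang = np.asarray(cosang, dtype=float)
    g = np.zeros_like(cosang)
    for n in range(1, n_terms + 1):
        g += (2 * n + 1) / (n * (n + 1)) ** m * eval_legendre(n, cosang)
    return g / (4.0 * np.pi)


def spline_interpolation_matrix(pos_good, pos_bad, m=4, n_terms=7, reg=1e-5):
    """Matrix mapping good-channel data to spherical-spline estimates.

    Positions are unit vectors.  Solves the Perrin spline system with a
    constant term and ridge regularization ``reg`` on the kernel diagonal;
    returns ``W`` with ``interp = W @ data_good``.
    """
    pos_good = np.asarray(pos_good, dtype=float)
    pos_bad = np.asarray(pos_bad, dtype=float)
    k = len(pos_good)
    G = _spline_g(np.clip(pos_good @ pos_good.T, -1, 1), m, n_terms)
    G = G + np.eye(k) * reg
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = G
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    B = np.zeros((k + 1, k))
    B[:k, :] = np.eye(k)
    sol = np.linalg.solve(A, B)          # rows: spline coefs then constant
    Gb = _spline_g(np.clip(pos_bad @ pos_good.T, -1, 1), m, n_terms)
    return Gb @ sol[:k, :] + sol[k:k + 1, :]


def detect_and_interpolate_bad(recording, layout, z_thresh=3.5,
                               max_bad_fraction=0.25):
    """Flag outlier/flat channels and replace them by spline interpolation.

    A channel is bad when the robust z-score of its log-variance (scaled
    MAD about the median) exceeds ``z_thresh`` in magnitude, or when it is
    flat.  More than ``max_bad_fraction`` bad channels aborts with an
    error.  Returns ``(recording, bad_labels)``.
    """
    missing = [ch for ch in recording.channel_labels if ch not in layout]
    if missing:
        raise ValueError(f"layout lacks positions for channels: {missing}")
    var = recording.samples.var(axis=1)
    flat = var <= 1e-12
    with np.errstate(divide="ignore"):
        logvar = np.log(np.where(flat, np.nan, var))
    med = np.nanmedian(logvar)
    mad = np.nanmedian(np.abs(logvar - med)) * 1.4826
    if mad <= 0:
        z = np.zeros_like(logvar)
    else:
        z = (logvar - med) / mad
    bad = flat | (np.abs(np.nan_to_num(z)) > z_thresh)
    bad_labels = [recording.channel_labels[i] for i in np.nonzero(bad)[0]]
    if not bad_labels:
        return recording.copy(), []
    if len(bad_labels) > max_bad_fraction * recording.n_channels:
        raise ValueError(
            f"{len(bad_labels)} of {recording.n_channels} channels bad; "
            f"exceeds the {max_bad_fraction:.0%} quality floor"
        )
    good_idx = np.nonzero(~bad)[0]
    bad_idx = np.nonzero(bad)[0]
    pos = np.array([layout[ch] for ch in recording.channel_labels])
    W = spline_interpolation_matrix(pos[good_idx], pos[bad_idx])
    out = recording.copy()
    out.samples[bad_idx] = W @ out.samples[good_idx]
    return out, bad_labels


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------


@dataclass
class EpochSet:
    """Stimulus-locked epochs: trials x channels x time, with metadata.

    ``time_ms[0] <= 0 < time_ms[-1]`` and time 0 is stimulus onset.  At
    512 Hz with the -100..800 ms window the span is samples onset-51 to
    onset+409 inclusive: 461 samples.
    """

    data: np.ndarray
    time_ms: np.ndarray
    channel_labels: list
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[2] != len(self.time_ms):
            raise ValueError("time axis length mismatch")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis length mismatch")
        if len(self.metadata) not in (0, self.data.shape[0]):
            raise ValueError("metadata rows must match trial count")

    @property
    def n_trials(self):
        return self.data.shape[0]

    def select(self, **criteria):
        mask = np.ones(self.n_trials, dtype=bool)
        for key, val in criteria.items():
            col = self.metadata[key]
            mask &= (col.isin(val) if isinstance(val, (list, tuple, set))
                     else col == val).to_numpy()
        return EpochSet(self.data[mask], self.time_ms, self.channel_labels,
                        self.metadata.loc[mask].reset_index(drop=True))

    def average(self):
        return self.data.mean(axis=0)

    def channel_index(self, label):
        return self.channel_labels.index(label)


def epoch(recording, onsets=None, window_ms=(-100.0, 800.0), baseline=True,
          baseline_ms=None, metadata=None):
    """Cut stimulus-locked epochs out of a continuous recording.

    ``onsets`` are 0-based sample indices (defaults to the recording's
    stimulus events).  The epoch spans ``round(|w0|/1000*rate)`` samples
    before the onset through ``round(w1/1000*rate) - 1`` after, inclusive
    of the onset sample.  Baseline correction subtracts each channel's mean
    over the pre-stimulus interval (default the full pre-onset span).
    Trials that would exceed the recording bounds are dropped with a
    warning (their metadata rows likewise).
    """
    if onsets is None:
        onsets = [s for s, _c in recording.events]
    onsets = np.asarray(onsets, dtype=int)
    rate = recording.rate
    w0, w1 = window_ms
    if w0 >= w1:
        raise ValueError("window start must precede window end")
    pre = int(round(-w0 / 1000.0 * rate))
    post = int(round(w1 / 1000.0 * rate)) - 1
    n_time = pre + post + 1
    time_ms = np.arange(-pre, post + 1) * 1000.0 / rate

    keep = (onsets - pre >= 0) & (onsets + post < recording.n_samples)
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} epoch(s) exceeding "
                      f"recording bounds")
    kept = onsets[keep]
    data = np.empty((len(kept), recording.n_channels, n_time))
    for i, onset in enumerate(kept):
        data[i] = recording.samples[:, onset - pre:onset + post + 1]

    if baseline:
        if baseline_ms is None:
            bmask = time_ms <= 0
        else:
            bmask = (time_ms >= baseline_ms[0]) & (time_ms <= baseline_ms[1])
        data -= data[:, :, bmask].mean(axis=2, keepdims=True)

    meta = pd.DataFrame()
    if metadata is not None:
        meta = metadata.loc[np.asarray(keep)].reset_index(drop=True)
    return EpochSet(data, time_ms, list(recording.channel_labels), meta)


# ---------------------------------------------------------------------------
# averages and peaks
# ---------------------------------------------------------------------------


def grand_average(epochs, by=("group", "condition", "response_type"),
                  subject_col="subject"):
    """Grand averages: per-subject averages first, then unweighted subject mean.

    Returns ``{key_tuple: {"waveform": (ch, time), "n_subjects": int,
    "n_trials": int}}`` for every combination of the ``by`` metadata columns
    present in the data.
    """
    if epochs.metadata.empty:
        raise ValueError("epochs need metadata for grand averaging")
    out = {}
    meta = epochs.metadata
    for key, trial_idx in meta.groupby(list(by), sort=True).groups.items():
        key = key if isinstance(key, tuple) else (key,)
        cell = meta.loc[trial_idx]
        subj_means = []
        for _subj, rows in cell.groupby(subject_col).groups.items():
            subj_means.append(epochs.data[np.asarray(rows)].mean(axis=0))
        out[key] = {
            "waveform": np.mean(subj_means, axis=0),
            "n_subjects": len(subj_means),
            "n_trials": len(cell),
        }
    return out


@dataclass
class PeakMeasure:
    """A signed extremum inside a component window at one electrode."""

    component: str
    electrode: str
    window_ms: tuple
    peak_amplitude_uv: float
    peak_latency_ms: float
    polarity: int
    at_edge: bool = False


def find_peak(waveform, time_ms, window_ms, polarity=1, electrode="",
              component="", channel_labels=None, mode="extremum",
              mean_halfwidth_ms=10.0):
    """Locate the component peak inside a latency window.

    ``waveform`` is 1-D (one electrode) or 2-D with ``channel_labels`` and
    ``electrode`` naming the row.  The peak is the signed extremum (maximum
    for positive polarity, minimum for negative); local extrema are
    preferred over window edges, and ties resolve to the earliest sample.
    ``mode="mean_around"`` reports the mean amplitude within
    ``± mean_halfwidth_ms`` of the detected peak instead of the raw
    extremum.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim == 2:
        if channel_labels is None:
            raise ValueError("2-D waveform needs channel_labels")
        waveform = waveform[channel_labels.index(electrode)]
    mask = (time_ms >= window_ms[0]) & (time_ms <= window_ms[1])
    if not mask.any():
        raise ValueError("window does not overlap the epoch")
    seg = waveform[mask] * polarity
    t_seg = time_ms[mask]
    if np.ptp(seg) == 0:
        raise ValueError("waveform is flat in the window; no identifiable peak")

    interior = np.zeros(len(seg), dtype=bool)
    if len(seg) > 2:
        interior[1:-1] = (seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:])
    if interior.any():
        cand = np.nonzero(interior)[0]
        best = cand[np.argmax(seg[cand])]
        ties = cand[seg[cand] == seg[best]]
        best = int(ties.min())
        at_edge = False
    else:
        best = int(np.argmax(seg))  # argmax returns the earliest maximum
        at_edge = True

    if mode == "mean_around":
        near = np.abs(t_seg - t_seg[best]) <= mean_halfwidth_ms
        amp = float(seg[near].mean() * polarity)
    else:
        amp = float(seg[best] * polarity)
    return PeakMeasure(component, electrode, tuple(window_ms), amp,
                       float(t_seg[best]), polarity, at_edge)


def two_pass_peak_windows(group_waveform, time_ms, channel_labels,
                          components=None):
    """Second-pass per-group windows centred on grand-average peak latencies.

    For each component the group grand-average peak is located inside the
    canonical window at the canonical electrode; the returned window is
    that latency ± the component's half-width (25 ms for P2/N2, 50 ms for
    P3), intersected with the epoch span.
    """
    components = components or CANONICAL_WINDOWS
    windows = {}
    for comp, (electrode, window, polarity, halfwidth) in components.items():
        peak = find_peak(group_waveform, time_ms, window, polarity,
                         electrode=electrode, component=comp,
                         channel_labels=channel_labels)
        lo = max(peak.peak_latency_ms - halfwidth, float(time_ms[0]))
        hi = min(peak.peak_latency_ms + halfwidth, float(time_ms[-1]))
        windows[comp] = {"electrode": electrode, "window_ms": (lo, hi),
                         "polarity": polarity,
                         "group_peak_latency_ms": peak.peak_latency_ms}
    return windows


# ---------------------------------------------------------------------------
# difference waves and topographies
# ---------------------------------------------------------------------------


def difference_wave(cr_avg, hit_avg):
    """Inhibition-related difference wave: CR average minus Hit average."""
    cr_avg = np.asarray(cr_avg, dtype=float)
    hit_avg = np.asarray(hit_avg, dtype=float)
    if cr_avg.shape != hit_avg.shape:
        raise ValueError("CR and Hit averages must have matching shapes")
    return cr_avg - hit_avg


def topo_segments(waveform, time_ms, span_ms=(100.0, 600.0), bin_ms=50.0):
    """Per-channel time-means in consecutive bins across a span.

    Default: ten 50 ms segments from 100 to 600 ms.  Returns
    ``(means, edges)`` with ``means`` of shape (n_bins, n_channels).
    """
    edges = np.arange(span_ms[0], span_ms[1] + 0.5 * bin_ms, bin_ms)
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (time_ms >= lo) & (time_ms < hi)
        if not mask.any():
            raise ValueError(f"bin {lo}-{hi} ms has no samples")
        means.append(np.asarray(waveform)[:, mask].mean(axis=1))
    return np.array(means), edges
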