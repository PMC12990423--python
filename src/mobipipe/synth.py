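"""Synthetic multimodal (behavior + EEG + gait) data with known ground truth.

The generator emulates the three recording streams of a treadmill Go/NoGo
study: per-block trial streams (180 trials, 20% NoGo, 400 ms stimuli,
200-400 ms uniform ISI), 64-channel 512 Hz EEG with Gaussian-bump P2/N2/P3
components on 1/f background noise, and 100 Hz heel-marker trajectories
whose stride time/length and step width follow configurable means and CV%.
Every operation is fully deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (
    GO_CODE,
    NOGO_CODE,
    PRESS_CODE,
    ConditionLabel,
    MarkerStream,
    Recording,
    STUDY_CONDITIONS,
    write_eeg,
    write_events_tsv,
    write_markers,
)

__all__ = [
    "BehaviorParams",
    "ErpComponentSpec",
    "GaitParams",
    "ScenarioSpec",
    "electrode_layout",
    "generate_trial_stream",
    "simulate_behavior",
    "simulate_eeg",
    "simulate_gait_markers",
    "default_scenario",
    "build_scenario",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorParams:
    """Response model: hit/false-alarm probabilities and log-normal RTs."""

    hit_rate: float
    fa_rate: float
    rt_mean_ms: float
    rt_sd_ms: float

    def __post_init__(self):
        if not 0 < self.hit_rate <= 1:
            raise ValueError("hit_rate must be in (0, 1]")
        if not 0 <= self.fa_rate < 1:
            raise ValueError("fa_rate must be in [0, 1)")
        if self.rt_mean_ms <= 0 or self.rt_sd_ms < 0:
            raise ValueError("RT mean must be positive, sd non-negative")
        if self.hit_rate <= self.fa_rate:
            import warnings

            warnings.warn("hit_rate <= fa_rate: d' fixture will be at or below chance")


@dataclass(frozen=True)
class ErpComponentSpec:
    """One stimulus-locked component: a spatio-temporal Gaussian bump.

    Amplitude is signed (negative for N2); the spatial profile is
    ``exp(-angular_distance**2 / (2 * spread**2))`` around the center
    electrode on the unit sphere.
    """

    name: str
    peak_latency_ms: float
    peak_amplitude_uv: float
    temporal_sd_ms: float
    center_electrode: str
    spatial_spread_rad: float = 0.7

    def __post_init__(self):
        if self.name == "N2" and self.peak_amplitude_uv >= 0:
            raise ValueError("N2 amplitude must be negative")
        if self.name in ("P2", "P3") and self.peak_amplitude_uv <= 0:
            raise ValueError(f"{self.name} amplitude must be positive")
        if self.temporal_sd_ms <= 0 or self.spatial_spread_rad <= 0:
            raise ValueError("temporal sd and spatial spread must be positive")


@dataclass(frozen=True)
class GaitParams:
    """Treadmill gait geometry: means and CV% of the three stride metrics.

    ``belt_speed_mms`` is the posterior speed of the heel during stance in
    the emulator; it must be high enough that the configured stride length
    fits inside a stride period.
    """

    belt_speed_mms: float = 1580.0
    stride_time_mean_ms: float = 1300.0
    stride_time_cv: float = 3.0
    stride_length_mean_mm: float = 1230.0
    stride_length_cv: float = 3.0
    step_width_mean_mm: float = 200.0
    step_width_cv: float = 8.0

    def __post_init__(self):
        for name in ("belt_speed_mms", "stride_time_mean_ms",
                     "stride_length_mean_mm", "step_width_mean_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("stride_time_cv", "stride_length_cv", "step_width_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# electrode layout
# ---------------------------------------------------------------------------

_LAYOUT_CACHE = None


def electrode_layout():
    """64-channel extended 10-20 layout as unit-sphere positions.

    Returns an ordered ``{name: (3,) ndarray}`` dict in the package axis
    convention (x = right, y = up, z = anterior); Cz sits at the vertex.
    Positions come from the standard BioSemi 64 montage, projected onto the
    unit sphere.
    """
    global _LAYOUT_CACHE
    if _LAYOUT_CACHE is None:
        import mne

        montage = mne.channels.make_standard_montage("biosemi64")
        pos = montage.get_positions()["ch_pos"]
        layout = {}
        for name in montage.ch_names:
            p = np.asarray(pos[name], dtype=float)
            # mne head coords: x right, y anterior, z up -> ours: x, y up, z ant
            v = np.array([p[0], p[2], p[1]])
            layout[name] = v / np.linalg.norm(v)
        _LAYOUT_CACHE = layout
    return {k: v.copy() for k, v in _LAYOUT_CACHE.items()}


def spatial_weights(layout, center, spread_rad):
    """Gaussian-in-angular-distance weights for all layout electrodes."""
    if center not in layout:
        raise KeyError(f"center electrode {center!r} not in layout")
    c = layout[center]
    names = list(layout)
    cosang = np.clip(np.array([layout[n] @ c for n in names]), -1.0, 1.0)
    ang = np.arccos(cosang)
    return names, np.exp(-(ang**2) / (2.0 * spread_rad**2))


# ---------------------------------------------------------------------------
# trial stream and behavior
# ---------------------------------------------------------------------------


def generate_trial_stream(n_trials, p_nogo=0.2, isi_range_ms=(200.0, 400.0),
                          stim_dur_ms=400.0, seed=0, exact_proportion=True):
    """Generate an ordered Go/NoGo trial stream with onset times.

    With ``exact_proportion`` (default) the number of NoGo trials is exactly
    ``round(n_trials * p_nogo)``, realized as a seeded permutation of a fixed
    multiset; otherwise trials are i.i.d. Bernoulli.  Onsets are strictly
    increasing: each trial occupies ``stim_dur_ms`` plus a uniform ISI drawn
    from ``isi_range_ms``.
    """
    if not 0 <= p_nogo < 1:
        raise ValueError("p_nogo must be in [0, 1)")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    lo, hi = isi_range_ms
    if lo > hi or lo < 0:
        raise ValueError("invalid ISI range")
    rng = np.random.default_rng(seed)
    if exact_proportion:
        n_nogo = int(round(n_trials * p_nogo))
        stim = np.array(["Go"] * (n_trials - n_nogo) + ["NoGo"] * n_nogo)
        rng.shuffle(stim)
    else:
        stim = np.where(rng.random(n_trials) < p_nogo, "NoGo", "Go")
    isi = rng.uniform(lo, hi, size=n_trials)
    onsets = np.concatenate([[0.0], np.cumsum(stim_dur_ms + isi)[:-1]])
    return pd.DataFrame({
        "trial": np.arange(n_trials),
        "onset_ms": onsets,
        "stim": stim,
        "stim_dur_ms": stim_dur_ms,
    })


def simulate_behavior(stream, params, seed=0, clip_ms=(100.0, 800.0)):
    """Simulate button presses for a trial stream.

    Go trials are pressed with probability ``hit_rate`` and NoGo trials with
    probability ``fa_rate``; press latencies are log-normal with the
    configured mean/sd on the millisecond scale, clipped to ``clip_ms``
    after stimulus onset.  Returns the stream with ``press_ms`` (absolute
    press time, NaN for no press) appended.
    """
    rng = np.random.default_rng(seed)
    n = len(stream)
    p_press = np.where(stream["stim"] == "Go", params.hit_rate, params.fa_rate)
    pressed = rng.random(n) < p_press
    if params.rt_sd_ms == 0:
        lat = np.full(n, params.rt_mean_ms)
    else:
        cv2 = (params.rt_sd_ms / params.rt_mean_ms) ** 2
        sigma = np.sqrt(np.log1p(cv2))
        mu = np.log(params.rt_mean_ms) - sigma**2 / 2
        lat = rng.lognormal(mu, sigma, size=n)
    lat = np.clip(lat, clip_ms[0], clip_ms[1])
    out = stream.copy()
    out["press_ms"] = np.where(pressed, stream["onset_ms"] + lat, np.nan)
    return out


def _response_type(stim, pressed):
    if stim == "Go":
        return "Hit" if pressed else "Miss"
    return "FA" if pressed else "CR"


# ---------------------------------------------------------------------------
# EEG simulation
# ---------------------------------------------------------------------------


def one_over_f_noise(shape, rate, rms, slope=1.0, rng=None):
    """Noise with a 1/f**slope amplitude spectrum and given per-channel RMS."""
    rng = np.random.default_rng(rng)
    n = shape[-1]
    white = rng.standard_normal(shape)
    if rms == 0:
        return np.zeros(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-slope / 2.0)
    shaping[0] = 0.0
    shaped = np.fft.irfft(spec * shaping, n=n, axis=-1)
    current = shaped.std(axis=-1, keepdims=True)
    current[current == 0] = 1.0
    return shaped / current * rms


def simulate_eeg(stream, responses=None, components=(), noise_rms=10.0,
                 noise_slope=1.0, rate=512, seed=0, layout=None,
                 pre_ms=500.0, post_ms=1000.0, epoch_span_ms=(0.0, 800.0)):
    """Render a trial stream into a continuous 64-channel Recording.

    Each trial adds, per component, ``amplitude * Gaussian(t; latency, sd) *
    spatial_weight``; the background is 1/f-shaped noise of ``noise_rms`` µV
    per channel.  ``components`` is either a sequence of
    :class:`ErpComponentSpec` applied to every trial, or a mapping from
    response type (``Hit``/``Miss``/``FA``/``CR``) to such sequences, which
    supports CR-vs-Hit amplitude scaling.  Stimulus triggers (Go=1, NoGo=2)
    and press triggers (64) are written into the event list.
    """
    layout = layout or electrode_layout()
    names = list(layout)
    if responses is None:
        responses = stream.copy()
        responses["press_ms"] = np.nan

    def comps_for(rtype):
        if isinstance(components, dict):
            return components.get(rtype, ())
        return components

    all_specs = []
    if isinstance(components, dict):
        for specs in components.values():
            all_specs.extend(specs)
    else:
        all_specs.extend(components)
    for spec in all_specs:
        if not epoch_span_ms[0] <= spec.peak_latency_ms <= epoch_span_ms[1]:
            raise ValueError(
                f"component {spec.name} latency {spec.peak_latency_ms} ms is "
                f"outside epoch coverage {epoch_span_ms}"
            )

    total_ms = pre_ms + float(responses["onset_ms"].iloc[-1]) + post_ms
    n_samples = int(np.ceil(total_ms / 1000.0 * rate))
    rng = np.random.default_rng(seed)
    data = one_over_f_noise((len(names), n_samples), rate, noise_rms,
                            slope=noise_slope, rng=rng)

    t_ms = np.arange(n_samples) * 1000.0 / rate
    events = []
    weight_cache = {}
    for row in responses.itertuples(index=False):
        onset_samp = int(round((row.onset_ms + pre_ms) / 1000.0 * rate))
        events.append((onset_samp, GO_CODE if row.stim == "Go" else NOGO_CODE))
        pressed = not np.isnan(row.press_ms)
        if pressed:
            press_samp = int(round((row.press_ms + pre_ms) / 1000.0 * rate))
            if press_samp < n_samples:
                events.append((press_samp, PRESS_CODE))
        rtype = _response_type(row.stim, pressed)
        for spec in comps_for(rtype):
            key = (spec.center_electrode, spec.spatial_spread_rad)
            if key not in weight_cache:
                _, weight_cache[key] = spatial_weights(layout, *key)
            w = weight_cache[key]
            peak_ms = row.onset_ms + pre_ms + spec.peak_latency_ms
            half = 4.0 * spec.temporal_sd_ms
            i0 = max(0, int((peak_ms - half) / 1000.0 * rate))
            i1 = min(n_samples, int((peak_ms + half) / 1000.0 * rate) + 1)
            bump = spec.peak_amplitude_uv * np.exp(
                -((t_ms[i0:i1] - peak_ms) ** 2) / (2.0 * spec.temporal_sd_ms**2)
            )
            data[:, i0:i1] += np.outer(w, bump)

    events.sort()
    return Recording(data, float(rate), names, events)


# ---------------------------------------------------------------------------
# gait simulation
# ---------------------------------------------------------------------------

_SWING_GUARD = 0.85  # stance may occupy at most this fraction of a stride


def _foot_z_trace(t_grid_ms, strikes_ms, lengths_mm, belt_mms, z0=0.0):
    """Heel AP trace: linear posterior stance drift + half-cosine swing return.

    The heel sits at ``z0`` at every strike, drifts posterior at belt speed
    for ``length / belt_speed`` seconds (reaching the heel-lift minimum at
    ``z0 - length``), then swings smoothly back so the next strike is a
    local maximum at exactly the next strike time.
    """
    z = np.empty_like(t_grid_ms)
    # lead-in: partial swing rising into the first strike
    first = strikes_ms[0]
    lead = t_grid_ms < first
    l0 = lengths_mm[0]
    tau = np.clip((t_grid_ms[lead] - (first - 600.0)) / 600.0, 0.0, 1.0)
    z[lead] = (z0 - l0) + l0 * (1.0 - np.cos(np.pi * tau)) / 2.0
    for i in range(len(strikes_ms) - 1):
        t0, t1 = strikes_ms[i], strikes_ms[i + 1]
        length = lengths_mm[i]
        stance_ms = length / belt_mms * 1000.0
        t_lift = t0 + stance_ms
        seg = (t_grid_ms >= t0) & (t_grid_ms < t1)
        ts = t_grid_ms[seg]
        stance = ts < t_lift
        out = np.empty(ts.shape)
        out[stance] = z0 - belt_mms * (ts[stance] - t0) / 1000.0
        tau = (ts[~stance] - t_lift) / (t1 - t_lift)
        out[~stance] = (z0 - length) + length * (1.0 - np.cos(np.pi * tau)) / 2.0
        z[seg] = out
    # tail: posterior drift after the last strike
    last = strikes_ms[-1]
    tail = t_grid_ms >= last
    z[tail] = z0 - belt_mms * (t_grid_ms[tail] - last) / 1000.0
    return z


def simulate_gait_markers(params, duration_s, rate=100.0, seed=0,
                          first_strike_ms=700.0):
    """Simulate heel-marker trajectories for treadmill walking.

    Returns ``(MarkerStream, ground_truth)`` where the ground truth holds the
    exact strike/lift times and the per-stride times, lengths, and per-right-
    strike step widths realized by the draw.  Feet are anti-phase; per-stride
    time and length jitter follow the configured CV%; lateral heel separation
    at right heel strikes has the configured mean and CV%.
    """
    rng = np.random.default_rng(seed)
    mean_t = params.stride_time_mean_ms
    if duration_s * 1000.0 < first_strike_ms + 5 * mean_t:
        raise ValueError("duration must cover at least 5 strides")

    def draw_strides(start_ms):
        strikes = [start_ms]
        times, lengths = [], []
        while strikes[-1] < duration_s * 1000.0:
            st = rng.normal(mean_t, params.stride_time_cv / 100.0 * mean_t)
            ln = rng.normal(params.stride_length_mean_mm,
                            params.stride_length_cv / 100.0
                            * params.stride_length_mean_mm)
            if st <= 0 or ln <= 0:
                raise ValueError(
                    "configured CV produced a non-positive stride; reduce CV"
                )
            if ln / params.belt_speed_mms * 1000.0 > _SWING_GUARD * st:
                raise ValueError(
                    "stride length does not fit in stride time at this belt "
                    "speed; raise belt_speed_mms or shorten strides"
                )
            strikes.append(strikes[-1] + st)
            times.append(st)
            lengths.append(ln)
        # drop the stride that crossed the end of the recording
        return np.array(strikes[:-1]), np.array(times[:-1]), np.array(lengths[:-1])

    left_strikes, left_times, left_lengths = draw_strides(first_strike_ms)
    right_strikes, right_times, right_lengths = draw_strides(
        first_strike_ms + mean_t / 2.0
    )

    n = int(round(duration_s * rate))
    t_grid = np.arange(n) * 1000.0 / rate
    z_left = _foot_z_trace(t_grid, left_strikes, left_lengths,
                           params.belt_speed_mms)
    z_right = _foot_z_trace(t_grid, right_strikes, right_lengths,
                            params.belt_speed_mms)

    widths = rng.normal(params.step_width_mean_mm,
                        params.step_width_cv / 100.0 * params.step_width_mean_mm,
                        size=len(right_strikes))
    if np.any(widths <= 0):
        raise ValueError("configured step-width CV produced non-positive widths")
    half = params.step_width_mean_mm / 2.0
    x_left = np.full(n, -half)
    x_right = np.interp(t_grid, right_strikes, widths - half)

    # small vertical heel rise during swing for realism (unused downstream)
    y_left = np.maximum(0.0, -np.gradient(z_left) * 0.5)
    y_right = np.maximum(0.0, -np.gradient(z_right) * 0.5)

    stream = MarkerStream(rate=rate, markers={
        "left_heel": np.column_stack([x_left, y_left, z_left]),
        "right_heel": np.column_stack([x_right, y_right, z_right]),
    })
    lift = {
        "left": left_strikes[:-1] + left_lengths / params.belt_speed_mms * 1000.0,
        "right": right_strikes[:-1] + right_lengths / params.belt_speed_mms * 1000.0,
    }
    ground_truth = {
        "strikes_ms": {"left": left_strikes.tolist(),
                       "right": right_strikes.tolist()},
        "lifts_ms": {"left": lift["left"].tolist(),
                     "right": lift["right"].tolist()},
        "stride_times_ms": {"left": np.diff(left_strikes).tolist(),
                            "right": np.diff(right_strikes).tolist()},
        "stride_lengths_mm": {"left": left_lengths.tolist(),
                              "right": right_lengths.tolist()},
        "step_widths_mm": widths.tolist(),
    }
    return stream, ground_truth


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSpec:
    """Complete description of a synthetic study.

    ``behavior[group][condition_code]`` -> :class:`BehaviorParams`;
    ``erp[group][condition_code][response_type]`` -> list of
    :class:`ErpComponentSpec`; ``gait[group][condition_code]`` ->
    :class:`GaitParams` (walking conditions only).  Everything is
    deterministic given ``seed``.
    """

    n_subjects: dict
    behavior: dict
    erp: dict
    gait: dict
    conditions: tuple = tuple(c.code for c in STUDY_CONDITIONS)
    n_blocks: int = 3
    n_trials: int = 180
    p_nogo: float = 0.2
    isi_range_ms: tuple = (200.0, 400.0)
    stim_dur_ms: float = 400.0
    noise_rms_uv: float = 10.0
    seed: int = 0
    permissive_conditions: bool = False

    def __post_init__(self):
        for code in self.conditions:
            ConditionLabel.from_code(code, permissive=self.permissive_conditions)


# Synthetic calibration of the default scenario.  Hit/FA rates are chosen so
# the implied d' roughly matches each group's reported task sensitivity
# (TD ~2.4, ASD ~1.7); ERP amplitudes/latencies follow the component loci and
# group windows; gait parameters follow the group-level stride geometry.
# These are generator settings, not estimates of any participant's data.
_TD_BEHAVIOR = {"S-NF-T": (0.94, 0.20, 348.0, 41.0),
                "W-NF-T": (0.95, 0.17, 352.0, 41.0),
                "W-F-T": (0.95, 0.17, 362.0, 41.0)}
_ASD_BEHAVIOR = {"S-NF-T": (0.89, 0.32, 353.0, 44.0),
                 "W-NF-T": (0.89, 0.32, 357.0, 44.0),
                 "W-F-T": (0.89, 0.32, 367.0, 44.0)}


def _erp_triplet(p2_amp, p2_lat, n2_amp, n2_lat, p3_amp, p3_lat):
    return [
        ErpComponentSpec("P2", p2_lat, p2_amp, 22.0, "FCz", 0.7),
        ErpComponentSpec("N2", n2_lat, n2_amp, 28.0, "FCz", 0.7),
        ErpComponentSpec("P3", p3_lat, p3_amp, 45.0, "CPz", 0.8),
    ]


_TD_ERP = {
    "Hit": _erp_triplet(4.0, 244.0, -2.5, 319.0, 5.0, 408.0),
    "CR": _erp_triplet(5.0, 240.0, -3.2, 327.0, 7.5, 420.0),
}
_ASD_ERP = {
    "Hit": _erp_triplet(3.5, 250.0, -2.3, 321.0, 4.5, 400.0),
    "CR": _erp_triplet(4.1, 247.0, -2.8, 328.0, 5.6, 412.0),
}
# Misses / FAs reuse the response class that shares the motor outcome
_TD_ERP["Miss"] = _TD_ERP["CR"]
_TD_ERP["FA"] = _TD_ERP["Hit"]
_ASD_ERP["Miss"] = _ASD_ERP["CR"]
_ASD_ERP["FA"] = _ASD_ERP["Hit"]


def _gait_for(group, cond):
    base = {
        "TD": dict(stride_time_mean_ms=1306.0, stride_time_cv=2.6,
                   stride_length_mean_mm=1237.0, stride_length_cv=2.23,
                   step_width_mean_mm=177.6, step_width_cv=9.2),
        "ASD": dict(stride_time_mean_ms=1306.0, stride_time_cv=3.83,
                    stride_length_mean_mm=1237.0, stride_length_cv=3.40,
                    step_width_mean_mm=218.9, step_width_cv=9.2),
    }[group]
    label = ConditionLabel.from_code(cond)
    if label.sensory == "flow":
        base["step_width_mean_mm"] += 3.6
        base["stride_time_mean_ms"] -= 8.0
        base["stride_length_mean_mm"] -= 7.0
        base["step_width_cv"] -= 0.4
    if label.has_task:
        base["stride_length_mean_mm"] -= 15.0
        base["stride_time_cv"] = max(0.5, base["stride_time_cv"] - 0.7)
        base["stride_length_cv"] = max(0.5, base["stride_length_cv"] - 0.5)
        base["step_width_cv"] -= 1.2
    return GaitParams(belt_speed_mms=1580.0, **base)


def default_scenario(n_td=18, n_asd=20, n_blocks=3, n_trials=180, seed=0,
                     noise_rms_uv=10.0, conditions=None):
    """Study-conforming scenario: two groups, five conditions, 180-trial blocks."""
    conditions = tuple(conditions or (c.code for c in STUDY_CONDITIONS))
    behavior, erp, gait = {}, {}, {}
    for group, table, erps in (("TD", _TD_BEHAVIOR, _TD_ERP),
                               ("ASD", _ASD_BEHAVIOR, _ASD_ERP)):
        behavior[group] = {
            code: BehaviorParams(*vals) for code, vals in table.items()
            if code in conditions
        }
        erp[group] = {code: dict(erps) for code in conditions}
        gait[group] = {
            code: _gait_for(group, code) for code in conditions
            if ConditionLabel.from_code(code).is_walking
        }
    return ScenarioSpec(
        n_subjects={"TD": n_td, "ASD": n_asd},
        behavior=behavior, erp=erp, gait=gait,
        conditions=conditions, n_blocks=n_blocks, n_trials=n_trials,
        noise_rms_uv=noise_rms_uv, seed=seed,
    )


def _block_seed(base_seed, *indices):
    """Deterministic child seed below 2**31 for a (subject, cond, block, role)."""
    ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, *indices])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def build_scenario(spec, out_dir, force=False, write_eeg_files=True):
    """Materialize a scenario as an on-disk synthetic study.

    Layout: ``subjects/<SUB>/<COND>/block_<k>.{bdf,events.tsv,markers.csv}``
    plus a top-level ``ground_truth.json`` and ``scenario_manifest.json``.
    Marker files are written only for walking conditions.  Refuses to write
    into an existing non-empty directory unless ``force``.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force)")
    out_dir.mkdir(parents=True, exist_ok=True)

    truth = {"seed": spec.seed, "subjects": {}}
    inventory = []
    subjects = [(g, f"{g.lower()}{i + 1:02d}")
                for g in sorted(spec.n_subjects)
                for i in range(spec.n_subjects[g])]
    for si, (group, sub) in enumerate(subjects):
        sub_truth = {"group": group, "conditions": {}}
        for ci, code in enumerate(spec.conditions):
            label = ConditionLabel.from_code(code, spec.permissive_conditions)
            cdir = out_dir / "subjects" / sub / code
            cdir.mkdir(parents=True, exist_ok=True)
            cond_truth = {"blocks": {}}
            for b in range(spec.n_blocks):
                block_truth = {}
                stream = generate_trial_stream(
                    spec.n_trials, spec.p_nogo, spec.isi_range_ms,
                    spec.stim_dur_ms, seed=_block_seed(spec.seed, si, ci, b, 0),
                )
                if label.has_task:
                    params = spec.behavior[group][code]
                    responses = simulate_behavior(
                        stream, params, seed=_block_seed(spec.seed, si, ci, b, 1)
                    )
                    block_truth["behavior_params"] = asdict(params)
                else:
                    responses = stream.copy()
                    responses["press_ms"] = np.nan

                events = pd.DataFrame({
                    "onset_sample": 0,  # filled after EEG render
                    "code": np.where(responses["stim"] == "Go",
                                     GO_CODE, NOGO_CODE),
                    "stim": responses["stim"],
                    "condition": code,
                    "onset_ms": responses["onset_ms"],
                    "press_ms": responses["press_ms"],
                })

                if write_eeg_files:
                    rec = simulate_eeg(
                        stream, responses,
                        components=spec.erp[group][code],
                        noise_rms=spec.noise_rms_uv,
                        seed=_block_seed(spec.seed, si, ci, b, 2),
                    )
                    write_eeg(rec, cdir / f"block_{b + 1}.bdf")
                    stim_events = [e for e in rec.events if e[1] != PRESS_CODE]
                    events["onset_sample"] = [e[0] for e in stim_events]
                    inventory.append(str(cdir / f"block_{b + 1}.bdf"))
                else:
                    events["onset_sample"] = np.round(
                        (events["onset_ms"] + 500.0) / 1000.0 * 512
                    ).astype(int)
                write_events_tsv(events, cdir / f"block_{b + 1}.events.tsv")
                inventory.append(str(cdir / f"block_{b + 1}.events.tsv"))

                if label.is_walking:
                    duration_s = (float(stream["onset_ms"].iloc[-1])
                                  + 2000.0) / 1000.0
                    markers, gait_truth = simulate_gait_markers(
                        spec.gait[group][code], duration_s,
                        seed=_block_seed(spec.seed, si, ci, b, 3),
                    )
                    write_markers(markers, cdir / f"block_{b + 1}.markers.csv")
                    inventory.append(str(cdir / f"block_{b + 1}.markers.csv"))
                    block_truth["gait"] = gait_truth
                    block_truth["gait_params"] = asdict(spec.gait[group][code])
                cond_truth["blocks"][str(b + 1)] = block_truth
            sub_truth["conditions"][code] = cond_truth
        truth["subjects"][sub] = sub_truth

    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    manifest = {
        "seed": spec.seed,
        "n_subjects": spec.n_subjects,
        "conditions": list(spec.conditions),
        "n_blocks": spec.n_blocks,
        "n_trials": spec.n_trials,
        "p_nogo": spec.p_nogo,
        "files": sorted(str(Path(p).relative_to(out_dir)) for p in inventory),
    }
    with open(out_dir / "scenario_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out_dir
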