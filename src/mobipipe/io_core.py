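"""Data model, file I/O, and configuration shared by all pipeline stages.

In-memory containers follow fixed unit and axis conventions: EEG voltages in
microvolts, marker positions in millimetres, event latencies as 0-based sample
indices (converted to milliseconds only at reporting time).  Marker axes are
x = mediolateral (positive right), y = vertical (positive up), z =
anterior-posterior (positive anterior, i.e. the direction of progression on
the treadmill).

EEG files are read with :mod:`mne` (EDF and BDF); written files use the
24-bit BDF layout produced by :func:`write_eeg`, with a ``Status`` channel
carrying the trigger codes.
"""

from __future__ import annotations

import hashlib
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigError,
    FormatError,
    MissingMarkerError,
    UnknownConfigKeyError,
)

__all__ = [
    "Recording",
    "MarkerStream",
    "ConditionLabel",
    "STUDY_CONDITIONS",
    "PipelineConfig",
    "read_eeg",
    "write_eeg",
    "read_markers",
    "write_markers",
    "read_events_tsv",
    "write_events_tsv",
    "load_config",
    "save_config",
    "config_hash",
    "write_results",
]

HEEL_MARKERS = ("left_heel", "right_heel")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    rate : float
        Sampling rate in samples per second.
    channel_labels : list of str
        Unique channel names (10-20 extended).
    events : list of (int, int)
        ``(sample_index, code)`` trigger events, 0-based sample indices.
    """

    samples: np.ndarray
    rate: float
    channel_labels: list
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match samples rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel_labels must be unique")
        n = self.samples.shape[1]
        for idx, _code in self.events:
            if not 0 <= idx < n:
                raise ValueError(f"event sample index {idx} outside [0, {n})")

    @property
    def n_channels(self):
        return self.samples.shape[0]

    @property
    def n_samples(self):
        return self.samples.shape[1]

    def copy(self):
        return Recording(
            self.samples.copy(), self.rate, list(self.channel_labels),
            [tuple(e) for e in self.events],
        )


@dataclass
class MarkerStream:
    """Motion-capture marker trajectories on a uniform time grid.

    ``markers`` maps a marker name to an ``(n_samples, 3)`` array of
    positions in millimetres with axes (x = mediolateral, y = vertical,
    z = anterior-posterior).
    """

    rate: float
    markers: dict

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        lengths = set()
        for name, trace in self.markers.items():
            trace = np.asarray(trace, dtype=float)
            if trace.ndim != 2 or trace.shape[1] != 3:
                raise ValueError(f"marker {name!r} must be an (n, 3) array")
            self.markers[name] = trace
            lengths.add(trace.shape[0])
        if len(lengths) > 1:
            raise ValueError("all marker traces must have equal length")

    @property
    def n_samples(self):
        for trace in self.markers.values():
            return trace.shape[0]
        return 0

    def times_ms(self):
        return np.arange(self.n_samples) * 1000.0 / self.rate

    def require_heels(self):
        missing = [m for m in HEEL_MARKERS if m not in self.markers]
        if missing:
            raise MissingMarkerError(missing)


_MOTOR = ("standing", "walking")
_SENSORY = ("no_flow", "flow")
_COGNITIVE = ("task", "no_task")

_CODE = {
    "standing": "S", "walking": "W",
    "no_flow": "NF", "flow": "F",
    "task": "T", "no_task": "NT",
}
_DECODE = {v: k for k, v in _CODE.items()}


@dataclass(frozen=True)
class ConditionLabel:
    """One experimental condition: motor x sensory x cognitive load."""

    motor: str
    sensory: str
    cognitive: str

    def __post_init__(self):
        if self.motor not in _MOTOR:
            raise ValueError(f"motor must be one of {_MOTOR}")
        if self.sensory not in _SENSORY:
            raise ValueError(f"sensory must be one of {_SENSORY}")
        if self.cognitive not in _COGNITIVE:
            raise ValueError(f"cognitive must be one of {_COGNITIVE}")

    @property
    def code(self):
        return "-".join(
            (_CODE[self.motor], _CODE[self.sensory], _CODE[self.cognitive])
        )

    @classmethod
    def from_code(cls, code, permissive=False):
        parts = code.strip().upper().split("-")
        if len(parts) != 3:
            raise ValueError(f"malformed condition code {code!r}")
        try:
            label = cls(_DECODE[parts[0]], _DECODE[parts[1]], _DECODE[parts[2]])
        except KeyError as exc:
            raise ValueError(f"malformed condition code {code!r}") from exc
        label.validate(permissive=permissive)
        return label

    def validate(self, permissive=False):
        """Reject combinations outside the five-condition study design.

        Standing with optic flow while performing the task (S-F-T) was not
        run; it is refused unless ``permissive`` is set.
        """
        if permissive:
            return self
        if self not in STUDY_CONDITIONS:
            raise ValueError(
                f"condition {self.code} is not part of the study design "
                f"(use permissive=True to allow)"
            )
        return self

    @property
    def has_task(self):
        return self.cognitive == "task"

    @property
    def is_walking(self):
        return self.motor == "walking"


STUDY_CONDITIONS = tuple(
    ConditionLabel.from_code(c, permissive=True)
    for c in ("S-NF-T", "W-NF-NT", "W-F-NT", "W-NF-T", "W-F-T")
)
TASK_CONDITIONS = tuple(c for c in STUDY_CONDITIONS if c.has_task)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Study defaults for every tunable pipeline parameter.
DEFAULT_CONFIG = {
    "filter": {"low_hz": 0.25, "high_hz": 40.0, "order": 4},
    "epoch": {
        "window_ms": [-100.0, 800.0],
        "baseline_ms": [-100.0, 0.0],
        "baseline_correct": True,
    },
    "peaks": {
        # canonical a-priori windows and measurement electrodes
        "P2": {"electrode": "FCz", "window_ms": [200.0, 280.0],
               "polarity": 1, "halfwidth_ms": 25.0},
        "N2": {"electrode": "FCz", "window_ms": [280.0, 380.0],
               "polarity": -1, "halfwidth_ms": 25.0},
        "P3": {"electrode": "CPz", "window_ms": [350.0, 500.0],
               "polarity": 1, "halfwidth_ms": 50.0},
    },
    "cluster": {"alpha": 0.05, "min_run": 10},
    "gait": {
        "min_stride_time_ms": 600.0,
        "min_prominence_mm": 20.0,
        "smooth_ms": 50.0,
        "smoothing": True,
    },
    "bad_channels": {"z_thresh": 3.5},
    "response": {"valid_window_ms": [100.0, 800.0]},
    "seed": 0,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with study defaults."""

    values: dict = field(default_factory=lambda: _deep_copy(DEFAULT_CONFIG))

    def __getitem__(self, key):
        return self.values[key]

    def to_dict(self):
        return _deep_copy(self.values)

    @classmethod
    def from_dict(cls, data):
        unknown = _unknown_keys(data, DEFAULT_CONFIG)
        if unknown:
            raise UnknownConfigKeyError(unknown)
        merged = _deep_merge(_deep_copy(DEFAULT_CONFIG), data)
        return cls(merged)


def _deep_copy(d):
    return json.loads(json.dumps(d))


def _unknown_keys(data, reference, prefix=""):
    unknown = []
    if not isinstance(data, dict):
        return unknown
    for key, val in data.items():
        path = f"{prefix}{key}"
        if key not in reference:
            unknown.append(path)
        elif isinstance(reference[key], dict):
            unknown.extend(_unknown_keys(val, reference[key], path + "."))
    return unknown


def _deep_merge(base, override):
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_merge(base[key], val)
        else:
            base[key] = val
    return base


def load_config(path):
    """Read a YAML config; absent keys get study defaults, unknown keys error."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return PipelineConfig.from_dict(data)


def save_config(config, path):
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config):
    """Stable hash of the configuration (canonical JSON, sorted keys)."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# EEG: BDF write, EDF/BDF read
# ---------------------------------------------------------------------------

_BDF_PHYS = 32768.0       # physical full scale, µV
_BDF_DIG = 8388607        # 24-bit signed full scale
_TRIGGER_HOLD = 8         # samples a trigger code is held on the Status line


def _ascii(value, width):
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _pack24(values):
    """Pack an int array into little-endian 24-bit two's complement bytes."""
    v = np.asarray(values, dtype=np.int32)
    u = np.where(v < 0, v + (1 << 24), v).astype(np.uint32)
    out = np.empty((u.size, 3), dtype=np.uint8)
    out[:, 0] = u & 0xFF
    out[:, 1] = (u >> 8) & 0xFF
    out[:, 2] = (u >> 16) & 0xFF
    return out.tobytes()


def write_eeg(recording, path):
    """Write a :class:`Recording` as a 24-bit BDF file.

    A ``Status`` channel is appended carrying each event code for a few
    samples starting at its onset sample.  Voltages are quantized at the
    ±32.768 mV physical range (~0.004 µV per bit).
    """
    path = Path(path)
    rec = recording
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("BDF writer requires an integer sampling rate")
    rate = int(round(rate))
    n_samples = rec.n_samples
    n_records = int(np.ceil(n_samples / rate)) if n_samples else 1
    padded = n_records * rate

    data = np.zeros((rec.n_channels, padded))
    data[:, :n_samples] = rec.samples

    status = np.zeros(padded, dtype=np.int32)
    events = sorted(rec.events)
    for i, (idx, code) in enumerate(events):
        stop = idx + _TRIGGER_HOLD
        if i + 1 < len(events):
            stop = min(stop, events[i + 1][0])
        status[idx:min(stop, padded)] = int(code)

    gain = 2 * _BDF_PHYS / (2 * _BDF_DIG + 1)
    digital = np.clip(np.round(data / gain), -_BDF_DIG - 1, _BDF_DIG)

    nchan = rec.n_channels + 1
    buf = io.BytesIO()
    buf.write(b"\xffBIOSEMI")
    buf.write(_ascii("mobipipe", 80))
    buf.write(_ascii("synthetic MoBI recording", 80))
    buf.write(_ascii("01.01.00", 8))
    buf.write(_ascii("00.00.00", 8))
    buf.write(_ascii(256 * (nchan + 1), 8))
    buf.write(_ascii("24BIT", 44))
    buf.write(_ascii(n_records, 8))
    buf.write(_ascii(1, 8))
    buf.write(_ascii(nchan, 4))

    labels = list(rec.channel_labels) + ["Status"]
    for lab in labels:
        buf.write(_ascii(lab, 16))
    for _ in labels:
        buf.write(_ascii("Active electrode", 80))
    for lab in labels:
        buf.write(_ascii("Boolean" if lab == "Status" else "uV", 8))
    for lab in labels:
        buf.write(_ascii(-_BDF_DIG - 1 if lab == "Status" else int(-_BDF_PHYS), 8))
    for lab in labels:
        buf.write(_ascii(_BDF_DIG if lab == "Status" else int(_BDF_PHYS), 8))
    for _ in labels:
        buf.write(_ascii(-_BDF_DIG - 1, 8))
    for _ in labels:
        buf.write(_ascii(_BDF_DIG, 8))
    for _ in labels:
        buf.write(_ascii("", 80))
    for _ in labels:
        buf.write(_ascii(rate, 8))
    for _ in labels:
        buf.write(_ascii("", 32))

    for r in range(n_records):
        sl = slice(r * rate, (r + 1) * rate)
        for ch in range(rec.n_channels):
            buf.write(_pack24(digital[ch, sl]))
        buf.write(_pack24(status[sl]))

    path.write_bytes(buf.getvalue())
    return path


def read_eeg(path, fmt=None):
    """Read an EDF or BDF file into a :class:`Recording` (µV).

    The trigger/``Status`` channel, when present, is decoded into events at
    the onset samples of nonzero code runs; a missing trigger channel yields
    a warning and an empty event list.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "bdf" if path.suffix.lower() == ".bdf" else "edf"
    if fmt not in ("edf", "bdf"):
        raise ValueError(f"format must be 'edf' or 'bdf', got {fmt!r}")
    reader = mne.io.read_raw_bdf if fmt == "bdf" else mne.io.read_raw_edf
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = reader(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"could not parse {path} as {fmt.upper()}: {exc}") from exc

    stim_names = [ch for ch in raw.ch_names
                  if ch.lower() in ("status", "trigger", "sti 014")]
    eeg_names = [ch for ch in raw.ch_names if ch not in stim_names]
    samples = raw.get_data(picks=eeg_names) * 1e6  # volts -> µV

    events = []
    if stim_names:
        stim = raw.get_data(picks=stim_names[:1])[0]
        codes = np.rint(stim).astype(np.int64) & 0xFFFF
        prev = np.concatenate([[0], codes[:-1]])
        onsets = np.nonzero((codes != 0) & (codes != prev))[0]
        events = [(int(i), int(codes[i])) for i in onsets]
    else:
        warnings.warn(f"{path.name}: no trigger channel found; events empty")

    return Recording(samples, float(raw.info["sfreq"]), eeg_names, events)


# ---------------------------------------------------------------------------
# markers CSV
# ---------------------------------------------------------------------------

_AXIS_NAMES = {"ml": 0, "vert": 1, "ap": 2}


def write_markers(stream, path, axes_comment=True):
    """Write a :class:`MarkerStream` as a long-format CSV.

    Columns are ``time`` (seconds), ``marker``, ``x``, ``y``, ``z`` in the
    package axis convention; a header comment records that convention.
    """
    path = Path(path)
    times = np.arange(stream.n_samples) / stream.rate
    frames = []
    for name in sorted(stream.markers):
        trace = stream.markers[name]
        frames.append(pd.DataFrame({
            "time": times, "marker": name,
            "x": trace[:, 0], "y": trace[:, 1], "z": trace[:, 2],
        }))
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        if axes_comment:
            fh.write("# axes: x=ml,y=vert,z=ap\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def _parse_axes_comment(line):
    """Parse '# axes: x=ml,y=vert,z=ap' into a (3,3) remap matrix."""
    spec = line.split(":", 1)[1].strip()
    mapping = np.zeros((3, 3))
    cols = {"x": 0, "y": 1, "z": 2}
    for part in spec.split(","):
        col, axis = part.strip().split("=")
        sign = 1.0
        axis = axis.strip().lower()
        if axis.startswith("-"):
            sign, axis = -1.0, axis[1:]
        if axis not in _AXIS_NAMES:
            raise FormatError(f"unknown axis name {axis!r} in axes comment")
        mapping[_AXIS_NAMES[axis], cols[col.strip().lower()]] = sign
    if not np.array_equal(np.abs(mapping).sum(0), np.ones(3)) or \
       not np.array_equal(np.abs(mapping).sum(1), np.ones(3)):
        raise FormatError("axes comment must map x,y,z onto ml,vert,ap exactly once")
    return mapping


def read_markers(path, require_heels=True):
    """Read a marker CSV into a :class:`MarkerStream`.

    The file must have columns ``time, marker, x, y, z`` on a uniform time
    grid; an optional leading ``# axes:`` comment declares the axis mapping
    (default ``x=ml,y=vert,z=ap``), which is remapped onto the package
    convention on read.
    """
    path = Path(path)
    remap = np.eye(3)
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line[1:].strip().lower().startswith("axes"):
                remap = _parse_axes_comment(line)
            skip += 1
    try:
        df = pd.read_csv(path, skiprows=skip)
    except Exception as exc:
        raise FormatError(f"could not parse {path} as marker CSV: {exc}") from exc
    required = {"time", "marker", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"marker CSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )

    markers = {}
    rate = None
    for name, grp in df.groupby("marker", sort=True):
        t = grp["time"].to_numpy(dtype=float)
        if len(t) < 2:
            raise FormatError(f"marker {name!r} has fewer than 2 samples")
        dt = np.diff(t)
        if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-6:
            raise FormatError(
                f"marker {name!r} timestamps are not on a uniform grid"
            )
        r = 1.0 / float(np.mean(dt))
        if rate is None:
            rate = r
        elif abs(r - rate) > 1e-6 * rate:
            raise FormatError("markers have inconsistent sampling rates")
        xyz = grp[["x", "y", "z"]].to_numpy(dtype=float)
        markers[str(name)] = xyz @ remap.T

    stream = MarkerStream(rate=float(rate), markers=markers)
    if require_heels:
        stream.require_heels()
    return stream


# ---------------------------------------------------------------------------
# events TSV
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["onset_sample", "code", "stim", "condition"]

#: trigger-code convention used throughout the package (the study's own
#: trigger table is not public): 1 = Go stimulus, 2 = NoGo stimulus,
#: 64 = button press.
GO_CODE, NOGO_CODE, PRESS_CODE = 1, 2, 64


def write_events_tsv(events_df, path):
    missing = [c for c in EVENT_COLUMNS if c not in events_df.columns]
    if missing:
        raise ValueError(f"events table lacks columns: {missing}")
    events_df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_events_tsv(path):
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"could not parse {path} as events TSV: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"events TSV lacks columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def write_results(tables, out_dir, seed=None, config=None, warnings_log=None):
    """Write tidy CSV tables plus a JSON run summary.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, table in tables.items():
        fname = f"{name}.csv"
        table.to_csv(out_dir / fname, index=False, float_format="%.12g")
        files[name] = fname
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "files": files,
        "warnings": list(warnings_log or []),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
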