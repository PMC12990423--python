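"""Go/NoGo trial classification, signal-detection d', and RT summaries.

Trials are classified into the four response types of a Go/NoGo task —
Hit (Go, valid press), Miss (Go, none), False Alarm (NoGo, valid press),
Correct Rejection (NoGo, none).  Sensitivity is the probit difference
d' = z(hit rate) - z(false-alarm rate), positive for above-chance
performance, with a selectable correction for extreme rates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["classify_trials", "dprime", "summarize_behavior"]

OUTCOMES = ("Hit", "Miss", "FA", "CR")

#: conditions in which the task was performed, in reporting order
TASK_CONDITION_CODES = ("S-NF-T", "W-NF-T", "W-F-T")


def classify_trials(stream, responses, valid_window_ms=(100.0, 800.0)):
    """Classify each trial of a stream given a list of press times.

    Parameters
    ----------
    stream : DataFrame
        Columns ``onset_ms`` (strictly increasing) and ``stim``
        (``Go``/``NoGo``); other columns are carried through.
    responses : sequence of float
        Absolute press times (ms), or a DataFrame with a ``press_ms``
        column (one press per trial, NaN for none) as produced by the
        simulator.
    valid_window_ms : (float, float)
        A press is attributed to the most recent stimulus onset; it counts
        only if its latency falls inside this window.  Earlier presses are
        flagged invalid and attributed to no trial, so a Go trial whose only
        press is anticipatory is a Miss.

    Returns
    -------
    DataFrame with ``response_latency_ms`` (NaN if none) and ``outcome``
    appended, plus ``n_invalid_presses`` recorded in ``.attrs``.
    """
    onsets = stream["onset_ms"].to_numpy(dtype=float)
    if len(onsets) == 0:
        raise ValueError("empty trial stream")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("trial onsets must be strictly increasing "
                         "(malformed stream)")
    if isinstance(responses, pd.DataFrame):
        presses = responses["press_ms"].to_numpy(dtype=float)
        presses = np.sort(presses[~np.isnan(presses)])
    else:
        presses = np.sort(np.asarray(list(responses), dtype=float))

    lo, hi = valid_window_ms
    latency = np.full(len(onsets), np.nan)
    n_invalid = 0
    for press in presses:
        idx = int(np.searchsorted(onsets, press, side="right")) - 1
        if idx < 0:
            n_invalid += 1
            continue
        lat = press - onsets[idx]
        if lat < lo:
            n_invalid += 1
            continue
        if lat > hi:
            continue  # outside every validity window: ignored
        if np.isnan(latency[idx]):  # first valid press wins
            latency[idx] = lat

    stim = stream["stim"].to_numpy()
    pressed = ~np.isnan(latency)
    outcome = np.where(
        stim == "Go",
        np.where(pressed, "Hit", "Miss"),
        np.where(pressed, "FA", "CR"),
    )
    out = stream.copy()
    out["response_latency_ms"] = latency
    out["outcome"] = outcome
    out.attrs["n_invalid_presses"] = n_invalid
    return out


def _adjust_rate(rate, n, correction):
    if correction == "loglinear":
        if rate in (0.0, 1.0):
            if n is None:
                raise ValueError("loglinear correction needs the trial count")
            count = rate * n
            return (count + 0.5) / (n + 1.0)
        return rate
    if correction == "clip":
        if n is None:
            raise ValueError("clip correction needs the trial count")
        return float(np.clip(rate, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)))
    if correction in (None, "none"):
        if rate in (0.0, 1.0):
            raise ValueError(
                "rate of 0 or 1 gives infinite d'; choose a correction"
            )
        return rate
    raise ValueError(f"unknown correction {correction!r}")


def dprime(hit_rate, fa_rate, n_go=None, n_nogo=None, correction="loglinear"):
    """Signal-detection sensitivity d' = z(hit) - z(false alarm).

    Extreme rates (0 or 1) are adjusted before the probit transform using
    the selected correction: ``loglinear`` maps a count of ``x`` out of
    ``n`` to ``(x + 0.5) / (n + 1)``; ``clip`` bounds rates to
    ``[1/(2n), 1 - 1/(2n)]``; ``none`` raises on extreme rates.
    """
    for name, rate in (("hit_rate", hit_rate), ("fa_rate", fa_rate)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    h = _adjust_rate(float(hit_rate), n_go, correction)
    f = _adjust_rate(float(fa_rate), n_nogo, correction)
    return float(norm.ppf(h) - norm.ppf(f))


def summarize_behavior(trials, correction="loglinear",
                       conditions=TASK_CONDITION_CODES):
    """Per-subject, per-condition behavioral summary table.

    ``trials`` must hold classified trials (from :func:`classify_trials`)
    with ``subject`` and ``condition`` columns; blocks belonging to the same
    condition pool together.  RT statistics are computed over Hits only.
    Cells without both Go and NoGo trials produce a row flagged ``missing``
    and a logged warning.
    """
    rows = []
    for (subject, condition), cell in trials.groupby(["subject", "condition"],
                                                     sort=True):
        if condition not in conditions:
            continue
        n_go = int((cell["stim"] == "Go").sum())
        n_nogo = int((cell["stim"] == "NoGo").sum())
        n_hit = int((cell["outcome"] == "Hit").sum())
        n_fa = int((cell["outcome"] == "FA").sum())
        if n_go == 0 or n_nogo == 0:
            warnings.warn(
                f"subject {subject} condition {condition}: empty Go or NoGo "
                f"cell; flagged missing"
            )
            rows.append({"subject": subject, "condition": condition,
                         "n_go": n_go, "n_nogo": n_nogo, "n_hit": n_hit,
                         "n_fa": n_fa, "hit_rate": np.nan, "fa_rate": np.nan,
                         "dprime": np.nan, "rt_mean_ms": np.nan,
                         "rt_sd_ms": np.nan, "missing": True})
            continue
        hit_rate = n_hit / n_go
        fa_rate = n_fa / n_nogo
        rts = cell.loc[cell["outcome"] == "Hit", "response_latency_ms"]
        rows.append({
            "subject": subject, "condition": condition,
            "n_go": n_go, "n_nogo": n_nogo, "n_hit": n_hit, "n_fa": n_fa,
            "hit_rate": hit_rate, "fa_rate": fa_rate,
            "dprime": dprime(hit_rate, fa_rate, n_go, n_nogo, correction),
            "rt_mean_ms": float(rts.mean()) if len(rts) else np.nan,
            "rt_sd_ms": float(rts.std(ddof=1)) if len(rts) > 1 else np.nan,
            "missing": False,
        })
    return pd.DataFrame(rows)
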