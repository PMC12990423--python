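"""End-to-end orchestration: behavior -> gait -> ERP -> stats on a study tree.

A study directory follows the layout written by
:func:`mobipipe.synth.build_scenario`::

    subjects/<SUB>/<COND>/block_<k>.bdf
    subjects/<SUB>/<COND>/block_<k>.events.tsv
    subjects/<SUB>/<COND>/block_<k>.markers.csv   (walking blocks only)

Each stage runs independently and fails atomically: a failure is logged in
the manifest and the remaining stages still produce their outputs.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import erp as erpmod
from . import gait as gaitmod
from . import stats as statsmod
from .io_core import (
    ConditionLabel,
    PipelineConfig,
    read_eeg,
    read_events_tsv,
    read_markers,
    write_results,
)
from .synth import electrode_layout

__all__ = ["discover_study", "run_all", "report_summary"]

TASK_CONDITIONS = ("S-NF-T", "W-NF-T", "W-F-T")
WALK_CONDITIONS = ("W-NF-NT", "W-F-NT", "W-NF-T", "W-F-T")
COMPONENTS = ("P2", "N2", "P3")


def discover_study(study_dir):
    """Inventory a study tree: one row per block with available file paths."""
    study_dir = Path(study_dir)
    root = study_dir / "subjects"
    if not root.is_dir():
        raise FileNotFoundError(f"no subjects/ directory under {study_dir}")
    groups = {}
    gt_path = study_dir / "ground_truth.json"
    if gt_path.exists():
        with open(gt_path) as fh:
            gt = json.load(fh)
        groups = {s: d["group"] for s, d in gt.get("subjects", {}).items()}
    rows = []
    for sub_dir in sorted(root.iterdir()):
        if not sub_dir.is_dir():
            continue
        sub = sub_dir.name
        group = groups.get(sub)
        if group is None:
            m = re.match(r"([A-Za-z]+)", sub)
            group = m.group(1).upper() if m else "UNKNOWN"
        for cond_dir in sorted(sub_dir.iterdir()):
            if not cond_dir.is_dir():
                continue
            code = cond_dir.name
            ConditionLabel.from_code(code, permissive=True)
            for ev in sorted(cond_dir.glob("block_*.events.tsv")):
                block = int(ev.name.split("_")[1].split(".")[0])
                stem = ev.with_suffix("").with_suffix("")  # strip .events.tsv
                rows.append({
                    "subject": sub, "group": group, "condition": code,
                    "block": block,
                    "events": str(ev),
                    "eeg": str(stem) + ".bdf"
                    if (cond_dir / f"block_{block}.bdf").exists() else None,
                    "markers": str(stem) + ".markers.csv"
                    if (cond_dir / f"block_{block}.markers.csv").exists()
                    else None,
                })
    if not rows:
        raise FileNotFoundError(f"no blocks found under {study_dir}")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _behavior_stage(inventory, config):
    valid = tuple(config["response"]["valid_window_ms"])
    frames = []
    for row in inventory.itertuples(index=False):
        if row.condition not in TASK_CONDITIONS:
            continue
        events = read_events_tsv(row.events)
        stream = events.rename(columns={"onset_ms": "onset_ms"})
        presses = events["press_ms"].dropna().to_numpy() \
            if "press_ms" in events else []
        trials = beh.classify_trials(stream, presses, valid)
        trials["subject"] = row.subject
        trials["group"] = row.group
        trials["block"] = row.block
        frames.append(trials)
    if not frames:
        raise ValueError("no task-condition events found")
    trials = pd.concat(frames, ignore_index=True)
    summary = beh.summarize_behavior(trials)
    groups = trials.drop_duplicates("subject").set_index("subject")["group"]
    summary["group"] = summary["subject"].map(groups)

    anovas = []
    usable = summary[~summary["missing"]]
    for dv, label in (("dprime", "dprime"), ("rt_mean_ms", "rt")):
        cell = usable.pivot_table(index="subject", columns="condition",
                                  values=dv)
        if set(cell.columns) != set(TASK_CONDITIONS):
            warnings.warn(f"behavior ANOVA for {label} skipped: not all "
                          f"task conditions present")
            continue
        complete = cell.dropna().index
        data = usable[usable["subject"].isin(complete)]
        if data["group"].nunique() == 2 and len(complete) >= 4:
            tab = statsmod.mixed_rm_anova(
                data, dv, "subject", "condition", "group",
                order={"condition": list(TASK_CONDITIONS)},
            )
            tab.insert(0, "measure", label)
            anovas.append(tab)
    return summary, anovas


def _gait_stage(inventory, config):
    gcfg = config["gait"]
    smooth = gcfg["smooth_ms"] if gcfg["smoothing"] else 0.0
    blocks = []
    qc = {}
    for row in inventory.itertuples(index=False):
        if row.markers is None:
            continue
        stream = read_markers(row.markers)
        events = gaitmod.analyze_marker_stream(
            stream, gcfg["min_stride_time_ms"], gcfg["min_prominence_mm"],
            smooth,
        )
        blocks.append((row.subject, row.condition, row.block, events))
        qc[f"{row.subject}/{row.condition}/block_{row.block}"] = \
            gaitmod.gait_qc(events)
    if not blocks:
        raise ValueError("no marker files found (standing-only study?)")
    block_table, cond_table = gaitmod.summarize_gait(blocks)
    groups = inventory.drop_duplicates("subject").set_index("subject")["group"]
    block_table["group"] = block_table["subject"].map(groups)
    cond_table["group"] = cond_table["subject"].map(groups)

    # 2 (flow) x 2 (task) within design over the four walking conditions
    walk = cond_table[cond_table["condition"].isin(WALK_CONDITIONS)].copy()
    walk["flow"] = np.where(
        walk["condition"].str.contains("-F-"), "flow", "no_flow")
    walk["task"] = np.where(
        walk["condition"].str.endswith("-NT"), "no_task", "task")
    anovas = []
    complete = walk.pivot_table(index="subject", columns=["flow", "task"],
                                values="stride_time_mean_ms")
    subjects = complete.dropna().index
    data = walk[walk["subject"].isin(subjects)]
    if len(complete.columns) != 4:
        warnings.warn("gait ANOVA skipped: not all four walking conditions "
                      "present")
    elif data["group"].nunique() == 2 and len(subjects) >= 4:
        for dv in gaitmod.GAIT_VARIABLES:
            tab = statsmod.mixed_rm_anova(
                data, dv, "subject", ["flow", "task"], "group",
                order={"flow": ["no_flow", "flow"],
                       "task": ["no_task", "task"]},
            )
            tab.insert(0, "measure", dv)
            anovas.append(tab)
    return block_table, cond_table, anovas, qc


def _classify_block_trials(events, valid):
    presses = events["press_ms"].dropna().to_numpy() \
        if "press_ms" in events else []
    return beh.classify_trials(events, presses, valid)


def _erp_stage(inventory, config):
    layout = electrode_layout()
    fcfg = config["filter"]
    ecfg = config["epoch"]
    valid = tuple(config["response"]["valid_window_ms"])
    z_thresh = config["bad_channels"]["z_thresh"]

    # running per-subject sums of epoch averages, keyed by (cond, rtype)
    acc = {}
    groups = {}
    channel_labels = None
    time_ms = None
    bad_log = {}
    for row in inventory.itertuples(index=False):
        if row.eeg is None or row.condition not in TASK_CONDITIONS:
            continue
        rec = read_eeg(row.eeg)
        rec = erpmod.bandpass(rec, fcfg["low_hz"], fcfg["high_hz"],
                              fcfg["order"])
        rec = erpmod.average_reference(rec)
        rec, bad = erpmod.detect_and_interpolate_bad(rec, layout, z_thresh)
        if bad:
            bad_log[f"{row.subject}/{row.condition}/{row.block}"] = bad

        events = read_events_tsv(row.events)
        trials = _classify_block_trials(events, valid)
        onsets = trials["onset_sample"].to_numpy(dtype=int)
        meta = pd.DataFrame({
            "subject": row.subject,
            "group": row.group,
            "condition": row.condition,
            "response_type": trials["outcome"],
        })
        epochs = erpmod.epoch(
            rec, onsets, tuple(ecfg["window_ms"]),
            baseline=ecfg["baseline_correct"],
            baseline_ms=tuple(ecfg["baseline_ms"]),
            metadata=meta,
        )
        channel_labels = epochs.channel_labels
        time_ms = epochs.time_ms
        groups[row.subject] = row.group
        for rtype in ("Hit", "CR"):
            sel = epochs.select(response_type=rtype)
            if sel.n_trials == 0:
                continue
            key = (row.subject, row.condition, rtype)
            total, count = acc.get(key, (0.0, 0))
            acc[key] = (total + sel.data.sum(axis=0), count + sel.n_trials)
    if not acc:
        raise ValueError("no EEG blocks found for task conditions")

    subj_avg = {key: total / count for key, (total, count) in acc.items()}

    # group grand averages (subject means first, then unweighted mean)
    grand = {}
    for (sub, cond, rtype), wave in subj_avg.items():
        grand.setdefault((groups[sub], cond, rtype), []).append(wave)
    grand = {k: np.mean(v, axis=0) for k, v in grand.items()}

    # two-pass windows per group, on the average across task conditions
    windows = {}
    for group in sorted(set(groups.values())):
        waves = [w for (g, _c, _r), w in grand.items() if g == group]
        windows[group] = erpmod.two_pass_peak_windows(
            np.mean(waves, axis=0), time_ms, channel_labels)

    rows = []
    for (sub, cond, rtype), wave in sorted(subj_avg.items()):
        group = groups[sub]
        for comp in COMPONENTS:
            spec = windows[group][comp]
            peak = erpmod.find_peak(
                wave, time_ms, spec["window_ms"], spec["polarity"],
                electrode=spec["electrode"], component=comp,
                channel_labels=channel_labels,
            )
            rows.append({
                "subject": sub, "group": group, "condition": cond,
                "response_type": rtype, "component": comp,
                "electrode": spec["electrode"],
                "window_lo_ms": spec["window_ms"][0],
                "window_hi_ms": spec["window_ms"][1],
                "peak_amplitude_uv": peak.peak_amplitude_uv,
                "peak_latency_ms": peak.peak_latency_ms,
                "at_edge": peak.at_edge,
            })
    measures = pd.DataFrame(rows)

    anovas = []
    for comp in COMPONENTS:
        for dv, label in (("peak_amplitude_uv", "amplitude"),
                          ("peak_latency_ms", "latency")):
            sub_tab = measures[measures["component"] == comp]
            cells = sub_tab.pivot_table(
                index="subject", columns=["response_type", "condition"],
                values=dv)
            subjects = cells.dropna().index
            data = sub_tab[sub_tab["subject"].isin(subjects)]
            if len(cells.columns) != 2 * len(TASK_CONDITIONS):
                continue  # not every response type x condition observed
            if data["group"].nunique() == 2 and len(subjects) >= 4:
                tab = statsmod.mixed_rm_anova(
                    data, dv, "subject", ["response_type", "condition"],
                    "group",
                    order={"response_type": ["Hit", "CR"],
                           "condition": list(TASK_CONDITIONS)},
                )
                tab.insert(0, "measure", f"{comp}_{label}")
                anovas.append(tab)

    # cluster suite on per-subject averages
    cells = {}
    for (sub, cond, rtype), wave in subj_avg.items():
        cells.setdefault((groups[sub], cond), {}).setdefault(
            rtype, {})[sub] = wave
    suite_cells = {}
    for key, d in cells.items():
        if "Hit" in d and "CR" in d:
            subs = sorted(set(d["Hit"]) & set(d["CR"]))
            if subs:
                suite_cells[key] = {
                    "Hit": np.stack([d["Hit"][s] for s in subs]),
                    "CR": np.stack([d["CR"][s] for s in subs]),
                }
    ccfg = config["cluster"]
    maps = statsmod.cluster_contrast_suite(
        suite_cells, groups=tuple(sorted(set(groups.values()))),
        conditions=TASK_CONDITIONS, alpha=ccfg["alpha"],
        min_run=ccfg["min_run"], channel_labels=channel_labels,
        time_ms=time_ms,
    )

    # difference waves and their 50 ms topographic segment means
    topo_rows = []
    for (group, cond) in sorted(suite_cells):
        dw = erpmod.difference_wave(
            grand[(group, cond, "CR")], grand[(group, cond, "Hit")])
        seg, edges = erpmod.topo_segments(dw, time_ms)
        for b, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            for ci, ch in enumerate(channel_labels):
                topo_rows.append({
                    "group": group, "condition": cond, "bin_lo_ms": lo,
                    "bin_hi_ms": hi, "channel": ch,
                    "mean_uv": seg[b, ci],
                })
    topo = pd.DataFrame(topo_rows)
    return measures, anovas, maps, topo, bad_log, channel_labels, time_ms


def _write_cluster_maps(maps, out_dir, channel_labels, time_ms):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = {}
    for key, cmap in maps.items():
        stem = "__".join(str(k) for k in key).replace("-", "")
        for kind, arr in (("t", cmap.t_values), ("p", cmap.p_values),
                          ("mask", cmap.mask.astype(int))):
            df = pd.DataFrame(arr, index=channel_labels,
                              columns=np.round(time_ms, 3))
            df.to_csv(out_dir / f"{stem}.{kind}.csv")
        index[stem] = {
            "contrast": cmap.contrast, "alpha": cmap.alpha,
            "min_run": cmap.min_run,
            "n_significant": cmap.n_significant,
        }
    with open(out_dir / "index.json", "w") as fh:
        json.dump(index, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_all(study_dir, out_dir, config=None, seed=None):
    """Run every stage on a study tree and write the results directory.

    Produces ``behavior.csv``, ``gait_blocks.csv``, ``gait_conditions.csv``,
    ``erp_measures.csv``, ``anova_tables.csv``, ``cluster_maps/``,
    ``topo_segments.csv``, and ``manifest.json``.  A stage that raises is
    recorded in the manifest and the remaining stages still run.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inventory = discover_study(study_dir)

    tables = {}
    anova_frames = []
    stage_status = {}
    warn_log = []

    def run_stage(name, fn):
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                result = fn()
            warn_log.extend(f"{name}: {w.message}" for w in caught)
            stage_status[name] = "ok"
            return result
        except Exception as exc:  # stage isolation
            stage_status[name] = f"failed: {exc}"
            return None

    res = run_stage("behavior", lambda: _behavior_stage(inventory, config))
    if res is not None:
        summary, anovas = res
        tables["behavior"] = summary
        for tab in anovas:
            tab.insert(0, "stage", "behavior")
        anova_frames.extend(anovas)

    res = run_stage("gait", lambda: _gait_stage(inventory, config))
    if res is not None:
        block_table, cond_table, anovas, qc = res
        tables["gait_blocks"] = block_table
        tables["gait_conditions"] = cond_table
        for tab in anovas:
            tab.insert(0, "stage", "gait")
        anova_frames.extend(anovas)
        with open(out_dir / "gait_qc.json", "w") as fh:
            json.dump(qc, fh, indent=1, sort_keys=True)

    res = run_stage("erp", lambda: _erp_stage(inventory, config))
    if res is not None:
        measures, anovas, maps, topo, bad_log, ch_labels, time_ms = res
        tables["erp_measures"] = measures
        tables["topo_segments"] = topo
        for tab in anovas:
            tab.insert(0, "stage", "erp")
        anova_frames.extend(anovas)
        _write_cluster_maps(maps, out_dir / "cluster_maps", ch_labels,
                            time_ms)
        if bad_log:
            warn_log.append(f"erp: interpolated bad channels {bad_log}")

    if anova_frames:
        tables["anova_tables"] = pd.concat(anova_frames, ignore_index=True)

    manifest = write_results(tables, out_dir, seed=seed, config=config,
                             warnings_log=warn_log)
    manifest["stages"] = stage_status
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def report_summary(results_dir, alpha=0.05):
    """Human-readable effect grid from a results directory.

    One row per dependent variable, one column per effect; entries are the
    GG-corrected p-values of effects significant at ``alpha`` (blank
    otherwise, ``.`` for effects absent from a partial run).  Returns the
    formatted string; raises ``FileNotFoundError`` on an empty results
    directory.
    """
    results_dir = Path(results_dir)
    path = results_dir / "anova_tables.csv"
    if not path.exists():
        raise FileNotFoundError(f"no results found in {results_dir}")
    tab = pd.read_csv(path)
    grid = {}
    effects = []
    for (stage, measure), sub in tab.groupby(["stage", "measure"],
                                             sort=True):
        row = {}
        for rec in sub.itertuples(index=False):
            if rec.effect not in effects:
                effects.append(rec.effect)
            row[rec.effect] = rec.p_gg
        grid[f"{stage}:{measure}"] = row
    lines = []
    header = ["measure"] + effects
    lines.append("\t".join(header))
    for measure, row in grid.items():
        cells = [measure]
        for eff in effects:
            p = row.get(eff)
            if p is None:
                cells.append(".")
            elif p < alpha:
                cells.append(f"{p:.3g}")
            else:
                cells.append("")
        lines.append("\t".join(cells))
    return "\n".join(lines)
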