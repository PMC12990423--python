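"""Shared helpers for recovery-style property tests."""

import numpy as np

from mobipipe.erp import find_peak
from mobipipe.synth import ErpComponentSpec, generate_trial_stream, \
    simulate_eeg


def erp_peak_recovery_errors(n_seeds=50, n_trials=200, rms=0.75,
                             amp=4.0, latency=240.0):
    """Amplitude/latency recovery errors of an injected fronto-central bump.

    Moderate background noise so that the tolerances probe systematic error
    of the epoching + peak-measurement chain rather than irreducible
    latency jitter of a wide component under broadband noise.
    Returns ``(amp_errors, lat_errors, analytic_se)``.
    """
    spec = ErpComponentSpec("P2", latency, amp, 22.0, "FCz", 0.7)
    amp_errors, lat_errors = [], []
    for seed in range(n_seeds):
        stream = generate_trial_stream(n_trials, 0.0, seed=seed)
        rec = simulate_eeg(stream, components=[spec], noise_rms=rms,
                           seed=1000 + seed)
        ch = rec.channel_labels.index("FCz")
        onsets = np.array([s for s, c in rec.events if c in (1, 2)])
        pre = 51
        trials = np.stack([rec.samples[ch, o - pre:o + 410] for o in onsets])
        avg = trials.mean(axis=0)
        t_ms = (np.arange(461) - pre) / 512 * 1000
        avg -= avg[t_ms <= 0].mean()
        peak = find_peak(avg, t_ms, (200, 280), 1)
        amp_errors.append(peak.peak_amplitude_uv - amp)
        lat_errors.append(peak.peak_latency_ms - latency)
    return np.array(amp_errors), np.array(lat_errors), rms / np.sqrt(n_trials)
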