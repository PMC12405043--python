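"""Intermuscular coherence: detecting a shared 20 Hz drive.

Two cohorts of 8 synthetic participants each: one whose motor pools share
80% of a 20 Hz (beta-band) oscillatory drive, one with fully independent
drives.  For each trial the steadiest 4 s of channel-1 EMG from both
muscles is enveloped (20 Hz high-pass, unit variance, analytic-signal
magnitude), cut into eight 460 ms segments, and pooled coherence is
estimated per cohort with its 95% confidence limit (CL).
"""

import numpy as np

from neuropinch import (CommonDriveSpec, ProtocolSpec, band_average,
                        estimate_spectra, find_steadiest_window,
                        generate_pool, pool_coherence, preprocess_envelope,
                        simulate_trial)

protocol = ProtocolSpec()


def cohort_pooled(strength, base_seed):
    drive = CommonDriveSpec(band_center=20.0, strength=strength)
    specs = []
    for p in range(8):
        pools = {"APB": generate_pool(12, seed=base_seed + p),
                 "FDS": generate_pool(12, seed=base_seed + 100 + p)}
        trial = simulate_trial(pools, drive, protocol, 0.35,
                               seed=base_seed + 200 + p)
        win = find_steadiest_window(trial.force_trace())
        specs.append(estimate_spectra(
            preprocess_envelope(trial.emg["APB"][0], win, protocol.emg_fs),
            preprocess_envelope(trial.emg["FDS"][0], win, protocol.emg_fs)))
    return pool_coherence(specs)


for name, strength in (("shared beta drive", 0.8), ("independent drives", 0.0)):
    pooled = cohort_pooled(strength, base_seed=400)
    bands = {b.band: b.mean_r2 for b in band_average(pooled)}
    mask = (pooled.freqs >= 8) & (pooled.freqs < 60)
    n_sig = int(pooled.significant[mask].sum())
    idx = np.flatnonzero(mask)[np.argmax(pooled.r2[mask])]
    print(f"{name:20s} CL={pooled.cl:.3f}  "
          + "  ".join(f"{k}={v:.3f}" for k, v in bands.items())
          + f"  peak {pooled.r2[idx]:.3f} @ {pooled.freqs[idx]:.1f} Hz"
          + f"  significant bins: {n_sig}")
# The shared drive produces a coherence peak at the bin nearest 20 Hz,
# well above the confidence limit; without sharing, only chance-level
# crossings (~5% of bins) remain and the peak sits near CL.
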