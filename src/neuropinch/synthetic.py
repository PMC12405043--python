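"""Synthetic motor-neuron-pool cohort generator.

Emulates an isometric five-finger pinch protocol: trapezoidal contractions
(2 s ramp, 10 s hold, 2 s ramp-down) at 15/35/55/70% of maximal voluntary
contraction (MVC), three repeats per level, with two muscles (analogues of
abductor pollicis brevis, APB, and flexor digitorum superficialis, FDS).
Each muscle is driven by a rate-coded motor-neuron pool: units recruit in
threshold order (size principle), fire at a rate linear in excess drive,
and contribute a twitch to force and a motor-unit action potential (MUAP)
to four surface-EMG channels sampled at 2222 Hz with a 20-450 Hz bandwidth.

Intermuscular coherence has a physiological origin here: an oscillatory,
band-limited common drive can be injected *pre-pool* — a fraction
``strength`` of the oscillatory drive variance is shared between the two
muscles' pools — so coherent content appears in the EMG because the motor
neurons themselves receive shared synaptic input, not because EMG channels
were mixed after the fact.

The drive command tracks the target closed-loop style: the excitation sent
to each pool is the inverse of that pool's analytic static
force-vs-excitation curve applied to the target profile, mimicking a
participant matching the on-screen force trace.  Consequently (a) mean
force tracks the target at every level, and (b) a unit's recruitment
threshold can be reported directly in force units (% MVC), which is what
threshold-detection downstream is compared against.

All randomness flows from a single integer seed through splittable
``numpy`` SeedSequences (one branch per participant/trial/muscle), so any
trial is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

from .firing import SpikeTrain
from .force import ForceTrace

__all__ = [
    "ProtocolSpec",
    "MotorUnitSpec",
    "CommonDriveSpec",
    "GroupSpec",
    "SyntheticTrial",
    "generate_pool",
    "pool_force_curve",
    "simulate_trial",
    "simulate_participant",
    "generate_cohort",
    "default_groups",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing and acquisition parameters of the pinch protocol."""

    force_levels: tuple[float, ...] = (0.15, 0.35, 0.55, 0.70)
    ramp_s: float = 2.0
    hold_s: float = 10.0
    repeats_per_level: int = 3
    emg_fs: float = 2222.0
    force_fs: float = 1000.0
    emg_band: tuple[float, float] = (20.0, 450.0)
    pre_s: float = 0.5
    post_s: float = 0.5

    def __post_init__(self):
        if self.ramp_s <= 0 or self.hold_s <= 0:
            raise ValueError("ramp and hold durations must be positive")
        if not all(0 < l <= 1 for l in self.force_levels):
            raise ValueError("force levels must lie in (0, 1]")
        if self.emg_fs <= 2 * self.emg_band[1]:
            raise ValueError("emg_fs must exceed twice the band upper edge")

    @property
    def duration(self) -> float:
        return self.pre_s + 2 * self.ramp_s + self.hold_s + self.post_s

    @property
    def hold_start(self) -> float:
        return self.pre_s + self.ramp_s

    @property
    def hold_end(self) -> float:
        return self.hold_start + self.hold_s

    def target_fraction(self, t: np.ndarray, level: float) -> np.ndarray:
        """Trapezoidal target profile in fraction-of-MVC units."""
        up0, up1 = self.pre_s, self.pre_s + self.ramp_s
        dn0 = self.hold_end
        dn1 = dn0 + self.ramp_s
        out = np.zeros_like(t)
        out = np.where((t >= up0) & (t < up1), level * (t - up0) / self.ramp_s, out)
        out = np.where((t >= up1) & (t < dn0), level, out)
        out = np.where((t >= dn0) & (t < dn1), level * (1 - (t - dn0) / self.ramp_s), out)
        return out


@dataclass(frozen=True)
class MotorUnitSpec:
    """One motor unit of a rate-coded pool.

    ``recruitment_threshold`` is expressed as the fraction of MVC at which
    the unit starts firing (mapped through the pool's static
    force-excitation curve); ``excitation_threshold`` is the same point in
    excitation units.  Twitches follow the classic first-order impulse
    shape P·(t/T)·exp(1−t/T); MUAPs are biphasic (derivative-of-Gaussian)
    kernels of 5-15 ms support whose amplitude grows with unit size.
    """

    recruitment_threshold: float
    excitation_threshold: float
    peak_rate: float
    min_rate: float
    isi_cv: float
    twitch_amplitude: float
    twitch_contraction_time: float
    muap_duration_s: float
    muap_amplitude: float

    def __post_init__(self):
        if not 0 <= self.recruitment_threshold < 1:
            raise ValueError("recruitment threshold must be in [0, 1)")
        if self.min_rate >= self.peak_rate:
            raise ValueError("min_rate must be below peak_rate")
        if not 0 <= self.isi_cv <= 0.3:
            raise ValueError("isi_cv must be in [0, 0.3]")

    #: excitation at which every unit reaches its peak rate; kept above the
    #: working range so drive noise around full excitation rarely saturates
    E_SAT = 1.2

    def rate_at(self, e: float | np.ndarray) -> np.ndarray:
        """Firing rate (Hz) at excitation e; 0 below threshold, linear in
        excess drive, saturating at peak_rate (reached at e = E_SAT)."""
        gain = (self.peak_rate - self.min_rate) / max(
            1e-9, self.E_SAT - self.excitation_threshold)
        r = self.min_rate + gain * (np.asarray(e, dtype=float) - self.excitation_threshold)
        r = np.clip(r, None, self.peak_rate)
        return np.where(np.asarray(e) >= self.excitation_threshold, r, 0.0)

    def muap_kernel(self, fs: float) -> np.ndarray:
        """Biphasic MUAP waveform sampled at ``fs``."""
        half = self.muap_duration_s / 2
        t = np.arange(-half, half, 1.0 / fs)
        sigma = self.muap_duration_s / 6
        w = -t / sigma * np.exp(0.5 - t ** 2 / (2 * sigma ** 2))
        return self.muap_amplitude * w

    def twitch_kernel(self, fs: float) -> np.ndarray:
        """Twitch force impulse response P·(t/T)·exp(1−t/T) sampled at fs."""
        T = self.twitch_contraction_time
        t = np.arange(0, 5 * T, 1.0 / fs)
        return self.twitch_amplitude * (t / T) * np.exp(1 - t / T)


@dataclass(frozen=True)
class CommonDriveSpec:
    """Band-limited oscillatory drive partly shared between the pools.

    ``strength`` is the fraction of the oscillatory drive variance common
    to both muscles (0 = fully independent, 1 = identical); ``sd`` is the
    oscillatory amplitude in excitation (fraction-of-MVC-equivalent) units.
    """

    band_center: float = 20.0
    band_width: float = 6.0
    strength: float = 0.0
    sd: float = 0.10
    broadband_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.strength <= 1:
            raise ValueError("strength must be in [0, 1]")
        lo = self.band_center - self.band_width / 2
        hi = self.band_center + self.band_width / 2
        if lo <= 0 or hi > 110:
            raise ValueError("drive band must lie within 0-110 Hz")


# ---------------------------------------------------------------------------
# pool construction
# ---------------------------------------------------------------------------

RECRUIT_RANGE = 30.0      # ratio of last to first excitation threshold slope
MAX_THRESHOLD = 0.6       # excitation threshold of the last-recruited unit
TWITCH_RANGE = 30.0       # twitch-amplitude ratio across the pool
PEAK_RATE_FIRST = 35.0    # Hz, earliest-recruited unit
PEAK_RATE_LAST = 25.0     # Hz, last-recruited unit
MIN_RATE = 8.0            # Hz at recruitment


def generate_pool(n_units: int, mvc_scale: float = 120.0, seed: int = 0,
                  isi_cv: float = 0.15,
                  max_threshold: float = MAX_THRESHOLD) -> list[MotorUnitSpec]:
    """Build a rate-coded pool with exponentially spaced thresholds.

    Excitation thresholds follow t_i = t_max·(exp(a·i/(n−1)) − 1)/(exp(a) − 1)
    with a = ln(30), so the first unit recruits at zero drive and spacing
    widens exponentially (many low-threshold, few high-threshold units).
    Twitch amplitude grows ~30-fold across the pool while contraction time
    shrinks 90 -> 30 ms; peak firing rate declines 35 -> 25 Hz.  MUAP
    amplitude scales with twitch amplitude^0.6 and support grows 5 -> 15 ms
    (small per-unit jitter).  Deterministic for a fixed seed.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    rng = np.random.default_rng(seed)
    a = np.log(RECRUIT_RANGE)
    if n_units == 1:
        exc = np.array([0.0])
    else:
        i = np.arange(n_units)
        exc = max_threshold * (np.exp(a * i / (n_units - 1)) - 1) / (np.exp(a) - 1)
    rel = exc / max_threshold
    twitch_amp = (mvc_scale / 120.0) * np.exp(np.log(TWITCH_RANGE) * rel)
    twitch_ct = 0.06 * 3.0 ** (-rel)  # 60 ms slow units -> 20 ms fast units
    peak = PEAK_RATE_FIRST + (PEAK_RATE_LAST - PEAK_RATE_FIRST) * rel
    muap_dur = (5e-3 + 10e-3 * rel) * rng.uniform(0.9, 1.1, n_units)
    muap_amp = twitch_amp ** 0.6 * rng.uniform(0.9, 1.1, n_units)

    # provisional specs (force-fraction thresholds filled after the curve)
    units = [MotorUnitSpec(recruitment_threshold=float(exc[i]) * 0.999,
                           excitation_threshold=float(exc[i]),
                           peak_rate=float(peak[i]), min_rate=MIN_RATE,
                           isi_cv=isi_cv,
                           twitch_amplitude=float(twitch_amp[i]),
                           twitch_contraction_time=float(twitch_ct[i]),
                           muap_duration_s=float(muap_dur[i]),
                           muap_amplitude=float(muap_amp[i]))
             for i in range(n_units)]
    e_grid, f_norm = pool_force_curve(units)
    return [replace(u, recruitment_threshold=float(
                np.interp(u.excitation_threshold, e_grid, f_norm)))
            for u in units]


def pool_force_curve(units: Sequence[MotorUnitSpec],
                     n_grid: int = 2001) -> tuple[np.ndarray, np.ndarray]:
    """Static normalised force-vs-excitation curve of a pool.

    A unit firing steadily at rate r delivers a mean force of
    r·P·T·e (the twitch integral), so the pool's static output at
    excitation e is F(e) = Σ_u r_u(e)·P_u·T_u·e.  Returns the excitation
    grid on [0, 1] and F(e)/F(1), which is monotone non-decreasing.
    """
    e_grid = np.linspace(0.0, 1.0, n_grid)
    F = np.zeros_like(e_grid)
    for u in units:
        F += u.rate_at(e_grid) * u.twitch_amplitude * u.twitch_contraction_time * np.e
    F1 = F[-1]
    return e_grid, F / F1


def _excitation_for_target(target_frac: np.ndarray,
                           e_grid: np.ndarray, f_norm: np.ndarray) -> np.ndarray:
    """Invert the static curve: excitation producing each target force."""
    # f_norm is non-decreasing; np.interp needs strictly usable x -> swap axes
    return np.interp(target_frac, f_norm, e_grid)


def _band_noise(n: int, fs: float, center: float, width: float, rng) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    lo = max(0.5, center - width / 2)
    hi = center + width / 2
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n + 2 * int(fs)))
    x = x[int(fs): int(fs) + n]
    sd = x.std()
    return x / sd if sd > 0 else x


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTrial:
    """One simulated trapezoidal contraction with ground truth attached."""

    level: float
    protocol: ProtocolSpec
    target_profile: np.ndarray        # N, at force_fs
    force: np.ndarray                 # N, at force_fs
    emg: dict[str, np.ndarray]        # muscle -> (4, n) at emg_fs
    spikes: dict[str, list[SpikeTrain]]
    mvc: float
    seed: int
    true_thresholds: dict[str, np.ndarray] = field(default_factory=dict)

    def force_trace(self) -> ForceTrace:
        p = self.protocol
        return ForceTrace(samples=self.force, fs=p.force_fs,
                          target=self.level * self.mvc, level=self.level,
                          hold_start=p.hold_start, hold_end=p.hold_end)


def _spike_times_for_unit(unit: MotorUnitSpec, t_drive: np.ndarray,
                          e: np.ndarray, rng) -> np.ndarray:
    """Inhomogeneous spike generation by time rescaling.

    The instantaneous rate r(t) (zero while drive is below the unit's
    threshold) is integrated to operational time Λ(t) = ∫r dτ; spikes fall
    where Λ crosses a cumulative sum of unit-mean intervals, lognormally
    jittered with CV ``isi_cv``.  This phase-locks spikes to oscillatory
    drive components (the momentary firing probability rises with drive),
    makes a constant-drive, zero-jitter unit exactly periodic at its
    programmed rate, and handles brief de-recruitments gracefully (Λ is
    flat there, stretching the interval instead of double-firing).
    """
    dt = t_drive[1] - t_drive[0]
    rate = np.asarray(unit.rate_at(e), dtype=float)
    if not np.any(rate > 0):
        return np.array([])
    lam = np.concatenate(([0.0], np.cumsum(rate) * dt))
    t_edges = np.concatenate((t_drive, [t_drive[-1] + dt]))
    total = lam[-1]
    n_exp = int(total + 6 * np.sqrt(max(total, 1.0)) + 10)
    if unit.isi_cv > 0:
        s = np.sqrt(np.log(1.0 + unit.isi_cv ** 2))
        intervals = np.exp(s * rng.standard_normal(n_exp) - s * s / 2)
    else:
        intervals = np.ones(n_exp)
    targets = np.cumsum(intervals)
    targets = targets[targets < total]
    # Λ is non-decreasing; interp inverts it onto the time axis
    return np.interp(targets, lam, t_edges)


def _impulse_sum(spike_sets: Sequence[np.ndarray], kernels: Sequence[np.ndarray],
                 n: int, fs: float, gains: Sequence[float] | None = None) -> np.ndarray:
    out = np.zeros(n)
    gains = gains if gains is not None else np.ones(len(spike_sets))
    for times, kern, g in zip(spike_sets, kernels, gains):
        if times.size == 0:
            continue
        train = np.zeros(n)
        idx = np.clip(np.round(times * fs).astype(int), 0, n - 1)
        np.add.at(train, idx, 1.0)
        out += g * np.convolve(train, kern)[:n]
    return out


def simulate_trial(pool_pair: dict[str, Sequence[MotorUnitSpec]],
                   drive: CommonDriveSpec, protocol: ProtocolSpec,
                   level: float, seed: int = 0,
                   mvc: float = 120.0,
                   force_noise_sd_frac: float = 0.002,
                   emg_noise_frac: float = 0.05,
                   accuracy_mean: float = 96.0,
                   accuracy_sd: float = 3.0) -> SyntheticTrial:
    """Simulate one trapezoidal trial for a pair of muscles.

    Excitation per pool = closed-loop trapezoid command + oscillatory
    band-limited noise (a fraction ``drive.strength`` of whose variance is
    shared between pools) + independent broadband noise.  Spike trains
    drive both the force output (twitch convolution, calibrated so full
    excitation produces ``mvc`` newtons) and the EMG channels (MUAP
    convolution + white noise, band-limited to the protocol's EMG band).
    """
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    muscles = list(pool_pair)
    ss = np.random.SeedSequence(entropy=seed)
    branches = ss.spawn(2 * len(muscles) + 1)
    rng_common = np.random.default_rng(branches[-1])

    drive_fs = 500.0
    n_drive = int(round(protocol.duration * drive_fs))
    t_drive = np.arange(n_drive) / drive_fs
    shared = _band_noise(n_drive, drive_fs, drive.band_center,
                         drive.band_width, rng_common)

    n_force = int(round(protocol.duration * protocol.force_fs))
    t_force = np.arange(n_force) / protocol.force_fs
    target = protocol.target_fraction(t_force, level) * mvc

    n_emg = int(round(protocol.duration * protocol.emg_fs))
    force_raw = np.zeros(n_force)
    force_ref = 0.0
    emg: dict[str, np.ndarray] = {}
    spikes: dict[str, list[SpikeTrain]] = {}
    true_thr: dict[str, np.ndarray] = {}

    for mi, muscle in enumerate(muscles):
        pool = list(pool_pair[muscle])
        rng = np.random.default_rng(branches[2 * mi])
        rng_emg = np.random.default_rng(branches[2 * mi + 1])
        e_grid, f_norm = pool_force_curve(pool)
        # anticipate the twitch lag (centroid of the twitch impulse response
        # is 2T): command leads the target, like a participant tracking the
        # on-screen trace feed-forward
        lag = 2.0 * (sum(u.twitch_amplitude * u.twitch_contraction_time
                         for u in pool)
                     / sum(u.twitch_amplitude for u in pool))
        command = _excitation_for_target(
            protocol.target_fraction(t_drive + lag, level), e_grid, f_norm)
        own = _band_noise(n_drive, drive_fs, drive.band_center,
                          drive.band_width, rng)
        osc = (np.sqrt(drive.strength) * shared
               + np.sqrt(1.0 - drive.strength) * own)
        # signal-dependent noise: oscillatory and broadband drive noise
        # scale with the momentary command (nominal at command = 0.5), so
        # recruitment near zero drive stays precise while the hold phase
        # carries a full-strength oscillation
        scale = command / 0.5
        e = command + scale * (drive.sd * osc
                               + drive.broadband_sd
                               * rng.standard_normal(n_drive))
        e = np.clip(e, 0.0, 1.2)

        unit_spikes = [_spike_times_for_unit(u, t_drive, e, rng) for u in pool]
        spikes[muscle] = [
            SpikeTrain(unit_id=f"{muscle}_{i:02d}", muscle=muscle,
                       spike_times=st,
                       accuracy=float(np.clip(
                           rng.normal(accuracy_mean, accuracy_sd), 60.0, 100.0)))
            for i, st in enumerate(unit_spikes) if st.size > 0]
        true_thr[muscle] = np.array(
            [pool[i].recruitment_threshold for i, st in enumerate(unit_spikes)
             if st.size > 0])

        twitch_kerns = [u.twitch_kernel(protocol.force_fs) for u in pool]
        force_raw += _impulse_sum(unit_spikes, twitch_kerns, n_force,
                                  protocol.force_fs)
        # static max output of this pool (for force calibration)
        force_ref += sum(u.rate_at(1.0) * u.twitch_amplitude
                         * u.twitch_contraction_time * np.e for u in pool)

        muap_kerns = [u.muap_kernel(protocol.emg_fs) for u in pool]
        chans = np.zeros((4, n_emg))
        for ch in range(4):
            gains = (np.ones(len(pool)) if ch == 0
                     else rng_emg.uniform(0.5, 1.0, len(pool)))
            chans[ch] = _impulse_sum(unit_spikes, muap_kerns, n_emg,
                                     protocol.emg_fs, gains)
        rms = np.sqrt(np.mean(chans[0][chans[0] != 0] ** 2)) if np.any(chans[0]) else 1.0
        chans += emg_noise_frac * rms * rng_emg.standard_normal(chans.shape)
        sos = signal.butter(4, protocol.emg_band, btype="bandpass",
                            fs=protocol.emg_fs, output="sos")
        emg[muscle] = signal.sosfiltfilt(sos, chans, axis=1)

    force = force_raw / force_ref * mvc
    force += force_noise_sd_frac * mvc * rng_common.standard_normal(n_force)
    return SyntheticTrial(level=level, protocol=protocol,
                          target_profile=target, force=force, emg=emg,
                          spikes=spikes, mvc=mvc, seed=seed,
                          true_thresholds=true_thr)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Per-group pool and drive parameters.

    ``drive_by_level`` maps each force level to the common-drive spec used
    at that level; levels not present fall back to ``drive``.
    """

    name: str
    n_units: int = 25
    mvc_mean: float = 120.0
    mvc_sd: float = 15.0
    drive: CommonDriveSpec = field(default_factory=CommonDriveSpec)
    drive_by_level: dict[float, CommonDriveSpec] = field(default_factory=dict)

    def drive_for(self, level: float) -> CommonDriveSpec:
        return self.drive_by_level.get(level, self.drive)


def default_groups() -> list[GroupSpec]:
    """Illustrative presets: a dexterity-like group with beta-band (20 Hz)
    common drive strongest at low force, and a strength-like group with
    beta drive strongest at high force.  These are demonstration settings
    for the pipeline, not claims about any human cohort."""
    beta = lambda s: CommonDriveSpec(band_center=20.0, band_width=6.0, strength=s)
    return [
        GroupSpec(name="dexterity", mvc_mean=112.0,
                  drive=beta(0.1),
                  drive_by_level={0.15: beta(0.5), 0.35: beta(0.3)}),
        GroupSpec(name="strength", mvc_mean=130.0,
                  drive=beta(0.1),
                  drive_by_level={0.55: beta(0.3), 0.70: beta(0.5)}),
    ]


def simulate_participant(group: GroupSpec, protocol: ProtocolSpec,
                         participant_seed: int) -> list[SyntheticTrial]:
    """All trials (levels x repeats) of one synthetic participant."""
    ss = np.random.SeedSequence(entropy=participant_seed)
    pool_seeds = ss.spawn(2)
    rng = np.random.default_rng(pool_seeds[0])
    mvc = float(max(20.0, rng.normal(group.mvc_mean, group.mvc_sd)))
    pools = {m: generate_pool(group.n_units, mvc_scale=mvc,
                              seed=int(rng.integers(2 ** 31)))
             for m in ("APB", "FDS")}
    trials = []
    trial_idx = 0
    for level in protocol.force_levels:
        for _ in range(protocol.repeats_per_level):
            # deterministic per-trial seed derived from the participant seed
            tseed = int((participant_seed * 1_000_003 + trial_idx * 9176) % (2 ** 31))
            trials.append(simulate_trial(pools, group.drive_for(level),
                                         protocol, level, seed=tseed, mvc=mvc))
            trial_idx += 1
    return trials


def generate_cohort(group_specs: Sequence[GroupSpec], protocol: ProtocolSpec,
                    n_per_group: int, seed: int, out_dir: str | Path) -> Path:
    """Write a cohort of trial bundles to ``out_dir``.

    Layout: out_dir/<group>/<participant>/trial<k>_* files in the
    delimited-text formats of :mod:`neuropinch.io`, plus a JSON manifest
    recording every file with its seed provenance.  Byte-identical for a
    fixed seed.
    """
    from . import io as npio

    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "protocol": protocol.__dict__ | {
        "force_levels": list(protocol.force_levels),
        "emg_band": list(protocol.emg_band)}, "participants": []}
    for gi, group in enumerate(group_specs):
        for p in range(n_per_group):
            pseed = int((seed * 2_654_435_761 + gi * 97_561 + p * 7919) % (2 ** 31))
            pid = f"{group.name}_{p:02d}"
            trials = simulate_participant(group, protocol, pseed)
            pdir = out_dir / group.name / pid
            pdir.mkdir(parents=True, exist_ok=True)
            entries = []
            for k, trial in enumerate(trials):
                stem = pdir / f"trial{k:02d}"
                files = npio.write_trial_bundle(trial, stem)
                entries.append({
                    "trial": k, "level": trial.level,
                    "repeat": k % protocol.repeats_per_level,
                    "seed": trial.seed, "mvc": trial.mvc,
                    "files": {kind: str(f.relative_to(out_dir))
                              for kind, f in files.items()}})
            manifest["participants"].append(
                {"participant": pid, "group": group.name, "seed": pseed,
                 "trials": entries})
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return out_dir / "manifest.json"
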