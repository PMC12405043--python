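import numpy as np
import pytest

from neuropinch.firing import filter_trains
from neuropinch.force import find_steadiest_window
from neuropinch.synthetic import (RECRUIT_RANGE, CommonDriveSpec,
                                  MotorUnitSpec, ProtocolSpec, generate_pool,
                                  pool_force_curve, simulate_trial)


class TestGeneratePool:
    def test_single_unit_threshold_zero(self):
        (unit,) = generate_pool(1, seed=0)
        assert unit.excitation_threshold == 0.0
        assert unit.twitch_amplitude > 0
        assert unit.twitch_kernel(1000.0).max() > 0

    def test_deterministic_for_seed(self):
        assert generate_pool(20, seed=9) == generate_pool(20, seed=9)

    def test_threshold_spacing_formula(self):
        # independent re-evaluation of the exponential spacing rule
        n, t_max = 30, 0.6
        pool = generate_pool(n, seed=0, max_threshold=t_max)
        a = np.log(RECRUIT_RANGE)
        i = np.arange(n)
        expected = t_max * (np.exp(a * i / (n - 1)) - 1) / (np.exp(a) - 1)
        got = np.array([u.excitation_threshold for u in pool])
        assert np.allclose(got, expected)
        assert np.all(np.diff(got) > 0)

    def test_twitch_amplitude_grows_with_threshold(self):
        pool = generate_pool(25, seed=0)
        amps = [u.twitch_amplitude for u in pool]
        assert np.all(np.diff(amps) > 0)

    def test_force_thresholds_monotone_in_unit_interval(self):
        pool = generate_pool(25, seed=0)
        thr = np.array([u.recruitment_threshold for u in pool])
        assert np.all(np.diff(thr) > 0)
        assert thr[0] < 0.02 and thr[-1] < 1.0

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            generate_pool(0)


class TestStaticCurve:
    def test_monotone_and_normalised(self):
        pool = generate_pool(20, seed=1)
        e, f = pool_force_curve(pool)
        assert f[-1] == pytest.approx(1.0)
        assert np.all(np.diff(f) >= 0)


class TestSimulateTrial:
    def test_deterministic_per_seed(self, protocol, small_pools):
        drive = CommonDriveSpec(strength=0.3)
        a = simulate_trial(small_pools, drive, protocol, 0.35, seed=11)
        b = simulate_trial(small_pools, drive, protocol, 0.35, seed=11)
        assert np.array_equal(a.force, b.force)
        assert np.array_equal(a.emg["APB"], b.emg["APB"])
        assert all(np.array_equal(x.spike_times, y.spike_times)
                   for x, y in zip(a.spikes["FDS"], b.spikes["FDS"]))

    def test_invalid_level_rejected(self, protocol, small_pools):
        with pytest.raises(ValueError):
            simulate_trial(small_pools, CommonDriveSpec(), protocol, 1.5)

    def test_series_time_aligned(self, trial35, protocol):
        dur_force = trial35.force.size / protocol.force_fs
        dur_emg = trial35.emg["APB"].shape[1] / protocol.emg_fs
        assert abs(dur_force - dur_emg) <= 1.0 / protocol.force_fs
        assert trial35.emg["APB"].shape[0] == 4

    def test_spikes_within_trial(self, trial35, protocol):
        for trains in trial35.spikes.values():
            for tr in trains:
                assert tr.spike_times.min() >= 0
                assert tr.spike_times.max() <= protocol.duration

    def test_hold_force_monotone_in_level(self, protocol, small_pools):
        means = []
        for level in protocol.force_levels:
            t = simulate_trial(small_pools, CommonDriveSpec(), protocol,
                               level, seed=5)
            i0 = int(protocol.hold_start * protocol.force_fs)
            i1 = int(protocol.hold_end * protocol.force_fs)
            means.append(t.force[i0:i1].mean())
        assert np.all(np.diff(means) > 0)

    def test_hold_force_tracks_target(self, protocol, small_pools):
        for level in (0.15, 0.55):
            t = simulate_trial(small_pools, CommonDriveSpec(), protocol,
                               level, seed=6)
            i0 = int((protocol.hold_start + 0.5) * protocol.force_fs)
            i1 = int((protocol.hold_end - 0.5) * protocol.force_fs)
            assert t.force[i0:i1].mean() == pytest.approx(
                level * t.mvc, rel=0.10)

    def test_recruitment_in_threshold_order(self, protocol, small_pools):
        t = simulate_trial(small_pools, CommonDriveSpec(strength=0.0),
                           protocol, 0.70, seed=8)
        for muscle in ("APB", "FDS"):
            firsts = [tr.spike_times[0] for tr in t.spikes[muscle]]
            thr = t.true_thresholds[muscle]
            order = np.argsort(thr)
            # later-threshold units must not fire before earlier ones by
            # more than the drive-noise jitter allows
            assert np.corrcoef(thr, firsts)[0, 1] > 0.9
            assert firsts[int(order[0])] <= min(firsts) + 0.5

    def test_periodic_unit_without_jitter(self, protocol):
        # one unit, constant drive, no jitter or noise -> exact periodicity
        pool = generate_pool(1, seed=0, isi_cv=0.0)
        drive = CommonDriveSpec(strength=0.0, sd=0.0, broadband_sd=0.0)
        t = simulate_trial({"A": pool, "B": pool}, drive, protocol, 0.35,
                           seed=1)
        tr = t.spikes["A"][0]
        hold = tr.spike_times[(tr.spike_times > protocol.hold_start + 0.5)
                              & (tr.spike_times < protocol.hold_end - 0.5)]
        ipis = np.diff(hold)
        assert np.allclose(ipis, ipis[0], atol=1e-3)
        e_grid, f_norm = pool_force_curve(pool)
        e = np.interp(0.35, f_norm, e_grid)
        assert 1.0 / ipis.mean() == pytest.approx(
            float(pool[0].rate_at(e)), rel=0.02)


class TestProtocolSpec:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ProtocolSpec(ramp_s=0.0)
        with pytest.raises(ValueError):
            ProtocolSpec(force_levels=(0.0, 0.5))
        with pytest.raises(ValueError):
            ProtocolSpec(emg_fs=800.0)

    def test_trapezoid_profile_shape(self):
        p = ProtocolSpec()
        t = np.linspace(0, p.duration, 2000)
        prof = p.target_fraction(t, 0.5)
        assert prof.max() == pytest.approx(0.5)
        assert prof[0] == 0.0 and prof[-1] == 0.0
        hold = prof[(t > p.hold_start + 0.1) & (t < p.hold_end - 0.1)]
        assert np.allclose(hold, 0.5)


class TestUnitSpecInvariants:
    def test_bad_parameters_rejected(self):
        ok = dict(recruitment_threshold=0.1, excitation_threshold=0.1,
                  peak_rate=30.0, min_rate=8.0, isi_cv=0.1,
                  twitch_amplitude=1.0, twitch_contraction_time=0.05,
                  muap_duration_s=0.01, muap_amplitude=1.0)
        MotorUnitSpec(**ok)
        with pytest.raises(ValueError):
            MotorUnitSpec(**{**ok, "recruitment_threshold": 1.0})
        with pytest.raises(ValueError):
            MotorUnitSpec(**{**ok, "min_rate": 40.0})
        with pytest.raises(ValueError):
            MotorUnitSpec(**{**ok, "isi_cv": 0.5})

    def test_drive_band_validated(self):
        with pytest.raises(ValueError):
            CommonDriveSpec(band_center=5.0, band_width=12.0)
        with pytest.raises(ValueError):
            CommonDriveSpec(strength=1.5)
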