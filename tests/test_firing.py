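import numpy as np
import pytest

from neuropinch.firing import (SpikeTrain, cov_ipis, filter_trains,
                               firing_threshold, fit_firing_lmm,
                               mean_firing_rate, simulate_firing_records)
from neuropinch.force import ForceTrace, SteadyWindow


def _train(times, acc=95.0, uid="u0", muscle="APB"):
    return SpikeTrain(unit_id=uid, muscle=muscle,
                      spike_times=np.asarray(times, float), accuracy=acc)


WIN = SteadyWindow(start=0.0, width=4.0, cov=1.0)


class TestFilterTrains:
    def test_six_ipis_removed(self):
        # 7 spikes = 6 interpulse intervals: below the >= 7 IPI rule
        tr = _train(np.arange(7) * 0.1)
        assert filter_trains([tr], WIN) == []

    def test_periodic_nine_spikes_kept(self):
        tr = _train(np.arange(9) * 0.1)  # 8 IPIs, COV = 0
        assert filter_trains([tr], WIN) == [tr]

    def test_low_accuracy_removed(self):
        tr = _train(np.arange(20) * 0.1, acc=89.9)
        assert filter_trains([tr], WIN) == []

    def test_matches_brute_force_rules(self, rng):
        # graded jitter levels straddling the 30% COV cut
        trains = []
        for i, cv in enumerate((0.0, 0.1, 0.25, 0.35, 0.6)):
            ipis = 0.1 * np.maximum(0.05, 1 + cv * rng.standard_normal(30))
            trains.append(_train(np.cumsum(ipis), uid=f"u{i}",
                                 acc=85.0 if i == 2 else 95.0))
        kept = filter_trains(trains, WIN)
        expected = []
        for tr in trains:
            t = tr.spike_times[(tr.spike_times >= WIN.start)
                               & (tr.spike_times <= WIN.end)]
            ipis = np.diff(t)
            if tr.accuracy < 90 or ipis.size < 7:
                continue
            if 100 * ipis.std() / ipis.mean() > 30:
                continue
            expected.append(tr)
        assert kept == expected

    def test_idempotent(self, trial35, steady_window):
        once = filter_trains(trial35.spikes["APB"], steady_window)
        assert filter_trains(once, steady_window) == once

    def test_cov_exactly_30_is_kept(self):
        # removal rule is strictly "> 30%": scale the IPI deviations so
        # the COV lands exactly on the boundary
        ipis = np.array([0.1, 0.1, 0.1, 0.1, 0.16, 0.16, 0.16, 0.16])
        cv = 100 * ipis.std() / ipis.mean()
        ipis30 = ipis.mean() + (ipis - ipis.mean()) * (30.0 / cv)
        times = np.concatenate([[0.0], np.cumsum(ipis30)])
        tr = _train(times)
        assert cov_ipis(tr.spike_times) == pytest.approx(30.0)
        assert filter_trains([tr], WIN) == [tr]


class TestMeanFiringRate:
    def test_periodic_train_exact(self):
        tr = _train(np.arange(11) * 0.1)
        assert mean_firing_rate(tr, WIN) == pytest.approx(10.0)

    def test_mean_of_reciprocals_not_reciprocal_of_mean(self):
        tr = _train([0.0, 0.1, 0.3])
        # mean(1/0.1, 1/0.2) = 7.5 Hz, not 2/0.3
        assert mean_firing_rate(tr, WIN) == pytest.approx(7.5)

    def test_matches_loop_oracle(self, rng):
        times = np.cumsum(rng.uniform(0.05, 0.2, 40))
        tr = _train(times)
        inside = times[(times >= WIN.start) & (times <= WIN.end)]
        expected = np.mean([1.0 / (b - a) for a, b in zip(inside, inside[1:])])
        assert mean_firing_rate(tr, WIN) == pytest.approx(expected)

    def test_no_ipi_rejected(self):
        with pytest.raises(ValueError):
            mean_firing_rate(_train([1.0]), WIN)


class TestFiringThreshold:
    @staticmethod
    def _ramp_force(mvc=100.0, fs=1000.0, dur=10.0):
        t = np.arange(int(dur * fs)) / fs
        return ForceTrace(samples=mvc * t / dur, fs=fs, target=mvc,
                          hold_start=0.0, hold_end=dur)

    def test_recruited_on_linear_ramp(self):
        # unit starts firing periodically when force passes 30% MVC
        force = self._ramp_force()
        t0 = 3.0  # force(3 s) = 30% of MVC
        tr = _train(t0 + np.arange(30) * 0.08)
        thr = firing_threshold(tr, force, 100.0)
        assert thr == pytest.approx(30.0, abs=1.0)

    def test_onset_at_first_spike_of_periodic_train(self):
        force = self._ramp_force()
        tr = _train(1.5 + np.arange(20) * 0.1)
        assert firing_threshold(tr, force, 100.0) == pytest.approx(
            100.0 * force.value_at(1.5) / 100.0)

    def test_single_spike_gives_sentinel(self):
        assert np.isnan(firing_threshold(_train([1.0]),
                                         self._ramp_force(), 100.0))

    def test_irregular_prefix_skipped(self):
        # erratic doublets first, regular firing from t = 4 s
        force = self._ramp_force()
        noisy = np.array([0.5, 0.52, 1.4, 1.43, 2.9])
        regular = 4.0 + np.arange(20) * 0.1
        tr = _train(np.concatenate([noisy, regular]))
        thr = firing_threshold(tr, force, 100.0)
        assert thr == pytest.approx(40.0, abs=1.0)


class TestFiringLmm:
    def test_programmed_effect_recovered(self):
        df = simulate_firing_records(group_effect_hz=3.0, seed=1)
        res = fit_firing_lmm(df)
        c = [c for c in res.contrasts
             if c.level == 0.35 and c.muscle == "APB"][0]
        assert c.ci_low <= 3.0 <= c.ci_high

    def test_null_effect_covers_zero(self):
        df = simulate_firing_records(group_effect_hz=0.0, seed=2)
        res = fit_firing_lmm(df)
        c = [c for c in res.contrasts
             if c.level == 0.35 and c.muscle == "APB"][0]
        assert c.ci_low <= 0.0 <= c.ci_high

    def test_conditional_r2_at_least_marginal(self):
        for seed in (3, 4):
            res = fit_firing_lmm(simulate_firing_records(seed=seed))
            assert res.marginal_r2 <= res.conditional_r2 <= 1.0

    def test_matches_cell_means_without_random_structure(self):
        # with no participant/threshold variance the EMM contrast is the
        # plain difference of cell means
        df = simulate_firing_records(participant_sd=0.0, threshold_slope=0.0,
                                     resid_sd=1.0, group_effect_hz=2.0,
                                     seed=5)
        res = fit_firing_lmm(df)
        cell = df[(df.level == 0.35) & (df.muscle == "APB")]
        expected = (cell[cell.group == "a"].rate.mean()
                    - cell[cell.group == "b"].rate.mean())
        c = [c for c in res.contrasts
             if c.level == 0.35 and c.muscle == "APB"][0]
        assert c.estimate == pytest.approx(expected, abs=0.3)

    def test_small_cells_flagged_for_caution(self):
        import pandas as pd

        df = simulate_firing_records(seed=6)
        mask = ((df.level == 0.55) & (df.muscle == "FDS") & (df.group == "a"))
        df = pd.concat([df[~mask], df[mask].head(2)], ignore_index=True)
        res = fit_firing_lmm(df)
        flagged = [c for c in res.contrasts
                   if c.level == 0.55 and c.muscle == "FDS"][0]
        assert flagged.caution

    def test_requires_two_groups_and_levels(self):
        df = simulate_firing_records(seed=7)
        with pytest.raises(ValueError):
            fit_firing_lmm(df[df.group == "a"])
        with pytest.raises(ValueError):
            fit_firing_lmm(df[df.level == 0.35])
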