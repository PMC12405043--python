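import numpy as np
import pytest

from neuropinch.coherence import (BANDS, CoherenceSpectrum, band_average,
                                  between_group_difference, coherence,
                                  confidence_limit, crosstalk_qc,
                                  estimate_spectra,
                                  percent_significant_trials, pool_coherence,
                                  preprocess_envelope,
                                  within_group_heterogeneity)
from neuropinch.force import SteadyWindow

FS = 2222.0
WIN = SteadyWindow(start=0.0, width=4.0, cov=1.0)


def _env(samples, fs=FS):
    from neuropinch.coherence import PreprocessedEnvelope

    return PreprocessedEnvelope(samples=np.asarray(samples, float), fs=fs,
                                window=WIN)


def _noise_pair(rng, n=None):
    n = n or int(4 * FS)
    return _env(rng.standard_normal(n)), _env(rng.standard_normal(n))


class TestPreprocess:
    def test_passband_tone_gives_flat_envelope(self):
        # analytic-signal magnitude of a unit-variance tone is sqrt(2)
        t = np.arange(int(5 * FS)) / FS
        x = np.sin(2 * np.pi * 50.0 * t)
        env = preprocess_envelope(x, WIN, FS)
        core = env.samples[1000:-1000]  # ignore filter edges
        assert np.allclose(core, np.sqrt(2), atol=0.02)

    def test_stopband_component_removed(self):
        # a large 10 Hz component below the 20 Hz high-pass must not
        # modulate the envelope of a 50 Hz tone
        t = np.arange(int(5 * FS)) / FS
        x = 10.0 * np.sin(2 * np.pi * 10.0 * t) + np.sin(2 * np.pi * 50.0 * t)
        env = preprocess_envelope(x, WIN, FS)
        core = env.samples[1000:-1000]
        assert np.std(core) < 0.05 * np.mean(core)

    def test_normalisation_step_unit_variance(self, rng):
        x = 3.0 + 5.0 * rng.standard_normal(int(5 * FS))
        env = preprocess_envelope(x, WIN, FS)
        # envelope of a unit-variance analytic signal has mean power 2
        assert np.mean(env.samples ** 2) == pytest.approx(2.0, rel=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            preprocess_envelope(np.zeros(int(5 * FS)), WIN, FS)

    def test_window_outside_series_rejected(self):
        with pytest.raises(ValueError):
            preprocess_envelope(np.ones(1000), WIN, FS)


class TestSpectra:
    def test_four_seconds_gives_eight_segments(self, rng):
        x, y = _noise_pair(rng)
        spec = estimate_spectra(x, y)
        assert spec.L == 8

    def test_frequency_resolution(self, rng):
        x, y = _noise_pair(rng)
        spec = estimate_spectra(x, y)
        assert spec.freqs[1] == pytest.approx(2.17, abs=0.01)

    def test_autospectrum_equals_cross_when_identical(self, rng):
        x = _env(rng.standard_normal(int(4 * FS)))
        spec = estimate_spectra(x, x)
        assert np.allclose(spec.f_xy.real, spec.f_xx)
        assert np.allclose(spec.f_xy.imag, 0.0, atol=1e-9)

    def test_too_short_record_rejected(self, rng):
        x = _env(rng.standard_normal(100))
        with pytest.raises(ValueError):
            estimate_spectra(x, x)


class TestCoherence:
    def test_identical_signals_unity(self, rng):
        x = _env(rng.standard_normal(int(4 * FS)))
        c = coherence(estimate_spectra(x, x))
        assert np.allclose(c.r2, 1.0)

    def test_bounded_unit_interval(self, rng):
        for _ in range(5):
            c = coherence(estimate_spectra(*_noise_pair(rng)))
            assert np.all((c.r2 >= 0) & (c.r2 <= 1))

    def test_null_exceedance_quick(self, rng):
        # ~5% of bins above CL for independent inputs (coarse check; the
        # full 500-replicate calibration lives in the acceptance suite)
        hits, total = 0, 0
        for _ in range(60):
            c = coherence(estimate_spectra(*_noise_pair(rng)))
            hits += int(c.significant.sum())
            total += c.r2.size
        assert 0.02 < hits / total < 0.09

    def test_single_segment_rejected(self, rng):
        x, y = _noise_pair(rng, n=1022)
        with pytest.raises(ValueError):
            coherence(estimate_spectra(x, y))


class TestConfidenceLimit:
    def test_two_segments(self):
        assert confidence_limit(2) == pytest.approx(0.95)

    def test_ninety_six_segments(self):
        assert confidence_limit(96) == pytest.approx(1 - 0.05 ** (1 / 95))

    def test_strictly_decreasing_in_l(self):
        cls = [confidence_limit(L) for L in range(2, 200)]
        assert np.all(np.diff(cls) < 0)

    def test_l_below_two_rejected(self):
        with pytest.raises(ValueError):
            confidence_limit(1)


class TestPooling:
    def test_copies_pool_to_same_coherence(self, rng):
        spec = estimate_spectra(*_noise_pair(rng))
        pooled = pool_coherence([spec] * 5)
        assert np.allclose(pooled.r2, coherence(spec).r2)
        assert pooled.total_segments == 40

    def test_order_invariant(self, rng):
        specs = [estimate_spectra(*_noise_pair(rng)) for _ in range(4)]
        a = pool_coherence(specs)
        b = pool_coherence(specs[::-1])
        assert np.allclose(a.r2, b.r2)

    def test_pooled_null_fraction(self, rng):
        hits, total = 0, 0
        for _ in range(15):
            specs = [estimate_spectra(*_noise_pair(rng)) for _ in range(6)]
            p = pool_coherence(specs)
            hits += int(p.significant.sum())
            total += p.r2.size
        assert 0.01 < hits / total < 0.10

    def test_mismatched_grids_rejected(self, rng):
        a = estimate_spectra(*_noise_pair(rng))
        x, y = _noise_pair(rng)
        b = estimate_spectra(x, y, segment_s=0.23)  # coarser grid
        with pytest.raises(ValueError):
            pool_coherence([a, b])


class TestHeterogeneity:
    def test_identical_records_zero(self, rng):
        spec = estimate_spectra(*_noise_pair(rng))
        chi2, flags = within_group_heterogeneity([spec] * 4)
        assert np.allclose(chi2, 0.0)
        assert not flags.any()

    def test_order_invariant(self, rng):
        specs = [estimate_spectra(*_noise_pair(rng)) for _ in range(4)]
        a, _ = within_group_heterogeneity(specs)
        b, _ = within_group_heterogeneity(specs[::-1])
        assert np.allclose(a, b)

    def test_outlier_record_flagged(self, rng):
        # one record with strong 20 Hz coherence among independent ones
        t = np.arange(int(4 * FS)) / FS
        carrier = np.sin(2 * np.pi * 20.0 * t)
        specs = [estimate_spectra(*_noise_pair(rng)) for _ in range(5)]
        shared = carrier + 0.2 * rng.standard_normal(t.size)
        specs.append(estimate_spectra(
            _env(shared + 0.1 * rng.standard_normal(t.size)),
            _env(shared + 0.1 * rng.standard_normal(t.size))))
        chi2, flags = within_group_heterogeneity(specs)
        bin20 = np.argmin(np.abs(specs[0].freqs - 20.0))
        assert flags[bin20]

    def test_single_record_rejected(self, rng):
        with pytest.raises(ValueError):
            within_group_heterogeneity([estimate_spectra(*_noise_pair(rng))])


class TestGroupDifference:
    def test_equal_groups_zero_statistic(self, rng):
        p = pool_coherence([estimate_spectra(*_noise_pair(rng))
                            for _ in range(4)])
        d = between_group_difference(p, p)
        assert np.allclose(d.statistic, 0.0)
        assert not d.a_greater.any() and not d.b_greater.any()

    def test_antisymmetric_under_swap(self, rng):
        pa = pool_coherence([estimate_spectra(*_noise_pair(rng))
                             for _ in range(4)])
        pb = pool_coherence([estimate_spectra(*_noise_pair(rng))
                             for _ in range(4)])
        d1 = between_group_difference(pa, pb)
        d2 = between_group_difference(pb, pa)
        assert np.allclose(d1.statistic, -d2.statistic)


class TestSummaries:
    @staticmethod
    def _spectrum(r2, freqs=None, L=8):
        freqs = freqs if freqs is not None else np.arange(r2.size) * 2.1739
        return CoherenceSpectrum(freqs=freqs, r2=r2, L=L,
                                 cl=confidence_limit(L))

    def test_percent_significant_extremes(self):
        freqs = np.arange(40) * 2.1739
        hot = np.zeros(40)
        hot[9] = 0.9  # ~19.6 Hz, above the L = 8 limit
        specs = [self._spectrum(hot, freqs) for _ in range(6)]
        pct = percent_significant_trials(specs)
        assert pct[9] == 100.0
        assert np.all((pct >= 0) & (pct <= 100))

    def test_band_average_flat(self):
        from neuropinch.coherence import PooledCoherence

        freqs = np.arange(50) * 2.1739
        p = PooledCoherence(freqs=freqs, r2=np.full(50, 0.3),
                            total_segments=96, cl=confidence_limit(96))
        for b in band_average(p):
            assert b.mean_r2 == pytest.approx(0.3)

    def test_band_average_matches_hand_computation(self, rng):
        from neuropinch.coherence import PooledCoherence

        freqs = np.arange(50) * 2.1739
        r2 = rng.uniform(0, 1, 50)
        p = PooledCoherence(freqs=freqs, r2=r2, total_segments=96,
                            cl=confidence_limit(96))
        for b in band_average(p):
            lo, hi = BANDS[b.band]
            assert b.mean_r2 == pytest.approx(
                r2[(freqs >= lo) & (freqs < hi)].mean())

    def test_single_elevated_bin_touches_one_band(self):
        from neuropinch.coherence import PooledCoherence

        freqs = np.arange(50) * 2.1739
        r2 = np.zeros(50)
        r2[np.argmin(np.abs(freqs - 20.0))] = 0.8
        p = PooledCoherence(freqs=freqs, r2=r2, total_segments=96,
                            cl=confidence_limit(96))
        means = {b.band: b.mean_r2 for b in band_average(p)}
        assert means["beta"] > 0
        assert means["alpha"] == 0 and means["gamma"] == 0

    def test_crosstalk_rule(self):
        freqs = np.arange(50) * 2.1739
        assert crosstalk_qc(self._spectrum(np.full(50, 0.9), freqs))
        assert not crosstalk_qc(self._spectrum(np.full(50, 0.1), freqs))
        beta_only = np.full(50, 0.1)
        beta_only[(freqs >= 16) & (freqs < 30)] = 0.9
        assert not crosstalk_qc(self._spectrum(beta_only, freqs))
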