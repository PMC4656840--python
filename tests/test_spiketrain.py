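"""Autocorrelogram, spectrum, periodicity, discrimination and ISI entropy."""

import numpy as np
import pytest
import statsmodels.api as sm

from fosmap.spiketrain import (
    Autocorrelogram,
    SpikeTrain,
    autocorrelogram,
    classify_firing_mode,
    discrimination_index,
    discrimination_trials,
    fit_discrimination_glmm,
    isi_entropy_from_intervals,
    isi_standardized_entropy,
    merge_sweeps,
    periodicity_index,
    power_spectrum,
)


def brute_force_acg(times: np.ndarray, lag_window=2.0, bin_width=0.1):
    """O(n^2) oracle: histogram of every ordered pair difference (self included)."""
    n_half = int(round(lag_window / bin_width))
    edges = (np.arange(-n_half, n_half + 2) - 0.5) * bin_width
    counts = np.zeros(2 * n_half + 1)
    for ti in times:
        for tj in times:
            d = tj - ti
            if edges[0] <= d < edges[-1]:
                counts[int((d - edges[0]) // bin_width)] += 1
    return counts / counts[n_half]


class TestMergeSweeps:
    def test_sorted_union(self):
        tr = SpikeTrain("c", "r", "control", [[0.2], [0.1]], 1.0)
        assert merge_sweeps(tr).sweeps[0].tolist() == [0.1, 0.2]

    def test_thirty_coincident_sweeps(self):
        tr = SpikeTrain("c", "r", "control", [[0.5]] * 30, 1.0)
        merged = merge_sweeps(tr)
        assert len(merged.sweeps) == 1
        assert merged.sweeps[0].size == 30
        assert merged.sweep_duration == 1.0

    def test_empty_sweeps_merge_to_empty(self):
        tr = SpikeTrain("c", "r", "control", [[], []], 1.0)
        assert merge_sweeps(tr).sweeps[0].size == 0

    def test_no_sweeps_raises(self):
        tr = SpikeTrain("c", "r", "control", [], 1.0)
        with pytest.raises(ValueError):
            merge_sweeps(tr)


class TestAutocorrelogram:
    def test_single_spike_degenerate(self):
        tr = SpikeTrain("c", "r", "control", [[1.0]], 120.0)
        acg = autocorrelogram(tr)
        assert acg.degenerate
        assert acg.values[acg.values.size // 2] == 1.0
        assert acg.values.sum() == 1.0

    def test_regular_train_matches_brute_force(self):
        times = np.arange(0.05, 120.0, 1.0)  # 1 Hz regular train
        tr = SpikeTrain("c", "r", "control", [times], 120.0)
        acg = autocorrelogram(tr)
        np.testing.assert_allclose(acg.values, brute_force_acg(times), atol=0)
        lags = acg.lags
        for lag in (1.0, -1.0, 2.0, -2.0):
            assert acg.values[np.argmin(np.abs(lags - lag))] > 0.9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_trains_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0, 30, rng.integers(5, 200)))
        tr = SpikeTrain("c", "r", "control", [times], 30.0)
        acg = autocorrelogram(tr)
        np.testing.assert_allclose(acg.values, brute_force_acg(times), atol=0)

    def test_symmetry(self, rng):
        times = np.sort(rng.uniform(0, 60, 150))
        acg = autocorrelogram(SpikeTrain("c", "r", "control", [times], 60.0))
        np.testing.assert_allclose(acg.values, acg.values[::-1], atol=0)
        assert acg.values[acg.values.size // 2] == 1.0


class TestPowerSpectrum:
    def test_impulse_gives_flat_spectrum(self):
        lags = np.arange(-20, 21) * 0.1
        vals = np.zeros(41)
        vals[20] = 1.0
        ps = power_spectrum(Autocorrelogram(lags, vals, 0.1))
        assert np.allclose(ps.power, ps.power[0])
        assert ps.power.sum() == pytest.approx(1.0)

    def test_raised_cosine_peaks_at_its_frequency(self):
        lags = np.arange(-20, 21) * 0.1
        vals = 0.5 * (1.0 + np.cos(2 * np.pi * 3.5 * lags))
        ps = power_spectrum(Autocorrelogram(lags, vals, 0.1))
        nz = ps.power.copy()
        nz[0] = 0.0  # ignore the DC term
        peak_f = ps.frequencies[np.argmax(nz)]
        assert abs(peak_f - 3.5) <= ps.frequencies[1]

    def test_unit_total_power(self, rng):
        lags = np.arange(-20, 21) * 0.1
        vals = rng.uniform(0, 1, 41)
        ps = power_spectrum(Autocorrelogram(lags, vals, 0.1))
        assert ps.power.sum() == pytest.approx(1.0)
        assert ps.frequencies[-1] <= 5.0


class TestPeriodicity:
    def test_flat_spectrum_is_non_periodic(self):
        lags = np.arange(-20, 21) * 0.1
        vals = np.zeros(41)
        vals[20] = 1.0
        res = periodicity_index(power_spectrum(Autocorrelogram(lags, vals, 0.1)))
        assert res.classification == "non_periodic"
        assert res.predominant_frequency is None

    def test_peak_below_threshold_is_non_periodic(self):
        from fosmap.spiketrain import PowerSpectrum

        f = np.linspace(0, 5, 21)
        p = np.full(21, 0.045)
        p[8] += 0.004  # peak height below the 0.008 detection threshold
        p /= p.sum()
        res = periodicity_index(PowerSpectrum(f, p))
        assert res.classification == "non_periodic"

    def test_periodic_train_recovers_generator_frequency(self):
        rng = np.random.default_rng(0)
        freq = 3.5
        t = np.cumsum(rng.normal(1 / freq, 0.05 / freq, 500))
        t = t[t < 120.0]
        tr = SpikeTrain("c", "r", "4AP", [t], 120.0)
        ps = power_spectrum(autocorrelogram(tr))
        res = periodicity_index(ps)
        assert res.classification == "periodic"
        assert abs(res.predominant_frequency - freq) <= ps.frequencies[1]
        assert res.periodicity_index >= 0.003

    def test_poisson_trains_mostly_non_periodic(self):
        rng = np.random.default_rng(7)
        flags = []
        for _ in range(50):
            rate = rng.uniform(1, 20)
            t = np.sort(rng.uniform(0, 120, rng.poisson(120 * rate)))
            tr = SpikeTrain("c", "r", "control", [t], 120.0)
            res = periodicity_index(power_spectrum(autocorrelogram(tr)))
            flags.append(res.classification == "non_periodic")
        assert np.mean(flags) >= 0.9


class TestFiringMode:
    @staticmethod
    def _burst_train(freq, m, isi, rng, duration=120.0):
        period = 1.0 / freq
        t0 = rng.uniform(0, period)
        times = []
        while t0 < duration:
            times.extend(t0 + k * isi for k in range(m) if t0 + k * isi < duration)
            t0 += period * (1 + 0.05 * rng.standard_normal())
        return np.sort(np.asarray(times))

    def test_single_spike_train_is_nonbursting(self, rng):
        t = self._burst_train(2.0, 1, 0.03, rng)
        acg = autocorrelogram(SpikeTrain("c", "r", "4AP", [t], 120.0))
        ps = power_spectrum(acg)
        res = classify_firing_mode(acg, ps)
        assert res.classification == "periodic_nonbursting"

    def test_four_spike_bursts_are_bursting(self, rng):
        t = self._burst_train(2.0, 4, 0.03, rng)
        acg = autocorrelogram(SpikeTrain("c", "r", "4AP", [t], 120.0))
        ps = power_spectrum(acg)
        res = classify_firing_mode(acg, ps)
        assert res.classification == "periodic_bursting"

    def test_poisson_passes_through_non_periodic(self, rng):
        t = np.sort(rng.uniform(0, 120, 600))
        acg = autocorrelogram(SpikeTrain("c", "r", "4AP", [t], 120.0))
        ps = power_spectrum(acg)
        res = classify_firing_mode(acg, ps)
        assert res.classification == "non_periodic"


class TestDiscrimination:
    def _train(self, during, after, protocol):
        on0 = protocol.pulse_onset
        on1 = on0 + protocol.pulse_duration
        t = np.concatenate(
            [
                np.linspace(on0 + 0.01, on1 - 0.01, during),
                np.linspace(on1 + 0.01, on1 + protocol.pulse_duration - 0.01, after),
            ]
        )
        return SpikeTrain("c", "r", "control", [np.sort(t)], 20.0)

    def test_arithmetic(self, protocol):
        m = discrimination_index(self._train(12, 4, protocol), protocol)
        assert m.discrimination_index == pytest.approx(0.5)
        assert m.cell_class == "ON"

    def test_all_post_pulse_is_off(self, protocol):
        m = discrimination_index(self._train(0, 9, protocol), protocol)
        assert m.discrimination_index == pytest.approx(-1.0)
        assert m.cell_class == "OFF"

    def test_equal_counts_give_zero(self, protocol):
        m = discrimination_index(self._train(7, 7, protocol), protocol)
        assert m.discrimination_index == pytest.approx(0.0)
        assert m.cell_class is None

    def test_no_spikes_flagged_undefined(self, protocol):
        tr = SpikeTrain("c", "r", "control", [[0.1]], 20.0)
        m = discrimination_index(tr, protocol)
        assert not m.defined and m.discrimination_index is None

    def test_bounded_and_sweep_order_invariant(self, protocol, rng):
        sweeps = [np.sort(rng.uniform(0, 20, 15)) for _ in range(10)]
        tr1 = SpikeTrain("c", "r", "control", sweeps, 20.0)
        tr2 = SpikeTrain("c", "r", "control", sweeps[::-1], 20.0)
        m1 = discrimination_index(tr1, protocol)
        m2 = discrimination_index(tr2, protocol)
        assert -1 <= m1.discrimination_index <= 1
        assert m1.discrimination_index == m2.discrimination_index


class TestIsiEntropy:
    def test_worked_examples(self):
        h, hs = isi_entropy_from_intervals([1.0, 1.0, 2.0])
        assert h == pytest.approx(1.0397, abs=1e-4)
        assert hs == pytest.approx(0.946, abs=1e-3)
        h2, hs2 = isi_entropy_from_intervals([1.0, 3.0])
        assert h2 == pytest.approx(0.5623, abs=1e-4)
        assert hs2 == pytest.approx(0.811, abs=1e-3)

    def test_equal_intervals_maximize(self):
        _, hs = isi_entropy_from_intervals([0.25] * 8)
        assert hs == pytest.approx(1.0)

    def test_rescaling_invariance(self, rng):
        isis = rng.uniform(0.01, 1.0, 20)
        _, hs1 = isi_entropy_from_intervals(isis)
        _, hs2 = isi_entropy_from_intervals(isis * 7.3)
        assert hs1 == pytest.approx(hs2, rel=1e-12)
        assert 0 <= hs1 <= 1

    def test_window_and_undefined(self, protocol):
        # two spikes -> one interval -> undefined
        tr = SpikeTrain(
            "c", "r", "control",
            [[protocol.pulse_onset + 0.1, protocol.pulse_onset + 0.2]], 20.0,
        )
        assert isi_standardized_entropy(tr, protocol) is None
        # spikes far outside the peristimulus window are ignored
        tr2 = SpikeTrain(
            "c", "r", "control",
            [np.array([0.1, 0.2, 0.3, 5.2, 5.4, 5.8])], 20.0,
        )
        hs = isi_standardized_entropy(tr2, protocol)
        h_expected, hs_expected = isi_entropy_from_intervals([0.2, 0.4])
        assert hs == pytest.approx(hs_expected)


class TestDiscriminationGlmm:
    def test_zero_variance_fit_matches_plain_logistic(self, spike_population, protocol):
        trains = [c.control_stim for c in spike_population] + [
            c.ap4_stim for c in spike_population
        ]
        trials = discrimination_trials(trains, protocol)
        fit = fit_discrimination_glmm(trials, fit_variances=False)
        y = trials[["successes", "failures"]].to_numpy(float)
        X = sm.add_constant(trials["is_4ap"].to_numpy(float))
        oracle = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coef, oracle.params, atol=1e-3)

    def test_condition_effect_detected_on_generator_population(
        self, spike_population, protocol
    ):
        trains = [c.control_stim for c in spike_population] + [
            c.ap4_stim for c in spike_population
        ]
        trials = discrimination_trials(trains, protocol)
        fit = fit_discrimination_glmm(trials)
        assert not fit.separation
        assert fit.coef[1] < 0  # stimulus-locked firing collapses under 4-AP
        assert fit.p_condition < 0.01

    def test_separation_flagged(self):
        import pandas as pd

        trials = pd.DataFrame(
            {
                "cell_id": ["a", "a", "b", "b"],
                "rat_id": ["r1", "r1", "r2", "r2"],
                "is_4ap": [0, 1, 0, 1],
                "successes": [5, 3, 2, 8],
                "failures": [0, 0, 0, 0],
            }
        )
        fit = fit_discrimination_glmm(trials)
        assert fit.separation
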