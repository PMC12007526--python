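"""The complex 40-Hz statistic: estimator, bootstrap, latency, laterality."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from assrlab import assr
from assrlab.cohort import ParticipantSpec, SourceParams
from assrlab.filters import measure_edge_hz
from assrlab.simulate import trial_source_waveforms
from assrlab.stimulus import StimulusSpec

FS = 1250.0


def _participant(lag_ms=48.0, amp=2.0, buildup=200.0):
    return ParticipantSpec(
        id="x", group="young", age=25.0, pta_db=5.0,
        sin_loss_db=float("nan"), gaba={},
        sources={"quiet": SourceParams(amp, amp, lag_ms, buildup)})


def _clean_estimate(lag_ms=48.0, amp=2.0, buildup=200.0):
    w = trial_source_waveforms(_participant(lag_ms, amp, buildup), "quiet",
                               StimulusSpec(), seed=0,
                               background_rms_nAm=0.0)
    prep = assr.prepare_average(w["left"][None, :], FS)
    return assr.compute_assr(prep, FS)


class TestWindows:
    def test_n_is_188_at_1250_hz(self):
        for onset in assr.DEFAULT_ONSETS_MS:
            k, t = assr.window_indices(onset, FS)
            assert len(k) == 188
            # windows anchored to the nearest sample: times stay within
            # half a sample of the nominal 250-400 ms interval
            half_sample = 0.5 / FS
            assert t[0] >= 0.250 - half_sample
            assert t[-1] <= 0.400 + half_sample

    def test_window_out_of_span_raises(self):
        x = np.zeros(1000)
        with pytest.raises(ValueError):
            assr.compute_assr(x, FS)


class TestEstimator:
    def test_direct_summation_oracle_single_window(self):
        """On a windowed unit cosine the estimator equals the brute-force
        demodulation sum, amplitude N/(2(N-1)) up to self-leakage."""
        k, t = assr.window_indices(0.0, FS)
        x = np.zeros(4000)
        x[k] = np.cos(2 * np.pi * 40.0 * t)
        est = assr.compute_assr(x, FS, onsets_ms=(0.0,))
        oracle = np.sum(np.cos(2 * np.pi * 40 * t)
                        * np.exp(-2j * np.pi * 40 * t)) / (len(t) - 1)
        assert est.amplitude == pytest.approx(abs(oracle), rel=1e-12)
        assert abs(oracle) == pytest.approx(188 / 374, rel=0.01)

    def test_gain_on_simulated_entrained_source(self):
        """Full pipeline (filter + five windows) reads amplitude x gain
        within 2%."""
        est = _clean_estimate(amp=2.0, buildup=0.0, lag_ms=0.0)
        assert est.amplitude == pytest.approx(2.0 * assr.ESTIMATOR_GAIN,
                                              rel=0.02)
        assert abs(est.phase) < 0.05

    def test_zero_signal_zero_amplitude(self):
        est = assr.compute_assr(np.zeros(4000), FS)
        assert est.amplitude == 0.0

    def test_amplitude_linearity(self):
        e1 = _clean_estimate(amp=1.0)
        e3 = _clean_estimate(amp=3.0)
        assert e3.amplitude == pytest.approx(3 * e1.amplitude, rel=1e-6)
        assert e3.phase == pytest.approx(e1.phase, abs=1e-9)

    def test_constant_offset_removed(self):
        x = np.full(4000, 7.3)
        prep = assr.prepare_average(x[None, :], FS)
        est = assr.compute_assr(prep, FS)
        assert est.amplitude < 1e-10

    def test_time_shift_invariance(self):
        """Shifting data and onsets together leaves the estimate unchanged."""
        k, t = assr.window_indices(0.0, FS)
        x = np.zeros(5000)
        x[k] = np.cos(2 * np.pi * 40.0 * t - 0.7)
        a = assr.compute_assr(x, FS, onsets_ms=(0.0,))
        shift = 400  # samples = 320 ms
        y = np.roll(x, shift)
        b = assr.compute_assr(y, FS, onsets_ms=(320.0,))
        assert b.amplitude == pytest.approx(a.amplitude, abs=1e-10)
        assert b.phase == pytest.approx(a.phase, abs=1e-10)

    def test_dft_and_hilbert_phase_agree(self):
        for lag in (0.0, 5.0, 48.0, 53.3):
            est = _clean_estimate(lag_ms=lag)
            d = np.angle(np.exp(1j * (est.phase - est.hilbert_phase)))
            assert abs(d) < 0.05

    def test_bandpass_lower_edge_28hz(self):
        from assrlab.assr import _bandpass
        assert measure_edge_hz(_bandpass(FS), FS, -3.0, 20, 35) \
            == pytest.approx(28.0, abs=0.5)

    def test_angle_mean_switch(self):
        """The mean-angle variant agrees with the complex mean on clean
        phase-consistent input."""
        w = trial_source_waveforms(_participant(), "quiet", StimulusSpec(),
                                   seed=0, background_rms_nAm=0.0)
        prep = assr.prepare_average(w["left"][None, :], FS)
        a = assr.compute_assr(prep, FS, angle_mean=False)
        b = assr.compute_assr(prep, FS, angle_mean=True)
        assert b.amplitude == pytest.approx(a.amplitude, rel=1e-3)
        assert b.phase == pytest.approx(a.phase, abs=1e-3)


class TestBootstrap:
    def test_strong_signal_beats_all_null_samples(self):
        rng = np.random.default_rng(0)
        stim = StimulusSpec()
        trials = np.stack([
            trial_source_waveforms(_participant(amp=7.0), "quiet", stim,
                                   seed=i, background_rms_nAm=8.0)["left"]
            for i in range(30)])
        res = assr.bootstrap_significance(trials, FS, n_resamples=1000,
                                          seed=1)
        assert res.p_value == pytest.approx(1 / 1001)

    def test_p_floor_and_determinism(self):
        rng = np.random.default_rng(2)
        trials = rng.standard_normal((10, 3750))
        r1 = assr.bootstrap_significance(trials, FS, n_resamples=500, seed=3)
        r2 = assr.bootstrap_significance(trials, FS, n_resamples=500, seed=3)
        assert r1.p_value == r2.p_value
        assert 1 / 501 <= r1.p_value <= 1.0

    def test_mean_contribution_equals_average_estimate(self):
        """Linearity: per-trial contributions average to the estimate of
        the trial average."""
        rng = np.random.default_rng(4)
        trials = rng.standard_normal((8, 3750))
        contrib = assr.trial_contributions(trials, FS)
        prep = assr.prepare_average(trials, FS)
        est = assr.compute_assr(prep, FS)
        assert abs(contrib.mean()) == pytest.approx(est.amplitude, rel=1e-6)

    def test_too_few_trials_raise(self):
        with pytest.raises(ValueError):
            assr.bootstrap_significance(np.zeros((1, 3750)), FS)

    def test_few_resamples_warn(self):
        rng = np.random.default_rng(5)
        with pytest.warns(UserWarning):
            assr.bootstrap_significance(rng.standard_normal((4, 3750)), FS,
                                        n_resamples=50, seed=0)


class TestLatency:
    def test_closed_form(self):
        lc = assr.latency_contrast(0.0, np.pi / 5)
        assert lc.delta_ms == pytest.approx(2.5)
        assert assr.latency_contrast(1.0, 1.0).delta_ms == 0.0

    def test_simulated_lag_difference_recovered(self):
        """A configured 4.39-ms lag difference between parameter sets is
        read back through the full estimator chain."""
        a = _clean_estimate(lag_ms=48.0)
        b = _clean_estimate(lag_ms=48.0 + 4.39)
        lc = assr.latency_contrast(a.phase_delay, b.phase_delay)
        assert lc.delta_ms == pytest.approx(4.39, abs=0.2)
        lch = assr.latency_contrast(a.hilbert_phase_delay,
                                    b.hilbert_phase_delay)
        assert lch.delta_ms == pytest.approx(4.39, abs=0.2)

    def test_condition_contrast_2_38ms(self):
        a = _clean_estimate(lag_ms=48.0, buildup=240.0)
        b = _clean_estimate(lag_ms=48.0 - 2.38, buildup=240.0)
        lc = assr.latency_contrast(a.phase_delay, b.phase_delay)
        assert lc.delta_ms == pytest.approx(-2.38, abs=0.2)

    @given(pa=st.floats(-np.pi + 1e-6, np.pi),
           pb=st.floats(-np.pi + 1e-6, np.pi))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_wrap_bounds_half_period(self, pa, pb):
        lc = assr.latency_contrast(pa, pb)
        assert abs(lc.delta_ms) <= 12.5
        assert -np.pi < lc.delta_phase <= np.pi


class TestLateralityAndAttenuation:
    def test_laterality_values(self):
        assert assr.laterality_index(1.0, 1.0).li == 0.0
        assert assr.laterality_index(1.0, 0.0).li == 1.0
        assert assr.laterality_index(1.13, 0.87).li == pytest.approx(0.13)

    def test_laterality_errors(self):
        with pytest.raises(ValueError):
            assr.laterality_index(0.0, 0.0)

    def test_attenuation_values(self):
        assert assr.attenuation_ratio(4.0, 1.0) == pytest.approx(75.0)
        assert assr.attenuation_ratio(2.2, 2.2) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            assr.attenuation_ratio(0.0, 1.0)

    def test_two_to_one_ratio_recovered_end_to_end(self):
        """quiet:noise source ratio 2:1 reads back as 50% attenuation."""
        stim = StimulusSpec()
        p = ParticipantSpec(
            id="x", group="young", age=25.0, pta_db=5.0,
            sin_loss_db=float("nan"), gaba={},
            sources={"quiet": SourceParams(6.0, 6.0, 48.0, 200.0),
                     "noise": SourceParams(3.0, 3.0, 46.0, 240.0)})
        amps = {}
        for cond in ("quiet", "noise"):
            trials = np.stack([
                trial_source_waveforms(p, cond, stim, seed=100 + i,
                                       background_rms_nAm=6.0)["left"]
                for i in range(40)])
            prep = assr.prepare_average(trials, FS)
            amps[cond] = assr.compute_assr(prep, FS).amplitude
        att = assr.attenuation_ratio(amps["quiet"], amps["noise"])
        assert att == pytest.approx(50.0, abs=3.0)
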