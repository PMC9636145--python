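"""Artifact removal, spectral cleaning, noise floor, and the acuity fit."""

import math

import numpy as np
import pytest

from pvretina.acuity import (
    NoiseFloor,
    bar_width_to_cpd,
    cpd_to_bar_width,
    fit_acuity,
    measure_amplitude,
    noise_floor,
    remove_artifact,
    reversal_amplitude,
    spectral_clean,
)
from pvretina.errors import DomainError, EstimationError
from pvretina.vep import GeneratorParams, synth_recording


class TestRemoveArtifact:
    def test_pure_scaled_template_removed_entirely(self):
        t = np.sin(np.linspace(0, 40 * np.pi, 4000))
        resid = remove_artifact(3.0 * t, t)
        assert np.max(np.abs(resid)) < 1e-12

    def test_orthogonal_component_unchanged(self):
        n = 4000
        x = np.linspace(0, 1, n)
        template = np.sin(2 * np.pi * 64 * x)
        response = np.sin(2 * np.pi * 2 * x)
        response -= (response @ template) / (template @ template) * template
        resid = remove_artifact(response + 5 * template, template)
        assert np.allclose(resid, response, atol=1e-10)
        assert abs(resid @ template) < 1e-8 * np.linalg.norm(template)

    def test_zero_template_rejected(self):
        with pytest.raises(DomainError):
            remove_artifact(np.ones(10), np.zeros(10))
        with pytest.raises(DomainError):
            remove_artifact(np.ones(10), np.ones(11))

    def test_synthetic_artifact_power_removed(self):
        """Residual carrier-locked power < 1% of the original."""
        p = GeneratorParams(noise_sd_trial=5.0)
        rec = synth_recording(p, [99.0], seed=3)[0]
        from pvretina.vep import synth_corneal_template

        tmpl = synth_corneal_template(
            p.carrier_pulse_ms, p.carrier_rate_hz, 4000.0, p.sampling_rate_hz
        )
        cleaned = remove_artifact(rec.trace, tmpl)
        p_before = (rec.trace @ tmpl) ** 2 / (tmpl @ tmpl)
        p_after = (cleaned @ tmpl) ** 2 / (tmpl @ tmpl)
        assert p_after < 0.01 * p_before


class TestSpectralClean:
    fs = 2000.0

    def test_subcarrier_band_preserved(self):
        t = np.arange(8000) / self.fs
        x = np.sin(2 * np.pi * 2.0 * t)
        y = spectral_clean(x, self.fs, 64.0)
        assert np.max(np.abs(y - x)) < 0.01 * np.max(np.abs(x))

    def test_carrier_suppressed_40db(self):
        t = np.arange(8000) / self.fs
        x = np.sin(2 * np.pi * 64.0 * t)
        y = spectral_clean(x, self.fs, 64.0)
        assert np.max(np.abs(y)) < 1e-2 * np.max(np.abs(x))  # > 40 dB

    def test_mixed_signal_recovery_within_2pct(self):
        t = np.arange(8000) / self.fs
        target = 7.0 * np.sin(2 * np.pi * 2.0 * t)
        x = target + 12.0 * np.sin(2 * np.pi * 64.0 * t) + 4.0 * np.sin(2 * np.pi * 128.0 * t)
        y = spectral_clean(x, self.fs, 64.0)
        spec = np.fft.rfft(y)
        freqs = np.fft.rfftfreq(len(y), 1 / self.fs)
        amp2 = 2 * np.abs(spec[np.argmin(np.abs(freqs - 2.0))]) / len(y)
        assert amp2 == pytest.approx(7.0, rel=0.02)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            spectral_clean(np.zeros(8000), self.fs, 1200.0)  # above Nyquist
        with pytest.raises(DomainError):
            spectral_clean(np.zeros(10), self.fs, 64.0)  # under two periods


class TestReversalAmplitude:
    def test_flat_trace_zero(self):
        assert reversal_amplitude(np.zeros(2000), 2000.0, 500.0) == 0.0

    def test_known_extrema(self):
        fs = 2000.0
        x = np.zeros(1000)  # one 500 ms reversal
        x[40] = 5.0  # +5 at 20 ms
        x[100] = -3.0  # -3 at 50 ms
        assert reversal_amplitude(x, fs, 500.0) == pytest.approx(8.0)

    def test_window_errors(self):
        with pytest.raises(DomainError):
            reversal_amplitude(np.zeros(2000), 2000.0, 500.0, window_ms=(100, 100))
        with pytest.raises(DomainError):
            reversal_amplitude(np.zeros(50), 2000.0, 500.0)


class TestNoiseFloor:
    def test_zero_noise_gives_zero_floor(self):
        p = GeneratorParams(noise_sd_trial=0.0, artifact_amplitude=0.0)
        recs = synth_recording(p, [120.0, 30.0], seed=0, static=True)
        nf = noise_floor(recs, template=False, clean=False)
        assert nf.mean == 0.0 and nf.sd == 0.0

    def test_requires_two_recordings(self):
        p = GeneratorParams()
        recs = synth_recording(p, [120.0], seed=0, static=True)
        with pytest.raises(DomainError):
            noise_floor(recs)

    def test_gaussian_mean_matches_order_statistic_oracle(self):
        """Mean p2p of white noise vs a brute-force range-statistic MC."""
        sigma_avg = 2.0
        n_trials = 4
        p = GeneratorParams(
            noise_sd_trial=sigma_avg * math.sqrt(n_trials),
            artifact_amplitude=0.0,
            n_trials=n_trials,
        )
        recs = synth_recording(
            p, list(range(1, 41)), seed=9, static=True, duration_ms=2000.0
        )
        nf = noise_floor(recs, template=False, clean=False)
        # oracle: expected range of 200 iid normals, simulated directly
        rng = np.random.default_rng(123)
        draws = rng.normal(0, sigma_avg, size=(4000, 200))
        expected = np.mean(draws.max(axis=1) - draws.min(axis=1))
        assert nf.mean == pytest.approx(expected, rel=0.03)


class TestFitAcuity:
    def widths(self):
        return [157.0, 120.0, 99.0, 81.0, 66.0, 54.0]

    def noiseless_amplitudes(self, beta0=-31.9, beta1=-12.0):
        return {w: beta0 + beta1 * math.log(1.0 / w) for w in self.widths()}

    def test_noiseless_points_give_analytic_intersection(self):
        nf = NoiseFloor(mean=8.89, sd=0.0, n=2)
        est = fit_acuity(self.noiseless_amplitudes(), nf)
        expected = math.exp((8.89 - (-31.9)) / -12.0) ** -1
        assert est.acuity_um == pytest.approx(expected, rel=1e-9)
        assert est.sd_um == pytest.approx(0.0, abs=1e-12)
        assert est.ci95_um[0] == pytest.approx(est.acuity_um, rel=1e-9)

    def test_all_points_below_noise_raises(self):
        nf = NoiseFloor(mean=100.0, sd=1.0, n=5)
        with pytest.raises(EstimationError):
            fit_acuity(self.noiseless_amplitudes(), nf)

    def test_nondeclining_amplitudes_raise(self):
        nf = NoiseFloor(mean=1.0, sd=0.0, n=2)
        rising = {w: 50.0 - 10.0 * math.log(w) for w in self.widths()}  # beta1 > 0
        with pytest.raises(EstimationError):
            fit_acuity(rising, nf)

    def test_higher_noise_gives_coarser_acuity(self):
        amps = self.noiseless_amplitudes()
        a_lo = fit_acuity(amps, NoiseFloor(mean=8.0, sd=0.0, n=2)).acuity_um
        a_hi = fit_acuity(amps, NoiseFloor(mean=12.0, sd=0.0, n=2)).acuity_um
        assert a_hi > a_lo

    def test_ci_uses_printed_multiplier(self):
        rng = np.random.default_rng(0)
        amps = {
            w: v + rng.normal(0, 2.0, 5)
            for w, v in self.noiseless_amplitudes().items()
        }
        nf = NoiseFloor(mean=8.89, sd=2.5, n=10)
        est = fit_acuity(amps, nf)
        assert est.ci95_um[1] - est.acuity_um == pytest.approx(1.92 * est.sd_um)
        est96 = fit_acuity(amps, nf, ci_multiplier=1.96)
        assert est96.ci95_um[1] - est96.acuity_um == pytest.approx(1.96 * est96.sd_um)


class TestUnitConversion:
    def test_printed_example(self):
        assert bar_width_to_cpd(27.9) == pytest.approx(1.15, abs=0.005)

    def test_exact_arithmetic(self):
        assert bar_width_to_cpd(32.15) == pytest.approx(1.000, rel=1e-9)

    def test_round_trip_identity(self):
        for w in [13.0, 27.9, 64.3, 157.0]:
            assert cpd_to_bar_width(bar_width_to_cpd(w)) == pytest.approx(w, rel=1e-12)

    def test_uncertainty_propagation(self):
        cpd, sd = bar_width_to_cpd(27.9, factor_sd=2.9)
        assert sd == pytest.approx(cpd * 2.9 / 64.3)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            bar_width_to_cpd(0.0)
        with pytest.raises(DomainError):
            cpd_to_bar_width(-1.0)


from hypothesis import given, settings, strategies as st


@settings(deadline=None, derandomize=True)
@given(
    w=st.floats(min_value=1.0, max_value=500.0),
    factor=st.floats(min_value=30.0, max_value=100.0),
)
def test_unit_conversion_round_trip_property(w, factor):
    assert cpd_to_bar_width(bar_width_to_cpd(w, factor), factor) == pytest.approx(
        w, rel=1e-12
    )
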