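"""Synthetic sweep-VEP recordings and stimulus-artifact templates.

The generator emulates the *statistics* of cortical recordings during
alternating-grating stimulation, not cortical physiology: a reversal-locked
biphasic response whose amplitude declines log-linearly with grating
density, a carrier-locked stimulus artifact, and white Gaussian noise whose
trial-averaged peak-to-peak floor matches the observed static-grating noise
level.  Recordings sample at 2 kHz; gratings reverse every 500 ms while the
near-infrared carrier pulses at 64 Hz.

Amplitude model (uV), with s = 1/bar_width in 1/um:

    A(s) = max(0, beta0 + beta1 * ln s),      beta1 < 0

so the response declines toward fine gratings and the acuity is the bar
width where A(s) meets the noise floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, TimingError

__all__ = [
    "GeneratorParams",
    "VEPRecording",
    "response_template",
    "synth_corneal_template",
    "synth_recording",
    "synth_cohort",
]


def response_template(t_ms: np.ndarray, n1_latency_ms: float = 30.0) -> np.ndarray:
    """Reversal-locked biphasic response, unit peak-to-peak, support in 0-100 ms.

    A damped sine with its dominant (N1-like) negative deflection near
    ``n1_latency_ms`` followed by a positive rebound; identically zero
    outside the first 100 ms after the reversal.
    """
    t = np.asarray(t_ms, float)
    w = np.zeros_like(t)
    inside = (t >= 0) & (t <= 100.0)
    ti = t[inside]
    shape = -np.sin(math.pi * ti / (2.0 * n1_latency_ms)) * np.exp(-ti / 45.0)
    shape *= np.sin(math.pi * ti / 100.0) ** 0.25  # soft onset/offset
    w[inside] = shape
    p2p = w.max() - w.min()
    return w / p2p if p2p > 0 else w


@dataclass(frozen=True)
class GeneratorParams:
    """Statistical parameters of the synthetic VEP generator.

    Amplitude-model defaults put the analytic acuity near 30 um
    (``exp((noise - beta0)/beta1) = 1/29.9 um^-1`` with the default noise
    mean); the per-trial noise SD is calibrated so that averaging 250 trials
    leaves a static-grating peak-to-peak floor of about 8.9 uV, and the
    per-animal noise spread reproduces the observed 2.52 uV scatter.
    """

    beta0: float = -31.9  # uV
    beta1: float = -12.0  # uV per ln(1/um); negative: decline toward fine gratings
    beta0_sd_animal: float = 6.0  # uV, per-animal intercept scatter
    noise_sd_trial: float = 26.0  # uV per trial per sample
    noise_scale_sd_animal: float = 0.2835  # fractional per-animal noise spread
    artifact_amplitude: float = 25.0  # uV
    sampling_rate_hz: float = 2000.0
    carrier_rate_hz: float = 64.0
    carrier_pulse_ms: float = 4.0
    reversal_period_ms: float = 500.0
    n_trials: int = 250
    n1_latency_ms: float = 30.0

    def amplitude(self, bar_width_um) -> np.ndarray | float:
        """Mean reversal-response amplitude A(s), uV, clipped at zero."""
        w = np.asarray(bar_width_um, float)
        if np.any(w <= 0):
            raise DomainError("bar widths must be positive")
        a = self.beta0 + self.beta1 * np.log(1.0 / w)
        out = np.maximum(a, 0.0)
        return float(out) if np.isscalar(bar_width_um) else out

    def analytic_acuity(self, noise_mean_uv: float) -> float:
        """Bar width (um) where A(s) crosses a given noise level."""
        s_star = math.exp((noise_mean_uv - self.beta0) / self.beta1)
        return 1.0 / s_star


@dataclass
class VEPRecording:
    """One synthetic recording (trial-averaged trace in uV at 2 kHz)."""

    t_ms: np.ndarray
    trace: np.ndarray  # trial-averaged, uV
    bar_width_um: float
    n_trials: int
    sampling_rate_hz: float
    carrier_rate_hz: float
    reversal_period_ms: float
    static: bool
    seed: int
    trials: np.ndarray | None = None  # (n_trials, T), only if requested

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame({"t_ms": self.t_ms, "vep_uV": self.trace})
        with open(path, "w") as fh:
            fh.write(
                f"# bar_width_um={self.bar_width_um} n_trials={self.n_trials} "
                f"fs_Hz={self.sampling_rate_hz} carrier_Hz={self.carrier_rate_hz} "
                f"reversal_ms={self.reversal_period_ms} static={self.static} "
                f"seed={self.seed}\n"
            )
            df.to_csv(fh, index=False)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("t_ms", data=self.t_ms)
            fh.create_dataset("vep_uV", data=self.trace)
            if self.trials is not None:
                fh.create_dataset("trials_uV", data=self.trials)
            fh.attrs.update(
                {
                    "bar_width_um": self.bar_width_um,
                    "n_trials": self.n_trials,
                    "fs_Hz": self.sampling_rate_hz,
                    "carrier_Hz": self.carrier_rate_hz,
                    "reversal_ms": self.reversal_period_ms,
                    "static": self.static,
                    "seed": self.seed,
                }
            )


def synth_corneal_template(
    pulse_width_ms: float,
    rate_hz: float,
    duration_ms: float,
    fs_hz: float = 2000.0,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Stimulus-locked corneal artifact template.

    A positive deflection confined to each pulse-locked window (the
    ``pulse_width_ms``-long segment after every carrier pulse onset), zero
    elsewhere.  A simulated far-field waveform from the circuit model can be
    substituted for this parametric shape.
    """
    if pulse_width_ms <= 0 or pulse_width_ms >= 1000.0 / rate_hz:
        raise TimingError("pulse width must be positive and shorter than the period")
    t = np.arange(0.0, duration_ms, 1000.0 / fs_hz)
    phase = t % (1000.0 / rate_hz)
    inside = phase < pulse_width_ms
    out = np.zeros_like(t)
    # half-sine within the pulse window: positive, zero at the window edges
    out[inside] = amplitude * np.sin(math.pi * phase[inside] / pulse_width_ms)
    return out


def _signal_trace(
    t_ms: np.ndarray, amplitude_uv: float, reversal_ms: float, n1_latency_ms: float
) -> np.ndarray:
    sig = np.zeros_like(t_ms)
    n_rev = int(math.floor(t_ms[-1] / reversal_ms)) + 1
    for k in range(n_rev):
        sig += amplitude_uv * response_template(t_ms - k * reversal_ms, n1_latency_ms)
    return sig


def synth_recording(
    params: GeneratorParams,
    bar_widths_um,
    seed: int,
    *,
    duration_ms: float = 4000.0,
    static: bool = False,
    noise_scale: float = 1.0,
    beta0_offset: float = 0.0,
    keep_trials: bool = False,
) -> list[VEPRecording]:
    """Generate one recording per bar width for a single simulated animal.

    Each trial is ``A(s) * template + artifact + N(0, sigma)``; the returned
    trace is the trial average (noise SD reduced by sqrt(n_trials)).
    ``static=True`` suppresses the reversal response (static-grating noise
    recordings).  Identical seeds give identical traces.
    """
    bar_widths = list(np.atleast_1d(np.asarray(bar_widths_um, float)))
    if not bar_widths:
        raise DomainError("bar_widths must not be empty")
    if any(w <= 0 for w in bar_widths):
        raise DomainError("bar widths must be positive")
    rng = np.random.default_rng(seed)
    fs = params.sampling_rate_hz
    t = np.arange(0.0, duration_ms, 1000.0 / fs)
    artifact = synth_corneal_template(
        params.carrier_pulse_ms,
        params.carrier_rate_hz,
        duration_ms,
        fs,
        params.artifact_amplitude,
    )
    out = []
    eff = replace(params, beta0=params.beta0 + beta0_offset)
    for w in bar_widths:
        amp = 0.0 if static else eff.amplitude(w)
        sig = _signal_trace(t, amp, params.reversal_period_ms, params.n1_latency_ms)
        sigma = params.noise_sd_trial * noise_scale
        if keep_trials:
            noise = rng.normal(0.0, sigma, size=(params.n_trials, len(t)))
            trials = sig[None, :] + artifact[None, :] + noise
            trace = trials.mean(axis=0)
        else:
            trials = None
            trace = sig + artifact + rng.normal(
                0.0, sigma / math.sqrt(params.n_trials), size=len(t)
            )
        out.append(
            VEPRecording(
                t_ms=t,
                trace=trace,
                bar_width_um=float(w),
                n_trials=params.n_trials,
                sampling_rate_hz=fs,
                carrier_rate_hz=params.carrier_rate_hz,
                reversal_period_ms=params.reversal_period_ms,
                static=static,
                seed=seed,
                trials=trials,
            )
        )
    return out


def synth_cohort(
    params: GeneratorParams,
    bar_widths_um,
    n_animals: int,
    seed: int,
    *,
    duration_ms: float = 4000.0,
    static_widths_um=(120.0, 30.0),
) -> dict:
    """Alternating-grating and static-grating recordings for a simulated cohort.

    Per-animal variation: the amplitude intercept beta0 and the noise scale
    are drawn once per animal.  Returns ``{"animals": [...]}`` where each
    animal holds its alternating recordings (one per bar width) and its
    static noise-floor recordings.
    """
    if n_animals < 1:
        raise DomainError("need at least one animal")
    rng = np.random.default_rng(seed)
    animals = []
    for a in range(n_animals):
        b0_off = rng.normal(0.0, params.beta0_sd_animal)
        nscale = max(0.1, rng.normal(1.0, params.noise_scale_sd_animal))
        sub = int(rng.integers(0, 2**31 - 1))
        rec = synth_recording(
            params, bar_widths_um, sub, duration_ms=duration_ms,
            beta0_offset=b0_off, noise_scale=nscale,
        )
        stat = synth_recording(
            params, static_widths_um, sub + 1, duration_ms=duration_ms,
            static=True, noise_scale=nscale,
        )
        animals.append(
            {"id": a, "beta0_offset": b0_off, "noise_scale": nscale,
             "recordings": rec, "static": stat}
        )
    return {"animals": animals, "bar_widths_um": list(np.atleast_1d(bar_widths_um))}
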