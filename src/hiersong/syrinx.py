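"""Sound production: a two-parameter labia oscillator model of the syrinx.

The avian vocal organ is reduced to the position x of the labia relative
to the syrinx midline, driven by the two vocal control signals -- air-sac
pressure p(t) and labia stiffness k(t):

    x'' = r (p - beta) x' - c x^2 x' - k x

(a simplified Titze-style vocal-fold model with polynomial nonlinear
dissipation).  The linear dissipation constant beta is the phonation
threshold: for p < beta the origin is stable and the labia are silent
(mini-breaths between syllables); for p > beta a Hopf bifurcation yields
a self-sustained limit cycle whose amplitude is saturated by the cubic
dissipation c and whose fundamental frequency grows monotonically with
the stiffness k (approximately sqrt(k)/2pi for small amplitude).  The
scalar r converts the dimensionless pressure excess into a growth rate
per second.  Integration runs at the audio sampling rate with classic
fixed-step 4th-order Runge-Kutta; control signals are linearly
interpolated from the model-time grid using the model-seconds-per-unit
factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .errors import (
    DivergenceError,
    InvalidControlError,
    InvalidParameterError,
)
from .oscillators import ControlSignal

__all__ = [
    "SyrinxParams",
    "Waveform",
    "synthesize",
    "phonation_threshold",
    "sonogram",
    "write_wav",
]


@dataclass
class SyrinxParams:
    beta: float = 1.0            # linear dissipation = phonation threshold (pressure units)
    c: float = 3000.0            # cubic dissipation, saturates the limit cycle
    timescale: float = 0.08      # seconds of real time per model time unit
    sample_rate: int = 12000     # Hz
    pressure_rate: float = 1000.0  # growth rate per unit pressure excess, 1/s
    noise_floor: float = 20.0    # aerodynamic forcing sd (labia velocity units/s)

    def __post_init__(self):
        if min(self.beta, self.c, self.timescale, self.pressure_rate) <= 0:
            raise InvalidParameterError("syrinx parameters must be positive")
        if self.noise_floor < 0:
            raise InvalidParameterError("noise_floor must be nonnegative")
        if self.sample_rate < 2000:
            raise InvalidParameterError("sample rate too low for song synthesis")


@dataclass
class Waveform:
    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidParameterError("waveform must be one-dimensional")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


def phonation_threshold(params: SyrinxParams) -> float:
    """Critical pressure below which no phonation is produced.

    The origin of the labia equation loses stability when the linear
    damping r (p - beta) changes sign, i.e. exactly at p = beta.  The
    marginal case p == beta is non-phonating by convention.
    """
    return params.beta


# integration guard for the labia position
_LABIA_BOUND = 1e3


def synthesize(
    control: ControlSignal,
    params: SyrinxParams | None = None,
    x0: tuple[float, float] = (1e-3, 0.0),
    seed: int = 0,
) -> Waveform:
    """Integrate the labia equation under the control signal; x(t) is the sound.

    The control times are interpreted in model units and stretched by
    ``params.timescale`` onto a real-time audio grid at ``sample_rate``.
    A weak seeded stochastic forcing on the labia velocity emulates the
    aerodynamic noise floor that re-seeds phonation after each silent
    interval; set ``noise_floor=0`` for the strictly deterministic
    equation.  Output is deterministic given (control, params, x0, seed).
    """
    params = params or SyrinxParams()
    if (control.k <= 0).any():
        raise InvalidControlError("stiffness k(t) must be positive everywhere")
    t_model = control.times
    t_end = (t_model[-1] - t_model[0]) * params.timescale
    n = int(np.floor(t_end * params.sample_rate)) + 1
    t_audio = np.arange(n) / params.sample_rate
    t_src = (t_model - t_model[0]) * params.timescale
    p = np.interp(t_audio, t_src, control.p)
    k = np.interp(t_audio, t_src, control.k)

    r, beta, c = params.pressure_rate, params.beta, params.c
    dt = 1.0 / params.sample_rate
    x, v = float(x0[0]), float(x0[1])
    out = np.empty(n)
    if params.noise_floor > 0:
        rng = np.random.default_rng(seed)
        forcing = params.noise_floor * np.sqrt(dt) * rng.standard_normal(n)
    else:
        forcing = np.zeros(n)
    # fixed-step RK4 with the controls held on the midpoint by averaging
    for i in range(n):
        out[i] = x
        if abs(x) > _LABIA_BOUND:
            raise DivergenceError(
                f"labia position diverged at t={t_audio[i]:.4f} s",
                time=float(t_audio[i]),
            )
        p0, k0 = p[i], k[i]
        p1, k1 = p[min(i + 1, n - 1)], k[min(i + 1, n - 1)]
        pm, km = 0.5 * (p0 + p1), 0.5 * (k0 + k1)

        a1 = v
        b1 = r * (p0 - beta) * v - c * x * x * v - k0 * x
        x2, v2 = x + 0.5 * dt * a1, v + 0.5 * dt * b1
        a2 = v2
        b2 = r * (pm - beta) * v2 - c * x2 * x2 * v2 - km * x2
        x3, v3 = x + 0.5 * dt * a2, v + 0.5 * dt * b2
        a3 = v3
        b3 = r * (pm - beta) * v3 - c * x3 * x3 * v3 - km * x3
        x4, v4 = x + dt * a3, v + dt * b3
        a4 = v4
        b4 = r * (p1 - beta) * v4 - c * x4 * x4 * v4 - k1 * x4
        x += dt * (a1 + 2 * a2 + 2 * a3 + a4) / 6.0
        v += dt * (b1 + 2 * b2 + 2 * b3 + b4) / 6.0 + forcing[i]
    return Waveform(samples=out, sample_rate=params.sample_rate)


def sonogram(w: Waveform, window_len: int = 256, hop: int = 64) -> tuple[
    np.ndarray, np.ndarray, np.ndarray
]:
    """Short-time Fourier magnitude (Hann window).

    Returns (frequencies, frame times, magnitude matrix F x T).
    """
    if len(w.samples) == 0:
        raise InvalidParameterError("empty waveform")
    if window_len < 16 or hop < 1:
        raise InvalidParameterError("window_len >= 16 and hop >= 1 required")
    stft = ShortTimeFFT(
        hann(window_len, sym=False), hop=hop, fs=w.sample_rate, scale_to="magnitude"
    )
    mag = np.abs(stft.stft(w.samples))
    times = stft.t(len(w.samples))
    return stft.f, times, mag


def write_wav(path, w: Waveform, peak: float = 0.9) -> None:
    """16-bit PCM mono writer, peak-normalized to ``peak`` of full scale."""
    top = np.abs(w.samples).max()
    scaled = w.samples * (peak / top) if top > 0 else w.samples
    wavfile.write(path, w.sample_rate, np.round(scaled * 32767).astype(np.int16))
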