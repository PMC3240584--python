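"""Vocal control signals from a bank of RA-gated harmonic oscillators.

The lowest neural level holds five quadrature-pair oscillators at integer
multiples of a fundamental angular frequency omega.  Their hidden
dynamics are autonomous (each pair rotates at kappa * m_i * omega); the
RA output gates them multiplicatively at the output:

    y1(t) = sum_i v_i(t) * s_i(t)

where s_i is the sine component of oscillator i and v_i the normalized
firing rate of RA ensemble i.  The second output is the phase-delayed
copy y2(t) = sum_i v_i(t) * s_i(t - phi), realized by rotating each
quadrature pair backwards by kappa * m_i * omega * phi, so that for
constant gates y2 is exactly the time-shifted copy of y1.  Affine maps
turn (y1, y2) into the two vocal control signals: air-sac pressure
p = a_p + b_p y1 (dimensionless, phonation threshold units) and labia
stiffness k = a_k + b_k y2 (rad^2/s^2, setting the fundamental frequency
of the syrinx).  Sweeping one oscillator traces ellipse-like closed
orbits in the (p, k) plane; mixtures of harmonics deform these ellipses
into the richer curves that encode syllables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .errors import AlignmentError, ConfigurationError, InvalidParameterError
from .hvc import LevelTrajectory

__all__ = ["OscParams", "ControlSignal", "simulate_oscillators", "control_signals"]


@dataclass
class OscParams:
    fundamental: float = 2.0 * np.pi / 5.0   # omega, rad per model time unit
    multipliers: tuple = (1, 2, 3, 4, 5)
    phase_shift: float = 1.25                # phi, model time units (quarter period)
    rate: float = 1.0                        # kappa, joint frequency scale
    p_affine: tuple = (0.8, 1.0)             # (a_p, b_p), pressure units
    k_affine: tuple = (1.58e7, 9.8e6)        # (a_k, b_k), rad^2/s^2
    noise_sd_hidden: float = 1e-3
    noise_sd_causal: float = 1e-4
    radial_rate: float = 4.0                 # unit-amplitude restoring rate

    def __post_init__(self):
        mult = tuple(int(m) for m in self.multipliers)
        if any(m <= 0 for m in mult) or list(mult) != sorted(set(mult)):
            raise InvalidParameterError(
                "multipliers must be strictly increasing positive integers"
            )
        self.multipliers = mult
        if self.fundamental <= 0 or self.rate <= 0:
            raise InvalidParameterError("fundamental and rate must be positive")
        if self.p_affine[1] == 0 or self.k_affine[1] == 0:
            raise InvalidParameterError("affine slopes b_p, b_k must be nonzero")

    @property
    def n_oscillators(self) -> int:
        return len(self.multipliers)

    @property
    def omegas(self) -> np.ndarray:
        """Effective angular frequencies kappa * m_i * omega."""
        return self.rate * self.fundamental * np.asarray(self.multipliers, float)


@dataclass
class ControlSignal:
    """Two-channel vocal control time series: pressure p(t), stiffness k(t)."""

    times: np.ndarray
    p: np.ndarray
    k: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if not (len(self.times) == len(self.p) == len(self.k)):
            raise AlignmentError("times, p, k must have equal length")
        if not (np.all(np.isfinite(self.p)) and np.all(np.isfinite(self.k))):
            raise InvalidParameterError("control signal must be finite")


def oscillator_states(params: OscParams, times: np.ndarray,
                      seed: int | None = None) -> np.ndarray:
    """Limit-cycle quadrature-pair hidden states.

    Each oscillator is a Stuart-Landau unit cycle: phase advances at its
    angular frequency while the radius relaxes to 1 at ``radial_rate``
    (dr/dt = radial_rate * r * (1 - r^2)).  On the unit cycle this is
    exactly the harmonic (sine/cosine) pair; the restoring force pins the
    amplitude against state noise.  Integration splits each step into an
    exact rotation and the exact radial relaxation.  Returns a T x 2n
    array ordered (s_1, c_1, s_2, c_2, ...).
    """
    omegas = params.omegas
    dt = float(times[1] - times[0])
    n = params.n_oscillators
    state = np.zeros((len(times), 2 * n))
    s = np.zeros(n)
    c = np.ones(n)
    cos_d, sin_d = np.cos(omegas * dt), np.sin(omegas * dt)
    decay = np.exp(-2.0 * params.radial_rate * dt)
    rng = np.random.default_rng(seed)
    sw = params.noise_sd_hidden
    sqdt = np.sqrt(dt)
    for t in range(len(times)):
        state[t, 0::2] = s
        state[t, 1::2] = c
        s, c = s * cos_d + c * sin_d, c * cos_d - s * sin_d
        r2 = s * s + c * c
        scale = np.sqrt(1.0 / (decay + (1.0 - decay) * np.where(r2 > 0, r2, 1.0)))
        s, c = s * scale, c * scale
        if sw > 0:
            s = s + sw * sqdt * rng.standard_normal(n)
            c = c + sw * sqdt * rng.standard_normal(n)
    return state


def delayed_sine(state: np.ndarray, params: OscParams) -> np.ndarray:
    """Sine components rotated back by the phase shift phi (per oscillator)."""
    theta = params.omegas * params.phase_shift
    s, c = state[..., 0::2], state[..., 1::2]
    return s * np.cos(theta) - c * np.sin(theta)


def simulate_oscillators(
    params: OscParams,
    ra_causal: LevelTrajectory,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray, LevelTrajectory]:
    """Gate the oscillator bank with RA output; return (y1, y2, hidden).

    Channel i of the RA causal trajectory gates oscillator i linearly.
    y1 mixes the sine components; y2 mixes the phase-delayed sines, which
    for piecewise-constant gates equals y1 delayed by phi.
    """
    gates = ra_causal.causal
    if gates.shape[1] != params.n_oscillators:
        raise ConfigurationError(
            f"RA trajectory has {gates.shape[1]} channels but there are "
            f"{params.n_oscillators} oscillators"
        )
    rng = np.random.default_rng(seed)
    state = oscillator_states(
        params, ra_causal.times,
        seed=rng.integers(2 ** 31) if params.noise_sd_hidden > 0 else None,
    )
    y1 = np.sum(gates * state[:, 0::2], axis=1)
    y2 = np.sum(gates * delayed_sine(state, params), axis=1)
    sz = params.noise_sd_causal
    if sz > 0:
        y1 = y1 + sz * rng.standard_normal(len(y1))
        y2 = y2 + sz * rng.standard_normal(len(y2))
    hidden = LevelTrajectory(
        times=ra_causal.times.copy(),
        hidden=state,
        causal=np.column_stack([y1, y2]),
    )
    return y1, y2, hidden


def control_signals(y1: np.ndarray, y2: np.ndarray, params: OscParams,
                    times: np.ndarray | None = None) -> ControlSignal:
    """Affine maps to air-sac pressure and labia stiffness.

    p = a_p + b_p y1 and k = a_k + b_k y2.  A non-positive stiffness
    anywhere is unphysical and triggers a configuration warning.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.shape != y2.shape:
        raise AlignmentError("y1 and y2 must be aligned")
    a_p, b_p = params.p_affine
    a_k, b_k = params.k_affine
    p = a_p + b_p * y1
    k = a_k + b_k * y2
    if (k <= 0).any():
        warnings.warn(
            "stiffness k(t) is non-positive somewhere: unphysical configuration",
            UserWarning,
            stacklevel=2,
        )
    if times is None:
        times = np.arange(len(p), dtype=float)
    return ControlSignal(times=times, p=p, k=k)
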