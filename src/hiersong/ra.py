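"""Attractor coding in RA: an asymmetric continuous Hopfield network.

The middle level models ``M`` RA ensembles whose membrane potentials obey

    dx/dt = kappa * C (-x + W tanh(x) + I)

with a diagonal positive rate matrix ``C`` and a (generally asymmetric)
synaptic matrix ``W`` whose spectral norm is kept below 1, the classical
sufficient condition (for unit-slope tanh) for a *unique, globally
asymptotically stable* equilibrium under any constant input.  Each HVC
ensemble supplies a constant input vector ``I`` that places that global
equilibrium on a chosen sign pattern xi in {+a, -a}^M -- a combination of
"active" and "inactive" RA ensembles.  As the HVC sequence unfolds, the
input switches and the network flows from attractor to attractor,
realizing the spatiotemporal code that drives the vocal output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    AlignmentError,
    DivergenceError,
    InvalidParameterError,
    InvalidSizeError,
)
from .hvc import NORM_CONST, STATE_BOUND, LevelTrajectory, normalize

__all__ = [
    "RAParams",
    "AttractorPattern",
    "is_globally_stable",
    "input_for_pattern",
    "ra_drift",
    "simulate_ra",
    "enumerate_patterns",
    "decode_pattern",
    "random_stable_weights",
]


def random_stable_weights(m: int, spectral_norm: float = 0.6, seed: int = 7) -> np.ndarray:
    """Random asymmetric synaptic matrix rescaled to the given spectral norm."""
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((m, m))
    return w * (spectral_norm / np.linalg.norm(w, 2))


@dataclass(frozen=True)
class AttractorPattern:
    """A nonempty subset of active RA ensembles (1-based indices)."""

    active_set: frozenset

    def __post_init__(self):
        object.__setattr__(self, "active_set", frozenset(int(i) for i in self.active_set))
        if not self.active_set:
            raise InvalidParameterError("active_set must be nonempty")
        if min(self.active_set) < 1:
            raise InvalidParameterError("ensemble indices are 1-based")

    def target(self, m: int, amplitude: float) -> np.ndarray:
        """Signed target state xi: +amplitude on the active set, -amplitude off it."""
        if max(self.active_set) > m:
            raise InvalidSizeError(f"pattern {sorted(self.active_set)} exceeds M={m}")
        xi = np.full(m, -float(amplitude))
        xi[[i - 1 for i in self.active_set]] = float(amplitude)
        return xi


@dataclass
class RAParams:
    n_ensembles: int = 5
    rate: float = 1.0                 # kappa
    rate_diag: np.ndarray = None      # diagonal of C, 1/time
    connectivity: np.ndarray = None   # W
    attractor_amplitude: float = 2.0  # a; tanh(+-a) ~ +-0.96
    noise_sd_hidden: float = 1e-3
    noise_sd_causal: float = 1e-4
    norm_const: float = NORM_CONST

    def __post_init__(self):
        m = self.n_ensembles
        if m < 1:
            raise InvalidSizeError("need at least 1 RA ensemble")
        if self.rate_diag is None:
            self.rate_diag = np.full(m, 2.0)
        self.rate_diag = np.asarray(self.rate_diag, dtype=float)
        if self.rate_diag.shape != (m,) or (self.rate_diag <= 0).any():
            raise InvalidParameterError("C must be diagonal with positive entries")
        if self.connectivity is None:
            self.connectivity = random_stable_weights(m)
        self.connectivity = np.asarray(self.connectivity, dtype=float)
        if self.connectivity.shape != (m, m):
            raise InvalidSizeError(f"W must be {m}x{m}")
        if self.rate <= 0 or self.attractor_amplitude <= 0:
            raise InvalidParameterError("rate and amplitude must be positive")
        ok, cert = is_globally_stable(self.connectivity, np.diag(self.rate_diag))
        if not ok:
            raise InvalidParameterError(
                f"W fails the global-stability certificate: |W|_2 = "
                f"{cert['spectral_norm']:.3f} >= 1"
            )

    @classmethod
    def default(cls, m: int = 5, spectral_norm: float = 0.6, seed_w: int = 7,
                **kwargs) -> "RAParams":
        return cls(
            n_ensembles=m,
            connectivity=random_stable_weights(m, spectral_norm, seed_w),
            **kwargs,
        )


def is_globally_stable(W: np.ndarray, C: np.ndarray | None = None) -> tuple[bool, dict]:
    """Sufficient certificate for a unique globally stable equilibrium.

    For the network dx/dt = C(-x + W tanh x + I) with unit-slope tanh and
    any constant I, a spectral norm of W strictly below 1 guarantees a
    unique equilibrium that attracts every trajectory (a Matsuoka-type
    contraction condition).  The certificate records the computed norm.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InvalidSizeError("W must be a square matrix")
    if C is not None:
        C = np.asarray(C, dtype=float)
        if C.shape != W.shape:
            raise InvalidSizeError("C and W dimensions disagree")
    norm = float(np.linalg.norm(W, 2))
    return norm < 1.0, {"spectral_norm": norm, "bound": 1.0}


def input_for_pattern(pattern: AttractorPattern, params: RAParams) -> np.ndarray:
    """Constant input that places the global equilibrium on the pattern.

    Solves the equilibrium condition 0 = -xi + W tanh(xi) + I for I, so
    the (unique, globally attracting) fixed point of the driven network is
    exactly the signed target xi of the pattern.
    """
    xi = pattern.target(params.n_ensembles, params.attractor_amplitude)
    return xi - params.connectivity @ np.tanh(xi)


def ra_drift(x: np.ndarray, I: np.ndarray, params: RAParams) -> np.ndarray:
    """Drift kappa * C(-x + W tanh x + I)."""
    x = np.asarray(x, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(I))):
        raise InvalidParameterError("non-finite input to ra_drift")
    return params.rate * params.rate_diag * (
        -x + params.connectivity @ np.tanh(x) + I
    )


def ra_drift_jacobian(x: np.ndarray, params: RAParams) -> np.ndarray:
    sech2 = 1.0 - np.tanh(np.asarray(x, dtype=float)) ** 2
    m = params.n_ensembles
    jac = params.connectivity * sech2[None, :] - np.eye(m)
    return params.rate * params.rate_diag[:, None] * jac


def ra_output(x: np.ndarray, norm_const: float = NORM_CONST) -> np.ndarray:
    """Normalized firing-rate output v = H((tanh x + 1) / 2)."""
    return normalize((np.tanh(x) + 1.0) / 2.0, norm_const)


def enumerate_patterns(m: int) -> list[AttractorPattern]:
    """All 2^M - 1 nonempty activation patterns, in binary-counting order."""
    if m < 1:
        raise InvalidParameterError("M must be at least 1")
    patterns = []
    for code in range(1, 2 ** m):
        active = frozenset(i + 1 for i in range(m) if code >> i & 1)
        patterns.append(AttractorPattern(active))
    return patterns


def decode_pattern(x: np.ndarray) -> frozenset:
    """Active set (1-based) read off the sign pattern of a hidden state."""
    return frozenset(int(i) + 1 for i in np.flatnonzero(np.asarray(x) > 0))


def input_matrix(patterns, params: RAParams) -> np.ndarray:
    """M x N matrix whose k-th column steers RA onto the k-th pattern."""
    return np.column_stack([input_for_pattern(p, params) for p in patterns])


def simulate_ra(
    params: RAParams,
    hvc_causal: LevelTrajectory,
    patterns,
    seed: int | None = 0,
    x0: np.ndarray | None = None,
) -> LevelTrajectory:
    """Integrate the RA network driven by the HVC output mixture.

    ``patterns`` is the ordered list of attractor patterns, one per HVC
    ensemble; ensemble k contributes the input vector steering RA onto
    pattern k, and the total drive at time t is the linear combination
    I(t) = sum_k v_hvc_k(t) I_k.  Returns hidden states plus two causal
    outputs: ``causal`` holds the normalized rates H((tanh x + 1)/2) that
    gate the oscillators, ``causal_aux`` the unnormalized rates
    (tanh x + 1)/2.
    """
    m = params.n_ensembles
    v3 = hvc_causal.causal
    if len(patterns) != v3.shape[1]:
        raise AlignmentError(
            "score length must equal the HVC ensemble count "
            f"({len(patterns)} patterns vs {v3.shape[1]} channels)"
        )
    input_vectors = input_matrix(patterns, params)
    rng = np.random.default_rng(seed)
    dt = hvc_causal.dt
    steps = len(hvc_causal.times)
    x = np.zeros(m) if x0 is None else np.array(x0, dtype=float)
    hidden = np.empty((steps, m))
    sw, sz = params.noise_sd_hidden, params.noise_sd_causal
    sqdt = np.sqrt(dt)
    drive = v3 @ input_vectors.T
    for t in range(steps):
        hidden[t] = x
        if np.abs(x).max() > STATE_BOUND:
            raise DivergenceError(
                f"RA state exceeded bound at t={hvc_causal.times[t]:.4f}",
                time=float(hvc_causal.times[t]),
            )
        dx = ra_drift(x, drive[t], params) * dt
        if sw > 0:
            dx += sw * sqdt * rng.standard_normal(m)
        x = x + dx
    raw = (np.tanh(hidden) + 1.0) / 2.0
    causal = normalize(raw, params.norm_const)
    if sz > 0:
        causal = np.clip(causal + sz * rng.standard_normal(causal.shape), 0.0, 1.0)
        raw = np.clip(raw + sz * rng.standard_normal(raw.shape), 0.0, 1.0)
    return LevelTrajectory(
        times=hvc_causal.times.copy(), hidden=hidden, causal=causal, causal_aux=raw
    )
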