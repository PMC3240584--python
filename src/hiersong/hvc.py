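"""Sequential premotor dynamics: a stable heteroclinic chain of HVC ensembles.

The top level of the song hierarchy models the sparse, temporally precise
sequence of HVC projection-neuron ensembles as winnerless competition
between ``N`` neural-mass units.  Each unit carries a mean membrane
potential (hidden state) ``x_i`` and a firing-rate output obtained by a
logistic sigmoid ``S`` followed by divisive normalization ``H``.  The
drift is a generalized Lotka-Volterra competition with linear decay:

    dx_i/dt = kappa * [ S(x_i) * (1 - sum_j rho_ij S(x_j)) - lambda x_i ]

With asymmetric lateral inhibition -- weak from the currently active
ensemble onto its successor, strong onto everybody else -- the saddle
(single-winner) states form a cyclic chain that the flow visits in index
order, activating each ensemble once per cycle.  The rate constant
``kappa`` rescales time exactly, which is the model's account of the HVC
cooling experiments: halving ``kappa`` doubles every activation duration
without changing the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import DivergenceError, InvalidParameterError, InvalidSizeError

__all__ = [
    "HVCParams",
    "LevelTrajectory",
    "build_chain_connectivity",
    "hvc_drift",
    "simulate_hvc",
    "winner_sequence",
    "chain_is_stable",
    "chain_preset",
    "sigmoid",
    "normalize",
]

#: default divisive-normalization constant of H(u) = u / (c + sum(u))
NORM_CONST = 0.05

#: integration guard: any |x| beyond this raises DivergenceError
STATE_BOUND = 1e3


def sigmoid(x: np.ndarray, gain: float = 10.0, offset: float = 0.3) -> np.ndarray:
    """Logistic firing-rate function S(x) = 1 / (1 + exp(-gain (x - offset)))."""
    return expit(gain * (np.asarray(x, dtype=float) - offset))


def normalize(u: np.ndarray, c: float = NORM_CONST) -> np.ndarray:
    """Divisive normalization H(u) = u / (c + sum u) along the last axis.

    Keeps every entry in [0, 1) and the total at most 1, so that a single
    dominant ensemble maps to an output close to 1 while multi-active
    transients stay bounded.
    """
    u = np.asarray(u, dtype=float)
    return u / (c + u.sum(axis=-1, keepdims=True))


@dataclass
class HVCParams:
    """Parameters of the heteroclinic-chain level.

    ``connectivity`` is the lateral inhibition matrix rho with rho_ij the
    strength of inhibition from ensemble j onto ensemble i.
    """

    n_ensembles: int
    rate: float = 1.0            # kappa, 1/time
    decay: float = 0.1           # lambda, dimensionless
    connectivity: np.ndarray = None
    sigmoid_gain: float = 10.0
    sigmoid_offset: float = 0.3
    noise_sd_hidden: float = 1e-3
    noise_sd_causal: float = 1e-4
    norm_const: float = NORM_CONST

    def __post_init__(self):
        if self.n_ensembles < 2:
            raise InvalidSizeError("need at least 2 HVC ensembles")
        if self.rate <= 0 or self.decay <= 0:
            raise InvalidParameterError("rate and decay must be positive")
        if self.connectivity is None:
            self.connectivity = build_chain_connectivity(self.n_ensembles)
        rho = np.asarray(self.connectivity, dtype=float)
        if rho.shape != (self.n_ensembles, self.n_ensembles):
            raise InvalidSizeError(
                f"connectivity must be {self.n_ensembles}x{self.n_ensembles}"
            )
        if (rho < 0).any():
            raise InvalidParameterError("inhibition strengths must be nonnegative")
        diag = np.diag(rho)
        if not np.allclose(diag, diag[0]):
            raise InvalidParameterError("all self-inhibition entries must be equal")
        self.connectivity = rho

    @classmethod
    def default(cls, n: int = 8, **kwargs) -> "HVCParams":
        return cls(n_ensembles=n, **kwargs)


@dataclass
class LevelTrajectory:
    """Uniformly sampled hidden/causal state paths of one level.

    ``hidden`` is T x n (e.g. mean membrane potentials), ``causal`` is the
    T x m output passed to the level below (e.g. normalized firing rates).
    ``causal_aux`` optionally carries a second output stream.
    """

    times: np.ndarray
    hidden: np.ndarray
    causal: np.ndarray
    causal_aux: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.hidden):
            raise InvalidSizeError("times and hidden must have matching length")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def chain_preset(n: int) -> tuple[float, float]:
    """(sigmoid gain, offset) keeping a chain of ``n`` ensembles sequential.

    With a logistic rate function the inactive ensembles sit at a small
    rate floor; the summed strong inhibition they exert on the winner
    grows with n and eventually silences the chain, while deepening the
    floor too far freezes the winner (the successor can no longer escape
    its rest state).  Both constraints can be met simultaneously only by
    sharpening the sigmoid as the chain grows; these presets were
    calibrated so that deterministic flow-through sequencing survives at
    the corresponding sizes.  (The pure Lotka-Volterra rate equations
    have an exact zero floor and need no such correction; this is the
    price of the smooth neural-mass form.)
    """
    if n <= 12:
        return 10.0, 0.3
    if n <= 40:
        return 20.0, 0.245
    return 50.0, 0.124


def build_chain_connectivity(
    n: int,
    weak: float = 0.5,
    strong: float = 1.5,
    self_strength: float = 1.0,
) -> np.ndarray:
    """Inhibition matrix of a cyclic heteroclinic chain.

    Each ensemble inhibits its successor weakly and every other ensemble
    strongly (self-inhibition ``self_strength`` in between), so each
    single-winner saddle has exactly one unstable direction pointing at
    the next ensemble.  Ensemble N precedes ensemble 1, closing the cycle.
    """
    if n < 2:
        raise InvalidSizeError("a chain needs at least 2 ensembles")
    if not (0 < weak < self_strength < strong):
        raise InvalidParameterError(
            "require 0 < weak < self_strength < strong "
            f"(got {weak}, {self_strength}, {strong})"
        )
    rho = np.full((n, n), float(strong))
    np.fill_diagonal(rho, float(self_strength))
    idx = np.arange(n)
    rho[idx, (idx - 1) % n] = float(weak)  # predecessor -> successor is weak
    return rho


def hvc_drift(x: np.ndarray, params: HVCParams) -> np.ndarray:
    """Deterministic drift of the winnerless-competition dynamics."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("non-finite state passed to hvc_drift")
    s = sigmoid(x, params.sigmoid_gain, params.sigmoid_offset)
    return params.rate * (s * (1.0 - params.connectivity @ s) - params.decay * x)


def hvc_drift_jacobian(x: np.ndarray, params: HVCParams) -> np.ndarray:
    """Analytic Jacobian of :func:`hvc_drift` (used by the recognition filter)."""
    x = np.asarray(x, dtype=float)
    g = params.sigmoid_gain
    s = sigmoid(x, g, params.sigmoid_offset)
    sp = g * s * (1.0 - s)
    rho = params.connectivity
    jac = -s[:, None] * rho * sp[None, :]
    jac[np.diag_indices_from(jac)] += sp * (1.0 - rho @ s) - params.decay
    return params.rate * jac


def default_initial_state(params: HVCParams, winner: int = 0) -> np.ndarray:
    """Initial condition near the saddle of ``winner`` (0-based)."""
    x0 = np.full(params.n_ensembles, -0.1)
    x0[winner] = 1.0
    return x0


def simulate_hvc(
    params: HVCParams,
    duration: float,
    dt: float = 0.01,
    seed: int | None = 0,
    x0: np.ndarray | None = None,
) -> LevelTrajectory:
    """Euler-Maruyama path of the chain; causal states v = H(S(x)).

    Identical (seed, params, x0, dt) give bitwise-identical output.  The
    hidden-state noise has standard deviation ``noise_sd_hidden`` per unit
    time (scaled by sqrt(dt)); the causal output noise is additive white
    with sd ``noise_sd_causal`` and the result is clipped back to [0, 1].
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if duration < 10 * dt:
        raise InvalidParameterError("duration must be much larger than dt")
    n = params.n_ensembles
    rng = np.random.default_rng(seed)
    x = default_initial_state(params) if x0 is None else np.array(x0, dtype=float)
    if x.shape != (n,):
        raise InvalidSizeError(f"x0 must have shape ({n},)")

    steps = int(round(duration / dt))
    times = np.arange(steps) * dt
    hidden = np.empty((steps, n))
    sw, sz = params.noise_sd_hidden, params.noise_sd_causal
    sqdt = np.sqrt(dt)
    for t in range(steps):
        hidden[t] = x
        if np.abs(x).max() > STATE_BOUND:
            raise DivergenceError(
                f"HVC state exceeded bound {STATE_BOUND} at t={times[t]:.4f}",
                time=float(times[t]),
            )
        dx = hvc_drift(x, params) * dt
        if sw > 0:
            dx += sw * sqdt * rng.standard_normal(n)
        x = x + dx
    causal = normalize(
        sigmoid(hidden, params.sigmoid_gain, params.sigmoid_offset),
        params.norm_const,
    )
    if sz > 0:
        causal = np.clip(causal + sz * rng.standard_normal(causal.shape), 0.0, 1.0)
    return LevelTrajectory(times=times, hidden=hidden, causal=causal)


def winner_sequence(
    traj: LevelTrajectory, threshold: float = 0.5
) -> list[tuple[int, float, float]]:
    """Decode the trajectory into (ensemble index, onset time, duration) runs.

    An ensemble is the winner at a time step when its causal state is the
    maximum and exceeds ``threshold``; consecutive duplicates are merged.
    Indices are 1-based.
    """
    if not (0.0 < threshold < 1.0):
        raise InvalidParameterError("threshold must lie in (0, 1)")
    v = traj.causal
    if v.size == 0:
        raise InvalidParameterError("empty trajectory")
    dt = traj.dt
    argmax = np.argmax(v, axis=1)
    active = v[np.arange(len(v)), argmax] > threshold
    runs: list[list] = []  # [winner, onset, above-threshold step count]
    for t in range(len(v)):
        if not active[t]:
            continue
        w = int(argmax[t]) + 1
        if runs and runs[-1][0] == w:
            runs[-1][2] += 1
        else:
            runs.append([w, float(traj.times[t]), 1])
    return [(w, onset, cnt * dt) for (w, onset, cnt) in runs]


def _lv_saddle_eigenvalues(rho: np.ndarray, k: int) -> np.ndarray:
    """Eigenvalues of the competition skeleton linearized at saddle k.

    The heteroclinic skeleton of the sigmoidal dynamics is the
    Lotka-Volterra system dr_i/dt = r_i (1 - sum_j rho_ij r_j) on the
    firing rates; its single-winner equilibria are r = e_k / rho_kk with a
    diagonal + rank-one Jacobian whose eigenvalues are available in closed
    form: -1 along the winner direction and 1 - rho_jk / rho_kk along each
    loser direction j.
    """
    n = rho.shape[0]
    lam = 1.0 - rho[:, k] / rho[k, k]
    lam[k] = -1.0
    return lam


def chain_is_stable(
    rho: np.ndarray, params: HVCParams | None = None, tol: float = 1e-9
) -> tuple[bool, dict]:
    """Check the saddle structure required for a stable heteroclinic chain.

    Linearizes the noise-free competition skeleton at each single-winner
    saddle and requires (i) exactly one unstable eigendirection per saddle,
    (ii) the unstable direction to point at the cyclic successor, and
    (iii) a non-expanding saddle value (weakest contraction at least as
    strong as the expansion, the Afraimovich-type ordering).  Returns the
    verdict plus a per-saddle diagnostic report.
    """
    rho = np.asarray(rho, dtype=float)
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
        raise InvalidSizeError("connectivity must be a square matrix")
    n = rho.shape[0]
    report: dict = {"saddles": [], "stable": True, "failures": []}
    if np.any(np.diag(rho) <= 0):
        report["stable"] = False
        report["failures"].append("equilibrium search failed: non-positive "
                                  "self-inhibition, no single-winner saddle")
        return False, report
    saddle_values = []
    for k in range(n):
        lam = _lv_saddle_eigenvalues(rho, k)
        unstable = np.flatnonzero(lam > tol)
        entry = {
            "saddle": k + 1,
            "eigenvalues": lam,
            "n_unstable": int(len(unstable)),
        }
        ok = len(unstable) == 1 and unstable[0] == (k + 1) % n
        if ok:
            stable_mag = np.abs(lam[lam < -tol])
            nu = float(stable_mag.min() / lam[unstable[0]])
            entry["saddle_value"] = nu
            saddle_values.append(nu)
            if nu < 1.0 - 1e-6:
                ok = False
                report["failures"].append(
                    f"saddle {k + 1}: expansion exceeds weakest contraction"
                )
        else:
            report["failures"].append(
                f"saddle {k + 1}: {len(unstable)} unstable directions "
                f"(need exactly 1, toward the successor)"
            )
        report["saddles"].append(entry)
        report["stable"] = report["stable"] and ok
    if saddle_values:
        report["chain_saddle_value"] = float(np.prod(saddle_values))
    return bool(report["stable"]), report
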