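"""Online Bayesian song recognition by precision-weighted prediction errors.

The listener inverts the hierarchical generative model from the vocal
control signals alone.  The model is written in the generic hierarchical
state-space form

    v_{i-1} = g_i(x_i, v_i) + z_i        (output, passed downward)
    dx_i/dt = f_i(x_i, v_i) + w_i        (hidden dynamics)

for levels i = 1..L, where v_0 = u is the sensory stream and v_L (the
input of the top level, possibly empty) carries a Gaussian prior.  Under
the Laplace assumption the posterior over all hidden and causal states is
summarized by its mode mu, held in generalized coordinates of motion
(state and velocity, embedding order 2).  The negative free energy is
the precision-weighted sum of squared prediction errors, formed at both
orders:

    eps_z_i  = mu_v_{i-1}  - g_i(mu_x_i, mu_v_i)
    eps_z_i' = mu_v_{i-1}' - (Gx mu_x_i' + Gv mu_v_i')
    eps_x_i  = mu_x_i'     - f_i(mu_x_i, mu_v_i)

where the primed coordinates are the velocity estimates, the sensory
stream enters with its temporal derivative, and Fx, Fv, Gx, Gv are the
model Jacobians evaluated at a linearization point (the current mode, as
in Gauss-Newton).  The first-order errors are what carries sensory
evidence upward: the observed output *velocity* constrains the gate and
hidden-state velocities, which in turn constrain the causal input of
each level through its drift.  Recognition integrates the gradient flow

    d mu/dt = D mu + dF/d mu

one sensory sample at a time (D is the generalized-coordinate shift) --
predictions descend the hierarchy while prediction errors ascend it.
Parameters (connectivities, score, rates, precisions) are fixed: the
listener has learned the song; only states are inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import expm

from .config import Config
from .errors import (
    ConfigurationError,
    DivergenceError,
    InvalidParameterError,
    InvalidSizeError,
)
from .generate import SongScore
from .hvc import hvc_drift, hvc_drift_jacobian, normalize, sigmoid
from .oscillators import ControlSignal
from .ra import input_matrix, ra_drift, ra_drift_jacobian

__all__ = [
    "LevelSpec",
    "GenerativeSpec",
    "PosteriorState",
    "RecognitionResult",
    "build_song_spec",
    "sensory_from_control",
    "embed_sensory",
    "prediction_errors",
    "free_energy",
    "free_energy_gradient",
    "filter_step",
    "recognize",
    "error_energy",
    "true_posterior",
    "initial_state",
]


@dataclass
class LevelSpec:
    """One level of the hierarchical form: maps, Jacobians and precisions.

    ``nx``/``nv`` are the hidden-state and causal-input dimensions, ``ny``
    the output dimension (equal to the causal dimension of the level
    below, or the sensory dimension at level 1).  Jacobian callables may
    be ``None``, in which case central finite differences are used.
    """

    nx: int
    nv: int
    ny: int
    f: Callable | None = None
    g: Callable | None = None
    fx: Callable | None = None
    fv: Callable | None = None
    gx: Callable | None = None
    gv: Callable | None = None
    pi_x: np.ndarray = None
    pi_z: np.ndarray = None
    pi_dv: float = 0.0      # precision of the zero-mean prior on dv (0 = none)
    clamped: bool = False   # hidden states evolve by f only (known dynamics)

    def __post_init__(self):
        if self.pi_x is None:
            self.pi_x = np.ones(self.nx)
        if self.pi_z is None:
            self.pi_z = np.ones(self.ny)
        self.pi_x = np.asarray(self.pi_x, dtype=float) * np.ones(self.nx)
        self.pi_z = np.asarray(self.pi_z, dtype=float) * np.ones(self.ny)
        if (self.pi_x <= 0).any() or (self.pi_z <= 0).any():
            raise ConfigurationError("precisions must be positive")


def _fd_jac(fun, x, *args, eps=1e-6):
    x = np.asarray(x, dtype=float)
    out = fun(x, *args)
    jac = np.empty((len(out), len(x)))
    for j in range(len(x)):
        dx = np.zeros_like(x)
        dx[j] = eps
        jac[:, j] = (fun(x + dx, *args) - fun(x - dx, *args)) / (2 * eps)
    return jac


@dataclass
class GenerativeSpec:
    """Stack of levels (bottom to top) plus filter settings."""

    levels: list            # LevelSpec, index 0 = sensory-adjacent level
    dt: float = 0.01        # sample spacing, model time units
    embed_order: int = 2    # generalized-coordinate orders: 1, 2 or 3
    eta: np.ndarray = None  # prior mean on the top causal input
    pi_eta: np.ndarray = None
    deriv_weight: object = 0.1  # precision factor for first-order causal
                                # errors; scalar or per-level sequence
    deriv_weight2: float = 0.03 # factor for second-order causal errors (d=3)
    dyn_weight1: float = 0.1    # factor for first-order dynamical errors (d=3)
    prior_x_mean: list = None   # optional per-level rest-state prior means
    prior_x_pi: list = None     # per-level prior precisions (None = no prior)
    step_scale: float = 1.0     # multiplies the free-energy gradient
    trust_radius: float = 5.0   # elementwise cap on a single update
    integrator: str = "ll"      # "ll" (local linearization) or "euler"
    n_inner: int = 1            # integrator substeps per sample

    def __post_init__(self):
        if self.embed_order not in (1, 2, 3):
            raise ConfigurationError("embed_order must be 1, 2 or 3")
        top = self.levels[-1]
        if self.eta is None:
            self.eta = np.zeros(top.nv)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.pi_eta is None:
            self.pi_eta = np.ones(top.nv)
        self.pi_eta = np.asarray(self.pi_eta, dtype=float) * np.ones(top.nv)
        if np.isscalar(self.deriv_weight):
            self.deriv_weight = [float(self.deriv_weight)] * len(self.levels)
        self.deriv_weight = list(self.deriv_weight)
        if self.prior_x_mean is None:
            self.prior_x_mean = [None] * len(self.levels)
        if self.prior_x_pi is None:
            self.prior_x_pi = [None] * len(self.levels)
        for lo, hi in zip(self.levels[:-1], self.levels[1:]):
            if hi.ny != lo.nv:
                raise InvalidSizeError(
                    "output dimension of each level must match the causal "
                    "input dimension of the level below"
                )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def jac(self, which: str, level: int, x, v) -> np.ndarray:
        """Jacobian of f or g at one level, analytic if available."""
        spec = self.levels[level]
        fun = getattr(spec, which[0])
        j = getattr(spec, which)
        if j is not None:
            return j(x, v)
        if which[1] == "x":
            return _fd_jac(lambda xx: fun(xx, v), x)
        return _fd_jac(lambda vv: fun(x, vv), v)


@dataclass
class PosteriorState:
    """Posterior mode in generalized coordinates (orders 0, 1 and, for
    embedding order 3, order 2)."""

    mu_x: list    # arrays (nx_i,)
    mu_dx: list   # arrays (nx_i,), hidden-state velocities
    mu_v: list    # arrays (nv_i,), causal input of level i
    mu_dv: list   # arrays (nv_i,), causal-input velocities
    mu_d2x: list = None  # hidden-state accelerations (order-3 filters)
    mu_d2v: list = None  # causal-input accelerations

    def __post_init__(self):
        if self.mu_d2x is None:
            self.mu_d2x = [np.zeros_like(a) for a in self.mu_x]
        if self.mu_d2v is None:
            self.mu_d2v = [np.zeros_like(a) for a in self.mu_v]

    @classmethod
    def zeros(cls, spec: GenerativeSpec) -> "PosteriorState":
        return cls(
            [np.zeros(l.nx) for l in spec.levels],
            [np.zeros(l.nx) for l in spec.levels],
            [np.zeros(l.nv) for l in spec.levels],
            [np.zeros(l.nv) for l in spec.levels],
        )

    def copy(self) -> "PosteriorState":
        return PosteriorState(
            [a.copy() for a in self.mu_x],
            [a.copy() for a in self.mu_dx],
            [a.copy() for a in self.mu_v],
            [a.copy() for a in self.mu_dv],
            [a.copy() for a in self.mu_d2x],
            [a.copy() for a in self.mu_d2v],
        )

    def flatten(self, spec: GenerativeSpec) -> np.ndarray:
        parts = []
        third = spec.embed_order >= 3
        for i in range(spec.n_levels):
            parts += [self.mu_x[i], self.mu_dx[i]]
            if third:
                parts.append(self.mu_d2x[i])
            parts += [self.mu_v[i], self.mu_dv[i]]
            if third:
                parts.append(self.mu_d2v[i])
        return np.concatenate(parts) if parts else np.zeros(0)

    @classmethod
    def unflatten(cls, vec: np.ndarray, spec: GenerativeSpec) -> "PosteriorState":
        mu_x, mu_dx, mu_v, mu_dv, mu_d2x, mu_d2v = [], [], [], [], [], []
        third = spec.embed_order >= 3
        pos = 0
        for l in spec.levels:
            mu_x.append(vec[pos:pos + l.nx]); pos += l.nx
            mu_dx.append(vec[pos:pos + l.nx]); pos += l.nx
            if third:
                mu_d2x.append(vec[pos:pos + l.nx]); pos += l.nx
            else:
                mu_d2x.append(np.zeros(l.nx))
            mu_v.append(vec[pos:pos + l.nv]); pos += l.nv
            mu_dv.append(vec[pos:pos + l.nv]); pos += l.nv
            if third:
                mu_d2v.append(vec[pos:pos + l.nv]); pos += l.nv
            else:
                mu_d2v.append(np.zeros(l.nv))
        return cls(mu_x, mu_dx, mu_v, mu_dv, mu_d2x, mu_d2v)


@dataclass
class RecognitionResult:
    """Time-indexed posterior modes, prediction errors and free energy."""

    times: np.ndarray
    mu_x: list      # arrays (T, nx_i)
    mu_dx: list
    mu_v: list      # arrays (T, nv_i)
    eps_z: list     # arrays (T, ny_i), order-0 causal errors
    eps_x: list     # arrays (T, nx_i), order-0 dynamical errors
    free_energy: np.ndarray
    spec: GenerativeSpec = field(repr=False, default=None)


# --------------------------------------------------------------------- errors
def _jacobians(mu: PosteriorState, spec: GenerativeSpec, lin: PosteriorState):
    """All level Jacobians at the linearization point."""
    out = []
    for i, l in enumerate(spec.levels):
        x, v = lin.mu_x[i], lin.mu_v[i]
        out.append({
            "fx": spec.jac("fx", i, x, v) if l.f is not None and l.nx else
            np.zeros((l.nx, l.nx)),
            "fv": spec.jac("fv", i, x, v) if l.f is not None and l.nx and l.nv
            else np.zeros((l.nx, l.nv)),
            "gx": spec.jac("gx", i, x, v) if l.g is not None and l.nx else
            np.zeros((l.ny, l.nx)),
            "gv": spec.jac("gv", i, x, v) if l.g is not None and l.nv else
            np.zeros((l.ny, l.nv)),
        })
    return out


def prediction_errors(
    mu: PosteriorState,
    sensory: np.ndarray,
    spec: GenerativeSpec,
    lin: PosteriorState | None = None,
) -> dict:
    """Per-level prediction errors at every generalized order.

    ``sensory`` is either a plain sample (ny,) or an embedded sample
    (d, ny) whose rows are the stream and its temporal derivatives.  The
    higher-order errors use model Jacobians evaluated at ``lin``
    (default: the mode itself), the local-linearization convention.
    Returns a dict with lists over levels: ``z``, ``dz``, ``d2z``
    (causal errors at orders 0..2), ``x``, ``dx`` (dynamical errors at
    orders 0..1) and ``eta`` (top prior error).  Orders beyond the
    embedding order are zero.
    """
    sensory = np.atleast_2d(np.asarray(sensory, dtype=float))
    if sensory.shape[1] != spec.levels[0].ny:
        raise InvalidSizeError("sensory sample has the wrong dimension")
    while len(sensory) < 3:
        sensory = np.vstack([sensory, np.zeros_like(sensory[0])])
    lin = mu if lin is None else lin
    jacs = _jacobians(mu, spec, lin)
    third = spec.embed_order >= 3
    eps = {"z": [], "dz": [], "d2z": [], "x": [], "dx": []}
    below = [sensory[0], sensory[1], sensory[2]]
    for i, l in enumerate(spec.levels):
        J = jacs[i]
        pred = l.g(mu.mu_x[i], mu.mu_v[i]) if l.g is not None else np.zeros(l.ny)
        eps["z"].append(below[0] - pred)
        eps["dz"].append(
            below[1] - J["gx"] @ mu.mu_dx[i] - J["gv"] @ mu.mu_dv[i]
        )
        if third:
            eps["d2z"].append(
                below[2] - J["gx"] @ mu.mu_d2x[i] - J["gv"] @ mu.mu_d2v[i]
            )
        else:
            eps["d2z"].append(np.zeros(l.ny))
        drift = l.f(mu.mu_x[i], mu.mu_v[i]) if l.f is not None else np.zeros(l.nx)
        eps["x"].append(mu.mu_dx[i] - drift)
        if third:
            eps["dx"].append(
                mu.mu_d2x[i] - J["fx"] @ mu.mu_dx[i] - J["fv"] @ mu.mu_dv[i]
            )
        else:
            eps["dx"].append(np.zeros(l.nx))
        below = [mu.mu_v[i], mu.mu_dv[i], mu.mu_d2v[i]]
    eps["eta"] = mu.mu_v[-1] - spec.eta
    return eps


def free_energy(
    mu: PosteriorState,
    sensory,
    spec: GenerativeSpec,
    lin: PosteriorState | None = None,
) -> float:
    """Laplace free energy (up to the state-independent normalization).

    F = -1/2 sum eps' Pi eps + 1/2 sum log Pi over all error terms;
    maximized exactly when every prediction error vanishes.  Higher-order
    errors are weighted by the per-level ``deriv_weight`` (order 1),
    ``deriv_weight2`` and ``dyn_weight1`` factors times the level
    precisions, and linearized around ``lin`` (default: the mode).
    """
    eps = prediction_errors(mu, sensory, spec, lin)
    third = spec.embed_order >= 3
    val = 0.0
    logdet = 0.0
    for i, l in enumerate(spec.levels):
        w1 = spec.deriv_weight[i] if spec.embed_order >= 2 else 0.0
        val += eps["z"][i] @ (l.pi_z * eps["z"][i])
        val += eps["x"][i] @ (l.pi_x * eps["x"][i])
        val += w1 * (eps["dz"][i] @ (l.pi_z * eps["dz"][i]))
        if third:
            val += spec.deriv_weight2 * (eps["d2z"][i] @ (l.pi_z * eps["d2z"][i]))
            val += spec.dyn_weight1 * (eps["dx"][i] @ (l.pi_x * eps["dx"][i]))
        logdet += np.sum(np.log(l.pi_z)) + np.sum(np.log(l.pi_x))
    val += eps["eta"] @ (spec.pi_eta * eps["eta"])
    logdet += np.sum(np.log(spec.pi_eta))
    for i, l in enumerate(spec.levels):
        if spec.prior_x_pi[i] is not None:
            d = mu.mu_x[i] - spec.prior_x_mean[i]
            val += spec.prior_x_pi[i] * (d @ d)
        if l.pi_dv > 0 and l.nv:
            val += l.pi_dv * (mu.mu_dv[i] @ mu.mu_dv[i])
            if third:
                val += l.pi_dv * (mu.mu_d2v[i] @ mu.mu_d2v[i])
    return float(-0.5 * val + 0.5 * logdet)


def free_energy_gradient(
    mu: PosteriorState,
    sensory,
    spec: GenerativeSpec,
    lin: PosteriorState | None = None,
) -> PosteriorState:
    """Gradient of :func:`free_energy` with respect to the mode.

    Exact for the stated objective: the Jacobians of the higher-order
    errors are held at ``lin``, so only first derivatives of the model
    maps appear.
    """
    lin_pt = mu if lin is None else lin
    eps = prediction_errors(mu, sensory, spec, lin_pt)
    jacs = _jacobians(mu, spec, lin_pt)
    third = spec.embed_order >= 3
    gx = [np.zeros(l.nx) for l in spec.levels]
    gdx = [np.zeros(l.nx) for l in spec.levels]
    gd2x = [np.zeros(l.nx) for l in spec.levels]
    gv = [np.zeros(l.nv) for l in spec.levels]
    gdv = [np.zeros(l.nv) for l in spec.levels]
    gd2v = [np.zeros(l.nv) for l in spec.levels]
    for i, l in enumerate(spec.levels):
        w1 = spec.deriv_weight[i] if spec.embed_order >= 2 else 0.0
        wz = l.pi_z * eps["z"][i]
        wdz = w1 * l.pi_z * eps["dz"][i]
        wd2z = (spec.deriv_weight2 * l.pi_z * eps["d2z"][i]) if third else 0.0
        wx = l.pi_x * eps["x"][i]
        wdx = (spec.dyn_weight1 * l.pi_x * eps["dx"][i]) if third else 0.0
        J = jacs[i]
        if l.g is not None:
            if l.nx:
                gx[i] += spec.jac("gx", i, mu.mu_x[i], mu.mu_v[i]).T @ wz
            if l.nv:
                gv[i] += spec.jac("gv", i, mu.mu_x[i], mu.mu_v[i]).T @ wz
        if l.f is not None and l.nx:
            gx[i] += spec.jac("fx", i, mu.mu_x[i], mu.mu_v[i]).T @ wx
            if l.nv:
                gv[i] += spec.jac("fv", i, mu.mu_x[i], mu.mu_v[i]).T @ wx
        gdx[i] += -wx + J["gx"].T @ wdz
        gdv[i] += J["gv"].T @ wdz
        if third:
            gdx[i] += J["fx"].T @ wdx
            gdv[i] += J["fv"].T @ wdx
            gd2x[i] += -wdx + J["gx"].T @ wd2z
            gd2v[i] += J["gv"].T @ wd2z
        if i + 1 < spec.n_levels:
            # this level's causal input is the datum of the level above
            up = spec.levels[i + 1]
            w1_up = spec.deriv_weight[i + 1] if spec.embed_order >= 2 else 0.0
            gv[i] -= up.pi_z * eps["z"][i + 1]
            gdv[i] -= w1_up * up.pi_z * eps["dz"][i + 1]
            if third:
                gd2v[i] -= spec.deriv_weight2 * up.pi_z * eps["d2z"][i + 1]
    gv[-1] -= spec.pi_eta * eps["eta"]
    for i, l in enumerate(spec.levels):
        if spec.prior_x_pi[i] is not None:
            gx[i] -= spec.prior_x_pi[i] * (mu.mu_x[i] - spec.prior_x_mean[i])
        if l.pi_dv > 0 and l.nv:
            gdv[i] -= l.pi_dv * mu.mu_dv[i]
            if third:
                gd2v[i] -= l.pi_dv * mu.mu_d2v[i]
    return PosteriorState(gx, gdx, gv, gdv, gd2x, gd2v)


def _offsets(spec: GenerativeSpec):
    third = spec.embed_order >= 3
    offs = []
    pos = 0
    for l in spec.levels:
        o = {"x": pos, "dx": pos + l.nx}
        pos += 2 * l.nx
        if third:
            o["d2x"] = pos
            pos += l.nx
        o["v"] = pos
        o["dv"] = pos + l.nv
        pos += 2 * l.nv
        if third:
            o["d2v"] = pos
            pos += l.nv
        offs.append(o)
    return offs, pos


def _error_jacobian(mu: PosteriorState, spec: GenerativeSpec,
                    lin: PosteriorState) -> tuple[np.ndarray, np.ndarray]:
    """Stacked Jacobian of all errors w.r.t. the flattened mode + weights."""
    offs, n = _offsets(spec)
    jacs = _jacobians(mu, spec, lin)
    third = spec.embed_order >= 3
    rows, weights = [], []
    for i, l in enumerate(spec.levels):
        w1 = spec.deriv_weight[i] if spec.embed_order >= 2 else 0.0
        o = offs[i]
        J = jacs[i]
        jz = np.zeros((l.ny, n))
        jz[:, o["x"]:o["x"] + l.nx] = -J["gx"]
        jz[:, o["v"]:o["v"] + l.nv] = -J["gv"]
        if i > 0:
            jz[:, offs[i - 1]["v"]:offs[i - 1]["v"] + l.ny] += np.eye(l.ny)
        rows.append(jz); weights.append(l.pi_z)
        jx = np.zeros((l.nx, n))
        jx[:, o["dx"]:o["dx"] + l.nx] = np.eye(l.nx)
        jx[:, o["x"]:o["x"] + l.nx] -= J["fx"]
        jx[:, o["v"]:o["v"] + l.nv] -= J["fv"]
        rows.append(jx); weights.append(l.pi_x)
        if w1 > 0:
            jdz = np.zeros((l.ny, n))
            jdz[:, o["dx"]:o["dx"] + l.nx] = -J["gx"]
            jdz[:, o["dv"]:o["dv"] + l.nv] = -J["gv"]
            if i > 0:
                jdz[:, offs[i - 1]["dv"]:offs[i - 1]["dv"] + l.ny] += np.eye(l.ny)
            rows.append(jdz); weights.append(w1 * l.pi_z)
        if third:
            if spec.deriv_weight2 > 0:
                jd2z = np.zeros((l.ny, n))
                jd2z[:, o["d2x"]:o["d2x"] + l.nx] = -J["gx"]
                jd2z[:, o["d2v"]:o["d2v"] + l.nv] = -J["gv"]
                if i > 0:
                    jd2z[:, offs[i - 1]["d2v"]:offs[i - 1]["d2v"] + l.ny] += (
                        np.eye(l.ny))
                rows.append(jd2z); weights.append(spec.deriv_weight2 * l.pi_z)
            if spec.dyn_weight1 > 0 and l.nx:
                jdx = np.zeros((l.nx, n))
                jdx[:, o["d2x"]:o["d2x"] + l.nx] = np.eye(l.nx)
                jdx[:, o["dx"]:o["dx"] + l.nx] -= J["fx"]
                jdx[:, o["dv"]:o["dv"] + l.nv] -= J["fv"]
                rows.append(jdx); weights.append(spec.dyn_weight1 * l.pi_x)
    top = spec.levels[-1]
    if top.nv:
        jp = np.zeros((top.nv, n))
        jp[:, offs[-1]["v"]:offs[-1]["v"] + top.nv] = np.eye(top.nv)
        rows.append(jp); weights.append(spec.pi_eta)
    for i, l in enumerate(spec.levels):
        if spec.prior_x_pi[i] is not None and l.nx:
            jq = np.zeros((l.nx, n))
            jq[:, offs[i]["x"]:offs[i]["x"] + l.nx] = np.eye(l.nx)
            rows.append(jq)
            weights.append(np.full(l.nx, float(spec.prior_x_pi[i])))
        if l.pi_dv > 0 and l.nv:
            jq = np.zeros((l.nv, n))
            jq[:, offs[i]["dv"]:offs[i]["dv"] + l.nv] = np.eye(l.nv)
            rows.append(jq)
            weights.append(np.full(l.nv, float(l.pi_dv)))
            if third:
                jq = np.zeros((l.nv, n))
                jq[:, offs[i]["d2v"]:offs[i]["d2v"] + l.nv] = np.eye(l.nv)
                rows.append(jq)
                weights.append(np.full(l.nv, float(l.pi_dv)))
    return np.vstack(rows), np.concatenate(weights)


def _update_mask(spec: GenerativeSpec) -> np.ndarray:
    """False on hidden-state coordinates of clamped levels."""
    offs, n = _offsets(spec)
    nd = 3 if spec.embed_order >= 3 else 2
    mask = np.ones(n, dtype=bool)
    for i, l in enumerate(spec.levels):
        if l.clamped:
            mask[offs[i]["x"]:offs[i]["x"] + nd * l.nx] = False
    return mask


def _flow_clamped(mu: PosteriorState, spec: GenerativeSpec, dt: float) -> None:
    """Advance clamped levels' hidden states by one RK4 step of their drift."""
    for i, l in enumerate(spec.levels):
        if not l.clamped or l.f is None or not l.nx:
            continue
        x, v = mu.mu_x[i], mu.mu_v[i]
        k1 = l.f(x, v)
        k2 = l.f(x + 0.5 * dt * k1, v)
        k3 = l.f(x + 0.5 * dt * k2, v)
        k4 = l.f(x + dt * k3, v)
        mu.mu_x[i] = x + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        mu.mu_dx[i] = l.f(mu.mu_x[i], v)


def _shift_matrix(spec: GenerativeSpec) -> np.ndarray:
    """Matrix form of the generalized-coordinate shift D."""
    offs, n = _offsets(spec)
    third = spec.embed_order >= 3
    D = np.zeros((n, n))
    for i, l in enumerate(spec.levels):
        o = offs[i]
        D[o["x"]:o["x"] + l.nx, o["dx"]:o["dx"] + l.nx] = np.eye(l.nx)
        D[o["v"]:o["v"] + l.nv, o["dv"]:o["dv"] + l.nv] = np.eye(l.nv)
        if third:
            D[o["dx"]:o["dx"] + l.nx, o["d2x"]:o["d2x"] + l.nx] = np.eye(l.nx)
            D[o["dv"]:o["dv"] + l.nv, o["d2v"]:o["d2v"] + l.nv] = np.eye(l.nv)
    return D


def filter_step(
    mu: PosteriorState,
    sensory,
    spec: GenerativeSpec,
    dt: float | None = None,
) -> PosteriorState:
    """Advance the posterior mode by one sample: d mu/dt = D mu + dF/d mu.

    With the default local-linearization integrator the flow is solved
    over the sample interval under a Gauss-Newton linearization (the
    matrix-exponential update); the Euler integrator subdivides the
    interval instead.  Updates are elementwise-capped by the trust
    radius.
    """
    dt = spec.dt if dt is None else dt
    cache = getattr(spec, "_step_cache", None)
    if cache is None:
        cache = {"D": _shift_matrix(spec), "mask": _update_mask(spec)}
        spec._step_cache = cache
    D, mask = cache["D"], cache["mask"]

    def rate(m: PosteriorState) -> np.ndarray:
        grad = free_energy_gradient(m, sensory, spec)
        return D @ m.flatten(spec) + spec.step_scale * grad.flatten(spec)

    vec = mu.flatten(spec)
    if spec.integrator == "euler":
        h = dt / spec.n_inner
        for _ in range(spec.n_inner):
            step = h * rate(PosteriorState.unflatten(vec, spec))
            step[~mask] = 0.0
            vec = vec + np.clip(step, -spec.trust_radius, spec.trust_radius)
    elif spec.integrator == "ll":
        h = dt / spec.n_inner
        n = len(vec)
        for _ in range(spec.n_inner):
            m = PosteriorState.unflatten(vec, spec)
            r = rate(m)
            jac, wts = _error_jacobian(m, spec, m)
            A = D - spec.step_scale * (jac.T @ (wts[:, None] * jac))
            r[~mask] = 0.0
            A[~mask, :] = 0.0
            aug = np.zeros((n + 1, n + 1))
            aug[:n, :n] = A * h
            aug[:n, n] = r * h
            step = expm(aug)[:n, n]
            step[~mask] = 0.0
            vec = vec + np.clip(step, -spec.trust_radius, spec.trust_radius)
    else:
        raise ConfigurationError(f"unknown integrator: {spec.integrator}")
    if not np.all(np.isfinite(vec)):
        raise DivergenceError("posterior mode diverged in filter_step")
    out = PosteriorState.unflatten(vec, spec)
    _flow_clamped(out, spec, dt)
    return out


def embed_sensory(sensory: np.ndarray, dt: float, order: int = 2) -> np.ndarray:
    """Augment a T x ny stream with temporal derivatives (T x order x ny).

    Derivatives are local polynomial fits (repeated centered differences,
    one-sided at the boundaries), the embedding the online filter runs on.
    """
    sensory = np.asarray(sensory, dtype=float)
    rows = [sensory]
    for _ in range(order - 1):
        rows.append(np.gradient(rows[-1], dt, axis=0))
    return np.stack(rows, axis=1)


def recognize(
    control,
    spec: GenerativeSpec,
    init: PosteriorState | None = None,
    sensory: np.ndarray | None = None,
    times: np.ndarray | None = None,
) -> RecognitionResult:
    """Online pass over the sensory stream; record mode, errors and F.

    ``control`` may be a :class:`ControlSignal` (converted to normalized
    sensory channels using the oscillator affine constants stored on the
    spec) or ``None`` if ``sensory`` (T x ny array) is given directly.
    """
    if sensory is None:
        if not isinstance(control, ControlSignal):
            raise InvalidParameterError(
                "pass a ControlSignal or an explicit sensory array"
            )
        sensory = sensory_from_control(control, spec)
        times = control.times
    sensory = np.asarray(sensory, dtype=float)
    if times is None:
        times = np.arange(len(sensory)) * spec.dt
    embedded = (
        embed_sensory(sensory, spec.dt, spec.embed_order)
        if sensory.ndim == 2 else sensory
    )
    mu = PosteriorState.zeros(spec) if init is None else init.copy()

    T = len(embedded)
    L = spec.n_levels
    res = RecognitionResult(
        times=np.asarray(times, dtype=float),
        mu_x=[np.empty((T, l.nx)) for l in spec.levels],
        mu_dx=[np.empty((T, l.nx)) for l in spec.levels],
        mu_v=[np.empty((T, l.nv)) for l in spec.levels],
        eps_z=[np.empty((T, l.ny)) for l in spec.levels],
        eps_x=[np.empty((T, l.nx)) for l in spec.levels],
        free_energy=np.empty(T),
        spec=spec,
    )
    for t in range(T):
        try:
            mu = filter_step(mu, embedded[t], spec)
        except DivergenceError as err:
            raise DivergenceError(
                f"recognition diverged at t={times[t]:.4f}", time=float(times[t])
            ) from err
        eps = prediction_errors(mu, embedded[t], spec)
        for i in range(L):
            res.mu_x[i][t] = mu.mu_x[i]
            res.mu_dx[i][t] = mu.mu_dx[i]
            res.mu_v[i][t] = mu.mu_v[i]
            res.eps_z[i][t] = eps["z"][i]
            res.eps_x[i][t] = eps["x"][i]
        res.free_energy[t] = free_energy(mu, embedded[t], spec)
    return res


def error_energy(
    result: RecognitionResult, level: int, window: tuple[float, float]
) -> float:
    """Mean squared precision-weighted prediction error of one level.

    ``level`` is 1-based from the bottom; the window is a (start, end)
    time interval.  Combines the level's order-0 causal and dynamical
    errors, normalized per error unit, averaged over the window.
    """
    t = result.times
    mask = (t >= window[0]) & (t < window[1])
    if not mask.any():
        raise InvalidParameterError("empty error-energy window")
    l = result.spec.levels[level - 1]
    ez = result.eps_z[level - 1][mask]
    ex = result.eps_x[level - 1][mask]
    num = (ez ** 2 * l.pi_z).sum(axis=1) + (ex ** 2 * l.pi_x).sum(axis=1)
    return float(num.mean() / (l.ny + l.nx))


# ------------------------------------------------------------------ song model
def sensory_from_control(control: ControlSignal, spec_or_params) -> np.ndarray:
    """Normalize (p, k) back to the oscillator outputs (y1, y2).

    The affine constants are part of the listener's (fixed, learned)
    model, so the two vocal control channels can be expressed on the
    common output scale before filtering.
    """
    params = spec_or_params
    if not hasattr(params, "p_affine"):
        params = params.osc_params
        if callable(params):
            params = params()
    a_p, b_p = params.p_affine
    a_k, b_k = params.k_affine
    return np.column_stack(
        [(control.p - a_p) / b_p, (control.k - a_k) / b_k]
    )


def true_posterior(full, spec: GenerativeSpec, t: int) -> PosteriorState:
    """Posterior mode equal to the generator's state at sample ``t``.

    Hidden velocities are the model drifts and causal velocities the
    linearized output derivatives, so on noise-free data every order-0
    prediction error vanishes identically (the generative form is
    exactly invertible on its own output).
    """
    mu = PosteriorState(
        mu_x=[
            full.osc.hidden[t].copy(),
            full.ra.hidden[t].copy(),
            full.hvc.hidden[t].copy(),
        ],
        mu_dx=[np.zeros(l.nx) for l in spec.levels],
        mu_v=[full.ra.causal[t].copy(), full.hvc.causal[t].copy(), np.zeros(0)],
        mu_dv=[np.zeros(l.nv) for l in spec.levels],
    )
    for i, l in enumerate(spec.levels):
        mu.mu_dx[i] = l.f(mu.mu_x[i], mu.mu_v[i])
    # causal velocities, top-down: dv_{i-1} = Gx dx_i + Gv dv_i
    for i in range(spec.n_levels - 1, 0, -1):
        jg = _jacobians(mu, spec, mu)[i]
        mu.mu_dv[i - 1] = jg["gx"] @ mu.mu_dx[i] + jg["gv"] @ mu.mu_dv[i]
    return mu


#: working precisions of the song listener (calibration constants).
#: The balance matters more than the absolute scale: the sensory gain is
#: kept moderate so gate evidence integrates over the rotating harmonic
#: basis instead of chasing each sample; RA-dynamics precision is low so
#: small drift residuals are absorbed by the input estimate rather than
#: shoving the chain; the top-down causal precisions act as elastic
#: couplings that transmit (not amplify) bottom-up forces.
DEFAULT_PRECISIONS = {
    "z1": 3e2,   # sensory channels
    "x1": 1e6,   # oscillator dynamics (clamped by default anyway)
    "z2": 3e3,   # gates vs RA prediction
    "x2": 3e0,   # RA dynamics
    "z3": 1e3,   # HVC output vs chain prediction
    "x3": 1e2,   # chain dynamics
    "dv1": 1e1,  # gate-velocity shrinkage (gates move only on evidence)
    "dv2": 1e1,  # chain-output-velocity shrinkage
}

#: rest value of the chain hidden states (loser baseline) used for the
#: listener's Gaussian position prior and default initial condition
CHAIN_REST = -0.1


def build_song_spec(
    config: Config | None = None,
    score: SongScore | None = None,
    precisions: dict | None = None,
    clamp_oscillators: bool = True,
    **spec_kwargs,
) -> GenerativeSpec:
    """The three-level song model in hierarchical state-space form.

    The listener's own parameters (possibly differing from the singer's,
    e.g. a different RA connectivity or an altered score) define the
    maps; precisions default to the working values in
    ``DEFAULT_PRECISIONS``.
    """
    from .generate import default_song  # late import to avoid a cycle

    config = config or Config()
    score = score or default_song()
    pi = dict(DEFAULT_PRECISIONS)
    pi.update(precisions or {})

    hvc_params = config.hvc_params(n=score.n_steps)
    ra_params = config.ra_params()
    osc_params = config.osc_params()
    I_mat = input_matrix(score.patterns, ra_params)
    omegas = osc_params.omegas
    theta = omegas * osc_params.phase_shift
    n_osc = osc_params.n_oscillators
    m = ra_params.n_ensembles
    n = hvc_params.n_ensembles

    # ----- level 1: oscillator bank (Stuart-Landau unit cycles),
    # output (y1, y2) gated by v1
    gam = osc_params.radial_rate

    def f1(x, v):
        s, c = x[0::2], x[1::2]
        rad = gam * (1.0 - (s * s + c * c))
        out = np.empty_like(x)
        out[0::2] = omegas * c + rad * s
        out[1::2] = -omegas * s + rad * c
        return out

    def f1x(x, v):
        s, c = x[0::2], x[1::2]
        r2 = s * s + c * c
        jac = np.zeros((2 * n_osc, 2 * n_osc))
        for i in range(n_osc):
            jac[2 * i, 2 * i] = gam * (1.0 - r2[i] - 2 * s[i] * s[i])
            jac[2 * i, 2 * i + 1] = omegas[i] - 2 * gam * s[i] * c[i]
            jac[2 * i + 1, 2 * i] = -omegas[i] - 2 * gam * c[i] * s[i]
            jac[2 * i + 1, 2 * i + 1] = gam * (1.0 - r2[i] - 2 * c[i] * c[i])
        return jac

    def g1(x, v):
        s, c = x[0::2], x[1::2]
        s_del = s * np.cos(theta) - c * np.sin(theta)
        return np.array([v @ s, v @ s_del])

    def g1x(x, v):
        jac = np.zeros((2, 2 * n_osc))
        jac[0, 0::2] = v
        jac[1, 0::2] = v * np.cos(theta)
        jac[1, 1::2] = -v * np.sin(theta)
        return jac

    def g1v(x, v):
        s, c = x[0::2], x[1::2]
        return np.vstack([s, s * np.cos(theta) - c * np.sin(theta)])

    level1 = LevelSpec(
        nx=2 * n_osc, nv=m, ny=2,
        f=f1, g=g1, fx=f1x,
        fv=lambda x, v: np.zeros((2 * n_osc, m)),
        gx=g1x, gv=g1v,
        pi_x=pi["x1"], pi_z=pi["z1"],
        pi_dv=pi["dv1"],
        clamped=clamp_oscillators,
    )

    # ----- level 2: RA attractor network, output = normalized rates
    c_norm = ra_params.norm_const

    def f2(x, v):
        return ra_drift(x, I_mat @ v, ra_params)

    def f2x(x, v):
        return ra_drift_jacobian(x, ra_params)

    _f2v_const = (ra_params.rate * ra_params.rate_diag)[:, None] * I_mat

    def g2(x, v):
        return normalize((np.tanh(x) + 1.0) / 2.0, c_norm)

    def g2x(x, v):
        u = (np.tanh(x) + 1.0) / 2.0
        tot = c_norm + u.sum()
        dh = (np.eye(m) * tot - np.outer(u, np.ones(m))) / tot ** 2
        return dh @ np.diag((1.0 - np.tanh(x) ** 2) / 2.0)

    level2 = LevelSpec(
        nx=m, nv=n, ny=m,
        f=f2, g=g2, fx=f2x, fv=lambda x, v: _f2v_const, gx=g2x,
        gv=lambda x, v: np.zeros((m, n)),
        pi_x=pi["x2"], pi_z=pi["z2"],
        pi_dv=pi["dv2"],
    )

    # ----- level 3: HVC chain, output = normalized firing rates
    def f3(x, v):
        return hvc_drift(x, hvc_params)

    def f3x(x, v):
        return hvc_drift_jacobian(x, hvc_params)

    def g3(x, v):
        return normalize(
            sigmoid(x, hvc_params.sigmoid_gain, hvc_params.sigmoid_offset),
            hvc_params.norm_const,
        )

    def g3x(x, v):
        s = sigmoid(x, hvc_params.sigmoid_gain, hvc_params.sigmoid_offset)
        tot = hvc_params.norm_const + s.sum()
        dh = (np.eye(n) * tot - np.outer(s, np.ones(n))) / tot ** 2
        return dh @ np.diag(hvc_params.sigmoid_gain * s * (1.0 - s))

    level3 = LevelSpec(
        nx=n, nv=0, ny=n,
        f=f3, g=g3, fx=f3x,
        fv=lambda x, v: np.zeros((n, 0)),
        gv=lambda x, v: np.zeros((n, 0)),
        pi_x=pi["x3"], pi_z=pi["z3"],
    )

    spec_kwargs.setdefault("deriv_weight", [0.3, 0.3, 0.0])
    spec_kwargs.setdefault("step_scale", 3.0)
    spec_kwargs.setdefault("trust_radius", 1.0)
    spec = GenerativeSpec(
        levels=[level1, level2, level3], dt=config.dt, **spec_kwargs
    )
    # weak prior keeping the chain near its responsive rest state
    spec.prior_x_mean = [None, None, np.full(n, CHAIN_REST)]
    spec.prior_x_pi = [None, None, 1.0]
    spec.osc_params = osc_params
    return spec


def initial_state(
    spec: GenerativeSpec, seed: int | None = None, sd: float = 0.02
) -> PosteriorState:
    """Listener initial condition for the song model.

    Oscillators start on their unit cycle at the phase convention both
    birds share; the chain starts at its rest baseline plus seeded noise
    of standard deviation ``sd`` -- deliberately different from the
    singer's initial state, which begins at the first saddle.
    """
    mu = PosteriorState.zeros(spec)
    mu.mu_x[0][1::2] = 1.0
    rng = np.random.default_rng(seed)
    mu.mu_x[-1][:] = CHAIN_REST + sd * rng.standard_normal(spec.levels[-1].nx)
    for i, l in enumerate(spec.levels):
        if l.f is not None and l.nx:
            mu.mu_dx[i] = l.f(mu.mu_x[i], mu.mu_v[i])
    return mu
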