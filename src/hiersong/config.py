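"""Flat, file-backed configuration for the full song model.

All tunable constants of the three neural levels and the syrinx live in
one dataclass; a YAML file of dotted keys (``hvc.kappa: 1.0``) round-trips
through :meth:`Config.load` / :meth:`Config.save`.  The defaults are the
calibration used throughout: eight HVC ensembles at roughly ten model
time units per activation, five RA ensembles, five harmonic oscillators,
and 0.08 s of real time per model unit so that one activation lasts about
800 ms and the example song about 6.5 s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

from .errors import ConfigurationError
from .hvc import HVCParams, build_chain_connectivity
from .oscillators import OscParams
from .ra import RAParams, random_stable_weights
from .syrinx import SyrinxParams

__all__ = ["Config"]


@dataclass
class Config:
    # shared integration grid
    dt: float = 0.01          # model time units per step
    seed: int = 0

    # HVC (third) level
    hvc_n: int = 8
    hvc_kappa: float = 1.0
    hvc_lambda: float = 0.1
    hvc_gain: float = 10.0
    hvc_offset: float = 0.3
    hvc_weak: float = 0.5
    hvc_strong: float = 1.5
    hvc_self: float = 1.0
    hvc_noise_hidden: float = 1e-3
    hvc_noise_causal: float = 1e-4

    # RA (second) level
    ra_m: int = 5
    ra_kappa: float = 1.0
    ra_c_diag: float = 12.0
    ra_spectral_norm: float = 0.6
    ra_amplitude: float = 2.0
    ra_seed_w: int = 7
    ra_noise_hidden: float = 1e-3
    ra_noise_causal: float = 1e-4

    # oscillator (first) level
    osc_omega: float = 2.0 * np.pi / 5.0
    osc_phi: float = 1.25
    osc_kappa: float = 1.0
    osc_ap: float = 0.9
    osc_bp: float = 0.7
    osc_ak: float = 1.58e7
    osc_bk: float = 9.8e6
    osc_noise_hidden: float = 1e-3
    osc_noise_causal: float = 1e-4

    # syrinx / audio
    syrinx_beta: float = 1.0
    syrinx_c: float = 3000.0
    syrinx_fs: int = 12000
    syrinx_seconds_per_unit: float = 0.08
    syrinx_pressure_rate: float = 1000.0
    syrinx_noise_floor: float = 20.0

    # ------------------------------------------------------------------ params
    def hvc_params(self, n: int | None = None) -> HVCParams:
        n = self.hvc_n if n is None else n
        return HVCParams(
            n_ensembles=n,
            rate=self.hvc_kappa,
            decay=self.hvc_lambda,
            connectivity=build_chain_connectivity(
                n, self.hvc_weak, self.hvc_strong, self.hvc_self
            ),
            sigmoid_gain=self.hvc_gain,
            sigmoid_offset=self.hvc_offset,
            noise_sd_hidden=self.hvc_noise_hidden,
            noise_sd_causal=self.hvc_noise_causal,
        )

    def ra_params(self, seed_w: int | None = None) -> RAParams:
        seed_w = self.ra_seed_w if seed_w is None else seed_w
        return RAParams(
            n_ensembles=self.ra_m,
            rate=self.ra_kappa,
            rate_diag=np.full(self.ra_m, self.ra_c_diag),
            connectivity=random_stable_weights(
                self.ra_m, self.ra_spectral_norm, seed_w
            ),
            attractor_amplitude=self.ra_amplitude,
            noise_sd_hidden=self.ra_noise_hidden,
            noise_sd_causal=self.ra_noise_causal,
        )

    def osc_params(self) -> OscParams:
        return OscParams(
            fundamental=self.osc_omega,
            phase_shift=self.osc_phi,
            rate=self.osc_kappa,
            p_affine=(self.osc_ap, self.osc_bp),
            k_affine=(self.osc_ak, self.osc_bk),
            noise_sd_hidden=self.osc_noise_hidden,
            noise_sd_causal=self.osc_noise_causal,
        )

    def syrinx_params(self) -> SyrinxParams:
        return SyrinxParams(
            beta=self.syrinx_beta,
            c=self.syrinx_c,
            timescale=self.syrinx_seconds_per_unit,
            sample_rate=self.syrinx_fs,
            pressure_rate=self.syrinx_pressure_rate,
            noise_floor=self.syrinx_noise_floor,
        )

    # ------------------------------------------------------------------ presets
    def replace(self, **kwargs) -> "Config":
        return dataclasses.replace(self, **kwargs)

    def noise_free(self) -> "Config":
        return self.replace(
            hvc_noise_hidden=0.0, hvc_noise_causal=0.0,
            ra_noise_hidden=0.0, ra_noise_causal=0.0,
            osc_noise_hidden=0.0, osc_noise_causal=0.0,
        )

    def high_noise(self, factor: float = 10.0) -> "Config":
        """Noise preset with every standard deviation scaled up."""
        return self.replace(
            hvc_noise_hidden=self.hvc_noise_hidden * factor,
            hvc_noise_causal=self.hvc_noise_causal * factor,
            ra_noise_hidden=self.ra_noise_hidden * factor,
            ra_noise_causal=self.ra_noise_causal * factor,
            osc_noise_hidden=self.osc_noise_hidden * factor,
            osc_noise_causal=self.osc_noise_causal * factor,
        )

    # ------------------------------------------------------------------ file IO
    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            key = f.name.replace("_", ".", 1) if "_" in f.name else f.name
            val = getattr(self, f.name)
            out[key] = val.item() if isinstance(val, np.generic) else val
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        names = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, val in d.items():
            name = key.replace(".", "_")
            if name not in names:
                raise ConfigurationError(f"unknown configuration key: {key}")
            kwargs[name] = val
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
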