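"""End-to-end song generation: score, calibration, pipeline and export.

A *song score* is the ordered mapping from sequentially activating HVC
ensembles to RA activation patterns.  :func:`generate` runs the three
neural levels on one shared time grid (HVC chain -> RA attractors ->
gated oscillators), producing the vocal control signals (p, k) and,
optionally, the synthesized waveform.  :func:`calibrate_rate` tunes the
HVC rate constant so each ensemble stays active for a target duration --
with the default 0.08 s-per-model-unit mapping, the 10-unit target makes
each of the eight activations last about 800 ms and the whole song about
6.5 s.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import Config
from .errors import CalibrationError, InvalidParameterError
from .hvc import LevelTrajectory, simulate_hvc, winner_sequence
from .oscillators import ControlSignal, control_signals, simulate_oscillators
from .ra import AttractorPattern, decode_pattern, simulate_ra
from .syrinx import Waveform, sonogram, synthesize, write_wav

__all__ = [
    "SongScore",
    "FullTrajectory",
    "default_song",
    "generate",
    "calibrate_rate",
    "export_bundle",
    "decode_ra_sequence",
]

#: fraction of one activation added to the simulation window as lead-in margin
SONG_MARGIN = 0.125

#: default per-ensemble activation target in model units (0.8 s at 0.08 s/unit)
DEFAULT_ACTIVATION = 10.0


@dataclass
class SongScore:
    """Ordered mapping of HVC ensembles onto RA activation patterns."""

    steps: list  # list of (hvc_index 1..N, AttractorPattern)
    per_ensemble_duration: float = DEFAULT_ACTIVATION  # model time units

    def __post_init__(self):
        indices = [i for i, _ in self.steps]
        if indices != list(range(1, len(self.steps) + 1)):
            raise InvalidParameterError(
                "score steps must map HVC ensembles 1..N in order"
            )
        if self.per_ensemble_duration <= 0:
            raise InvalidParameterError("per-ensemble duration must be positive")

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def patterns(self) -> list:
        return [p for _, p in self.steps]

    def duration(self) -> float:
        """Model-time window for one rendition, including lead-in margin."""
        return (self.n_steps + SONG_MARGIN) * self.per_ensemble_duration

    def with_pattern(self, step: int, pattern: AttractorPattern) -> "SongScore":
        """Copy of the score with the pattern of ``step`` (1-based) replaced."""
        steps = list(self.steps)
        steps[step - 1] = (step, pattern)
        return SongScore(steps, self.per_ensemble_duration)


@dataclass
class FullTrajectory:
    """All level trajectories of one rendition on a shared time grid."""

    hvc: LevelTrajectory
    ra: LevelTrajectory
    osc: LevelTrajectory
    control: ControlSignal
    waveform: Waveform | None
    config: Config
    score: SongScore
    seed: int


# the first three patterns are the documented example (ensembles 2-4,
# 1-3-5 and 1-4); the remaining five are fixed repository constants chosen
# so that the eight steps use exactly 7 distinct patterns of the 31
# possible, with {1, 4} occurring twice.
_DEFAULT_PATTERNS = (
    {2, 3, 4},
    {1, 3, 5},
    {1, 4},
    {5},
    {2, 5},
    {1, 2, 3},
    {1, 4},
    {3, 4, 5},
)


def default_song(per_ensemble_duration: float = DEFAULT_ACTIVATION) -> SongScore:
    """The eight-step example score over five RA ensembles."""
    steps = [
        (i + 1, AttractorPattern(frozenset(p)))
        for i, p in enumerate(_DEFAULT_PATTERNS)
    ]
    return SongScore(steps, per_ensemble_duration)


def generate(
    score: SongScore,
    config: Config | None = None,
    seed: int = 0,
    synth: bool = False,
    duration: float | None = None,
) -> FullTrajectory:
    """Run the full hierarchy for one rendition of the score.

    Deterministic given (score, config, seed).  ``synth=True`` also runs
    the syrinx to produce the waveform.
    """
    config = config or Config()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3)]
    duration = score.duration() if duration is None else duration

    hvc_params = config.hvc_params(n=score.n_steps)
    hvc = simulate_hvc(hvc_params, duration=duration, dt=config.dt, seed=seeds[0])
    ra = simulate_ra(config.ra_params(), hvc, score.patterns, seed=seeds[1])
    osc_params = config.osc_params()
    y1, y2, osc = simulate_oscillators(osc_params, ra, seed=seeds[2])
    control = control_signals(y1, y2, osc_params, times=osc.times)
    waveform = synthesize(control, config.syrinx_params()) if synth else None
    return FullTrajectory(
        hvc=hvc, ra=ra, osc=osc, control=control, waveform=waveform,
        config=config, score=score, seed=seed,
    )


def activation_intervals(traj: LevelTrajectory, threshold: float = 0.5) -> np.ndarray:
    """Onset-to-onset intervals between consecutive decoded activations.

    One ensemble's 'activation duration' is its full reign over the
    chain, measured from its onset to the onset of its successor (the
    above-threshold time reported by :func:`winner_sequence` excludes the
    handover transients).
    """
    onsets = np.array([onset for (_, onset, _) in winner_sequence(traj, threshold)])
    return np.diff(onsets)


def mean_activation_duration(
    params, duration: float, dt: float, skip: int = 4, count: int = 8,
    threshold: float = 0.5,
) -> float:
    """Steady-state mean activation duration of a noise-free run.

    Averages ``count`` onset-to-onset intervals after discarding the
    first ``skip`` (the startup transient washes out within a few
    activations).
    """
    traj = simulate_hvc(params, duration=duration, dt=dt, seed=None)
    intervals = activation_intervals(traj, threshold)
    if len(intervals) < skip + count:
        raise CalibrationError(
            f"only {len(intervals)} activation intervals decoded in the "
            "calibration window"
        )
    return float(np.mean(intervals[skip:skip + count]))


def calibrate_rate(
    target_per_ensemble: float,
    config: Config | None = None,
    tol: float = 0.02,
    max_iter: int = 12,
) -> tuple[float, float]:
    """HVC rate constant giving the target mean activation duration.

    Exploits the exact time-rescaling of the chain (duration scales as
    1/kappa) for a first proposal, then refines by bisection on the
    noise-free simulated mean duration until within ``tol`` of the target.
    Returns (kappa, achieved mean duration in model units).  The probe
    window grows adaptively, since long chains with a deep rate floor can
    be far slower than the configured rate suggests.
    """
    if target_per_ensemble <= 0:
        raise InvalidParameterError("calibration target must be positive")
    config = (config or Config()).noise_free()
    params = config.hvc_params()
    need = 14.0  # activations required by the steady-interval average

    def measure(kappa: float, expected: float) -> float:
        p = dataclasses.replace(params, rate=kappa)
        window = need * expected
        for _ in range(7):
            try:
                return mean_activation_duration(p, duration=window, dt=config.dt)
            except CalibrationError:
                window *= 2.0
        raise CalibrationError("no full activation cycle found")

    duration0 = measure(params.rate, target_per_ensemble)
    kappa = params.rate * duration0 / target_per_ensemble
    achieved = measure(kappa, target_per_ensemble)
    if abs(achieved - target_per_ensemble) <= tol * target_per_ensemble:
        return float(kappa), achieved

    lo, hi = kappa / 2.0, kappa * 2.0   # duration decreases in kappa
    if not (measure(lo, 2 * target_per_ensemble) > target_per_ensemble
            > measure(hi, target_per_ensemble)):
        raise CalibrationError("failed to bracket the calibration target")
    for _ in range(max_iter):
        kappa = np.sqrt(lo * hi)
        achieved = measure(kappa, target_per_ensemble)
        if abs(achieved - target_per_ensemble) <= tol * target_per_ensemble:
            return float(kappa), achieved
        if achieved > target_per_ensemble:
            lo = kappa
        else:
            hi = kappa
    raise CalibrationError("bisection did not converge")


def decode_ra_sequence(traj: FullTrajectory, threshold: float = 0.5) -> list:
    """RA pattern decoded within each HVC activation window.

    The pattern is read off the sign of the RA hidden state at the
    midpoint of each decoded HVC activation, where the attractor has
    settled.
    """
    runs = winner_sequence(traj.hvc, threshold)
    dt = traj.hvc.dt
    out = []
    for (_, onset, dur) in runs:
        mid = int(round((onset + 0.6 * dur) / dt))
        mid = min(mid, len(traj.ra.hidden) - 1)
        out.append(decode_pattern(traj.ra.hidden[mid]))
    return out


def _traj_frame(traj: LevelTrajectory, prefix: str, names=None) -> pd.DataFrame:
    data = {"time": traj.times}
    for j in range(traj.hidden.shape[1]):
        data[f"x{prefix}_{j + 1}"] = traj.hidden[:, j]
    cols = names or [f"v{prefix}_{j + 1}" for j in range(traj.causal.shape[1])]
    for j, name in enumerate(cols):
        data[name] = traj.causal[:, j]
    if traj.causal_aux is not None:
        for j in range(traj.causal_aux.shape[1]):
            data[f"v{prefix}b_{j + 1}"] = traj.causal_aux[:, j]
    return pd.DataFrame(data)


def export_bundle(traj: FullTrajectory, out_dir) -> list[Path]:
    """Write per-level CSVs, control CSV, WAV, sonogram CSV and a manifest.

    Returns the list of written paths (manifest last).  Re-exporting the
    same trajectory reproduces identical file contents.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    files = []

    hvc_df = _traj_frame(traj.hvc, "3")
    ra_df = _traj_frame(
        traj.ra, "2",
        names=[f"v2a_{j + 1}" for j in range(traj.ra.causal.shape[1])],
    )
    osc_df = pd.DataFrame({"time": traj.osc.times})
    for j in range(traj.osc.hidden.shape[1] // 2):
        osc_df[f"s_{j + 1}"] = traj.osc.hidden[:, 2 * j]
        osc_df[f"c_{j + 1}"] = traj.osc.hidden[:, 2 * j + 1]
    osc_df["y1"] = traj.osc.causal[:, 0]
    osc_df["y2"] = traj.osc.causal[:, 1]
    control_df = pd.DataFrame(
        {"time": traj.control.times, "p": traj.control.p, "k": traj.control.k}
    )
    for name, df in [
        ("hvc.csv", hvc_df), ("ra.csv", ra_df),
        ("osc.csv", osc_df), ("control.csv", control_df),
    ]:
        path = out / name
        df.to_csv(path, index=False, float_format=fmt)
        files.append(path)

    waveform = traj.waveform
    if waveform is None:
        waveform = synthesize(traj.control, traj.config.syrinx_params())
    wav_path = out / "song.wav"
    write_wav(wav_path, waveform)
    files.append(wav_path)

    freqs, stimes, mag = sonogram(waveform)
    sono = pd.DataFrame(mag, index=freqs, columns=np.round(stimes, 6))
    sono_path = out / "sonogram.csv"
    sono.to_csv(sono_path, float_format="%.6g")
    files.append(sono_path)

    manifest = {
        "files": [f.name for f in files],
        "seed": traj.seed,
        "config": traj.config.to_dict(),
        "score": [sorted(p.active_set) for p in traj.score.patterns],
        "versions": {
            "hiersong": __version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    files.append(manifest_path)
    return files
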