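"""Scripted listening experiments: the four core scenarios plus scaling.

Each ``run_*`` function generates a song with the singer's model,
recognizes it with the listener's model (which may differ), and reports
tracking correlations, windowed prediction-error energies and pass flags
against the repository's calibration thresholds.  The scenarios:

``ideal``
    Singer and listener share the model; only initial states differ.
``deviation``
    The listener expects a different third syllable (RA pattern {1}
    instead of {1, 4}), so prediction errors should surge at every level
    during that syllable only, and recovery should be quick.
``rewired``
    The listener's RA connectivity W differs from the singer's; each
    bird's HVC->RA input vectors are computed from its own W, so the
    same song is recognized despite the anatomical difference.
``cooling``
    Rate-constant manipulations: halving the HVC rate doubles every
    activation (timing is set at the top of the hierarchy), halving the
    RA rates leaves the vocal output essentially unchanged, and a 3%
    tempo mismatch between singer and listener yields sustained
    prediction errors at all levels.
``scaling``
    A 100-ensemble chain (generation only) and a 32-ensemble song with
    24 distinct RA patterns (generation plus recognition).

All thresholds are repository calibration constants, not literature
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Config
from .errors import InvalidParameterError
from .generate import (
    DEFAULT_ACTIVATION,
    mean_activation_duration,
    FullTrajectory,
    SongScore,
    activation_intervals,
    calibrate_rate,
    decode_ra_sequence,
    default_song,
    generate,
)
from .hvc import chain_preset, winner_sequence
from .ra import AttractorPattern, enumerate_patterns
from . import recognize as rz

__all__ = [
    "ScenarioConfig",
    "ScenarioReport",
    "calibrated_config",
    "run_ideal",
    "run_deviation",
    "run_rewired",
    "run_cooling",
    "run_tempo",
    "run_scaling",
    "report",
    "CORR_THRESHOLD",
    "ENERGY_RATIO_THRESHOLD",
    "RECOVERY_FACTOR",
    "RMS_TOLERANCE",
]

# ---- calibration thresholds (repository constants, validated on fixtures)
CORR_THRESHOLD = 0.9          # per-level tracking correlation, ideal scenario
ENERGY_RATIO_THRESHOLD = 3.0  # deviation-window / baseline error energy
RECOVERY_FACTOR = 2.0         # post-deviation energy relative to baseline
RMS_TOLERANCE = 0.02          # relative (p, k) change under RA-rate halving
DURATION_RATIO_TOL = 0.02     # tolerance on the x2 slow-down under HVC cooling
SUSTAINED_FRACTION = 0.8      # fraction of windows with elevated error (tempo)
BURN_IN_ACTIVATIONS = 2.0     # listener lock-in allowance before scoring


@dataclass
class ScenarioConfig:
    """Inputs of one scenario run."""

    scenario: str
    singer: Config
    listener: Config = None
    singer_score: SongScore = None
    listener_score: SongScore = None
    seed: int = 0

    def __post_init__(self):
        if self.listener is None:
            self.listener = self.singer
        if self.singer_score is None:
            self.singer_score = default_song()
        if self.listener_score is None:
            self.listener_score = self.singer_score
        if self.listener_score.n_steps != self.singer_score.n_steps:
            raise InvalidParameterError(
                "listener and singer scores must have the same length"
            )


@dataclass
class ScenarioReport:
    """Metrics, thresholds and outcomes of one scenario."""

    scenario: str
    metrics: list = field(default_factory=list)  # (metric, level, value, threshold, passed)
    files: list = field(default_factory=list)

    def add(self, metric: str, level, value: float, threshold: float,
            passed: bool) -> None:
        self.metrics.append((metric, level, float(value), threshold, bool(passed)))

    @property
    def passed(self) -> bool:
        return all(p for (_, _, _, _, p) in self.metrics)

    def value(self, metric: str, level=None) -> float:
        for (m, l, v, _t, _p) in self.metrics:
            if m == metric and (level is None or l == level):
                return v
        raise KeyError(f"{metric}/{level} not in report")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.metrics,
            columns=["metric", "level", "value", "threshold", "passed"],
        ).assign(scenario=self.scenario)


@lru_cache(maxsize=4)
def calibrated_config(target: float = DEFAULT_ACTIVATION) -> Config:
    """Default configuration with the HVC rate calibrated to the target
    activation duration (10 model units = 0.8 s at the default mapping)."""
    cfg = Config()
    kappa, _ = calibrate_rate(target, cfg)
    return cfg.replace(hvc_kappa=kappa)


def _flat_corr(a, b) -> float:
    a = np.asarray(a).ravel() - np.mean(a)
    b = np.asarray(b).ravel() - np.mean(b)
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else 0.0


def tracking_correlations(
    res: rz.RecognitionResult, full: FullTrajectory, spec, burn: float
) -> dict:
    """Per-level correlation between reconstructed and true states.

    Level 1 compares the reconstructed sensory prediction with the
    sensory stream; levels 2 and 3 compare the inferred causal states
    (oscillator gates, chain output) with the generator's.
    """
    mask = res.times - res.times[0] >= burn
    u = rz.sensory_from_control(full.control, spec)
    recon = u - res.eps_z[0]
    return {
        1: _flat_corr(recon[mask], u[mask]),
        2: _flat_corr(res.mu_v[0][mask], full.ra.causal[mask]),
        3: _flat_corr(res.mu_v[1][mask], full.hvc.causal[mask]),
    }


def _recognize_song(cfg: ScenarioConfig, **spec_kwargs):
    """Generate with the singer, recognize with the listener."""
    full = generate(cfg.singer_score, cfg.singer, seed=cfg.seed)
    spec = rz.build_song_spec(cfg.listener, cfg.listener_score, **spec_kwargs)
    init = rz.initial_state(spec, seed=cfg.seed + 10_000)
    res = rz.recognize(full.control, spec, init)
    return full, spec, res


def _activation_windows(score: SongScore, config: Config) -> list:
    """True activation interval of each HVC ensemble (noise-free run)."""
    full = generate(score, config.noise_free(), seed=0)
    runs = winner_sequence(full.hvc)
    onsets = [onset for (_, onset, _) in runs]
    ends = onsets[1:] + [float(full.hvc.times[-1])]
    return list(zip(onsets, ends))


def run_ideal(cfg: ScenarioConfig | None = None, seed: int = 0) -> ScenarioReport:
    """Shared model, different initial states: track at every level."""
    if cfg is None:
        cfg = ScenarioConfig("ideal", calibrated_config(), seed=seed)
    full, spec, res = _recognize_song(cfg)
    burn = BURN_IN_ACTIVATIONS * cfg.singer_score.per_ensemble_duration
    corrs = tracking_correlations(res, full, spec, burn)
    rep = ScenarioReport("ideal")
    for level in (1, 2, 3):
        rep.add("tracking_correlation", level, corrs[level], CORR_THRESHOLD,
                corrs[level] > CORR_THRESHOLD)
        t_end = float(res.times[-1])
        rep.add("error_energy", level,
                rz.error_energy(res, level, (burn, t_end)), np.inf, True)
    return rep


def run_deviation(cfg: ScenarioConfig | None = None, seed: int = 0) -> ScenarioReport:
    """Listener expects RA pattern {1} at step 3; singer sings {1, 4}."""
    if cfg is None:
        base = calibrated_config()
        singer_score = default_song()
        listener_score = singer_score.with_pattern(3, AttractorPattern({1}))
        cfg = ScenarioConfig("deviation", base, singer_score=singer_score,
                             listener_score=listener_score, seed=seed)
    if cfg.listener_score.patterns[2] == cfg.singer_score.patterns[2]:
        raise InvalidParameterError(
            "deviation scenario requires differing step-3 patterns"
        )
    full, spec, res = _recognize_song(cfg)
    windows = _activation_windows(cfg.singer_score, cfg.singer)
    dev_win = windows[2]   # the deviant (third) syllable
    base_win = windows[7]  # a late, fully locked syllable of matched length
    post_win = windows[4]  # one syllable after re-locking
    rep = ScenarioReport("deviation")
    for level in (1, 2, 3):
        e_dev = rz.error_energy(res, level, dev_win)
        e_base = rz.error_energy(res, level, base_win)
        e_post = rz.error_energy(res, level, post_win)
        ratio = e_dev / e_base if e_base > 0 else np.inf
        rec = e_post / e_base if e_base > 0 else np.inf
        rep.add("deviation_energy_ratio", level, ratio,
                ENERGY_RATIO_THRESHOLD, ratio > ENERGY_RATIO_THRESHOLD)
        rep.add("recovery_energy_ratio", level, rec,
                RECOVERY_FACTOR, rec <= RECOVERY_FACTOR)
    # level-1 reconstruction inside the window still follows the input
    u = rz.sensory_from_control(full.control, spec)
    t = res.times

    def _win_rms(win):
        m = (t >= win[0]) & (t < win[1])
        return float(np.sqrt(np.mean(res.eps_z[0][m] ** 2)))

    rms_ratio = _win_rms(dev_win) / _win_rms(base_win)
    rep.add("sensory_rms_ratio", 1, rms_ratio, 3.0, rms_ratio <= 3.0)
    return rep


def run_rewired(cfg: ScenarioConfig | None = None, seed: int = 0,
                listener_seed_w: int = 8) -> ScenarioReport:
    """Different RA connectivity in the listener, compensated by its inputs."""
    if cfg is None:
        base = calibrated_config()
        cfg = ScenarioConfig(
            "rewired", base, listener=base.replace(ra_seed_w=listener_seed_w),
            seed=seed,
        )
    w_singer = cfg.singer.ra_params().connectivity
    w_listener = cfg.listener.ra_params().connectivity  # validates stability
    full, spec, res = _recognize_song(cfg)
    burn = BURN_IN_ACTIVATIONS * cfg.singer_score.per_ensemble_duration
    corrs = tracking_correlations(res, full, spec, burn)
    rep = ScenarioReport("rewired")
    rep.add("connectivity_difference", 2,
            float(np.linalg.norm(w_singer - w_listener)), 0.0,
            True)
    for level in (1, 2, 3):
        rep.add("tracking_correlation", level, corrs[level], CORR_THRESHOLD,
                corrs[level] > CORR_THRESHOLD)
    return rep


def run_cooling(seed: int = 0, tempo: bool = True) -> ScenarioReport:
    """Rate-constant manipulations at the two neural levels (+ tempo test)."""
    base = calibrated_config()
    score = default_song()
    rep = ScenarioReport("cooling")

    # (a) halve the HVC rate constant: every activation doubles, the RA
    # pattern sequence is unchanged
    nf = base.noise_free()
    full_a = generate(score, nf, seed=0)
    cooled = generate(score, nf.replace(hvc_kappa=nf.hvc_kappa / 2), seed=0,
                      duration=2 * score.duration())
    iv_base = activation_intervals(full_a.hvc)[: score.n_steps - 1]
    iv_cool = activation_intervals(cooled.hvc)[: score.n_steps - 1]
    ratio = float(np.mean(iv_cool / iv_base))
    rep.add("hvc_cooling_duration_ratio", 3, ratio, 2.0,
            abs(ratio - 2.0) <= DURATION_RATIO_TOL * 2.0)
    seq_ok = (decode_ra_sequence(cooled) ==
              [p.active_set for p in score.patterns])
    rep.add("hvc_cooling_pattern_sequence", 2, float(seq_ok), 1.0, seq_ok)

    # (b) halve the RA rate matrix: vocal output essentially unchanged
    full_b = generate(score, nf.replace(ra_c_diag=nf.ra_c_diag / 2), seed=0)
    scale = np.std(full_a.control.p), np.std(full_a.control.k)
    rel_p = float(np.sqrt(np.mean((full_b.control.p - full_a.control.p) ** 2))
                  / scale[0])
    rel_k = float(np.sqrt(np.mean((full_b.control.k - full_a.control.k) ** 2))
                  / scale[1])
    rel = max(rel_p, rel_k)
    rep.add("ra_cooling_rms_change", 2, rel, RMS_TOLERANCE, rel < RMS_TOLERANCE)

    if tempo:
        for m in run_tempo(seed=seed).metrics:
            rep.metrics.append(m)
    return rep


def run_tempo(seed: int = 0, tempo_factor: float = 0.97,
              reference: rz.RecognitionResult | None = None) -> ScenarioReport:
    """3%-slowed singer vs an unslowed listener: sustained errors everywhere.

    ``reference`` may supply a previously computed ideal-communication
    recognition result (same seed) to serve as the per-window baseline.
    """
    base = calibrated_config()
    score = default_song()
    slow = base.replace(
        hvc_kappa=base.hvc_kappa * tempo_factor,
        ra_kappa=base.ra_kappa * tempo_factor,
        osc_kappa=base.osc_kappa * tempo_factor,
    )
    cfg_slow = ScenarioConfig("tempo", slow, listener=base, seed=seed)
    _full_s, _spec_s, res_s = _recognize_song(cfg_slow)
    if reference is None:
        cfg_ref = ScenarioConfig("ideal", base, seed=seed)
        _f, _s, reference = _recognize_song(cfg_ref)
    act = score.per_ensemble_duration
    burn = BURN_IN_ACTIVATIONS * act
    t_end = float(res_s.times[-1])
    edges = np.arange(burn, t_end - act / 2, act)
    rep = ScenarioReport("tempo")
    for level in (1, 2, 3):
        elevated = [
            rz.error_energy(res_s, level, (a, a + act)) >
            rz.error_energy(reference, level, (a, a + act))
            for a in edges
        ]
        frac = float(np.mean(elevated))
        rep.add("tempo_sustained_error_fraction", level, frac,
                SUSTAINED_FRACTION, frac >= SUSTAINED_FRACTION)
    return rep


def _scaling_score(n_steps: int = 32, n_distinct: int = 24) -> SongScore:
    """Fixed large score: n_steps steps drawing on n_distinct patterns.

    The first n_distinct steps use distinct patterns; the remaining
    steps reuse earlier patterns at pairwise-different offsets, so no
    two song positions are related by a constant shift (a cyclic reuse
    would make whole segments exact aliases of each other and the
    sequence unidentifiable from the sound alone).
    """
    pool = enumerate_patterns(5)
    # deterministic spread over the 31 patterns
    idx = np.linspace(0, len(pool) - 1, n_distinct).astype(int)
    distinct = [pool[i] for i in idx]
    reuse = [1 + 3 * j for j in range(n_steps - n_distinct)]
    patterns = distinct + [distinct[r] for r in reuse]
    steps = [(k + 1, patterns[k]) for k in range(n_steps)]
    return SongScore(steps)


def scaled_chain_config(n: int, dt: float | None = None) -> Config:
    """Configuration for a length-``n`` chain at the standard activation.

    Applies the size preset for the rate function and rescales the rate
    constant so each activation lasts the default 10 model units (the
    chain's exact time-rescaling makes one probe measurement enough).
    """
    gain, offset = chain_preset(n)
    if dt is None:
        dt = 0.002 if n > 40 else 0.01
    cfg = Config(hvc_n=n, hvc_gain=gain, hvc_offset=offset, dt=dt)
    params = cfg.noise_free().hvc_params()
    window = 1000.0
    for _ in range(4):
        try:
            probe = mean_activation_duration(
                params, duration=window, dt=0.01, skip=2, count=4
            )
            break
        except Exception:
            window *= 2.0
    else:
        raise InvalidParameterError(f"no activation cycle found for n={n}")
    return cfg.replace(hvc_kappa=probe / DEFAULT_ACTIVATION)


def run_scaling(seed: int = 0, n_generate: int = 100,
                recognition: bool = True) -> ScenarioReport:
    """Scale the chain up: 100 ensembles (generation), 32 (recognition)."""
    from .hvc import simulate_hvc

    rep = ScenarioReport("scaling")

    # (i) 100-ensemble chain, generation only, default noise
    n = n_generate
    cfg_n = scaled_chain_config(n)
    traj = simulate_hvc(
        cfg_n.hvc_params(), duration=(n + 1.5) * DEFAULT_ACTIVATION,
        dt=cfg_n.dt, seed=seed,
    )
    winners = [w for (w, _, _) in winner_sequence(traj)]
    distinct = len(set(winners))
    ordered = all(b == a % n + 1 for a, b in zip(winners, winners[1:]))
    rep.add("chain_activations", 3, distinct, n, distinct == n)
    rep.add("chain_ordered", 3, float(ordered), 1.0, ordered)

    if recognition:
        # (ii) 32-step song with 24 distinct RA patterns, full recognition
        # (coarsened sample grid keeps the filter affordable)
        score = _scaling_score()
        cfg32 = scaled_chain_config(score.n_steps)
        full = generate(score, cfg32, seed=seed)
        stride = 2
        ctrl = rz.ControlSignal(
            times=full.control.times[::stride],
            p=full.control.p[::stride], k=full.control.k[::stride],
        )
        spec = rz.build_song_spec(cfg32.replace(dt=cfg32.dt * stride), score)
        res = rz.recognize(ctrl, spec, rz.initial_state(spec, seed=seed + 10_000))
        est = np.argmax(res.mu_v[1], axis=1)
        windows = _activation_windows(score, cfg32)
        lag = 2.5  # typical recognition latency, model units
        hits = 0
        for k, (a, b) in enumerate(windows):
            m = (res.times >= a + lag) & (res.times < b + lag)
            if m.any():
                modal = np.bincount(est[m], minlength=score.n_steps).argmax()
                hits += int(modal == k)
        # the first step falls inside the listener's lock-in window
        rep.add("sequence_steps_tracked", 3, hits, score.n_steps - 1,
                hits >= score.n_steps - 1)
        burn = BURN_IN_ACTIVATIONS * score.per_ensemble_duration
        mask = res.times >= burn
        u = rz.sensory_from_control(ctrl, spec)
        corrs = {
            1: _flat_corr((u - res.eps_z[0])[mask], u[mask]),
            2: _flat_corr(res.mu_v[0][mask], full.ra.causal[::stride][mask]),
            3: _flat_corr(res.mu_v[1][mask], full.hvc.causal[::stride][mask]),
        }
        for level in (1, 2, 3):
            rep.add("tracking_correlation", level, corrs[level], np.nan, True)
    return rep


def report(reports: list, out_dir=None) -> tuple[pd.DataFrame, bool]:
    """Summary table (and optional CSV + text file) over scenario reports."""
    if not reports:
        raise InvalidParameterError("no scenario reports given")
    frame = pd.concat([r.frame() for r in reports], ignore_index=True)
    frame = frame[["scenario", "metric", "level", "value", "threshold", "passed"]]
    all_pass = bool(frame["passed"].all())
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "summary.csv", index=False, float_format="%.6g")
        lines = [f"overall: {'PASS' if all_pass else 'FAIL'}"]
        for _, row in frame.iterrows():
            lines.append(
                f"{row.scenario:10s} {row.metric:32s} level={row.level} "
                f"value={row.value:.4g} threshold={row.threshold} "
                f"{'ok' if row.passed else 'FAIL'}"
            )
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return frame, all_pass
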