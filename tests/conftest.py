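"""Shared fixtures: calibrated configuration and cached scenario runs.

The recognition filter is the expensive part of the suite, so every run
that several tests need (the ideal-communication listening run, the
noise-free generation) is computed once per session.
"""

import numpy as np
import pytest

import hiersong as hs
import hiersong.experiments as ex
from hiersong import recognize as rz


@pytest.fixture(scope="session")
def cal_config():
    """Default configuration with the HVC rate calibrated to 10 units."""
    return ex.calibrated_config()


@pytest.fixture(scope="session")
def song():
    return hs.default_song()


@pytest.fixture(scope="session")
def nf_run(cal_config, song):
    """Noise-free rendition of the default song (no waveform)."""
    return hs.generate(song, cal_config.noise_free(), seed=1)


@pytest.fixture(scope="session")
def noisy_run(cal_config, song):
    """Default-noise rendition used by the listening scenarios."""
    return hs.generate(song, cal_config, seed=0)


@pytest.fixture(scope="session")
def song_spec(cal_config, song):
    """Listener model for the default song."""
    return rz.build_song_spec(cal_config, song)


@pytest.fixture(scope="session")
def ideal_result(noisy_run, song_spec):
    """One full ideal-communication recognition pass (seed 0)."""
    init = rz.initial_state(song_spec, seed=10_000)
    return rz.recognize(noisy_run.control, song_spec, init)


def flat_corr(a, b):
    a = np.asarray(a).ravel() - np.mean(a)
    b = np.asarray(b).ravel() - np.mean(b)
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))
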