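"""The RA attractor level: stability certificate, steering inputs, coding."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hiersong.errors import InvalidParameterError, InvalidSizeError
from hiersong.hvc import LevelTrajectory
from hiersong.ra import (
    AttractorPattern,
    RAParams,
    decode_pattern,
    enumerate_patterns,
    input_for_pattern,
    is_globally_stable,
    ra_drift,
    random_stable_weights,
    simulate_ra,
)


@pytest.fixture(scope="module")
def params():
    return RAParams.default()


class TestStabilityCertificate:
    def test_zero_matrix_certified(self):
        ok, cert = is_globally_stable(np.zeros((4, 4)))
        assert ok and cert["spectral_norm"] == 0.0

    def test_subunit_norm_certified_with_value(self):
        w = random_stable_weights(5, spectral_norm=0.9, seed=1)
        ok, cert = is_globally_stable(w)
        assert ok
        assert cert["spectral_norm"] == pytest.approx(0.9)

    def test_expansive_matrix_rejected(self):
        ok, _ = is_globally_stable(2.0 * np.eye(3))
        assert not ok

    def test_non_square_raises(self):
        with pytest.raises(InvalidSizeError):
            is_globally_stable(np.zeros((3, 4)))

    def test_certificate_predicts_multistart_convergence(self, params):
        # independent oracle: integrate the ODE from many random starts
        # and confirm a unique attracting fixed point
        I = input_for_pattern(AttractorPattern({2, 3}), params)
        rng = np.random.default_rng(5)
        ends = []
        for _ in range(10):
            x0 = rng.normal(0, 3.0, 5)
            sol = solve_ivp(
                lambda t, x: ra_drift(x, I, params), (0, 12.0), x0,
                rtol=1e-8, atol=1e-10,
            )
            ends.append(sol.y[:, -1])
        ends = np.array(ends)
        assert np.abs(ends - ends[0]).max() < 1e-6


class TestSteeringInputs:
    def test_zero_coupling_input_is_the_target(self):
        p = RAParams(n_ensembles=5, connectivity=np.zeros((5, 5)),
                     attractor_amplitude=2.0)
        I = input_for_pattern(AttractorPattern({1}), p)
        assert np.allclose(I, [2, -2, -2, -2, -2])

    def test_equilibrium_residual_is_tiny(self, params):
        pattern = AttractorPattern({2, 3, 4})
        xi = pattern.target(5, params.attractor_amplitude)
        I = input_for_pattern(pattern, params)
        assert np.abs(ra_drift(xi, I, params)).max() < 1e-10

    def test_all_default_song_patterns_have_correct_sign_structure(self, params):
        from hiersong.generate import default_song

        for pattern in default_song().patterns:
            xi = pattern.target(5, params.attractor_amplitude)
            I = input_for_pattern(pattern, params)
            sol = solve_ivp(
                lambda t, x: ra_drift(x, I, params), (0, 12.0), np.zeros(5),
                rtol=1e-8,
            )
            assert decode_pattern(sol.y[:, -1]) == pattern.active_set

    def test_empty_pattern_rejected(self):
        with pytest.raises(InvalidParameterError):
            AttractorPattern(frozenset())

    def test_rewiring_is_compensated_by_different_inputs(self):
        # two admissible connectivities need different inputs for the
        # same pattern, yet reach the same sign structure
        pa = RAParams.default(seed_w=7)
        pb = RAParams.default(seed_w=8)
        pattern = AttractorPattern({1, 4})
        Ia, Ib = input_for_pattern(pattern, pa), input_for_pattern(pattern, pb)
        assert not np.allclose(Ia, Ib)
        for p, I in ((pa, Ia), (pb, Ib)):
            sol = solve_ivp(lambda t, x: ra_drift(x, I, p), (0, 12.0),
                            np.zeros(5), rtol=1e-8)
            assert decode_pattern(sol.y[:, -1]) == pattern.active_set


class TestDrift:
    def test_zero_at_steered_equilibrium(self, params):
        pattern = AttractorPattern({1, 5})
        xi = pattern.target(5, params.attractor_amplitude)
        I = input_for_pattern(pattern, params)
        assert np.allclose(ra_drift(xi, I, params), 0.0, atol=1e-12)

    def test_linear_in_rate_matrix(self, params):
        import dataclasses

        x = np.array([0.3, -0.7, 1.1, 0.0, -0.2])
        I = np.ones(5)
        doubled = dataclasses.replace(params, rate_diag=2 * params.rate_diag)
        assert np.allclose(ra_drift(x, I, doubled), 2 * ra_drift(x, I, params))

    def test_origin_is_input_free_equilibrium(self, params):
        assert np.allclose(ra_drift(np.zeros(5), np.zeros(5), params), 0.0)


class TestEnumeration:
    @pytest.mark.parametrize("m,count", [(1, 1), (3, 7), (5, 31)])
    def test_counts(self, m, count):
        assert len(enumerate_patterns(m)) == count

    def test_patterns_distinct_and_nonempty(self):
        pats = enumerate_patterns(4)
        assert len({p.active_set for p in pats}) == 15
        assert all(p.active_set for p in pats)

    def test_invalid_size(self):
        with pytest.raises(InvalidParameterError):
            enumerate_patterns(0)


class TestSimulation:
    def test_constant_hvc_drive_reaches_the_mapped_pattern(self, params):
        from hiersong.generate import default_song

        score = default_song()
        times = np.arange(0, 8.0, 0.01)
        v3 = np.zeros((len(times), 8))
        v3[:, 1] = 0.9  # ensemble 2 held active
        hvc = LevelTrajectory(times=times, hidden=np.zeros_like(v3), causal=v3)
        ra = simulate_ra(params, hvc, score.patterns, seed=None)
        assert decode_pattern(ra.hidden[-1]) == score.patterns[1].active_set

    def test_score_length_mismatch_raises(self, params):
        from hiersong.errors import AlignmentError

        times = np.arange(0, 1.0, 0.01)
        v3 = np.zeros((len(times), 8))
        hvc = LevelTrajectory(times=times, hidden=v3, causal=v3)
        with pytest.raises(AlignmentError):
            simulate_ra(params, hvc, [AttractorPattern({1})] * 5, seed=None)

    def test_unstable_connectivity_rejected_at_construction(self):
        with pytest.raises(InvalidParameterError):
            RAParams(n_ensembles=3, connectivity=1.5 * np.eye(3))
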