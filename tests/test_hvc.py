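"""The heteroclinic-chain level: connectivity, drift, sequencing, stability."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import root

import hiersong as hs
from hiersong.errors import (
    DivergenceError,
    InvalidParameterError,
    InvalidSizeError,
)
from hiersong.hvc import (
    HVCParams,
    build_chain_connectivity,
    chain_is_stable,
    chain_preset,
    hvc_drift,
    hvc_drift_jacobian,
    normalize,
    simulate_hvc,
    winner_sequence,
)


@pytest.fixture(scope="module")
def params():
    return HVCParams.default(8)


@pytest.fixture(scope="module")
def nf_params():
    return HVCParams.default(8, noise_sd_hidden=0.0, noise_sd_causal=0.0)


class TestConnectivity:
    def test_chain_structure(self):
        rho = build_chain_connectivity(3, weak=0.5, strong=1.5, self_strength=1.0)
        assert np.allclose(np.diag(rho), 1.0)
        off = rho[~np.eye(3, dtype=bool)]
        assert sorted(off) == [0.5, 0.5, 0.5, 1.5, 1.5, 1.5]
        # the weak entry couples each predecessor into its successor, cyclically
        for i in range(3):
            assert rho[i, (i - 1) % 3] == 0.5

    def test_degenerate_size_rejected(self):
        with pytest.raises(InvalidSizeError):
            build_chain_connectivity(1)

    def test_ordering_violations_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_chain_connectivity(4, weak=1.2, strong=1.5, self_strength=1.0)
        with pytest.raises(InvalidParameterError):
            build_chain_connectivity(4, weak=0.5, strong=0.9, self_strength=1.0)


class TestDrift:
    def test_rate_constant_scales_linearly(self, params):
        x = np.linspace(-0.5, 1.0, 8)
        doubled = dataclasses.replace(params, rate=2 * params.rate)
        assert np.allclose(hvc_drift(x, doubled), 2 * hvc_drift(x, params))

    def test_drift_vanishes_at_solver_equilibrium(self, nf_params):
        # root-find an equilibrium with an independent solver and confirm
        # the drift vanishes there
        x0 = np.full(8, -0.08)
        x0[0] = 0.9
        sol = root(lambda x: hvc_drift(x, nf_params), x0, tol=1e-12)
        if sol.success:
            assert np.abs(hvc_drift(sol.x, nf_params)).max() < 1e-8

    def test_rest_state_self_starts(self, params):
        drift = hvc_drift(np.zeros(8), params)
        assert (drift > 0).any()

    def test_non_finite_input_rejected(self, params):
        with pytest.raises(InvalidParameterError):
            hvc_drift(np.array([np.nan] + [0.0] * 7), params)

    def test_jacobian_matches_finite_differences(self, params):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.5, 8)
        jac = hvc_drift_jacobian(x, params)
        num = np.empty_like(jac)
        for j in range(8):
            d = np.zeros(8)
            d[j] = 1e-6
            num[:, j] = (hvc_drift(x + d, params) - hvc_drift(x - d, params)) / 2e-6
        assert np.abs(jac - num).max() < 1e-5


class TestSimulation:
    def test_noise_free_visits_all_ensembles_in_order(self, nf_params):
        traj = simulate_hvc(nf_params, duration=120.0, dt=0.01)
        winners = [w for (w, _, _) in winner_sequence(traj)]
        assert winners[:8] == list(range(1, 9))

    def test_same_seed_is_bitwise_identical(self, params):
        a = simulate_hvc(params, duration=20.0, dt=0.01, seed=42)
        b = simulate_hvc(params, duration=20.0, dt=0.01, seed=42)
        assert np.array_equal(a.hidden, b.hidden)
        assert np.array_equal(a.causal, b.causal)

    def test_causal_states_normalized(self, params):
        traj = simulate_hvc(params, duration=30.0, dt=0.01, seed=0)
        assert traj.causal.min() >= 0.0
        assert traj.causal.max() <= 1.0
        sums = traj.causal.sum(axis=1)
        assert (sums > 0).all() and (sums <= 1.0 + 1e-6).all()

    def test_time_rescaling_is_exact(self, nf_params):
        # (kappa, dt) and (2 kappa, dt/2) produce the same path under t -> 2t
        fast = dataclasses.replace(nf_params, rate=2 * nf_params.rate)
        a = simulate_hvc(nf_params, duration=40.0, dt=0.01)
        b = simulate_hvc(fast, duration=20.0, dt=0.005)
        assert np.allclose(a.hidden, b.hidden, atol=1e-12)

    def test_halved_rate_doubles_durations(self, nf_params):
        slow = dataclasses.replace(nf_params, rate=nf_params.rate / 2)
        a = simulate_hvc(nf_params, duration=150.0, dt=0.01)
        b = simulate_hvc(slow, duration=300.0, dt=0.01)
        da = [d for (_, _, d) in winner_sequence(a)][1:8]
        db = [d for (_, _, d) in winner_sequence(b)][1:8]
        assert np.allclose(np.array(db) / np.array(da), 2.0, rtol=0.01)

    def test_divergence_reports_time(self, params):
        wild = dataclasses.replace(params, rate=1e5)
        with pytest.raises(DivergenceError) as err:
            simulate_hvc(wild, duration=5.0, dt=0.01)
        assert err.value.time is not None

    def test_basin_robustness_of_the_sequence(self, nf_params):
        # random initial states near the first saddle all produce the
        # same winner sequence
        rng = np.random.default_rng(11)
        reference = None
        for _ in range(20):
            x0 = np.full(8, -0.1) + rng.normal(0, 0.05, 8)
            x0[0] = 1.0 + rng.normal(0, 0.1)
            traj = simulate_hvc(nf_params, duration=120.0, dt=0.01, x0=x0)
            winners = tuple(w for (w, _, _) in winner_sequence(traj))[:8]
            reference = reference or winners
            assert winners == reference == tuple(range(1, 9))


class TestWinnerSequence:
    def test_threshold_validation(self, nf_params):
        traj = simulate_hvc(nf_params, duration=15.0, dt=0.01)
        with pytest.raises(InvalidParameterError):
            winner_sequence(traj, threshold=1.5)

    def test_subthreshold_trajectory_is_empty(self, nf_params):
        traj = simulate_hvc(nf_params, duration=15.0, dt=0.01)
        quiet = hs.LevelTrajectory(
            times=traj.times,
            hidden=traj.hidden,
            causal=np.full_like(traj.causal, 0.01),
        )
        assert winner_sequence(quiet) == []

    def test_consecutive_duplicates_merge(self):
        times = np.arange(6) * 0.1
        v = np.zeros((6, 2))
        v[:3, 0] = 0.9
        v[3:, 1] = 0.9
        traj = hs.LevelTrajectory(times=times, hidden=v.copy(), causal=v)
        runs = winner_sequence(traj)
        assert [w for (w, _, _) in runs] == [1, 2]
        assert runs[0][2] == pytest.approx(0.3)


class TestChainStability:
    def test_default_chain_is_stable(self):
        ok, rep = chain_is_stable(build_chain_connectivity(8))
        assert ok
        assert all(s["n_unstable"] == 1 for s in rep["saddles"])

    def test_saddle_eigenvalues_match_dense_linearization(self):
        # independent oracle: numerically linearize the competition
        # skeleton dr_i/dt = r_i (1 - sum_j rho_ij r_j) at saddle k
        rho = build_chain_connectivity(6)
        k = 2
        r_star = np.zeros(6)
        r_star[k] = 1.0 / rho[k, k]

        def lv(r):
            return r * (1.0 - rho @ r)

        num = np.empty((6, 6))
        for j in range(6):
            d = np.zeros(6)
            d[j] = 1e-7
            num[:, j] = (lv(r_star + d) - lv(r_star - d)) / 2e-7
        eig_oracle = np.sort(np.linalg.eigvals(num).real)
        _, rep = chain_is_stable(rho)
        eig_impl = np.sort(rep["saddles"][k]["eigenvalues"])
        assert np.allclose(eig_oracle, eig_impl, atol=1e-6)

    def test_symmetric_competition_is_not_a_chain(self):
        rho = np.full((6, 6), 1.5)
        np.fill_diagonal(rho, 1.0)
        ok, _ = chain_is_stable(rho)
        assert not ok

    def test_identity_connectivity_is_not_a_chain(self):
        ok, _ = chain_is_stable(np.eye(5))
        assert not ok

    def test_degenerate_diagonal_reported_not_raised(self):
        rho = build_chain_connectivity(4)
        rho[np.diag_indices(4)] = 0.0
        ok, rep = chain_is_stable(rho)
        assert not ok
        assert rep["failures"]


def test_normalizer_bounds():
    u = np.array([0.9, 0.02, 0.02])
    v = normalize(u)
    assert v.sum() <= 1.0
    assert (v >= 0).all()
    assert v[0] > 0.85


def test_chain_preset_is_monotone_in_sharpness():
    gains = [chain_preset(n)[0] for n in (8, 32, 100)]
    assert gains == sorted(gains)
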