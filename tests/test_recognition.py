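"""The hierarchical filter: errors, free energy, gradients, filtering."""

import numpy as np
import pytest

import hiersong as hs
from hiersong import recognize as rz
from hiersong.errors import InvalidSizeError


@pytest.fixture(scope="module")
def nf_spec(cal_config, song):
    return rz.build_song_spec(cal_config.noise_free(), song)


@pytest.fixture(scope="module")
def embedded(nf_run, nf_spec, cal_config):
    u = rz.sensory_from_control(nf_run.control, nf_spec)
    return rz.embed_sensory(u, cal_config.dt)


def random_state(spec, seed=0, scale=0.5):
    rng = np.random.default_rng(seed)
    mu = rz.PosteriorState.zeros(spec)
    for i, l in enumerate(spec.levels):
        mu.mu_x[i] = rng.normal(0, scale, l.nx)
        mu.mu_dx[i] = rng.normal(0, scale, l.nx)
        mu.mu_v[i] = rng.normal(0, scale, l.nv)
        mu.mu_dv[i] = rng.normal(0, scale, l.nv)
    return mu


class TestPredictionErrors:
    def test_true_state_has_vanishing_errors(self, nf_run, nf_spec, embedded):
        """The generative form is exactly invertible on its own output."""
        for t in (200, 2500, 6000):
            mu = rz.true_posterior(nf_run, nf_spec, t)
            eps = rz.prediction_errors(mu, embedded[t], nf_spec)
            for e in eps["z"] + eps["x"]:
                assert np.abs(e).max() < 1e-6
            # derivative-channel errors are limited by the sensory
            # finite-difference embedding, not by the model
            for e in eps["dz"]:
                assert np.abs(e).max() < 1e-2

    def test_zero_state_returns_the_sensory_sample(self, nf_spec, embedded):
        mu = rz.PosteriorState.zeros(nf_spec)
        eps = rz.prediction_errors(mu, embedded[700], nf_spec)
        assert np.allclose(eps["z"][0], embedded[700][0])

    def test_perturbations_are_local(self, nf_run, nf_spec, embedded):
        """Only error terms touching a perturbed RA state change."""
        t = 3000
        mu = rz.true_posterior(nf_run, nf_spec, t)
        base = rz.prediction_errors(mu, embedded[t], nf_spec)
        mu2 = mu.copy()
        mu2.mu_x[1][2] += 0.1  # one RA hidden state
        pert = rz.prediction_errors(mu2, embedded[t], nf_spec)
        # level-2 output and dynamics errors change ...
        assert np.abs(pert["z"][1] - base["z"][1]).max() > 1e-4
        assert np.abs(pert["x"][1] - base["x"][1]).max() > 1e-4
        # ... while level-1 and level-3 errors are untouched
        assert np.allclose(pert["z"][0], base["z"][0])
        assert np.allclose(pert["z"][2], base["z"][2])
        assert np.allclose(pert["x"][0], base["x"][0])
        assert np.allclose(pert["x"][2], base["x"][2])

    def test_dimension_mismatch_raises(self, nf_spec):
        mu = rz.PosteriorState.zeros(nf_spec)
        with pytest.raises(InvalidSizeError):
            rz.prediction_errors(mu, np.zeros(3), nf_spec)


class TestFreeEnergy:
    def test_maximal_at_vanishing_errors(self, nf_run, nf_spec, embedded):
        t = 2500
        truth = rz.true_posterior(nf_run, nf_spec, t)
        f_true = rz.free_energy(truth, embedded[t], nf_spec)
        for seed in range(3):
            off = random_state(nf_spec, seed=seed, scale=0.3)
            assert rz.free_energy(off, embedded[t], nf_spec) < f_true

    def test_quadratic_form_in_a_single_error(self):
        # one level, one causal channel, identity precision: F drops by
        # exactly half the squared error
        level = rz.LevelSpec(nx=0, nv=1, ny=1, g=lambda x, v: v.copy())
        spec = rz.GenerativeSpec(levels=[level], deriv_weight=0.0)
        mu = rz.PosteriorState.zeros(spec)
        f0 = rz.free_energy(mu, np.zeros(1), spec)
        f1 = rz.free_energy(mu, np.array([2.0]), spec)
        assert f0 - f1 == pytest.approx(0.5 * 4.0)

    def test_gradient_matches_finite_differences(self, nf_spec, embedded):
        """Analytic free-energy gradient vs central differences < 1e-4."""
        mu = random_state(nf_spec, seed=1)
        lin = mu.copy()
        grad = rz.free_energy_gradient(mu, embedded[500], nf_spec, lin)
        vec = mu.flatten(nf_spec)
        gvec = grad.flatten(nf_spec)
        num = np.empty_like(vec)
        for j in range(len(vec)):
            d = np.zeros_like(vec)
            d[j] = 1e-6
            fp = rz.free_energy(
                rz.PosteriorState.unflatten(vec + d, nf_spec),
                embedded[500], nf_spec, lin)
            fm = rz.free_energy(
                rz.PosteriorState.unflatten(vec - d, nf_spec),
                embedded[500], nf_spec, lin)
            num[j] = (fp - fm) / 2e-6
        rel = np.linalg.norm(gvec - num) / np.linalg.norm(num)
        assert rel < 1e-4


class TestFilterStep:
    def test_zero_gradient_scale_leaves_pure_motion(self, cal_config, song):
        spec = rz.build_song_spec(cal_config, song, step_scale=0.0)
        mu = random_state(spec, seed=2)
        out = rz.filter_step(mu, np.zeros(2), spec)
        dt = spec.dt
        for i, l in enumerate(spec.levels):
            if l.clamped:
                continue
            # x advances by its velocity; v by its velocity estimate
            assert np.allclose(out.mu_x[i], mu.mu_x[i] + dt * mu.mu_dx[i],
                               atol=1e-8)
            assert np.allclose(out.mu_v[i], mu.mu_v[i] + dt * mu.mu_dv[i],
                               atol=1e-8)

    def test_linear_gaussian_toy_matches_analytic_posterior(self):
        """Static one-level model: the filter converges to the exact
        Gaussian posterior mean (G v + noise observed, Gaussian prior)."""
        G, pi_u, pi_prior, eta, u = 1.7, 4.0, 2.0, 0.3, 1.2
        level = rz.LevelSpec(
            nx=0, nv=1, ny=1,
            g=lambda x, v: G * v,
            gv=lambda x, v: np.array([[G]]),
            pi_z=np.array([pi_u]),
            pi_dv=10.0,
        )
        spec = rz.GenerativeSpec(
            levels=[level], dt=0.05, eta=np.array([eta]),
            pi_eta=np.array([pi_prior]), deriv_weight=0.1,
        )
        expected = (G * pi_u * u + pi_prior * eta) / (G * G * pi_u + pi_prior)
        mu = rz.PosteriorState.zeros(spec)
        sample = np.vstack([[u], [0.0]])
        for _ in range(400):
            mu = rz.filter_step(mu, sample, spec)
        assert mu.mu_v[0][0] == pytest.approx(expected, abs=1e-4)

    def test_self_recognition_errors_stay_small(self, nf_run, nf_spec):
        """Initialized on the truth, noise-free data keeps the running
        prediction errors small for the whole song (brief handover
        transients aside, measured as RMS per level)."""
        res = rz.recognize(
            nf_run.control, nf_spec, rz.true_posterior(nf_run, nf_spec, 0)
        )
        rms = lambda a: float(np.sqrt(np.mean(np.square(a))))
        assert rms(res.eps_z[0]) < 0.08   # sensory channels
        assert rms(res.eps_z[1]) < 0.02   # gates
        assert rms(res.eps_z[2]) < 0.02   # chain output
        for level in range(3):
            assert rms(res.eps_x[level]) < 0.05


class TestErrorEnergy:
    def test_zero_errors_give_zero_energy(self, nf_spec):
        res = rz.RecognitionResult(
            times=np.arange(10) * 0.01,
            mu_x=[np.zeros((10, l.nx)) for l in nf_spec.levels],
            mu_dx=[np.zeros((10, l.nx)) for l in nf_spec.levels],
            mu_v=[np.zeros((10, l.nv)) for l in nf_spec.levels],
            eps_z=[np.zeros((10, l.ny)) for l in nf_spec.levels],
            eps_x=[np.zeros((10, l.nx)) for l in nf_spec.levels],
            free_energy=np.zeros(10),
            spec=nf_spec,
        )
        assert rz.error_energy(res, 2, (0.0, 0.05)) == 0.0
        with pytest.raises(Exception):
            rz.error_energy(res, 2, (5.0, 6.0))  # empty window


class TestSensoryMapping:
    def test_affine_inversion_roundtrip(self, cal_config, nf_run, nf_spec):
        u = rz.sensory_from_control(nf_run.control, nf_spec)
        a_p, b_p = cal_config.osc_ap, cal_config.osc_bp
        a_k, b_k = cal_config.osc_ak, cal_config.osc_bk
        assert np.allclose(a_p + b_p * u[:, 0], nf_run.control.p)
        assert np.allclose(a_k + b_k * u[:, 1], nf_run.control.k)

    def test_embedding_orders(self):
        stream = np.column_stack([np.sin(np.arange(100) * 0.1),
                                  np.cos(np.arange(100) * 0.1)])
        emb = rz.embed_sensory(stream, 0.1, order=3)
        assert emb.shape == (100, 3, 2)
        # derivative of sin is cos (interior points)
        assert np.allclose(emb[5:-5, 1, 0], np.cos(np.arange(100) * 0.1)[5:-5],
                           atol=5e-3)
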