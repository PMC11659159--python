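import numpy as np
import pytest
from scipy import stats

from pocketdiff.diffusion import (
    com_project,
    draw_noise,
    fit_size_model,
    forward_noise,
    generate,
    posterior_mean_var,
    posterior_step,
    predict_data,
    sample_ligand_size,
    training_loss,
)
from pocketdiff.molsys import AtomPointCloud
from pocketdiff.schedule import build_schedule
from pocketdiff.synthdata import random_rotation

SCHED = build_schedule(100)


def _cloud(rng, n=6, d=4):
    return AtomPointCloud(rng.normal(0, 2, (n, 3)), rng.normal(0, 1, (n, d)))


class TestForwardNoise:
    def test_zero_noise_scales_data(self, rng):
        z = _cloud(rng)
        out = forward_noise(z, 40, SCHED, np.zeros((6, 7)))
        np.testing.assert_allclose(out.coords, SCHED.alpha[40] * z.coords)
        np.testing.assert_allclose(out.feats, SCHED.alpha[40] * z.feats)

    def test_t0_keeps_signal(self, rng):
        z = _cloud(rng)
        noise = rng.standard_normal((6, 7))
        out = forward_noise(z, 0, SCHED, noise)
        bound = SCHED.sigma[0] * np.abs(noise) + 1e-4 * np.abs(np.hstack([z.coords, z.feats]))
        np.testing.assert_array_less(
            np.abs(np.hstack([out.coords - z.coords, out.feats - z.feats])), bound + 1e-12)

    def test_monte_carlo_moments(self, rng):
        z = _cloud(rng, n=2, d=1)
        t = 50
        draws = np.stack([
            np.hstack([c.coords, c.feats])
            for c in (forward_noise(z, t, SCHED, rng.standard_normal((2, 4)))
                      for _ in range(10_000))
        ])
        target = SCHED.alpha[t] * np.hstack([z.coords, z.feats])
        se = SCHED.sigma[t] / np.sqrt(10_000)
        assert np.all(np.abs(draws.mean(axis=0) - target) < 4 * se)
        var = draws.var(axis=0)
        assert np.all(np.abs(var - SCHED.sigma[t] ** 2) < 0.05 * SCHED.sigma[t] ** 2 * 5)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            forward_noise(_cloud(rng), 10, SCHED, np.zeros((3, 3)))


class TestPredictData:
    def test_true_noise_recovers_data(self, rng):
        z = _cloud(rng)
        noise = rng.standard_normal((6, 7))
        z_t = forward_noise(z, 60, SCHED, noise)
        rec = predict_data(z_t, noise, 60, SCHED)
        np.testing.assert_allclose(rec.coords, z.coords, atol=1e-9)
        np.testing.assert_allclose(rec.feats, z.feats, atol=1e-9)

    def test_zero_eps_returns_scaled_state(self, rng):
        z_t = _cloud(rng)
        out = predict_data(z_t, np.zeros((6, 7)), 30, SCHED)
        np.testing.assert_allclose(out.coords, z_t.coords / SCHED.alpha[30])

    def test_round_trip_renoise(self, rng):
        z_t = _cloud(rng)
        eps_hat = rng.standard_normal((6, 7))
        t = 45
        z_hat = predict_data(z_t, eps_hat, t, SCHED)
        back = forward_noise(z_hat, t, SCHED, eps_hat)
        np.testing.assert_allclose(back.coords, z_t.coords, atol=1e-9)
        np.testing.assert_allclose(back.feats, z_t.feats, atol=1e-9)

    def test_t_zero_rejected(self, rng):
        with pytest.raises(ValueError):
            predict_data(_cloud(rng), np.zeros((6, 7)), 0, SCHED)


class TestPosteriorStep:
    def test_mean_weights_convexity_identity(self):
        # alpha_{t|s} sig_s^2 / sig_t^2 * alpha_s + alpha_s sig_{t|s}^2 / sig_t^2
        # equals alpha_s because sig_t^2 = alpha_{t|s}^2 sig_s^2 + sig_{t|s}^2
        from pocketdiff.schedule import transition_coeffs

        for (s, t) in [(0, 1), (10, 40), (98, 99)]:
            a_ts, var_ts = transition_coeffs(SCHED, s, t)
            w_t = a_ts * SCHED.sigma[s] ** 2 / SCHED.sigma[t] ** 2
            w_ref = SCHED.alpha[s] * var_ts / SCHED.sigma[t] ** 2
            assert w_t * SCHED.alpha[t] + w_ref == pytest.approx(SCHED.alpha[s], abs=1e-12)

    def test_monte_carlo_moments(self, rng):
        z_t = _cloud(rng, n=1, d=1)
        z_ref = _cloud(rng, n=1, d=1)
        s, t = 20, 60
        n = 100_000
        draws = np.stack([
            np.hstack([c.coords, c.feats])
            for c in (posterior_step(z_t, z_ref, s, t, SCHED, rng) for _ in range(n))
        ])
        mean, var = posterior_mean_var(np.hstack([z_t.coords, z_t.feats]),
                                       np.hstack([z_ref.coords, z_ref.feats]),
                                       s, t, SCHED)
        se_mean = np.sqrt(var / n)
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 3 * se_mean)
        se_var = var * np.sqrt(2 / (n - 1))
        assert np.all(np.abs(draws.var(axis=0) - var) < 3 * se_var)

    def test_order_rejected(self, rng):
        with pytest.raises(ValueError):
            posterior_step(_cloud(rng), _cloud(rng), 10, 10, SCHED, rng)

    def test_com_projection_flag(self, rng):
        z = posterior_step(_cloud(rng), _cloud(rng), 5, 50, SCHED, rng,
                           com_project_after=True)
        np.testing.assert_allclose(z.coords.mean(axis=0), 0, atol=1e-12)


class TestTrainingLoss:
    def test_identity_zero(self, rng):
        eps = rng.standard_normal((3, 4))
        assert training_loss(eps, eps) == 0.0

    def test_half_sum_of_squares(self):
        eps = np.ones((2, 3))
        assert training_loss(eps, np.zeros((2, 3))) == pytest.approx(3.0)

    def test_matches_elementwise_loop(self, rng):
        a, b = rng.standard_normal((4, 5)), rng.standard_normal((4, 5))
        manual = 0.0
        for i in range(4):
            for j in range(5):
                manual += 0.5 * (a[i, j] - b[i, j]) ** 2
        assert training_loss(a, b) == pytest.approx(manual, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            training_loss(np.zeros((2, 2)), np.zeros((3, 2)))


class TestComProject:
    def test_idempotent(self, rng):
        x = com_project(rng.normal(0, 1, (5, 3)))
        np.testing.assert_allclose(com_project(x), x, atol=1e-12)

    def test_single_point(self):
        np.testing.assert_allclose(com_project([[3.0, 4.0, 5.0]]), [[0, 0, 0]])

    def test_reference_subset_and_distances(self, rng):
        x = rng.normal(0, 2, (20, 3))
        ref = [2, 5, 7]
        out = com_project(x, ref)
        np.testing.assert_allclose(out[ref].mean(axis=0), 0, atol=1e-12)
        d_before = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        d_after = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
        np.testing.assert_allclose(d_after, d_before, atol=1e-12)

    def test_empty_reference_rejected(self, rng):
        with pytest.raises(ValueError):
            com_project(rng.normal(0, 1, (4, 3)), [])


class TestSizeModel:
    def test_single_pair_mode(self):
        model = fit_size_model([(10, 30)], smoothing_sigma=1.0)
        cond = model.conditional(30)
        assert np.argmax(cond) + 1 == 10

    def test_conditionals_normalized(self, rng):
        pairs = list(zip(rng.integers(3, 15, 50), rng.integers(10, 40, 50)))
        model = fit_size_model(pairs)
        for n_p in range(1, model.max_np + 1):
            assert model.conditional(n_p).sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(model.joint >= 0)

    def test_sigma_zero_limit_is_empirical(self):
        model = fit_size_model([(8, 20), (12, 20)], smoothing_sigma=0.0)
        cond = model.conditional(20)
        assert cond[7] == pytest.approx(0.5)
        assert cond[11] == pytest.approx(0.5)

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError):
            fit_size_model([(0, 5)])

    def test_sampling_concentrates_at_mode(self, rng):
        model = fit_size_model([(10, 30)])
        draws = [sample_ligand_size(model, 30, rng) for _ in range(10_000)]
        values, counts = np.unique(draws, return_counts=True)
        assert values[np.argmax(counts)] == 10

    def test_mean_shift_five(self, rng):
        pairs = [(8, 20), (10, 20), (12, 20)] * 10
        base = fit_size_model(pairs, mean_shift=0)
        shifted = fit_size_model(pairs, mean_shift=5)
        m0 = np.mean([sample_ligand_size(base, 20, rng) for _ in range(10_000)])
        m5 = np.mean([sample_ligand_size(shifted, 20, rng) for _ in range(10_000)])
        assert m5 - m0 == pytest.approx(5.0, abs=0.2)

    def test_chi_square_goodness_of_fit(self, rng):
        pairs = [(5, 20), (6, 20), (7, 20), (5, 20), (6, 20)] * 20
        model = fit_size_model(pairs)
        n = 10_000
        draws = np.array([sample_ligand_size(model, 20, rng) for _ in range(n)])
        probs = model.conditional(20)
        keep = probs * n >= 5  # standard chi-square validity threshold
        observed = np.array([(draws == k + 1).sum() for k in np.nonzero(keep)[0]])
        expected = probs[keep] * n
        observed = observed * expected.sum() / observed.sum()
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01


class TestGenerate:
    def test_pocket_untouched_and_determinism(self, tiny_model):
        pocket = AtomPointCloud(np.random.default_rng(3).normal(0, 3, (8, 3)),
                                np.eye(8, 20))
        before = pocket.coords.copy()
        a = generate(tiny_model, pocket, 2, mode="cond", rng=9)
        b = generate(tiny_model, pocket, 2, mode="cond", rng=9)
        c = generate(tiny_model, pocket, 2, mode="cond", rng=10)
        np.testing.assert_array_equal(pocket.coords, before)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.coords, s2.coords)
            assert s1.labels == s2.labels
        assert any(not np.array_equal(s1.coords, s3.coords) for s1, s3 in zip(a, c))

    def test_sample_count_and_sizes(self, tiny_model):
        pocket = AtomPointCloud(np.random.default_rng(4).normal(0, 3, (8, 3)),
                                np.eye(8, 20))
        out = generate(tiny_model, pocket, 3, mode="cond", rng=1, sizes=[4, 5, 6])
        assert [s.n_atoms for s in out] == [4, 5, 6]
        assert all(s.is_one_hot() for s in out)

    def test_invalid_inputs_rejected(self, tiny_model):
        pocket = AtomPointCloud(np.zeros((2, 3)), np.eye(2, 20))
        with pytest.raises(ValueError):
            generate(tiny_model, pocket, 0, mode="cond", rng=1)
        with pytest.raises(ValueError):
            generate(tiny_model, pocket, 1, mode="sideways", rng=1)

    def test_se3_equivariant_sampling(self, tiny_model):
        """Rotating the pocket and expressing the noise stream in the rotated
        frame must rotate the sampled ligands."""
        rng = np.random.default_rng(12)
        pocket = AtomPointCloud(rng.normal(0, 3, (8, 3)), np.eye(8, 20))
        rot = random_rotation(rng)
        shift = rng.normal(0, 5, 3)
        pocket_r = AtomPointCloud(pocket.coords @ rot.T + shift, pocket.feats)
        base = generate(tiny_model, pocket, 2, mode="cond", rng=21, sizes=[5, 5])
        moved = generate(tiny_model, pocket_r, 2, mode="cond", rng=21, sizes=[5, 5],
                         coord_transform=rot)
        for s_b, s_m in zip(base, moved):
            np.testing.assert_allclose(s_m.coords, s_b.coords @ rot.T + shift,
                                       atol=1e-4)
            assert s_m.labels == s_b.labels


def test_draw_noise_com_free(rng):
    eps = draw_noise(rng, 10, 4, com_free=True)
    np.testing.assert_allclose(eps[:, :3].mean(axis=0), 0, atol=1e-12)
    assert eps.shape == (10, 7)
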