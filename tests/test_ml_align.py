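"""EM alignment: preparation ops, E/M oracle equivalence, convergence,
parameter recovery, and the cross-correlation limit."""

import numpy as np
import pytest

from bofem import ml_align, simulate
from bofem.flc_pick import ParticleStack
from bofem.ml_align import ModelState, TransformGrid
from bofem.transforms import apply_inverse_transform, apply_transform


def toy_grid():
    """8 transform samples: 4 right-angle rotations x 2 shifts."""
    return TransformGrid(rotations=np.array([0.0, 90.0, 180.0, 270.0]),
                         shifts=np.array([[0, 0], [1, 0]]))


def brute_force_em(images, theta, grid):
    """Independent enumeration of posterior weights and weighted updates."""
    n = len(images)
    K = theta.n_classes
    J = images[0].size
    if np.isfinite(theta.xi):
        ls = -np.array([(tx**2 + ty**2) for tx, ty in grid.shifts]) / (2 * theta.xi**2)
        ls = ls - np.log(np.exp(ls).sum())
    else:
        ls = np.full(len(grid.shifts), -np.log(len(grid.shifts)))
    logw = np.zeros((n, K, grid.n_rot, grid.n_shift))
    for i in range(n):
        for k in range(K):
            for r, ang in enumerate(grid.rotations):
                for s, (tx, ty) in enumerate(grid.shifts):
                    ref = apply_transform(theta.A[k], float(ang), int(tx), int(ty))
                    d2 = float(((images[i] - ref) ** 2).sum())
                    logw[i, k, r, s] = (
                        -d2 / (2 * theta.sigma**2)
                        - 0.5 * J * np.log(2 * np.pi * theta.sigma**2)
                        + np.log(theta.weights[k]) - np.log(grid.n_rot) + ls[s]
                    )
    flat = logw.reshape(n, -1)
    m = flat.max(axis=1, keepdims=True)
    w = np.exp(flat - m)
    resp = (w / w.sum(axis=1, keepdims=True)).reshape(logw.shape)
    log_ev = m[:, 0] + np.log(np.exp(flat - m).sum(axis=1))
    # weighted class averages via back-transformed images
    a_new = np.zeros_like(theta.A)
    for k in range(K):
        acc = np.zeros_like(theta.A[k])
        for i in range(n):
            for r, ang in enumerate(grid.rotations):
                for s, (tx, ty) in enumerate(grid.shifts):
                    acc += resp[i, k, r, s] * apply_inverse_transform(
                        images[i], float(ang), int(tx), int(ty))
        a_new[k] = acc / resp[:, k].sum()
    return resp, log_ev, a_new


@pytest.fixture()
def toy_stack(rng):
    return ParticleStack(rng.normal(size=(3, 16, 16)), pixel_size=1.0)


@pytest.fixture()
def toy_theta(rng):
    a = rng.normal(size=(2, 16, 16))
    return ModelState(A=a, weights=np.array([0.6, 0.4]), sigma=1.3, xi=1.5)


class TestNormalize:
    def test_annulus_stats_after_normalization(self, rng):
        stack = ParticleStack(rng.normal(2.0, 3.0, size=(5, 48, 48)).astype(np.float32),
                              pixel_size=1.0)
        out = ml_align.normalize_particles(stack)
        mask = ml_align._annulus_mask(48, 0.40 * 48, 0.50 * 48)
        for img in out.images:
            assert abs(img[mask].mean()) < 1e-5
            assert abs(img[mask].std() - 1.0) < 1e-5

    def test_idempotent(self, rng):
        stack = ParticleStack(rng.normal(size=(3, 32, 32)).astype(np.float64), 1.0)
        once = ml_align.normalize_particles(stack)
        twice = ml_align.normalize_particles(once)
        np.testing.assert_allclose(twice.images, once.images, atol=1e-6)

    def test_constant_image_rejected(self):
        stack = ParticleStack(np.ones((2, 32, 32), dtype=np.float32), 1.0)
        with pytest.raises(ValueError, match="zero background"):
            ml_align.normalize_particles(stack)


class TestBinParticles:
    def test_factor_one_identity(self, rng):
        stack = ParticleStack(rng.normal(size=(2, 30, 30)).astype(np.float32), 1.0)
        out = ml_align.bin_particles(stack, 1)
        np.testing.assert_array_equal(out.images, stack.images)

    def test_factor_three_shape_and_pixel_size(self, rng):
        stack = ParticleStack(rng.normal(size=(4, 180, 180)).astype(np.float32), 1.0)
        out = ml_align.bin_particles(stack, 3)
        assert out.images.shape == (4, 60, 60)
        assert out.pixel_size == pytest.approx(3.0)

    def test_mean_preserved_by_fourier_crop(self, rng):
        stack = ParticleStack(rng.normal(size=(3, 60, 60)).astype(np.float64), 1.0)
        out = ml_align.bin_particles(stack, 3)
        np.testing.assert_allclose(out.images.mean(axis=(1, 2)),
                                   stack.images.mean(axis=(1, 2)), atol=1e-6)


class TestStartReferences:
    def test_unaligned_average_k1_is_plain_mean(self, rng):
        stack = ParticleStack(rng.normal(size=(10, 24, 24)), 1.0)
        state = ml_align.make_start_references(stack, "unaligned_average", 1, 0)
        np.testing.assert_allclose(state.A[0], stack.images.mean(axis=0), atol=1e-6)

    def test_gaussian_circle_nearly_symmetric(self, rng):
        stack = ParticleStack(rng.normal(size=(8, 33, 33)), 1.0)
        state = ml_align.make_start_references(stack, "gaussian_circle", 3, 0)
        for a in state.A:
            rot = np.rot90(a)
            # symmetric up to the 1% symmetry-breaking perturbation
            assert np.abs(a - rot).max() < 0.05 * np.abs(a).max()
        # perturbation makes the K copies distinct
        assert np.abs(state.A[0] - state.A[1]).max() > 0

    def test_random_noise_image_draws_distinct_particles(self, rng):
        stack = ParticleStack(rng.normal(size=(6, 16, 16)), 1.0)
        state = ml_align.make_start_references(stack, "random_noise_image", 3, 0)
        matches = [
            int(np.argmin([np.abs(a - img).sum() for img in stack.images]))
            for a in state.A
        ]
        assert len(set(matches)) == 3

    def test_k_exceeding_stack_rejected(self, rng):
        stack = ParticleStack(rng.normal(size=(3, 8, 8)), 1.0)
        with pytest.raises(ValueError):
            ml_align.make_start_references(stack, "gaussian_circle", 5, 0)


class TestEStep:
    def test_delta_posterior_for_noiseless_match(self, rng):
        grid = toy_grid()
        a = rng.normal(size=(2, 16, 16))
        theta = ModelState(A=a, weights=np.array([0.5, 0.5]), sigma=0.01, xi=np.inf)
        x = apply_transform(a[1], 90.0, 1, 0)
        stack = ParticleStack(x[None], 1.0)
        post = ml_align.e_step(stack, theta, grid)
        assert post.resp[0, 1, 1, 1] > 0.999

    def test_identical_classes_split_equally(self, rng):
        grid = toy_grid()
        a = rng.normal(size=(16, 16))
        theta = ModelState(A=np.stack([a, a]), weights=np.array([0.5, 0.5]),
                           sigma=1.0, xi=1.5)
        stack = ParticleStack(rng.normal(size=(2, 16, 16)), 1.0)
        post = ml_align.e_step(stack, theta, grid)
        np.testing.assert_allclose(post.resp[:, 0], post.resp[:, 1], atol=1e-10)

    def test_matches_enumeration_oracle(self, toy_stack, toy_theta):
        grid = toy_grid()
        post = ml_align.e_step(toy_stack, toy_theta, grid)
        resp_ref, log_ev_ref, _ = brute_force_em(toy_stack.images, toy_theta, grid)
        np.testing.assert_allclose(post.resp, resp_ref, atol=1e-10)
        np.testing.assert_allclose(post.log_evidence, log_ev_ref, atol=1e-10)

    def test_responsibilities_normalized(self, toy_stack, toy_theta):
        post = ml_align.e_step(toy_stack, toy_theta, toy_grid())
        np.testing.assert_allclose(post.resp.sum(axis=(1, 2, 3)), 1.0, atol=1e-9)

    def test_invalid_sigma_rejected(self, toy_stack, toy_theta):
        toy_theta.sigma = 0.0
        with pytest.raises(ValueError):
            ml_align.e_step(toy_stack, toy_theta, toy_grid())


class TestMStep:
    def test_delta_identity_posterior_reduces_to_plain_mean(self, rng):
        grid = toy_grid()
        stack = ParticleStack(rng.normal(size=(4, 16, 16)), 1.0)
        resp = np.zeros((4, 1, grid.n_rot, grid.n_shift))
        resp[:, 0, 0, 0] = 1.0  # identity transform, single class
        post = ml_align.PosteriorTable(resp=resp, log_evidence=np.zeros(4),
                                       expected_sq_residual=4 * 256.0)
        theta = ml_align.m_step(stack, post, grid)
        np.testing.assert_allclose(theta.A[0], stack.images.mean(axis=0), atol=1e-12)
        assert theta.weights[0] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, toy_stack, toy_theta):
        grid = toy_grid()
        post = ml_align.e_step(toy_stack, toy_theta, grid)
        _, _, a_ref = brute_force_em(toy_stack.images, toy_theta, grid)
        theta = ml_align.m_step(toy_stack, post, grid, old_theta=toy_theta)
        np.testing.assert_allclose(theta.A, a_ref, atol=1e-10)

    def test_weights_sum_to_one(self, toy_stack, toy_theta):
        post = ml_align.e_step(toy_stack, toy_theta, toy_grid())
        theta = ml_align.m_step(toy_stack, post, toy_grid(), old_theta=toy_theta)
        assert theta.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(theta.weights >= 0)


class TestEMAlign:
    def test_noiseless_views_classified_in_two_iterations(self, rng):
        grid = TransformGrid(rotations=np.array([0.0]), shifts=np.array([[0, 0]]))
        views = rng.normal(size=(3, 20, 20))
        images = np.concatenate([np.repeat(v[None], 4, axis=0) for v in views])
        images = images + 1e-6 * rng.normal(size=images.shape)
        stack = ParticleStack(images, 1.0)
        start = ModelState(A=views + 0.01 * rng.normal(size=views.shape),
                           weights=np.full(3, 1 / 3), sigma=0.5, xi=np.inf)
        theta, trace, post = ml_align.em_align(stack, start, grid, max_iter=2)
        labels = post.resp.sum(axis=(2, 3)).argmax(axis=1)
        assert len(np.unique(labels)) == 3
        for g in range(3):
            assert len(np.unique(labels[4 * g:4 * g + 4])) == 1

    def test_log_likelihood_monotone(self, rng):
        grid = TransformGrid.make(rot_step=90.0, max_shift=1)
        a = simulate.make_gaussian_circle(24, 4.0).astype(np.float64)
        images = np.stack([
            apply_transform(a, float(rng.choice([0, 90, 180, 270])),
                            int(rng.integers(-1, 2)), int(rng.integers(-1, 2)))
            + 0.8 * rng.normal(size=(24, 24))
            for _ in range(40)
        ])
        stack = ParticleStack(images, 1.0)
        start = ml_align.make_start_references(stack, "unaligned_average", 2, 0)
        theta, trace, _ = ml_align.em_align(stack, start, grid, max_iter=15)
        l = np.array(trace.log_likelihood)
        assert np.all(np.diff(l) >= -1e-6 * np.abs(l[:-1]))

    def test_sigma_and_signal_recovery(self, rng):
        """Generative-model recovery: known signal, sigma and Gaussian shifts."""
        from bofem import evaluate
        box = 32
        a_true = simulate.lowpass_filter(rng.normal(size=(box, box)), 3.2,
                                         pixel_size=1.0)
        a_true *= 1.0 / a_true.std()
        sp_snr = 0.01
        sigma_true = float(a_true.std() / np.sqrt(sp_snr))
        n = 1500
        shifts = np.clip(np.rint(rng.normal(0, 1.0, size=(n, 2))), -2, 2).astype(int)
        images = np.stack([
            apply_transform(a_true, 0.0, tx, ty) + sigma_true * rng.normal(size=(box, box))
            for tx, ty in shifts
        ])
        stack = ParticleStack(images, 1.0)
        grid = TransformGrid(rotations=np.array([0.0]),
                             shifts=TransformGrid.make(max_shift=2).shifts)
        start = ml_align.make_start_references(stack, "unaligned_average", 1, 0)
        start.sigma = sigma_true * 1.3
        theta, trace, _ = ml_align.em_align(stack, start, grid, max_iter=30)
        assert theta.sigma == pytest.approx(sigma_true, rel=0.05)
        curve = evaluate.frc(theta.A[0], a_true, pixel_size=1.0)
        half_nyq = curve.frequencies <= 0.25
        assert np.all(curve.values[half_nyq] > 0.9)

    def test_divergent_sigma_aborts(self, rng):
        grid = toy_grid()
        stack = ParticleStack(rng.normal(size=(3, 16, 16)), 1.0)
        start = ModelState(A=rng.normal(size=(1, 16, 16)), weights=np.ones(1),
                           sigma=np.nan, xi=1.5)
        with pytest.raises((FloatingPointError, ValueError)):
            ml_align.em_align(stack, start, grid, max_iter=3)


class TestCCAlign:
    def test_single_image_reproduces_itself(self, rng):
        img = rng.normal(size=(20, 20))
        stack = ParticleStack(img[None], 1.0)
        grid = TransformGrid(rotations=np.array([0.0]), shifts=np.array([[0, 0]]))
        avg, params = ml_align.cc_align(stack, img, max_iter=3, grid=grid)
        np.testing.assert_allclose(avg, img, atol=1e-10)

    def test_recovers_known_shifts(self, rng):
        a = simulate.make_gaussian_circle(32, 5.0).astype(np.float64)
        a[10:14, 16:20] += 0.7  # break symmetry
        true_shifts = [(1, -2), (0, 1), (-2, 0), (2, 2), (-1, -1), (0, 0)]
        images = np.stack([apply_transform(a, 0.0, tx, ty) for tx, ty in true_shifts])
        stack = ParticleStack(images, 1.0)
        grid = TransformGrid(rotations=np.array([0.0]),
                             shifts=TransformGrid.make(max_shift=2).shifts)
        avg, params = ml_align.cc_align(stack, a, max_iter=5, grid=grid)
        recovered = [(int(tx), int(ty)) for _, tx, ty in params]
        assert recovered == list(true_shifts)
        unaligned = images.mean(axis=0)
        assert avg.max() > unaligned.max()  # aligned average is sharper

    def test_em_with_tiny_sigma_matches_cc_assignments(self, rng):
        a = simulate.make_gaussian_circle(24, 4.0).astype(np.float64)
        a[6:9, 14:17] += 1.0
        grid = TransformGrid(rotations=np.array([0.0, 90.0, 180.0, 270.0]),
                             shifts=np.array([[0, 0], [1, 1], [-1, 0]]))
        cases = [(90.0, 1, 1), (0.0, 0, 0), (270.0, -1, 0), (180.0, 0, 0)]
        images = np.stack([
            apply_transform(a, ang, tx, ty) + 0.02 * rng.normal(size=(24, 24))
            for ang, tx, ty in cases
        ])
        stack = ParticleStack(images, 1.0)
        _, cc_params = ml_align.cc_align(stack, a, max_iter=1, grid=grid)
        theta = ModelState(A=a[None], weights=np.ones(1), sigma=0.05, xi=np.inf)
        post = ml_align.e_step(stack, theta, grid)
        em_best = post.resp[:, 0].reshape(len(images), -1).argmax(axis=1)
        cc_best = [
            list(grid.rotations).index(p[0]) * grid.n_shift
            + next(s for s, (tx, ty) in enumerate(grid.shifts)
                   if (tx, ty) == (p[1], p[2]))
            for p in cc_params
        ]
        assert list(em_best) == cc_best
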