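"""Reconstruction stage: operators, diffusion tensor, Poisson solver, pipeline."""

import numpy as np
import pytest

from msmdenoise import (
    DataError,
    DenoiseConfig,
    FeatureMask,
    GradientField,
    SolverConfig,
    TensorField,
    build_diffusion_tensor,
    denoise,
    identity_tensor,
    image_gradients,
    restrict_gradients,
    solve_weighted_poisson,
)
from msmdenoise.reconstruct import _assemble


def random_spd_tensor(rng, shape):
    a = rng.uniform(0.2, 2.0, shape)
    c = rng.uniform(0.2, 2.0, shape)
    b = rng.uniform(-0.9, 0.9, shape) * np.sqrt(a * c)
    return TensorField(j11=a, j12=b, j22=c)


def apply_weighted_laplacian_loops(v, J):
    """Independent loop-free reference for G^T J G v (forward diff + scatter adjoint)."""
    vx = np.zeros_like(v)
    vy = np.zeros_like(v)
    vx[:, :-1] = v[:, 1:] - v[:, :-1]
    vy[:-1, :] = v[1:, :] - v[:-1, :]
    px = J.j11 * vx + J.j12 * vy
    py = J.j12 * vx + J.j22 * vy
    out = np.zeros_like(v)
    out[:, :-1] -= px[:, :-1]
    out[:, 1:] += px[:, :-1]
    out[:-1, :] -= py[:-1, :]
    out[1:, :] += py[:-1, :]
    return out


# ---------------------------------------------------------------- gradients

def test_constant_image_has_zero_gradients():
    g = image_gradients(np.full((8, 8), 3.0))
    assert not g.gx.any() and not g.gy.any()


def test_column_ramp_gradients():
    b = np.tile(np.arange(6, dtype=float), (5, 1))
    g = image_gradients(b)
    assert np.all(g.gx[:, :-1] == 1.0)
    assert np.all(g.gx[:, -1] == 0.0)
    assert not g.gy.any()


def test_gradients_match_difference_oracle(rng):
    b = rng.normal(size=(5, 5))
    g = image_gradients(b)
    for i in range(5):
        for j in range(5):
            assert g.gx[i, j] == (b[i, j + 1] - b[i, j] if j < 4 else 0.0)
            assert g.gy[i, j] == (b[i + 1, j] - b[i, j] if i < 4 else 0.0)


def test_tiny_image_rejected():
    with pytest.raises(DataError):
        image_gradients(np.ones((1, 5)))


# -------------------------------------------------------------- restriction

def test_full_and_empty_mask_restriction(rng):
    g = GradientField(gx=rng.normal(size=(6, 6)), gy=rng.normal(size=(6, 6)))
    full = restrict_gradients(g, np.ones((6, 6), bool))
    np.testing.assert_array_equal(full.gx, g.gx)
    empty = restrict_gradients(g, np.zeros((6, 6), bool))
    assert not empty.gx.any() and not empty.gy.any()


def test_checkerboard_restriction_is_elementwise_product(rng):
    g = GradientField(gx=rng.normal(size=(6, 6)), gy=rng.normal(size=(6, 6)))
    mask = np.indices((6, 6)).sum(axis=0) % 2 == 0
    out = restrict_gradients(g, FeatureMask(mask=mask, d_threshold=0.0))
    np.testing.assert_array_equal(out.gx, g.gx * mask)
    np.testing.assert_array_equal(out.gy, g.gy * mask)


def test_restriction_shape_mismatch_rejected(rng):
    g = GradientField(gx=np.zeros((4, 4)), gy=np.zeros((4, 4)))
    with pytest.raises(DataError):
        restrict_gradients(g, np.ones((5, 5), bool))


# ----------------------------------------------------------------- tensor

def test_constant_image_gives_identity_tensor():
    J = build_diffusion_tensor(np.full((32, 32), 0.5), smoothing_sigma=1.5, contrast_k=0.1)
    np.testing.assert_allclose(J.j11, 1.0, atol=1e-12)
    np.testing.assert_allclose(J.j12, 0.0, atol=1e-12)
    np.testing.assert_allclose(J.j22, 1.0, atol=1e-12)


def test_vertical_step_edge_larger_eigenvector_is_vertical():
    """On a vertical step the strong-diffusion direction runs along the edge."""
    b = np.zeros((40, 40))
    b[:, 20:] = 1.0
    J = build_diffusion_tensor(b, smoothing_sigma=1.5, contrast_k=0.05)
    col = 20
    for row in range(10, 30):
        M = np.array([[J.j11[row, col], J.j12[row, col]], [J.j12[row, col], J.j22[row, col]]])
        w, v = np.linalg.eigh(M)
        leading = v[:, np.argmax(w)]  # (ex, ey)
        assert abs(leading[0]) < 1e-6  # no horizontal component: vertical vector
        assert abs(abs(leading[1]) - 1.0) < 1e-6


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_tensor_always_spd(seed, rng):
    img = np.random.default_rng(seed).uniform(0, 1, (24, 24))
    J = build_diffusion_tensor(img)
    assert J.j11.min() > 0
    assert (J.j11 * J.j22 - J.j12**2).min() > 0


# ----------------------------------------------------------------- solver

def test_zero_source_zero_mean_gives_zero():
    g = GradientField(gx=np.zeros((8, 8)), gy=np.zeros((8, 8)))
    v = solve_weighted_poisson(g, identity_tensor((8, 8)), SolverConfig(mean_fix="zero_mean"))
    np.testing.assert_allclose(v, 0.0, atol=1e-12)


def test_full_gradient_identity_tensor_reproduces_image(rng):
    """Discrete exactness: solving with the image's own full gradients returns it."""
    b = rng.uniform(0, 1, (32, 32))
    v = solve_weighted_poisson(
        image_gradients(b), identity_tensor((32, 32)),
        SolverConfig(mean_fix="input_mean"), target_mean=float(b.mean()),
    )
    assert np.abs(v - b).max() < 1e-6


def test_operator_symmetry_and_nullspace(rng):
    J = random_spd_tensor(rng, (10, 10))
    g = GradientField(gx=np.zeros((10, 10)), gy=np.zeros((10, 10)))
    lap, _ = _assemble(g, J)
    x, y = rng.normal(size=100), rng.normal(size=100)
    lhs, rhs_ip = x @ (lap @ y), y @ (lap @ x)
    assert abs(lhs - rhs_ip) <= 1e-10 * max(abs(lhs), 1.0)
    assert np.abs(lap @ np.ones(100)).max() <= 1e-10


def test_iterative_matches_loop_assembled_dense_solve(rng):
    """CG solution == dense direct solve built from an independent operator."""
    for _ in range(5):
        J = random_spd_tensor(rng, (12, 12))
        g = GradientField(gx=rng.normal(size=(12, 12)), gy=rng.normal(size=(12, 12)))
        v_cg = solve_weighted_poisson(g, J, SolverConfig(method="cg", tol=1e-12, mean_fix="zero_mean"))
        n = 144
        basis = np.eye(n)
        L = np.column_stack(
            [apply_weighted_laplacian_loops(basis[:, i].reshape(12, 12), J).ravel() for i in range(n)]
        )
        px = J.j11 * g.gx + J.j12 * g.gy
        py = J.j12 * g.gx + J.j22 * g.gy
        b = np.zeros((12, 12))
        b[:, :-1] -= px[:, :-1]
        b[:, 1:] += px[:, :-1]
        b[:-1, :] -= py[:-1, :]
        b[1:, :] += py[:-1, :]
        v_dense, *_ = np.linalg.lstsq(L, b.ravel(), rcond=None)
        v_dense = v_dense.reshape(12, 12)
        v_dense -= v_dense.mean()
        assert np.abs(v_cg - v_dense).max() < 1e-8


def test_direct_and_cg_paths_agree(rng):
    J = random_spd_tensor(rng, (16, 16))
    g = GradientField(gx=rng.normal(size=(16, 16)), gy=rng.normal(size=(16, 16)))
    v_dir = solve_weighted_poisson(g, J, SolverConfig(method="direct", mean_fix="zero_mean"))
    v_cg = solve_weighted_poisson(g, J, SolverConfig(method="cg", tol=1e-12, mean_fix="zero_mean"))
    assert np.abs(v_dir - v_cg).max() < 1e-8


def test_non_spd_tensor_rejected():
    g = GradientField(gx=np.zeros((6, 6)), gy=np.zeros((6, 6)))
    bad = TensorField(j11=np.ones((6, 6)), j12=np.full((6, 6), 2.0), j22=np.ones((6, 6)))
    with pytest.raises(DataError):
        solve_weighted_poisson(g, bad)


def test_nonconvergence_reports_residual(rng):
    from msmdenoise import SolverError

    J = random_spd_tensor(rng, (32, 32))
    g = GradientField(gx=rng.normal(size=(32, 32)), gy=rng.normal(size=(32, 32)))
    with pytest.raises(SolverError) as exc_info:
        solve_weighted_poisson(g, J, SolverConfig(method="cg", tol=1e-14, max_iter=2))
    assert exc_info.value.residual is not None
    assert exc_info.value.residual > 0


# ----------------------------------------------------------------- pipeline

def test_full_mask_identity_tensor_pipeline_is_identity(small_phantom):
    b = small_phantom.image.channels
    cfg = DenoiseConfig(msm_quantile=1.0, use_identity_tensor=True)
    out = denoise(b, cfg)
    assert np.abs(out - b).max() < 1e-6


def test_pipeline_deterministic(small_phantom):
    b = small_phantom.image.channels[:1]
    cfg = DenoiseConfig()
    np.testing.assert_array_equal(denoise(b, cfg), denoise(b, cfg))


def test_pipeline_shift_equivariance(small_phantom):
    """Adding a constant shifts the output by exactly that constant."""
    b = small_phantom.image.channels[0][:64, :64]
    cfg = DenoiseConfig(use_identity_tensor=True)
    base = denoise(b, cfg)[0]
    shifted = denoise(b + 0.3, cfg)[0]
    np.testing.assert_allclose(shifted - base, 0.3, atol=1e-9)


def test_pipeline_improves_psnr_on_noisy_phantom(small_phantom):
    from msmdenoise import add_noise_multichannel, psnr

    clean = small_phantom.image.channels
    noisy = add_noise_multichannel(clean, g0=0.1, sigma=0.1, seed=123)
    den = denoise(noisy, DenoiseConfig())
    for c in range(3):
        assert psnr(clean[c], den[c]) > psnr(clean[c], noisy[c])


@pytest.mark.parametrize("level", [10**-1.5, 10**-1.0])
def test_pipeline_wins_majority_of_seeds_at_high_noise(level):
    """In the shot-noise-dominated regime the pipeline beats the noisy
    input in a majority of seeded trials.  (At the low-noise end of the
    schedule the reconstruction's own error floor exceeds the noise floor
    and no improvement is expected; see the methods note.)"""
    from msmdenoise import PhantomSpec, add_noise_multichannel, generate_phantom, psnr

    wins = 0
    for seed in range(5):
        truth = generate_phantom(
            PhantomSpec(height=128, width=128, n_cells=8, n_clusters=3,
                        cell_radius_range=(10.0, 16.0), seed=seed)
        )
        clean = truth.image.channels
        noisy = add_noise_multichannel(clean, g0=level, sigma=level, seed=700 + seed)
        den = denoise(noisy, DenoiseConfig())
        p_n = np.mean([psnr(clean[c], noisy[c]) for c in range(3)])
        p_d = np.mean([psnr(clean[c], den[c]) for c in range(3)])
        wins += p_d > p_n
    assert wins >= 3


def test_channel_errors_are_identified():
    bad = np.full((1, 64, 64), np.nan)
    with pytest.raises(DataError, match="channel 0"):
        denoise(bad, DenoiseConfig())
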