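"""Jacobian, Tikhonov solver and L-curve corner against independent oracles."""

import numpy as np
import pytest

from oeseit import (
    Electrode,
    ElectrodeSet,
    PhantomSpec,
    PriorModel,
    adjacent_protocol,
    assemble_cem,
    assign_conductivity,
    build_phantom,
    compute_jacobian,
    lcurve_scan,
    reconstruct,
    reconstruct_at_corner,
    solve_forward,
)
from oeseit.phantom import ConductivityField


@pytest.fixture(scope="module")
def coarse_jacobian(small_external, protocol16):
    spec, mesh, electrodes = small_external
    sigma = assign_conductivity(mesh, spec, include_target=False)
    return spec, mesh, electrodes, sigma, compute_jacobian(
        mesh, sigma, electrodes, protocol16
    )


def smoothing_toy(n=32, noise=1e-3, seed=2):
    """Classic ill-posed discretized Gaussian smoothing kernel."""
    t = np.linspace(0, 1, n)
    K = np.exp(-((t[:, None] - t[None, :]) ** 2) / (2 * 0.05**2)) / n
    x_true = np.exp(-((t - 0.4) ** 2) / (2 * 0.08**2))
    b_clean = K @ x_true
    rng = np.random.default_rng(seed)
    b = b_clean + rng.normal(0, noise * np.abs(b_clean).max(), n)
    return K, b_clean, b


def test_jacobian_matches_central_finite_differences(coarse_jacobian, protocol16):
    """The adjoint-field sensitivity against a brute-force perturbation oracle."""
    spec, mesh, electrodes, sigma, J = coarse_jacobian
    rng = np.random.default_rng(0)
    elements = rng.choice(mesh.n_elements, 10, replace=False)
    rows = rng.choice(protocol16.n_measurements, 5, replace=False)
    checked = 0
    for k in elements:
        eps = 1e-3 * sigma.sigma[k]
        frames = []
        for sgn in (+1.0, -1.0):
            sig = sigma.sigma.copy()
            sig[k] += sgn * eps
            _, fr = solve_forward(
                assemble_cem(mesh, ConductivityField(sig, mesh), electrodes),
                protocol16,
            )
            frames.append(fr.values)
        fd = (frames[0] - frames[1]) / (2 * eps)
        for m in rows:
            if abs(fd[m]) > 1e-9 * np.abs(fd).max():
                assert abs(J.matrix[m, k] - fd[m]) / abs(fd[m]) < 1e-3
                checked += 1
    assert checked >= 30


def test_jacobian_global_conductivity_scaling(small_homogeneous, protocol16):
    """J at (a*sigma, z_c/a) equals J at (sigma, z_c) divided by a^2."""
    spec, mesh, electrodes, sigma = small_homogeneous
    J1 = compute_jacobian(mesh, sigma, electrodes, protocol16)
    a = 2.0
    sig2 = ConductivityField(a * sigma.sigma, mesh)
    els2 = ElectrodeSet(
        [Electrode(e.number, e.facets, e.center, e.z_contact / a) for e in electrodes]
    )
    J2 = compute_jacobian(mesh, sig2, els2, protocol16)
    assert np.abs(J2.matrix - J1.matrix / a**2).max() <= 1e-6 * np.abs(J1.matrix).max()


def test_uniform_increase_lowers_voltage_magnitudes(coarse_jacobian, protocol16):
    """Full-field perturbation oracle: raising sigma everywhere shrinks |V|."""
    spec, mesh, electrodes, sigma, J = coarse_jacobian
    _, f0 = solve_forward(assemble_cem(mesh, sigma, electrodes), protocol16)
    bump = 0.01 * sigma.sigma
    _, f1 = solve_forward(
        assemble_cem(mesh, ConductivityField(sigma.sigma + bump, mesh), electrodes),
        protocol16,
    )
    predicted = J.matrix @ bump
    actual = f1.values - f0.values
    # the linearisation reproduces the full-field change direction and size
    cos = predicted @ actual / (np.linalg.norm(predicted) * np.linalg.norm(actual))
    assert cos > 0.999
    # and the measured voltages shrink in magnitude on (almost) all channels
    assert np.mean(np.abs(f1.values) < np.abs(f0.values)) > 0.95


def test_tikhonov_matches_dense_normal_equations_oracle():
    rng = np.random.default_rng(1)
    A = rng.normal(size=(5, 3))
    b = rng.normal(size=5)
    lam = 0.37
    x = reconstruct(A, b, lam).delta_sigma
    oracle = np.linalg.solve(A.T @ A + lam**2 * np.eye(3), A.T @ b)
    assert np.abs(x - oracle).max() < 1e-10


def test_tikhonov_diagonal_prior_matches_dense_oracle():
    rng = np.random.default_rng(4)
    A = rng.normal(size=(6, 4))
    b = rng.normal(size=6)
    w = np.array([1.0, 2.0, 0.5, 3.0])
    lam = 0.11
    x = reconstruct(A, b, lam, PriorModel(L_dsigma=w)).delta_sigma
    oracle = np.linalg.solve(A.T @ A + lam**2 * np.diag(w**2), A.T @ b)
    assert np.abs(x - oracle).max() < 1e-10


def test_tikhonov_general_matrix_prior_matches_dense_oracle():
    rng = np.random.default_rng(5)
    A = rng.normal(size=(6, 4))
    b = rng.normal(size=6)
    L = rng.normal(size=(4, 4)) + 2 * np.eye(4)
    lam = 0.2
    x = reconstruct(A, b, lam, PriorModel(L_dsigma=L)).delta_sigma
    oracle = np.linalg.solve(A.T @ A + lam**2 * L.T @ L, A.T @ b)
    assert np.abs(x - oracle).max() < 1e-8


def test_reconstruction_linear_in_data():
    rng = np.random.default_rng(2)
    A = rng.normal(size=(8, 5))
    b = rng.normal(size=8)
    x1 = reconstruct(A, b, 0.1).delta_sigma
    x2 = reconstruct(A, 3.0 * b, 0.1).delta_sigma
    assert np.abs(x2 - 3.0 * x1).max() < 1e-10 * np.abs(x1).max()


def test_prior_dominated_limit_returns_prior_mean():
    rng = np.random.default_rng(3)
    A = rng.normal(size=(8, 5))
    b = rng.normal(size=8)
    x_star = rng.normal(size=5)
    smax = np.linalg.svd(A, compute_uv=False)[0]
    rec = reconstruct(A, b, 1e6 * smax, PriorModel(dsigma_star=x_star))
    assert np.linalg.norm(rec.delta_sigma - x_star) / np.linalg.norm(x_star) < 1e-9


def test_zero_data_reconstructs_exact_zero(coarse_jacobian):
    *_, J = coarse_jacobian
    for lam_hat in (1e-6, 1e-3, 1e-1):
        rec = reconstruct(J, np.zeros(J.matrix.shape[0]), lam_hat * J.smax)
        assert np.all(rec.delta_sigma == 0.0)
    rec, lc = reconstruct_at_corner(J, np.zeros(J.matrix.shape[0]))
    assert lc.corner_index == 0  # corner defined as grid minimum by convention
    assert np.all(rec.delta_sigma == 0.0)


def test_invalid_lambda_and_grid_rejected():
    A = np.eye(3)
    b = np.ones(3)
    with pytest.raises(ValueError):
        reconstruct(A, b, -1.0)
    with pytest.raises(ValueError):
        lcurve_scan(A, b, lambdas=np.logspace(-2, -1, 20))  # too narrow
    with pytest.raises(ValueError):
        lcurve_scan(A, b, lambdas=np.logspace(-8, -1, 5))  # too few


def test_lcurve_monotonicity_and_noisy_corner_vs_dense_oracle():
    K, b_clean, b = smoothing_toy()
    lc = lcurve_scan(K, b)
    assert np.all(np.diff(lc.residual_norms) >= -1e-14)
    assert np.all(np.diff(lc.solution_seminorms) <= 1e-14)
    # dense-SVD curvature-maximum oracle on a 50x finer lambda grid
    U, s, Vt = np.linalg.svd(K)
    beta = U.T @ b
    lams = s[0] * np.logspace(-8, -1, 2000)
    l2 = lams[:, None] ** 2
    den = s[None, :] ** 2 + l2
    rho = np.sqrt(np.sum((l2 * beta[None, :] / den) ** 2, axis=1))
    eta = np.sqrt(np.sum((s[None, :] * beta[None, :] / den) ** 2, axis=1))
    u = np.log(lams)
    x, y = np.log(rho), np.log(eta)
    dx, dy = np.gradient(x, u), np.gradient(y, u)
    ddx, ddy = np.gradient(dx, u), np.gradient(dy, u)
    kappa = (dx * ddy - dy * ddx) / (dx**2 + dy**2) ** 1.5
    interior = slice(50, -50)  # keep clear of end effects of the dense stencil
    lam_oracle = lams[interior][np.argmax(kappa[interior])]
    step = np.log(lc.lambdas[1] / lc.lambdas[0])
    assert abs(np.log(lc.lambda_corner / lam_oracle)) <= 1.5 * step
    # within one grid step of the oracle's nearest grid point
    nearest = np.argmin(np.abs(np.log(lc.lambdas) - np.log(lam_oracle)))
    assert abs(lc.corner_index - nearest) <= 1


def test_noiseless_consistent_data_corner_at_grid_minimum():
    K, b_clean, _ = smoothing_toy()
    lc = lcurve_scan(K, b_clean)
    assert lc.corner_index == 0


def test_corner_reconstruction_is_deterministic(coarse_jacobian):
    *_, J = coarse_jacobian
    rng = np.random.default_rng(9)
    dv = rng.normal(0, 1e-7, J.matrix.shape[0])
    out = [reconstruct_at_corner(J, dv, PriorModel.noser(J)) for _ in range(2)]
    assert out[0][1].corner_index == out[1][1].corner_index
    assert np.array_equal(out[0][0].delta_sigma, out[1][0].delta_sigma)


def test_small_contrast_recovery_sign_and_magnitude(small_external, protocol16):
    """End-to-end parameter recovery: a +5% sigma target reconstructs with the
    right sign, its bulk in the correct half-plane, and total strength within
    a factor of three of truth (linearisation bias acknowledged)."""
    spec, mesh, electrodes = small_external
    ref = assign_conductivity(mesh, spec, include_target=False)
    target_mask = assign_conductivity(mesh, spec, include_target=True).sigma == 0.7
    sig = ref.sigma.copy()
    sig[target_mask] += 0.05 * sig[target_mask]
    _, f_ref = solve_forward(assemble_cem(mesh, ref, electrodes), protocol16)
    _, f_tgt = solve_forward(
        assemble_cem(mesh, ConductivityField(sig, mesh), electrodes), protocol16
    )
    dv = f_tgt.values - f_ref.values
    # reconstruct on an independent coarser mesh
    ispec = PhantomSpec(arrangement="external", target_diameter=0.0)
    imesh, iels = build_phantom(ispec, 1500, seed=13)
    isigma = assign_conductivity(imesh, ispec, include_target=False)
    J = compute_jacobian(imesh, isigma, iels, protocol16)
    rec, _ = reconstruct_at_corner(J, dv, PriorModel.noser(J))
    vols = imesh.volumes()
    total = float(rec.delta_sigma @ vols)
    truth = float((0.05 * ref.sigma[target_mask]) @ mesh.volumes()[target_mask])
    assert total > 0
    assert truth / 3 < total < truth * 3
    # peak of the image lies in the target's half-plane (y < 0)
    peak = imesh.centroids()[np.argmax(rec.delta_sigma)]
    assert peak[1] < 0
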