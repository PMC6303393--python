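import numpy as np
import pytest
from scipy.integrate import solve_ivp

from rdpattern import (
    ModelKind,
    SimulationConfig,
    StateField,
    classify_outcome,
    default_alpha_grid,
    find_fixed_points,
    integrate,
    laplacian,
    make_initial_condition,
    phase_diagram,
    reaction_terms,
    select_fixed_point,
)


# ---------------------------------------------------------------- laplacian


def test_laplacian_of_constant_is_zero():
    for boundary in ("no_flux", "periodic"):
        assert np.allclose(laplacian(np.full(50, 3.7), 2.0, boundary), 0.0)
        assert np.allclose(laplacian(np.full((20, 20), 3.7), 2.0, boundary), 0.0)


def test_laplacian_periodic_sine_eigenfunction():
    """A periodic Fourier mode is an eigenfunction with eigenvalue
    -(2/dx^2)(1 - cos(k dx)), the exact discrete dispersion relation."""
    n, dx = 128, 5.0
    x = np.arange(n) * dx
    k = 2 * np.pi * 3 / (n * dx)  # 3 full periods fit the ring
    u = np.sin(k * x)
    eig = -(2.0 / dx**2) * (1.0 - np.cos(k * dx))
    np.testing.assert_allclose(laplacian(u, dx, "periodic"), eig * u, atol=1e-12)


def test_laplacian_interior_quadratic():
    """d2/dx2 of x^2 is 2 exactly for a second-order central difference."""
    n, dx = 40, 1.5
    x = np.arange(n) * dx
    lap = laplacian(x**2, dx, "no_flux")
    np.testing.assert_allclose(lap[1:-1], 2.0, atol=1e-10)


def test_laplacian_2d_separability(rng):
    a = rng.uniform(size=(30, 25))
    dx = 3.0
    full = laplacian(a, dx, "periodic")
    by_rows = np.apply_along_axis(lambda row: laplacian(row, dx, "periodic"), 1, a)
    by_cols = np.apply_along_axis(lambda col: laplacian(col, dx, "periodic"), 0, a)
    np.testing.assert_allclose(full, by_rows + by_cols, atol=1e-12)


def test_laplacian_rejects_bad_input():
    with pytest.raises(ValueError):
        laplacian(np.ones(10), -1.0)
    with pytest.raises(ValueError):
        laplacian(np.ones((2, 2, 2)), 1.0)
    with pytest.raises(ValueError):
        laplacian(np.ones(10), 1.0, "reflecting")


# ------------------------------------------------------------ configuration


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(dimensionality=3)
    with pytest.raises(ValueError):
        SimulationConfig(domain_length=95.0, dx=10.0)  # not divisible
    with pytest.raises(ValueError):
        SimulationConfig(domain_length=50.0, dx=10.0)  # fewer than 8 points
    with pytest.raises(ValueError):
        SimulationConfig(boundary="open")


def test_stability_bound_enforced(params):
    cfg = SimulationConfig(domain_length=500.0, dx=10.0, dt=1.0, duration=10.0)
    # bound = dx^2 / (2 * 1 * 56.39) = 0.8867 < 1.0
    assert cfg.stability_bound(params) == pytest.approx(100.0 / (2 * 56.39))
    init = make_initial_condition("two_pulses", cfg)
    with pytest.raises(ValueError, match="stability"):
        integrate(init, params, ModelKind.COMPETITIVE, cfg)


# ------------------------------------------------------- initial conditions


def test_initial_condition_kinds(fast_config):
    n = fast_config.n_points
    two = make_initial_condition("two_pulses", fast_config, amplitude=20.0, pulse_width=50.0)
    assert two.N_field.shape == (n,)
    assert np.count_nonzero(two.N_field) == 2 * round(50.0 / fast_config.dx)
    assert two.N_field.max() == 20.0
    np.testing.assert_array_equal(two.N_field, two.L_field)

    uni = make_initial_condition("uniform", fast_config, amplitude=3.0)
    assert np.all(uni.N_field == 3.0)

    noise = make_initial_condition("random_noise", fast_config, amplitude=2.0, seed=7)
    noise2 = make_initial_condition("random_noise", fast_config, amplitude=2.0, seed=7)
    np.testing.assert_array_equal(noise.N_field, noise2.N_field)
    assert 0 <= noise.N_field.min() and noise.N_field.max() <= 2.0

    mixed = make_initial_condition("mixed_fraction", fast_config, amplitude=5.0, fraction=0.2, seed=1)
    assert np.count_nonzero(mixed.N_field) == round(0.2 * n)

    with pytest.raises(ValueError):
        make_initial_condition("plateau", fast_config)


def test_two_pulse_placement_is_controllable(fast_config):
    a = make_initial_condition("two_pulses", fast_config, centers=(0.25, 0.75))
    b = make_initial_condition("two_pulses", fast_config, centers=(0.4, 0.6))
    assert not np.array_equal(a.N_field, b.N_field)


def test_state_field_validation():
    with pytest.raises(ValueError):
        StateField(np.ones(10), np.ones(11), 1.0)
    with pytest.raises(ValueError):
        StateField(-np.ones(10), np.ones(10), 1.0)
    with pytest.raises(ValueError):
        StateField(np.full(10, np.nan), np.ones(10), 1.0)


# ---------------------------------------------------------------- dynamics


def test_zero_state_stays_zero(params, fast_config):
    init = StateField(np.zeros(fast_config.n_points), np.zeros(fast_config.n_points), fast_config.dx)
    for kind in ModelKind:
        res = integrate(init, params, kind, fast_config)
        assert np.all(res.final.N_field == 0.0)
        assert np.all(res.final.L_field == 0.0)


def test_uniform_state_at_fixed_point_is_stationary(turing_point_params):
    """A homogeneous field at the high fixed point must stay put (the
    instability needs spatial structure to grow from)."""
    p = turing_point_params
    fp = select_fixed_point(find_fixed_points(p, ModelKind.COMPETITIVE))
    cfg = SimulationConfig(domain_length=500.0, dx=10.0, dt=0.4, duration=400.0)  # 1000 steps
    init = StateField(
        np.full(cfg.n_points, fp.N_star), np.full(cfg.n_points, fp.L_star), cfg.dx
    )
    res = integrate(init, p, ModelKind.COMPETITIVE, cfg)
    assert np.max(np.abs(res.final.N_field - fp.N_star)) < 1e-6
    assert np.max(np.abs(res.final.L_field - fp.L_star)) < 1e-6


def test_integrator_matches_numpy_reference(params, fast_config):
    """The compiled kernel must agree with a plain numpy Euler loop to
    rounding error, for both boundary modes and both models."""
    for boundary in ("no_flux", "periodic"):
        cfg = SimulationConfig(
            domain_length=500.0, dx=10.0, dt=0.4, duration=40.0, boundary=boundary
        )
        init = make_initial_condition("random_noise", cfg, amplitude=10.0, seed=3)
        for kind in ModelKind:
            N = init.N_field.copy()
            L = init.L_field.copy()
            for _ in range(cfg.n_steps):
                f, g = reaction_terms(N, L, params, kind)
                N = N + cfg.dt * (f + params.D_N * laplacian(N, cfg.dx, boundary))
                L = L + cfg.dt * (g + params.D_L * laplacian(L, cfg.dx, boundary))
                N = np.clip(N, 0.0, None)
                L = np.clip(L, 0.0, None)
            res = integrate(init, params, kind, cfg)
            np.testing.assert_allclose(res.final.N_field, N, rtol=1e-12, atol=1e-14)
            np.testing.assert_allclose(res.final.L_field, L, rtol=1e-12, atol=1e-14)


def test_integrator_matches_numpy_reference_2d(params):
    cfg = SimulationConfig(
        dimensionality=2, domain_length=200.0, dx=10.0, dt=0.2, duration=20.0
    )
    init = make_initial_condition("random_noise", cfg, amplitude=10.0, seed=5)
    N = init.N_field.copy()
    L = init.L_field.copy()
    for _ in range(cfg.n_steps):
        f, g = reaction_terms(N, L, params, ModelKind.COMPETITIVE_PLUS_DIRECT)
        N = np.clip(N + cfg.dt * (f + params.D_N * laplacian(N, cfg.dx)), 0.0, None)
        L = np.clip(L + cfg.dt * (g + params.D_L * laplacian(L, cfg.dx)), 0.0, None)
    res = integrate(init, params, ModelKind.COMPETITIVE_PLUS_DIRECT, cfg)
    np.testing.assert_allclose(res.final.N_field, N, rtol=1e-12, atol=1e-14)


def test_zero_diffusion_limit_matches_ode_solver(params):
    """With D -> 0 each grid point is an independent ODE; forward Euler with a
    small dt must track a high-accuracy adaptive solution."""
    p = params.replace(D_N=1e-12, D_L=1e-12)
    cfg = SimulationConfig(domain_length=80.0, dx=10.0, dt=0.05, duration=2000.0)
    N0, L0 = 5.0, 1.0
    init = StateField(np.full(8, N0), np.full(8, L0), cfg.dx)
    res = integrate(init, p, ModelKind.COMPETITIVE, cfg)

    def rhs(_t, y):
        f, g = reaction_terms(y[0], y[1], p, ModelKind.COMPETITIVE)
        return [f, g]

    sol = solve_ivp(rhs, (0, cfg.duration), [N0, L0], rtol=1e-10, atol=1e-12)
    assert res.final.N_field[0] == pytest.approx(sol.y[0, -1], rel=1e-3)
    assert res.final.L_field[0] == pytest.approx(sol.y[1, -1], rel=1e-3)


def test_time_step_refinement_converges(turing_point_params):
    """Forward Euler is first order: against a fine-dt reference, the error
    halves when dt halves, and the default dt is already within 1%."""
    p = turing_point_params
    init = make_initial_condition(
        "two_pulses", SimulationConfig(domain_length=500.0, dx=10.0, dt=0.4, duration=2000.0)
    )

    def run(dt):
        cfg = SimulationConfig(domain_length=500.0, dx=10.0, dt=dt, duration=2000.0)
        return integrate(init, p, ModelKind.COMPETITIVE, cfg).final.N_field

    ref = run(0.0125)
    e1 = np.max(np.abs(run(0.4) - ref))
    e2 = np.max(np.abs(run(0.2) - ref))
    assert e1 / np.max(ref) < 0.01
    assert 1.7 < e1 / e2 < 2.5  # first-order error reduction


def test_integrate_does_not_mutate_initial_state(params, fast_config):
    """The kernel's internal buffer swap must never leak into the caller's
    arrays (regression: a second run from the same state gave different
    results because the first run overwrote it)."""
    init = make_initial_condition("two_pulses", fast_config)
    before_N = init.N_field.copy()
    before_L = init.L_field.copy()
    first = integrate(init, params, ModelKind.COMPETITIVE, fast_config)
    np.testing.assert_array_equal(init.N_field, before_N)
    np.testing.assert_array_equal(init.L_field, before_L)
    second = integrate(init, params, ModelKind.COMPETITIVE, fast_config)
    np.testing.assert_array_equal(first.final.N_field, second.final.N_field)


def test_snapshots_and_clamping(params, fast_config):
    cfg = SimulationConfig(domain_length=500.0, dx=10.0, dt=0.4, duration=40.0, record_every=8.0)
    init = make_initial_condition("two_pulses", cfg)
    res = integrate(init, params, ModelKind.COMPETITIVE, cfg)
    np.testing.assert_allclose(res.times, [0.0, 8.0, 16.0, 24.0, 32.0, 40.0])
    assert res.max_clamped < 1e-9  # clamping only absorbs rounding error


def test_shape_mismatch_rejected(params, fast_config):
    init = StateField(np.zeros(13), np.zeros(13), fast_config.dx)
    with pytest.raises(ValueError, match="shape"):
        integrate(init, params, ModelKind.COMPETITIVE, fast_config)


# ----------------------------------------------------------- classification


def test_classification_rule():
    dx = 10.0
    flat_high = StateField(np.full(10, 5.0), np.zeros(10), dx)
    assert classify_outcome(flat_high) == "high"
    dead = StateField(np.full(10, 0.005), np.zeros(10), dx)
    assert classify_outcome(dead) == "low"
    patterned = StateField(np.array([0.0, 5.0] * 5), np.zeros(10), dx)
    assert classify_outcome(patterned) == "pattern"
    # max must clear the floor even if the ratio test passes
    faint = StateField(np.array([0.0, 0.005] * 5), np.zeros(10), dx)
    assert classify_outcome(faint) == "low"


def test_default_alpha_grid_is_log_spaced():
    g = default_alpha_grid(9)
    assert g[0] == 0.25 and g[-1] == 8.0
    np.testing.assert_allclose(np.diff(np.log(g)), np.log(g[1] / g[0]), rtol=1e-12)


def test_phase_diagram_runs_and_labels(params):
    cfg = SimulationConfig(domain_length=500.0, dx=10.0, dt=0.4, duration=2000.0)
    pd = phase_diagram([0.8], [4.0], params, ModelKind.COMPETITIVE, cfg)
    assert pd.outcomes.shape == (1, 1)
    assert pd.outcomes[0, 0] in {"pattern", "high", "low"}
    assert pd.pattern_mask().shape == (1, 1)
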