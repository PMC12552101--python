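"""Simulator correctness: ODE solutions, truth invariants, perturbations."""

import numpy as np
import pytest
from scipy import stats

import velotime as vt
from velotime.errors import ConfigError, DataError
from velotime.simulate import (_rk4_integrate, circular_limit_cycle,
                               circular_params, modality_profile_noise_free)


def _closed_form_US(alpha, beta, gamma, U0, S0, t):
    """Analytic solution of dU/dt = a - bU, dS/dt = bU - gS (constant a)."""
    t = np.asarray(t, float)
    Uss = alpha / beta
    U = Uss + (U0 - Uss) * np.exp(-beta * t)
    Sss = alpha / gamma
    cb = beta * (U0 - Uss) / (gamma - beta)
    cg = S0 - Sss - cb
    S = Sss + cb * np.exp(-beta * t) + cg * np.exp(-gamma * t)
    return U, S


def test_rk4_matches_analytic_solution():
    alpha, beta, gamma = 2.0, 1.0, 0.5
    U0, S0 = 0.3, 0.1
    tg, Ug, Sg = _rk4_integrate(lambda t: np.array([[alpha]]),
                                np.array([beta]), np.array([gamma]),
                                [U0], [S0], 0.0, 1.0)
    U_exact, S_exact = _closed_form_US(alpha, beta, gamma, U0, S0, tg)
    assert np.max(np.abs(Ug[:, 0] - U_exact)) < 1e-4
    assert np.max(np.abs(Sg[:, 0] - S_exact)) < 1e-4


def test_steady_state_initial_condition_stays_fixed():
    alpha, beta, gamma = 1.5, 1.2, 0.8
    U0 = alpha / beta
    S0 = beta * U0 / gamma
    _, Ug, Sg = _rk4_integrate(lambda t: np.array([[alpha]]),
                               np.array([beta]), np.array([gamma]),
                               [U0], [S0], 0.0, 1.0)
    np.testing.assert_allclose(Ug, U0, rtol=1e-10)
    np.testing.assert_allclose(Sg, S0, rtol=1e-10)


def test_linear_simulation_is_deterministic():
    cfg = vt.SimulationConfig(n_cells=40, n_genes=10, seed=7)
    a1, t1 = vt.simulate_linear(cfg)
    a2, t2 = vt.simulate_linear(cfg)
    np.testing.assert_array_equal(a1.S, a2.S)
    np.testing.assert_array_equal(a1.U, a2.U)
    np.testing.assert_array_equal(t1.Vs_true, t2.Vs_true)


def test_truth_velocities_recomputable_from_clean_expression(small_linear):
    _, truth = small_linear
    np.testing.assert_array_equal(
        truth.Vu_true, truth.alpha_true - truth.beta_true * truth.U_clean)
    np.testing.assert_array_equal(
        truth.Vs_true,
        truth.beta_true * truth.U_clean - truth.gamma_true * truth.S_clean)


def test_noise_free_expression_satisfies_ode_residual():
    """Finite-difference dS/dt along true time matches beta*U - gamma*S."""
    cfg = vt.SimulationConfig(n_cells=400, n_genes=5, noise_sd=0.0, seed=3)
    ds, truth = vt.simulate_linear(cfg)
    o = np.argsort(truth.t_true)
    t = truth.t_true[o]
    S, U = truth.S_clean[o], truth.U_clean[o]
    mid_rhs = 0.5 * (truth.Vs_true[o][1:] + truth.Vs_true[o][:-1])
    dt = np.diff(t)[:, None]
    keep = (dt > 1e-4).ravel()
    fd = (S[1:] - S[:-1]) / dt
    assert np.median(np.abs(fd[keep] - mid_rhs[keep])) < 0.05


def test_noise_free_dataset_equals_clean_truth():
    cfg = vt.SimulationConfig(n_cells=30, n_genes=8, noise_sd=0.0, seed=2)
    ds, truth = vt.simulate_linear(cfg)
    np.testing.assert_array_equal(ds.U, truth.U_clean)
    np.testing.assert_array_equal(ds.S, truth.S_clean)


# ------------------------------------------------------------- circular
def test_circular_limit_cycle_closes():
    cfg = vt.SimulationConfig(n_cells=10, n_genes=20, topology="circular",
                              seed=3)
    _, Ug, Sg = circular_limit_cycle(cfg)
    scale = np.abs(Ug).max(axis=0) + 1e-12
    assert np.max(np.abs(Ug[0] - Ug[-1]) / scale) < 0.02
    scale_s = np.abs(Sg).max(axis=0) + 1e-12
    assert np.max(np.abs(Sg[0] - Sg[-1]) / scale_s) < 0.02


def test_circular_simulation_deterministic_and_modal():
    cfg = vt.SimulationConfig(n_cells=50, n_genes=10, topology="circular",
                              seed=5, with_modality=True, noise_sd=0.0)
    ds1, tr1 = vt.simulate_circular(cfg)
    ds2, _ = vt.simulate_circular(cfg)
    np.testing.assert_array_equal(ds1.S, ds2.S)
    assert ds1.O is not None and ds1.O.shape == (50, 10)


def test_modality_plateaus_inside_induction_arc():
    cfg = vt.SimulationConfig(n_cells=300, n_genes=6, topology="circular",
                              seed=9, with_modality=True, noise_sd=0.0)
    params = circular_params(cfg)
    O = modality_profile_noise_free(cfg)
    t = params["t_true"]
    lead, edge = 0.05, 0.02
    for g in range(cfg.n_genes):
        u = np.mod(t - (params["on"][g] - lead), 1.0)
        plateau = (u > 5 * edge) & (u < params["arc"][g] - 5 * edge)
        if plateau.any():
            assert np.all(O[plateau, g] > 0.9)
        outside = (u > params["arc"][g] + 5 * edge) & (u < 1 - 5 * edge)
        if outside.any():
            assert np.all(O[outside, g] < 0.1)


# ---------------------------------------------------------- perturbations
def test_thinning_identity_at_keep_prob_one(small_linear):
    ds, _ = small_linear
    out = vt.binomial_thinning(ds, 1.0, seed=0)
    np.testing.assert_array_equal(out.S, np.rint(ds.S))
    np.testing.assert_array_equal(out.U, np.rint(ds.U))


def test_thinning_mean_matches_binomial_expectation():
    cfg = vt.SimulationConfig(n_cells=500, n_genes=100, seed=4)
    ds, _ = vt.simulate_linear(cfg)
    keep = 0.3
    out = vt.binomial_thinning(ds, keep, seed=1)
    x = np.rint(ds.S)
    expected = keep * x.mean()
    se = np.sqrt((x * keep * (1 - keep)).sum()) / x.size
    assert abs(out.S.mean() - expected) < 3 * se


def test_thinning_deterministic_and_validated(small_linear):
    ds, _ = small_linear
    a = vt.binomial_thinning(ds, 0.5, seed=3)
    b = vt.binomial_thinning(ds, 0.5, seed=3)
    np.testing.assert_array_equal(a.S, b.S)
    with pytest.raises(ConfigError):
        vt.binomial_thinning(ds, 0.0, seed=0)
    with pytest.raises(ConfigError):
        vt.binomial_thinning(ds, 1.5, seed=0)


def test_downsampling_totals_are_exact(small_linear):
    ds, _ = small_linear
    frac = 0.4
    out = vt.downsample_depth(ds, frac, seed=0)
    tot_in = (np.rint(ds.S) + np.rint(ds.U)).sum(axis=1)
    tot_out = (out.S + out.U).sum(axis=1)
    np.testing.assert_array_equal(tot_out, np.floor(frac * tot_in))
    ident = vt.downsample_depth(ds, 1.0, seed=0)
    np.testing.assert_array_equal(ident.S, np.rint(ds.S))


def test_downsampling_preserves_composition():
    """Multivariate hypergeometric draws keep gene proportions (chi-square
    goodness of fit on pooled draws from a 1-cell, 10-gene toy)."""
    colors = np.array([50, 10, 200, 5, 80, 40, 30, 100, 15, 70])
    nsample = int(0.5 * colors.sum())
    rng = np.random.default_rng(0)
    draws = rng.multivariate_hypergeometric(colors, nsample, size=100_000)
    pooled = draws.sum(axis=0)
    expected = pooled.sum() * colors / colors.sum()
    p = stats.chisquare(pooled, expected).pvalue
    assert p > 0.01


def test_remove_cell_type_counts_and_errors(small_linear):
    ds, _ = small_linear
    label = ds.cell_labels[0]
    k = ds.cell_labels.count(label)
    out = vt.remove_cell_type(ds, label)
    assert out.n_cells == ds.n_cells - k
    assert label not in out.cell_labels
    # the remaining cells are exactly the non-label ones, order preserved
    kept = [c for c, l in zip(ds.cell_ids, ds.cell_labels) if l != label]
    assert out.cell_ids == kept
    with pytest.raises(DataError, match="label-not-found"):
        vt.remove_cell_type(ds, "no-such-label")


def test_config_validation():
    with pytest.raises(ConfigError):
        vt.SimulationConfig(n_cells=1, n_genes=5)
    with pytest.raises(ConfigError):
        vt.SimulationConfig(n_cells=5, n_genes=0)
    with pytest.raises(ConfigError):
        vt.SimulationConfig(n_cells=5, n_genes=5, topology="spiral")
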