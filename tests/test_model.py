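"""Model components: initialization, encoders, latent ODE, rates, velocity."""

import numpy as np
import pytest

import velotime as vt
from velotime._autodiff import Tensor
from velotime.errors import ConfigError, DataError


@pytest.fixture(scope="module")
def state():
    return vt.init_model(vt.ModelConfig(latent_dim=4, hidden_dim=16, seed=0),
                         n_genes=5, n_features_total=10)


def test_rate_initialization_is_lognormal():
    big = vt.init_model(vt.ModelConfig(latent_dim=2, hidden_dim=4, seed=1),
                        n_genes=20_000, n_features_total=40_000)
    beta = big.beta
    # log-normal(0, 0.1): median e^0 = 1
    assert abs(np.median(beta) - 1.0) < 0.01
    inside = np.mean((beta >= np.exp(-0.196)) & (beta <= np.exp(0.196)))
    assert 0.94 < inside < 0.96
    assert np.all(beta > 0) and np.all(big.gamma > 0)


def test_initialization_deterministic_under_seed():
    cfg = vt.ModelConfig(seed=11)
    a = vt.init_model(cfg, 10, 20)
    b = vt.init_model(cfg, 10, 20)
    for pa, pb in zip(a.parameters(), b.parameters()):
        np.testing.assert_array_equal(pa.data, pb.data)


def test_encode_outputs_and_sampling(state, rng):
    X = rng.uniform(0, 2, size=(6, 10))
    lat = vt.encode(state, X, sample=False)
    np.testing.assert_array_equal(lat.Z.data, lat.mu.data)
    assert np.all((lat.t.data > 0) & (lat.t.data < 1))
    lat_s = vt.encode(state, X, sample=True, rng=np.random.default_rng(0))
    assert not np.array_equal(lat_s.Z.data, lat_s.mu.data)
    # identical input rows give identical outputs
    X2 = np.tile(X[0], (3, 1))
    lat2 = vt.encode(state, X2, sample=False)
    assert np.ptp(lat2.mu.data, axis=0).max() == 0
    assert np.ptp(lat2.t.data) == 0
    with pytest.raises(DataError, match="shape-mismatch"):
        vt.encode(state, X[:, :7])


def test_time_encoder_shares_first_layer_with_state_encoder(state, rng):
    X = rng.uniform(0, 2, size=(4, 10))
    t_before = vt.encode(state, X).t.data.copy()
    mu_before = vt.encode(state, X).mu.data.copy()
    old = state.enc_shared.W.data.copy()
    state.enc_shared.W.data = old + 0.5
    try:
        assert not np.array_equal(vt.encode(state, X).t.data, t_before)
        assert not np.array_equal(vt.encode(state, X).mu.data, mu_before)
    finally:
        state.enc_shared.W.data = old


def test_latent_ode_zero_drift_is_constant(state):
    # zero the drift net's output layer: f_ode == 0
    saved = [(state.fode.l2.W.data.copy(), state.fode.l2.b.data.copy())]
    state.fode.l2.W.data = np.zeros_like(state.fode.l2.W.data)
    state.fode.l2.b.data = np.zeros_like(state.fode.l2.b.data)
    try:
        z0 = Tensor(np.array([1.0, -1.0, 0.5, 2.0]))
        out = vt.integrate_latent(state, z0, np.linspace(0, 1, 7))
        np.testing.assert_array_equal(out.data,
                                      np.tile(z0.data, (7, 1)))
    finally:
        state.fode.l2.W.data, state.fode.l2.b.data = saved[0]


def test_latent_ode_constant_drift_is_exact(state):
    """With f_ode frozen to a constant c, Euler (and RK4) integrate
    exactly: Z(t_k) = Z0 + c (t_k - t_0)."""
    saved_W = state.fode.l1.W.data.copy()
    saved_b = state.fode.l1.b.data.copy()
    c = state.fode.l2.b.data.copy()
    state.fode.l1.W.data = np.zeros_like(saved_W)
    state.fode.l1.b.data = np.zeros_like(saved_b)
    try:
        z0 = Tensor(np.zeros(4))
        times = np.array([0.2, 0.3, 0.55, 0.55, 0.9])
        out = vt.integrate_latent(state, z0, times)
        expected = (times - times[0])[:, None] * c
        np.testing.assert_allclose(out.data, expected, atol=1e-12)
        # duplicate times give identical consecutive rows
        np.testing.assert_array_equal(out.data[2], out.data[3])
        state.cfg.ode_solver = "rk4"
        out_rk = vt.integrate_latent(state, z0, times)
        np.testing.assert_allclose(out_rk.data, expected, atol=1e-12)
    finally:
        state.cfg.ode_solver = "euler"
        state.fode.l1.W.data = saved_W
        state.fode.l1.b.data = saved_b


def test_latent_ode_rejects_unsorted_times(state):
    with pytest.raises(DataError, match="times-not-sorted"):
        vt.integrate_latent(state, Tensor(np.zeros(4)),
                            np.array([0.5, 0.2, 0.8]))


def test_rk4_close_to_euler_on_smooth_drift(state):
    z0 = Tensor(np.array([0.1, 0.2, -0.1, 0.05]))
    times = np.linspace(0, 0.5, 50)
    out_e = vt.integrate_latent(state, z0, times).data
    state.cfg.ode_solver = "rk4"
    try:
        out_r = vt.integrate_latent(state, z0, times).data
    finally:
        state.cfg.ode_solver = "euler"
    assert np.max(np.abs(out_e - out_r)) < 0.05


def test_decode_contract(state, rng):
    Z = rng.normal(size=(3, 4))
    out = vt.decode(state, Z)
    assert out.data.shape == (3, 10)
    Z2 = np.tile(Z[0], (2, 1))
    out2 = vt.decode(state, Z2)
    np.testing.assert_array_equal(out2.data[0], out2.data[1])
    # the same decoder object serves both latent paths
    np.testing.assert_array_equal(vt.decode(state, Z).data, out.data)
    with pytest.raises(DataError):
        vt.decode(state, rng.normal(size=(3, 7)))


def test_transcription_rate_nonnegative_by_default(state, rng):
    Zt = rng.normal(scale=3.0, size=(8, 4))
    alpha = vt.transcription_rate(state, Zt)
    assert alpha.data.shape == (8, 5)
    assert np.all(alpha.data > 0)
    lin_state = vt.init_model(
        vt.ModelConfig(latent_dim=4, hidden_dim=16, seed=0,
                       alpha_nonneg=False), 5, 10)
    raw = vt.transcription_rate(lin_state, Zt)
    assert np.any(raw.data < 0)


def test_compute_velocity_examples():
    one = np.ones((1, 1))
    est = vt.compute_velocity(U=one, S=one, alpha=2 * one,
                              beta=np.array([1.0]), gamma=np.array([1.0]))
    assert est.Vu[0, 0] == 1.0 and est.Vs[0, 0] == 0.0
    # steady state alpha = beta U, beta U = gamma S
    est0 = vt.compute_velocity(U=one, S=2 * one, alpha=one,
                               beta=np.array([1.0]), gamma=np.array([0.5]))
    assert est0.Vu[0, 0] == 0.0 and est0.Vs[0, 0] == 0.0
    # doubling all rates doubles both velocities at fixed (U, S)
    U = np.array([[1.0, 2.0]])
    S = np.array([[0.5, 1.5]])
    al = np.array([[2.0, 3.0]])
    b = np.array([0.7, 1.3])
    g = np.array([0.9, 1.1])
    v1 = vt.compute_velocity(U, S, al, b, g)
    v2 = vt.compute_velocity(U, S, 2 * al, 2 * b, 2 * g)
    np.testing.assert_allclose(v2.Vu, 2 * np.asarray(v1.Vu))
    np.testing.assert_allclose(v2.Vs, 2 * np.asarray(v1.Vs))
    with pytest.raises(DataError, match="invalid-rates"):
        vt.compute_velocity(U, S, al, -b, g)


def test_outputs_finite_for_finite_inputs(state, rng):
    X = rng.uniform(0, 100, size=(5, 10))
    lat = vt.encode(state, X)
    Zt = vt.integrate_latent(state, lat.mu.take([0]),
                             np.sort(lat.t.data))
    for arr in (lat.mu.data, lat.log_sigma2.data, lat.t.data, Zt.data,
                vt.decode(state, lat.mu).data,
                vt.transcription_rate(state, Zt).data):
        assert np.all(np.isfinite(arr))


def test_checkpoint_round_trip(tmp_path, small_fit):
    dsp, _, res = small_fit
    path = str(tmp_path / "ckpt.npz")
    res.model.save(path)
    loaded = vt.ModelState.load(path)
    for pa, pb in zip(res.model.parameters(), loaded.parameters()):
        np.testing.assert_array_equal(pa.data, pb.data)
    t1, v1, _ = vt.predict(res.model, dsp)
    t2, v2, _ = vt.predict(loaded, dsp)
    np.testing.assert_array_equal(t1, t2)
    np.testing.assert_array_equal(np.asarray(v1.Vs), np.asarray(v2.Vs))


def test_model_config_validation():
    with pytest.raises(ConfigError):
        vt.ModelConfig(latent_dim=1)
    with pytest.raises(ConfigError):
        vt.ModelConfig(latent_dim=20, hidden_dim=10)
    with pytest.raises(ConfigError):
        vt.ModelConfig(ode_solver="dopri5")
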