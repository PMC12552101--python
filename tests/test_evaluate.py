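"""Benchmark metrics: correlations, circular scoring, boundary metrics."""

import numpy as np
import pytest
from scipy import stats

import velotime as vt
from velotime.errors import DataError
from velotime.evaluate import EvaluationReport, boundary_metrics


def test_pearson_pseudotime_basics(rng):
    t = rng.uniform(size=20)
    assert vt.pearson_pseudotime(t, t) == pytest.approx(1.0)
    assert vt.pearson_pseudotime(1 - t, t) == pytest.approx(-1.0)
    with pytest.raises(DataError, match="degenerate"):
        vt.pearson_pseudotime(np.ones(5), t[:5])


def test_pearson_agrees_with_independent_implementation(rng):
    a = rng.normal(size=5)
    b = rng.normal(size=5)
    assert vt.pearson_pseudotime(a, b) == pytest.approx(
        stats.pearsonr(a, b).statistic, abs=1e-12)


def test_circular_cross_correlation_shift_and_reflection(rng):
    t = rng.uniform(size=10)
    assert vt.circular_cross_correlation(t, t) == pytest.approx(1.0)
    shifted = np.mod(t + 0.3, 1.0)
    assert vt.circular_cross_correlation(shifted, t) == pytest.approx(
        1.0, abs=1e-9)
    reflected = np.mod(-t + 0.7, 1.0)
    assert vt.circular_cross_correlation(reflected, t) == pytest.approx(
        1.0, abs=1e-9)


def test_circular_dominates_plain_pearson(rng):
    t_true = rng.uniform(size=50)
    t_est = np.mod(t_true + rng.normal(scale=0.05, size=50), 1.0)
    assert (vt.circular_cross_correlation(t_est, t_true)
            >= vt.pearson_pseudotime(t_est, t_true) - 1e-12)


def test_velocity_correlation_affine_invariance(rng):
    V = rng.normal(size=(30, 50))
    assert vt.velocity_correlation(V, V) == pytest.approx(1.0)
    assert vt.velocity_correlation(2 * V + 1, V) == pytest.approx(1.0)


def test_velocity_correlation_null_is_centered(rng):
    n, p = 40, 200
    V = rng.normal(size=(n, p))
    shuffled = np.array([rng.permutation(row) for row in V])
    val = vt.velocity_correlation(shuffled, V)
    assert abs(val) < 3 / np.sqrt(p * n)


def test_stability_cosine_cases(rng):
    V = rng.normal(size=(10, 6))
    np.testing.assert_allclose(vt.stability_cosine(V, V), 1.0)
    np.testing.assert_allclose(vt.stability_cosine(V, -V), -1.0)
    a = np.array([[1.0, 0.0]])
    b = np.array([[0.0, 1.0]])
    assert vt.stability_cosine(a, b)[0] == 0.0
    with pytest.warns(UserWarning, match="zero-velocity"):
        out = vt.stability_cosine(np.zeros((2, 3)), np.ones((2, 3)))
    np.testing.assert_array_equal(out, 0.0)


# ------------------------------------------------------- boundary metrics
def _boundary_toy():
    """One 'A' cell at the origin; its single 'B' neighbor at (1,0);
    two 'C' neighbors on the orthogonal axis."""
    S = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
    labels = ["A", "B", "C", "C"]
    Vs = np.zeros((4, 2))
    Vs[0] = [1.0, 0.0]  # exactly toward the B neighbor
    return S, labels, Vs


def test_cbdir2_and_transcosine_exact_on_toys():
    S, labels, Vs = _boundary_toy()
    _, cb2, tc, _ = boundary_metrics(Vs, S, None, labels, [("A", "B")],
                                     knn_k=3)
    assert cb2 == pytest.approx(1.0)
    assert tc == pytest.approx(1.0)
    _, cb2n, tcn, _ = boundary_metrics(-Vs, S, None, labels, [("A", "B")],
                                       knn_k=3)
    assert cb2n == pytest.approx(-1.0)
    assert tcn == pytest.approx(-1.0)


def test_direction_metrics_antisymmetric_under_negation(rng):
    n = 30
    S = rng.uniform(size=(n, 4))
    labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    Vs = rng.normal(size=(n, 4))
    _, cb2, tc, _ = boundary_metrics(Vs, S, None, labels, [("A", "B")],
                                     knn_k=5)
    _, cb2n, tcn, _ = boundary_metrics(-Vs, S, None, labels, [("A", "B")],
                                       knn_k=5)
    assert cb2n == pytest.approx(-cb2, abs=1e-12)
    assert tcn == pytest.approx(-tc, abs=1e-12)


def test_cbdir_uses_embedding_projection(rng):
    S, labels, Vs = _boundary_toy()
    emb = S[:, :2].copy()
    cb, _, _, _ = boundary_metrics(Vs, S, emb, labels, [("A", "B")], knn_k=3)
    cbn, _, _, _ = boundary_metrics(-Vs, S, emb, labels, [("A", "B")],
                                    knn_k=3)
    assert cb > 0 > cbn


def test_lenacc_perfect_on_proportional_norms(rng):
    n, p = 25, 3
    base = np.linspace(0, 10, n)[:, None] * np.ones(p)
    S = base + 0.001 * rng.uniform(size=(n, p))
    labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    direction = np.ones(p) / np.sqrt(p)
    # velocity norm proportional to the forward displacement norm
    Vs = np.tile(direction, (n, 1))
    _, _, _, la0 = boundary_metrics(Vs, S, None, labels, [("A", "B")],
                                    knn_k=4)
    from velotime.data_io import knn_indices
    nbrs = knn_indices(S, 5)[:, 1:]
    norms = np.empty(n)
    for i in range(n):
        disp = S[nbrs[i]] - S[i]
        fwd = disp[disp @ direction > 0]
        fwd = fwd if len(fwd) else disp
        norms[i] = np.linalg.norm(fwd, axis=1).mean()
    Vs_scaled = direction[None, :] * norms[:, None]
    _, _, _, la = boundary_metrics(Vs_scaled, S, None, labels, [("A", "B")],
                                   knn_k=4)
    assert la == pytest.approx(1.0, abs=1e-9)
    # LenAcc invariant under positive rescaling of the whole field
    _, _, _, la2 = boundary_metrics(3.7 * Vs_scaled, S, None, labels,
                                    [("A", "B")], knn_k=4)
    assert la2 == pytest.approx(la, abs=1e-12)


def test_boundary_metrics_error_and_skip(rng):
    S = rng.uniform(size=(10, 3))
    labels = ["A"] * 10
    Vs = rng.normal(size=(10, 3))
    with pytest.warns(UserWarning, match="no boundary cells"):
        with pytest.raises(DataError, match="no-boundaries"):
            boundary_metrics(Vs, S, None, labels, [("A", "B")], knn_k=3)


def test_metrics_invariant_to_consistent_reordering(rng):
    n = 30
    S = rng.uniform(size=(n, 4))
    labels = np.array(["A"] * 15 + ["B"] * 15)
    Vs = rng.normal(size=(n, 4))
    ref = boundary_metrics(Vs, S, None, list(labels), [("A", "B")], knn_k=5)
    perm = rng.permutation(n)
    out = boundary_metrics(Vs[perm], S[perm], None, list(labels[perm]),
                           [("A", "B")], knn_k=5)
    np.testing.assert_allclose(out, ref, atol=1e-9)


def test_report_serialization_round_trip(small_fit, small_linear):
    dsp, truth, res = small_fit
    report = vt.run_benchmark(dsp, truth, res, topology="linear")
    back = EvaluationReport.from_json(report.to_json())
    assert back == report
    assert -1 <= report.velocity_corr <= 1


def test_perfect_estimates_score_one(small_linear):
    ds, truth = small_linear
    from velotime.model import VelocityEstimate
    from velotime.train import FitResult

    perfect = FitResult(model=None, t=truth.t_true.copy(),
                        t_raw=np.zeros_like(truth.t_true),
                        velocity=VelocityEstimate(alpha=truth.alpha_true,
                                                  Vu=truth.Vu_true,
                                                  Vs=truth.Vs_true),
                        Zt=None, flipped=False, retrained=False,
                        l_pearson=0.0, vpt_corr=0.0)
    report = vt.run_benchmark(ds, truth, perfect, topology="linear")
    assert report.pearson_t == pytest.approx(1.0)
    assert report.velocity_corr == pytest.approx(1.0)


def test_random_velocity_scores_near_zero(small_linear, rng):
    ds, truth = small_linear
    rand = rng.normal(size=truth.Vs_true.shape)
    val = vt.velocity_correlation(rand, truth.Vs_true)
    assert abs(val) < 0.2
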