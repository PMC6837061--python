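"""Bayesian engine: log posterior, MAP/dropout training, SVGD, decomposition."""

import numpy as np
import pytest

from molbayes.bayes import (
    DropoutConfig,
    LinearModel,
    Prior,
    SVGDConfig,
    TrainConfig,
    decompose,
    log_posterior,
    predict_dropout,
    predict_ensemble,
    svgd_phi,
    train_dropout,
    train_map,
    train_svgd,
)
from molbayes.synthetic import make_conjugate_task


def test_log_posterior_hand_computed_two_points():
    """Closed form evaluated by hand for two residuals and variances.

    Residuals r = (0.5, -1.0), variances s2 = (2.0, 0.5), flat prior:
    data term = -[0.25/4 + 0.5*ln 2] - [1.0/1.0 + 0.5*ln 0.5]
              = -0.0625 - 0.5*ln 2 - 1.0 + 0.5*ln 2 = -1.0625.
    """
    X = np.eye(2)
    w = np.array([1.0, 2.0, np.log(2.0), np.log(0.5)])
    model = LinearModel(2, heteroscedastic=True)
    y = np.array([1.5, 1.0])  # residuals 0.5, -1.0
    lp = log_posterior(model, w, X, y, Prior(scale=np.inf))
    assert lp == pytest.approx(-1.0625, abs=1e-12)


def test_log_posterior_reduces_to_mse_with_fixed_unit_variance():
    rng = np.random.default_rng(0)
    model = LinearModel(3)
    X = rng.normal(size=(8, 3))
    y = rng.normal(size=8)
    w = rng.normal(size=3)
    lp = log_posterior(model, w, X, y, Prior(np.inf), fixed_variance=1.0)
    r = y - X @ w
    assert lp == pytest.approx(-0.5 * np.sum(r**2), rel=1e-12)
    # perfect predictions, unit variance, flat prior -> data term 0
    y_perfect = X @ w
    assert log_posterior(model, w, X, y_perfect, Prior(np.inf), fixed_variance=1.0) == 0.0


def test_train_map_matches_ridge_closed_form():
    """Gaussian prior + fixed noise => the MAP fit is ridge regression."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, 3))
    w_true = np.array([1.0, -2.0, 0.5])
    y = X @ w_true + 0.1 * rng.normal(size=40)
    prior = Prior(scale=1.0)
    model = LinearModel(3, noise_variance=1.0)
    fitted = train_map(
        model, X, y, prior, TrainConfig(epochs=4000, lr=0.05, seed=0)
    )
    ridge = np.linalg.solve(X.T @ X + np.eye(3), X.T @ y)
    np.testing.assert_allclose(fitted, ridge, atol=1e-6)


def test_train_map_single_point_drives_residual_to_zero():
    model = LinearModel(1)
    X = np.array([[1.0]])
    y = np.array([3.0])
    fitted = train_map(model, X, y, Prior(np.inf), TrainConfig(epochs=3000, lr=0.1, seed=0))
    assert abs(y[0] - fitted[0]) < 1e-6


def test_training_is_seeded_and_deterministic(three_molecule_batch, tiny_model):
    graphs, y = three_molecule_batch
    cfg = TrainConfig(epochs=20, lr=1e-2, seed=42, batch_size=2)
    a = train_map(tiny_model, graphs, y, Prior(1.0), cfg)
    b = train_map(tiny_model, graphs, y, Prior(1.0), cfg)
    np.testing.assert_array_equal(a, b)


def test_dropout_p_zero_is_bitwise_map(three_molecule_batch, tiny_model):
    graphs, y = three_molecule_batch
    cfg = TrainConfig(epochs=15, lr=1e-2, seed=3, batch_size=2)
    via_map = train_map(tiny_model, graphs, y, Prior(1.0), cfg)
    via_dropout = train_dropout(
        tiny_model, graphs, y, Prior(1.0), DropoutConfig(p=0.0, n_samples=5), cfg
    )
    np.testing.assert_array_equal(via_map, via_dropout)


def test_dropout_training_reproducible(three_molecule_batch, tiny_model):
    graphs, y = three_molecule_batch
    cfg = TrainConfig(epochs=10, lr=1e-2, seed=5, batch_size=2)
    dc = DropoutConfig(p=0.2, n_samples=5)
    a = train_dropout(tiny_model, graphs, y, Prior(1.0), dc, cfg)
    b = train_dropout(tiny_model, graphs, y, Prior(1.0), dc, cfg)
    np.testing.assert_array_equal(a, b)


def test_predict_dropout_decomposition(three_molecule_batch, tiny_model):
    graphs, y = three_molecule_batch
    vec = tiny_model.init(np.random.default_rng(0))
    dc = DropoutConfig(p=0.3, n_samples=16, seed=9)
    pred = predict_dropout(tiny_model, vec, graphs, dc)
    # recompute the decomposition from the stored raw samples: exact match
    np.testing.assert_array_equal(pred.mean, pred.raw_means.mean(axis=0))
    np.testing.assert_array_equal(pred.var_epistemic, pred.raw_means.var(axis=0))
    np.testing.assert_array_equal(pred.var_aleatoric, pred.raw_variances.mean(axis=0))
    np.testing.assert_array_equal(
        pred.var_total, pred.var_epistemic + pred.var_aleatoric
    )
    # p = 0 -> every pass identical -> epistemic exactly 0
    pred0 = predict_dropout(tiny_model, vec, graphs, DropoutConfig(p=0.0, n_samples=4))
    np.testing.assert_array_equal(pred0.var_epistemic, np.zeros(len(graphs)))
    # N = 1 -> warning, and total == aleatoric
    with pytest.warns(UserWarning):
        pred1 = predict_dropout(
            tiny_model, vec, graphs, DropoutConfig(p=0.3, n_samples=1)
        )
    np.testing.assert_array_equal(pred1.var_total, pred1.var_aleatoric)


def test_svgd_phi_hand_enumerated_double_sum():
    """3 particles in 2-D against an independent brute-force double loop."""
    theta = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
    grads = np.array([[1.0, -1.0], [0.5, 0.5], [-2.0, 0.0]])
    h = 1.0  # unit bandwidth
    n = 3
    expected = np.zeros_like(theta)
    for i in range(n):
        for j in range(n):
            k = np.exp(-np.sum((theta[j] - theta[i]) ** 2) / h)
            grad_k = 2.0 * (theta[i] - theta[j]) / h * k
            expected[i] += k * grads[j] + grad_k
    expected /= n
    np.testing.assert_allclose(svgd_phi(theta, grads, bandwidth=h), expected, atol=1e-14)


def test_svgd_phi_single_particle_is_plain_gradient():
    theta = np.array([[1.0, -2.0, 3.0]])
    grad = np.array([[0.5, 0.25, -1.0]])
    np.testing.assert_array_equal(svgd_phi(theta, grad), grad)


def test_svgd_phi_coincident_particles_zero_gradient():
    """Repulsion cancels by antisymmetry when particles coincide."""
    theta = np.zeros((2, 3))
    grads = np.zeros((2, 3))
    np.testing.assert_array_equal(svgd_phi(theta, grads, bandwidth=1.0), np.zeros((2, 3)))


def test_svgd_recovers_1d_conjugate_posterior():
    """Gaussian prior + Gaussian likelihood, 100 particles, moments within 10%."""
    task = make_conjugate_task(dim=1, n=30, noise_scale=0.8, seed=5,
                               coef_magnitude_range=(0.8, 1.2))
    model = LinearModel(1, noise_variance=task.noise_scale**2)
    ens = train_svgd(
        model, task.X, task.y, Prior(task.prior_scale),
        SVGDConfig(steps=1500, lr=0.005, seed=6), n_particles=100,
    )
    mean = ens.particles.mean()
    var = ens.particles.var()
    assert abs(mean - task.post_mean[0]) / abs(task.post_mean[0]) < 0.10
    assert abs(var - task.post_cov[0, 0]) / task.post_cov[0, 0] < 0.10


def test_svgd_checkpoint_error_decreases():
    """Particle-moment error shrinks toward the analytic posterior over checkpoints."""
    task = make_conjugate_task(dim=2, n=40, seed=3)
    model = LinearModel(2, noise_variance=task.noise_scale**2)
    checkpoints = []
    train_svgd(
        model, task.X, task.y, Prior(task.prior_scale),
        SVGDConfig(steps=1200, lr=0.005, seed=4), n_particles=60,
        checkpoints=checkpoints, checkpoint_every=300,
    )
    errs = [
        np.linalg.norm(c.mean(axis=0) - task.post_mean) for c in checkpoints
    ]
    assert errs[-1] < errs[0]


def test_svgd_seeded_determinism():
    task = make_conjugate_task(dim=2, n=20, seed=0)
    model = LinearModel(2, noise_variance=task.noise_scale**2)
    kw = dict(n_particles=8)
    cfg = SVGDConfig(steps=50, lr=0.01, seed=7)
    a = train_svgd(model, task.X, task.y, Prior(1.0), cfg, **kw)
    b = train_svgd(model, task.X, task.y, Prior(1.0), cfg, **kw)
    np.testing.assert_array_equal(a.particles, b.particles)


def test_predict_ensemble_decomposition_and_mean():
    """Ensemble mean equals the arithmetic mean of per-particle predictions;
    identical particles give exactly zero epistemic variance."""
    rng = np.random.default_rng(2)
    model = LinearModel(3)
    X = rng.normal(size=(6, 3))
    particles = rng.normal(size=(5, 3))
    from molbayes.bayes import ParticleEnsemble

    ens = ParticleEnsemble(particles=particles)
    pred = predict_ensemble(model, ens, X)
    per_particle = np.stack([X @ p for p in particles])
    np.testing.assert_allclose(pred.mean, per_particle.mean(axis=0), atol=1e-14)
    np.testing.assert_array_equal(pred.var_total, pred.var_epistemic + pred.var_aleatoric)
    same = ParticleEnsemble(particles=np.tile(particles[0], (4, 1)))
    pred_same = predict_ensemble(model, same, X)
    np.testing.assert_array_equal(pred_same.var_epistemic, np.zeros(6))


def test_epistemic_variance_inflates_in_coverage_gap():
    """1-D regression with a gap in x: SVGD epistemic variance is larger in
    the gap than on the training support (polynomial feature basis)."""
    rng = np.random.default_rng(8)
    x = np.concatenate([rng.uniform(-1, -0.3, 40), rng.uniform(0.3, 1, 40)])
    def feats(x):
        return np.stack([x**k for k in range(6)], axis=1)
    y = np.sin(3 * x) + 0.05 * rng.normal(size=len(x))
    model = LinearModel(6, noise_variance=0.05**2)
    ens = train_svgd(
        model, feats(x), y, Prior(1.0),
        SVGDConfig(steps=800, lr=0.01, seed=9), n_particles=50,
    )
    gap = predict_ensemble(model, ens, feats(np.linspace(-0.15, 0.15, 25)))
    support = predict_ensemble(model, ens, feats(np.linspace(0.45, 0.85, 25)))
    assert np.median(gap.var_epistemic) > np.median(support.var_epistemic)


def test_divergence_raises_with_iteration_index():
    model = LinearModel(1)
    X = np.array([[1e4]])
    y = np.array([1.0])
    with np.errstate(over="ignore"), pytest.raises(FloatingPointError, match="epoch"):
        train_map(model, X, y, Prior(1.0), TrainConfig(epochs=50, lr=1e6, optimizer="sgd"))


def test_decompose_single_sample():
    pred = decompose(np.array([[1.0, 2.0]]), np.array([[0.5, 0.25]]))
    np.testing.assert_array_equal(pred.var_epistemic, [0.0, 0.0])
    np.testing.assert_array_equal(pred.var_total, [0.5, 0.25])
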