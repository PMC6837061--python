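"""Scikit-learn style estimators over the Bayesian graph-convolution stack.

:class:`GraphConvUncertaintyRegressor` is the main entry point: a regressor
taking SMILES strings (or pre-parsed graphs) as samples, with the
representation ("supervised" fingerprint network, or "semisupervised"
frozen embeddings with a supervised readout) and the inference route
("map", "dropout", "svgd") selected by constructor arguments. It follows
sklearn conventions — ``fit`` / ``predict`` / ``get_params`` /
``set_params``, trailing-underscore fitted attributes, ``clone``
compatibility — so it composes with sklearn model selection; note the
samples are molecule objects, not a numeric matrix, as with text
vectorizers.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import NotFittedError

from . import bayes
from .bayes import (
    DropoutConfig,
    Prior,
    SVGDConfig,
    TrainConfig,
    UncertainPrediction,
)
from .molgraph import DEFAULT_ELEMENTS, MolecularGraph, parse_smiles
from .mpnn import MPNNConfig, MPNNModel
from .semisup import (
    SemiSupModel,
    SemiSupReadoutModel,
    SemiSupTrainConfig,
    train_semisupervised,
)


def _as_graphs(X, elements) -> list[MolecularGraph]:
    graphs = []
    for item in X:
        if isinstance(item, MolecularGraph):
            graphs.append(item)
        elif isinstance(item, str):
            graphs.append(parse_smiles(item, elements))
        else:
            raise TypeError(
                f"samples must be SMILES strings or MolecularGraph, got {type(item)}"
            )
    return graphs


class GraphConvUncertaintyRegressor(RegressorMixin, BaseEstimator):
    """Bayesian graph-convolutional regressor with decomposed uncertainty.

    Parameters
    ----------
    representation : "supervised" | "semisupervised"
        Whether molecular descriptors are learned jointly with the property
        (supervised) or pre-trained on unlabelled structures and frozen
        (semisupervised). In the semi-supervised case, rows of ``y`` that
        are NaN are treated as unlabelled: their structures feed the
        embedding stage but not the supervised loss.
    inference : "map" | "dropout" | "svgd"
        Point estimate, Monte-Carlo dropout, or Stein variational gradient
        descent particle ensemble.
    steps, hidden, fingerprint, head_hidden
        Architecture: message-passing depth T, hidden width, fingerprint
        length (reference configuration uses 2 * hidden) and head widths.
    prior_scale : standard deviation of the isotropic Gaussian weight
        prior (the regulariser); <= 0 or inf gives a flat prior.
    warmup_epochs, warmup_lr : optional homoscedastic warm-up phase (noise
        variance pinned to 1) before the heteroscedastic loss takes over;
        stabilises small-data fits where the variance head can chase
        individual residuals.
    dropout_p, n_forward_samples : unit drop probability and number of
        stochastic forward passes at prediction time.
    n_particles, svgd_steps, svgd_lr, svgd_optimizer : ensemble settings.
    random_state : seed; every stage (init, shuffling, masks, particles)
        derives from it, making fit and predict bit-reproducible.

    Attributes
    ----------
    params_ : fitted flat parameter vector (map / dropout).
    ensemble_ : :class:`ParticleEnsemble` (svgd).
    embedding_ : :class:`SemiSupModel` (semisupervised representation).
    model_ : the underlying flat-vector model.
    n_labelled_ : number of labelled examples used in the supervised stage.
    """

    def __init__(
        self,
        representation: str = "supervised",
        inference: str = "map",
        steps: int = 3,
        hidden: int = 128,
        fingerprint: int = 256,
        head_hidden: tuple[int, int] = (128, 128),
        elements: tuple[str, ...] = DEFAULT_ELEMENTS,
        prior_scale: float = 1.0,
        epochs: int = 100,
        batch_size: int | None = None,
        learning_rate: float = 1e-3,
        optimizer: str = "adam",
        warmup_epochs: int = 0,
        warmup_lr: float | None = None,
        dropout_p: float = 0.2,
        n_forward_samples: int = 50,
        n_particles: int = 50,
        svgd_steps: int = 500,
        svgd_lr: float = 0.05,
        svgd_optimizer: str = "adagrad",
        svgd_batch_size: int | None = None,
        semisup_epochs: int = 20,
        semisup_batch_size: int = 32,
        semisup_lr: float = 1e-3,
        n_negatives: int = 5,
        random_state: int | None = None,
    ):
        self.representation = representation
        self.inference = inference
        self.steps = steps
        self.hidden = hidden
        self.fingerprint = fingerprint
        self.head_hidden = head_hidden
        self.elements = elements
        self.prior_scale = prior_scale
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.warmup_epochs = warmup_epochs
        self.warmup_lr = warmup_lr
        self.dropout_p = dropout_p
        self.n_forward_samples = n_forward_samples
        self.n_particles = n_particles
        self.svgd_steps = svgd_steps
        self.svgd_lr = svgd_lr
        self.svgd_optimizer = svgd_optimizer
        self.svgd_batch_size = svgd_batch_size
        self.semisup_epochs = semisup_epochs
        self.semisup_batch_size = semisup_batch_size
        self.semisup_lr = semisup_lr
        self.n_negatives = n_negatives
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _seed(self, offset: int) -> int:
        base = 0 if self.random_state is None else int(self.random_state)
        return (base * 7919 + offset) % (2**31 - 1)

    def _config(self) -> MPNNConfig:
        return MPNNConfig(
            steps=self.steps,
            hidden=self.hidden,
            fingerprint=self.fingerprint,
            head_hidden=tuple(self.head_hidden),
            elements=tuple(self.elements),
        )

    def _validate(self):
        if self.representation not in ("supervised", "semisupervised"):
            raise ValueError(f"unknown representation {self.representation!r}")
        if self.inference not in ("map", "dropout", "svgd"):
            raise ValueError(f"unknown inference {self.inference!r}")

    def fit(self, X, y, embedding: SemiSupModel | None = None, init_params=None):
        """Fit on SMILES/graphs ``X`` and targets ``y`` (NaN = unlabelled).

        ``embedding`` injects a pre-trained semi-supervised model (frozen;
        used by the active-learning loop to share one embedding across
        retrainings); ``init_params`` warm-starts the supervised stage.
        """
        self._validate()
        y = np.asarray(y, dtype=float)
        graphs = _as_graphs(X, tuple(self.elements))
        if len(graphs) != len(y):
            raise ValueError("X and y have different lengths")
        labelled = ~np.isnan(y)
        if not labelled.any():
            raise ValueError("need at least one labelled example")
        config = self._config()
        self.config_ = config

        if self.representation == "semisupervised":
            if embedding is not None:
                self.embedding_ = embedding
            else:
                self.embedding_ = train_semisupervised(
                    graphs,
                    config,
                    SemiSupTrainConfig(
                        epochs=self.semisup_epochs,
                        batch_size=self.semisup_batch_size,
                        lr=self.semisup_lr,
                        n_negatives=self.n_negatives,
                        seed=self._seed(11),
                    ),
                )
            self.model_ = SemiSupReadoutModel(
                self.embedding_,
                fingerprint=self.fingerprint,
                head_hidden=tuple(self.head_hidden),
            )
        else:
            self.embedding_ = None
            self.model_ = MPNNModel(config)

        graphs_l = [g for g, keep in zip(graphs, labelled) if keep]
        y_l = y[labelled]
        self.n_labelled_ = len(y_l)
        prior = Prior(self.prior_scale)
        tc = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.learning_rate,
            optimizer=self.optimizer,
            seed=self._seed(23),
            warmup_epochs=self.warmup_epochs,
            warmup_lr=self.warmup_lr,
        )
        if self.inference == "map":
            self.params_ = bayes.train_map(
                self.model_, graphs_l, y_l, prior, tc, init=init_params
            )
            self.ensemble_ = None
        elif self.inference == "dropout":
            self.dropout_config_ = DropoutConfig(
                p=self.dropout_p,
                n_samples=self.n_forward_samples,
                seed=self._seed(37),
            )
            self.params_ = bayes.train_dropout(
                self.model_, graphs_l, y_l, prior, self.dropout_config_, tc,
                init=init_params,
            )
            self.ensemble_ = None
        else:
            self.ensemble_ = bayes.train_svgd(
                self.model_,
                graphs_l,
                y_l,
                prior,
                SVGDConfig(
                    steps=self.svgd_steps,
                    lr=self.svgd_lr,
                    optimizer=self.svgd_optimizer,
                    seed=self._seed(23),
                ),
                n_particles=self.n_particles,
                batch_size=self.svgd_batch_size,
            )
            self.params_ = None
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise NotFittedError(
                "this GraphConvUncertaintyRegressor instance is not fitted yet"
            )

    def predict_dist(self, X) -> UncertainPrediction:
        """Predictive mean and epistemic/aleatoric/total variances."""
        self._check_fitted()
        graphs = _as_graphs(X, tuple(self.elements))
        if self.inference == "map":
            mu, s2 = self.model_.predict(self.params_, graphs)
            return bayes.decompose(mu[None, :], s2[None, :])
        if self.inference == "dropout":
            return bayes.predict_dropout(
                self.model_, self.params_, graphs, self.dropout_config_
            )
        return bayes.predict_ensemble(self.model_, self.ensemble_, graphs)

    def predict(self, X, return_std: bool = False):
        """Predictive mean; with ``return_std``, also sqrt(total variance)."""
        pred = self.predict_dist(X)
        if return_std:
            return pred.mean, np.sqrt(pred.var_total)
        return pred.mean


def pretrain_embedding(
    X,
    config: MPNNConfig | None = None,
    train_config: SemiSupTrainConfig | None = None,
    elements: tuple[str, ...] = DEFAULT_ELEMENTS,
) -> SemiSupModel:
    """Train a standalone semi-supervised embedding on unlabelled structures."""
    graphs = _as_graphs(X, tuple(elements))
    return train_semisupervised(
        graphs, config or MPNNConfig(elements=tuple(elements)), train_config
    )
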