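"""scikit-learn estimator wrapping the attention encoder + CRF sequence model.

One training example is a whole night: a (T, F) feature matrix (T epochs,
F = 152 x channels features) with its per-epoch stage labels. Each night is
one optimization step (the batch is the full 1,140-epoch sequence, as the
chain loss couples all epochs of a night), using Adam with learning rate
1e-4 and weight decay 0.01. The loss is the class-weighted CRF negative
log-likelihood (stage weights scale the gold path's emission term, so rare
upweighted stages pull their scores up harder); decoding is Viterbi over
unweighted emissions.

Weight decay (classic L2, added to the gradient) applies to connection
weights only - biases and the CRF transition/start/end scores are exempt, so
the learned transition structure is shaped by the data alone.
"""

from __future__ import annotations

import copy

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .crf import (
    CrfParams,
    class_weighted_gradients,
    class_weighted_nll,
    forward_backward,
    viterbi,
)
from .features import NormalizationParams, apply_normalizer, fit_normalizer
from .stages import N_STAGES

__all__ = ["SleepStageClassifier"]


def _as_night_list(X):
    if isinstance(X, np.ndarray) and X.ndim == 2:
        return [X], True
    return [np.asarray(x, dtype=float) for x in X], False


class SleepStageClassifier(ClassifierMixin, BaseEstimator):
    """Whole-night sleep stager: bi-GRU attention encoder + linear-chain CRF.

    Parameters
    ----------
    learning_rate : float
        Adam step size (one step per night).
    weight_decay : float
        L2 coefficient on connection weights (not biases/CRF scores).
    max_epochs : int
        Maximum passes over the training nights.
    patience : int
        Early-stopping patience in epochs, monitored on held-out validation
        nights (a ``val_fraction`` share of the training nights).
    val_fraction : float
        Fraction of training nights held out for early stopping (at least
        one night when there are two or more training nights).
    class_weights : sequence of 5 positive floats or None
        Per-stage weights in the CRF loss, order W, N1, N2, N3, REM.
        None means unit weights. The stage-imbalance setting from the
        method's study is (1, 6, 1, 2, 1).
    standardize : bool
        z-score features using statistics of the (non-validation) training
        nights.
    random_state : int or None
        Seed for parameter initialization, validation split and night order.

    Attributes
    ----------
    encoder_params_ : dict of arrays
        GRU and emission-layer parameters.
    crf_ : CrfParams
        Learned transition/start/end scores.
    norm_ : NormalizationParams or None
    classes_ : ndarray (5,)
    history_ : dict with per-epoch train/validation losses.
    """

    def __init__(
        self,
        learning_rate: float = 1e-4,
        weight_decay: float = 1e-2,
        max_epochs: int = 100,
        patience: int = 10,
        val_fraction: float = 0.1,
        class_weights=None,
        standardize: bool = True,
        random_state=None,
    ):
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.class_weights = class_weights
        self.standardize = standardize
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _all_params(self):
        params = dict(self.encoder_params_)
        params["crf.A"] = self.crf_.transitions
        params["crf.start"] = self.crf_.start
        params["crf.end"] = self.crf_.end
        return params

    def _night_loss_and_grads(self, X, y, weights):
        E, cache = nn.encoder_forward(X, self.encoder_params_)
        dE, dA, dstart, dend, loss = class_weighted_gradients(
            E, y, self.crf_, weights
        )
        grads = nn.encoder_backward(dE, cache, self.encoder_params_)
        grads["crf.A"] = dA
        grads["crf.start"] = dstart
        grads["crf.end"] = dend
        return loss, grads

    def _night_loss(self, X, y, weights):
        E, _ = nn.encoder_forward(X, self.encoder_params_)
        return class_weighted_nll(E, y, self.crf_, weights)

    @staticmethod
    def _decayed(key: str) -> bool:
        # connection weights only: emit.W and the GRU W*/U* matrices
        return key == "emit.W" or (
            key.split(".")[-1][0] in ("W", "U") and not key.startswith("crf.")
        )

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        """Fit on a list of nights.

        X : list of (T_i, F) arrays (or a single 2-D array for one night)
        y : list of length-T_i integer stage vectors
        """
        nights, single = _as_night_list(X)
        labels = [np.asarray(t, dtype=np.int64) for t in ([y] if single else y)]
        if len(nights) != len(labels):
            raise ValueError("X and y must contain the same number of nights")
        for Xi, yi in zip(nights, labels):
            if Xi.shape[0] != yi.shape[0]:
                raise ValueError("per-night feature/label lengths differ")
            if yi.size and (yi.min() < 0 or yi.max() >= N_STAGES):
                raise ValueError("stage labels must lie in 0-4")
        F = nights[0].shape[1]
        if any(n.shape[1] != F for n in nights):
            raise ValueError("all nights must share one feature width")

        rng = np.random.default_rng(self.random_state)
        n_nights = len(nights)
        order = rng.permutation(n_nights)
        n_val = 0
        if self.val_fraction > 0 and n_nights >= 2:
            n_val = max(1, int(round(self.val_fraction * n_nights)))
        val_idx = list(order[:n_val])
        train_idx = list(order[n_val:])

        if self.standardize:
            stacked = np.vstack([nights[i] for i in train_idx])
            self.norm_: NormalizationParams | None = fit_normalizer(stacked)
            nights = [apply_normalizer(n, self.norm_) for n in nights]
        else:
            self.norm_ = None

        weights = (
            None
            if self.class_weights is None
            else np.asarray(self.class_weights, dtype=float)
        )
        self.classes_ = np.arange(N_STAGES)
        self.n_features_in_ = F
        self.encoder_params_ = nn.init_encoder_params(
            F, seed=int(rng.integers(2**31))
        )
        self.crf_ = CrfParams()

        params = self._all_params()
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(val) for k, val in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        best_val = np.inf
        best_state = None
        best_epoch = 0
        bad_epochs = 0
        history = {"train_loss": [], "val_loss": []}

        for epoch in range(self.max_epochs):
            train_losses = []
            for i in rng.permutation(train_idx):
                loss, grads = self._night_loss_and_grads(
                    nights[i], labels[i], weights
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}, night {i}"
                    )
                train_losses.append(loss / len(labels[i]))
                step += 1
                params = self._all_params()
                for key, g in grads.items():
                    if self.weight_decay and self._decayed(key):
                        g = g + self.weight_decay * params[key]
                    m[key] = beta1 * m[key] + (1 - beta1) * g
                    v[key] = beta2 * v[key] + (1 - beta2) * g * g
                    mhat = m[key] / (1 - beta1**step)
                    vhat = v[key] / (1 - beta2**step)
                    params[key] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            history["train_loss"].append(float(np.mean(train_losses)))

            if val_idx:
                val_loss = float(
                    np.mean(
                        [
                            self._night_loss(nights[i], labels[i], weights)
                            / len(labels[i])
                            for i in val_idx
                        ]
                    )
                )
                history["val_loss"].append(val_loss)
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_state = (
                        copy.deepcopy(self.encoder_params_),
                        copy.deepcopy(self.crf_),
                    )
                    best_epoch = epoch
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                    if bad_epochs >= self.patience:
                        break

        if best_state is not None:
            self.encoder_params_, self.crf_ = best_state
        self.best_epoch_ = best_epoch
        self.history_ = history
        return self

    def _check_fitted_width(self, nights):
        for Xi in nights:
            if Xi.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"night has {Xi.shape[1]} features but the model was fitted "
                    f"with {self.n_features_in_}"
                )

    def predict(self, X):
        """Viterbi stage sequence per night (list in, list out)."""
        nights, single = _as_night_list(X)
        self._check_fitted_width(nights)
        out = []
        for Xi in nights:
            if self.norm_ is not None:
                Xi = apply_normalizer(Xi, self.norm_)
            E, _ = nn.encoder_forward(Xi, self.encoder_params_)
            path, _ = viterbi(E, self.crf_)
            out.append(path)
        return out[0] if single else out

    def predict_marginals(self, X):
        """Per-epoch posterior stage marginals (forward-backward, unit weights)."""
        nights, single = _as_night_list(X)
        self._check_fitted_width(nights)
        out = []
        for Xi in nights:
            if self.norm_ is not None:
                Xi = apply_normalizer(Xi, self.norm_)
            E, _ = nn.encoder_forward(Xi, self.encoder_params_)
            gamma, _, _ = forward_backward(E, self.crf_)
            out.append(gamma)
        return out[0] if single else out

    def score(self, X, y):
        """Pooled per-epoch accuracy over the given nights."""
        nights, single = _as_night_list(X)
        labels = [np.asarray(t, dtype=np.int64) for t in ([y] if single else y)]
        preds = self.predict(X)
        if single:
            preds = [preds]
        correct = sum(int((p == t).sum()) for p, t in zip(preds, labels))
        total = sum(t.size for t in labels)
        return correct / total
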