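"""Scikit-learn-style estimator facade over the model and trainer.

``N2GNetRegressor`` exposes the network as a standard ``fit``/``predict``
regressor so it composes with sklearn model selection and pipelines.
Inputs are LFP windows shaped ``(n_windows, 2, window_len)`` (a flattened
``(n_windows, 2*window_len)`` layout is also accepted); targets are the
normalized weight-shift labels in [0, 1].

Validation data for early stopping is passed explicitly via
``fit(..., X_val=, y_val=)`` — the natural use with chronological visit
splits — or, if omitted, taken as the chronological tail of the training
set (``validation_fraction``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .model import ModelConfig, build_model
from .training import TrainConfig, restore_best, train


class N2GNetRegressor(BaseEstimator, RegressorMixin):
    """Neural-to-gait regression from bilateral STN LFP windows.

    Parameters mirror :class:`~n2gnet.model.ModelConfig` (architecture and
    ablation flags) and :class:`~n2gnet.training.TrainConfig` (optimization).
    Defaults are the published-scale settings; for single-CPU work pass the
    desk-scale overrides from :mod:`n2gnet.pipeline`.

    Attributes (after fit): ``model_``, ``history_``, ``best_epoch_``,
    ``n_parameters_``, ``loss_curve_``, ``validation_scores_``.
    """

    def __init__(self, use_division: bool = True, use_se: bool = True,
                 use_bilstm: bool = True, n_filters_per_lead: int = 16,
                 kernel_len: int = 53, pool_len: int = 21,
                 pool_stride: int = 10, se_reduction: int = 4,
                 lstm_hidden: int = 32, lstm_layers: int = 3,
                 head_channels: int = 16, head_kernel_len: int = 5,
                 division_eps: float = 1e-6, learning_rate: float = 1e-5,
                 batch_size: int = 16, max_epochs: int = 2000,
                 patience_epochs: int = 100,
                 validation_fraction: float = 0.2,
                 shuffle_each_epoch: bool = True, random_state: int = 0,
                 verbose: bool = False):
        self.use_division = use_division
        self.use_se = use_se
        self.use_bilstm = use_bilstm
        self.n_filters_per_lead = n_filters_per_lead
        self.kernel_len = kernel_len
        self.pool_len = pool_len
        self.pool_stride = pool_stride
        self.se_reduction = se_reduction
        self.lstm_hidden = lstm_hidden
        self.lstm_layers = lstm_layers
        self.head_channels = head_channels
        self.head_kernel_len = head_kernel_len
        self.division_eps = division_eps
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience_epochs = patience_epochs
        self.validation_fraction = validation_fraction
        self.shuffle_each_epoch = shuffle_each_epoch
        self.random_state = random_state
        self.verbose = verbose

    # -- config plumbing -------------------------------------------------

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            use_division=self.use_division, use_se=self.use_se,
            use_bilstm=self.use_bilstm,
            n_filters_per_lead=self.n_filters_per_lead,
            kernel_len=self.kernel_len, pool_len=self.pool_len,
            pool_stride=self.pool_stride, se_reduction=self.se_reduction,
            lstm_hidden=self.lstm_hidden, lstm_layers=self.lstm_layers,
            head_channels=self.head_channels,
            head_kernel_len=self.head_kernel_len,
            division_eps=self.division_eps, seed=self.random_state)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience_epochs=self.patience_epochs, seed=self.random_state,
            shuffle_each_epoch=self.shuffle_each_epoch)

    @staticmethod
    def _as_windows(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] % 2:
                raise ValueError("flattened windows must have an even "
                                 "number of columns (2 channels)")
            X = X.reshape(X.shape[0], 2, -1)
        if X.ndim != 3 or X.shape[1] != 2:
            raise ValueError("expected windows shaped (n, 2, length)")
        return X

    # -- sklearn API -----------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None) -> "N2GNetRegressor":
        X = self._as_windows(X)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of windows")
        if X_val is None:
            # chronological tail: later windows validate, mirroring the
            # prospective visit split at the within-session scale
            n_val = max(1, int(round(X.shape[0]
                                     * self.validation_fraction)))
            if n_val >= X.shape[0]:
                raise ValueError("validation_fraction leaves no training "
                                 "windows")
            X, X_val = X[:-n_val], X[-n_val:]
            y, y_val = y[:-n_val], y[-n_val:]
        else:
            X_val = self._as_windows(X_val)
            y_val = np.asarray(y_val, dtype=float)

        model = build_model(self._model_config())
        history = train(model, X, y, X_val, y_val, self._train_config(),
                        verbose=self.verbose)
        restore_best(model, history)
        self.model_ = model
        self.history_ = history
        self.best_epoch_ = history.best_epoch
        self.n_parameters_ = model.parameter_count
        self.loss_curve_ = list(history.train_loss)
        self.validation_scores_ = list(history.val_loss)
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise AttributeError("this N2GNetRegressor is not fitted yet")
        return self.model_.predict(self._as_windows(X))
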