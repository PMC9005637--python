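"""Scikit-learn-style estimator for continuous gait-phase regression.

``PhaseLSTMRegressor`` maps a sliding window of kinematic channels
(shape ``(n_windows, window_len, n_channels)``) to the polar-encoded gait
phase (px, py) at the window's last sample.  The default architecture is
five layers: four recurrent layers of 128, 64, 64 and 32 units — the first
bidirectional, its 128 units split 64 per direction — and a dense output of
size 2.  Training uses Adam on mean-squared error with batch size 64, up to
100 epochs, early-stopped when validation loss has not improved for 10
epochs; the weights from the best validation epoch are restored.

Channels are z-scored with statistics computed on the training windows only
and reused unchanged at prediction time.  Decoding network outputs to the
bounded linear phase uses only the angle of (px, py), so outputs are not
re-projected onto the unit circle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .nn import Adam, SequenceRegressorNet
from .phase import decode

__all__ = ["PhaseLSTMRegressor"]


class PhaseLSTMRegressor(RegressorMixin, BaseEstimator):
    """Sliding-window recurrent regressor for the encoded gait phase.

    Parameters
    ----------
    hidden_units : tuple of int
        Units per recurrent layer (a bidirectional layer's count is split
        evenly across directions).
    bidirectional : tuple of bool
        Bidirectionality flag per recurrent layer.
    learning_rate, batch_size, max_epochs, patience
        Adam step size and the training schedule; early stopping monitors
        validation MSE (training MSE when no validation data exists).
    validation_fraction : float
        Fraction of training *windows* held out for early stopping when no
        explicit validation set is passed to :meth:`fit`.  Subject-level
        splits should be made upstream and passed explicitly.
    normalize : bool
        Per-channel z-scoring with training-set statistics.
    random_state : int or None
        Seeds weight init, batch shuffling and the internal split.
    """

    def __init__(self, hidden_units=(128, 64, 64, 32),
                 bidirectional=(True, False, False, False),
                 learning_rate: float = 1e-3, batch_size: int = 64,
                 max_epochs: int = 100, patience: int = 10,
                 validation_fraction: float = 0.0, normalize: bool = True,
                 random_state=None, verbose: int = 0):
        self.hidden_units = hidden_units
        self.bidirectional = bidirectional
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.normalize = normalize
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _validate_windows(self, X, fitted: bool) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(f"expected 3-d window array, got shape {X.shape}")
        if fitted and X.shape[2] != self.n_channels_:
            raise ValueError(
                f"channel mismatch: model expects {self.n_channels_} channels, "
                f"got {X.shape[2]}")
        return X

    def _apply_norm(self, X: np.ndarray) -> np.ndarray:
        if not self.normalize:
            return X
        return (X - self.norm_mean_) / self.norm_std_

    def fit(self, X, y, validation_data=None):
        """Train on windows X (n, T, C) and polar targets y (n, 2)."""
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        X = self._validate_windows(X, fitted=False)
        y = np.asarray(y, dtype=float)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if y.shape != (X.shape[0], 2):
            raise ValueError(f"targets must have shape (n, 2), got {y.shape}")
        rng = np.random.default_rng(self.random_state)

        if validation_data is None and self.validation_fraction > 0:
            n_val = max(1, int(round(self.validation_fraction * X.shape[0])))
            perm = rng.permutation(X.shape[0])
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            validation_data = (X[val_idx], y[val_idx])
            X, y = X[tr_idx], y[tr_idx]
            if X.shape[0] == 0:
                raise ValueError("validation split left no training windows")

        self.n_channels_ = X.shape[2]
        self.window_len_ = X.shape[1]
        if self.normalize:
            flat = X.reshape(-1, self.n_channels_)
            self.norm_mean_ = flat.mean(axis=0)
            sd = flat.std(axis=0)
            self.norm_std_ = np.where(sd > 1e-12, sd, 1.0)
        Xn = self._apply_norm(X)
        if validation_data is not None:
            Xv = self._apply_norm(self._validate_windows(validation_data[0], fitted=True))
            yv = np.asarray(validation_data[1], dtype=float)
        else:
            Xv = yv = None

        net = SequenceRegressorNet(self.n_channels_, self.hidden_units,
                                   self.bidirectional, n_outputs=2, rng=rng)
        opt = Adam(net.params, learning_rate=self.learning_rate)

        n = Xn.shape[0]
        history = []
        best_loss = np.inf
        best_weights = net.get_weights()
        best_epoch = 0
        since_best = 0
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n)
            losses = []
            for s in range(0, n, self.batch_size):
                idx = order[s:s + self.batch_size]
                loss, grads = net.loss_and_grads(Xn[idx], y[idx])
                opt.step(grads)
                losses.append(loss)
            train_mse = float(np.mean(losses))
            if Xv is not None:
                val_mse = float(np.mean((net.predict(Xv) - yv) ** 2))
            else:
                val_mse = train_mse
            history.append({"epoch": epoch, "train_mse": train_mse,
                            "val_mse": val_mse})
            if self.verbose:
                print(f"epoch {epoch:3d}  train {train_mse:.5f}  val {val_mse:.5f}")
            if val_mse < best_loss - 1e-12:
                best_loss = val_mse
                best_weights = net.get_weights()
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        net.set_weights(best_weights)
        self.net_ = net
        self.history_ = pd.DataFrame(history)
        self.best_epoch_ = best_epoch
        self.best_val_mse_ = float(best_loss)
        self.final_train_mse_ = float(self.history_["train_mse"].iloc[-1])
        return self

    def predict(self, X) -> np.ndarray:
        """Raw network outputs (px, py), one row per window."""
        check_is_fitted(self, "net_")
        X = self._validate_windows(X, fitted=True)
        if X.shape[0] == 0:
            return np.empty((0, 2))
        return self.net_.predict(self._apply_norm(X))

    def predict_phase(self, X) -> np.ndarray:
        """Bounded linear phase tau_hat in [0, 1) for each window."""
        p = self.predict(X)
        return decode(p[:, 0], p[:, 1])

    def score(self, X, y) -> float:
        """Negative MSE on (px, py) (higher is better, sklearn convention)."""
        return -float(np.mean((self.predict(X) - np.asarray(y)) ** 2))
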