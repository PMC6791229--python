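"""Single-hidden-layer sigmoid network for small-sample regression.

A deliberately small feed-forward network in the classic single-hidden-layer
tradition: logistic hidden units, a logistic *output* unit, sum-of-squares
loss with an L2 weight-decay penalty, and full-batch quasi-Newton training.
Inputs and labels are min-max scaled to [0, 1] on the training window;
predictions are unscaled afterwards.  Because the output unit is bounded,
predictions can never leave the training-label range — the network
saturates rather than extrapolates, which is the behaviour wanted when the
feature columns (grey-model forecasts) keep growing outside the training
window.

Training restarts from ``restarts`` random initializations (uniform on
[-init_scale, init_scale]) and keeps the weights with the lowest
training-set RMSE.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["SigmoidNeuralRegressor"]

_EPS = 1e-12


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


class SigmoidNeuralRegressor(BaseEstimator, RegressorMixin):
    """Sigmoid-output multilayer perceptron regressor.

    Parameters
    ----------
    hidden_units : int, default 5
        Number of logistic hidden units.
    decay : float, default 1e-8
        L2 penalty on all weights (applied on the scaled problem).
    max_iter : int, default 10000
        Iteration cap per restart for the L-BFGS-B optimizer.
    tol : float, default 1e-8
        Convergence tolerance on the (scaled) penalized loss.
    restarts : int, default 50
        Random initializations; the restart with the lowest training RMSE
        (on the original label scale) is kept.
    init_scale : float, default 0.7
        Initial weights drawn uniformly from [-init_scale, init_scale].
    random_state : int or None
        Seed for the restart initializations.

    Attributes
    ----------
    weights_ : flat parameter vector of the selected restart
    train_rmse_ : training RMSE of the selected restart (original scale)
    converged_ : True if the selected restart's optimizer converged
    n_features_in_ : number of input features
    """

    def __init__(
        self,
        hidden_units: int = 5,
        decay: float = 1e-8,
        max_iter: int = 10000,
        tol: float = 1e-8,
        restarts: int = 50,
        init_scale: float = 0.7,
        random_state: int | None = None,
    ):
        self.hidden_units = hidden_units
        self.decay = decay
        self.max_iter = max_iter
        self.tol = tol
        self.restarts = restarts
        self.init_scale = init_scale
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _split_weights(self, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h, p = self.hidden_units, self.n_features_in_
        n1 = h * (p + 1)
        return w[:n1].reshape(h, p + 1), w[n1:]

    def _forward(self, w: np.ndarray, x_scaled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w1, w2 = self._split_weights(w)
        hidden = _sigmoid(x_scaled @ w1[:, 1:].T + w1[:, 0])
        out = _sigmoid(hidden @ w2[1:] + w2[0])
        return out, hidden

    def _loss_grad(self, w, x_scaled, y_scaled):
        yhat, hidden = self._forward(w, x_scaled)
        r = yhat - y_scaled
        _, w2 = self._split_weights(w)
        d_out = 2.0 * r * yhat * (1.0 - yhat)
        g2 = np.concatenate([[d_out.sum()], d_out @ hidden])
        d_hid = np.outer(d_out, w2[1:]) * hidden * (1.0 - hidden)
        g1 = np.column_stack([d_hid.sum(0), d_hid.T @ x_scaled])
        grad = np.concatenate([g1.ravel(), g2]) + 2.0 * self.decay * w
        return float(r @ r + self.decay * (w @ w)), grad

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        if len(y) < 3:
            raise ValueError("need at least 3 training rows")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite training data")
        self.n_features_in_ = X.shape[1]
        self.x_min_ = X.min(axis=0)
        self.x_range_ = np.maximum(X.max(axis=0) - self.x_min_, _EPS)
        self.y_min_ = y.min()
        self.y_range_ = max(y.max() - self.y_min_, _EPS)
        xs = (X - self.x_min_) / self.x_range_
        ys = (y - self.y_min_) / self.y_range_

        n_weights = self.hidden_units * (self.n_features_in_ + 1) + self.hidden_units + 1
        seeds = np.random.SeedSequence(self.random_state).spawn(max(int(self.restarts), 1))
        best = None
        for child in seeds:
            rng = np.random.default_rng(child)
            w0 = rng.uniform(-self.init_scale, self.init_scale, n_weights)
            res = minimize(
                self._loss_grad,
                w0,
                args=(xs, ys),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-10},
            )
            yhat = self._forward(res.x, xs)[0] * self.y_range_ + self.y_min_
            rmse = float(np.sqrt(np.mean((yhat - y) ** 2)))
            if best is None or rmse < best[0]:
                best = (rmse, res.x, bool(res.success))
        self.train_rmse_, self.weights_, self.converged_ = best
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        xs = (X - self.x_min_) / self.x_range_
        return self._forward(self.weights_, xs)[0] * self.y_range_ + self.y_min_
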