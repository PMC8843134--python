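"""Single-hidden-layer perceptron trained by Levenberg-Marquardt.

The network maps a dose triple x through p tanh hidden units to a linear
output,

    yhat = w0 + sum_j wj * tanh(sum_i wji x_i + wj0),

and is trained in full batch by damped Gauss-Newton (Levenberg-Marquardt)
on the mean squared error, with an analytically computed residual
Jacobian. The hidden-layer size is chosen by cross-validation over a
candidate range with several seeded restarts per candidate, which makes
trial-and-error architecture search reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def mean_squared_error(y, yhat) -> float:
    """The training criterion: mean of squared residuals."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("y and yhat must be non-empty and the same length")
    return float(np.mean((y - yhat) ** 2))


@dataclass
class MLP:
    """Weights of a 3-layer perceptron: tanh hidden layer, identity output."""

    W1: np.ndarray  # (p, n_inputs) input->hidden weights
    b1: np.ndarray  # (p,) hidden biases
    w2: np.ndarray  # (p,) hidden->output weights
    b2: float  # output bias
    training_log: dict = field(default_factory=dict)

    @property
    def hidden_size(self) -> int:
        return len(self.b1)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        scalar = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.W1.shape[1]:
            raise ValueError(
                f"expected {self.W1.shape[1]} input features, got {X.shape[1]}"
            )
        h = np.tanh(X @ self.W1.T + self.b1)
        yhat = h @ self.w2 + self.b2
        return float(yhat[0]) if scalar else yhat

    def to_dict(self) -> dict:
        return {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": float(self.b2),
            "hidden_activation": "tanh",
            "output_activation": "identity",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLP":
        return cls(
            W1=np.array(d["W1"], float),
            b1=np.array(d["b1"], float),
            w2=np.array(d["w2"], float),
            b2=float(d["b2"]),
        )


def mlp_forward(model: MLP, x) -> float | np.ndarray:
    """Functional alias for :meth:`MLP.predict`."""
    return model.predict(x)


def _pack(W1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([W1.ravel(), b1, w2, [b2]])


def _unpack(theta: np.ndarray, p: int, d: int):
    W1 = theta[: p * d].reshape(p, d)
    b1 = theta[p * d : p * d + p]
    w2 = theta[p * d + p : p * d + 2 * p]
    b2 = theta[-1]
    return W1, b1, w2, b2


def _residual_jacobian(theta, X, y, p):
    """Residuals r = yhat - y and their analytic Jacobian d r / d theta."""
    n, d = X.shape
    W1, b1, w2, b2 = _unpack(theta, p, d)
    a = X @ W1.T + b1
    h = np.tanh(a)
    yhat = h @ w2 + b2
    r = yhat - y
    sech2 = 1.0 - h**2
    J = np.empty((n, theta.size))
    # d yhat / d W1_{ji} = w2_j * sech2_j * x_i
    J[:, : p * d] = ((w2 * sech2)[:, :, None] * X[:, None, :]).reshape(n, p * d)
    J[:, p * d : p * d + p] = w2 * sech2  # d/d b1_j
    J[:, p * d + p : p * d + 2 * p] = h  # d/d w2_j
    J[:, -1] = 1.0  # d/d b2
    return r, J


def train_lm(
    X,
    y,
    p: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-8,
    mu0: float = 1e-3,
    mu_max: float = 1e10,
) -> MLP:
    """Fit an MLP with ``p`` hidden units by Levenberg-Marquardt.

    Weights are initialized uniformly in [-0.5, 0.5] from ``seed``. Each
    iteration solves (J'J + mu I) delta = -J'r; the damping ``mu`` is
    divided by 10 on an accepted step and multiplied by 10 on a rejected
    one. Training stops at ``max_iter`` iterations, an infinity-norm
    gradient below ``tol``, or ``mu`` exceeding ``mu_max``; the
    best-SSE weights ever seen are returned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("training data must be finite")
    if p < 1:
        raise ValueError("hidden size must be >= 1")
    n, d = X.shape
    if n < 5 * p:
        warnings.warn(
            f"only {n} rows for {p} hidden units; fewer than 5 rows per unit"
        )
    rng = np.random.default_rng(seed)
    theta = rng.uniform(-0.5, 0.5, size=p * d + 2 * p + 1)

    r, J = _residual_jacobian(theta, X, y, p)
    sse = float(r @ r)
    best_theta, best_sse = theta.copy(), sse
    sse_path = [sse]  # SSE after each accepted step
    mu = mu0
    n_iter = 0
    stop = "max_iter"
    for n_iter in range(1, max_iter + 1):
        g = J.T @ r
        if np.max(np.abs(g)) < tol:
            stop = "gradient"
            break
        JtJ = J.T @ J
        accepted = False
        while mu <= mu_max:
            try:
                delta = np.linalg.solve(JtJ + mu * np.eye(theta.size), -g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            r_new, J_new = _residual_jacobian(theta + delta, X, y, p)
            sse_new = float(r_new @ r_new)
            if np.isfinite(sse_new) and sse_new < sse:
                theta = theta + delta
                r, J, sse = r_new, J_new, sse_new
                mu = max(mu / 10.0, 1e-12)
                accepted = True
                sse_path.append(sse)
                if sse < best_sse:
                    best_sse, best_theta = sse, theta.copy()
                break
            mu *= 10.0
        if not accepted:
            stop = "mu_overflow"
            break

    W1, b1, w2, b2 = _unpack(best_theta, p, d)
    return MLP(
        W1=W1,
        b1=b1,
        w2=w2,
        b2=float(b2),
        training_log={
            "iterations": n_iter,
            "final_sse": best_sse,
            "sse_path": sse_path,
            "stop_reason": stop,
            "seed": int(seed),
            "hidden_size": p,
        },
    )


@dataclass
class MLPRegressor:
    """Estimator-style wrapper around :func:`train_lm` (fit/predict API)."""

    p: int
    seed: int = 0
    max_iter: int = 1000
    tol: float = 1e-8
    model_: MLP | None = None

    def fit(self, X, y) -> "MLPRegressor":
        self.model_ = train_lm(
            X, y, p=self.p, seed=self.seed, max_iter=self.max_iter, tol=self.tol
        )
        return self

    def predict(self, X):
        if self.model_ is None:
            raise ValueError("estimator is not fitted")
        return self.model_.predict(X)


def select_hidden_size(
    X,
    y,
    candidates=range(1, 11),
    folds=None,
    restarts: int = 5,
    seed: int = 0,
    k: int = 5,
    max_iter: int = 200,
) -> tuple[int, pd.DataFrame]:
    """Choose the hidden size minimizing median CV-RMSE over restarts.

    For each candidate ``p``, ``restarts`` seeded trainings are run per
    fold and the median cross-validated RMSE over restarts is recorded;
    the smallest ``p`` attaining the minimum wins. ``max_iter`` defaults
    lower than :func:`train_lm`'s, which is ample for architecture
    ranking on small factorial data.
    """
    from .preprocessing import kfold_split

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    if folds is None:
        folds = kfold_split(len(y), k=k, seed=seed)
    folds = np.asarray(folds)

    rows = []
    for p in candidates:
        rmses = []
        for rs in range(restarts):
            sq_errs = []
            for f in np.unique(folds):
                test = folds == f
                with warnings.catch_warnings():
                    # the scan deliberately visits sizes the data cannot
                    # support well; the rows-per-unit warning is expected
                    warnings.simplefilter("ignore", UserWarning)
                    model = train_lm(
                        X[~test], y[~test], p=p,
                        seed=seed + 1000 * rs + 17 * p + int(f),
                        max_iter=max_iter,
                    )
                sq_errs.append((model.predict(X[test]) - y[test]) ** 2)
            rmses.append(np.sqrt(np.mean(np.concatenate(sq_errs))))
        rows.append({"p": p, "median_cv_rmse": float(np.median(rmses))})
    profile = pd.DataFrame(rows)
    best = profile["median_cv_rmse"].min()
    tol = 1e-12 * max(best, 1.0)
    p_star = int(profile.loc[profile["median_cv_rmse"] <= best + tol, "p"].min())
    return p_star, profile
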