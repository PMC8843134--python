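"""Generalized regression neural network (Nadaraya-Watson kernel regression).

The GRNN stores its training exemplars (x_i, y_i) and predicts a query x
as the Gaussian-kernel weighted mean of the training targets,

    yhat(x) = sum_i y_i exp(-D_i^2 / (2 sigma^2)) / sum_i exp(-D_i^2 / (2 sigma^2)),
    D_i^2   = (x - x_i)^T (x - x_i),

with a single isotropic width parameter sigma. Predictions are convex
combinations of the training targets, so they can never leave
[min y_i, max y_i]; sigma -> 0 interpolates the exemplars and
sigma -> inf collapses every prediction to the training mean. The
evaluation subtracts the maximum exponent before exponentiating, which
makes the weights immune to underflow without changing the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: default bandwidth grid in scaled-feature units: spans interpolation to
#: oversmoothing on a [0, 1]^3 feature cube
DEFAULT_SIGMA_GRID = np.geomspace(0.01, 2.0, 20)


@dataclass
class GRNN:
    """Kernel-regression surrogate with width ``sigma`` (> 0)."""

    sigma: float
    X_: np.ndarray | None = field(default=None, repr=False)
    y_: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")

    def fit(self, X, y) -> "GRNN":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if len(X) != len(y) or len(y) == 0:
            raise ValueError("X and y must be non-empty and the same length")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("training data must be finite")
        self.X_, self.y_ = X, y
        return self

    def predict(self, Xq) -> np.ndarray:
        if self.X_ is None:
            raise ValueError("model is not fitted")
        Xq = np.asarray(Xq, dtype=float)
        scalar = Xq.ndim == 1
        Xq = np.atleast_2d(Xq)
        if not np.all(np.isfinite(Xq)):
            raise ValueError("query points must be finite")
        # squared Euclidean distances, (n_query, n_train)
        d2 = (
            (Xq**2).sum(axis=1)[:, None]
            + (self.X_**2).sum(axis=1)[None, :]
            - 2.0 * Xq @ self.X_.T
        )
        np.maximum(d2, 0.0, out=d2)
        expo = -d2 / (2.0 * self.sigma**2)
        expo -= expo.max(axis=1, keepdims=True)  # max exponent 0: no underflow
        w = np.exp(expo)
        yhat = (w @ self.y_) / w.sum(axis=1)
        return float(yhat[0]) if scalar else yhat

    def to_dict(self) -> dict:
        return {
            "sigma": float(self.sigma),
            "X": None if self.X_ is None else self.X_.tolist(),
            "y": None if self.y_ is None else self.y_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GRNN":
        m = cls(sigma=d["sigma"])
        if d.get("X") is not None:
            m.fit(np.array(d["X"]), np.array(d["y"]))
        return m


def grnn_predict(model: GRNN, query) -> float | np.ndarray:
    """Functional alias for :meth:`GRNN.predict`."""
    return model.predict(query)


def select_sigma(
    X, y, grid=None, folds=None, seed: int = 0, k: int = 5
) -> tuple[float, pd.DataFrame]:
    """Pick sigma minimizing cross-validated RMSE over a candidate grid.

    Ties (within 1e-12 relative) are broken toward the larger, smoother
    sigma. Returns ``(sigma_star, profile)`` where ``profile`` has columns
    ``sigma`` and ``cv_rmse`` for reporting.
    """
    from .preprocessing import kfold_split

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    grid = DEFAULT_SIGMA_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("sigma grid must be non-empty")
    if np.any(grid <= 0):
        raise ValueError("sigma candidates must be > 0")
    if folds is None:
        folds = kfold_split(len(y), k=k, seed=seed)
    folds = np.asarray(folds)

    rmses = np.empty(len(grid))
    for gi, sigma in enumerate(grid):
        sq_errs = []
        for f in np.unique(folds):
            test = folds == f
            model = GRNN(sigma=sigma).fit(X[~test], y[~test])
            sq_errs.append((model.predict(X[test]) - y[test]) ** 2)
        rmses[gi] = np.sqrt(np.mean(np.concatenate(sq_errs)))
    best = rmses.min()
    tol = 1e-12 * max(best, 1.0)
    sigma_star = float(grid[np.flatnonzero(rmses <= best + tol)].max())
    profile = pd.DataFrame({"sigma": grid, "cv_rmse": rmses})
    return sigma_star, profile
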