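"""Model-comparison criteria (R^2, RMSE, MBE) and cross-validated evaluation.

The three criteria compare observed o and predicted p vectors:

    RMSE = sqrt(mean (o - p)^2)
    MBE  = mean (p - o)              (predicted minus observed)
    R^2  = 1 - SS_res / SS_tot       (about the observed mean)

Under 5-fold cross-validation, each fold's model is fitted on the other
folds; "training" metrics pool the in-fold fitted predictions across
folds and "testing" metrics pool the held-out predictions, both computed
in original trait units after inverting any target transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .preprocessing import boxcox_fit


@dataclass
class Metrics:
    r2: float | None
    rmse: float
    mbe: float

    def as_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "mbe": self.mbe}


def compute_metrics(observed, predicted) -> Metrics:
    """R^2, RMSE and MBE of predictions against observations."""
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.size == 0 or o.shape != p.shape:
        raise ValueError("observed and predicted must be non-empty, same length")
    if not (np.all(np.isfinite(o)) and np.all(np.isfinite(p))):
        raise ValueError("metrics require finite vectors")
    resid = o - p
    rmse = float(np.sqrt(np.mean(resid**2)))
    mbe = float(np.mean(p - o))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("zero-variance observations: R^2 undefined")
        r2 = None
    else:
        r2 = float(1.0 - np.sum(resid**2) / ss_tot)
    return Metrics(r2=r2, rmse=rmse, mbe=mbe)


def cv_evaluate(
    make_model: Callable[[int], object],
    X,
    y,
    group_fold: np.ndarray,
    groups: np.ndarray | None = None,
    use_boxcox: bool = True,
) -> dict:
    """Pooled training/testing metrics under a shared fold assignment.

    Parameters
    ----------
    make_model
        ``make_model(fold_id)`` returns an unfitted estimator with
        ``fit(X, y)`` and ``predict(X)``.
    X, y
        Feature matrix (already scaled) and targets in original units.
    group_fold
        Fold id per group (e.g. per treatment).
    groups
        Group id per row of ``X``; defaults to one group per row. Rows of
        a group always land in the same fold, so replicates of a held-out
        treatment are never seen at fit time.
    use_boxcox
        Fit a Box-Cox transform to the *training* targets of each fold
        and model the transformed values; predictions are inverted back
        to original units before pooling.

    Returns a dict with pooled ``training``/``testing`` metrics, the raw
    pooled vectors, and per-fold sizes.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    group_fold = np.asarray(group_fold)
    groups = np.arange(len(y)) if groups is None else np.asarray(groups)
    row_fold = group_fold[groups]

    pools: dict[str, list] = {"obs_tr": [], "pred_tr": [], "obs_te": [], "pred_te": []}
    fold_sizes = []
    fold_ids = np.unique(row_fold)
    fold_ids = fold_ids[fold_ids >= 0]  # negative ids mark excluded rows
    for f in fold_ids:
        test = row_fold == f
        if (~test).sum() < 2 or test.sum() < 1:
            raise ValueError(f"fold {f} leaves fewer than 2 rows to fit on")
        fold_sizes.append(int(test.sum()))
        bc = boxcox_fit(y[~test]) if use_boxcox else None
        z_train = bc.forward(y[~test]) if bc else y[~test]
        model = make_model(int(f))
        model.fit(X[~test], z_train)
        pred_tr = model.predict(X[~test])
        pred_te = model.predict(X[test])
        if bc:
            pred_tr = bc.inverse(pred_tr)
            pred_te = bc.inverse(pred_te)
        pools["obs_tr"].append(y[~test])
        pools["pred_tr"].append(np.asarray(pred_tr, dtype=float))
        pools["obs_te"].append(y[test])
        pools["pred_te"].append(np.asarray(pred_te, dtype=float))

    obs_tr = np.concatenate(pools["obs_tr"])
    pred_tr = np.concatenate(pools["pred_tr"])
    obs_te = np.concatenate(pools["obs_te"])
    pred_te = np.concatenate(pools["pred_te"])
    return {
        "training": compute_metrics(obs_tr, pred_tr),
        "testing": compute_metrics(obs_te, pred_te),
        "pooled": {
            "training": (obs_tr, pred_tr),
            "testing": (obs_te, pred_te),
        },
        "fold_sizes": fold_sizes,
        "n": int(len(y)),
    }
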