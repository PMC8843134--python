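"""End-to-end analysis: load, preprocess, fit GRNN and MLP, compare, optimize.

The full run mirrors the study workflow: the factorial trait table is
loaded (fixture, user CSV or synthetic), replicate-level observations are
reconstructed from means and SEMs, both surrogate families are evaluated
under one shared 5-fold assignment over treatments, and for each trait
the family with the higher pooled testing R^2 is refitted on all data and
handed to the genetic algorithm as the objective over the dose box.
Dose reductions of each optimum are reported against a reference
treatment (default: the best-yield treatment, 200/300/50 g).

Every stochastic stage derives its seed from the single global seed by a
fixed offset, so a run is fully reproducible from its config echo.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataset as ds
from . import synthetic_data as sd
from .dataset import TRAITS, FertilizerLevels, TraitTable
from .descriptive import trait_correlations, upgma_cluster
from .ga import GAConfig, OptimizationResult, optimize
from .grnn import GRNN, select_sigma
from .metrics import cv_evaluate
from .mlp import MLPRegressor, select_hidden_size
from .preprocessing import (
    MinMaxScaler, PreprocessState, boxcox_fit, kfold_split, pca_outlier_flags,
)

log = logging.getLogger("fertopt")

# per-stage seed offsets from the global seed
SEED_OFFSETS = {
    "reconstruct": 1,
    "folds": 2,
    "mlp": 3,
    "ga": 10,  # + trait index
}

DEFAULT_REFERENCE = FertilizerLevels(200.0, 300.0, 50.0)


@dataclass
class RunConfig:
    source: str = "fixture"  # fixture | csv | synthetic
    data_path: str | None = None
    traits: tuple[str, ...] = TRAITS
    fit_granularity: str = "means"  # means | replicates
    ga_family: str = "auto"  # auto (higher testing R^2) | GRNN | MLP
    use_boxcox: bool = True
    outlier_threshold_sd: float = 3.0
    outlier_action: str = "flag"  # flag | remove
    cv_folds: int = 5
    sigma_grid: list | None = None
    mlp_candidates: tuple[int, ...] = tuple(range(1, 11))
    mlp_restarts: int = 5
    mlp_select_max_iter: int = 200
    ga: GAConfig = field(default_factory=GAConfig)
    reference: tuple[float, float, float] = tuple(DEFAULT_REFERENCE)
    outdir: str | None = None
    seed: int = 42

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ga"] = self.ga.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "ga" in d and isinstance(d["ga"], dict):
            ga = dict(d["ga"])
            if "bounds" in ga:
                ga["bounds"] = tuple(tuple(b) for b in ga["bounds"])
            d["ga"] = GAConfig(**ga)
        for key in ("traits", "mlp_candidates", "reference"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RunReport:
    metrics: pd.DataFrame
    selection: dict
    chosen_family: dict
    optimizations: dict
    reductions: dict
    correlations: pd.DataFrame
    cluster_labels: np.ndarray
    state: PreprocessState
    config: dict

    def metric(self, model: str, trait: str, split: str, name: str) -> float:
        row = self.metrics[
            (self.metrics.model == model)
            & (self.metrics.trait == trait)
            & (self.metrics.split == split)
        ]
        return float(row.iloc[0][name])


def _load_data(config: RunConfig) -> TraitTable:
    if config.source == "fixture":
        return ds.load_table1()
    if config.source == "csv":
        if not config.data_path:
            raise ValueError("source='csv' requires data_path")
        return ds.load_table(config.data_path)
    if config.source == "synthetic":
        return sd.generate_experiment(sd.default_specs(seed=config.seed))
    raise ValueError(f"unknown data source {config.source!r}")


def _design_bounds(table: TraitTable) -> tuple:
    lv = table.levels
    return tuple((float(lv[:, i].min()), float(lv[:, i].max())) for i in range(3))


def compute_reduction(optimal, reference) -> tuple:
    """Per-factor percent dose reduction, 100 * (1 - optimal / reference).

    Factors with a zero reference dose are undefined and reported None.
    """
    out = []
    for opt, ref in zip(optimal, reference):
        if ref == 0:
            out.append(None)
        else:
            out.append(100.0 * (1.0 - float(opt) / float(ref)))
    return tuple(out)


def _fit_objective(family, trait_X, trait_y, scaler, sigma, p_star, seed,
                   use_boxcox):
    """Refit the winning family on all data; return objective in trait units."""
    bc = boxcox_fit(trait_y) if use_boxcox else None
    z = bc.forward(trait_y) if bc else trait_y
    if family == "GRNN":
        model = GRNN(sigma=sigma).fit(scaler.transform(trait_X), z)
    else:
        model = MLPRegressor(p=p_star, seed=seed).fit(scaler.transform(trait_X), z)

    def objective(levels):
        levels = np.atleast_2d(np.asarray(levels, dtype=float))
        pred = model.predict(scaler.transform(levels))
        pred = np.atleast_1d(pred)
        return bc.inverse(pred) if bc else pred

    return objective, model, bc


def run_full_analysis(config: RunConfig) -> RunReport:
    log.info("loading data (source=%s)", config.source)
    table = _load_data(config)
    if table.replicates is None:
        table = ds.reconstruct_replicates(
            table, seed=config.seed + SEED_OFFSETS["reconstruct"]
        )

    # outlier screen on [doses | trait means]
    screen = np.column_stack(
        [table.levels] + [table.means(t) for t in TRAITS]
    )
    flags = pca_outlier_flags(screen, threshold_sd=config.outlier_threshold_sd)
    if len(flags):
        log.warning("outlier screen flagged treatments at rows %s", list(flags))
    n_treat = len(table.records)
    # removal drops flagged treatments from the fitting data only; the
    # table itself keeps its complete factorial
    if config.outlier_action == "remove":
        kept_treatments = np.setdiff1d(np.arange(n_treat), flags)
    else:
        kept_treatments = np.arange(n_treat)

    fold_of_treatment = np.full(n_treat, -1, dtype=int)
    fold_of_treatment[kept_treatments] = kfold_split(
        len(kept_treatments), k=config.cv_folds,
        seed=config.seed + SEED_OFFSETS["folds"],
    )
    scaler = MinMaxScaler.from_bounds(_design_bounds(table))

    state = PreprocessState(
        scaler=scaler,
        outlier_flags=[int(i) for i in flags],
        folds=fold_of_treatment,
        seed=config.seed,
        options={
            "boxcox": config.use_boxcox,
            "outlier_threshold_sd": config.outlier_threshold_sd,
            "outlier_action": config.outlier_action,
            "cv_folds": config.cv_folds,
            "fit_granularity": config.fit_granularity,
        },
    )

    level_lookup = {
        tuple(row): i for i, row in enumerate(map(tuple, table.levels))
    }

    metric_rows = []
    selection: dict = {}
    chosen: dict = {}
    optimizations: dict = {}
    reductions: dict = {}

    for ti, trait in enumerate(config.traits):
        if config.fit_granularity == "replicates":
            X, y = table.replicate_arrays(trait)
            groups = np.array([level_lookup[tuple(r)] for r in map(tuple, X)])
        else:
            X, y = table.levels, table.means(trait)
            groups = np.arange(len(y))
        keep_rows = fold_of_treatment[groups] >= 0
        X, y, groups = X[keep_rows], y[keep_rows], groups[keep_rows]
        Xs = scaler.transform(X)
        row_fold = fold_of_treatment[groups]

        bc_full = boxcox_fit(y) if config.use_boxcox else None
        state.boxcox[trait] = bc_full
        z = bc_full.forward(y) if bc_full else y

        sigma_star, sigma_profile = select_sigma(
            Xs, z, grid=config.sigma_grid, folds=row_fold
        )
        p_star, p_profile = select_hidden_size(
            Xs, z,
            candidates=config.mlp_candidates,
            folds=row_fold,
            restarts=config.mlp_restarts,
            seed=config.seed + SEED_OFFSETS["mlp"],
            max_iter=config.mlp_select_max_iter,
        )
        selection[trait] = {
            "sigma": sigma_star,
            "sigma_profile": sigma_profile,
            "p": p_star,
            "p_profile": p_profile,
        }
        log.info("%s: sigma*=%.4g, p*=%d", trait, sigma_star, p_star)

        results = {}
        results["GRNN"] = cv_evaluate(
            lambda f: GRNN(sigma=sigma_star),
            X=Xs, y=y, group_fold=fold_of_treatment, groups=groups,
            use_boxcox=config.use_boxcox,
        )
        results["MLP"] = cv_evaluate(
            lambda f: MLPRegressor(
                p=p_star, seed=config.seed + SEED_OFFSETS["mlp"] + 100 * f
            ),
            X=Xs, y=y, group_fold=fold_of_treatment, groups=groups,
            use_boxcox=config.use_boxcox,
        )
        for model_name, res in results.items():
            for split in ("training", "testing"):
                m = res[split]
                metric_rows.append(
                    dict(model=model_name, trait=trait, split=split,
                         r2=m.r2, rmse=m.rmse, mbe=m.mbe, n=res["n"])
                )

        if config.ga_family == "auto":
            fam = max(
                results, key=lambda name: (results[name]["testing"].r2 or -np.inf)
            )
        elif config.ga_family in results:
            fam = config.ga_family
        else:
            raise ValueError(f"unknown ga_family {config.ga_family!r}")
        chosen[trait] = fam
        log.info(
            "%s: GA objective family %s (testing R2 %.3f vs %.3f)",
            trait, fam,
            results[fam]["testing"].r2,
            results["GRNN" if fam == "MLP" else "MLP"]["testing"].r2,
        )

        objective, _, _ = _fit_objective(
            fam, X, y, scaler, sigma_star, p_star,
            seed=config.seed + SEED_OFFSETS["mlp"], use_boxcox=config.use_boxcox,
        )
        ga_conf = dataclasses.replace(
            config.ga,
            bounds=_design_bounds(table),
            seed=config.seed + SEED_OFFSETS["ga"] + ti,
        )
        result = optimize(objective, ga_conf)
        optimizations[trait] = result
        reductions[trait] = compute_reduction(result.best_levels, config.reference)
        log.info(
            "%s: GA best %.3f at N=%.1f K=%.1f Mg=%.1f", trait,
            result.best_value, *result.best_levels,
        )

    report = RunReport(
        metrics=pd.DataFrame(metric_rows),
        selection=selection,
        chosen_family=chosen,
        optimizations=optimizations,
        reductions=reductions,
        correlations=trait_correlations(table),
        cluster_labels=upgma_cluster(table, groups=min(5, n_treat)).labels,
        state=state,
        config=config.to_dict(),
    )
    if config.outdir:
        _write_report(report, Path(config.outdir))
    return report


def _write_report(report: RunReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.metrics.to_csv(outdir / "metrics.csv", index=False)
    report.correlations.to_csv(outdir / "correlations.csv")
    (outdir / "preprocess_state.json").write_text(report.state.to_json())
    summary = {
        "config": report.config,
        "chosen_family": report.chosen_family,
        "selection": {
            t: {"sigma": s["sigma"], "p": s["p"]}
            for t, s in report.selection.items()
        },
        "reductions": report.reductions,
        "optima": {
            t: {"levels": r.best_levels.tolist(), "value": r.best_value}
            for t, r in report.optimizations.items()
        },
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=2))
    for trait, res in report.optimizations.items():
        (outdir / f"optimization_{trait}.json").write_text(
            json.dumps(res.to_dict(), indent=2)
        )
        pd.DataFrame(
            {"generation": np.arange(len(res.history_best)),
             "best": res.history_best, "mean": res.history_mean}
        ).to_csv(outdir / f"convergence_{trait}.csv", index=False)
    log.info("wrote report to %s", outdir)
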