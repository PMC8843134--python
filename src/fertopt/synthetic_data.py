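"""Synthetic factorial dose-response experiments with a known optimum.

Ground truth is a quadratic response surface with an N x K interaction,

    f(n, k, mg) = c0 + sum_f b_f x_f + sum_f a_f x_f^2 + g * n * k,

which captures the phenomenology of the real trial — strong nitrogen and
potassium main effects with diminishing returns, a positive N x K synergy
and a weak magnesium effect — while keeping a closed-form/brute-force
oracle for the optimum. Replicate noise is i.i.d. Gaussian at the scale of
the fixture's SEMs, so generated tables are drop-in inputs for every
downstream stage (preprocessing, GRNN, MLP, GA).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize as sopt

from .dataset import (
    LEVEL_COLS, MEAN_COL, SEM_COL, TRAITS, FertilizerLevels, TraitTable,
)

#: the fixture's factor grids (grams per plant)
DEFAULT_DESIGN = (
    (0.0, 100.0, 200.0),
    (0.0, 100.0, 200.0, 300.0),
    (0.0, 50.0, 100.0),
)

DEFAULT_BOUNDS = ((0.0, 200.0), (0.0, 300.0), (0.0, 100.0))


@dataclass
class SurfaceSpec:
    """Parameters of one quadratic-with-interaction trait surface.

    All coefficients are in trait units per (gram, gram^2); ``noise_sd``
    is the replicate-level noise SD in trait units. Defaults are
    calibrated so the FY-like surface spans roughly 40-125 kg/plant with
    SEMs of a few kg — the signal-to-noise regime of the fixture.
    """

    intercept: float = 42.0
    linear: tuple[float, float, float] = (0.30, 0.10, 0.06)
    quadratic: tuple[float, float, float] = (-9.0e-4, -2.5e-4, -6.0e-4)
    interaction_nk: float = 6.5e-4
    noise_sd: float = 6.0
    n_reps: int = 3
    seed: int = 0
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("bounds must satisfy low < high per factor")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["linear"] = list(self.linear)
        d["quadratic"] = list(self.quadratic)
        d["bounds"] = [list(b) for b in self.bounds]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SurfaceSpec":
        d = dict(d)
        for key in ("linear", "quadratic"):
            if key in d:
                d[key] = tuple(d[key])
        if "bounds" in d:
            d["bounds"] = tuple(tuple(b) for b in d["bounds"])
        return cls(**d)


def default_specs(seed: int = 0) -> dict[str, SurfaceSpec]:
    """FY/FL/NRPS surface specs resembling the fixture's trait scales."""
    fy = SurfaceSpec(seed=seed)
    fl = SurfaceSpec(
        intercept=9.6,
        linear=(0.055, 0.020, 0.014),
        quadratic=(-1.6e-4, -5.0e-5, -1.4e-4),
        interaction_nk=1.2e-4,
        noise_sd=1.0,
        seed=seed + 1,
    )
    nrps = SurfaceSpec(
        intercept=5.8,
        linear=(0.030, 0.011, 0.008),
        quadratic=(-9.0e-5, -2.7e-5, -8.0e-5),
        interaction_nk=6.5e-5,
        noise_sd=0.45,
        seed=seed + 2,
    )
    return {"FY": fy, "FL": fl, "NRPS": nrps}


def _as_matrix(levels) -> np.ndarray:
    x = np.asarray(levels, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != 3:
        raise ValueError("levels must be (n, 3) dose triples")
    return x


def true_surface(spec: SurfaceSpec, levels) -> np.ndarray | float:
    """Evaluate the noiseless surface at one or many dose triples."""
    x = _as_matrix(levels)
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
        raise ValueError("levels outside the spec bounds")
    b = np.asarray(spec.linear)
    a = np.asarray(spec.quadratic)
    y = (
        spec.intercept
        + x @ b
        + (x**2) @ a
        + spec.interaction_nk * x[:, 0] * x[:, 1]
    )
    scalar = np.asarray(levels, dtype=float).ndim == 1
    return float(y[0]) if scalar else y


def generate_experiment(
    specs: SurfaceSpec | dict[str, SurfaceSpec],
    design: tuple = DEFAULT_DESIGN,
) -> TraitTable:
    """Simulate a full-factorial replicated experiment.

    ``specs`` is either one :class:`SurfaceSpec` (reused, with per-trait
    seed offsets, for all three traits) or a mapping trait -> spec. Per
    design cell, ``n_reps`` replicates of ``true_surface + N(0, noise_sd^2)``
    are drawn; treatment means and SEMs are computed from the replicates.
    Deterministic given the spec seeds.
    """
    if isinstance(specs, SurfaceSpec):
        specs = {
            t: SurfaceSpec.from_dict({**specs.to_dict(), "seed": specs.seed + i})
            for i, t in enumerate(TRAITS)
        }
    if any(len(axis) == 0 for axis in design) or len(design) != 3:
        raise ValueError("design must provide non-empty levels for all 3 factors")
    grid = np.array(
        [(n, k, mg) for n in design[0] for k in design[1] for mg in design[2]],
        dtype=float,
    )
    n_reps = {specs[t].n_reps for t in TRAITS}
    if len(n_reps) != 1:
        raise ValueError("all trait specs must share n_reps")
    r = n_reps.pop()

    rep_rows = []
    rec = {c: grid[:, i] for i, c in enumerate(LEVEL_COLS)}
    for trait in TRAITS:
        spec = specs[trait]
        rng = np.random.default_rng(spec.seed)
        mu = true_surface(spec, grid)
        draws = mu[:, None] + rng.standard_normal((len(grid), r)) * spec.noise_sd
        rec[MEAN_COL[trait]] = draws.mean(axis=1)
        rec[SEM_COL[trait]] = draws.std(axis=1, ddof=1) / np.sqrt(r) if r > 1 else np.zeros(len(grid))
        for cell in range(len(grid)):
            for i in range(r):
                rep_rows.append(
                    dict(n_g=grid[cell, 0], k_g=grid[cell, 1], mg_g=grid[cell, 2],
                         trait=trait, rep=i, value=float(draws[cell, i]))
                )
    table = TraitTable(
        records=pd.DataFrame(rec),
        replicates=pd.DataFrame(rep_rows),
        n_reps=r,
        provenance={"source": "synthetic",
                    "specs": {t: specs[t].to_dict() for t in TRAITS}},
    )
    return table


def true_optimum(
    spec: SurfaceSpec, grid_points: int = 201, refine: bool = True
) -> tuple[FertilizerLevels, float]:
    """Brute-force argmax of the surface over its bound box.

    A dense lexicographically ordered grid (``grid_points`` per axis) is
    scanned; ties go to the lexicographically smallest grid point. A local
    L-BFGS-B polish from the best grid point is kept only if it strictly
    improves the value.
    """
    axes = [np.linspace(lo, hi, grid_points) for lo, hi in spec.bounds]
    best_val = -np.inf
    best_pt = None
    # chunk over the first axis to bound memory on dense grids
    kk, mm = np.meshgrid(axes[1], axes[2], indexing="ij")
    flat = np.column_stack([kk.ravel(), mm.ravel()])
    for n_val in axes[0]:
        pts = np.column_stack([np.full(len(flat), n_val), flat])
        vals = true_surface(spec, pts)
        i = int(np.argmax(vals))
        if vals[i] > best_val:  # strict: preserves lexicographic tie-break
            best_val = float(vals[i])
            best_pt = pts[i]
    if refine:
        res = sopt.minimize(
            lambda x: -true_surface(spec, x),
            best_pt,
            method="L-BFGS-B",
            bounds=spec.bounds,
        )
        if res.success and -res.fun > best_val + 1e-12:
            best_val = float(-res.fun)
            best_pt = res.x
    return FertilizerLevels(*map(float, best_pt)), best_val
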