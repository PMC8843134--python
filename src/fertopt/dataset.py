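"""Factorial fertilizer-trial data: typed access and replicate reconstruction.

The packaged fixture holds the 36-treatment greenhouse banana experiment:
a full 3x4x3 factorial of nitrogen (0/100/200 g per plant), potassium
(0/100/200/300 g) and magnesium (0/50/100 g), with treatment means and
standard errors of the mean (SEM, 3 replications) for three traits:

* FY   — fruit yield, kg per plant
* FL   — fruit length, cm
* NRPS — number of rows per spike

Only means and SEMs are published, so replicate-level observations are
reconstructed as moment-matched normal draws when a fitting stage needs
them (see :func:`reconstruct_replicates`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

TRAITS = ("FY", "FL", "NRPS")

#: records-frame column holding the mean / SEM of each trait
MEAN_COL = {"FY": "fy_mean", "FL": "fl_mean", "NRPS": "nrps_mean"}
SEM_COL = {"FY": "fy_sem", "FL": "fl_sem", "NRPS": "nrps_sem"}

LEVEL_COLS = ["n_g", "k_g", "mg_g"]

RECORD_COLUMNS = LEVEL_COLS + [
    "fy_mean", "fy_sem", "fl_mean", "fl_sem", "nrps_mean", "nrps_sem",
]

#: design dose box for the fixture experiment, grams per plant
DESIGN_BOUNDS = ((0.0, 200.0), (0.0, 300.0), (0.0, 100.0))


class FertilizerLevels(NamedTuple):
    """A dose triple in grams per plant."""

    n_g: float
    k_g: float
    mg_g: float


@dataclass
class TraitTable:
    """A factorial trait table: one row per treatment, optional replicates.

    Parameters
    ----------
    records
        One row per treatment with columns ``n_g, k_g, mg_g`` and
        ``<trait>_mean`` / ``<trait>_sem`` for each trait, sorted
        lexicographically by dose levels.
    replicates
        Optional long-format replicate frame with columns
        ``n_g, k_g, mg_g, trait, rep, value``.
    n_reps
        Number of replications behind each mean/SEM.
    provenance
        Free-form origin metadata (fixture path, reconstruction seed, ...).
    """

    records: pd.DataFrame
    replicates: pd.DataFrame | None = None
    n_reps: int = 3
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records frame is missing columns: {missing}")
        self.records = (
            self.records.sort_values(LEVEL_COLS).reset_index(drop=True)
        )
        validate_factorial(self.records)
        means = self.records[[MEAN_COL[t] for t in TRAITS]].to_numpy()
        sems = self.records[[SEM_COL[t] for t in TRAITS]].to_numpy()
        if not np.all(means > 0):
            raise ValueError("trait means must be positive")
        if not np.all(sems >= 0):
            raise ValueError("trait SEMs must be non-negative")

    @property
    def levels(self) -> np.ndarray:
        """(n_treatments, 3) array of dose triples."""
        return self.records[LEVEL_COLS].to_numpy(dtype=float)

    def means(self, trait: str) -> np.ndarray:
        return self.records[MEAN_COL[_check_trait(trait)]].to_numpy(dtype=float)

    def sems(self, trait: str) -> np.ndarray:
        return self.records[SEM_COL[_check_trait(trait)]].to_numpy(dtype=float)

    def replicate_arrays(self, trait: str) -> tuple[np.ndarray, np.ndarray]:
        """Replicate-level (X, y) for one trait.

        Returns the (n_reps * n_treatments, 3) dose matrix and matching
        trait values. Requires :attr:`replicates`.
        """
        trait = _check_trait(trait)
        if self.replicates is None:
            raise ValueError(
                "table has no replicates; call reconstruct_replicates() first"
            )
        sub = self.replicates[self.replicates["trait"] == trait]
        return sub[LEVEL_COLS].to_numpy(dtype=float), sub["value"].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def _check_trait(trait: str) -> str:
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    return trait


def validate_factorial(records: pd.DataFrame) -> None:
    """Require a complete full-factorial grid with no duplicate treatments."""
    triples = list(map(tuple, records[LEVEL_COLS].to_numpy()))
    if len(set(triples)) != len(triples):
        raise ValueError("duplicate treatment level triples in records")
    axes = [sorted(records[c].unique()) for c in LEVEL_COLS]
    expected = {
        (a, b, c) for a in axes[0] for b in axes[1] for c in axes[2]
    }
    if set(triples) != expected:
        raise ValueError(
            "records do not form a full factorial over their level sets"
        )


def _fixture_path() -> Path:
    return Path(str(resources.files("fertopt").joinpath("data/table1.csv")))


def load_table(path: str | Path, n_reps: int = 3) -> TraitTable:
    """Load a trait table from a CSV in the fixture schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trait-table CSV not found: {path}")
    try:
        records = pd.read_csv(path)
        table = TraitTable(records=records, n_reps=n_reps)
    except Exception as exc:  # corrupt fixture is a fatal load error
        raise ValueError(f"could not load trait table from {path}: {exc}") from exc
    table.provenance = {"source": str(path)}
    return table


def load_table1() -> TraitTable:
    """Load the packaged 36-treatment banana factorial fixture."""
    return load_table(_fixture_path(), n_reps=3)


def argmax_trait(table: TraitTable, trait: str) -> tuple[FertilizerLevels, float]:
    """Treatment with the highest mean for ``trait``.

    Ties are broken toward the lexicographically smallest (N, K, Mg)
    triple; records are stored level-sorted, so the first maximum wins.
    """
    values = table.means(trait)
    idx = int(np.argmax(values))
    row = table.records.iloc[idx]
    levels = FertilizerLevels(float(row.n_g), float(row.k_g), float(row.mg_g))
    return levels, float(values[idx])


def reconstruct_replicates(table: TraitTable, seed: int) -> TraitTable:
    """Moment-matched replicate reconstruction from means and SEMs.

    For each treatment x trait, ``n_reps`` values are drawn from a normal
    distribution and then affinely corrected so the sample mean equals the
    printed mean exactly and the sample standard deviation (ddof=1) equals
    ``SEM * sqrt(n_reps)`` — the identity relating the SEM of ``r``
    replicates to their SD. Deterministic given ``seed``.
    """
    r = table.n_reps
    if r < 2:
        raise ValueError("replicate reconstruction requires n_reps >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for _, rec in table.records.iterrows():
        for trait in TRAITS:
            mean = float(rec[MEAN_COL[trait]])
            sd = float(rec[SEM_COL[trait]]) * np.sqrt(r)
            z = rng.standard_normal(r)
            zc = z - z.mean()
            zsd = zc.std(ddof=1)
            if sd == 0.0 or zsd == 0.0:
                vals = np.full(r, mean)
            else:
                vals = mean + zc / zsd * sd
            for i, v in enumerate(vals):
                rows.append(
                    dict(n_g=rec.n_g, k_g=rec.k_g, mg_g=rec.mg_g,
                         trait=trait, rep=i, value=float(v))
                )
    replicates = pd.DataFrame(rows)
    prov = dict(table.provenance)
    prov["reconstruction_seed"] = int(seed)
    return TraitTable(
        records=table.records.copy(),
        replicates=replicates,
        n_reps=r,
        provenance=prov,
    )
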