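"""Reading, writing and validating feeding-experiment datasets.

A dataset is two long-format tables:

``trials.csv`` — one row per animal x plant:
    animal_id, species, replicate, plant, ntot

``feces.csv`` — one row per animal x collection time x plant:
    animal_id, time_h, defec, w_g, wd_g, wg_g, plant, y_count, g_count

Weights are per animal x time (repeated across the plant rows of that
time); ``defec = 0`` rows carry zero weights and counts.  Times are hours
since the last seed ingestion (t = 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ObservationGrid

__all__ = [
    "FeedingDataset",
    "SchemaError",
    "ValidationError",
    "TRIALS_COLUMNS",
    "FECES_COLUMNS",
    "load_and_validate",
    "write_dataset",
    "read_model_spec",
    "write_model_spec",
]


def write_model_spec(spec, path: str | Path) -> None:
    """Serialize a ModelSpec (priors, switches, pinned parameters) as YAML."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=True)


def read_model_spec(path: str | Path):
    import yaml

    from .model import ModelSpec

    with open(path) as fh:
        return ModelSpec.from_dict(yaml.safe_load(fh) or {})

TRIALS_COLUMNS = ["animal_id", "species", "replicate", "plant", "ntot"]
FECES_COLUMNS = [
    "animal_id", "time_h", "defec", "w_g", "wd_g", "wg_g", "plant", "y_count", "g_count",
]

FORMAT_VERSION = "seedpassage-dataset v1"


class SchemaError(ValueError):
    """A table's columns do not match the declared schema."""


class ValidationError(ValueError):
    """Row-level invariant violations in an otherwise well-formed table."""


@dataclass
class FeedingDataset:
    """A validated feeding experiment: trials, feces records and the grid."""

    trials: pd.DataFrame
    feces: pd.DataFrame
    grid: ObservationGrid = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.grid is None:
            times = np.sort(self.feces["time_h"].unique())
            self.grid = ObservationGrid.from_times(times)
        validate(self.trials, self.feces, self.grid)

    @property
    def species(self) -> list[str]:
        return sorted(self.trials["species"].unique())

    @property
    def plants(self) -> list[str]:
        return sorted(self.trials["plant"].unique())

    @property
    def animals(self) -> list[str]:
        return list(self.trials["animal_id"].unique())

    def species_of(self) -> dict[str, str]:
        return dict(self.trials.drop_duplicates("animal_id")[["animal_id", "species"]].values)

    def cell_arrays(self, animal_id: str, plant: str) -> dict[str, np.ndarray]:
        """Time-ordered observation arrays for one animal x plant."""
        rows = self.feces[(self.feces.animal_id == animal_id) & (self.feces.plant == plant)]
        rows = rows.set_index("time_h").reindex(self.grid.times)
        if rows.isna().any().any():
            raise ValidationError(f"missing collection times for {animal_id} x {plant}")
        defec = rows["defec"].to_numpy(dtype=int)
        w = rows["w_g"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            wd = np.where(defec == 1, rows["wd_g"].to_numpy(float) / w, 0.0)
            wg_abs = np.where(defec == 1, rows["wg_g"].to_numpy(float) / w, 0.0)
            wg = np.where(defec == 1, wg_abs / (1.0 - wd), 0.0)
        return {
            "defec": defec,
            "wd": wd,
            "wg": wg,
            "y": rows["y_count"].to_numpy(dtype=int),
            "g": rows["g_count"].to_numpy(dtype=int),
        }

    def ntot(self, animal_id: str, plant: str) -> int:
        sel = self.trials[(self.trials.animal_id == animal_id) & (self.trials.plant == plant)]
        if len(sel) != 1:
            raise ValidationError(f"expected one trial row for {animal_id} x {plant}")
        return int(sel["ntot"].iloc[0])


def _check_schema(df: pd.DataFrame, expected: list[str], name: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{name}: column mismatch (missing: {missing or 'none'}, unexpected: {extra or 'none'})"
        )


def validate(trials: pd.DataFrame, feces: pd.DataFrame, grid: ObservationGrid) -> None:
    """Enforce every row-level invariant; raise listing offending rows."""
    _check_schema(trials, TRIALS_COLUMNS, "trials")
    _check_schema(feces, FECES_COLUMNS, "feces")
    problems: list[str] = []

    if (trials["ntot"] < 0).any():
        bad = trials.index[trials["ntot"] < 0].tolist()
        problems.append(f"trials rows {bad}: negative ntot")
    dup = trials.duplicated(["animal_id", "plant"])
    if dup.any():
        problems.append(f"trials rows {trials.index[dup].tolist()}: duplicate animal x plant")

    known = set(map(tuple, trials[["animal_id", "plant"]].values))
    for idx, r in feces.iterrows():
        if (r.animal_id, r.plant) not in known:
            problems.append(f"feces row {idx}: unknown animal x plant {(r.animal_id, r.plant)}")
            continue
        if r.defec not in (0, 1):
            problems.append(f"feces row {idx}: defec must be 0 or 1")
        elif r.defec == 0:
            if r.w_g != 0 or r.wd_g != 0 or r.wg_g != 0 or r.y_count != 0 or r.g_count != 0:
                problems.append(f"feces row {idx}: nonzero weights/counts with defec = 0")
        else:
            if not (r.w_g > 0 and r.wd_g > 0 and r.wg_g > 0):
                problems.append(f"feces row {idx}: defec = 1 requires positive weights")
            elif not (r.wd_g + r.wg_g <= r.w_g * (1 + 1e-9)):  # tolerate CSV rounding
                problems.append(f"feces row {idx}: sample weights exceed whole-feces weight")
        if r.y_count < 0 or r.g_count < 0:
            problems.append(f"feces row {idx}: negative counts")
        if float(r.time_h) not in set(grid.times):
            problems.append(f"feces row {idx}: time {r.time_h} not on the collection grid")
    if problems:
        raise ValidationError("; ".join(problems[:20]) + ("; ..." if len(problems) > 20 else ""))


def load_and_validate(trials_path: str | Path, feces_path: str | Path) -> FeedingDataset:
    """Read the two CSVs and return a validated dataset."""
    for p in (trials_path, feces_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    trials = pd.read_csv(trials_path, comment="#")
    feces = pd.read_csv(feces_path, comment="#")
    return FeedingDataset(trials=trials, feces=feces)


def write_dataset(dataset, outdir: str | Path, truth: dict | None = None) -> dict[str, Path]:
    """Write trials.csv + feces.csv (and truth.json when latent truth is
    given) under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": outdir / "trials.csv",
        "feces": outdir / "feces.csv",
    }
    for key, df in (("trials", dataset.trials), ("feces", dataset.feces)):
        with open(paths[key], "w") as fh:
            fh.write(f"# {FORMAT_VERSION}\n")
            df.to_csv(fh, index=False)
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1)
    return paths
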