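"""Tidy-CSV readers and writers and the in-memory dataset container.

Three tables describe one experiment:

``plants.csv``
    plant_id, genotype, regime, block, initial_fresh_g, final_fresh_g,
    rdw_g, sdw_g — one row per harvested plant.
``pot_weights.csv``
    pot_id, plant_id, regime, block, day, weight_kg, is_control,
    post_irrigation — the gravimetric time series; control pots have an
    empty plant_id and is_control = True.
``root_segments.csv``
    plant_id, depth_cm, length_mm, diameter_mm — one row per scanned root
    segment.

CSV dialect: comma-separated, UTF-8, '.' decimal, header row mandatory;
missing values are empty cells and are read back as missing, never as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .water_accounting import PotWeightSeries

logger = logging.getLogger(__name__)

__all__ = ["SchemaError", "ExperimentData", "read_tables", "write_tables"]

PLANTS_COLUMNS = {
    "plant_id": str,
    "genotype": str,
    "regime": str,
    "block": int,
    "initial_fresh_g": float,
    "final_fresh_g": float,
    "rdw_g": float,
    "sdw_g": float,
}
POT_WEIGHTS_COLUMNS = {
    "pot_id": str,
    "plant_id": str,
    "regime": str,
    "block": int,
    "day": float,
    "weight_kg": float,
    "is_control": bool,
    "post_irrigation": bool,
}
SEGMENTS_COLUMNS = {
    "plant_id": str,
    "depth_cm": float,
    "length_mm": float,
    "diameter_mm": float,
}

_SCHEMAS = {
    "plants": PLANTS_COLUMNS,
    "pot_weights": POT_WEIGHTS_COLUMNS,
    "root_segments": SEGMENTS_COLUMNS,
}


class SchemaError(ValueError):
    """A table is missing a required column or holds an unparseable cell."""


@dataclass
class ExperimentData:
    """One experiment: plant records, pot-weight series and root segments."""

    plants: pd.DataFrame
    pot_weights: pd.DataFrame
    root_segments: pd.DataFrame

    def __post_init__(self) -> None:
        for name, frame in (
            ("plants", self.plants),
            ("pot_weights", self.pot_weights),
            ("root_segments", self.root_segments),
        ):
            _validate(frame, name)

    def plant_series(self, plant_id: str) -> PotWeightSeries:
        rows = self.pot_weights[self.pot_weights["plant_id"] == plant_id]
        if rows.empty:
            raise KeyError(f"no pot-weight series for plant {plant_id}")
        rows = rows.sort_values(["day", "post_irrigation"])
        return PotWeightSeries(
            pot_id=str(rows["pot_id"].iloc[0]),
            days=rows["day"].to_numpy(float),
            weights=rows["weight_kg"].to_numpy(float),
            is_control=False,
            post_irrigation=rows["post_irrigation"].to_numpy(bool),
        )

    def control_series(self, regime: str, block: int | None = None) -> PotWeightSeries:
        rows = self.pot_weights[
            self.pot_weights["is_control"] & (self.pot_weights["regime"] == regime)
        ]
        if block is not None and (rows["block"] == block).any():
            rows = rows[rows["block"] == block]
        if rows.empty:
            raise KeyError(f"no control pot for regime {regime}")
        first = rows["pot_id"].iloc[0]
        rows = rows[rows["pot_id"] == first].sort_values("day")
        return PotWeightSeries(
            pot_id=str(first),
            days=rows["day"].to_numpy(float),
            weights=rows["weight_kg"].to_numpy(float),
            is_control=True,
        )

    def segments_for(self, plant_id: str) -> pd.DataFrame:
        return self.root_segments[self.root_segments["plant_id"] == plant_id]


def _validate(frame: pd.DataFrame, name: str) -> pd.DataFrame:
    schema = _SCHEMAS[name]
    missing = set(schema) - set(frame.columns)
    if missing:
        raise SchemaError(f"{name}: missing column(s) {sorted(missing)}")
    for column, kind in schema.items():
        if kind in (float, int):
            try:
                frame[column] = pd.to_numeric(frame[column])
            except (ValueError, TypeError) as exc:
                bad = frame.index[
                    pd.to_numeric(frame[column], errors="coerce").isna()
                    & frame[column].notna()
                ]
                row = int(bad[0]) if len(bad) else -1
                raise SchemaError(
                    f"{name}.{column}: non-numeric cell at row {row}"
                ) from exc
        elif kind is bool:
            frame[column] = frame[column].astype(bool)
        else:
            frame[column] = frame[column].astype("string").fillna("")
    return frame


def read_tables(directory: str | Path) -> ExperimentData:
    """Read and validate the three experiment tables from ``directory``."""
    directory = Path(directory)
    frames = {}
    for name in _SCHEMAS:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"required table missing: {path}")
        frames[name] = pd.read_csv(path)
        logger.info("read %s: %d rows", path.name, len(frames[name]))
    data = ExperimentData(
        plants=frames["plants"],
        pot_weights=frames["pot_weights"],
        root_segments=frames["root_segments"],
    )
    if data.root_segments.empty:
        logger.warning("root_segments.csv is empty: all root traits will be zero")
    return data


def write_tables(data: ExperimentData, directory: str | Path) -> None:
    """Write the three experiment tables as tidy CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, frame in (
        ("plants", data.plants),
        ("pot_weights", data.pot_weights),
        ("root_segments", data.root_segments),
    ):
        frame.to_csv(directory / f"{name}.csv", index=False)
        logger.info("wrote %s.csv: %d rows", name, len(frame))


def frame_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    """Loss-free round-trip check used by tests and the manifest."""
    try:
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True), check_dtype=False
        )
    except AssertionError:
        return False
    return True
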