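"""Gravimetric water-use and water-productivity accounting.

Water use (WU) of a potted plant is estimated from successive pot
weighings, corrected for drainage/evaporation measured on unplanted
control pots and for the plant's own fresh-biomass gain (PBG):

    WU = sum_i [ (PW_{i-1} - PW_i) - (CPW_{i-1} - CPW_i) - PBG * dt_i ]

where PW and CPW are the planted and control pot weights (kg), the sum
runs over successive measurement intervals, and the PBG term (g/day,
converted to kg) removes weight gained as plant tissue rather than lost
as water.  With 1 kg of water == 1 L, WU is reported in litres.

Well-watered pots are refilled to field capacity at irrigation events;
such a refill appears in the series as two entries on the same day (the
pre-irrigation and post-irrigation weight).  Refill jumps carry no
information about transpiration, so only intervals that span time
(dt > 0) enter the sum — the water added at a refill is thereby excluded
while the water transpired between weighings is kept.

Water productivity is dry biomass per unit water: WP = (RDW + SDW) / WU
in g/L, numerically equal to kg m^-3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentError",
    "PotWeightSeries",
    "plant_biomass_gain",
    "water_use",
    "water_productivity",
    "root_shoot_ratio",
    "water_results_table",
]


class AlignmentError(ValueError):
    """Raised when planted and control series cannot be aligned by day."""


@dataclass(frozen=True)
class PotWeightSeries:
    """Dated weights of a single pot.

    ``days`` is nondecreasing; a day may appear twice when the pot was
    weighed before and after an irrigation refill, in which case
    ``post_irrigation`` distinguishes the two entries.
    """

    pot_id: str
    days: np.ndarray
    weights: np.ndarray
    is_control: bool = False
    post_irrigation: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if days.ndim != 1 or weights.shape != days.shape:
            raise ValueError("days and weights must be 1-D and equally long")
        if days.size < 2:
            raise ValueError("a pot weight series needs >= 2 measurements")
        if np.any(np.diff(days) < 0):
            raise ValueError("days must be nondecreasing")
        if np.any(weights <= 0):
            raise ValueError("pot weights must be > 0")
        post = self.post_irrigation
        post = (
            np.zeros(days.size, dtype=bool)
            if post is None
            else np.asarray(post, dtype=bool)
        )
        if post.shape != days.shape:
            raise ValueError("post_irrigation must match days in length")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "post_irrigation", post)

    def __len__(self) -> int:
        return int(self.days.size)

    def weight_on(self, day: float) -> float:
        """Weight recorded on ``day`` (pre-irrigation entry if duplicated)."""
        idx = np.nonzero(self.days == day)[0]
        if idx.size == 0:
            raise AlignmentError(f"pot {self.pot_id}: no measurement on day {day}")
        return float(self.weights[idx[0]])


def plant_biomass_gain(
    initial_fresh_weight: float, final_fresh_weight: float, n_days: float
) -> float:
    """Daily fresh-biomass gain, PBG = (final - initial) / n_days, in g/day.

    May be negative: plants under water deficit can lose fresh weight.
    """
    if n_days <= 0:
        raise ZeroDivisionError("n_days must be > 0")
    if initial_fresh_weight < 0 or final_fresh_weight < 0:
        raise ValueError("fresh weights must be >= 0")
    return (final_fresh_weight - initial_fresh_weight) / n_days


def water_use(
    plant_series: PotWeightSeries,
    control_series: PotWeightSeries,
    pbg: float = 0.0,
) -> float:
    """Water use in litres from a planted and a control pot-weight series.

    Parameters
    ----------
    plant_series
        Weights of the planted pot; may contain pre/post-irrigation pairs.
    control_series
        Weights of the unplanted control pot on the same measurement days;
        estimates drainage and surface evaporation.
    pbg
        Plant biomass gain in g/day, subtracted (as kg) per interval.

    Only intervals spanning time (dt > 0) contribute; same-day refill
    jumps are skipped so irrigation water added does not count as negative
    consumption.
    """
    if plant_series.is_control:
        raise ValueError("plant_series flagged as a control pot")
    if len(plant_series) < 2:
        raise ValueError("need at least 2 measurements")
    plant_days = set(np.unique(plant_series.days).tolist())
    control_days = set(np.unique(control_series.days).tolist())
    if not plant_days <= control_days:
        raise AlignmentError(
            f"control pot {control_series.pot_id} misses days "
            f"{sorted(plant_days - control_days)}"
        )
    days = plant_series.days
    weights = plant_series.weights
    total = 0.0
    for i in range(1, len(days)):
        dt = days[i] - days[i - 1]
        if dt <= 0:  # same-day pre -> post irrigation refill entry
            continue
        plant_loss = weights[i - 1] - weights[i]
        control_loss = control_series.weight_on(days[i - 1]) - control_series.weight_on(
            days[i]
        )
        total += plant_loss - control_loss - (pbg / 1000.0) * dt
    return total


def water_productivity(rdw: float, sdw: float, wu: float) -> float:
    """Water productivity WP = (RDW + SDW) / WU in kg m^-3 (== g/L).

    Returns NaN with a warning when WU is nonpositive (undefined).
    """
    if rdw < 0 or sdw < 0:
        raise ValueError("dry weights must be >= 0")
    if wu <= 0:
        warnings.warn("water use <= 0: water productivity undefined", stacklevel=2)
        return float("nan")
    return (rdw + sdw) / wu


def root_shoot_ratio(rdw: float, sdw: float) -> float:
    """Root:shoot ratio RDW/SDW; NaN with a warning when SDW is zero."""
    if rdw < 0 or sdw < 0:
        raise ValueError("dry weights must be >= 0")
    if sdw == 0:
        warnings.warn("SDW is zero: root:shoot ratio undefined", stacklevel=2)
        return float("nan")
    return rdw / sdw


def water_results_table(
    plants: pd.DataFrame,
    series_by_plant: dict[str, PotWeightSeries],
    controls: dict[str, PotWeightSeries],
    duration_days: float,
) -> pd.DataFrame:
    """Per-plant water accounting over a whole experiment.

    Parameters
    ----------
    plants
        One row per plant with columns ``plant_id, genotype, regime, block,
        initial_fresh_g, final_fresh_g, rdw_g, sdw_g``.
    series_by_plant
        Planted pot series keyed by plant id.
    controls
        Control pot series keyed by ``"<regime>:<block>"`` (fallback to a
        single control per regime keyed by ``"<regime>"``).
    duration_days
        Experiment length used for the PBG denominator.
    """
    rows = []
    for rec in plants.itertuples(index=False):
        series = series_by_plant[rec.plant_id]
        key = f"{rec.regime}:{rec.block}"
        control = controls.get(key) or controls.get(str(rec.regime))
        if control is None:
            raise AlignmentError(f"no control pot for regime {rec.regime}")
        pbg = plant_biomass_gain(rec.initial_fresh_g, rec.final_fresh_g, duration_days)
        wu = water_use(series, control, pbg)
        wp = water_productivity(rec.rdw_g, rec.sdw_g, wu) if wu > 0 else float("nan")
        rows.append(
            {
                "plant_id": rec.plant_id,
                "genotype": rec.genotype,
                "regime": rec.regime,
                "block": rec.block,
                "pbg_g_per_day": pbg,
                "wu_l": wu,
                "wp_kg_m3": wp,
                "root_shoot": root_shoot_ratio(rec.rdw_g, rec.sdw_g),
            }
        )
    return pd.DataFrame(rows)
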