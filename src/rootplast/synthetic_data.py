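"""Seeded generator of complete pot-experiment datasets.

The generator emulates a randomized complete block design: a panel of
genotypes grown under two irrigation regimes — well-watered (WW), refilled
to field capacity at every weighing, and water-deficit (WD), irrigation
suspended for the whole run — in ``n_blocks`` complete blocks.  It emits
the three tidy tables the analysis consumes: plant biomass records,
pot-weight time series (planted and unplanted control pots) and per-plant
root-segment tables.

Statistical structure
---------------------
* Trait expectations are multiplicative: panel base × genotype multiplier
  × regime reduction × block effect, with log-normal residual noise.
  Setting ``residual_sd = block_sd = weighing_sd = 0`` gives the exact
  noise-free limit in which WD expectations equal the configured reduction
  factor times the WW expectations — the regime contract the plasticity
  closed forms rely on.
* WD pot weights decline monotonically by construction: noise is applied
  to the (nonnegative) daily water loss, never to the weights, and the
  daily loss decays exponentially toward zero so the drydown curve
  flattens as the plants die late in the run.
* Root segments have log-normal diameters (right-skewed, as fine-root
  diameter distributions are) whose median shifts with genotype and
  regime; under defaults the largest share of total root length falls in
  the 0.5–1.0 mm diameter class.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import ConfigurationError, EffectConfig, ExperimentDesign
from .io import ExperimentData
from .water_accounting import PotWeightSeries

__all__ = [
    "make_schedule",
    "generate_pot_series",
    "generate_control_series",
    "generate_root_segments",
    "expected_layer_length",
    "generate_experiment",
]


def make_schedule(design: ExperimentDesign) -> np.ndarray:
    """Measurement days for a run: day 0, the final day, and ``k`` evenly
    spaced weighings per week in between.

    For the default 35-day, 3-per-week design this is the Mon/Wed/Fri
    pattern {0, 2, 4, 7, 9, 11, ..., 32, 35}.
    """
    k = design.weighings_per_week
    if not 1 <= k <= 7:
        raise ConfigurationError("weighings_per_week must be in 1..7")
    offsets = [int(np.floor(j * 7 / k)) for j in range(k)]
    days = {0, design.duration_days}
    week = 0
    while week * 7 <= design.duration_days:
        for off in offsets:
            day = week * 7 + off
            if day <= design.duration_days:
                days.add(day)
        week += 1
    return np.array(sorted(days), dtype=int)


def _daily_losses(
    design: ExperimentDesign,
    effects: EffectConfig,
    regime: str,
    transpiration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Water lost (kg) on each day 1..duration; nonnegative by construction."""
    t = np.arange(1, design.duration_days + 1, dtype=float)
    base = effects.base_daily_loss * transpiration
    if regime == "WD":
        losses = base * np.exp(-(t - 1.0) / effects.wd_decay_tau)
    else:
        losses = np.full_like(t, base)
    if effects.weighing_sd > 0:
        losses = losses * rng.lognormal(
            mean=-0.5 * effects.weighing_sd**2, sigma=effects.weighing_sd, size=t.size
        )
    return losses


def generate_pot_series(
    design: ExperimentDesign,
    effects: EffectConfig,
    regime: str,
    rng: np.random.Generator,
    *,
    pot_id: str = "pot",
    transpiration: float = 1.0,
) -> PotWeightSeries:
    """Simulate the weight series of one planted pot.

    WW pots are refilled to field capacity on every weighing day except
    the last (harvest); both the pre- and the post-irrigation weight are
    recorded, so successive-difference accounting can exclude the refill
    jumps.  WD pots decline monotonically and flatten near the end.
    """
    if regime not in ("WW", "WD"):
        raise ConfigurationError(f"unknown regime {regime!r}")
    schedule = set(make_schedule(design).tolist())
    losses = _daily_losses(design, effects, regime, transpiration, rng)
    fc = design.field_capacity_weight
    days: list[float] = [0.0]
    weights: list[float] = [fc]
    post: list[bool] = [True]
    weight = fc
    for day in range(1, design.duration_days + 1):
        weight = max(weight - losses[day - 1], 0.05 * fc)
        if day in schedule:
            days.append(float(day))
            weights.append(weight)
            post.append(False)
            if regime == "WW" and day != design.duration_days:
                weight = fc
                days.append(float(day))
                weights.append(fc)
                post.append(True)
    return PotWeightSeries(
        pot_id=pot_id,
        days=np.array(days),
        weights=np.array(weights),
        is_control=False,
        post_irrigation=np.array(post),
    )


def generate_control_series(
    design: ExperimentDesign,
    effects: EffectConfig,
    rng: np.random.Generator,
    *,
    pot_id: str = "control",
) -> PotWeightSeries:
    """Simulate an unplanted control pot: drainage/evaporation-only decline."""
    schedule = make_schedule(design)
    losses = np.full(design.duration_days, effects.control_drainage, dtype=float)
    if effects.weighing_sd > 0 and effects.control_drainage > 0:
        losses = losses * rng.lognormal(
            mean=-0.5 * effects.weighing_sd**2,
            sigma=effects.weighing_sd,
            size=losses.size,
        )
    cumulative = np.concatenate([[0.0], np.cumsum(losses)])
    weights = np.maximum(
        design.field_capacity_weight - cumulative[schedule],
        0.05 * design.field_capacity_weight,
    )
    return PotWeightSeries(
        pot_id=pot_id,
        days=schedule.astype(float),
        weights=weights,
        is_control=True,
    )


def expected_layer_length(
    design: ExperimentDesign,
    effects: EffectConfig,
    genotype: str,
    regime: str,
) -> np.ndarray:
    """Expected total root length (mm) per depth layer for one plant.

    Analytic expectation of the segment generator: segment count ×
    mean segment length × layer allocation, with the WD reduction applied
    to the count.  In the noise-free limit the WD/WW ratio of every entry
    is exactly the configured root-trait reduction factor.
    """
    geno = effects.genotype(genotype)
    lam = effects.n_segments_base * geno.rl
    if regime == "WD":
        lam *= effects.root_reduction(genotype)
    alloc = effects.layer_allocation(genotype, regime)
    return lam * effects.mean_segment_length * alloc


def generate_root_segments(
    design: ExperimentDesign,
    effects: EffectConfig,
    genotype: str,
    regime: str,
    rng: np.random.Generator,
    *,
    n_segments: int | None = None,
    layer_allocation: np.ndarray | None = None,
    count_multiplier: float = 1.0,
) -> pd.DataFrame:
    """Simulate the root-segment table of one plant.

    Returns a frame with columns ``depth_cm, length_mm, diameter_mm``.
    Depths fall in [0, max layer edge); lengths are positive and shorter
    than a layer; diameters are log-normal with a genotype- and
    regime-shifted median.
    """
    if genotype not in design.genotypes:
        raise ConfigurationError(f"unknown genotype {genotype!r}")
    if regime not in ("WW", "WD"):
        raise ConfigurationError(f"unknown regime {regime!r}")
    alloc = (
        np.asarray(layer_allocation, dtype=float)
        if layer_allocation is not None
        else effects.layer_allocation(genotype, regime)
    )
    edges = np.asarray(design.layer_edges, dtype=float)
    if alloc.size != edges.size - 1:
        raise ConfigurationError("allocation length must match number of layers")
    if np.any(alloc < 0) or not np.isclose(alloc.sum(), 1.0):
        raise ConfigurationError("layer allocation must be nonnegative and sum to 1")
    alloc = alloc / alloc.sum()

    geno = effects.genotype(genotype)
    noise_free = effects.residual_sd == 0
    if n_segments is None:
        lam = effects.n_segments_base * geno.rl * count_multiplier
        if regime == "WD":
            lam *= effects.root_reduction(genotype)
        n = int(round(lam)) if noise_free else int(rng.poisson(lam))
    else:
        n = int(n_segments)
    n = max(n, 1)

    layers = rng.choice(alloc.size, size=n, p=alloc)
    lower, upper = edges[layers], edges[layers + 1]
    if noise_free:
        depths = 0.5 * (lower + upper)
        lengths = np.full(n, effects.mean_segment_length)
    else:
        depths = rng.uniform(lower, upper)
        # Uniform on [0.2m, 1.8m]: mean exactly m, support positive and
        # shorter than the 10 cm layer thickness for default m.
        lengths = rng.uniform(
            0.2 * effects.mean_segment_length, 1.8 * effects.mean_segment_length, n
        )
    median = effects.diameter_median * geno.mrd
    if regime == "WD":
        median *= effects.wd_mrd_reduction
    if noise_free:
        diameters = np.full(n, median)
    else:
        diameters = rng.lognormal(np.log(median), effects.diameter_sigma, n)
    # Depths at the top edge of the profile would fall outside the layers.
    depths = np.minimum(depths, np.nextafter(edges[-1], 0.0))
    return pd.DataFrame(
        {"depth_cm": depths, "length_mm": lengths, "diameter_mm": diameters}
    )


def _series_frame(
    series: PotWeightSeries, plant_id: str, regime: str, block: int
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pot_id": series.pot_id,
            "plant_id": plant_id,
            "regime": regime,
            "block": block,
            "day": series.days,
            "weight_kg": series.weights,
            "is_control": series.is_control,
            "post_irrigation": series.post_irrigation,
        }
    )


def generate_experiment(
    design: ExperimentDesign,
    effects: EffectConfig,
    seed: int,
    *,
    qc_biomass_bound: float | None = None,
) -> ExperimentData:
    """Generate a full seeded dataset: plants, pot weights, root segments.

    Deterministic given (design, effects, seed).  With
    ``qc_biomass_bound`` set (g of dry biomass per litre of pot volume),
    a warning is emitted when the mean generated biomass density exceeds
    it — plants grown past ~2 g/L are considered pot-bound, so their
    water-deficit responses confound with container limitation.
    """
    rng = np.random.default_rng(seed)
    plant_rows = []
    weight_frames = []
    segment_frames = []

    block_mult = (
        np.exp(rng.normal(0.0, effects.block_sd, design.n_blocks))
        if effects.block_sd > 0
        else np.ones(design.n_blocks)
    )

    for regime in ("WW", "WD"):
        for block in range(1, design.n_blocks + 1):
            control = generate_control_series(
                design, effects, rng, pot_id=f"CTRL-{regime}-B{block}"
            )
            weight_frames.append(_series_frame(control, "", regime, block))

    for genotype in design.genotypes:
        geno = effects.genotype(genotype)
        for regime in ("WW", "WD"):
            for block in range(1, design.n_blocks + 1):
                for rep in range(1, design.plants_per_block + 1):
                    plant_id = f"{genotype}-{regime}-B{block}" + (
                        f"-P{rep}" if design.plants_per_block > 1 else ""
                    )
                    bmult = block_mult[block - 1]
                    noise = (
                        rng.lognormal(0.0, effects.residual_sd, 3)
                        if effects.residual_sd > 0
                        else np.ones(3)
                    )
                    sdw = effects.sdw_base * geno.biomass * bmult * noise[0]
                    rdw = effects.rdw_base * geno.biomass * bmult * noise[1]
                    if regime == "WD":
                        sdw *= effects.wd_sdw_reduction
                        rdw *= effects.wd_rdw_reduction
                    final_fresh = effects.fresh_dry_ratio * (rdw + sdw)
                    transpiration = geno.biomass * bmult * noise[2]
                    series = generate_pot_series(
                        design,
                        effects,
                        regime,
                        rng,
                        pot_id=f"POT-{plant_id}",
                        transpiration=transpiration,
                    )
                    weight_frames.append(
                        _series_frame(series, plant_id, regime, block)
                    )
                    segments = generate_root_segments(
                        design, effects, genotype, regime, rng,
                        count_multiplier=bmult,
                    )
                    segments.insert(0, "plant_id", plant_id)
                    segment_frames.append(segments)
                    plant_rows.append(
                        {
                            "plant_id": plant_id,
                            "genotype": genotype,
                            "regime": regime,
                            "block": block,
                            "initial_fresh_g": effects.initial_fresh_weight,
                            "final_fresh_g": final_fresh,
                            "rdw_g": rdw,
                            "sdw_g": sdw,
                        }
                    )

    plants = pd.DataFrame(plant_rows)
    if qc_biomass_bound is not None:
        density = (plants["rdw_g"] + plants["sdw_g"]) / design.pot_volume
        if density.mean() > qc_biomass_bound:
            warnings.warn(
                f"mean biomass density {density.mean():.2f} g/L exceeds the "
                f"{qc_biomass_bound:g} g/L pot-binding guidance bound",
                stacklevel=2,
            )
    return ExperimentData(
        plants=plants,
        pot_weights=pd.concat(weight_frames, ignore_index=True),
        root_segments=pd.concat(segment_frames, ignore_index=True),
    )
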