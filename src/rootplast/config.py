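"""Configuration objects for the experiment design, effect sizes and pipeline.

The experiment emulated throughout the package is a glasshouse pot trial:
eight bottle-gourd genotypes grown under two irrigation regimes
(well-watered, WW, refilled to field capacity three times a week; and
water-deficit, WD, irrigation suspended) in a randomized complete block
design with three blocks, run for 35 days with pots weighed three times a
week.  All knobs of that design live in :class:`ExperimentDesign`; the
magnitudes of genotype / regime / block effects and of residual noise live
in :class:`EffectConfig`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ConfigurationError",
    "DEFAULT_GENOTYPES",
    "ExperimentDesign",
    "GenotypeEffect",
    "EffectConfig",
    "PipelineConfig",
    "load_config",
]


class ConfigurationError(ValueError):
    """Raised when a design/effect/pipeline configuration is invalid."""


#: Default genotype panel: three South African, two Asian and three Chilean
#: bottle-gourd accessions.
DEFAULT_GENOTYPES = (
    "BG-58",
    "BG-78",
    "GC",
    "Philippines",
    "South Korea",
    "Illapel",
    "Chepica",
    "Osorno",
)

REGIMES = ("WW", "WD")


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of the pot experiment.

    Parameters
    ----------
    genotypes
        Labels of the genotypes (factor G).
    n_blocks
        Number of complete blocks; each block holds one plant per
        genotype × regime cell by default.
    plants_per_block
        Plants per genotype × regime cell within each block.
    duration_days
        Length of the drydown / irrigation run in days.
    weighings_per_week
        Gravimetric sampling frequency (1..7).
    field_capacity_weight
        Pot weight (kg) at 100% substrate water content, the re-watering
        reference for the WW regime.
    pot_volume
        Pot volume in litres (QC bound on biomass density).
    layer_edges
        Substrate depth layer boundaries in cm (default 0–40 cm in 10 cm
        layers).
    class_edges
        Root diameter class boundaries in mm (default 0–4.5 mm in 0.5 mm
        steps, nine classes).
    """

    genotypes: tuple[str, ...] = DEFAULT_GENOTYPES
    n_blocks: int = 3
    plants_per_block: int = 1
    duration_days: int = 35
    weighings_per_week: int = 3
    field_capacity_weight: float = 38.0
    pot_volume: float = 20.0
    layer_edges: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0)
    class_edges: tuple[float, ...] = (
        0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5,
    )

    def __post_init__(self) -> None:
        if len(self.genotypes) < 1:
            raise ConfigurationError("at least one genotype required")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ConfigurationError("genotype labels must be unique")
        if self.n_blocks < 2:
            raise ConfigurationError("n_blocks must be >= 2")
        if self.plants_per_block < 1:
            raise ConfigurationError("plants_per_block must be >= 1")
        if self.duration_days < 1:
            raise ConfigurationError("duration_days must be >= 1")
        if not 1 <= self.weighings_per_week <= 7:
            raise ConfigurationError("weighings_per_week must be in 1..7")
        if self.field_capacity_weight <= 0:
            raise ConfigurationError("field_capacity_weight must be > 0")
        if self.pot_volume <= 0:
            raise ConfigurationError("pot_volume must be > 0")
        edges = np.asarray(self.layer_edges, dtype=float)
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ConfigurationError("layer_edges must be strictly increasing")
        cls = np.asarray(self.class_edges, dtype=float)
        if cls.size < 2 or np.any(np.diff(cls) <= 0):
            raise ConfigurationError("class_edges must be strictly increasing")
        steps = np.diff(cls)
        if not np.allclose(steps, steps[0]):
            raise ConfigurationError("class_edges must use a uniform step")

    @property
    def regimes(self) -> tuple[str, str]:
        return REGIMES

    @property
    def n_plants(self) -> int:
        return len(self.genotypes) * 2 * self.n_blocks * self.plants_per_block


@dataclass(frozen=True)
class GenotypeEffect:
    """Multiplicative genotype effects, 1.0 = panel average.

    ``biomass`` scales shoot/root dry weight, ``rl`` the expected number of
    root segments (hence total root length), ``mrd`` the median root
    diameter, and ``depth`` shifts the depth allocation toward deeper layers
    (0 = design default allocation, 1 = fully shifted to the deep profile).
    ``root_reduction``, if set, overrides the panel-wide WD root-trait
    reduction factor for this genotype — the knob that configures one
    accession with an exact proportional WD response.
    """

    biomass: float = 1.0
    rl: float = 1.0
    mrd: float = 1.0
    depth: float = 0.0
    root_reduction: float | None = None

    def __post_init__(self) -> None:
        if self.biomass <= 0 or self.rl <= 0 or self.mrd <= 0:
            raise ConfigurationError("genotype multipliers must be > 0")
        if not 0.0 <= self.depth <= 1.0:
            raise ConfigurationError("depth shift must lie in [0, 1]")
        if self.root_reduction is not None and not 0 < self.root_reduction <= 1:
            raise ConfigurationError("root_reduction must lie in (0, 1]")


def _default_genotype_effects() -> dict[str, GenotypeEffect]:
    # South African accessions: high biomass and root length; Chilean
    # Illapel/Chepica: thicker roots allocated deeper under stress.
    return {
        "BG-58": GenotypeEffect(biomass=1.15, rl=1.20, mrd=0.90, depth=0.0),
        "BG-78": GenotypeEffect(biomass=1.10, rl=1.10, mrd=0.95, depth=0.0),
        "GC": GenotypeEffect(biomass=1.15, rl=1.25, mrd=0.90, depth=0.0),
        "Philippines": GenotypeEffect(biomass=0.75, rl=0.70, mrd=0.95, depth=0.1),
        "South Korea": GenotypeEffect(biomass=0.90, rl=0.90, mrd=0.90, depth=0.1),
        "Illapel": GenotypeEffect(biomass=0.90, rl=0.95, mrd=1.30, depth=0.5),
        "Chepica": GenotypeEffect(biomass=0.90, rl=0.90, mrd=1.25, depth=0.5),
        # Osorno responds to WD with an exact proportional 50% reduction of
        # its root traits, the canonical RDPI = 1/3 plasticity signature.
        "Osorno": GenotypeEffect(
            biomass=1.00, rl=0.80, mrd=1.00, depth=0.2, root_reduction=0.5
        ),
    }


@dataclass(frozen=True)
class EffectConfig:
    """Effect sizes and noise levels for the synthetic-data generator.

    Trait-family reduction factors give the expected WD value as a fraction
    of the WW value for the same genotype; the default 0.5 for root traits
    reproduces the at-least-50% decline seen across depth layers under
    water deficit.  Noise standard deviations are fractional (coefficient
    of variation); setting them all to 0 yields the deterministic,
    noise-free limit used by the closed-form plasticity checks.
    """

    genotype_effects: Mapping[str, GenotypeEffect] = field(
        default_factory=_default_genotype_effects
    )
    # WD/WW expected-value ratios per trait family.  Root totals drop to
    # 0.4 of the WW expectation so that, after the WD depth reallocation,
    # every depth layer still loses at least half of each additive trait.
    wd_root_reduction: float = 0.4
    wd_sdw_reduction: float = 0.2
    wd_rdw_reduction: float = 0.64
    wd_mrd_reduction: float = 0.85
    # Biomass scale (grams, panel-average WW plant).
    sdw_base: float = 95.0
    rdw_base: float = 3.3
    fresh_dry_ratio: float = 10.0
    initial_fresh_weight: float = 8.0
    # Gravimetric dynamics (kg of water per day).
    base_daily_loss: float = 0.65
    wd_decay_tau: float = 10.0
    control_drainage: float = 0.02
    # Root segment model.
    n_segments_base: int = 280
    mean_segment_length: float = 25.0
    diameter_median: float = 0.70
    diameter_sigma: float = 0.5
    layer_allocation_ww: tuple[float, ...] = (0.32, 0.28, 0.22, 0.18)
    layer_allocation_wd: tuple[float, ...] = (0.28, 0.32, 0.23, 0.17)
    deep_allocation: tuple[float, ...] = (0.18, 0.26, 0.28, 0.28)
    # Noise (fractional SDs) and block effect.
    residual_sd: float = 0.10
    block_sd: float = 0.05
    weighing_sd: float = 0.10

    def __post_init__(self) -> None:
        for name in (
            "wd_root_reduction",
            "wd_sdw_reduction",
            "wd_rdw_reduction",
            "wd_mrd_reduction",
        ):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ConfigurationError(f"{name} must lie in (0, 1]")
        for name in (
            "sdw_base", "rdw_base", "fresh_dry_ratio", "initial_fresh_weight",
            "base_daily_loss", "wd_decay_tau", "mean_segment_length",
            "diameter_median", "diameter_sigma",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("control_drainage", "residual_sd", "block_sd", "weighing_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_segments_base < 1:
            raise ConfigurationError("n_segments_base must be >= 1")
        for name in ("layer_allocation_ww", "layer_allocation_wd", "deep_allocation"):
            alloc = np.asarray(getattr(self, name), dtype=float)
            if np.any(alloc < 0) or not np.isclose(alloc.sum(), 1.0):
                raise ConfigurationError(f"{name} must be nonnegative and sum to 1")

    def genotype(self, name: str) -> GenotypeEffect:
        return self.genotype_effects.get(name, GenotypeEffect())

    def root_reduction(self, name: str) -> float:
        """WD root-trait reduction factor for a genotype (with override)."""
        override = self.genotype(name).root_reduction
        return self.wd_root_reduction if override is None else override

    def layer_allocation(self, genotype: str, regime: str) -> np.ndarray:
        """Depth allocation for a genotype × regime, after the deep shift."""
        base = np.asarray(
            self.layer_allocation_ww if regime == "WW" else self.layer_allocation_wd,
            dtype=float,
        )
        shift = self.genotype(genotype).depth if regime == "WD" else 0.0
        deep = np.asarray(self.deep_allocation, dtype=float)
        return (1.0 - shift) * base + shift * deep


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level pipeline configuration (design + effects + analysis knobs)."""

    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    effects: EffectConfig = field(default_factory=EffectConfig)
    seed: int = 0
    alpha: float = 0.05
    rdpi_mode: str = "pairs"  # or "blocks"
    pca_observations: str = "genotype_means"  # or "plants"
    mrd_weighting: str = "length"  # or "unweighted"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.rdpi_mode not in {"pairs", "blocks"}:
            raise ConfigurationError("rdpi_mode must be 'pairs' or 'blocks'")
        if self.pca_observations not in {"genotype_means", "plants"}:
            raise ConfigurationError(
                "pca_observations must be 'genotype_means' or 'plants'"
            )
        if self.mrd_weighting not in {"length", "unweighted"}:
            raise ConfigurationError("mrd_weighting must be 'length' or 'unweighted'")


def _build(cls, data: Mapping[str, Any], path: str):
    """Construct a (frozen) dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key == "genotype_effects":
            value = {
                name: _build(GenotypeEffect, entry, f"{path}.{key}.{name}")
                for name, entry in value.items()
            }
        elif isinstance(value, Sequence) and not isinstance(value, str):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path_or_mapping: str | Mapping[str, Any]) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file or a plain mapping.

    Unknown keys anywhere in the document raise :class:`ConfigurationError`
    so that typos fail loudly instead of silently falling back to defaults.
    """
    if isinstance(path_or_mapping, Mapping):
        raw: Mapping[str, Any] = path_or_mapping
    else:
        with open(path_or_mapping, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError("configuration root must be a mapping")
    names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - names
    if unknown:
        raise ConfigurationError(f"config: unknown keys {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    if "design" in raw:
        kwargs["design"] = _build(ExperimentDesign, raw["design"], "design")
    if "effects" in raw:
        kwargs["effects"] = _build(EffectConfig, raw["effects"], "effects")
    for key in ("seed", "alpha", "rdpi_mode", "pca_observations", "mrd_weighting"):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)
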