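"""End-to-end runner: simulate/read, water accounting, traits, RDPI, stats.

``run_pipeline`` chains the stages on one dataset and returns (and
optionally writes) every result table plus a reproducibility manifest
(config hash, seed, library versions, row counts).  Given the same
configuration and seed the outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import PipelineConfig
from .io import ExperimentData, read_tables, write_tables
from .plasticity import PLASTICITY_TRAITS, rdpi, rdpi_table
from .root_traits import aggregate_traits, trait_table
from .stats_inference import (
    assumption_checks,
    contrasts_table,
    correlation_matrix,
    lsd_letters,
    one_way_anova,
    pca_correlation,
    two_way_anova,
)
from .synthetic_data import generate_experiment
from .water_accounting import water_results_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineStageError", "PipelineResult", "run_pipeline", "analysis_table"]

#: Traits entering the correlation panel (per water condition).
CORRELATION_TRAITS = (
    "wu_l", "wp_kg_m3", "root_shoot", "rdw_g", "sdw_g",
    "rl_cm", "mrd_mm", "rv_cm3", "sa_cm2",
)
#: Traits entering the screening PCA (per water condition).
PCA_TRAITS = ("wp_kg_m3", "rl_cm", "sa_cm2", "mrd_mm", "rv_cm3")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    data: ExperimentData
    water: pd.DataFrame
    traits_plant: pd.DataFrame
    traits_by_layer: pd.DataFrame
    traits_by_class: pd.DataFrame
    analysis: pd.DataFrame
    rdpi: pd.DataFrame
    anova: pd.DataFrame
    letters: pd.DataFrame
    contrasts: pd.DataFrame
    rdpi_anova: pd.DataFrame
    rdpi_letters: pd.DataFrame
    correlations: dict[str, tuple[pd.DataFrame, pd.DataFrame]]
    pca: dict[str, object]
    manifest: dict


def config_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump(
        json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


def analysis_table(
    data: ExperimentData, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plant analysis table: water results joined with root traits."""
    controls = {}
    for regime in ("WW", "WD"):
        for block in sorted(data.plants["block"].unique()):
            try:
                controls[f"{regime}:{block}"] = data.control_series(regime, block)
            except KeyError:
                pass
        controls[regime] = data.control_series(regime)
    series = {pid: data.plant_series(pid) for pid in data.plants["plant_id"]}
    water = water_results_table(
        data.plants, series, controls, config.design.duration_days
    )
    traits = trait_table(
        data.root_segments,
        data.plants,
        layer_edges=config.design.layer_edges,
        class_edges=config.design.class_edges,
        mrd_weighting=config.mrd_weighting,
    )
    analysis = water.merge(
        data.plants[["plant_id", "rdw_g", "sdw_g"]], on="plant_id"
    ).merge(traits.drop(columns=["genotype", "regime", "block"]), on="plant_id")
    return water, analysis


def _rdpi_observations(
    analysis: pd.DataFrame, trait: str, mode: str
) -> tuple[list[float], list[str]]:
    """Observations for the RDPI one-way ANOVA across genotypes.

    ``pairs`` mode passes every cross-environment relative distance as an
    observation (pseudo-replicated: the 9 pairs come from 6 plants);
    ``blocks`` mode computes one RDPI per block from the plants of that
    block, giving independent but fewer observations.
    """
    values: list[float] = []
    groups: list[str] = []
    for genotype, sub in analysis.groupby("genotype", sort=False):
        ww = sub[sub["regime"] == "WW"]
        wd = sub[sub["regime"] == "WD"]
        if ww.empty or wd.empty:
            continue
        if mode == "pairs":
            result = rdpi(
                ww[trait].dropna().to_numpy(float),
                wd[trait].dropna().to_numpy(float),
                genotype=str(genotype),
                trait=trait,
            )
            values.extend(result.relative_distances.tolist())
            groups.extend([str(genotype)] * result.n)
        else:
            for block, blk in sub.groupby("block"):
                bww = blk.loc[blk["regime"] == "WW", trait].dropna()
                bwd = blk.loc[blk["regime"] == "WD", trait].dropna()
                if bww.empty or bwd.empty:
                    continue
                result = rdpi(bww.to_numpy(float), bwd.to_numpy(float))
                values.append(result.rdpi)
                groups.append(str(genotype))
    return values, groups


def run_pipeline(
    config: PipelineConfig,
    *,
    input_dir: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on synthetic (default) or on-disk input tables."""

    def stage(name):
        logger.info("stage %s", name)
        return name

    name = stage("simulate" if input_dir is None else "read")
    try:
        if input_dir is None:
            data = generate_experiment(config.design, config.effects, config.seed)
        else:
            data = read_tables(input_dir)
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
        raise PipelineStageError(name, exc) from exc

    name = stage("water")
    try:
        water, analysis = analysis_table(data, config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(name, exc) from exc

    name = stage("traits")
    try:
        kwargs = dict(
            layer_edges=config.design.layer_edges,
            class_edges=config.design.class_edges,
            mrd_weighting=config.mrd_weighting,
        )
        traits_plant = aggregate_traits(data.root_segments, "plant", **kwargs)
        traits_by_layer = aggregate_traits(data.root_segments, "layer", **kwargs)
        traits_by_class = aggregate_traits(
            data.root_segments, "layer_class", **kwargs
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(name, exc) from exc

    name = stage("rdpi")
    try:
        rdpi_df, _ = rdpi_table(analysis, PLASTICITY_TRAITS)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(name, exc) from exc

    name = stage("stats")
    try:
        anova_rows = []
        letter_rows = []
        contrasts = contrasts_table(analysis, PLASTICITY_TRAITS[:1] + ("wu_l",))
        for trait in ("wu_l",) + PLASTICITY_TRAITS:
            table = two_way_anova(analysis, trait)
            model = table.attrs["model"]
            checks = assumption_checks(
                model.resid,
                [g[trait].to_numpy(float)
                 for _, g in analysis.groupby(["genotype", "regime"])],
                alpha=config.alpha,
            )
            t = table.reset_index(names="term")
            t.insert(0, "trait", trait)
            t["shapiro_p"] = checks.shapiro_p
            t["bartlett_p"] = checks.bartlett_p
            anova_rows.append(t)
            means = analysis.groupby("genotype")[trait].mean()
            n = analysis.groupby("genotype")[trait].count()
            letters = lsd_letters(
                means, n, table.attrs["mse"], table.attrs["df_error"],
                alpha=config.alpha,
            )
            letters = letters.reset_index()
            letters.insert(0, "trait", trait)
            letter_rows.append(letters)
        anova = pd.concat(anova_rows, ignore_index=True)
        letters = pd.concat(letter_rows, ignore_index=True)
        contrasts = contrasts_table(analysis, ("wu_l",) + PLASTICITY_TRAITS)

        rdpi_anova_rows = []
        rdpi_letter_rows = []
        for trait in PLASTICITY_TRAITS:
            values, groups = _rdpi_observations(analysis, trait, config.rdpi_mode)
            table = one_way_anova(values, groups)
            t = table.reset_index(names="term")
            t.insert(0, "trait", trait)
            t["pseudo_replicated"] = config.rdpi_mode == "pairs"
            rdpi_anova_rows.append(t)
            obs = pd.DataFrame({"value": values, "genotype": groups})
            means = obs.groupby("genotype")["value"].mean()
            n = obs.groupby("genotype")["value"].count()
            rl = lsd_letters(
                means, n, table.attrs["mse"], table.attrs["df_error"],
                alpha=config.alpha,
            ).reset_index()
            rl.insert(0, "trait", trait)
            rdpi_letter_rows.append(rl)
        rdpi_anova = pd.concat(rdpi_anova_rows, ignore_index=True)
        rdpi_letters = pd.concat(rdpi_letter_rows, ignore_index=True)

        correlations = {}
        pca = {}
        for regime in ("WW", "WD"):
            sub = analysis[analysis["regime"] == regime]
            if config.pca_observations == "genotype_means":
                obs = sub.groupby("genotype")[list(CORRELATION_TRAITS)].mean()
            else:
                obs = sub.set_index("plant_id")[list(CORRELATION_TRAITS)]
            correlations[regime] = correlation_matrix(obs)
            pca[regime] = pca_correlation(obs[list(PCA_TRAITS)])
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(name, exc) from exc

    manifest = {
        "package": "rootplast",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config_hash(config),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "rows": {
            "plants": int(len(data.plants)),
            "pot_weights": int(len(data.pot_weights)),
            "root_segments": int(len(data.root_segments)),
            "rdpi": int(len(rdpi_df)),
        },
    }
    result = PipelineResult(
        data=data,
        water=water,
        traits_plant=traits_plant,
        traits_by_layer=traits_by_layer,
        traits_by_class=traits_by_class,
        analysis=analysis,
        rdpi=rdpi_df,
        anova=anova,
        letters=letters,
        contrasts=contrasts,
        rdpi_anova=rdpi_anova,
        rdpi_letters=rdpi_letters,
        correlations=correlations,
        pca=pca,
        manifest=manifest,
    )
    if out_dir is not None:
        write_results(result, out_dir)
    return result


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    """Write every result table (and the input tables) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tables(result.data, out)
    result.water.to_csv(out / "water_results.csv", index=False)
    result.traits_plant.to_csv(out / "traits_plant.csv", index=False)
    result.traits_by_layer.to_csv(out / "traits_by_layer.csv", index=False)
    result.traits_by_class.to_csv(out / "traits_by_class.csv", index=False)
    result.analysis.to_csv(out / "analysis_table.csv", index=False)
    result.rdpi.to_csv(out / "rdpi.csv", index=False)
    result.anova.to_csv(out / "anova.csv", index=False)
    result.letters.to_csv(out / "letters.csv", index=False)
    result.contrasts.to_csv(out / "contrasts.csv", index=False)
    result.rdpi_anova.to_csv(out / "rdpi_anova.csv", index=False)
    result.rdpi_letters.to_csv(out / "rdpi_letters.csv", index=False)
    for regime, (r, p) in result.correlations.items():
        r.to_csv(out / f"correlations_r_{regime}.csv")
        p.to_csv(out / f"correlations_p_{regime}.csv")
    biplot = {}
    for regime, res in result.pca.items():
        res.loadings.to_csv(out / f"pca_loadings_{regime}.csv")
        res.scores.to_csv(out / f"pca_scores_{regime}.csv")
        biplot[regime] = {
            "eigenvalues": res.eigenvalues.tolist(),
            "proportion": res.proportion.tolist(),
            "variables": {
                v: res.variable_coords.loc[v, ["PC1", "PC2"]].tolist()
                for v in res.variable_coords.index
            },
            "observations": {
                str(o): res.scores.loc[o, ["PC1", "PC2"]].tolist()
                for o in res.scores.index
            },
        }
    (out / "biplot_data.json").write_text(json.dumps(biplot, indent=2))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
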