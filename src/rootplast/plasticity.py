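"""Relative distance plasticity index (RDPI).

For a trait x measured on individuals of one genotype grown under two
environments, every cross-environment pair (a from WW, b from WD)
contributes a relative distance

    rd = |x_b - x_a| / (x_b + x_a)        (0 <= rd <= 1 for x >= 0)

and the RDPI is the mean of rd over all such pairs.  RDPI is 0 when the
trait is identical across environments and approaches 1 when one
environment drives the trait to zero.  Pairs with x_a = x_b = 0 have an
undefined relative distance and are excluded (the pair count n is
decremented) rather than scored 0.

Useful closed form: if every WD value is exactly k times the paired WW
value, each rd equals (1-k)/(1+k), hence RDPI = (1-k)/(1+k) — e.g. a 50%
reduction (k = 0.5) gives RDPI = 1/3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RDPIResult", "relative_distance", "rdpi", "rdpi_table", "PLASTICITY_TRAITS"]

#: Trait columns of the per-plant analysis table the RDPI grid runs over.
PLASTICITY_TRAITS = (
    "wp_kg_m3",
    "root_shoot",
    "rdw_g",
    "sdw_g",
    "rl_cm",
    "sa_cm2",
    "rv_cm3",
    "mrd_mm",
)


@dataclass(frozen=True)
class RDPIResult:
    """All cross-environment relative distances of one genotype × trait."""

    genotype: str
    trait: str
    distances: np.ndarray = field(repr=False)
    relative_distances: np.ndarray = field(repr=False)
    n: int
    rdpi: float
    excluded_pairs: int = 0


def relative_distance(x_a: float, x_b: float) -> float:
    """Relative distance |x_b - x_a| / (x_b + x_a) between two trait values.

    Undefined (NaN, with a warning) when both values are zero; negative
    inputs are an error since the index is defined for nonnegative traits.
    """
    if x_a < 0 or x_b < 0:
        raise ValueError("relative distance requires nonnegative trait values")
    if x_a + x_b == 0:
        warnings.warn("both trait values zero: relative distance undefined",
                      stacklevel=2)
        return float("nan")
    return abs(x_b - x_a) / (x_b + x_a)


def rdpi(
    values_ww, values_wd, *, genotype: str = "", trait: str = ""
) -> RDPIResult:
    """RDPI over all cross-environment pairs of one genotype.

    Vectorized over the full (len(values_ww) × len(values_wd)) pair grid;
    within-environment pairs never enter.  Zero–zero pairs are excluded
    from the mean and counted in ``excluded_pairs``.
    """
    ww = np.asarray(values_ww, dtype=float)
    wd = np.asarray(values_wd, dtype=float)
    if ww.size == 0 or wd.size == 0:
        raise ValueError("both environments need at least one individual")
    if np.any(ww < 0) or np.any(wd < 0):
        raise ValueError("RDPI requires nonnegative trait values")
    a = ww[:, None]
    b = wd[None, :]
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        rd = np.abs(b - a) / total
    distances = np.abs(b - a).ravel()
    rd = rd.ravel()
    defined = total.ravel() > 0
    excluded = int((~defined).sum())
    if excluded:
        warnings.warn(
            f"{excluded} zero-zero pair(s) excluded from RDPI", stacklevel=2
        )
    kept = rd[defined]
    if kept.size == 0:
        raise ValueError("no defined cross-environment pairs")
    return RDPIResult(
        genotype=genotype,
        trait=trait,
        distances=distances[defined],
        relative_distances=kept,
        n=int(kept.size),
        rdpi=float(kept.mean()),
        excluded_pairs=excluded,
    )


def rdpi_table(
    analysis: pd.DataFrame, traits=PLASTICITY_TRAITS
) -> tuple[pd.DataFrame, list[RDPIResult]]:
    """Per genotype × trait RDPI grid from a per-plant analysis table.

    ``analysis`` holds one row per plant with ``genotype``, ``regime``
    and the trait columns.  Genotypes lacking either environment are
    skipped with a warning.  Returns the tidy summary frame
    (genotype, trait, n, rdpi, excluded_pairs) and the full per-pair
    results for downstream ANOVA on the relative distances.
    """
    rows = []
    results: list[RDPIResult] = []
    for genotype, group in analysis.groupby("genotype", sort=False):
        ww = group[group["regime"] == "WW"]
        wd = group[group["regime"] == "WD"]
        if ww.empty or wd.empty:
            warnings.warn(
                f"genotype {genotype}: missing one environment, skipped",
                stacklevel=2,
            )
            continue
        for trait in traits:
            vww = ww[trait].dropna().to_numpy(float)
            vwd = wd[trait].dropna().to_numpy(float)
            if vww.size == 0 or vwd.size == 0:
                warnings.warn(
                    f"genotype {genotype}, trait {trait}: no data", stacklevel=2
                )
                continue
            result = rdpi(vww, vwd, genotype=str(genotype), trait=trait)
            results.append(result)
            rows.append(
                {
                    "genotype": genotype,
                    "trait": trait,
                    "n": result.n,
                    "rdpi": result.rdpi,
                    "excluded_pairs": result.excluded_pairs,
                }
            )
    return pd.DataFrame(rows), results
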