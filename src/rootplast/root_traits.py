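"""Root-system-architecture trait summaries from root-segment tables.

Each scanned root segment is modelled as a cylinder of diameter ``d`` (mm)
and length ``L`` (mm), so its surface area is pi*d*L and its volume
pi*(d/2)^2*L.  Segments are binned by substrate depth layer (default
0–10, 10–20, 20–30, 30–40 cm, assigned by segment midpoint depth) and by
root diameter class (default nine 0.5 mm classes from 0 to 4.5 mm), and
four traits are aggregated per group:

* RL  — total root length, cm
* SA  — total root surface area, cm^2
* RV  — total root volume, cm^3
* MRD — mean root diameter, mm (length-weighted by default)

Binning intervals are half-open [a, b) with the final bin closed at the
top edge, so the layers and classes partition the segments and the
per-group RL/SA/RV sum exactly to the whole-plant totals.  Diameters
beyond the last class edge go to a flagged overflow class rather than
being dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "OVERFLOW_CLASS",
    "segment_geometry",
    "assign_depth_layer",
    "assign_diameter_class",
    "aggregate_traits",
    "trait_table",
]

#: Label index used for diameters beyond the last class edge.
OVERFLOW_CLASS = -1

DEFAULT_LAYER_EDGES = (0.0, 10.0, 20.0, 30.0, 40.0)
DEFAULT_CLASS_EDGES = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5)


def segment_geometry(length_mm, diameter_mm):
    """Cylinder surface area (mm^2) and volume (mm^3) of segments.

    Accepts scalars or arrays; rejects nonpositive lengths or diameters.
    """
    length = np.asarray(length_mm, dtype=float)
    diameter = np.asarray(diameter_mm, dtype=float)
    if np.any(length <= 0) or np.any(diameter <= 0):
        raise ValueError("segment length and diameter must be > 0")
    surface = np.pi * diameter * length
    volume = np.pi * (diameter / 2.0) ** 2 * length
    return surface, volume


def _bin_half_open(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """1-based bin index for half-open [a, b) bins, last bin closed."""
    idx = np.digitize(values, edges, right=False)  # 0 below, len(edges) above
    idx[values == edges[-1]] = len(edges) - 1  # close the top edge
    return idx


def assign_depth_layer(depth_cm, layer_edges=DEFAULT_LAYER_EDGES) -> np.ndarray:
    """1-based depth-layer index; depths outside [0, max edge] are an error."""
    edges = np.asarray(layer_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("layer_edges must be strictly increasing")
    depth = np.atleast_1d(np.asarray(depth_cm, dtype=float))
    if np.any(depth < edges[0]) or np.any(depth > edges[-1]):
        raise ValueError(
            f"depth outside [{edges[0]:g}, {edges[-1]:g}] cm profile"
        )
    return _bin_half_open(depth, edges)


def assign_diameter_class(diameter_mm, class_edges=DEFAULT_CLASS_EDGES) -> np.ndarray:
    """1-based diameter-class index; oversized diameters get OVERFLOW_CLASS."""
    edges = np.asarray(class_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("class_edges must be strictly increasing")
    diameter = np.atleast_1d(np.asarray(diameter_mm, dtype=float))
    if np.any(diameter <= 0):
        raise ValueError("diameter must be > 0")
    idx = _bin_half_open(diameter, edges)
    idx[diameter > edges[-1]] = OVERFLOW_CLASS
    return idx


def _traits_of(group: pd.DataFrame, mrd_weighting: str) -> pd.Series:
    length = group["length_mm"].to_numpy(float)
    diameter = group["diameter_mm"].to_numpy(float)
    surface, volume = segment_geometry(length, diameter)
    if length.size == 0:
        mrd = np.nan
    elif mrd_weighting == "length":
        mrd = float(np.average(diameter, weights=length))
    else:
        mrd = float(diameter.mean())
    return pd.Series(
        {
            "rl_cm": length.sum() / 10.0,
            "sa_cm2": surface.sum() / 100.0,
            "rv_cm3": volume.sum() / 1000.0,
            "mrd_mm": mrd,
            "n_segments": length.size,
        }
    )


def aggregate_traits(
    segments: pd.DataFrame,
    grouping: str = "plant",
    *,
    layer_edges=DEFAULT_LAYER_EDGES,
    class_edges=DEFAULT_CLASS_EDGES,
    mrd_weighting: str = "length",
) -> pd.DataFrame:
    """Aggregate RL/SA/RV/MRD over the requested grouping.

    Parameters
    ----------
    segments
        Frame with columns ``plant_id, depth_cm, length_mm, diameter_mm``.
    grouping
        One of ``"plant"`` (whole-plant totals), ``"layer"``, ``"class"``
        or ``"layer_class"``; all are additionally grouped by plant.
    mrd_weighting
        ``"length"`` for a length-weighted mean diameter (default) or
        ``"unweighted"`` for a plain per-segment mean.

    Empty groups are omitted (an absent layer contributes zero to every
    additive trait); the whole-plant grouping on an empty table returns an
    empty frame.
    """
    if grouping not in {"plant", "layer", "class", "layer_class"}:
        raise ValueError(f"unknown grouping {grouping!r}")
    if mrd_weighting not in {"length", "unweighted"}:
        raise ValueError("mrd_weighting must be 'length' or 'unweighted'")
    segments = segments.copy()
    keys = ["plant_id"]
    if grouping in {"layer", "layer_class"}:
        segments["layer"] = assign_depth_layer(
            segments["depth_cm"].to_numpy(float), layer_edges
        )
        keys.append("layer")
    if grouping in {"class", "layer_class"}:
        segments["diameter_class"] = assign_diameter_class(
            segments["diameter_mm"].to_numpy(float), class_edges
        )
        keys.append("diameter_class")
    if segments.empty:
        return pd.DataFrame(
            columns=keys + ["rl_cm", "sa_cm2", "rv_cm3", "mrd_mm", "n_segments"]
        )
    out = (
        segments.groupby(keys, sort=True)
        .apply(_traits_of, mrd_weighting, include_groups=False)
        .reset_index()
    )
    out["n_segments"] = out["n_segments"].astype(int)
    return out


def trait_table(
    segments: pd.DataFrame,
    plants: pd.DataFrame,
    *,
    layer_edges=DEFAULT_LAYER_EDGES,
    class_edges=DEFAULT_CLASS_EDGES,
    mrd_weighting: str = "length",
) -> pd.DataFrame:
    """Whole-plant trait table joined with plant identity.

    Plants with no recorded segments appear with zero RL/SA/RV and
    missing MRD, so an empty scan never silently drops a plant.
    """
    per_plant = aggregate_traits(
        segments,
        "plant",
        layer_edges=layer_edges,
        class_edges=class_edges,
        mrd_weighting=mrd_weighting,
    )
    out = plants[["plant_id", "genotype", "regime", "block"]].merge(
        per_plant, on="plant_id", how="left"
    )
    for column in ("rl_cm", "sa_cm2", "rv_cm3"):
        out[column] = out[column].fillna(0.0)
    out["n_segments"] = out["n_segments"].fillna(0).astype(int)
    return out
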