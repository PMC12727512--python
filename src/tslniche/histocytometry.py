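"""Flow-cytometry-style gating and normalisation on cell/event tables.

Gates are named 2D polygons on pairs of feature columns, arranged in a
parent hierarchy exactly as in conventional flow analysis; membership is
boundary-inclusive. The module also provides the z-score heatmap matrix,
naive-reference marker normalisation and the cDC1-density^high gate
(mean + 1 population SD of max-normalised density).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

__all__ = [
    "GateDef",
    "HeatmapMatrix",
    "apply_gate",
    "apply_gates",
    "zscore_matrix",
    "normalize_to_reference_patch",
    "dc_high_gate",
]


@dataclass
class GateDef:
    """A named polygonal gate on two feature columns, with an optional parent."""

    name: str
    x_feature: str
    y_feature: str
    vertices: list[tuple[float, float]]
    parent: str | None = None

    def __post_init__(self) -> None:
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        if len(self.vertices) < 3:
            raise ValueError(f"gate {self.name!r} needs >= 3 vertices")
        self._polygon = Polygon(self.vertices)
        if self._polygon.area <= 0:
            raise ValueError(f"gate {self.name!r} polygon is degenerate (zero area)")

    @property
    def polygon(self) -> Polygon:
        return self._polygon


def apply_gate(
    table: pd.DataFrame, gate: GateDef, parent_mask: np.ndarray | None = None
) -> np.ndarray:
    """Boolean membership of each table row in the gate polygon.

    Points on the polygon boundary (including vertices) count as inside.
    When ``parent_mask`` is given, membership is intersected with it.
    """
    for feat in (gate.x_feature, gate.y_feature):
        if feat not in table.columns:
            raise KeyError(f"gate {gate.name!r}: feature column {feat!r} missing from table")
    x = np.asarray(table[gate.x_feature], dtype=float)
    y = np.asarray(table[gate.y_feature], dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError(f"gate {gate.name!r}: non-finite feature values")
    # intersects == covers for points: interior or boundary
    inside = shapely.intersects_xy(gate.polygon, x, y)
    if parent_mask is not None:
        inside = inside & np.asarray(parent_mask, dtype=bool)
    return inside


def apply_gates(table: pd.DataFrame, gates: list[GateDef]) -> pd.DataFrame:
    """Resolve a gate hierarchy; returns one boolean column per gate name."""
    by_name = {g.name: g for g in gates}
    masks: dict[str, np.ndarray] = {}

    def resolve(name: str, trail: tuple[str, ...] = ()) -> np.ndarray:
        if name in masks:
            return masks[name]
        if name in trail:
            raise ValueError(f"gate hierarchy cycle: {' -> '.join(trail + (name,))}")
        g = by_name[name]
        parent = None
        if g.parent is not None:
            if g.parent not in by_name:
                raise KeyError(f"gate {name!r} references unknown parent {g.parent!r}")
            parent = resolve(g.parent, trail + (name,))
        masks[name] = apply_gate(table, g, parent)
        return masks[name]

    for g in gates:
        resolve(g.name)
    return pd.DataFrame({g.name: masks[g.name] for g in gates}, index=table.index)


@dataclass
class HeatmapMatrix:
    """Per-cell z-scores sorted by subset, ready for heatmap rendering."""

    values: np.ndarray  # (cells, parameters)
    parameters: list[str]
    row_ids: np.ndarray
    subsets: list[str]
    subset_boundaries: list[int]  # cumulative row counts per subset


def zscore_matrix(
    table: pd.DataFrame,
    parameters: list[str],
    subset_col: str,
    subset_order: list[str],
    *,
    ddof: int = 0,
) -> HeatmapMatrix:
    """Standardize each parameter to a per-cell z-score and sort by subset.

    z = (x − mean) / SD with population SD by default (``ddof=0``); a column
    with zero spread maps to all-zero z with a warning. Rows are grouped in
    ``subset_order``; cells whose subset is not listed are dropped.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    if len(table) < 2:
        raise ValueError("z-scores need >= 2 rows")
    missing = [p for p in parameters if p not in table.columns]
    if missing:
        raise KeyError(f"missing parameter columns: {missing}")

    sel = table[table[subset_col].isin(subset_order)]
    order = pd.Categorical(sel[subset_col], categories=subset_order, ordered=True)
    sel = sel.iloc[np.argsort(order.codes, kind="stable")]

    X = sel[parameters].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    Z = np.zeros_like(X)
    for j, p in enumerate(parameters):
        if sd[j] == 0:
            warnings.warn(f"parameter {p!r} is constant; z-scores set to 0", stacklevel=2)
        else:
            Z[:, j] = (X[:, j] - mean[j]) / sd[j]

    counts = sel[subset_col].value_counts()
    boundaries = np.cumsum([int(counts.get(s, 0)) for s in subset_order]).tolist()
    row_ids = sel.index.to_numpy()
    return HeatmapMatrix(Z, list(parameters), row_ids, list(subset_order), boundaries)


def normalize_to_reference_patch(
    values: np.ndarray | pd.Series, patch_mean: float, threshold: float = 0.7
) -> tuple[np.ndarray, np.ndarray]:
    """Normalise marker means to a naive-reference patch mean; flag ``> threshold``.

    The reference is the mean channel intensity over a patch of the T cell
    zone densely populated with naive cells; the high flag is strict
    (a value exactly at the threshold is not flagged).
    """
    if patch_mean <= 0:
        raise ValueError(f"patch_mean must be > 0, got {patch_mean}")
    norm = np.asarray(values, dtype=float) / patch_mean
    return norm, norm > threshold


def dc_high_gate(
    dc_densities: np.ndarray | pd.Series, *, ddof: int = 0
) -> tuple[np.ndarray, float, np.ndarray]:
    """Gate cells in dense cDC1 regions: density above mean + 1 SD.

    Densities are first normalised to the population maximum (so the gate is
    scale-invariant); the threshold is mean + 1 population SD of the
    normalised values and membership is strict (>).

    Returns (membership flags, threshold, normalised densities).
    """
    d = np.asarray(dc_densities, dtype=float)
    if d.size < 2:
        raise ValueError("dc_high_gate needs >= 2 cells")
    dmax = d.max()
    if dmax <= 0:
        raise ValueError("all cDC1 densities are zero; cannot normalise")
    norm = d / dmax
    threshold = float(norm.mean() + norm.std(ddof=ddof))
    return norm > threshold, threshold, norm
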