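"""Multi-criteria suitability surfaces (0-255) per land-use class.

Evidence comes in two flavours. *Factors* are continuous fuzzy memberships
standardized to the byte range 0-255: categorical environmental factors are
scored by the percentage of a class's union extent falling on each factor
category (percent x 2.55), while distance-based factors (to settlements,
rivers, roads, or to existing patches of the class itself) are Euclidean
distances normalized to [0, 1] over the study mask and reverse-stretched to
255-0. *Constraints* are binary masks that exclude cells outright: water
cells for every class but water, cells fixed by persistence of the land cover
across the observed period, and — for human-driven classes — cells outside
the union of the class's observed extents.

The class suitability surface is the weighted linear combination of its
factors multiplied by the product of its constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import GridGeometry, LandUseGrid, require_coregistered
from .weights import WeightVector

__all__ = [
    "FactorLayer",
    "ConstraintLayer",
    "SuitabilityStack",
    "categorical_factor_scores",
    "distance_factor",
    "autocorrelation_factor",
    "build_constraints",
    "wlc_suitability",
    "bin_continuous",
]

#: Classes whose historical extent is bounded by the union of observed extents.
HUMAN_CLASSES = ("arable", "settlement")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (inputs here are always non-negative)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


@dataclass
class FactorLayer:
    """Byte-scaled (0-255) suitability evidence on a grid."""

    geometry: GridGeometry
    values: np.ndarray
    name: str = "factor"
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != self.geometry.shape:
            raise ValueError("factor shape does not match geometry")
        if self.valid_mask is None:
            self.valid_mask = np.ones(v.shape, dtype=bool)
        inside = v[self.valid_mask]
        if inside.size and (inside.min() < 0 or inside.max() > 255):
            raise ValueError(f"factor {self.name!r} has values outside [0, 255]")
        self.values = v.astype(np.int64)


@dataclass
class ConstraintLayer:
    """Binary exclusion mask: 0 removes the cell from consideration."""

    geometry: GridGeometry
    values: np.ndarray
    name: str = "constraint"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != self.geometry.shape:
            raise ValueError("constraint shape does not match geometry")
        if not np.all(np.isin(v, (0, 1))):
            raise ValueError(f"constraint {self.name!r} must be binary")
        self.values = v.astype(np.int64)


@dataclass
class SuitabilityStack:
    """Per-class suitability surfaces plus the constraints that shaped them."""

    geometry: GridGeometry
    suitability: dict[str, FactorLayer]
    constraints: dict[str, ConstraintLayer] = field(default_factory=dict)

    def classes(self) -> list[str]:
        return list(self.suitability.keys())

    def as_array(self, class_order: Sequence[str] | None = None) -> np.ndarray:
        order = list(class_order) if class_order is not None else self.classes()
        return np.stack([self.suitability[c].values for c in order]).astype(float)


def bin_continuous(values: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    """Bin a continuous surface (elevation, slope) into 1-based class codes."""
    return np.digitize(np.asarray(values, dtype=float), np.asarray(edges, dtype=float)) + 1


def categorical_factor_scores(
    class_union_mask: np.ndarray,
    factor_grid: LandUseGrid,
) -> tuple[FactorLayer, pd.Series]:
    """Score a categorical factor by class occupancy percentages.

    For each factor category k, percent(k) is 100 x the share of the class
    union falling on k; the cell score is round(2.55 x percent at the cell's
    category). Returns the scored layer and the percent table.
    """
    mask = np.asarray(class_union_mask, dtype=bool)
    valid = factor_grid.valid_mask
    union = mask & valid
    n_union = int(union.sum())
    if n_union == 0:
        raise ValueError("class union mask is empty on the valid factor area")
    percents = {}
    scores = np.zeros(factor_grid.geometry.shape, dtype=np.int64)
    for code, name in factor_grid.schema.entries:
        on_k = factor_grid.values == code
        pct = 100.0 * np.count_nonzero(union & on_k) / n_union
        percents[name] = pct
        scores[on_k] = _round_half_up(2.55 * pct)
    layer = FactorLayer(factor_grid.geometry, scores, name="categorical", valid_mask=valid)
    return layer, pd.Series(percents, name="percent")


def distance_factor(
    feature_mask: np.ndarray,
    geometry: GridGeometry,
    valid_mask: np.ndarray | None = None,
    name: str = "distance",
) -> FactorLayer:
    """Reverse-stretched Euclidean-distance factor.

    Distance to the nearest feature cell is normalized by its maximum over
    the valid study area and mapped to round(255 x (1 - d/d_max)); feature
    cells score 255 and the farthest cell scores 0.
    """
    mask = np.asarray(feature_mask, dtype=bool)
    if mask.shape != geometry.shape:
        raise ValueError("feature mask shape does not match geometry")
    if not mask.any():
        raise ValueError("feature mask is empty")
    if valid_mask is None:
        valid_mask = np.ones(mask.shape, dtype=bool)
    d = ndimage.distance_transform_edt(~mask, sampling=geometry.cell_size)
    d_max = d[valid_mask].max()
    if d_max == 0:  # features cover the whole valid area
        scores = np.full(mask.shape, 255, dtype=np.int64)
    else:
        scores = _round_half_up(255.0 * (1.0 - d / d_max))
        scores = np.clip(scores, 0, 255)
    return FactorLayer(geometry, scores, name=name, valid_mask=np.asarray(valid_mask, bool))


def autocorrelation_factor(reference_map: LandUseGrid, class_code: int) -> FactorLayer:
    """Distance factor anchored on existing patches of the class itself.

    Encodes spatial autocorrelation: a class is likelier near where it already
    occurs in the reference map.
    """
    mask = reference_map.class_mask(class_code)
    if not mask.any():
        raise ValueError(
            f"class {reference_map.schema.name_of(class_code)!r} absent from reference map"
        )
    return distance_factor(
        mask,
        reference_map.geometry,
        valid_mask=reference_map.valid_mask,
        name=f"autocorr_{reference_map.schema.name_of(class_code)}",
    )


def build_constraints(
    class_name: str,
    geometry: GridGeometry,
    water_mask: np.ndarray | None = None,
    unchanged_map: LandUseGrid | None = None,
    union_masks: Mapping[str, np.ndarray] | None = None,
    human_classes: Sequence[str] = HUMAN_CLASSES,
) -> ConstraintLayer:
    """Combine the exclusion rules for one class into a binary layer.

    A cell is excluded (0) when it lies on the water mask and the class is not
    water, when the persistence map fixes a different class there, or when the
    class is human-driven (arable, settlement) and the cell falls outside the
    union of that class's observed extents.
    """
    ok = np.ones(geometry.shape, dtype=bool)
    if water_mask is not None and class_name != "water":
        ok &= ~np.asarray(water_mask, dtype=bool)
    if unchanged_map is not None:
        fixed = unchanged_map.valid_mask
        try:
            code = unchanged_map.schema.code_of(class_name)
            ok &= ~fixed | (unchanged_map.values == code)
        except KeyError:
            ok &= ~fixed
    if union_masks is not None and class_name in human_classes:
        if class_name not in union_masks:
            raise KeyError(f"union mask required for human class {class_name!r}")
        ok &= np.asarray(union_masks[class_name], dtype=bool)
    return ConstraintLayer(geometry, ok.astype(np.int64), name=f"constraint_{class_name}")


def wlc_suitability(
    factors: Sequence[FactorLayer],
    weights: WeightVector,
    constraints: Sequence[ConstraintLayer] = (),
    name: str = "suitability",
) -> FactorLayer:
    """Weighted linear combination of factors gated by constraints.

    S(cell) = round( sum_i w_i x_i(cell) ) x prod_j c_j(cell), in [0, 255].
    """
    if len(factors) != len(weights.w):
        raise ValueError(
            f"{len(factors)} factors but {len(weights.w)} weights"
        )
    if not factors:
        raise ValueError("at least one factor is required")
    geom = factors[0].geometry
    for layer in list(factors) + list(constraints):
        if layer.geometry != geom:
            raise ValueError("all layers must be co-registered")
    combo = np.zeros(geom.shape, dtype=float)
    for w, f in zip(weights.w, factors):
        combo += w * f.values
    score = _round_half_up(combo)
    for c in constraints:
        score = score * c.values
    valid = np.logical_and.reduce([f.valid_mask for f in factors])
    return FactorLayer(geom, np.clip(score, 0, 255), name=name, valid_mask=valid)
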