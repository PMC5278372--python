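"""Quantity control: how much of each class existed at the reconstruction date.

The target year predates systematic observation, so per-class totals are
estimated by fusing several imperfect sources (historical documents, Markov
extrapolation of later maps, areas digitized from period topographic maps),
each class carrying its own AHP-derived source weights. Fused areas are then
normalized so they sum exactly to the study-area total.

When a later-interval cross-tabulation serves as the transition model for the
reconstruction interval, it may first be edited by explicit rules (moving a
flow from one destination class to another, e.g. when a climatic regime change
makes a conversion implausible for the earlier interval), then backcast:
every column is rescaled to the known later-year margin and the earlier-year
quantities are the rescaled row totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster import GridGeometry, TransitionMatrix

__all__ = [
    "SourceAreaTable",
    "QuantityTable",
    "TransitionEditRule",
    "fuse_sources",
    "normalize_to_total",
    "edit_transitions",
    "backcast_quantities",
    "areas_to_cells",
]


@dataclass
class SourceAreaTable:
    """Per-class areas from several sources with per-class source weights.

    ``areas`` and ``weights`` are class x source DataFrames; NaN marks a
    source unavailable for that class. ``fused_override`` supplies classes
    whose fused area is taken as given (e.g. when the source breakdown is
    unavailable) and bypasses weighting.
    """

    areas: pd.DataFrame
    weights: pd.DataFrame
    fused_override: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.areas.index.equals(self.weights.index) or not self.areas.columns.equals(
            self.weights.columns
        ):
            raise ValueError("areas and weights must share index and columns")
        if np.any(self.areas.to_numpy() < 0):
            raise ValueError("areas must be non-negative")
        for cls in self.areas.index:
            if cls in self.fused_override:
                continue
            a = self.areas.loc[cls]
            w = self.weights.loc[cls]
            if np.any(w.notna() & a.isna()):
                bad = list(w.index[w.notna() & a.isna()])
                raise ValueError(f"class {cls!r}: weight given for missing area in source(s) {bad}")
            if np.any(a.notna() & w.isna()):
                bad = list(a.index[a.notna() & w.isna()])
                raise ValueError(f"class {cls!r}: area without weight in source(s) {bad}")
            avail = w.dropna()
            if len(avail) == 0:
                raise ValueError(f"class {cls!r} has no sources and no override")
            if abs(avail.sum() - 1.0) > 1e-6:
                raise ValueError(
                    f"class {cls!r}: source weights sum to {avail.sum():.6f}, expected 1"
                )


@dataclass
class QuantityTable:
    """Per-class target areas (ha) constrained to a study-area total."""

    targets: pd.Series
    study_total: float

    def __post_init__(self) -> None:
        self.targets = self.targets.astype(float)
        if np.any(self.targets < 0):
            raise ValueError("target areas must be non-negative")
        if abs(self.targets.sum() - self.study_total) > 0.01:
            raise ValueError(
                f"targets sum to {self.targets.sum():.4f}, expected {self.study_total:.4f}"
            )


@dataclass(frozen=True)
class TransitionEditRule:
    """Move a flow from one destination to another within a source row.

    ``amount`` is "all" (the whole ``from_class -> old_to`` flow) or a value
    in the matrix's unit. The source-row total is preserved exactly.
    """

    from_class: str
    old_to: str
    new_to: str
    amount: float | str = "all"


def fuse_sources(table: SourceAreaTable) -> pd.Series:
    """Weighted fusion: fused(c) = sum_s w(c, s) * area(c, s)."""
    fused = {}
    for cls in table.areas.index:
        if cls in table.fused_override:
            fused[cls] = float(table.fused_override[cls])
            continue
        a = table.areas.loc[cls]
        w = table.weights.loc[cls]
        avail = w.notna()
        fused[cls] = float((a[avail] * w[avail]).sum())
    return pd.Series(fused, name="fused_area_ha")


def normalize_to_total(areas: pd.Series, study_total: float) -> QuantityTable:
    """Scale all areas proportionally so they sum to the study-area total."""
    s = float(areas.sum())
    if s <= 0:
        raise ValueError("cannot normalize all-zero areas")
    scaled = areas.astype(float) * (study_total / s)
    # remove residual float error so the QuantityTable invariant holds exactly
    scaled.iloc[-1] += study_total - scaled.sum()
    return QuantityTable(scaled, study_total)


def edit_transitions(
    matrix: TransitionMatrix, rules: Sequence[TransitionEditRule]
) -> TransitionMatrix:
    """Apply move-flow rules in list order; row totals are invariant."""
    out = matrix.copy()
    names_i = list(matrix.schema_initial.names)
    names_f = list(matrix.schema_final.names)
    for rule in rules:
        if rule.from_class not in names_i:
            raise KeyError(f"unknown source class {rule.from_class!r}")
        for cls in (rule.old_to, rule.new_to):
            if cls not in names_f:
                raise KeyError(f"unknown destination class {cls!r}")
        i = names_i.index(rule.from_class)
        j_old = names_f.index(rule.old_to)
        j_new = names_f.index(rule.new_to)
        avail = out.cells[i, j_old]
        amount = avail if rule.amount == "all" else float(rule.amount)
        if amount > avail + 1e-9:
            raise ValueError(
                f"rule moves {amount} from {rule.from_class}->{rule.old_to} "
                f"but only {avail} is available"
            )
        out.cells[i, j_old] -= amount
        out.cells[i, j_new] += amount
    return out


def backcast_quantities(
    model_matrix: TransitionMatrix, known_final_margins: pd.Series
) -> QuantityTable:
    """Backcast earlier-year quantities from a transition model.

    Each column j is rescaled by known_final(j) / column_total(j); the
    earlier-year quantity of class i is the rescaled row total. Columns with
    zero total stay zero; a nonzero target margin on such a column is an
    error (the model provides no pathway into that class).
    """
    names_f = list(model_matrix.schema_final.names)
    margins = known_final_margins.reindex(names_f)
    if margins.isna().any():
        missing = list(margins.index[margins.isna()])
        raise ValueError(f"final margins missing for class(es) {missing}")
    if np.any(margins.to_numpy() < 0):
        raise ValueError("final margins must be non-negative")
    col_tot = model_matrix.final_totals
    m = margins.to_numpy(dtype=float)
    scale = np.zeros_like(col_tot)
    nonzero = col_tot > 0
    scale[nonzero] = m[nonzero] / col_tot[nonzero]
    dead = (~nonzero) & (m > 0)
    if np.any(dead):
        bad = [names_f[k] for k in np.flatnonzero(dead)]
        raise ValueError(
            f"nonzero target margin for class(es) {bad} whose model column is all zero"
        )
    rescaled = model_matrix.cells * scale[np.newaxis, :]
    backcast = pd.Series(
        rescaled.sum(axis=1), index=list(model_matrix.schema_initial.names), name="backcast_ha"
    )
    total = float(m.sum())
    backcast.iloc[-1] += total - backcast.sum()  # absorb float residual
    return QuantityTable(backcast, total)


def areas_to_cells(
    quantities: QuantityTable, geometry: GridGeometry, n_valid_cells: int
) -> pd.Series:
    """Convert per-class areas to integer cell quotas by largest remainder.

    The quotas sum to ``n_valid_cells`` exactly; the conversion is feasible
    only when the total area matches the valid-cell area within 1%.
    """
    cell_area = geometry.cell_area_ha
    grid_total = n_valid_cells * cell_area
    if abs(quantities.study_total - grid_total) > 0.01 * grid_total:
        raise ValueError(
            f"quantity total {quantities.study_total:.2f} ha is incompatible with "
            f"{n_valid_cells} cells of {cell_area} ha ({grid_total:.2f} ha)"
        )
    exact = quantities.targets.to_numpy(dtype=float) / cell_area
    exact = exact * (n_valid_cells / exact.sum())  # remove rounding drift
    base = np.floor(exact).astype(int)
    remainder = exact - base
    short = n_valid_cells - int(base.sum())
    if short > 0:
        top = np.argsort(-remainder, kind="stable")[:short]
        base[top] += 1
    return pd.Series(base, index=quantities.targets.index, name="cells")
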