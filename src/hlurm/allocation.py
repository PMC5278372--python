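"""Cellular-automata spatial allocation of per-class cell quotas.

Classes are allocated one at a time in a configured order (by default the
most anthropogenically constrained first: settlement, arable, water, wetland,
forest, grassland, other-unused). Within a class, candidate cells — unassigned
and not excluded by the class constraint — are visited in descending
suitability (ties broken by row-major index) over repeated passes:

* a STRICT pass accepts a cell only if (a) the class's suitability is the
  strict maximum over all classes at that cell, (b) any evidence value at the
  cell agrees with the class, and (c) at least ``neighbor_threshold`` of the
  cell's Moore-8 neighbours already carry the class (pre-assigned persistence
  cells seed this rule);
* when a pass assigns nothing and the quota is unmet, rules are dropped one
  at a time in the relaxation schedule (default: neighbour rule first, then
  the max-suitability rule, then the evidence rule), keeping the quota — the
  quantity control — as the binding constraint.

Everything is deterministic: identical inputs produce identical maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import CategorySchema, GridGeometry, LandUseGrid, require_coregistered
from .suitability import ConstraintLayer, SuitabilityStack

__all__ = ["AllocationConfig", "AllocationResult", "AllocationError", "neighbor_count", "allocate"]

#: Default reconstruction order.
DEFAULT_CLASS_ORDER = (
    "settlement",
    "arable",
    "water",
    "wetland",
    "forest",
    "grassland",
    "other_unused",
)

#: Rule identifiers, in default relaxation (drop) order.
RULE_NEIGHBOR = "neighbor"
RULE_MAX_PROB = "max_prob"
RULE_EVIDENCE = "evidence"
DEFAULT_RELAXATION = (RULE_NEIGHBOR, RULE_MAX_PROB, RULE_EVIDENCE)

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.int64)


class AllocationError(RuntimeError):
    pass


@dataclass(frozen=True)
class AllocationConfig:
    class_order: tuple[str, ...] = DEFAULT_CLASS_ORDER
    neighbor_threshold: int = 5
    relaxation_schedule: tuple[str, ...] = DEFAULT_RELAXATION

    def __post_init__(self) -> None:
        if not 0 <= self.neighbor_threshold <= 8:
            raise ValueError("neighbor_threshold must be in [0, 8]")
        unknown = set(self.relaxation_schedule) - {RULE_NEIGHBOR, RULE_MAX_PROB, RULE_EVIDENCE}
        if unknown:
            raise ValueError(f"unknown relaxation rule(s) {sorted(unknown)}")


@dataclass
class AllocationResult:
    map: LandUseGrid
    realized_counts: pd.Series
    pass_of_cell: np.ndarray  # -1 nodata, 0 pre-assigned, >=1 allocation pass
    audit: pd.DataFrame  # one row per allocated cell: row, col, class, pass, ruleset


def neighbor_count(map_values: np.ndarray, class_code: int, cell: tuple[int, int]) -> int:
    """Moore-8 neighbours of ``cell`` currently carrying ``class_code``.

    Off-grid neighbours count as non-matching.
    """
    r, c = cell
    n_rows, n_cols = map_values.shape
    if not (0 <= r < n_rows and 0 <= c < n_cols):
        raise IndexError(f"cell {cell} outside grid {map_values.shape}")
    count = 0
    for dr, dc in _MOORE:
        rr, cc = r + dr, c + dc
        if 0 <= rr < n_rows and 0 <= cc < n_cols and map_values[rr, cc] == class_code:
            count += 1
    return count


def _bump_neighbors(nbr: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> None:
    """Increment a per-class neighbour-count plane around assigned cells."""
    n_rows, n_cols = nbr.shape
    for dr, dc in _MOORE:
        rr = rows + dr
        cc = cols + dc
        ok = (rr >= 0) & (rr < n_rows) & (cc >= 0) & (cc < n_cols)
        np.add.at(nbr, (rr[ok], cc[ok]), 1)


def allocate(
    stack: SuitabilityStack,
    quotas: Mapping[str, int],
    constraints: Mapping[str, ConstraintLayer] | None = None,
    evidence_map: LandUseGrid | None = None,
    config: AllocationConfig = AllocationConfig(),
    schema: CategorySchema | None = None,
    fixed_map: LandUseGrid | None = None,
    valid_mask: np.ndarray | None = None,
) -> AllocationResult:
    """Distribute per-class cell quotas over the grid.

    ``fixed_map`` carries cells whose class is already known (persistence of
    the land cover across the observed period); they are assigned first and
    debited from the quotas, and they seed the neighbour rule. Quotas must sum
    exactly to the number of allocatable (valid) cells.
    """
    geom = stack.geometry
    classes = list(config.class_order)
    if set(classes) != set(stack.classes()):
        raise ValueError("class_order must be a permutation of the stack's classes")
    if schema is None:
        schema = CategorySchema(tuple((i + 1, n) for i, n in enumerate(classes)))
    code_of = {n: schema.code_of(n) for n in classes}
    n_rows, n_cols = geom.shape

    if valid_mask is None:
        valid_mask = np.logical_and.reduce(
            [stack.suitability[c].valid_mask for c in classes]
        )
    valid_mask = np.asarray(valid_mask, dtype=bool)
    n_alloc = int(valid_mask.sum())

    quotas = {c: int(quotas.get(c, 0)) for c in classes}
    if any(q < 0 for q in quotas.values()):
        raise AllocationError("quotas must be non-negative")
    if sum(quotas.values()) != n_alloc:
        raise AllocationError(
            f"quotas sum to {sum(quotas.values())} but {n_alloc} cells are allocatable"
        )

    suit = stack.as_array(classes)  # (k, rows, cols)
    k = len(classes)

    cons = {}
    for c in classes:
        if constraints and c in constraints:
            layer = constraints[c]
            if layer.geometry != geom:
                raise ValueError(f"constraint for {c!r} is not co-registered")
            cons[c] = layer.values.astype(bool)
        else:
            cons[c] = np.ones(geom.shape, dtype=bool)

    if evidence_map is not None:
        if evidence_map.geometry != geom:
            raise ValueError("evidence map is not co-registered")
        ev_values = evidence_map.values
        ev_valid = evidence_map.valid_mask
    else:
        ev_values = ev_valid = None

    out = np.full(geom.shape, schema.nodata_code, dtype=np.int64)
    pass_of_cell = np.full(geom.shape, -1, dtype=np.int64)
    assigned = ~valid_mask.copy()  # nodata cells are never allocatable
    remaining = dict(quotas)
    nbr = np.zeros((k, n_rows, n_cols), dtype=np.int64)
    audit_rows: list[tuple[int, int, str, int, str]] = []

    # Step 0: pre-assign constraint-fixed cells and debit quotas.
    if fixed_map is not None:
        if fixed_map.geometry != geom:
            raise ValueError("fixed map is not co-registered")
        for ci, c in enumerate(classes):
            code = code_of[c]
            m = (fixed_map.values == code) & valid_mask
            n_fixed = int(m.sum())
            if n_fixed == 0:
                continue
            if n_fixed > remaining[c]:
                raise AllocationError(
                    f"{n_fixed} cells are fixed as {c!r} but its quota is {remaining[c]}"
                )
            out[m] = code
            pass_of_cell[m] = 0
            assigned |= m
            remaining[c] -= n_fixed
            nbr[ci] = ndimage.correlate(m.astype(np.int64), _KERNEL, mode="constant")

    # Static per-class rule masks.
    flat_suit = suit.reshape(k, -1)
    order_of = {c: i for i, c in enumerate(classes)}

    for c in classes:
        ci = order_of[c]
        quota = remaining[c]
        if quota == 0:
            continue
        code = code_of[c]
        cand_mask = valid_mask & cons[c] & ~assigned
        cand = np.flatnonzero(cand_mask.ravel())
        if cand.size:
            s_c = flat_suit[ci, cand]
            cand = cand[np.lexsort((cand, -s_c))]

        # strict max-probability: S_c strictly greater than every other class
        others = np.max(np.delete(flat_suit, ci, axis=0), axis=0) if k > 1 else np.full(
            flat_suit.shape[1], -np.inf
        )
        max_ok_flat = flat_suit[ci] > others
        if ev_values is not None:
            ev_ok_flat = (~ev_valid | (ev_values == code)).ravel()
        else:
            ev_ok_flat = np.ones(n_rows * n_cols, dtype=bool)

        active = {RULE_MAX_PROB, RULE_EVIDENCE, RULE_NEIGHBOR}
        drop_queue = list(config.relaxation_schedule)
        nbr_c = nbr[ci]
        assigned_flat = assigned.ravel()
        pass_no = 0

        while quota > 0:
            pass_no += 1
            tag = "strict" if len(active) == 3 else "-" + "-".join(
                r for r in DEFAULT_RELAXATION if r not in active
            )
            cand = cand[~assigned_flat[cand]]
            ok = cand
            if RULE_MAX_PROB in active:
                ok = ok[max_ok_flat[ok]]
            if RULE_EVIDENCE in active:
                ok = ok[ev_ok_flat[ok]]
            if RULE_NEIGHBOR in active:
                thr = config.neighbor_threshold
                taken: list[int] = []
                nbr_flat = nbr_c.ravel()
                for idx in ok:
                    if nbr_flat[idx] >= thr:
                        r, cc_ = divmod(int(idx), n_cols)
                        out[r, cc_] = code
                        assigned_flat[idx] = True
                        _bump_neighbors(nbr_c, np.array([r]), np.array([cc_]))
                        taken.append(int(idx))
                        quota -= 1
                        if quota == 0:
                            break
                take = np.asarray(taken, dtype=np.int64)
            else:
                take = ok[:quota]
                if take.size:
                    rows, cols = np.divmod(take, n_cols)
                    out[rows, cols] = code
                    assigned_flat[take] = True
                    _bump_neighbors(nbr_c, rows, cols)
                    quota -= take.size
            if take.size:
                rows, cols = np.divmod(take, n_cols)
                pass_of_cell[rows, cols] = pass_no
                audit_rows.extend(
                    (int(r), int(col), c, pass_no, tag) for r, col in zip(rows, cols)
                )
            if quota == 0:
                break
            if take.size == 0:
                # stalled pass: relax by dropping the next active rule
                dropped = False
                while drop_queue:
                    rule = drop_queue.pop(0)
                    if rule in active:
                        active.discard(rule)
                        dropped = True
                        break
                if not dropped:
                    # no rules left to drop: with an empty active set a pass
                    # assigns every live candidate, so a stall means none exist
                    raise AllocationError(
                        f"class {c!r} has quota {quota} left but no feasible cells "
                        "after all relaxations"
                    )
        remaining[c] = quota

    # Fallback: any still-unassigned allocatable cell goes to the class with
    # the highest remaining quota (then highest suitability, then class order).
    left = np.flatnonzero(valid_mask.ravel() & ~assigned.ravel())
    for idx in left:
        best = max(
            classes,
            key=lambda c: (remaining[c], flat_suit[order_of[c], idx], -order_of[c]),
        )
        r, cc_ = divmod(int(idx), n_cols)
        out[r, cc_] = code_of[best]
        assigned.ravel()[idx] = True
        if remaining[best] > 0:
            remaining[best] -= 1
        pass_of_cell[r, cc_] = -2  # fallback marker
        audit_rows.append((r, cc_, best, -1, "fallback"))

    grid = LandUseGrid(geom, out, schema)
    counts = pd.Series(
        {c: int(np.count_nonzero(out == code_of[c])) for c in classes}, name="cells"
    )
    audit = pd.DataFrame(audit_rows, columns=["row", "col", "class", "pass", "ruleset"])
    return AllocationResult(grid, counts, pass_of_cell, audit)
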