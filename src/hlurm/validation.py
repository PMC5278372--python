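"""Three-map comparison of a simulated map against two reference dates.

Overlaying reference time 1, reference time 2 and simulation time 2 classifies
every cell into one of four components: null success (persistence observed and
predicted), hit (change observed and predicted), miss (observed change
predicted as persistence) and false alarm (observed persistence predicted as
change). In categorical mode a hit additionally requires the simulated class
to match the reference-time-2 class; cells where both maps change but to
different classes (partial hits) are then counted as misses. In binary mode
change alone is compared and partial hits sit inside the hits.

From the component percentages the summary budget follows: observed change
OC = H + M, predicted change PC = H + F, quantity error EQ = |M - F|,
allocation error EA = 2 min(M, F), figure of merit FOM = H / (H + M + F), and
the observed-change ratios HOC = H/OC, MOC = M/OC, FOC = F/OC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import LandUseGrid, TransitionMatrix, require_coregistered

__all__ = [
    "ComponentCounts",
    "ValidationBudget",
    "three_map_components",
    "comparison_budgets",
    "change_budget",
    "COMPONENT_CODES",
]

#: Component grid codes.
COMPONENT_CODES = {"null_success": 0, "hit": 1, "miss": 2, "false_alarm": 3}


@dataclass(frozen=True)
class ComponentCounts:
    """Accuracy/error components as percentages of the valid study area."""

    N: float  # null successes
    H: float  # hits
    M: float  # misses
    F: float  # false alarms
    PH: float = 0.0  # partial hits (within H in binary mode, within M otherwise)
    mode: str = "categorical"
    n_valid: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "categorical"):
            raise ValueError("mode must be 'binary' or 'categorical'")
        for name in ("N", "H", "M", "F", "PH"):
            if getattr(self, name) < 0:
                raise ValueError(f"component {name} must be non-negative")
        total = self.N + self.H + self.M + self.F
        # published component tables are rounded to 0.01%, so allow that slack
        if abs(total - 100.0) > 0.01 + 1e-6:
            raise ValueError(f"components must sum to 100% (got {total:.4f})")
        host = self.H if self.mode == "binary" else self.M
        if self.PH > host + 1e-9:
            raise ValueError("partial hits exceed their host component")


@dataclass(frozen=True)
class ValidationBudget:
    OC: float  # observed change
    PC: float  # predicted change
    total_error: float
    EQ: float  # quantity error
    EA: float  # allocation error
    FOM: float  # figure of merit, percent
    HOC: float
    MOC: float
    FOC: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "OC": self.OC,
                "PC": self.PC,
                "total_error": self.total_error,
                "EQ": self.EQ,
                "EA": self.EA,
                "FOM": self.FOM,
                "HOC": self.HOC,
                "MOC": self.MOC,
                "FOC": self.FOC,
            }
        )


def three_map_components(
    ref_t1: LandUseGrid,
    ref_t2: LandUseGrid,
    sim_t2: LandUseGrid,
    mode: str = "categorical",
) -> tuple[np.ndarray, ComponentCounts]:
    """Classify each cell as null success / hit / miss / false alarm.

    Returns the component grid (codes 0-3, -1 at nodata) and the counts as
    percentages of the cells valid in all three maps. A second value in the
    grid is not needed for partial hits: they are a subset of hits (binary) or
    misses (categorical) and are reported in the counts.
    """
    require_coregistered(ref_t1, ref_t2, sim_t2)
    if ref_t1.schema.codes != ref_t2.schema.codes or ref_t1.schema.codes != sim_t2.schema.codes:
        raise ValueError("the three maps must share one category schema")
    if mode not in ("binary", "categorical"):
        raise ValueError("mode must be 'binary' or 'categorical'")
    valid = ref_t1.valid_mask & ref_t2.valid_mask & sim_t2.valid_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no jointly valid cells")
    obs_change = ref_t1.values != ref_t2.values
    pred_change = ref_t1.values != sim_t2.values
    correct_class = sim_t2.values == ref_t2.values

    comp = np.full(ref_t1.geometry.shape, -1, dtype=np.int64)
    null_s = ~obs_change & ~pred_change
    partial = obs_change & pred_change & ~correct_class
    if mode == "binary":
        hit = obs_change & pred_change
        miss = obs_change & ~pred_change
    else:
        hit = obs_change & pred_change & correct_class
        miss = (obs_change & ~pred_change) | partial
    false_alarm = ~obs_change & pred_change

    comp[valid & null_s] = COMPONENT_CODES["null_success"]
    comp[valid & hit] = COMPONENT_CODES["hit"]
    comp[valid & miss] = COMPONENT_CODES["miss"]
    comp[valid & false_alarm] = COMPONENT_CODES["false_alarm"]

    pct = lambda m: 100.0 * np.count_nonzero(m & valid) / n_valid
    counts = ComponentCounts(
        N=pct(null_s),
        H=pct(hit),
        M=pct(miss),
        F=pct(false_alarm),
        PH=pct(partial),
        mode=mode,
        n_valid=n_valid,
    )
    return comp, counts


def comparison_budgets(counts: ComponentCounts) -> ValidationBudget:
    """Summary metrics from the component percentages.

    FOM is a percentage; HOC/MOC/FOC are ratios of observed change and are
    NaN (with a warning) when no change was observed.
    """
    h, m, f = counts.H, counts.M, counts.F
    oc = h + m
    pc = h + f
    total_error = m + f
    eq = abs(m - f)
    ea = 2.0 * min(m, f)
    fom = 100.0 * h / (h + m + f) if (h + m + f) > 0 else np.nan
    if oc == 0:
        warnings.warn("no observed change: HOC/MOC/FOC are undefined", UserWarning, stacklevel=2)
        hoc = moc = foc = np.nan
    else:
        hoc, moc, foc = h / oc, m / oc, f / oc
    return ValidationBudget(oc, pc, total_error, eq, ea, fom, hoc, moc, foc)


def change_budget(matrix: TransitionMatrix) -> pd.DataFrame:
    """Per-class gross gain/loss and the landscape total change.

    Gross loss of class i is its initial total minus persistence; gross gain
    of class j its final total minus persistence. Total change (= sum of
    losses = sum of gains) equals the matrix's off-diagonal mass.
    """
    if matrix.schema_initial.codes != matrix.schema_final.codes:
        raise ValueError("change budget requires a square matrix on one schema")
    names = list(matrix.schema_initial.names)
    df = pd.DataFrame(
        {
            "initial_total": matrix.initial_totals,
            "final_total": matrix.final_totals,
            "persistence": np.diag(matrix.cells),
            "gross_loss": matrix.gross_loss,
            "gross_gain": matrix.gross_gain,
        },
        index=names,
    )
    df.attrs["total_change"] = float(matrix.gross_loss.sum())
    df.attrs["unit"] = matrix.unit
    return df
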