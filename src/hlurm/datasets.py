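"""Packaged example tables from the Zhenlai County 1930s reconstruction.

These are the published summary tables of the case study — the multi-source
per-class area estimates with their AHP source weights, the per-class factor
weights used for suitability mapping, the reference and simulated 1954-1932
change matrices (six merged classes), and the printed accuracy components of
the three-map comparison. The spatial rasters themselves were never deposited;
see :mod:`hlurm.synthetic` for generated stand-ins.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .quantity import SourceAreaTable
from .raster import MERGED_SCHEMA, TransitionMatrix
from .validation import ComponentCounts

__all__ = [
    "STUDY_TOTAL_HA",
    "FUSED_OVERRIDES",
    "load_source_area_table",
    "load_factor_weights",
    "load_change_matrix",
    "reference_components",
]

#: Study-area total controlling the 1930s quantity normalization (ha).
STUDY_TOTAL_HA = 531606.14

#: Classes whose fused area is carried as published: the other-unused source
#: breakdown is incomplete, so its fused value cannot be recomputed.
FUSED_OVERRIDES: dict[str, float] = {"other_unused": 618.69}

_SOURCE_ORDER = ["markov", "documents", "dtm_500k", "dtm_100k", "dtm_50k"]


def _data_path(name: str):
    return resources.files("hlurm.data").joinpath(name)


def load_source_area_table() -> SourceAreaTable:
    """Multi-source 1930s area estimates and per-class source weights."""
    with resources.as_file(_data_path("zhenlai_1930s_sources.csv")) as p:
        long = pd.read_csv(p)
    classes = list(dict.fromkeys(long["class"]))
    areas = long.pivot(index="class", columns="source", values="area_ha")
    weights = long.pivot(index="class", columns="source", values="weight")
    areas = areas.reindex(index=classes, columns=_SOURCE_ORDER)
    weights = weights.reindex(index=classes, columns=_SOURCE_ORDER)
    # override classes keep their published fused value, so drop their partial rows
    for cls in FUSED_OVERRIDES:
        areas.loc[cls] = np.nan
        weights.loc[cls] = np.nan
    return SourceAreaTable(areas, weights, fused_override=dict(FUSED_OVERRIDES))


def load_factor_weights() -> pd.DataFrame:
    """Factor-by-class suitability weights (blank = factor unused)."""
    with resources.as_file(_data_path("zhenlai_factor_weights.csv")) as p:
        return pd.read_csv(p, index_col=0)


def load_change_matrix(which: str) -> TransitionMatrix:
    """Reference or simulated 1954-1932 change matrix (six classes, ha)."""
    if which not in ("reference", "simulated"):
        raise ValueError("which must be 'reference' or 'simulated'")
    with resources.as_file(_data_path(f"zhenlai_{which}_change.csv")) as p:
        df = pd.read_csv(p, index_col=0)
    return TransitionMatrix.from_dataframe(df, MERGED_SCHEMA, unit="ha")


def reference_components() -> ComponentCounts:
    """Published three-map accuracy components (% of study area)."""
    return ComponentCounts(N=36.45, H=30.62, M=26.97, F=5.95, mode="binary")
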