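"""Seeded synthetic landscapes, factor surfaces and forward change.

Real historical rasters for the study region are not distributable, so every
other module is exercised on generated fixtures: spatially autocorrelated
categorical landscapes with a chosen class composition, environmental factor
surfaces correlated with class placement, point/line feature masks for the
distance factors, a partial evidence raster, and forward change driven by a
specified transition matrix (so that backcasting has a known truth).

The default composition is the seven-class 1930s reconstruction of the study
county (grassland-dominated, arable second); the default forward-change matrix
is persistence-heavy (85% staying put per interval). A single integer seed
fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .raster import CategorySchema, DEFAULT_SCHEMA, GridGeometry, LandUseGrid, TransitionMatrix
from .suitability import SuitabilityStack

__all__ = [
    "SynthConfig",
    "generate_landscape",
    "generate_factors",
    "simulate_forward_change",
    "DEFAULT_PROPORTIONS",
]

#: Seven-class area shares of the reconstructed 1930s landscape.
DEFAULT_PROPORTIONS: dict[str, float] = {
    "arable": 0.24448,
    "forest": 0.00127,
    "grassland": 0.63167,
    "water": 0.01745,
    "settlement": 0.00707,
    "wetland": 0.09690,
    "other_unused": 0.00116,
}


def _default_transitions(k: int) -> np.ndarray:
    """Persistence-heavy row-stochastic matrix: 85% stay, rest spread evenly."""
    p = np.full((k, k), 0.15 / (k - 1))
    np.fill_diagonal(p, 0.85)
    return p


@dataclass
class SynthConfig:
    n_rows: int = 200
    n_cols: int = 200
    proportions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    smoothing_radius: int = 3  # cells; box-filter half-width
    cell_size: float = 90.0  # metres
    n_point_features: int = 12  # e.g. settlements
    n_line_features: int = 3  # e.g. rivers, roads
    evidence_coverage: float = 0.3
    transition_probs: np.ndarray | None = None  # row-stochastic, class order of schema
    seed: int = 0
    schema: CategorySchema = DEFAULT_SCHEMA

    def __post_init__(self) -> None:
        p = np.array([self.proportions.get(n, 0.0) for n in self.schema.names], dtype=float)
        if np.any(p < 0):
            raise ValueError("class proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"class proportions must sum to 1 (got {p.sum():.6f})")
        unknown = set(self.proportions) - set(self.schema.names)
        if unknown:
            raise ValueError(f"proportions given for unknown class(es) {sorted(unknown)}")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.n_rows, self.n_cols, self.cell_size)

    @property
    def proportion_vector(self) -> np.ndarray:
        return np.array([self.proportions.get(n, 0.0) for n in self.schema.names], dtype=float)


def _smoothed_uniform_fields(rng, k: int, shape: tuple[int, int], radius: int) -> np.ndarray:
    """Per-class random fields, box-smoothed then rank-transformed to [0, 1]."""
    fields = rng.standard_normal((k, *shape))
    if radius > 0:
        size = 2 * radius + 1
        for i in range(k):
            fields[i] = ndimage.uniform_filter(fields[i], size=size, mode="reflect")
    n = shape[0] * shape[1]
    flat = fields.reshape(k, n)
    ranks = np.empty_like(flat)
    for i in range(k):
        order = np.argsort(flat[i], kind="stable")
        ranks[i, order] = np.arange(n, dtype=float) / max(n - 1, 1)
    return ranks  # (k, n)


def _quota_argmax_labels(ranks: np.ndarray, quotas: np.ndarray) -> np.ndarray:
    """Label cells by the class of their highest calibrated field, subject to
    exact per-class quotas: classes that fill up release their weaker cells to
    the runner-up class, preserving spatial coherence."""
    k, n = ranks.shape
    labels = np.full(n, -1, dtype=np.int64)
    remaining = quotas.astype(np.int64).copy()
    work = ranks.copy()
    unassigned = np.arange(n)
    while unassigned.size:
        open_classes = np.flatnonzero(remaining > 0)
        sub = work[np.ix_(open_classes, unassigned)]
        best = np.argmax(sub, axis=0)
        progressed = False
        for bi, ci in enumerate(open_classes):
            mine = unassigned[best == bi]
            if mine.size == 0:
                continue
            if mine.size > remaining[ci]:
                keep = mine[np.argsort(-work[ci, mine], kind="stable")[: remaining[ci]]]
            else:
                keep = mine
            labels[keep] = ci
            remaining[ci] -= keep.size
            if keep.size:
                progressed = True
        unassigned = np.flatnonzero(labels < 0)
        if not progressed:  # pragma: no cover - quotas sum to n, so this ends
            break
    return labels


def _largest_remainder(p: np.ndarray, n: int) -> np.ndarray:
    exact = p * n
    base = np.floor(exact).astype(np.int64)
    short = n - int(base.sum())
    if short > 0:
        base[np.argsort(-(exact - base), kind="stable")[:short]] += 1
    return base


def generate_landscape(config: SynthConfig) -> LandUseGrid:
    """Generate a spatially autocorrelated categorical landscape.

    Per-class random fields are box-smoothed with the configured radius,
    rank-calibrated, and cells labelled by their best class under exact
    per-class quotas derived from the target proportions (largest remainder),
    so realized proportions match the targets to within one cell each.
    """
    rng = np.random.default_rng(config.seed)
    k = len(config.schema)
    shape = (config.n_rows, config.n_cols)
    ranks = _smoothed_uniform_fields(rng, k, shape, config.smoothing_radius)
    p = config.proportion_vector
    ranks[p == 0] = -np.inf  # absent classes never win
    quotas = _largest_remainder(p, config.n_rows * config.n_cols)
    labels = _quota_argmax_labels(ranks, quotas)
    codes = np.array(config.schema.codes)[labels].reshape(shape)
    return LandUseGrid(config.geometry, codes, config.schema)


def _random_polyline_mask(rng, shape: tuple[int, int]) -> np.ndarray:
    """A sinuous line spanning the grid (random drift around a straight path)."""
    n_rows, n_cols = shape
    mask = np.zeros(shape, dtype=bool)
    horizontal = bool(rng.integers(2))
    length = n_cols if horizontal else n_rows
    lateral = n_rows if horizontal else n_cols
    pos = float(rng.integers(lateral))
    for t in range(length):
        pos = float(np.clip(pos + rng.normal(0, 0.8), 0, lateral - 1))
        r, c = (int(pos), t) if horizontal else (t, int(pos))
        mask[r, c] = True
    return mask


def generate_factors(landscape: LandUseGrid, config: SynthConfig):
    """Factor, feature and evidence rasters correlated with the landscape.

    Returns a dict with:

    * ``categorical``: dict of factor grids (soil, geomorphology, aspect);
      each factor category preferentially overlaps one land-use class
      (75% adherence, 25% uniform noise), giving positive class-factor
      mutual information;
    * ``features``: dict of boolean masks (settlements = points, rivers and
      roads = polylines) for distance factors;
    * ``evidence``: a partial copy of the landscape covering the configured
      fraction of cells (nodata elsewhere).
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    shape = landscape.geometry.shape
    k = len(landscape.schema)
    codes = np.array(landscape.schema.codes)

    categorical: dict[str, LandUseGrid] = {}
    for fname in ("soil", "geomorphology", "aspect"):
        n_cat = k
        fschema = CategorySchema(tuple((i + 1, f"{fname}_{i + 1}") for i in range(n_cat)))
        preferred = rng.permutation(n_cat) + 1  # class index -> factor category
        class_idx = np.searchsorted(codes, landscape.values)
        vals = preferred[class_idx]
        noise = rng.random(shape) < 0.25
        vals = np.where(noise, rng.integers(1, n_cat + 1, size=shape), vals)
        vals = np.where(landscape.valid_mask, vals, fschema.nodata_code)
        categorical[fname] = LandUseGrid(landscape.geometry, vals, fschema)

    features: dict[str, np.ndarray] = {}
    pts = np.zeros(shape, dtype=bool)
    idx = rng.choice(shape[0] * shape[1], size=min(config.n_point_features, pts.size), replace=False)
    pts.ravel()[idx] = True
    features["settlements"] = pts
    for fname in ("rivers", "roads"):
        m = np.zeros(shape, dtype=bool)
        for _ in range(config.n_line_features):
            m |= _random_polyline_mask(rng, shape)
        features[fname] = m

    ev_vals = np.full(shape, landscape.schema.nodata_code, dtype=np.int64)
    if config.evidence_coverage > 0:
        cover = rng.random(shape) < config.evidence_coverage
        cover &= landscape.valid_mask
        ev_vals[cover] = landscape.values[cover]
    evidence = LandUseGrid(landscape.geometry, ev_vals, landscape.schema)

    return {"categorical": categorical, "features": features, "evidence": evidence}


def _row_stochastic(matrix, k: int) -> np.ndarray:
    if isinstance(matrix, TransitionMatrix):
        cells = matrix.cells
        totals = cells.sum(axis=1)
        p = np.eye(k)
        nz = totals > 0
        p[nz] = cells[nz] / totals[nz, None]
        return p
    p = np.asarray(matrix, dtype=float)
    if p.shape != (k, k) or np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition probabilities must be a non-negative row-stochastic k x k matrix")
    return p


def simulate_forward_change(
    map_t1: LandUseGrid,
    transition_matrix,
    suitability: SuitabilityStack | None = None,
    seed: int = 0,
) -> LandUseGrid:
    """Advance a landscape one interval under a transition model.

    Without suitability, each cell of class i independently moves to class j
    with probability p_ij, so realized transition proportions converge to the
    matrix as the grid grows. With a suitability stack, per-class destination
    counts are fixed at round(n_i * p_ij) (largest remainder) and the cells
    most suitable for each destination are the ones converted, preserving the
    marginal transition rates while making change spatially structured.
    """
    schema = map_t1.schema
    k = len(schema)
    p = _row_stochastic(transition_matrix, k)
    rng = np.random.default_rng(seed)
    codes = np.array(schema.codes)
    out = map_t1.values.copy()
    flat = map_t1.values.ravel()
    out_flat = out.ravel()
    for i, code in enumerate(codes):
        cells = np.flatnonzero(flat == code)
        if cells.size == 0:
            continue
        if suitability is None:
            dest = rng.choice(k, size=cells.size, p=p[i])
            out_flat[cells] = codes[dest]
        else:
            counts = _largest_remainder(p[i], cells.size)
            remaining = cells.copy()
            # allocate destinations from rarest to commonest so small flows
            # get first pick of their most suitable cells
            for j in np.argsort(counts, kind="stable"):
                nij = int(counts[j])
                if nij == 0 or remaining.size == 0:
                    continue
                s_j = suitability.suitability[schema.names[j]].values.ravel()[remaining]
                pick = remaining[np.argsort(-s_j, kind="stable")[:nij]]
                out_flat[pick] = codes[j]
                remaining = np.setdiff1d(remaining, pick, assume_unique=True)
    return LandUseGrid(map_t1.geometry, out_flat.reshape(map_t1.geometry.shape), schema)
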