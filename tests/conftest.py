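import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hlurm.raster import CategorySchema, GridGeometry, LandUseGrid
from hlurm.suitability import ConstraintLayer, FactorLayer, SuitabilityStack

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


TOY_SCHEMA = CategorySchema(entries=((1, "A"), (2, "B"), (3, "C")))


def make_grid(values, cell_size=90.0, schema=None, nodata=-9999):
    """Build a LandUseGrid from a nested list / array of codes."""
    values = np.asarray(values)
    if schema is None:
        codes = sorted(int(v) for v in np.unique(values) if v != nodata)
        schema = CategorySchema(
            entries=tuple((c, f"class_{c}") for c in codes), nodata_code=nodata
        )
    geom = GridGeometry(values.shape[0], values.shape[1], cell_size)
    return LandUseGrid(geom, values, schema)


def feasible_random_scenario(seed, n=100, k=4):
    """A random allocation problem the ordered sweep can always solve.

    Mirrors the intended workflow: a water-style mask is pre-assigned to one
    class (and excluded for the rest), one human-style class is confined to a
    union-range mask, the remaining classes are unconstrained. Returns
    (stack, quotas, constraints, fixed_map, config kwargs).
    """
    from hlurm.allocation import AllocationConfig

    rng = np.random.default_rng(seed)
    geom = GridGeometry(n, n, 90.0)
    names = [f"c{i}" for i in range(k)]
    schema = CategorySchema(tuple((i + 1, nm) for i, nm in enumerate(names)))
    suit = {
        nm: FactorLayer(geom, rng.integers(0, 256, size=(n, n)), name=nm) for nm in names
    }
    stack = SuitabilityStack(geom, suit)

    water, human = names[0], names[1]
    water_mask = rng.random((n, n)) < 0.03
    union = water_mask | (rng.random((n, n)) < 0.5)  # human range, must cover quota

    n_cells = n * n
    n_water = int(water_mask.sum()) + int(rng.integers(0, 50))
    pool_human = int((union & ~water_mask).sum())
    n_human = int(rng.integers(1, max(2, pool_human // 2)))
    rest = n_cells - n_water - n_human
    split = rng.multinomial(rest, np.ones(k - 2) / (k - 2))
    quotas = {water: n_water, human: n_human}
    quotas.update({nm: int(v) for nm, v in zip(names[2:], split)})

    constraints = {}
    for nm in names:
        ok = np.ones((n, n), dtype=bool)
        if nm != water:
            ok &= ~water_mask
        if nm == human:
            ok &= union
        constraints[nm] = ConstraintLayer(geom, ok.astype(int), name=nm)

    fixed_vals = np.where(water_mask, schema.code_of(water), schema.nodata_code)
    fixed = LandUseGrid(geom, fixed_vals, schema)
    config = AllocationConfig(class_order=tuple(names))
    return stack, quotas, constraints, fixed, schema, config
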