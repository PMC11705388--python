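import numpy as np
import pytest

from cropswitch import (
    build_default_cfts,
    gen_baseline_allocation,
    gen_region,
)
from cropswitch.cfts import DEMAND_CATEGORIES
from cropswitch.demand import DemandSet


@pytest.fixture(scope="session")
def cfts():
    return build_default_cfts()


@pytest.fixture(scope="session")
def region10():
    """The default toy region: 10 counties × 4 cells, national-scale area."""
    return gen_region(10, 4, seed=1)


@pytest.fixture(scope="session")
def baseline_alloc(region10, cfts):
    return gen_baseline_allocation(region10, cfts, seed=2)


@pytest.fixture
def unit_demand():
    """Positive but negligible demand: p_sf saturates at 1 only with real production."""
    return DemandSet(
        year=0, by_category={c: 1.0 for c in DEMAND_CATEGORIES}, per_capita={}
    )


def naive_front_peel(F: np.ndarray) -> list[np.ndarray]:
    """Independent O(n²)-per-front dominance oracle: peel nondominated layers.

    A point is nondominated in the current layer iff no other remaining point
    is <= in all objectives and < in at least one — checked directly from the
    definition, point by point.
    """
    remaining = np.arange(len(F))
    fronts = []
    while len(remaining):
        keep = []
        for i in remaining:
            others = F[remaining]
            dominated = (
                (others <= F[i]).all(axis=1) & (others < F[i]).any(axis=1)
            ).any()
            if not dominated:
                keep.append(i)
        keep = np.array(keep)
        fronts.append(keep)
        remaining = np.setdiff1d(remaining, keep)
    return fronts
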