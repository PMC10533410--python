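import numpy as np
import pandas as pd
import pytest

from icbspatial.registry import PhenotypeRegistry, make_generic_registry
from icbspatial.simulate import SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def registry():
    return PhenotypeRegistry()


@pytest.fixture(scope="session")
def small_registry():
    return make_generic_registry(2, 3)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact two-timepoint cohort reused by read-only tests."""
    cfg = SyntheticConfig(
        seed=11,
        n_tumours_per_arm=6,
        timepoints=("baseline", "on_treatment"),
        images_per_tumour=(1, 2),
        cells_per_image=(60, 100),
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def toy_cells(records):
    """Cell table from (cell_id, phenotype, compartment[, ki67]) tuples."""
    rows = []
    for rec in records:
        cid, ph, comp = rec[:3]
        ki = rec[3] if len(rec) > 3 else False
        rows.append(
            {
                "cell_id": cid,
                "x_um": float(cid),
                "y_um": 0.0,
                "area_um2": 60.0,
                "phenotype": ph,
                "compartment": comp,
                "ki67_positive": ki,
            }
        )
    return pd.DataFrame(rows)
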