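import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dosimargin import (
    CoverageCriterion,
    DoseProfileParams,
    GridSpec,
    PhantomSpec,
    StudyConfig,
    generate_dose,
    make_phantom,
    run_study,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    """A compact test grid: ±40 mm at 2 mm spacing (41^3 voxels)."""
    return GridSpec.centered(half_extent=40.0, spacing=2.0)


@pytest.fixture(scope="session")
def structures(grid):
    return make_phantom(PhantomSpec(), grid)


@pytest.fixture(scope="session")
def ctv(structures):
    return structures["CTV"]


@pytest.fixture(scope="session")
def point_dose(structures, grid):
    return generate_dose(DoseProfileParams("point"), structures, grid, 48.0)


@pytest.fixture(scope="session")
def marginal80_dose(structures, grid):
    return generate_dose(
        DoseProfileParams("marginal", isodose_level=80.0), structures, grid, 48.0
    )


@pytest.fixture(scope="session")
def criterion():
    return CoverageCriterion()


@pytest.fixture(scope="session")
def study_result():
    """One full default-configuration sweep, shared across tests."""
    return run_study(StudyConfig())
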