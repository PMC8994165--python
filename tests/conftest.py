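import numpy as np
import pytest

import perimetry as pm


@pytest.fixture(scope="session")
def grid24():
    return pm.build_standard_grid("24-2")


@pytest.fixture(scope="session")
def tess24(grid24):
    return pm.voronoi_tessellate(grid24)


@pytest.fixture(scope="session")
def adj24(tess24):
    return pm.adjacency_from_tessellation(tess24)


@pytest.fixture(scope="session")
def plan24(grid24):
    return pm.build_growth_plan(grid24)


@pytest.fixture(scope="session")
def cohort_spec():
    return pm.CohortSpec(n_subjects=200, seed=20210406)


@pytest.fixture(scope="session")
def cohort(cohort_spec):
    fields, truth = pm.synth_healthy_cohort(cohort_spec)
    return fields, truth


@pytest.fixture(scope="session")
def norm_model(cohort):
    return pm.fit_normative_model(cohort[0])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
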