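import numpy as np
import pytest

import betabym as bb

# ---- the 4-county toy used for oracle comparisons -------------------------
# path graph 0-1-2-3; one centered covariate; outcomes consistent with a
# mild positive slope around 68% prevalence
TOY_X = np.array([-5.0, -1.0, 2.0, 4.0])
TOY_Y = np.array([0.62, 0.66, 0.71, 0.74])
TOY_PHI = 150.0
TOY_SIGMA_W2 = 0.02


@pytest.fixture(scope="session")
def toy_table():
    return bb.CountyTable(
        area_id=[f"T{i}" for i in range(4)],
        area_name=[f"toy {i}" for i in range(4)],
        y=TOY_Y,
        X=TOY_X[:, None],
        covariate_names=["x1"],
    )


@pytest.fixture(scope="session")
def toy_graph():
    return bb.graph_from_edgelist(4, [(0, 1), (1, 2), (2, 3)])


# ---- the default 8x8 synthetic fixture ------------------------------------


@pytest.fixture(scope="session")
def fixture_dataset():
    return bb.generate_dataset(bb.default_fixture_config())


@pytest.fixture(scope="session")
def fixture_samples(fixture_dataset):
    """A default-budget posterior sample of the 8x8 fixture, shared by tests."""
    ds = fixture_dataset
    return bb.run_sampler(ds.table, ds.graph, bb.PriorSpec(), bb.MCMCConfig(seed=11))


@pytest.fixture(scope="session")
def fixture_fit(fixture_samples, fixture_dataset):
    return bb.fit_result(fixture_samples, fixture_dataset.table)
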