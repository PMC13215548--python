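import numpy as np
import pandas as pd
import pytest

from u5trends import spacetime_model as st
from u5trends import synthetic_data as sd


@pytest.fixture(scope="session")
def path3_graph():
    return sd.AdjacencyGraph(
        region_names=("A", "B", "C"),
        edges=frozenset({frozenset(("A", "B")), frozenset(("B", "C"))}),
    )


@pytest.fixture(scope="session")
def fixture_graph():
    return sd.default_adjacency()


@pytest.fixture(scope="session")
def toy_records():
    """Three equal-weight children, all born in month 0, one death at age 6."""
    return pd.DataFrame(
        {
            "child_id": ["a", "b", "c"],
            "cluster_id": ["k1", "k1", "k2"],
            "stratum_id": ["R_urban"] * 3,
            "region": ["R"] * 3,
            "weight": [1.0, 1.0, 1.0],
            "birth_month": [0, 0, 0],
            "death_age_months": [6.0, np.nan, np.nan],
            "interview_month": [119, 119, 119],
        }
    )


@pytest.fixture(scope="session")
def model2_fit(fixture_graph):
    """A moderate-noise fit of the full space-time model, reused across tests."""
    spec = sd.default_truth_spec(seed=42, graph=fixture_graph)
    surface = sd.simulate_truth(spec)
    rng = np.random.default_rng(7)
    v = np.full(surface.eta.shape, 0.01)
    y = surface.eta + rng.standard_normal(surface.eta.shape) * np.sqrt(v)
    cells = st.ObservedCells(
        regions=surface.regions, years=surface.years, y=y, v=v
    )
    mspec = st.ModelSpec(n_iter=2500, n_burn=500, thin=2, seed=11)
    fit = st.gibbs_fit(cells, fixture_graph, mspec)
    return surface, cells, fit
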