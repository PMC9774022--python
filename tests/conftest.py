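import numpy as np
import pandas as pd
import pytest

import microbiodx as m


@pytest.fixture
def tiny_table():
    counts = np.array([[5, 0], [3, 2], [1, 7]], dtype=float)
    return m.FeatureTable(
        ["OTU1", "OTU2", "OTU3"], ["s1", "s2"], counts,
        lineages=["k__Bacteria;p__Firmicutes;g__Blautia",
                  "k__Bacteria;p__Firmicutes;g__Roseburia",
                  "k__Bacteria;p__Bacteroidota;g__Bacteroides"],
    )


@pytest.fixture
def tiny_metadata():
    return m.CohortMetadata(pd.DataFrame({
        "sample_id": ["s1", "s2"],
        "group": ["HC", "IgAN"],
        "sex": ["M", "F"],
        "age": [35, 41],
        "Scr": [70.0, 130.0],
        "ALB": [46.0, np.nan],
    }))


@pytest.fixture(scope="session")
def planted_cohort():
    """Medium cohort with 8 planted 4-fold markers, shared across tests."""
    return m.simulate_cohort({"HC": 30, "IgAN": 30}, n_features=80,
                             n_planted=8, effect_size=4.0, depth=5000, seed=11)


@pytest.fixture(scope="session")
def metabolome_batch():
    return m.simulate_metabolome({"HC": 20, "IgAN": 20}, n_qc=10,
                                 n_metabolites=40, seed=7)
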