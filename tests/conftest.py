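import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import omnidiet as od

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixtures():
    return od.make_table_fixtures()


@pytest.fixture()
def toy_table():
    """2-sample x 3-ASV annotated table, all retained by the filter ladder."""
    counts = pd.DataFrame(
        [[90, 10, 0], [30, 30, 40]],
        index=["s1", "s2"],
        columns=["a1", "a2", "a3"],
    )
    taxonomy = pd.DataFrame(
        {
            "phylum": ["Streptophyta"] * 3,
            "order": ["Poales", "Poales", "Fagales"],
            "family": ["Poaceae", "Poaceae", "Casuarinaceae"],
            "genus": ["Eleusine", "Cynodon", "Casuarina"],
            "species": ["Eleusine indica", "Cynodon sp.", "Casuarina equisetifolia"],
        },
        index=["a1", "a2", "a3"],
    )
    return od.AnnotatedASVTable(counts=counts, taxonomy=taxonomy, marker="plant_ITS2")


@pytest.fixture(scope="session")
def sim_asv():
    cfg = od.AsvSimConfig(n_samples=60, seed=11)
    return od.simulate_asv_table(cfg)


@pytest.fixture(scope="session")
def occ_sim(sim_asv):
    table, meta, truth = sim_asv
    filt = od.filter_asv_table(
        table, "Streptophyta", excluded_genera=("Arachis", "Avena")
    )
    rra, zero = od.relative_read_abundance(filt)
    return od.occurrence_from_rra(rra, 0.01, zero), meta


@pytest.fixture(scope="session")
def iso_small():
    """Small K=3 isotope study with no random effects."""
    from omnidiet.simulate import default_source_truth

    cfg = od.IsotopeSimConfig(
        source_truth=default_source_truth(3),
        p_true=np.array([0.5, 0.3, 0.2]),
        n_consumers=40,
        seed=3,
    )
    return od.simulate_isotope_study(cfg), cfg
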