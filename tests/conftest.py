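import warnings

import numpy as np
import pandas as pd
import pytest

import canmorb as cm
from canmorb.registry_data import CANONICAL_REGIONS

warnings.filterwarnings("ignore", message="ArviZ")


def make_small_table(n_regions=3, years=(2000, 2001), cancer_type="lung", seed=0):
    """Tiny valid registration table over a few canonical regions/bands."""
    rng = np.random.default_rng(seed)
    rows = []
    for region in CANONICAL_REGIONS[:n_regions]:
        for band in ("45-49", "60-64", "85+"):
            for gender in ("male", "female"):
                for year in years:
                    rows.append(
                        {
                            "age_band": band,
                            "year": year,
                            "gender": gender,
                            "region": region,
                            "count": int(rng.integers(0, 50)),
                            "exposure": float(rng.uniform(5e4, 2e5)),
                        }
                    )
    return cm.RegistrationTable(pd.DataFrame(rows), cancer_type=cancer_type)


@pytest.fixture
def small_table():
    return make_small_table()


@pytest.fixture(scope="session")
def lung_sim():
    """One default-size synthetic lung-like dataset with its truth."""
    truth = cm.default_truth(seed=20160101)
    table, design, log_theta = cm.simulate_registrations(truth)
    return truth, table, design, log_theta


@pytest.fixture(scope="session")
def lung_fit(lung_sim):
    """A fitted posterior on the session dataset (moderate chain length)."""
    truth, table, design, _ = lung_sim
    config = cm.SamplerConfig(
        seed=7, n_chains=2, n_iterations=1200, burn_in=600, thinning=2
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = cm.run_chain(table, design, config)
    return truth, table, design, draws
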