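import numpy as np
import pandas as pd
import pytest

import wpindex as w


@pytest.fixture(scope="session")
def small_events():
    """One season, 3 sites: site A active days 1-3 with a day-2 detection."""
    events = pd.DataFrame(
        {
            "species_id": ["paca", "paca", "agouti"],
            "site_id": ["A", "A", "B"],
            "date": pd.to_datetime(["2008-02-02", "2008-02-02", "2008-02-01"]),
        }
    )
    deployments = pd.DataFrame(
        {
            "site_id": ["A", "B", "C"],
            "start_date": pd.to_datetime(["2008-02-01", "2008-02-01", "2008-02-02"]),
            "end_date": pd.to_datetime(["2008-02-03", "2008-02-02", "2008-02-03"]),
        }
    )
    return events, deployments


@pytest.fixture(scope="session")
def recovery_data():
    """One well-identified dataset: 200 sites x 5 years x 15 periods,
    truth psi1=0.6, phi=0.8, gamma=0.1, p=0.4 (intercept-only)."""
    params = w.SpeciesSimParams(
        "sp", beta_psi=[np.log(0.6 / 0.4)], phi=[0.8] * 4, gamma=[0.1] * 4, p=[0.4] * 5
    )
    cov = w.simulate_site_covariates(200, seed=41)
    Z, y = w.simulate_species(params, cov, 5, 15, seed=42)
    spec = w.ModelSpec((), "constant", "constant", "constant", 5, 15)
    return y, Z, spec, np.ones((200, 1))
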