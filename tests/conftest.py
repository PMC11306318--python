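import numpy as np
import pandas as pd
import pytest

from h2sindex import GasLog, SimParams, simulate_latent_cohort

SEASON_CYCLE = ("winter", "spring", "summer", "autumn")
SEG_CYCLE = ("wastewater_network", "treatment_plant", "pumping_station", "water_network")


def make_log(values, **kwargs):
    return GasLog.from_ppm(values, **kwargs)


@pytest.fixture(scope="session")
def small_latent_cohort():
    """A small but structurally complete latent cohort (4 SEGs, 6 weeks)."""
    params = SimParams(
        n_persons={
            "wastewater_network": 5,
            "treatment_plant": 3,
            "pumping_station": 2,
            "water_network": 4,
        },
        study_weeks=6,
        study_months=1.5,
        seed=12345,
    )
    return params, simulate_latent_cohort(params)


def balanced_index_frame(
    n_persons=60,
    n_days=15,
    within_fraction=0.71,
    total_var=1.0,
    grand_log_mean=1.5,
    seed=0,
):
    """Index values drawn from the declared worker-random-intercept model."""
    rng = np.random.default_rng(seed)
    s_within = np.sqrt(total_var * within_fraction)
    s_between = np.sqrt(total_var * (1.0 - within_fraction))
    rows = []
    for i in range(n_persons):
        b = rng.normal(0.0, s_between)
        seg = SEG_CYCLE[i % 4]
        for j in range(n_days):
            y = grand_log_mean + b + rng.normal(0.0, s_within)
            rows.append(
                {
                    "person_id": f"p{i:03d}",
                    "seg": seg,
                    "season": SEASON_CYCLE[j % 4],
                    "index": float(np.exp(y)),
                    "censored": False,
                }
            )
    return pd.DataFrame(rows)
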