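import numpy as np
import pandas as pd
import pytest

from rotipop import CohortTable, default_otu_config, simulate_otu_table


def make_cohort(survivors, births=None, mictic=None, interval=8.0, replicate=1):
    """Tidy single-replicate cohort frame from parallel count lists."""
    n = len(survivors)
    births = births or [0] * n
    mictic = mictic or [0] * n
    rows = [
        {
            "replicate": replicate,
            "time_h": i * interval,
            "survivors": s,
            "births_total": b,
            "births_mictic": m,
        }
        for i, (s, b, m) in enumerate(zip(survivors, births, mictic))
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_otu_table():
    """48-sample study-design table, small enough for fast reuse."""
    table, truth = simulate_otu_table(
        default_otu_config(seed=42, n_otus=60, depth_range=(1500, 2500))
    )
    return table, truth


@pytest.fixture()
def three_replicate_cohort():
    frames = []
    for rep, (b, m) in enumerate([(8, 1), (12, 2), (20, 3)], start=1):
        frames.append(
            make_cohort([10, 10, 0], births=[b, 0, 0], mictic=[m, 0, 0], replicate=rep)
        )
    return CohortTable(pd.concat(frames, ignore_index=True))


@pytest.fixture(scope="session")
def global_rng():
    return np.random.default_rng(2024)
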