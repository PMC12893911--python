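import numpy as np
import pandas as pd
import pytest

from microrank.profiles import AbundanceTable
from microrank.ranking import MarkerPanel, RankingTable
from microrank.simulate import CohortSimConfig, make_planted_truth


@pytest.fixture
def small_config():
    """Reduced SGB universe for fast case-control / intervention tests."""
    return CohortSimConfig(n_sgbs=60, n_favourable=10, n_unfavourable=10)


@pytest.fixture
def small_truth(small_config):
    return make_planted_truth(small_config)


@pytest.fixture
def truth_ranking(small_truth):
    """A ranking consistent with the planted truth (jittered, deterministic)."""
    rng = np.random.default_rng(99)
    base = {1: 0.15, 0: 0.5, -1: 0.85}
    ranks = pd.Series(
        {s: base[d] + rng.uniform(-0.1, 0.1) for s, d in small_truth.direction.items()}
    ).sort_index()
    return RankingTable(pd.DataFrame({"health_rank": ranks, "diet_rank": ranks}))


@pytest.fixture
def toy_panel():
    return MarkerPanel.from_records(
        [
            ("hdl", "fasting", +1),
            ("triglycerides", "fasting", -1),
            ("pp_glucose", "postprandial", -1),
            ("blood_pressure", "personal", -1),
            ("hei", "dietary", +1),
        ]
    )


@pytest.fixture
def toy_table():
    data = pd.DataFrame(
        {
            "SGB0001": [0.10, 0.00, 0.30],
            "SGB0002": [0.25, 0.25, 0.25],
            "SGB0003": [0.00, 0.00, 0.40],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return AbundanceTable(data)


def write_profile_tsv(path, clades, samples, values):
    """Write a merged-profile TSV (percent scale) for reader tests."""
    df = pd.DataFrame(values, index=clades, columns=samples)
    df.index.name = "clade_name"
    df.to_csv(path, sep="\t")
    return path
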