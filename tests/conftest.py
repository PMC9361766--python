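import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from guildnet.containers import CountTable, SampleMetadata, parse_lineage
from guildnet.simulate import default_cohort_config, simulate

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def small_counts() -> CountTable:
    """3 taxa x 4 samples with full lineage annotation."""
    counts = pd.DataFrame(
        [[2, 7, 0, 5], [2, 0, 0, 3], [4, 0, 6, 2]],
        index=["t1", "t2", "t3"], columns=["s1", "s2", "s3", "s4"])
    lineage = {
        "t1": parse_lineage("k__Bacteria;p__Firmicutes;g__Blautia"),
        "t2": parse_lineage("k__Bacteria;p__Firmicutes;g__Roseburia"),
        "t3": parse_lineage("k__Bacteria;p__Bacteroidetes;g__Bacteroides"),
    }
    return CountTable(counts, lineage=lineage)


@pytest.fixture
def small_metadata() -> SampleMetadata:
    table = pd.DataFrame({
        "group": ["G1", "G1", "G2", "G3"],
        "family_id": ["F1", "F2", "F1", "F1"],
        "generation": [1, 1, 2, 3],
        "il6": [3.2, 2.8, np.nan, 1.0],
    }, index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"))
    return SampleMetadata(table)


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated default cohort shared by the read-only tests."""
    return simulate(default_cohort_config(seed=11))


def random_count_frame(rng: np.random.Generator, n_taxa=6, n_samples=5):
    counts = rng.integers(0, 50, size=(n_taxa, n_samples))
    counts[:, counts.sum(axis=0) == 0] += 1
    return pd.DataFrame(counts,
                        index=[f"t{i}" for i in range(n_taxa)],
                        columns=[f"s{j}" for j in range(n_samples)])
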