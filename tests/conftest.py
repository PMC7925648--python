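import numpy as np
import pytest

from drugsurv import SimConfig, SurvivalRecord, simulate_cohort


def records_from_arrays(times, events, prefix="P"):
    return [
        SurvivalRecord(f"{prefix}{i}", float(t), bool(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


def random_survival(rng, n, censor_frac=0.3, tie_prob=0.3):
    """Small random survival sample with ties and censoring for oracle
    comparisons."""
    times = rng.integers(1, 8, size=n).astype(float)  # integer times force ties
    if tie_prob == 0:
        times = rng.exponential(100, size=n) + 1
    events = rng.random(n) > censor_frac
    return times, events


@pytest.fixture(scope="session")
def single_group_cohort():
    """200-patient cohort forming one cancer-drug group, with 5 signal
    genes and 2 hazard-carrying blocks planted (generator defaults)."""
    cfg = SimConfig(
        n_genes=200,
        cancer_labels=("LUAD",),
        drug_names=(("cisplatin", ("Cisplatin", "CISPLATIN")),),
        seed=11,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted survival signal anywhere."""
    cfg = SimConfig(
        n_patients=100,
        n_genes=150,
        n_signal_genes=0,
        n_blocks=0,
        cancer_labels=("LUAD",),
        drug_names=(("cisplatin", ("Cisplatin",)),),
        seed=5,
    )
    return cfg, simulate_cohort(cfg)
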