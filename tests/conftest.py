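import numpy as np
import pytest

import episenet as ep
from episenet.intervals import intervals_from_bed


def call_sample_ses(cohort, params=None):
    """Stitch, rank and call SEs for every sample of a cohort."""
    params = params or ep.SECallingParams()
    se_sets = {}
    for sample, df in cohort.peaks.items():
        stitched = ep.stitch_enhancers(
            intervals_from_bed(df), cohort.genome, params
        )
        ranked = ep.rank_enhancers(
            stitched, df[["chrom", "start", "end", "ip", "input"]]
        )
        called, _ = ep.call_superenhancers(ranked, params)
        se_sets[sample] = called
    return se_sets


@pytest.fixture(scope="session")
def default_cohort():
    """The default 24-sample synthetic cohort."""
    return ep.simulate_cohort(ep.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_repertoire(default_cohort):
    return ep.build_consensus(call_sample_ses(default_cohort))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 5v5 Luminal/Basal cohort for differential tests."""
    return ep.simulate_cohort(
        ep.CohortConfig(n_samples_per_group={"Luminal": 5, "Basal": 5}, seed=11)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
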