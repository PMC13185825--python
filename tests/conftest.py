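import numpy as np
import pytest
from hypothesis import settings

from repsv.annotate import annotate_cohort
from repsv.simulate import CohortConfig, GenomeModel, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by read-only tests."""
    cfg = CohortConfig(seed=11, n_svs=1200, n_taurine=6, n_indicine=6, n_hybrid=3)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_annotations(small_cohort):
    return annotate_cohort(
        small_cohort.cohort,
        small_cohort.repeats,
        small_cohort.genes,
        small_cohort.metadata,
    )


@pytest.fixture(scope="session")
def big_genome():
    """A roomier genome for dense simulations (29 x 3 Mb autosomes + 4.5 Mb X)."""
    chroms = tuple((str(i), 3_000_000) for i in range(1, 30)) + (("X", 4_500_000),)
    return GenomeModel(chroms)
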