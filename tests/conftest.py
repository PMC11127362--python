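import pytest

from prebioresponse import synthetic


@pytest.fixture(scope="session")
def small_params() -> synthetic.SimParams:
    """A small cohort: fast enough for per-module tests."""
    return synthetic.SimParams(
        n_subjects=12,
        n_contigs=8,
        genes_per_contig=25,
        n_decoy_targets=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return synthetic.simulate_cohort(small_params)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-sized cohort (40 donors), shared across tests."""
    return synthetic.simulate_cohort(synthetic.SimParams(seed=1))
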