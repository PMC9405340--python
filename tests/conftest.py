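import pytest

from icdmir.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic dataset at the documented fixed seed."""
    return generate_dataset(SyntheticSpec(rng_seed=0))


@pytest.fixture(scope="session")
def tiny_spec():
    """A small spec for fast generator-level tests."""
    return SyntheticSpec(
        n_mirna=20, n_mrna=40, icd_up_mirnas=3, icd_down_mirnas=3,
        icd_up_genes=3, icd_down_genes=3, n_replicates=3,
        transcript_length=200, rng_seed=7,
    )
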