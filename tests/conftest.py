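import pytest

from alchemap.fixtures import FixtureSpec, generate_family, worked_example_set


@pytest.fixture(scope="session")
def worked_set():
    return worked_example_set()


@pytest.fixture(scope="session")
def family_set():
    """Two scaffold families x 5 substituents + 4 decoys (14 molecules)."""
    return generate_family(FixtureSpec(n_scaffolds=2, substituents_per_scaffold=5,
                                       n_decoys=4, seed=0))


@pytest.fixture(scope="session")
def family_dms(family_set):
    from alchemap.fingerprints import all_distance_matrices
    return all_distance_matrices(family_set)
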