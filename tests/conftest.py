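import pytest

from mybsurvey import synthetic_data as sd


@pytest.fixture(scope="session")
def profile():
    return sd.default_profile()


@pytest.fixture(scope="session")
def small_proteome():
    """Zero-noise planted proteome shared across scanner/phylogeny tests."""
    records, truth = sd.make_myb_proteome(
        {"1R": 4, "2R": 8, "3R": 3, "4R": 2}, noise_rate=0.0,
        n_decoys=5, seed=101)
    return records, truth.table.set_index("protein_id")
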