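import numpy as np
import pytest

from rpistack import SequenceRecord, SimulationConfig, simulate

RNA_ALPHABET = "ACGU"
AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_rna(rng, length):
    return "".join(rng.choice(list(RNA_ALPHABET), size=length))


def random_protein(rng, length):
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture(scope="session")
def small_dataset():
    """A small noisy motif-implanted dataset shared by pipeline-level tests."""
    cfg = SimulationConfig(
        n_pairs=120, n_rna=40, n_protein=40, noise=0.05, seed=7,
        rna_len_range=(60, 120), protein_len_range=(60, 120),
    )
    return simulate(cfg)


@pytest.fixture
def rna_record():
    return SequenceRecord(id="r", seq="ACGUACGUGGACUCAAGU", kind="rna")


@pytest.fixture
def protein_record():
    return SequenceRecord(id="p", seq="MKVLHWKRDEACDEFGHIKLMNPQRSTVWY", kind="protein")
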