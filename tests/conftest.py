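import numpy as np
import pytest

from replicomp.sequence_io import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AA))[rng.integers(0, 20, size=length)])


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def make_records(seqs: dict[str, str], species: str = "sp") -> list[ProteinRecord]:
    return [
        ProteinRecord(pid, species, f"{species}_chr", k, seq)
        for k, (pid, seq) in enumerate(seqs.items())
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
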