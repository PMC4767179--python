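import numpy as np
import pytest
from hypothesis import settings

from algbarcode.seqio import SeqRecord
from algbarcode.simulate import SimConfig, simulate_reference_db

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def records(*seqs: str, species: list[str] | None = None) -> tuple[SeqRecord, ...]:
    """Build records r0, r1, ... from raw sequences."""
    return tuple(
        SeqRecord(
            id=f"r{i}",
            sequence=s,
            species=None if species is None else species[i],
        )
        for i, s in enumerate(seqs)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_db():
    """A small simulated reference database with exact known divergences."""
    cfg = SimConfig(
        n_genera=2,
        species_per_genus=3,
        seqs_per_species=3,
        seq_length=600,
        intra_divergence=0.01,
        inter_divergence=0.10,
        seed=7,
    )
    recs, truth = simulate_reference_db(cfg)
    return cfg, recs, truth


def random_seq(rng, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
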