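import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from motupipe import CommunityConfig, SequenceRecord, generate_community

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def rec(rid: str, residues: str, **kw) -> SequenceRecord:
    return SequenceRecord(id=rid, residues=residues, **kw)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def small_community():
    """One deterministic 5-species community reused across modules."""
    config = CommunityConfig(
        n_species=5, reads_per_species=8, seq_length=600,
        within_substitutions=2, homopolymer_indel_rate=0.05,
        fragment_fraction=0.15, min_separation=30, seed=11,
    )
    records, truth, references = generate_community(config)
    return config, records, truth, references
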