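import numpy as np
import pytest

from satellite_miner.seqio import Read, ReadPair


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_read(rng, read_id="r", length=100, q_low=0, q_high=41):
    seq = "".join(rng.choice(list("ACGT"), size=length))
    quals = rng.integers(q_low, q_high, size=length).tolist()
    return Read(read_id, seq, quals)


def random_pair(rng, pair_id="p", length=100):
    return ReadPair(
        random_read(rng, pair_id, length), random_read(rng, pair_id, length), pair_id
    )
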