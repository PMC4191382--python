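import numpy as np
import pytest

from bayesmerge.records import AdaptorPair, ReadRecord, revcomp_str


@pytest.fixture
def rng():
    return np.random.default_rng(20140806)


@pytest.fixture
def adaptors():
    return AdaptorPair("AGATCGGAAGAGCACACGTC", "AGATCGGAAGAGCGTCGTGT")


def random_read(rng, length, name="r", alphabet="ACGT", qmin=2, qmax=41):
    bases = "".join(rng.choice(list(alphabet), size=length))
    return ReadRecord(name, bases, rng.integers(qmin, qmax + 1, size=length))


def make_noiseless_pair(rng, molecule_len, read_len, adaptors, q=40, name="p"):
    """Construct the exact reads a perfect sequencer would emit.

    Read 1 is the molecule followed by adaptor 1; read 2 the reverse
    complement followed by adaptor 2; random bases pad past the adaptor.
    Returns (r1, r2, molecule).
    """
    molecule = "".join(rng.choice(list("ACGT"), size=molecule_len))

    def build(template, adaptor):
        ideal = (template + adaptor)[:read_len]
        if len(ideal) < read_len:
            ideal += "".join(rng.choice(list("ACGT"), size=read_len - len(ideal)))
        return ReadRecord(name, ideal, np.full(read_len, q))

    return build(molecule, adaptors.a1), build(revcomp_str(molecule), adaptors.a2), molecule
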