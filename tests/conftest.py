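import numpy as np
import pytest

from ssrkit.io import Contig, GenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_genotypes() -> GenotypeTable:
    """Three markers on four individuals, including a missing call.

    m1: all heterozygous (150,152); m2: mixed; m3: monomorphic with one
    missing call.
    """
    individuals = ["i1", "i2", "i3", "i4"]
    markers = ["m1", "m2", "m3"]
    calls = {}
    for ind in individuals:
        calls[(ind, "m1")] = (150.0, 152.0)
    calls[("i1", "m2")] = (200.0, 200.0)
    calls[("i2", "m2")] = (200.0, 204.0)
    calls[("i3", "m2")] = (204.0, 208.0)
    calls[("i4", "m2")] = (200.0, 200.0)
    for ind in individuals:
        calls[(ind, "m3")] = (99.0, 99.0)
    calls[("i4", "m3")] = None
    return GenotypeTable(individuals, markers, calls)


def random_contig(rng, length: int) -> Contig:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return Contig(id="rand", sequence=seq)
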