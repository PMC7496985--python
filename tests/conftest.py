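import numpy as np
import pytest

from introscan.model import GenotypeMatrix, SampleInfo


def make_gm(calls, groups, chrom=None, pos=None):
    """Small GenotypeMatrix from a (samples x sites) list/array.

    ``groups`` is a list of group labels per sample; sample ids are
    s00, s01, ...  Sites default to one chromosome at positions 1..m.
    """
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    samples = [SampleInfo(f"s{i:02d}", g) for i, g in enumerate(groups)]
    chrom = np.asarray(chrom if chrom is not None else ["c1"] * m, dtype=object)
    pos = np.asarray(pos if pos is not None else np.arange(1, m + 1))
    ref = np.asarray(["A"] * m, dtype=object)
    alt = np.asarray(["T"] * m, dtype=object)
    return GenotypeMatrix(samples, chrom, pos, ref, alt, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def gm_factory():
    return make_gm
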