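import random

import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

from boilerplate import compressor, decompressor
from boilerplate import synthetic_data as sd


@pytest.fixture
def rng():
    return random.Random(1234)


@pytest.fixture
def small_transcriptome():
    return sd.gen_transcriptome(8, exons_per_gene=(1, 3), seed=11)


def roundtrip(alignments, chrom_table, seed=0, **opts):
    """compress -> decompress, returning (archive bytes, recovered alignments)."""
    data, _ = compressor.compress_alignments(alignments, chrom_table, seed=seed, **opts)
    _, out = decompressor.decompress_archive(data, seed)
    return data, out


@pytest.fixture
def compress_roundtrip():
    return roundtrip
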