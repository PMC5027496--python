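import zlib

import numpy as np
import pytest
from hypothesis import given, strategies as st

from boilerplate.bundler import Bundle, prepare_bundles
from boilerplate.compressor import (
    ArchiveFormatError,
    ArchiveReader,
    BucketKey,
    CoverageVector,
    Tally,
    assign_bucket,
    build_buckets,
    compress_alignments,
    decode_bundle_payload,
    deserialize_index,
    partition_bundle,
    rle_decode,
    rle_encode,
)
from boilerplate import synthetic_data as sd
from helpers import make_alignment as mk


def bundle_of(alns, start=None, end=None):
    alns = sorted(alns, key=lambda a: a.start)
    return Bundle(
        chrom=alns[0].chrom,
        start=alns[0].start if start is None else start,
        end=max(a.end for a in alns) if end is None else end,
        alignments=list(alns),
        index=0,
    )


class TestRle:
    def test_example(self):
        cv = rle_encode([0, 0, 3, 3, 3, 1])
        assert cv.runs == ((0, 2), (3, 3), (1, 1))

    def test_empty(self):
        assert rle_encode([]).runs == ()
        assert rle_decode(CoverageVector(())).size == 0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rle_encode([1, -1])

    @given(st.lists(st.integers(0, 5), max_size=200))
    def test_roundtrip(self, depths):
        assert list(rle_decode(rle_encode(depths))) == depths

    @given(st.lists(st.integers(0, 5), max_size=200))
    def test_canonical_maximal_runs(self, depths):
        runs = rle_encode(depths).runs
        assert all(a[0] != b[0] for a, b in zip(runs, runs[1:]))
        assert sum(l for _, l in runs) == len(depths)


class TestPartitionBundle:
    def test_single_junction(self):
        b = bundle_of([mk("chr1", [(0, 100), (200, 300)])], start=0, end=300)
        assert partition_bundle(b) == [(0, 100), (100, 200), (200, 300)]

    def test_no_junctions(self):
        b = bundle_of([mk("chr1", [(0, 300)])])
        assert partition_bundle(b) == [(0, 300)]

    def test_shared_donor_deduplicated(self):
        # two junctions sharing a donor: cut set {0,100,200,250,300} -> 4 partitions
        b = bundle_of(
            [
                mk("chr1", [(0, 100), (200, 300)]),
                mk("chr1", [(50, 100), (250, 300)]),
            ],
            start=0,
            end=300,
        )
        assert partition_bundle(b) == [(0, 100), (100, 200), (200, 250), (250, 300)]


class TestAssignBucket:
    PARTS = [(0, 100), (100, 200), (200, 300)]

    def test_unspliced(self):
        key = assign_bucket(mk("chr1", [(120, 180)]), self.PARTS)
        assert key == BucketKey((1,), 1, None)

    def test_spliced_skips_partition(self):
        key = assign_bucket(
            mk("chr1", [(50, 100), (200, 250)], strand="+", nh=4), self.PARTS
        )
        assert key == BucketKey((0, 2), 4, "+")

    def test_nh_separates(self):
        k1 = assign_bucket(mk("chr1", [(0, 50)], nh=1), self.PARTS)
        k2 = assign_bucket(mk("chr1", [(0, 50)], nh=2), self.PARTS)
        assert k1 != k2

    def test_block_outside_partitions_raises(self):
        with pytest.raises(ValueError):
            assign_bucket(mk("chr1", [(250, 400)]), self.PARTS)


class TestBuildBuckets:
    def test_identical_reads_merge(self):
        b = bundle_of([mk("chr1", [(0, 100)]), mk("chr1", [(0, 100)])])
        (bucket,) = build_buckets(b, partition_bundle(b))
        assert bucket.coverage.runs == ((2, 100),)
        assert bucket.length_tally == {100: 2}
        assert bucket.paired_count == 0

    def test_pair_outer_distance(self):
        a = mk("chr1", [(0, 100)], paired=True, mate_chrom="chr1", mate_start=200, qname="p")
        c = mk("chr1", [(200, 300)], paired=True, mate_chrom="chr1", mate_start=0, qname="p")
        b = bundle_of([a, c])
        buckets = build_buckets(b, partition_bundle(b), pairs=[(a, c)])
        assert sum(dict(bk.tlen_tally).get(300, 0) for bk in buckets) == 1
        assert sum(bk.paired_count for bk in buckets) == 2

    def test_strand_separates(self):
        b = bundle_of([mk("chr1", [(0, 100)], strand="+"), mk("chr1", [(0, 100)], strand="-")])
        assert len(build_buckets(b, partition_bundle(b))) == 2

    def test_conservation_invariant_random(self, rng):
        genes, ct = sd.gen_transcriptome(6, seed=5)
        sim = sd.gen_reads(genes, ct, 600, read_length={100: 2, 75: 1}, seed=5)
        res = prepare_bundles(sim.to_alignments())
        for bun in res.bundles:
            parts = partition_bundle(bun)
            for bk in build_buckets(bun, parts):
                assert bk.coverage.total() == bk.length_tally.weighted_total()


class TestArchive:
    def test_empty_input(self):
        data, stats = compress_alignments([], [("chr1", 1000)])
        reader = deserialize_index(data)
        assert reader.n_bundles() == 0
        assert stats.n_bundles == 0

    def test_offsets_strictly_increasing(self):
        alns = [mk("chr1", [(0, 100)]), mk("chr1", [(500, 600)])]
        data, _ = compress_alignments(alns, [("chr1", 1000)])
        reader = deserialize_index(data)
        assert reader.n_bundles() == 2
        assert reader.bundles[0].offset < reader.bundles[1].offset

    def test_structural_roundtrip(self):
        """serialize -> deserialize -> inflate all blocks == bucket sets built directly."""
        genes, ct = sd.gen_transcriptome(5, seed=9)
        sim = sd.gen_reads(genes, ct, 400, read_length=100, paired=True, seed=9)
        alns = sim.to_alignments()
        data, _ = compress_alignments(alns, ct, seed=0)
        reader = ArchiveReader(data)

        res = prepare_bundles(sim.to_alignments())
        pair_map = {}
        for a, b in res.pairs:
            bi = next(bn.index for bn in res.bundles if a in bn.alignments)
            pair_map.setdefault(bi, []).append((a, b))
        assert reader.n_bundles() == len(res.bundles)
        for bun in res.bundles:
            parts = partition_bundle(bun)
            expected = build_buckets(bun, parts, pair_map.get(bun.index))
            payload = reader.bundle_payload(bun.index)
            assert payload.partitions == parts
            assert payload.buckets == expected

    def test_bad_magic(self):
        with pytest.raises(ArchiveFormatError, match="magic"):
            ArchiveReader(b"NOPE" + b"\x00" * 10)

    def test_truncation(self):
        alns = [mk("chr1", [(0, 100)])]
        data, _ = compress_alignments(alns, [("chr1", 1000)])
        with pytest.raises(ArchiveFormatError):
            ArchiveReader(data[: len(data) - 5])

    def test_corrupt_block_reports_bundle(self):
        alns = [mk("chr1", [(0, 100)])]
        data, _ = compress_alignments(alns, [("chr1", 1000)])
        reader = ArchiveReader(data)
        corrupted = bytearray(data)
        corrupted[reader._bundle_data_start] ^= 0xFF
        with pytest.raises(ArchiveFormatError, match="inflate"):
            ArchiveReader(bytes(corrupted)).bundle_payload(0)

    def test_deterministic_bytes(self):
        genes, ct = sd.gen_transcriptome(4, seed=2)
        sim = sd.gen_reads(genes, ct, 300, paired=True, discordant_rate=0.1, seed=2)
        d1, _ = compress_alignments(sim.to_alignments(), ct, seed=7)
        sim2 = sd.gen_reads(genes, ct, 300, paired=True, discordant_rate=0.1, seed=2)
        d2, _ = compress_alignments(sim2.to_alignments(), ct, seed=7)
        assert d1 == d2

    def test_index_read_without_inflation(self):
        # deserialize_index must not touch block bytes: corrupt every block
        genes, ct = sd.gen_transcriptome(3, seed=4)
        sim = sd.gen_reads(genes, ct, 200, seed=4)
        data, _ = compress_alignments(sim.to_alignments(), ct)
        reader = ArchiveReader(data)
        blob = bytearray(data)
        for i in range(reader._bundle_data_start, len(blob)):
            blob[i] = 0
        reader2 = deserialize_index(bytes(blob))
        assert reader2.n_bundles() == reader.n_bundles()


class TestSublinearGrowth:
    def test_archive_grows_sublinearly_with_depth(self):
        genes, ct = sd.gen_transcriptome(20, seed=6)
        sizes = {}
        for depth, n in ((1, 2000), (10, 20000)):
            sim = sd.gen_reads(genes, ct, n, read_length=100, seed=6)
            data, _ = compress_alignments(sim.to_alignments(), ct)
            sizes[depth] = len(data)
        assert sizes[10] < 4 * sizes[1]
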