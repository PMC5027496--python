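import random
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from boilerplate.compressor import (
    ArchiveReader,
    Tally,
    compress_alignments,
    rle_encode,
)
from boilerplate.decompressor import (
    decompress_archive,
    expand_bundle,
    expand_unbundled,
    pair_reads,
    recover_reads,
)
from helpers import (
    enumerate_exact_solutions,
    induced_coverage,
    make_alignment as mk,
    max_recoverable_length,
)


def tally(d):
    t = Tally()
    for v, c in d.items():
        t.add(v, c)
    return t


class TestRecoverReads:
    def test_uniform_exact(self):
        reads = recover_reads(rle_encode([2] * 100), tally({100: 2}))
        assert sorted((r.start, r.end) for r in reads) == [(0, 100), (0, 100)]

    def test_staggered_uniform_unique(self):
        cov = [1] * 50 + [2] * 50 + [1] * 50
        # oracle: brute-force enumeration confirms the solution is unique
        sols = enumerate_exact_solutions(cov, {100: 2})
        assert sols == {((0, 100), (50, 150))}
        reads = recover_reads(rle_encode(cov), tally({100: 2}))
        assert sorted((r.start, r.end) for r in reads) == [(0, 100), (50, 150)]

    def test_two_length_ambiguity(self):
        l1, l2 = 80, 120
        reads = recover_reads(rle_encode([1] * (l1 + l2)), tally({l1: 1, l2: 1}))
        intervals = sorted((r.start, r.end) for r in reads)
        assert intervals in (
            [(0, l1), (l1, l1 + l2)],
            [(0, l2), (l2, l1 + l2)],
        )
        assert sum(r.length for r in reads) == l1 + l2

    def test_incompatible_inputs_best_effort(self):
        # tally promises more reads than the coverage can hold
        reads = recover_reads(rle_encode([1] * 100), tally({100: 5}))
        assert len(reads) == 1

    def test_empty_coverage(self):
        assert recover_reads(rle_encode([]), tally({100: 1})) == []

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_safety_never_exceeds_coverage(self, data):
        depths = data.draw(st.lists(st.integers(0, 4), min_size=1, max_size=120))
        lengths = data.draw(
            st.dictionaries(st.integers(1, 40), st.integers(1, 4), min_size=1, max_size=4)
        )
        reads = recover_reads(rle_encode(depths), tally(lengths))
        induced = induced_coverage(reads, len(depths))
        assert np.all(induced <= np.asarray(depths))

    def test_greedy_near_optimal_small_instances(self, rng):
        from helpers import random_feasible_bucket

        total_greedy = total_opt = 0
        for _ in range(60):
            cov, lt = random_feasible_bucket(rng)
            reads = recover_reads(rle_encode(cov), tally(lt))
            greedy = sum(r.length for r in reads)
            opt = max_recoverable_length(cov, lt)
            assert greedy <= opt or greedy <= int(cov.sum())
            total_greedy += greedy
            total_opt += opt
        assert total_greedy >= 0.95 * total_opt


class TestPairReads:
    def test_unique_feasible_pairing(self):
        reads = [mk("c", [(0, 100)]), mk("c", [(200, 300)])]
        pairs, singles = pair_reads(reads, tally({300: 1}), 2, random.Random(0))
        assert len(pairs) == 1 and singles == []
        assert pairs[0][2] == 300

    def test_nested_fragments_exact(self):
        # two nested fragments; greedy from the extremes is provably exact here
        reads = [
            mk("c", [(0, 100)]),
            mk("c", [(50, 150)]),
            mk("c", [(850, 950)]),
            mk("c", [(900, 1000)]),
        ]
        truth = tally({1000: 1, 900: 1})
        pairs, singles = pair_reads(reads, truth, 4, random.Random(0))
        assert singles == []
        assert Counter(p[2] for p in pairs) == Counter({1000: 1, 900: 1})

    def test_paired_count_budget(self):
        reads = [mk("c", [(0, 100)]), mk("c", [(200, 300)]), mk("c", [(400, 500)])]
        pairs, singles = pair_reads(reads, tally({500: 1}), 2, random.Random(0))
        assert len(pairs) == 1 and len(singles) == 1

    def test_second_pass_random_but_seeded(self):
        reads = [mk("c", [(i * 10, i * 10 + 100)]) for i in range(6)]
        out1 = pair_reads(list(reads), tally({999: 1}), 6, random.Random(5))
        out2 = pair_reads(list(reads), tally({999: 1}), 6, random.Random(5))
        assert [(id(a), id(b)) for a, b, _ in out1[0]] == [
            (id(a), id(b)) for a, b, _ in out2[0]
        ]
        assert len(out1[0]) == 3  # all consumed by the random second pass


class TestExpandBundle:
    def _archive(self, alns, ct, seed=0):
        data, _ = compress_alignments(
            sorted(alns, key=lambda a: (a.chrom, a.start)), ct, seed=seed
        )
        return ArchiveReader(data)

    def test_uniform_bucket_exact(self):
        alns = [mk("chr1", [(i * 30, i * 30 + 100)]) for i in range(5)]
        reader = self._archive(alns, [("chr1", 1000)])
        out = expand_bundle(reader.bundle_block_bytes(0), "chr1", 0)
        assert Counter(a.blocks for a in out) == Counter(a.blocks for a in alns)

    def test_spliced_reads_carry_junction(self):
        alns = [mk("chr1", [(0, 50), (150, 200)], strand="+") for _ in range(3)]
        alns.append(mk("chr1", [(60, 140)]))  # populates the skipped partition
        reader = self._archive(alns, [("chr1", 1000)])
        out = expand_bundle(reader.bundle_block_bytes(0), "chr1", 0)
        spliced = [a for a in out if len(a.blocks) > 1]
        assert len(spliced) == 3
        for a in spliced:
            assert a.junction_points() == ((50, 150),)
            assert a.strand == "+"

    def test_nh_and_strand_reattached(self):
        alns = [mk("chr1", [(0, 100)], nh=3, strand="-")]
        reader = self._archive(alns, [("chr1", 1000)])
        (out,) = expand_bundle(reader.bundle_block_bytes(0), "chr1", 0)
        assert out.nh == 3 and out.strand == "-"

    def test_deterministic_given_seed(self):
        rng = random.Random(0)
        alns = []
        for i in range(20):
            s = i * 15
            a = mk("chr1", [(s, s + 100)], paired=True, mate_chrom="chr1",
                   mate_start=s + 150, tlen=250, qname=f"p{i}")
            b = mk("chr1", [(s + 150, s + 250)], paired=True, mate_chrom="chr1",
                   mate_start=s, tlen=-250, qname=f"p{i}")
            alns += [a, b]
        reader = self._archive(alns, [("chr1", 1000)])
        o1 = expand_bundle(reader.bundle_block_bytes(0), "chr1", 3)
        o2 = expand_bundle(reader.bundle_block_bytes(0), "chr1", 3)
        assert [(a.blocks, a.qname, a.tlen) for a in o1] == [
            (a.blocks, a.qname, a.tlen) for a in o2
        ]


class TestExpandUnbundled:
    CT = [("chr1", 10000), ("chr2", 10000)]

    def _pair(self, chrom_a, start_a, chrom_b, start_b, qname):
        a = mk(chrom_a, [(start_a, start_a + 100)], paired=True,
               mate_chrom=chrom_b, mate_start=start_b, qname=qname)
        b = mk(chrom_b, [(start_b, start_b + 100)], paired=True,
               mate_chrom=chrom_a, mate_start=start_a, qname=qname)
        return a, b

    def test_cross_chromosome_pair(self):
        a, b = self._pair("chr1", 100, "chr2", 700, "x")
        data, stats = compress_alignments(
            sorted([a, b], key=lambda x: (x.chrom, x.start)), self.CT
        )
        assert stats.n_unbundled_pairs == 1
        out = expand_unbundled(ArchiveReader(data), 0)
        assert len(out) == 2
        left, right = sorted(out, key=lambda x: x.chrom)
        assert (left.chrom, left.start) == ("chr1", 100)
        assert (right.chrom, right.start) == ("chr2", 700)
        assert left.mate_chrom == "chr2" and right.mate_chrom == "chr1"
        assert left.qname == right.qname
        assert left.tlen == 0

    def test_distant_pair_roundtrip(self):
        a, b = self._pair("chr1", 100, "chr1", 6000, "d")
        data, _ = compress_alignments([a, b], self.CT)
        out = expand_unbundled(ArchiveReader(data), 0)
        assert sorted(x.start for x in out) == [100, 6000]
        left = min(out, key=lambda x: x.start)
        assert left.tlen == 6000  # outer distance from geometry

    def test_empty_section(self):
        data, _ = compress_alignments([mk("chr1", [(0, 100)])], self.CT)
        assert expand_unbundled(ArchiveReader(data), 0) == []


class TestDecompressArchive:
    def test_full_roundtrip_sorted(self):
        alns = [mk("chr1", [(i * 40, i * 40 + 100)]) for i in range(10)]
        alns += [mk("chr2", [(5, 105)])]
        data, _ = compress_alignments(
            sorted(alns, key=lambda a: (a.chrom, a.start)), self.CT
        )
        ct, out = decompress_archive(data, 0)
        starts = [(a.chrom, a.start) for a in out]
        assert starts == sorted(starts)
        assert Counter((a.chrom, a.blocks) for a in out) == Counter(
            (a.chrom, a.blocks) for a in alns
        )

    CT = [("chr1", 10000), ("chr2", 10000)]
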