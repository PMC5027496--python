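"""Greedy recovery of alignments from coverage vectors and tallies.

Read recovery scans the coverage vector left to right. At the leftmost
position with nonzero depth it extracts a read whose length is drawn from the
remaining length tally and is *consistent*: subtracting the read must not
drive any coverage element below zero. When reads are uniform-length the
leftmost nonzero position is always a true read start, so the reconstruction
is exact. With mixed lengths a heuristic picks among consistent lengths
(preferring choices that do not strand an unfillable sliver of coverage) and
may lengthen or shorten a read by up to ``k_repair`` bases to absorb small
discrepancies — coverage fidelity is favored over length-distribution
fidelity. Induced coverage never exceeds the stored vector.

Pairing walks recovered reads inward from the two extremes, alternating ends,
greedily pairing each read with the most distant partner whose genomic outer
distance still has remaining count in the stored tally; leftovers are paired
randomly in a second pass (seeded).
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alignment_model import Alignment
from .compressor import (
    ArchiveFormatError,
    ArchiveReader,
    BundlePayload,
    CoverageVector,
    SpanningBucket,
    Tally,
    _ConcatMap,
    decode_bundle_payload,
)

__all__ = [
    "RecoveredRead",
    "recover_reads",
    "pair_reads",
    "expand_bundle",
    "expand_unbundled",
    "decompress_archive",
    "DEFAULT_K_REPAIR",
]

DEFAULT_K_REPAIR = 5


@dataclass(slots=True)
class RecoveredRead:
    """A recovered interval in concatenated-partition space."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def recover_reads(
    coverage: CoverageVector,
    length_tally: Tally,
    *,
    k_repair: int = DEFAULT_K_REPAIR,
) -> list[RecoveredRead]:
    """Extract reads consistent with ``coverage`` whose lengths follow the tally.

    Best-effort on incompatible inputs: tallied reads may be left unplaced and
    repaired reads may deviate from tallied lengths by up to ``k_repair``.
    The induced coverage of the result never exceeds the input anywhere.
    """
    cov = coverage.decode().copy()
    n = cov.size
    remaining = dict(length_tally.sorted_items())
    reads: list[RecoveredRead] = []
    pos = 0
    while pos < n:
        if cov[pos] == 0:
            pos += 1
            continue
        if not remaining:
            break
        # maximal stretch of positive coverage starting at pos
        zero_rel = np.flatnonzero(cov[pos:] == 0)
        run = int(zero_rel[0]) if zero_rel.size else n - pos
        lengths_desc = sorted(remaining, reverse=True)
        consistent = [l for l in lengths_desc if l <= run]
        chosen: Optional[int] = None  # length drawn from the tally
        emitted: Optional[int] = None  # actual emitted read length
        if consistent:
            min_len = min(remaining)

            def preference(l: int) -> tuple:
                end = pos + l
                # a coverage step-down right at the read end marks a likely
                # true read boundary
                drop = cov[end - 1] - (cov[end] if end < n else 0)
                leftover = run - l
                no_sliver = leftover == 0 or leftover >= min_len
                return (drop > 0, no_sliver, l)

            chosen = emitted = max(consistent, key=preference)
        else:
            # repair: shorten the closest longer tallied length to fit the run
            best = None
            for l in lengths_desc:
                if 0 < l - run <= k_repair and (best is None or l - run < best[0]):
                    best = (l - run, l)
            if best is not None:
                chosen, emitted = best[1], run
        if chosen is None:
            pos += run  # unfillable sliver; leave its coverage unconsumed
            continue
        cov[pos : pos + emitted] -= 1
        reads.append(RecoveredRead(pos, pos + emitted))
        remaining[chosen] -= 1
        if remaining[chosen] == 0:
            del remaining[chosen]
    return reads


@dataclass(slots=True)
class _End:
    """A recovered end awaiting pairing, in genomic coordinates."""

    start: int
    end: int
    payload: object = None


def pair_reads(
    reads: Sequence,
    tlen_tally: Tally,
    paired_count: int,
    rng: random.Random,
) -> tuple[list[tuple], list]:
    """Pair reads to reproduce the stored outer-distance tally.

    ``reads`` must be sorted by start and expose ``start``/``end`` attributes
    (genomic coordinates, introns included so distances match TLEN semantics).
    Returns ``(pairs, singles)`` where each pair is ``(left, right, distance)``.
    At most ``paired_count`` reads end up inside pairs.
    """
    n = len(reads)
    tally = dict(tlen_tally)
    paired = [False] * n
    examined = [False] * n
    pairs: list[tuple] = []

    def outer_distance(i: int, j: int) -> int:
        lo = min(reads[i].start, reads[j].start)
        hi = max(reads[i].end, reads[j].end)
        return hi - lo

    lo_ptr, hi_ptr = 0, n - 1
    from_left = True
    budget = paired_count
    while lo_ptr <= hi_ptr and tally and budget >= 2:
        if from_left:
            while lo_ptr <= hi_ptr and examined[lo_ptr]:
                lo_ptr += 1
            idx = lo_ptr if lo_ptr <= hi_ptr else None
        else:
            while hi_ptr >= lo_ptr and examined[hi_ptr]:
                hi_ptr -= 1
            idx = hi_ptr if hi_ptr >= lo_ptr else None
        from_left = not from_left
        if idx is None:
            break
        examined[idx] = True
        if paired[idx]:
            continue
        # most distant unpaired partner whose distance remains in the tally
        best_j = None
        best_d = -1
        for j in range(n):
            if j == idx or paired[j]:
                continue
            d = outer_distance(idx, j)
            if d > best_d and tally.get(d, 0) > 0:
                best_d, best_j = d, j
        if best_j is not None:
            paired[idx] = paired[best_j] = True
            tally[best_d] -= 1
            if tally[best_d] == 0:
                del tally[best_d]
            left, right = (idx, best_j) if reads[idx].start <= reads[best_j].start else (best_j, idx)
            pairs.append((reads[left], reads[right], best_d))
            budget -= 2

    # second pass: pair leftovers randomly up to the paired_count budget
    leftovers = [i for i in range(n) if not paired[i]]
    rng.shuffle(leftovers)
    while budget >= 2 and len(leftovers) >= 2:
        i = leftovers.pop()
        j = leftovers.pop()
        left, right = (i, j) if reads[i].start <= reads[j].start else (j, i)
        pairs.append((reads[left], reads[right], outer_distance(i, j)))
        paired[i] = paired[j] = True
        budget -= 2
    singles = [reads[i] for i in range(n) if not paired[i]]
    return pairs, singles


def _payload_from_block(block: bytes) -> BundlePayload:
    try:
        inflated = zlib.decompress(block)
    except zlib.error as exc:
        raise ArchiveFormatError(f"bundle block fails to inflate: {exc}") from exc
    return decode_bundle_payload(inflated)


def expand_bundle(
    block: bytes,
    chrom: str,
    seed: int = 0,
    *,
    bundle_index: int = 0,
    k_repair: int = DEFAULT_K_REPAIR,
) -> list[Alignment]:
    """Recover the alignments of one compressed bundle block.

    Reads are recovered per bucket and mapped back through the bucket's
    spanned partitions (skipped partitions become introns). Pairing is then
    solved once over the whole bundle so pairs whose ends fell into different
    buckets can be restored; the per-bucket ``paired_count`` fields say how
    many ends of each bucket take part.
    """
    payload = _payload_from_block(block)
    rng = random.Random(f"{seed}:bundle:{bundle_index}")
    partitions = payload.partitions

    candidates: list[_End] = []
    unpaired_out: list[Alignment] = []
    merged_tally = Tally()
    total_paired = 0
    for bucket in payload.buckets:
        cmap = _ConcatMap(bucket.key.spanned, partitions)
        recs = recover_reads(bucket.coverage, bucket.length_tally, k_repair=k_repair)
        ends: list[_End] = []
        for rr in recs:
            blocks = cmap.interval_to_blocks(rr.start, rr.end)
            aln = Alignment(
                chrom=chrom,
                blocks=blocks,
                strand=bucket.key.strand,
                nh=bucket.key.nh,
            )
            ends.append(_End(aln.start, aln.end, aln))
        ends.sort(key=lambda e: (e.start, e.end))
        take = min(bucket.paired_count, len(ends))
        candidates.extend(ends[:take])
        unpaired_out.extend(e.payload for e in ends[take:])
        total_paired += bucket.paired_count
        for d, c in bucket.tlen_tally.items():
            merged_tally.add(d, c)

    candidates.sort(key=lambda e: (e.start, e.end))
    pairs, singles = pair_reads(candidates, merged_tally, total_paired, rng)
    out = list(unpaired_out)
    out.extend(s.payload for s in singles)
    for i, (left, right, d) in enumerate(pairs):
        la: Alignment = left.payload
        ra: Alignment = right.payload
        name = f"b{bundle_index}.p{i}"
        la.paired = ra.paired = True
        la.qname = ra.qname = name
        la.mate_chrom, la.mate_start = ra.chrom, ra.start
        ra.mate_chrom, ra.mate_start = la.chrom, la.start
        la.tlen, ra.tlen = d, -d
        out.append(la)
        out.append(ra)
    out.sort(key=lambda a: (a.start, a.end))
    return out


def _recover_side(
    sb: SpanningBucket,
    cov: np.ndarray,
    cmap: "_ConcatMap",
    tally: Tally,
    chrom: str,
    nh: int,
    strand: Optional[str],
    k_repair: int,
) -> list[Alignment]:
    from .compressor import rle_encode

    recs = recover_reads(rle_encode(cov), tally, k_repair=k_repair)
    out = []
    for rr in recs:
        blocks = cmap.interval_to_blocks(rr.start, rr.end)
        out.append(Alignment(chrom=chrom, blocks=blocks, strand=strand, nh=nh))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def expand_unbundled(
    reader: ArchiveReader,
    seed: int = 0,
    *,
    chunk_indices: Optional[Sequence[int]] = None,
    k_repair: int = DEFAULT_K_REPAIR,
) -> list[Alignment]:
    """Recover paired alignments from the archive's unbundled section."""
    if chunk_indices is None:
        chunk_indices = range(len(reader.chunks))
    payload_cache: dict[int, BundlePayload] = {}

    def partitions_for(bi: int) -> list[tuple[int, int]]:
        if bi not in payload_cache:
            payload_cache[bi] = reader.bundle_payload(bi)
        return payload_cache[bi].partitions

    out: list[Alignment] = []
    for k in chunk_indices:
        rng = random.Random(f"{seed}:unbundled:{k}")
        for bidx, sb in enumerate(reader.chunk_buckets(k)):
            chrom_l = reader.bundle_span(sb.bundle_left)[0]
            chrom_r = reader.bundle_span(sb.bundle_right)[0]
            cmap_l = _ConcatMap(sb.spanned_left, partitions_for(sb.bundle_left))
            cmap_r = _ConcatMap(sb.spanned_right, partitions_for(sb.bundle_right))
            cov = sb.coverage.decode()
            if cov.size != cmap_l.length + cmap_r.length:
                raise ArchiveFormatError("unbundled coverage length mismatch")
            lefts = _recover_side(
                sb, cov[: cmap_l.length], cmap_l, sb.left_length_tally,
                chrom_l, sb.nh_left, sb.strand_left, k_repair,
            )
            rights = _recover_side(
                sb, cov[cmap_l.length :], cmap_r, sb.right_length_tally,
                chrom_r, sb.nh_right, sb.strand_right, k_repair,
            )
            # greedy distance matching when same-chromosome, positional zip otherwise
            used_r: set[int] = set()
            tally = dict(sb.tlen_tally)
            n_pairs = min(len(lefts), len(rights), sb.n_pairs)
            matches: list[tuple[Alignment, Alignment]] = []
            if chrom_l == chrom_r and tally:
                for la in lefts:
                    best = None
                    for j, ra in enumerate(rights):
                        if j in used_r:
                            continue
                        d = max(la.end, ra.end) - min(la.start, ra.start)
                        if tally.get(d, 0) > 0 and (best is None or d > best[0]):
                            best = (d, j)
                    if best is not None:
                        used_r.add(best[1])
                        tally[best[0]] -= 1
                        if tally[best[0]] == 0:
                            del tally[best[0]]
                        matches.append((la, rights[best[1]]))
            matched_l = {id(a) for a, _ in matches}
            rem_l = [a for a in lefts if id(a) not in matched_l]
            rem_r = [r for j, r in enumerate(rights) if j not in used_r]
            rng.shuffle(rem_r)
            matches.extend(zip(rem_l, rem_r))
            matches = matches[:n_pairs]
            paired_l = {id(a) for a, _ in matches}
            paired_r = {id(b) for _, b in matches}
            for i, (la, ra) in enumerate(matches):
                name = f"u{k}.{bidx}.p{i}"
                la.paired = ra.paired = True
                la.qname = ra.qname = name
                la.mate_chrom, la.mate_start = ra.chrom, ra.start
                ra.mate_chrom, ra.mate_start = la.chrom, la.start
                if la.chrom == ra.chrom:
                    d = max(la.end, ra.end) - min(la.start, ra.start)
                    if la.start <= ra.start:
                        la.tlen, ra.tlen = d, -d
                    else:
                        la.tlen, ra.tlen = -d, d
                else:
                    la.tlen = ra.tlen = 0
                out.append(la)
                out.append(ra)
            out.extend(a for a in lefts if id(a) not in paired_l)
            out.extend(b for b in rights if id(b) not in paired_r)
    return out


def decompress_archive(
    data: bytes, seed: int = 0, *, k_repair: int = DEFAULT_K_REPAIR
) -> tuple[list[tuple[str, int]], list[Alignment]]:
    """Expand a whole archive back to coordinate-sorted alignments."""
    reader = data if isinstance(data, ArchiveReader) else ArchiveReader(data)
    chrom_id = {name: i for i, (name, _) in enumerate(reader.chrom_table)}
    out: list[Alignment] = []
    for i in range(reader.n_bundles()):
        chrom = reader.bundle_span(i)[0]
        out.extend(
            expand_bundle(
                reader.bundle_block_bytes(i),
                chrom,
                seed,
                bundle_index=i,
                k_repair=k_repair,
            )
        )
    out.extend(expand_unbundled(reader, seed, k_repair=k_repair))
    out.sort(key=lambda a: (chrom_id[a.chrom], a.start, a.end))
    return reader.chrom_table, out
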