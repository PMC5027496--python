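"""Coverage-domain encoding of bundles and the indexed archive format.

Each bundle is cut into partitions at every observed splice site. Every
alignment maps to a bucket keyed by (spanned partition subset, NH, strand);
the bucket stores a run-length encoded coverage vector over the concatenation
of its spanned partitions, a tally of read lengths and — for paired data — a
tally of genomic outer distances. Each bundle's bucket set is DEFLATEd
independently; pairs spanning two bundles go to a separate chunked, indexed
"unbundled" section. The archive header carries the chromosome table and a
bundle index so queries can reach any bundle with a single index lookup.
"""

from __future__ import annotations

import random
import zlib
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .alignment_model import Alignment
from .bundler import Bundle, BundlingResult, UnbundledPair, prepare_bundles

__all__ = [
    "MAGIC",
    "VERSION",
    "ArchiveFormatError",
    "Tally",
    "CoverageVector",
    "rle_encode",
    "rle_decode",
    "BucketKey",
    "Bucket",
    "SpanningBucket",
    "BundlePayload",
    "partition_bundle",
    "assign_bucket",
    "build_buckets",
    "compress_alignments",
    "ArchiveReader",
    "deserialize_index",
    "CompressionStats",
]

MAGIC = b"BOIL"
VERSION = 1
UNBUNDLED_CHUNK_SIZE = 64

_STRAND_CODE = {None: 0, "+": 1, "-": 2}
_STRAND_FROM_CODE = {0: None, 1: "+", 2: "-"}


class ArchiveFormatError(ValueError):
    """Raised when archive bytes fail structural validation."""


# ---------------------------------------------------------------------------
# primitives: tallies and run-length encoded coverage


class Tally(dict):
    """Multiset of integers: value -> positive count."""

    def add(self, value: int, count: int = 1) -> None:
        if count <= 0:
            raise ValueError("count must be positive")
        self[value] = self.get(value, 0) + count

    def total(self) -> int:
        return sum(self.values())

    def weighted_total(self) -> int:
        return sum(v * c for v, c in self.items())

    def sorted_items(self) -> list[tuple[int, int]]:
        return sorted(self.items())


@dataclass(frozen=True)
class CoverageVector:
    """Per-base depth stored as maximal (depth, run_length) runs."""

    runs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_depth = None
        for depth, length in self.runs:
            if depth < 0:
                raise ValueError("negative depth")
            if length <= 0:
                raise ValueError("non-positive run length")
            if prev_depth is not None and depth == prev_depth:
                raise ValueError("adjacent runs must have distinct depths")
            prev_depth = depth

    def __len__(self) -> int:
        return sum(length for _, length in self.runs)

    def decode(self) -> np.ndarray:
        return rle_decode(self)

    def total(self) -> int:
        return sum(depth * length for depth, length in self.runs)


def rle_encode(depths: Sequence[int]) -> CoverageVector:
    """Canonical (maximal-run) RLE of a non-negative integer sequence."""
    arr = np.asarray(depths, dtype=np.int64)
    if arr.size == 0:
        return CoverageVector(())
    if arr.min() < 0:
        raise ValueError("coverage depths must be non-negative")
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    return CoverageVector(
        tuple((int(arr[s]), int(e - s)) for s, e in zip(starts, ends))
    )


def rle_decode(vector: CoverageVector) -> np.ndarray:
    if not vector.runs:
        return np.zeros(0, dtype=np.int64)
    depths = np.fromiter((d for d, _ in vector.runs), dtype=np.int64)
    lengths = np.fromiter((l for _, l in vector.runs), dtype=np.int64)
    return np.repeat(depths, lengths)


# ---------------------------------------------------------------------------
# partitions and buckets


@dataclass(frozen=True)
class BucketKey:
    spanned: tuple[int, ...]
    nh: int
    strand: Optional[str]

    def sort_key(self) -> tuple:
        return (self.spanned, _STRAND_CODE[self.strand], self.nh)


@dataclass
class Bucket:
    key: BucketKey
    coverage: CoverageVector
    length_tally: Tally
    tlen_tally: Tally
    paired_count: int = 0


@dataclass
class SpanningBucket:
    """Bundle-spanning bucket for the unbundled section.

    Coverage concatenates the spanned partitions of the left bundle then the
    right bundle; side-specific length tallies let each side be recovered
    independently.
    """

    bundle_left: int
    bundle_right: int
    spanned_left: tuple[int, ...]
    spanned_right: tuple[int, ...]
    nh_left: int
    strand_left: Optional[str]
    nh_right: int
    strand_right: Optional[str]
    coverage: CoverageVector
    left_length_tally: Tally
    right_length_tally: Tally
    tlen_tally: Tally
    n_pairs: int

    def sort_key(self) -> tuple:
        return (
            self.bundle_left,
            self.bundle_right,
            self.spanned_left,
            self.spanned_right,
            _STRAND_CODE[self.strand_left],
            _STRAND_CODE[self.strand_right],
            self.nh_left,
            self.nh_right,
        )


def partition_bundle(bundle: Bundle) -> list[tuple[int, int]]:
    """Tile the bundle span with intervals cut at every observed splice site."""
    cuts = {bundle.start, bundle.end}
    for donor, acceptor in bundle.junction_points():
        cuts.add(donor)
        cuts.add(acceptor)
    bounds = sorted(c for c in cuts if bundle.start <= c <= bundle.end)
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def _spanned_ordinals(
    blocks: Sequence[tuple[int, int]], partitions: Sequence[tuple[int, int]]
) -> tuple[int, ...]:
    starts = [p[0] for p in partitions]
    spanned: list[int] = []
    for bs, be in blocks:
        lo = bisect_right(starts, bs) - 1
        if lo < 0 or bs >= partitions[lo][1]:
            raise ValueError(f"block ({bs},{be}) outside all partitions")
        i = lo
        while i < len(partitions) and partitions[i][0] < be:
            if not spanned or spanned[-1] != i:
                spanned.append(i)
            i += 1
        if partitions[min(i, len(partitions)) - 1][1] < be:
            raise ValueError(f"block ({bs},{be}) outside all partitions")
    return tuple(spanned)


def assign_bucket(
    alignment: Alignment, partitions: Sequence[tuple[int, int]]
) -> BucketKey:
    return BucketKey(
        spanned=_spanned_ordinals(alignment.blocks, partitions),
        nh=alignment.nh,
        strand=alignment.strand,
    )


class _ConcatMap:
    """Map between genomic coordinates and the concatenated-partition axis."""

    def __init__(
        self, spanned: Sequence[int], partitions: Sequence[tuple[int, int]]
    ) -> None:
        self.parts = [partitions[i] for i in spanned]
        self.offsets = [0]
        for s, e in self.parts:
            self.offsets.append(self.offsets[-1] + (e - s))
        self.length = self.offsets[-1]
        self._starts = [p[0] for p in self.parts]

    def to_concat(self, gpos: int) -> int:
        i = bisect_right(self._starts, gpos) - 1
        s, e = self.parts[i]
        if not (s <= gpos < e):
            raise ValueError(f"genomic position {gpos} not in spanned partitions")
        return self.offsets[i] + (gpos - s)

    def interval_to_blocks(self, start: int, end: int) -> tuple[tuple[int, int], ...]:
        """Map a contiguous concat-space interval back to genomic blocks,
        merging genomically adjacent pieces (gaps become introns)."""
        blocks: list[tuple[int, int]] = []
        for (gs, ge), off in zip(self.parts, self.offsets):
            lo = max(start, off)
            hi = min(end, off + (ge - gs))
            if lo < hi:
                b = (gs + (lo - off), gs + (hi - off))
                if blocks and blocks[-1][1] == b[0]:
                    blocks[-1] = (blocks[-1][0], b[1])
                else:
                    blocks.append(b)
        return tuple(blocks)


def _pair_outer_distance(a: Alignment, b: Alignment) -> int:
    return max(a.end, b.end) - min(a.start, b.start)


def _pair_tlen(a: Alignment, b: Alignment) -> int:
    """|TLEN| as the aligner reported it, falling back to the block geometry."""
    if a.tlen:
        return abs(a.tlen)
    if b.tlen:
        return abs(b.tlen)
    return _pair_outer_distance(a, b)


def build_buckets(
    bundle: Bundle,
    partitions: Sequence[tuple[int, int]],
    pairs: Optional[Sequence[tuple[Alignment, Alignment]]] = None,
) -> list[Bucket]:
    """Group the bundle's alignments into buckets with coverage + tallies.

    ``pairs`` lists ordinary pairs whose two ends both live in this bundle;
    each contributes one |TLEN| entry (recorded in the left end's bucket) and
    marks both ends as needing re-pairing at decompression.
    """
    groups: dict[BucketKey, list[Alignment]] = {}
    for a in bundle.alignments:
        groups.setdefault(assign_bucket(a, partitions), []).append(a)

    key_of = {id(a): k for k, members in groups.items() for a in members}
    tlen_tallies: dict[BucketKey, Tally] = {}
    paired_counts: dict[BucketKey, int] = {}
    if pairs:
        for a, b in pairs:
            left, right = (a, b) if a.start <= b.start else (b, a)
            ka, kb = key_of[id(left)], key_of[id(right)]
            tlen_tallies.setdefault(ka, Tally()).add(_pair_tlen(a, b))
            paired_counts[ka] = paired_counts.get(ka, 0) + 1
            paired_counts[kb] = paired_counts.get(kb, 0) + 1

    buckets: list[Bucket] = []
    for key in sorted(groups, key=BucketKey.sort_key):
        members = groups[key]
        cmap = _ConcatMap(key.spanned, partitions)
        diff = np.zeros(cmap.length + 1, dtype=np.int64)
        length_tally = Tally()
        for a in members:
            cs = cmap.to_concat(a.start)
            diff[cs] += 1
            diff[cs + a.length] -= 1
            length_tally.add(a.length)
        coverage = rle_encode(np.cumsum(diff[:-1]))
        buckets.append(
            Bucket(
                key=key,
                coverage=coverage,
                length_tally=length_tally,
                tlen_tally=tlen_tallies.get(key, Tally()),
                paired_count=paired_counts.get(key, 0),
            )
        )
    return buckets


def build_spanning_buckets(
    unbundled: Sequence[UnbundledPair],
    partitions_of: dict[int, list[tuple[int, int]]],
) -> list[SpanningBucket]:
    groups: dict[tuple, list[UnbundledPair]] = {}
    for up in unbundled:
        bi, bj = up.bundle_indices
        key = (
            bi,
            bj,
            _spanned_ordinals(up.left.blocks, partitions_of[bi]),
            _spanned_ordinals(up.right.blocks, partitions_of[bj]),
            up.left.nh,
            up.left.strand,
            up.right.nh,
            up.right.strand,
        )
        groups.setdefault(key, []).append(up)

    out: list[SpanningBucket] = []
    for key, members in groups.items():
        bi, bj, sp_l, sp_r, nh_l, st_l, nh_r, st_r = key
        cmap_l = _ConcatMap(sp_l, partitions_of[bi])
        cmap_r = _ConcatMap(sp_r, partitions_of[bj])
        diff = np.zeros(cmap_l.length + cmap_r.length + 1, dtype=np.int64)
        lt, rt, tt = Tally(), Tally(), Tally()
        for up in members:
            cl = cmap_l.to_concat(up.left.start)
            diff[cl] += 1
            diff[cl + up.left.length] -= 1
            cr = cmap_l.length + cmap_r.to_concat(up.right.start)
            diff[cr] += 1
            diff[cr + up.right.length] -= 1
            lt.add(up.left.length)
            rt.add(up.right.length)
            if up.left.chrom == up.right.chrom:
                tt.add(_pair_tlen(up.left, up.right))
        out.append(
            SpanningBucket(
                bundle_left=bi,
                bundle_right=bj,
                spanned_left=sp_l,
                spanned_right=sp_r,
                nh_left=nh_l,
                strand_left=st_l,
                nh_right=nh_r,
                strand_right=st_r,
                coverage=rle_encode(np.cumsum(diff[:-1])),
                left_length_tally=lt,
                right_length_tally=rt,
                tlen_tally=tt,
                n_pairs=len(members),
            )
        )
    out.sort(key=SpanningBucket.sort_key)
    return out


# ---------------------------------------------------------------------------
# varint byte framing


class _Writer:
    def __init__(self) -> None:
        self.buf = bytearray()

    def uvarint(self, v: int) -> None:
        if v < 0:
            raise ValueError("uvarint cannot encode negative values")
        while True:
            b = v & 0x7F
            v >>= 7
            if v:
                self.buf.append(b | 0x80)
            else:
                self.buf.append(b)
                return

    def bytes_field(self, data: bytes) -> None:
        self.uvarint(len(data))
        self.buf.extend(data)

    def tally(self, tally: Tally) -> None:
        items = tally.sorted_items()
        self.uvarint(len(items))
        prev = 0
        for value, count in items:
            self.uvarint(value - prev)
            self.uvarint(count)
            prev = value

    def coverage(self, cv: CoverageVector) -> None:
        self.uvarint(len(cv.runs))
        for depth, length in cv.runs:
            self.uvarint(depth)
            self.uvarint(length)

    def ordinals(self, spanned: Sequence[int]) -> None:
        self.uvarint(len(spanned))
        prev = 0
        for o in spanned:
            self.uvarint(o - prev)
            prev = o

    def getvalue(self) -> bytes:
        return bytes(self.buf)


class _Reader:
    def __init__(self, data: bytes, section: str = "archive") -> None:
        self.data = data
        self.pos = 0
        self.section = section

    def uvarint(self) -> int:
        shift = 0
        result = 0
        while True:
            if self.pos >= len(self.data):
                raise ArchiveFormatError(f"truncated {self.section}")
            b = self.data[self.pos]
            self.pos += 1
            result |= (b & 0x7F) << shift
            if not b & 0x80:
                return result
            shift += 7

    def bytes_field(self) -> bytes:
        n = self.uvarint()
        if self.pos + n > len(self.data):
            raise ArchiveFormatError(f"truncated {self.section}")
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    def tally(self) -> Tally:
        n = self.uvarint()
        t = Tally()
        value = 0
        for _ in range(n):
            value += self.uvarint()
            t[value] = self.uvarint()
        return t

    def coverage(self) -> CoverageVector:
        n = self.uvarint()
        return CoverageVector(
            tuple((self.uvarint(), self.uvarint()) for _ in range(n))
        )

    def ordinals(self) -> tuple[int, ...]:
        n = self.uvarint()
        out = []
        o = 0
        for _ in range(n):
            o += self.uvarint()
            out.append(o)
        return tuple(out)


# ---------------------------------------------------------------------------
# bundle payloads


@dataclass
class BundlePayload:
    """Decoded contents of one bundle block."""

    bounds: list[int]  # partition boundaries, bounds[0] == span start
    buckets: list[Bucket]

    @property
    def partitions(self) -> list[tuple[int, int]]:
        return [
            (self.bounds[i], self.bounds[i + 1]) for i in range(len(self.bounds) - 1)
        ]


def encode_bundle_payload(
    bounds: Sequence[int], buckets: Sequence[Bucket]
) -> bytes:
    w = _Writer()
    w.uvarint(len(bounds))
    prev = 0
    for b in bounds:
        w.uvarint(b - prev)
        prev = b
    w.uvarint(len(buckets))
    for bk in buckets:
        w.ordinals(bk.key.spanned)
        w.uvarint(bk.key.nh)
        w.uvarint(_STRAND_CODE[bk.key.strand])
        w.coverage(bk.coverage)
        w.tally(bk.length_tally)
        w.tally(bk.tlen_tally)
        w.uvarint(bk.paired_count)
    return w.getvalue()


def decode_bundle_payload(data: bytes) -> BundlePayload:
    r = _Reader(data, "bundle block")
    n_bounds = r.uvarint()
    bounds: list[int] = []
    pos = 0
    for _ in range(n_bounds):
        pos += r.uvarint()
        bounds.append(pos)
    buckets = []
    for _ in range(r.uvarint()):
        spanned = r.ordinals()
        nh = r.uvarint()
        strand = _STRAND_FROM_CODE[r.uvarint()]
        coverage = r.coverage()
        length_tally = r.tally()
        tlen_tally = r.tally()
        paired_count = r.uvarint()
        buckets.append(
            Bucket(BucketKey(spanned, nh, strand), coverage, length_tally, tlen_tally, paired_count)
        )
    return BundlePayload(bounds=bounds, buckets=buckets)


def _encode_spanning_bucket(w: _Writer, sb: SpanningBucket) -> None:
    w.uvarint(sb.bundle_left)
    w.uvarint(sb.bundle_right)
    w.ordinals(sb.spanned_left)
    w.ordinals(sb.spanned_right)
    w.uvarint(sb.nh_left)
    w.uvarint(_STRAND_CODE[sb.strand_left])
    w.uvarint(sb.nh_right)
    w.uvarint(_STRAND_CODE[sb.strand_right])
    w.coverage(sb.coverage)
    w.tally(sb.left_length_tally)
    w.tally(sb.right_length_tally)
    w.tally(sb.tlen_tally)
    w.uvarint(sb.n_pairs)


def _decode_spanning_bucket(r: _Reader) -> SpanningBucket:
    return SpanningBucket(
        bundle_left=r.uvarint(),
        bundle_right=r.uvarint(),
        spanned_left=r.ordinals(),
        spanned_right=r.ordinals(),
        nh_left=r.uvarint(),
        strand_left=_STRAND_FROM_CODE[r.uvarint()],
        nh_right=r.uvarint(),
        strand_right=_STRAND_FROM_CODE[r.uvarint()],
        coverage=r.coverage(),
        left_length_tally=r.tally(),
        right_length_tally=r.tally(),
        tlen_tally=r.tally(),
        n_pairs=r.uvarint(),
    )


# ---------------------------------------------------------------------------
# whole-archive serialization


@dataclass
class CompressionStats:
    n_alignments: int = 0
    n_bundles: int = 0
    n_buckets: int = 0
    n_unbundled_pairs: int = 0
    archive_bytes: int = 0


def serialize_archive(
    chrom_table: Sequence[tuple[str, int]],
    bundle_meta: Sequence[tuple[int, int, int]],  # (chrom_id, start, end)
    bundle_blocks: Sequence[bytes],  # compressed
    unbundled_chunks: Sequence[tuple[int, int, bytes]],  # (bmin, bmax, compressed)
) -> bytes:
    w = _Writer()
    w.buf.extend(MAGIC)
    w.uvarint(VERSION)
    w.uvarint(len(chrom_table))
    for name, length in chrom_table:
        w.bytes_field(name.encode())
        w.uvarint(length)
    w.uvarint(len(bundle_blocks))
    offset = 0
    for (chrom_id, start, end), block in zip(bundle_meta, bundle_blocks):
        w.uvarint(chrom_id)
        w.uvarint(start)
        w.uvarint(end - start)
        w.uvarint(offset)
        w.uvarint(len(block))
        offset += len(block)
    w.uvarint(len(unbundled_chunks))
    uoffset = 0
    for bmin, bmax, chunk in unbundled_chunks:
        w.uvarint(bmin)
        w.uvarint(bmax)
        w.uvarint(uoffset)
        w.uvarint(len(chunk))
        uoffset += len(chunk)
    w.uvarint(offset)  # bundle data section length
    for block in bundle_blocks:
        w.buf.extend(block)
    for _, _, chunk in unbundled_chunks:
        w.buf.extend(chunk)
    return w.getvalue()


@dataclass
class _BundleEntry:
    chrom_id: int
    start: int
    end: int
    offset: int
    length: int


@dataclass
class _ChunkEntry:
    bundle_min: int
    bundle_max: int
    offset: int
    length: int


class ArchiveReader:
    """Random-access handle over serialized archive bytes.

    Construction parses only the header and indexes; blocks are inflated on
    demand (and not cached — blocks are stateless and independent).
    """

    def __init__(self, data: bytes) -> None:
        if data[:4] != MAGIC:
            raise ArchiveFormatError("bad magic in header")
        r = _Reader(data, "header")
        r.pos = 4
        version = r.uvarint()
        if version != VERSION:
            raise ArchiveFormatError(f"unsupported version {version}")
        self.chrom_table: list[tuple[str, int]] = []
        for _ in range(r.uvarint()):
            name = r.bytes_field().decode()
            self.chrom_table.append((name, r.uvarint()))
        self.bundles: list[_BundleEntry] = []
        r.section = "bundle index"
        prev_off = -1
        for _ in range(r.uvarint()):
            chrom_id = r.uvarint()
            start = r.uvarint()
            span = r.uvarint()
            offset = r.uvarint()
            length = r.uvarint()
            if offset <= prev_off:
                raise ArchiveFormatError("bundle index offsets not increasing")
            prev_off = offset
            self.bundles.append(_BundleEntry(chrom_id, start, start + span, offset, length))
        r.section = "unbundled index"
        self.chunks: list[_ChunkEntry] = []
        for _ in range(r.uvarint()):
            self.chunks.append(
                _ChunkEntry(r.uvarint(), r.uvarint(), r.uvarint(), r.uvarint())
            )
        bundle_section_len = r.uvarint()
        self._bundle_data_start = r.pos
        self._unbundled_data_start = r.pos + bundle_section_len
        if self._unbundled_data_start > len(data):
            raise ArchiveFormatError("truncated bundle data section")
        self._data = data
        self._chrom_id = {name: i for i, (name, _) in enumerate(self.chrom_table)}

    # -- bundles ------------------------------------------------------------

    def n_bundles(self) -> int:
        return len(self.bundles)

    def bundle_span(self, i: int) -> tuple[str, int, int]:
        e = self.bundles[i]
        return (self.chrom_table[e.chrom_id][0], e.start, e.end)

    def bundle_block_bytes(self, i: int) -> bytes:
        e = self.bundles[i]
        start = self._bundle_data_start + e.offset
        raw = self._data[start : start + e.length]
        if len(raw) != e.length:
            raise ArchiveFormatError("truncated bundle data section")
        return raw

    def bundle_payload(self, i: int) -> BundlePayload:
        try:
            inflated = zlib.decompress(self.bundle_block_bytes(i))
        except zlib.error as exc:
            raise ArchiveFormatError(f"bundle block {i} fails to inflate: {exc}") from exc
        return decode_bundle_payload(inflated)

    def bundles_overlapping(self, chrom: str, start: int, end: int) -> list[int]:
        cid = self._chrom_id.get(chrom)
        if cid is None:
            raise KeyError(chrom)
        return [
            i
            for i, e in enumerate(self.bundles)
            if e.chrom_id == cid and e.start < end and start < e.end
        ]

    # -- unbundled section --------------------------------------------------

    def chunk_buckets(self, k: int) -> list[SpanningBucket]:
        e = self.chunks[k]
        start = self._unbundled_data_start + e.offset
        raw = self._data[start : start + e.length]
        if len(raw) != e.length:
            raise ArchiveFormatError("truncated unbundled data section")
        try:
            inflated = zlib.decompress(raw)
        except zlib.error as exc:
            raise ArchiveFormatError(f"unbundled chunk {k} fails to inflate: {exc}") from exc
        r = _Reader(inflated, "unbundled chunk")
        out = [_decode_spanning_bucket(r) for _ in range(r.uvarint())]
        for sb in out:
            if sb.bundle_left >= len(self.bundles) or sb.bundle_right >= len(self.bundles):
                raise ArchiveFormatError("dangling bundle index in unbundled section")
        return out

    def chunks_for_bundles(self, bundle_indices: Iterable[int]) -> list[int]:
        wanted = set(bundle_indices)
        if not wanted:
            return []
        lo, hi = min(wanted), max(wanted)
        return [
            k
            for k, e in enumerate(self.chunks)
            if e.bundle_min <= hi and lo <= e.bundle_max
        ]

    def all_spanning_buckets(self) -> list[SpanningBucket]:
        out: list[SpanningBucket] = []
        for k in range(len(self.chunks)):
            out.extend(self.chunk_buckets(k))
        return out


def deserialize_index(data: bytes) -> ArchiveReader:
    """Parse header + indexes only; no block inflation."""
    return ArchiveReader(data)


# ---------------------------------------------------------------------------
# top-level compression


def compress_alignments(
    alignments: Sequence[Alignment],
    chrom_table: Sequence[tuple[str, int]],
    *,
    seed: int = 0,
    preserve_nested: bool = False,
    split_discordant: bool = False,
) -> tuple[bytes, CompressionStats]:
    """Compress coordinate-sorted alignments into archive bytes."""
    rng = random.Random(seed)
    result = prepare_bundles(
        alignments,
        preserve_nested=preserve_nested,
        split_discordant=split_discordant,
        rng=rng,
    )
    return _compress_prepared(result, chrom_table, n_alignments=len(alignments))


def _compress_prepared(
    result: BundlingResult,
    chrom_table: Sequence[tuple[str, int]],
    n_alignments: int,
) -> tuple[bytes, CompressionStats]:
    chrom_id = {name: i for i, (name, _) in enumerate(chrom_table)}
    pairs_by_bundle: dict[int, list[tuple[Alignment, Alignment]]] = {}
    member_bundle: dict[int, int] = {
        id(a): b.index for b in result.bundles for a in b.alignments
    }
    for a, b in result.pairs:
        bi = member_bundle.get(id(a))
        if bi is not None and member_bundle.get(id(b)) == bi:
            pairs_by_bundle.setdefault(bi, []).append((a, b))

    stats = CompressionStats(n_alignments=n_alignments, n_bundles=len(result.bundles))
    bundle_meta: list[tuple[int, int, int]] = []
    bundle_blocks: list[bytes] = []
    partitions_of: dict[int, list[tuple[int, int]]] = {}
    for bundle in result.bundles:
        partitions = partition_bundle(bundle)
        partitions_of[bundle.index] = partitions
        buckets = build_buckets(bundle, partitions, pairs_by_bundle.get(bundle.index))
        stats.n_buckets += len(buckets)
        bounds = [partitions[0][0]] + [p[1] for p in partitions] if partitions else [bundle.start, bundle.end]
        payload = encode_bundle_payload(bounds, buckets)
        bundle_blocks.append(zlib.compress(payload, 6))
        bundle_meta.append((chrom_id[bundle.chrom], bundle.start, bundle.end))

    spanning = build_spanning_buckets(result.unbundled, partitions_of)
    stats.n_unbundled_pairs = len(result.unbundled)
    chunks: list[tuple[int, int, bytes]] = []
    for i in range(0, len(spanning), UNBUNDLED_CHUNK_SIZE):
        group = spanning[i : i + UNBUNDLED_CHUNK_SIZE]
        w = _Writer()
        w.uvarint(len(group))
        for sb in group:
            _encode_spanning_bucket(w, sb)
        bmin = min(min(sb.bundle_left, sb.bundle_right) for sb in group)
        bmax = max(max(sb.bundle_left, sb.bundle_right) for sb in group)
        chunks.append((bmin, bmax, zlib.compress(w.getvalue(), 6)))

    data = serialize_archive(chrom_table, bundle_meta, bundle_blocks, chunks)
    stats.archive_bytes = len(data)
    return data, stats
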