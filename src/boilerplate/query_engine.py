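"""Indexed queries against an archive without full decompression.

Three query types: bundle spans (index lookup only), coverage over a region
(inflate + RLE-decode the overlapping blocks, no read recovery) and alignments
over a region (runs the greedy recovery on overlapping bundles). Blocks are
stateless, so results are independent of any other region queried.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np

from .alignment_model import Alignment
from .compressor import ArchiveReader, _ConcatMap
from .decompressor import expand_bundle, expand_unbundled

__all__ = ["QueryError", "query_bundles", "query_coverage", "query_alignments"]


class QueryError(ValueError):
    """Raised for invalid query parameters (e.g. unknown chromosome)."""


def _reader(archive: Union[bytes, ArchiveReader]) -> ArchiveReader:
    return archive if isinstance(archive, ArchiveReader) else ArchiveReader(archive)


def query_bundles(archive: Union[bytes, ArchiveReader]) -> list[tuple[str, int, int]]:
    """Bundle spans in genomic order, straight from the index."""
    reader = _reader(archive)
    return [reader.bundle_span(i) for i in range(reader.n_bundles())]


def _check_region(reader: ArchiveReader, chrom: str, start: int, end: int) -> None:
    if chrom not in {name for name, _ in reader.chrom_table}:
        raise QueryError(f"unknown chromosome {chrom!r}")
    if not start < end:
        raise QueryError(f"empty query interval [{start},{end})")


def _add_concat_runs(
    out: np.ndarray,
    qstart: int,
    qend: int,
    runs,
    cmap: _ConcatMap,
) -> None:
    """Add a bucket's concat-space RLE runs into a genomic accumulator."""
    cpos = 0
    for depth, rlen in runs:
        if depth:
            for gs, ge in cmap.interval_to_blocks(cpos, cpos + rlen):
                lo, hi = max(gs, qstart), min(ge, qend)
                if lo < hi:
                    out[lo - qstart : hi - qstart] += depth
        cpos += rlen


def query_coverage(
    archive: Union[bytes, ArchiveReader], chrom: str, start: int, end: int
) -> np.ndarray:
    """Per-base depth over [start, end); positions inside a bucket's skipped
    introns contribute nothing from that bucket."""
    reader = _reader(archive)
    _check_region(reader, chrom, start, end)
    out = np.zeros(end - start, dtype=np.int64)
    overlapping = reader.bundles_overlapping(chrom, start, end)
    for i in overlapping:
        payload = reader.bundle_payload(i)
        partitions = payload.partitions
        for bucket in payload.buckets:
            cmap = _ConcatMap(bucket.key.spanned, partitions)
            _add_concat_runs(out, start, end, bucket.coverage.runs, cmap)
    # unbundled pairs contribute coverage inside their home bundles too
    for k in reader.chunks_for_bundles(overlapping):
        for sb in reader.chunk_buckets(k):
            sides = []
            if sb.bundle_left in overlapping:
                sides.append((sb.bundle_left, sb.spanned_left, 0))
            if sb.bundle_right in overlapping:
                sides.append((sb.bundle_right, sb.spanned_right, 1))
            if not sides:
                continue
            cov = sb.coverage.decode()
            for bi, spanned, side in sides:
                cmap = _ConcatMap(spanned, reader.bundle_payload(bi).partitions)
                part = cov[: cmap.length] if side == 0 else cov[-cmap.length :]
                from .compressor import rle_encode

                _add_concat_runs(out, start, end, rle_encode(part).runs, cmap)
    return out


def query_alignments(
    archive: Union[bytes, ArchiveReader],
    chrom: str,
    start: int,
    end: int,
    seed: int = 0,
) -> list[Alignment]:
    """Alignments with any block overlapping [start, end).

    Expands overlapping bundles (and unbundled chunks whose bundle ranges
    intersect) with per-bundle seeded RNG, so results do not depend on which
    other regions were queried.
    """
    reader = _reader(archive)
    _check_region(reader, chrom, start, end)
    overlapping = reader.bundles_overlapping(chrom, start, end)
    out: list[Alignment] = []
    for i in overlapping:
        out.extend(
            expand_bundle(reader.bundle_block_bytes(i), chrom, seed, bundle_index=i)
        )
    chunk_indices = reader.chunks_for_bundles(overlapping)
    out.extend(expand_unbundled(reader, seed, chunk_indices=chunk_indices))

    def overlaps(a: Alignment) -> bool:
        return a.chrom == chrom and any(bs < end and start < be for bs, be in a.blocks)

    return sorted((a for a in out if overlaps(a)), key=lambda a: (a.start, a.end))
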