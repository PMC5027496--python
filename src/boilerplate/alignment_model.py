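"""Normalized in-memory representation of spliced alignments and SAM round-tripping.

Alignments are reduced to the information the archive keeps: position, block
structure (gapped at introns), read length, strand tag, multi-mapping count
and pairing. Coordinates are 0-based half-open internally; conversion to and
from 1-based SAM happens only at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Optional, Sequence, Union

import pysam

__all__ = [
    "Alignment",
    "Junction",
    "CigarError",
    "OrderingError",
    "PairingError",
    "parse_cigar",
    "blocks_to_cigar",
    "read_alignments",
    "read_sam",
    "write_alignments",
]


class CigarError(ValueError):
    """Raised for malformed CIGAR strings."""


class OrderingError(ValueError):
    """Raised when input SAM is not coordinate-sorted."""


class PairingError(ValueError):
    """Raised when a reconstructed pair carries inconsistent mate fields."""


_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar: str, start: int) -> tuple[tuple[tuple[int, int], ...], int]:
    """Parse a SAM CIGAR into genomic blocks split only at ``N`` ops.

    ``M``/``=``/``X`` and ``D`` consume reference within a block; ``N`` ends the
    current block and opens a gap; ``I``/``S``/``H``/``P`` consume no reference
    and are dropped from the block model. The returned length is the total
    genomic footprint (sum of block lengths), which is what coverage vectors
    and length tallies are built from.
    """
    if not cigar or cigar == "*":
        raise CigarError("missing CIGAR string")
    consumed = 0
    pos = start
    blocks: list[tuple[int, int]] = []
    block_start: Optional[int] = None
    for m in _CIGAR_TOKEN.finditer(cigar):
        tok_start, tok_end = m.span()
        if tok_start != consumed:
            raise CigarError(f"malformed CIGAR near {cigar[consumed:tok_start]!r}")
        consumed = tok_end
        n = int(m.group(1))
        op = m.group(2)
        if n <= 0:
            raise CigarError(f"zero-length CIGAR op {m.group(0)!r}")
        if op in "M=XD":
            if block_start is None:
                block_start = pos
            pos += n
        elif op == "N":
            if block_start is not None:
                blocks.append((block_start, pos))
                block_start = None
            pos += n
        # I/S/H/P: no reference consumed, nothing kept
    if consumed != len(cigar):
        raise CigarError(f"malformed CIGAR near {cigar[consumed:]!r}")
    if block_start is not None:
        blocks.append((block_start, pos))
    if not blocks:
        raise CigarError(f"CIGAR {cigar!r} aligns no reference bases")
    length = sum(e - s for s, e in blocks)
    return tuple(blocks), length


def blocks_to_cigar(blocks: Sequence[tuple[int, int]]) -> str:
    """Inverse of :func:`parse_cigar` for the flattened block model (M/N only)."""
    parts: list[str] = []
    prev_end: Optional[int] = None
    for s, e in blocks:
        if prev_end is not None:
            parts.append(f"{s - prev_end}N")
        parts.append(f"{e - s}M")
        prev_end = e
    return "".join(parts)


@dataclass(frozen=True)
class Junction:
    """An intron: ``donor`` is the first intronic base, ``acceptor`` one past the last."""

    chrom: str
    donor: int
    acceptor: int

    def __post_init__(self) -> None:
        if not self.donor < self.acceptor:
            raise ValueError(f"junction donor {self.donor} !< acceptor {self.acceptor}")


@dataclass(slots=True)
class Alignment:
    """One aligned end in normalized coordinates.

    ``blocks`` are sorted, non-overlapping genomic intervals (half-open),
    gapped only at introns. ``strand`` is ``'+'``/``'-'`` from ``XS:A`` or
    ``None`` when unknown; ``nh`` comes from ``NH:i`` (default 1).
    """

    chrom: str
    blocks: tuple[tuple[int, int], ...]
    strand: Optional[str] = None
    nh: int = 1
    paired: bool = False
    mate_chrom: Optional[str] = None
    mate_start: Optional[int] = None
    tlen: int = 0
    qname: Optional[str] = None

    def __post_init__(self) -> None:
        self.blocks = tuple((int(s), int(e)) for s, e in self.blocks)
        if not self.blocks:
            raise ValueError("alignment needs at least one block")
        prev_end = None
        for s, e in self.blocks:
            if e <= s:
                raise ValueError(f"empty block ({s},{e})")
            if prev_end is not None and s <= prev_end:
                raise ValueError("blocks must be sorted and separated by gaps")
            prev_end = e
        if self.nh < 1:
            raise ValueError("nh must be positive")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def junctions(self) -> tuple[Junction, ...]:
        return tuple(
            Junction(self.chrom, self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        )

    def junction_points(self) -> tuple[tuple[int, int], ...]:
        """(donor, acceptor) pairs, convenient as a hashable match key."""
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        )

    def copy(self, **changes) -> "Alignment":
        return replace(self, **changes)


SamSource = Union[str, IO]


def _alignment_from_record(rec: pysam.AlignedSegment) -> Alignment:
    blocks, _ = parse_cigar(rec.cigarstring, rec.reference_start)
    try:
        strand = rec.get_tag("XS")
    except KeyError:
        strand = None
    if strand not in ("+", "-"):
        strand = None
    try:
        nh = int(rec.get_tag("NH"))
    except KeyError:
        nh = 1
    paired = bool(rec.is_paired) and not rec.mate_is_unmapped
    mate_chrom = rec.next_reference_name if paired else None
    mate_start = rec.next_reference_start if paired else None
    if paired and (mate_chrom is None or mate_start is None or mate_start < 0):
        paired, mate_chrom, mate_start = False, None, None
    return Alignment(
        chrom=rec.reference_name,
        blocks=blocks,
        strand=strand,
        nh=max(nh, 1),
        paired=paired,
        mate_chrom=mate_chrom,
        mate_start=mate_start if paired else None,
        tlen=rec.template_length if paired else 0,
        qname=rec.query_name,
    )


def read_sam(source: SamSource) -> tuple[list[tuple[str, int]], list[Alignment]]:
    """Read a coordinate-sorted SAM; return (chromosome table, alignments).

    Unaligned records are skipped. Orphaned ends (mate unmapped) are converted
    to unpaired reads. Raises :class:`OrderingError` on unsorted input.
    """
    mode = "r"
    with pysam.AlignmentFile(source, mode, check_sq=False) as sam:
        chrom_table = [(name, length) for name, length in zip(sam.references, sam.lengths)]
        alignments: list[Alignment] = []
        last_tid = -1
        last_pos = -1
        for i, rec in enumerate(sam):
            if rec.is_unmapped or rec.reference_id < 0:
                continue
            if rec.reference_id < last_tid or (
                rec.reference_id == last_tid and rec.reference_start < last_pos
            ):
                raise OrderingError(f"input not coordinate-sorted at record {i}")
            last_tid, last_pos = rec.reference_id, rec.reference_start
            alignments.append(_alignment_from_record(rec))
    return chrom_table, alignments


def read_alignments(source: SamSource) -> list[Alignment]:
    """Shorthand for ``read_sam(source)[1]``."""
    return read_sam(source)[1]


def write_alignments(
    alignments: Iterable[Alignment],
    chrom_table: Sequence[tuple[str, int]],
    dest: Union[str, IO],
) -> None:
    """Emit alignments as coordinate-sorted SAM with placeholder names.

    Sequences and qualities are written as ``'*'`` (not preserved by design).
    Paired alignments must share a ``qname`` with their mate and carry mutually
    consistent mate fields; the leftmost mate gets positive TLEN.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": length} for name, length in chrom_table],
        }
    )
    tid = {name: i for i, (name, _) in enumerate(chrom_table)}
    alns = sorted(alignments, key=lambda a: (tid[a.chrom], a.start, a.end))
    # index mates by qname for flag assignment / consistency checks
    by_name: dict[str, list[Alignment]] = {}
    for a in alns:
        if a.paired and a.qname is not None:
            by_name.setdefault(a.qname, []).append(a)
    for name, group in by_name.items():
        if len(group) != 2:
            raise PairingError(f"paired alignment {name!r} has {len(group)} ends")
        a, b = group
        if (a.mate_chrom, a.mate_start) != (b.chrom, b.start) or (
            b.mate_chrom,
            b.mate_start,
        ) != (a.chrom, a.start):
            raise PairingError(f"pair {name!r} carries inconsistent mate fields")

    counter = 0
    first_of: dict[str, Alignment] = {}

    with pysam.AlignmentFile(dest, "wh", header=header) as out:
        for a in alns:
            rec = pysam.AlignedSegment(header)
            if a.qname is not None:
                rec.query_name = a.qname
            else:
                counter += 1
                rec.query_name = f"r{counter}"
            rec.reference_id = tid[a.chrom]
            rec.reference_start = a.start
            rec.cigarstring = blocks_to_cigar(a.blocks)
            rec.mapping_quality = 50
            flag = 0
            if a.paired:
                flag |= 0x1
                if a.qname in first_of:
                    flag |= 0x80
                else:
                    first_of[a.qname] = a
                    flag |= 0x40
                rec.next_reference_id = tid[a.mate_chrom]
                rec.next_reference_start = a.mate_start
                rec.template_length = a.tlen
            else:
                rec.next_reference_id = -1
                rec.next_reference_start = -1
                rec.template_length = 0
            rec.flag = flag
            tags = [("NH", a.nh)]
            if a.strand is not None:
                tags.append(("XS", a.strand))
            rec.set_tags(tags)
            out.write(rec)
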