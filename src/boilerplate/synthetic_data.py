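"""Deterministic synthetic transcriptomes and spliced-alignment fixtures.

Genes are laid out with inter-gene gaps comfortably above the bundling gap so
each gene maps to exactly one bundle. Reads are sampled in transcript
coordinates and projected onto genomic blocks (introducing N CIGAR ops across
introns); the generator also returns exact truth records — per-end match keys,
pair keys and the outer-distance tally — so lossy round trips can be checked
by plain bookkeeping.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Optional, Sequence, Union

import pysam

from .alignment_model import Alignment
from .compressor import Tally

__all__ = [
    "GeneModel",
    "SimulatedReads",
    "gen_transcriptome",
    "gen_reads",
    "write_gtf",
    "write_sam",
]


@dataclass
class GeneModel:
    """One gene with a single transcript."""

    tid: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # genomic, sorted, half-open

    @property
    def tx_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def project(self, tx_start: int, length: int) -> tuple[tuple[int, int], ...]:
        """Map a transcript-coordinate interval to genomic blocks."""
        if tx_start < 0 or tx_start + length > self.tx_length:
            raise ValueError("interval outside transcript")
        blocks: list[tuple[int, int]] = []
        offset = 0
        lo, hi = tx_start, tx_start + length
        for s, e in self.exons:
            elen = e - s
            a = max(lo, offset)
            b = min(hi, offset + elen)
            if a < b:
                blocks.append((s + (a - offset), s + (b - offset)))
            offset += elen
        return tuple(blocks)


def gen_transcriptome(
    n_genes: int,
    exons_per_gene: tuple[int, int] = (1, 3),
    exon_length: tuple[int, int] = (150, 400),
    intron_length: tuple[int, int] = (60, 300),
    gene_gap: tuple[int, int] = (100, 400),
    chroms: Sequence[str] = ("chr1",),
    seed: int = 0,
) -> tuple[list[GeneModel], list[tuple[str, int]]]:
    """Non-overlapping genes, gaps > 50 bases, deterministic given ``seed``."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if gene_gap[0] <= 50:
        raise ValueError("gene gaps must exceed the 50-base bundling gap")
    rng = random.Random(seed)
    genes: list[GeneModel] = []
    cursor = {c: 100 for c in chroms}
    for i in range(n_genes):
        chrom = chroms[i % len(chroms)]
        n_exons = rng.randint(*exons_per_gene)
        pos = cursor[chrom]
        exons = []
        for j in range(n_exons):
            if j:
                pos += rng.randint(*intron_length)
            length = rng.randint(*exon_length)
            exons.append((pos, pos + length))
            pos += length
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i}", chrom, strand, tuple(exons)))
        cursor[chrom] = pos + rng.randint(*gene_gap)
    chrom_table = [(c, cursor[c] + 1000) for c in chroms]
    return genes, chrom_table


@dataclass
class _SimRecord:
    qname: str
    flag: int
    chrom: str
    pos: int
    blocks: tuple[tuple[int, int], ...]
    mate_chrom: Optional[str]
    mate_pos: Optional[int]
    tlen: int
    nh: int
    xs: Optional[str]


@dataclass
class SimulatedReads:
    records: list[_SimRecord]
    chrom_table: list[tuple[str, int]]
    # exact bookkeeping for oracle-style tests
    end_keys: Counter = field(default_factory=Counter)  # (chrom, start, junctions)
    pair_keys: Counter = field(default_factory=Counter)
    tlen_tally: Tally = field(default_factory=Tally)
    n_orphans: int = 0

    def to_alignments(self) -> list[Alignment]:
        """Alignments as ``read_alignments`` would produce them (orphans
        already demoted to unpaired)."""
        out = []
        for r in self.records:
            paired = bool(r.flag & 0x1) and not r.flag & 0x8
            out.append(
                Alignment(
                    chrom=r.chrom,
                    blocks=r.blocks,
                    strand=r.xs,
                    nh=r.nh,
                    paired=paired,
                    mate_chrom=r.mate_chrom if paired else None,
                    mate_start=r.mate_pos if paired else None,
                    tlen=r.tlen if paired else 0,
                    qname=r.qname,
                )
            )
        return out


def _sample_length(spec, rng: random.Random) -> int:
    if isinstance(spec, int):
        return spec
    if isinstance(spec, dict):
        values = sorted(spec)
        weights = [spec[v] for v in values]
        return rng.choices(values, weights=weights)[0]
    raise ValueError(f"bad read length spec {spec!r}")


def _sample_nh(spec, rng: random.Random) -> int:
    if spec is None:
        return 1
    if isinstance(spec, int):
        return spec
    values = sorted(spec)
    weights = [spec[v] for v in values]
    return rng.choices(values, weights=weights)[0]


def _key(chrom: str, blocks) -> tuple:
    juncs = tuple((blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1))
    return (chrom, blocks[0][0], juncs)


def gen_reads(
    genes: Sequence[GeneModel],
    chrom_table: Sequence[tuple[str, int]],
    n_reads: int,
    read_length: Union[int, dict] = 100,
    paired: bool = False,
    tlen_spec: Union[int, tuple[int, int]] = (200, 350),
    nh_spec: Union[None, int, dict] = None,
    orphan_rate: float = 0.0,
    discordant_rate: float = 0.0,
    seed: int = 0,
) -> SimulatedReads:
    """Sample reads (or pairs) from transcripts; coordinate-sorted output.

    ``n_reads`` counts fragments: unpaired reads, or pairs when ``paired``.
    ``tlen_spec`` is the fragment length in transcript coordinates (fixed int
    or inclusive uniform range); the recorded TLEN is the genomic outer
    distance after projection. Multi-mappers (``nh_spec``) emit NH copies at
    independently sampled placements sharing a read name.
    """
    rng = random.Random(seed)
    sim = SimulatedReads(records=[], chrom_table=list(chrom_table))
    tid_order = {name: i for i, (name, _) in enumerate(chrom_table)}

    def place_single(gene: GeneModel, rl: int):
        if rl > gene.tx_length:
            raise ValueError(
                f"read length {rl} exceeds transcript {gene.tid} length {gene.tx_length}"
            )
        s = rng.randint(0, gene.tx_length - rl)
        return gene.project(s, rl)

    for i in range(n_reads):
        nh = _sample_nh(nh_spec, rng)
        qname = f"s{i}"
        if not paired:
            rl = _sample_length(read_length, rng)
            for _ in range(nh):
                gene = rng.choice(genes)
                blocks = place_single(gene, rl)
                xs = gene.strand if len(blocks) > 1 else None
                sim.records.append(
                    _SimRecord(qname, 0, gene.chrom, blocks[0][0], blocks, None, None, 0, nh, xs)
                )
                sim.end_keys[_key(gene.chrom, blocks)] += 1
        else:
            rl1 = _sample_length(read_length, rng)
            rl2 = _sample_length(read_length, rng)
            discordant = rng.random() < discordant_rate
            orphan = not discordant and rng.random() < orphan_rate
            for _ in range(nh):
                gene = rng.choice(genes)
                if isinstance(tlen_spec, int):
                    frag = tlen_spec
                else:
                    frag = rng.randint(*tlen_spec)
                frag = max(frag, rl1, rl2)
                if frag > gene.tx_length:
                    frag = gene.tx_length
                s = rng.randint(0, gene.tx_length - frag)
                lb = gene.project(s, rl1)
                rb = gene.project(s + frag - rl2, rl2)
                d = rb[-1][1] - lb[0][0]
                xs_l = gene.strand if len(lb) > 1 else None
                xs_r = gene.strand if len(rb) > 1 else None
                if discordant:
                    xs_l, xs_r = "+", "-"
                if orphan:
                    drop_left = rng.random() < 0.5
                    keep_blocks, keep_xs = (rb, xs_r) if drop_left else (lb, xs_l)
                    flag = 0x1 | 0x8 | (0x80 if drop_left else 0x40)
                    sim.records.append(
                        _SimRecord(
                            qname, flag, gene.chrom, keep_blocks[0][0], keep_blocks,
                            gene.chrom, keep_blocks[0][0], 0, nh, keep_xs,
                        )
                    )
                    sim.end_keys[_key(gene.chrom, keep_blocks)] += 1
                    sim.n_orphans += 1
                    continue
                sim.records.append(
                    _SimRecord(
                        qname, 0x1 | 0x40, gene.chrom, lb[0][0], lb,
                        gene.chrom, rb[0][0], d, nh, xs_l,
                    )
                )
                sim.records.append(
                    _SimRecord(
                        qname, 0x1 | 0x80, gene.chrom, rb[0][0], rb,
                        gene.chrom, lb[0][0], -d, nh, xs_r,
                    )
                )
                sim.end_keys[_key(gene.chrom, lb)] += 1
                sim.end_keys[_key(gene.chrom, rb)] += 1
                kl, kr = _key(gene.chrom, lb), _key(gene.chrom, rb)
                sim.pair_keys[(min(kl, kr), max(kl, kr))] += 1
                sim.tlen_tally.add(d)

    sim.records.sort(key=lambda r: (tid_order[r.chrom], r.pos))
    return sim


def write_gtf(genes: Sequence[GeneModel], dest: Union[str, IO]) -> None:
    fh = open(dest, "w") if isinstance(dest, str) else dest
    try:
        for g in genes:
            for s, e in g.exons:
                attrs = f'gene_id "{g.tid}"; transcript_id "{g.tid}";'
                fh.write(
                    f"{g.chrom}\tsynth\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
    finally:
        if isinstance(dest, str):
            fh.close()


def _cigar(blocks: Sequence[tuple[int, int]]) -> str:
    parts = []
    prev = None
    for s, e in blocks:
        if prev is not None:
            parts.append(f"{s - prev}N")
        parts.append(f"{e - s}M")
        prev = e
    return "".join(parts)


def write_sam(sim: SimulatedReads, dest: Union[str, IO]) -> None:
    """Write the simulated records as coordinate-sorted SAM text."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": length} for name, length in sim.chrom_table],
        }
    )
    tid = {name: i for i, (name, _) in enumerate(sim.chrom_table)}
    with pysam.AlignmentFile(dest, "wh", header=header) as out:
        for r in sim.records:
            rec = pysam.AlignedSegment(header)
            rec.query_name = r.qname
            rec.flag = r.flag
            rec.reference_id = tid[r.chrom]
            rec.reference_start = r.pos
            rec.cigarstring = _cigar(r.blocks)
            rec.mapping_quality = 50
            if r.mate_chrom is not None:
                rec.next_reference_id = tid[r.mate_chrom]
                rec.next_reference_start = r.mate_pos
            else:
                rec.next_reference_id = -1
                rec.next_reference_start = -1
            rec.template_length = r.tlen
            tags = [("NH", r.nh)]
            if r.xs is not None:
                tags.append(("XS", r.xs))
            rec.set_tags(tags)
            out.write(rec)
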