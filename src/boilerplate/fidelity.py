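"""Fidelity metrics: how much did compression shuffle the data?

Alignment-level precision/recall match alignments on (chromosome, start,
junction set), each at most once, with an optional pairs mode requiring both
ends of a pair to match. Transcript-level scores compare transcriptomes with
an exon-boundary-tolerant score aggregated by a coverage-weighted best-match
average, normalized so that a transcriptome scores 1 against itself.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .alignment_model import Alignment
from .compressor import Tally

__all__ = [
    "DEFAULT_K",
    "Exon",
    "Transcript",
    "exon_score",
    "transcript_score",
    "weighted_precision",
    "weighted_recall",
    "alignment_pr",
    "pair_up",
    "tlen_ratio",
    "read_gtf",
    "read_coverage_table",
]

DEFAULT_K = 10


@dataclass(frozen=True)
class Exon:
    x: int
    y: int

    def __post_init__(self) -> None:
        if not self.x < self.y:
            raise ValueError(f"exon start {self.x} !< end {self.y}")


@dataclass
class Transcript:
    id: str
    chrom: str
    strand: Optional[str]
    exons: tuple[Exon, ...]
    coverage: float = 1.0

    def __post_init__(self) -> None:
        self.exons = tuple(self.exons)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.x < a.y:
                raise ValueError("exons must be sorted and non-overlapping")


def exon_score(e1: Exon, e2: Exon, k: int = DEFAULT_K) -> float:
    """Boundary-offset score in [0, 1]; each side saturates at k (−1/2 each)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return (
        1.0
        - min(abs(e2.x - e1.x), k) / (2 * k)
        - min(abs(e2.y - e1.y), k) / (2 * k)
    )


def transcript_score(t: Transcript, t_hat: Transcript, k: int = DEFAULT_K) -> float:
    """Best order-preserving one-to-one exon matching, averaged over
    ``max(|t|, |t_hat|)``; 1 iff the exon chains are identical.

    Transcripts on different chromosomes, or on opposite known strands, score 0.
    """
    if t.chrom != t_hat.chrom:
        return 0.0
    if t.strand is not None and t_hat.strand is not None and t.strand != t_hat.strand:
        return 0.0
    n, m = len(t.exons), len(t_hat.exons)
    if n == 0 or m == 0:
        return 0.0
    # dp[i][j]: best total exon score using t.exons[:i] and t_hat.exons[:j]
    prev = [0.0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0.0] * (m + 1)
        for j in range(1, m + 1):
            cur[j] = max(
                prev[j],
                cur[j - 1],
                prev[j - 1] + exon_score(t.exons[i - 1], t_hat.exons[j - 1], k),
            )
        prev = cur
    return prev[m] / max(n, m)


def _weighted_best_match(
    first: Sequence[Transcript], second: Sequence[Transcript], k: int
) -> float:
    if not first:
        raise ValueError("cannot score an empty transcriptome")
    total_weight = sum(t.coverage for t in first)
    if total_weight <= 0:
        raise ValueError("total coverage weight must be positive")
    by_chrom: dict[str, list[Transcript]] = {}
    for t in second:
        by_chrom.setdefault(t.chrom, []).append(t)
    acc = 0.0
    for t in first:
        candidates = by_chrom.get(t.chrom, ())
        best = max((transcript_score(t, u, k) for u in candidates), default=0.0)
        acc += best * t.coverage
    return acc / total_weight


def weighted_precision(
    t_hat: Sequence[Transcript], t_ref: Sequence[Transcript], k: int = DEFAULT_K
) -> float:
    """Coverage-weighted average over assembled transcripts of their best
    match in the reference (normalized to 1 for identical sets)."""
    return _weighted_best_match(t_hat, t_ref, k)


def weighted_recall(
    t_ref: Sequence[Transcript], t_hat: Sequence[Transcript], k: int = DEFAULT_K
) -> float:
    """Coverage-weighted average over reference transcripts of their best
    match in the assembly."""
    return _weighted_best_match(t_ref, t_hat, k)


# ---------------------------------------------------------------------------
# alignment-level precision / recall


def _end_key(a: Alignment) -> tuple:
    return (a.chrom, a.start, a.junction_points())


def pair_up(alignments: Sequence[Alignment]) -> list[tuple[Alignment, Alignment]]:
    """Group paired ends sharing a read name into pairs."""
    groups: dict[str, list[Alignment]] = {}
    for a in alignments:
        if a.paired and a.qname is not None:
            groups.setdefault(a.qname, []).append(a)
    pairs = []
    for group in groups.values():
        if len(group) == 2:
            a, b = sorted(group, key=lambda x: (x.chrom, x.start))
            pairs.append((a, b))
    return pairs


def alignment_pr(
    original: Sequence[Alignment],
    compressed: Sequence[Alignment],
    mode: str = "ends",
) -> tuple[float, float]:
    """Multiset precision/recall of alignment match keys.

    ``ends`` mode matches single ends on (chrom, start, junctions); ``pairs``
    mode matches whole pairs on the combination of both ends' keys.
    """
    if mode == "ends":
        orig_keys = Counter(_end_key(a) for a in original)
        comp_keys = Counter(_end_key(a) for a in compressed)
    elif mode == "pairs":
        orig_keys = Counter(
            (_end_key(a), _end_key(b)) for a, b in pair_up(original)
        )
        comp_keys = Counter(
            (_end_key(a), _end_key(b)) for a, b in pair_up(compressed)
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    matched = sum((orig_keys & comp_keys).values())
    n_orig = sum(orig_keys.values())
    n_comp = sum(comp_keys.values())
    precision = matched / n_comp if n_comp else float("nan")
    recall = matched / n_orig if n_orig else float("nan")
    return precision, recall


def tlen_ratio(original: Tally, compressed: Tally) -> dict[int, float]:
    """Per-distance frequency ratio, compressed over original.

    Distances absent from the original but present in the compressed tally map
    to ``math.inf``.
    """
    if not original and not compressed:
        raise ValueError("both tallies are empty")
    out: dict[int, float] = {}
    for d in sorted(set(original) | set(compressed)):
        o = original.get(d, 0)
        c = compressed.get(d, 0)
        out[d] = (c / o) if o else math.inf
    return out


# ---------------------------------------------------------------------------
# external formats


def _gtf_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for item in text.strip().rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str) -> list[Transcript]:
    """Load transcripts from GTF exon features grouped by ``transcript_id``."""
    exons: dict[str, list[tuple[str, Optional[str], int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            chrom, _, _, start, end, _, strand, _, attr_text = fields[:9]
            attrs = _gtf_attributes(attr_text)
            tid = attrs.get("transcript_id")
            if tid is None:
                continue
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
            exons[tid].append(
                (chrom, strand if strand in "+-" else None, int(start) - 1, int(end))
            )
    out = []
    for tid in order:
        rows = sorted(exons[tid], key=lambda r: r[2])
        chrom, strand = rows[0][0], rows[0][1]
        out.append(
            Transcript(
                id=tid,
                chrom=chrom,
                strand=strand,
                exons=tuple(Exon(s, e) for _, _, s, e in rows),
            )
        )
    return out


def read_coverage_table(path: str) -> dict[str, float]:
    """Two-column (transcript_id, coverage) TSV, '#' comments allowed."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tid, value = line.split("\t")[:2]
            out[tid] = float(value)
    return out
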