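"""Group sorted alignments into gene-scale bundles; classify pairs that do not fit.

A bundle grows while the next alignment starts within ``BUNDLE_GAP`` (50) bases
of the running bundle end, where the running end is the maximal block end seen
so far (spliced reads extend a bundle across their introns). Pairs that fall
outside the normal per-bundle scheme come in four flavors:

* ``intron_nested``  — one end lies entirely inside an intron of the other,
* ``cross_chromosome`` — ends on different chromosomes,
* ``distant``        — same chromosome but resolving to different bundles,
* ``discordant_strand`` — ends carry opposite known strand tags.

The first is split into unpaired reads by default; the middle two are kept
whole in the archive's unbundled section; the last is strand-harmonized by
default (one end, chosen by the seeded RNG, adopts the other's strand).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .alignment_model import Alignment

__all__ = [
    "BUNDLE_GAP",
    "Bundle",
    "UnbundledPair",
    "BundlingResult",
    "build_bundles",
    "prepare_bundles",
    "classify_pair",
    "handle_special_pairs",
    "find_pairs",
]

BUNDLE_GAP = 50

INTRON_NESTED = "intron_nested"
CROSS_CHROMOSOME = "cross_chromosome"
DISTANT = "distant"
DISCORDANT_STRAND = "discordant_strand"


@dataclass
class Bundle:
    chrom: str
    start: int
    end: int
    alignments: list[Alignment]
    index: int
    # junctions contributed by ends later moved to the unbundled section; they
    # must still cut this bundle's partitions so those ends can be expressed
    # as partition subsets
    extra_junctions: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def junction_points(self) -> set[tuple[int, int]]:
        pts: set[tuple[int, int]] = set()
        for a in self.alignments:
            pts.update(a.junction_points())
        pts.update(self.extra_junctions)
        return pts


@dataclass
class UnbundledPair:
    left: Alignment
    right: Alignment
    category: str
    bundle_indices: tuple[int, int]


@dataclass
class BundlingResult:
    bundles: list[Bundle]
    unbundled: list[UnbundledPair]
    pairs: list[tuple[Alignment, Alignment]]  # ordinary pairs, both ends bundled


def _raw_bundles(alignments: Sequence[Alignment]) -> list[Bundle]:
    bundles: list[Bundle] = []
    cur: Optional[Bundle] = None
    for a in alignments:
        if cur is not None and a.chrom == cur.chrom and a.start <= cur.end + BUNDLE_GAP:
            cur.alignments.append(a)
            if a.end > cur.end:
                cur.end = a.end
        else:
            cur = Bundle(a.chrom, a.start, a.end, [a], index=len(bundles))
            bundles.append(cur)
    return bundles


def find_pairs(alignments: Sequence[Alignment]) -> list[tuple[Alignment, Alignment]]:
    """Link paired ends by read name and mutual mate coordinates.

    Ends whose mate record is absent from the input (e.g. filtered upstream)
    are demoted to unpaired.
    """
    groups: dict[str, list[Alignment]] = {}
    for a in alignments:
        if a.paired and a.qname is not None:
            groups.setdefault(a.qname, []).append(a)
    pairs: list[tuple[Alignment, Alignment]] = []
    for group in groups.values():
        remaining = list(group)
        while remaining:
            a = remaining.pop(0)
            mate_idx = None
            for j, b in enumerate(remaining):
                if (
                    a.mate_chrom == b.chrom
                    and a.mate_start == b.start
                    and b.mate_chrom == a.chrom
                    and b.mate_start == a.start
                ):
                    mate_idx = j
                    break
            if mate_idx is None:
                a.paired = False
                a.mate_chrom = a.mate_start = None
                a.tlen = 0
            else:
                b = remaining.pop(mate_idx)
                pairs.append((a, b) if (a.chrom, a.start) <= (b.chrom, b.start) else (b, a))
    return pairs


def classify_pair(
    a: Alignment, b: Alignment, bundle_of: dict[int, int]
) -> Optional[str]:
    """Return the unbundled category of a pair, or ``None`` for ordinary pairs."""
    if a.chrom == b.chrom:
        for outer, inner in ((a, b), (b, a)):
            for donor, acceptor in outer.junction_points():
                if donor <= inner.start and inner.end <= acceptor:
                    return INTRON_NESTED
    if a.chrom != b.chrom:
        return CROSS_CHROMOSOME
    if bundle_of[id(a)] != bundle_of[id(b)]:
        return DISTANT
    if a.strand is not None and b.strand is not None and a.strand != b.strand:
        return DISCORDANT_STRAND
    return None


def _unpair(a: Alignment) -> None:
    a.paired = False
    a.mate_chrom = None
    a.mate_start = None
    a.tlen = 0


def handle_special_pairs(
    classified: list[tuple[Alignment, Alignment, Optional[str]]],
    bundles: list[Bundle],
    bundle_of: dict[int, int],
    *,
    preserve_nested: bool = False,
    split_discordant: bool = False,
    rng: Optional[random.Random] = None,
) -> tuple[list[UnbundledPair], list[tuple[Alignment, Alignment]]]:
    """Apply the per-category policies; return (unbundled pairs, ordinary pairs).

    Cross-chromosome and distant pairs are pulled out of their bundles (their
    junctions remain as partition cuts); nested and discordant pairs are either
    split into unpaired reads or kept, per the options.
    """
    rng = rng or random.Random(0)
    unbundled: list[UnbundledPair] = []
    ordinary: list[tuple[Alignment, Alignment]] = []
    to_remove: set[int] = set()
    for a, b, cat in classified:
        if cat is None:
            ordinary.append((a, b))
        elif cat == INTRON_NESTED:
            if preserve_nested:
                ordinary.append((a, b))
            else:
                _unpair(a)
                _unpair(b)
        elif cat == DISCORDANT_STRAND:
            if split_discordant:
                _unpair(a)
                _unpair(b)
            else:
                if rng.random() < 0.5:
                    a.strand = b.strand
                else:
                    b.strand = a.strand
                ordinary.append((a, b))
        else:  # CROSS_CHROMOSOME or DISTANT
            bi, bj = bundle_of[id(a)], bundle_of[id(b)]
            unbundled.append(UnbundledPair(a, b, cat, (bi, bj)))
            to_remove.add(id(a))
            to_remove.add(id(b))
            bundles[bi].extra_junctions.extend(a.junction_points())
            bundles[bj].extra_junctions.extend(b.junction_points())
    if to_remove:
        for bundle in bundles:
            bundle.alignments = [x for x in bundle.alignments if id(x) not in to_remove]
    return unbundled, ordinary


def prepare_bundles(
    alignments: Sequence[Alignment],
    *,
    preserve_nested: bool = False,
    split_discordant: bool = False,
    rng: Optional[random.Random] = None,
) -> BundlingResult:
    """Full bundling pipeline: bundle, pair, classify, route."""
    bundles = _raw_bundles(alignments)
    bundle_of = {id(a): b.index for b in bundles for a in b.alignments}
    pairs = find_pairs(alignments)
    classified = [(a, b, classify_pair(a, b, bundle_of)) for a, b in pairs]
    unbundled, ordinary = handle_special_pairs(
        classified,
        bundles,
        bundle_of,
        preserve_nested=preserve_nested,
        split_discordant=split_discordant,
        rng=rng,
    )
    return BundlingResult(bundles=bundles, unbundled=unbundled, pairs=ordinary)


def build_bundles(
    alignments: Sequence[Alignment],
    *,
    preserve_nested: bool = False,
    split_discordant: bool = False,
    rng: Optional[random.Random] = None,
) -> tuple[list[Bundle], list[UnbundledPair]]:
    """Spec-surface wrapper around :func:`prepare_bundles`."""
    res = prepare_bundles(
        alignments,
        preserve_nested=preserve_nested,
        split_discordant=split_discordant,
        rng=rng,
    )
    return res.bundles, res.unbundled
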