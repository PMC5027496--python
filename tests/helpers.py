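"""Independent oracles for the test suite.

Everything here is deliberately brute-force and kept free of the package's
own greedy/DP code paths so it can certify them.
"""

from __future__ import annotations

import numpy as np

from boilerplate.alignment_model import Alignment
from boilerplate.fidelity import Exon, Transcript, exon_score


def make_alignment(chrom, blocks, **kw):
    return Alignment(chrom=chrom, blocks=tuple(blocks), **kw)


def brute_pileup(alignments, chrom, length):
    """Per-base coverage computed directly from alignment blocks."""
    out = np.zeros(length, dtype=np.int64)
    for a in alignments:
        if a.chrom != chrom:
            continue
        for s, e in a.blocks:
            out[s:e] += 1
    return out


def induced_coverage(reads, length):
    out = np.zeros(length, dtype=np.int64)
    for r in reads:
        out[r.start : r.end] += 1
    return out


def max_recoverable_length(cov, tally):
    """Exhaustive optimum of the read recovery problem.

    Maximize the total length of placed reads whose lengths are drawn from
    ``tally`` and whose induced coverage never exceeds ``cov``. Exact search
    over canonical placements (reads in nondecreasing start order, each
    starting at the current leftmost position with unconsumed coverage),
    memoized on (position, local coverage window, remaining counts): reads
    are at most ``max(tally)`` long, so coverage further right is untouched.
    """
    import sys

    cov = [int(x) for x in cov]
    n = len(cov)
    if not tally or n == 0:
        return 0
    lengths = sorted(tally)
    maxlen = lengths[-1]
    counts = [tally[l] for l in lengths]
    memo: dict = {}
    sys.setrecursionlimit(20000)
    ceiling = min(sum(l * c for l, c in tally.items()), sum(cov))
    found = 0

    class _Done(Exception):
        pass

    def rec(pos, placed):
        nonlocal found
        if placed > found:
            found = placed
            if found >= ceiling:
                raise _Done
        while pos < n and cov[pos] == 0:
            pos += 1
        if pos >= n or not any(counts):
            return 0
        key = (pos, tuple(cov[pos : pos + maxlen]), tuple(counts))
        if key in memo:
            return memo[key]
        best = 0
        for li in range(len(lengths) - 1, -1, -1):  # longest first
            l = lengths[li]
            if counts[li] == 0 or pos + l > n:
                continue
            if min(cov[pos : pos + l]) < 1:
                continue
            for i in range(pos, pos + l):
                cov[i] -= 1
            counts[li] -= 1
            best = max(best, l + rec(pos, placed + l))
            counts[li] += 1
            for i in range(pos, pos + l):
                cov[i] += 1
        # no (further) read starts at pos -> its coverage is unconsumable
        saved = cov[pos]
        cov[pos] = 0
        best = max(best, rec(pos + 1, placed))
        cov[pos] = saved
        memo[key] = best
        return best

    try:
        return rec(0, 0)
    except _Done:
        return found


def enumerate_exact_solutions(cov, tally):
    """All multisets of intervals that consume the tally fully and reproduce
    ``cov`` exactly. Only usable on tiny instances."""
    cov = list(int(x) for x in cov)
    n = len(cov)
    solutions = set()
    placed: list[tuple[int, int]] = []

    def dfs(pos, remaining):
        while pos < n and cov[pos] == 0:
            pos += 1
        if pos >= n:
            if not remaining:
                solutions.add(tuple(sorted(placed)))
            return
        for l in sorted(remaining):
            if pos + l > n or min(cov[pos : pos + l]) < 1:
                continue
            for i in range(pos, pos + l):
                cov[i] -= 1
            remaining[l] -= 1
            if remaining[l] == 0:
                del remaining[l]
            placed.append((pos, pos + l))
            dfs(pos, remaining)
            placed.pop()
            remaining[l] = remaining.get(l, 0) + 1
            for i in range(pos, pos + l):
                cov[i] += 1

    dfs(0, {k: v for k, v in tally.items()})
    return solutions


def brute_transcript_score(t: Transcript, t_hat: Transcript, k: int = 10) -> float:
    """Best monotone one-to-one exon matching by full enumeration."""
    if t.chrom != t_hat.chrom:
        return 0.0
    if t.strand is not None and t_hat.strand is not None and t.strand != t_hat.strand:
        return 0.0
    n, m = len(t.exons), len(t_hat.exons)
    if n == 0 or m == 0:
        return 0.0
    best = 0.0

    def rec(i, j, acc):
        nonlocal best
        if acc > best:
            best = acc
        if i >= n or j >= m:
            return
        rec(i + 1, j + 1, acc + exon_score(t.exons[i], t_hat.exons[j], k))
        rec(i + 1, j, acc)
        rec(i, j + 1, acc)

    rec(0, 0, 0.0)
    return best / max(n, m)


def random_feasible_bucket(rng, max_reads=12, max_lengths=3, min_len=5, max_len=20):
    """A coverage vector + tally generated from actual reads, so a perfect
    solution exists; returns (cov array, tally dict)."""
    n_lengths = rng.randint(1, max_lengths)
    lengths = rng.sample(range(min_len, max_len + 1), n_lengths)
    n_reads = rng.randint(1, max_reads)
    span = max_len * 6
    reads = []
    for _ in range(n_reads):
        l = rng.choice(lengths)
        s = rng.randint(0, span - l)
        reads.append((s, s + l))
    cov = np.zeros(span, dtype=np.int64)
    tally: dict[int, int] = {}
    for s, e in reads:
        cov[s:e] += 1
        tally[e - s] = tally.get(e - s, 0) + 1
    return cov, tally
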