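"""Seed-chain-extend local nucleotide matching.

Exact k-mer seeds shared between two sequences are chained within
diagonal bands; inter-anchor gaps are aligned by edit-distance dynamic
programming (edlib, NW mode).  Each chain yields a MatchBlock carrying
the matched/aligned column counts from which ANI, aligned fraction and
shared-region identity are computed.  Flanks beyond the outermost
anchors are not extended, so blocks stay local: a prophage embedded in
a host chromosome is reported as one block covering (almost exactly)
the provirus, not dragged into the flanking host sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .io_formats import revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class MatchBlock:
    """One chained local match between sequence a and sequence b.

    Coordinates are 0-based half-open on the forward strand of each
    sequence; ``strand`` is the strand of b that matched.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    matches: int
    columns: int
    strand: str

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def length(self) -> int:
        return self.columns


def _cigar_counts(cigar: str) -> tuple[int, int]:
    """(matches, columns) from an edlib extended CIGAR."""
    matches = columns = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def _anchors(a: str, b: str, k: int, max_occ: int = 50) -> list[tuple[int, int]]:
    """Positions (i, j) of exact shared k-mers; repetitive seeds capped."""
    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        index.setdefault(a[i : i + k], []).append(i)
    out: list[tuple[int, int]] = []
    for j in range(len(b) - k + 1):
        hits = index.get(b[j : j + k])
        if hits and len(hits) <= max_occ:
            for i in hits:
                out.append((i, j))
    return out


def _chain_anchors(
    anchors: list[tuple[int, int]], k: int, band: int, merge_gap: int
) -> list[list[tuple[int, int]]]:
    """Greedy colinear chaining of anchors grouped by diagonal band."""
    by_band: dict[int, list[tuple[int, int]]] = {}
    for i, j in anchors:
        by_band.setdefault((i - j) // band, []).append((i, j))
    chains: list[list[tuple[int, int]]] = []
    for band_anchors in by_band.values():
        band_anchors.sort()
        current: list[tuple[int, int]] = []
        for i, j in band_anchors:
            if not current:
                current = [(i, j)]
                continue
            pi, pj = current[-1]
            if j > pj and i - (pi + k) <= merge_gap and j - (pj + k) <= merge_gap:
                current.append((i, j))
            elif i - (pi + k) > merge_gap:
                chains.append(current)
                current = [(i, j)]
            # else: anchor out of colinear order within the band; drop it
        if current:
            chains.append(current)
    return chains


def _score_chain(
    a: str, b: str, chain: list[tuple[int, int]], k: int
) -> tuple[int, int, int, int, int, int]:
    """Exact runs + edlib gap fills -> (a0, a1, b0, b1, matches, columns)."""
    # merge same-diagonal overlapping anchors into maximal exact runs
    runs: list[list[int]] = []  # [i, j, length]
    for i, j in chain:
        if runs and i - j == runs[-1][0] - runs[-1][1] and i <= runs[-1][0] + runs[-1][2]:
            runs[-1][2] = max(runs[-1][2], i + k - runs[-1][0])
        elif runs and (i < runs[-1][0] + runs[-1][2] or j < runs[-1][1] + runs[-1][2]):
            continue  # off-diagonal anchor shadowed by the previous run
        else:
            runs.append([i, j, k])
    matches = columns = 0
    for idx, (i, j, length) in enumerate(runs):
        matches += length
        columns += length
        if idx + 1 < len(runs):
            ni, nj, _ = runs[idx + 1]
            ga = a[i + length : ni]
            gb = b[j + length : nj]
            if ga and gb:
                res = edlib.align(ga, gb, mode="NW", task="path")
                m, c = _cigar_counts(res["cigar"])
                matches += m
                columns += c
            else:
                columns += max(len(ga), len(gb))
    a0, b0 = runs[0][0], runs[0][1]
    a1 = runs[-1][0] + runs[-1][2]
    b1 = runs[-1][1] + runs[-1][2]
    return a0, a1, b0, b1, matches, columns


def local_matches(
    a: str,
    b: str,
    k: int = 15,
    band: int = 32,
    merge_gap: int = 100,
    min_columns: int = 0,
) -> list[MatchBlock]:
    """All chained local matches between a and b, both strands of b."""
    blocks: list[MatchBlock] = []
    for strand, bseq in (("+", b), ("-", revcomp(b))):
        anchors = _anchors(a, bseq, k)
        for chain in _chain_anchors(anchors, k, band, merge_gap):
            a0, a1, b0, b1, m, c = _score_chain(a, bseq, chain, k)
            if c < max(min_columns, k):
                continue
            if strand == "-":
                b0, b1 = len(b) - b1, len(b) - b0
            blocks.append(MatchBlock(a0, a1, b0, b1, m, c, strand))
    return blocks


def select_blocks(blocks: list[MatchBlock], max_overlap: float = 0.5) -> list[MatchBlock]:
    """Greedy non-redundant block subset, longest first, by a-axis overlap."""
    chosen: list[MatchBlock] = []
    for blk in sorted(blocks, key=lambda x: (-x.columns, x.a_start, x.b_start)):
        span = blk.a_end - blk.a_start
        overlap = 0
        for kept in chosen:
            lo = max(blk.a_start, kept.a_start)
            hi = min(blk.a_end, kept.a_end)
            overlap += max(0, hi - lo)
        if span == 0 or overlap / span <= max_overlap:
            chosen.append(blk)
    return chosen


def union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    total += cur_hi - cur_lo
    return total
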