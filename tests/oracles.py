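"""Independent brute-force oracles used to verify the implementation.

Each oracle re-derives its quantity from first principles by a route
deliberately different from the package's own (pure-Python loops, exact
integer arithmetic, explicit reference walks), so agreement is evidence
of correctness rather than of shared code.
"""

from __future__ import annotations

import math
import re


def greedy_collapse_oracle(counts: dict, window: int, min_reads: int) -> list:
    """Literal greedy peak collapsing on a plain dict, one step at a time."""
    remaining = dict(counts)
    kept = []
    while remaining:
        # highest count first, smallest (chrom, strand, position) on ties
        peak = min(remaining, key=lambda k: (-remaining[k], k))
        chrom, strand, pos = peak
        absorbed = [
            key for key in remaining
            if key[0] == chrom and key[1] == strand and abs(key[2] - pos) <= window
        ]
        total = sum(remaining[key] for key in absorbed)
        for key in absorbed:
            del remaining[key]
        if total >= min_reads:
            kept.append((chrom, strand, pos, total))
    kept.sort()
    return kept


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")


def cigar_reference_span(cigar: str) -> int:
    """Reference bases consumed by a CIGAR string, by explicit walk."""
    span = 0
    for length, op in _CIGAR_RE.findall(cigar):
        if op in _REF_CONSUMING:
            span += int(length)
    return span


def fisher_tail_exact(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p for [[a, b], [c, d]], exactly.

    Enumerates every table with the observed margins and at least ``a``
    in the top-left cell, summing hypergeometric probabilities with
    integer arithmetic before a single final division.
    """
    row1, row2, col1 = a + b, c + d, a + c
    n_total = row1 + row2
    numerator = 0
    for k in range(a, min(row1, col1) + 1):
        if col1 - k > row2:
            continue
        numerator += math.comb(row1, k) * math.comb(row2, col1 - k)
    return numerator / math.comb(n_total, col1)


def lof_bruteforce(points, k: int, lrd_floor: float = 1e-10) -> list[float]:
    """Local Outlier Factor by direct per-point loops over the definition.

    k-distance of p = distance to the k-th nearest other point; the
    neighbourhood holds every other point within that distance (ties
    included).  reach(p, o) = max(kdist(o), d(p, o)); lrd(p) = inverse
    mean reach over the neighbourhood (floored); LOF(p) = mean
    lrd(o)/lrd(p) over the neighbourhood.
    """
    n = len(points)
    dist = [[math.dist(points[i], points[j]) for j in range(n)] for i in range(n)]
    kdist = []
    neighborhoods = []
    for p in range(n):
        others = sorted(dist[p][q] for q in range(n) if q != p)
        kd = others[k - 1]
        kdist.append(kd)
        neighborhoods.append([q for q in range(n) if q != p and dist[p][q] <= kd])
    lrd = []
    for p in range(n):
        reach = [max(kdist[o], dist[p][o]) for o in neighborhoods[p]]
        lrd.append(1.0 / max(sum(reach) / len(reach), lrd_floor))
    return [
        sum(lrd[o] for o in neighborhoods[p]) / len(neighborhoods[p]) / lrd[p]
        for p in range(n)
    ]


def region_membership_oracle(gene, position: int) -> str:
    """Base-by-base classification of a position against a gene model."""
    in_exon = any(s <= position <= e for s, e in gene.exon_union)
    in_intron = any(s <= position <= e for s, e in gene.introns)
    in_span = gene.span[0] <= position <= gene.span[1]
    assert in_exon + in_intron == (1 if in_span else 0), "sub-regions must partition the span"
    if in_exon:
        return "exon"
    if in_intron:
        return "intron"
    return "outside"
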