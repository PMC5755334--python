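"""Independent oracles used by the test suite.

These re-derive expected results by brute force (position-wise coverage
arrays, combinatorial enumeration, hand-coded step-up rules) and share no
logic with the library's interval-arithmetic implementation.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def brute_force_pair_events(a, b):
    """All (type, region) events between two transcripts, via coverage arrays.

    The common span is rasterized into per-position exonic flags; variable
    regions are maximal runs not exonic in both transcripts, and the type is
    read off the pattern of exonic runs inside the region:

    * one transcript fully exonic, the other fully intronic -> IR
    * one fully intronic, the other with a single exonic island strictly
      inside the region -> ES
    * one fully intronic, the other with a single exonic run touching one
      region edge -> AD/AA depending on which edge and the strand
    * anything else -> COMPLEX
    """
    span = (max(a.start, b.start), min(a.end, b.end))
    if span[1] <= span[0]:
        return []
    n = span[1] - span[0]

    def coverage(t):
        arr = np.zeros(n, dtype=bool)
        for s, e in t.exons:
            s2, e2 = max(s, span[0]), min(e, span[1])
            if e2 > s2:
                arr[s2 - span[0] : e2 - span[0]] = True
        return arr

    cov_a, cov_b = coverage(a), coverage(b)
    non_common = ~(cov_a & cov_b)

    def runs(mask):
        out = []
        i, m = 0, len(mask)
        while i < m:
            if mask[i]:
                j = i
                while j < m and mask[j]:
                    j += 1
                out.append((i, j))
                i = j
            else:
                i += 1
        return out

    events = []
    for rs, re_ in runs(non_common):
        region = (rs + span[0], re_ + span[0])
        # terminal difference: an intron of either transcript overlapping the
        # region sticks out of the common span
        skip = False
        for t in (a, b):
            for s, e in t.introns:
                if e > region[0] and s < region[1] and (s < span[0] or e > span[1]):
                    skip = True
        if skip:
            continue
        ra = runs(cov_a[rs:re_])
        rb = runs(cov_b[rs:re_])
        if not ra and not rb:
            continue  # both intronic with identical boundaries: chains agree
        events.append((_classify_runs(ra, rb, re_ - rs, a.strand), region))
    return events


def _classify_runs(ra, rb, length, strand):
    def full(rr):
        return len(rr) == 1 and rr[0] == (0, length)

    def empty(rr):
        return len(rr) == 0

    for one, other in ((ra, rb), (rb, ra)):
        if full(one) and empty(other):
            return "IR"
        if empty(other) and len(one) == 1:
            s, e = one[0]
            if 0 < s and e < length:
                return "ES"
            if s == 0 and e < length:  # island touches genomic-left edge
                return "AD" if strand == "+" else "AA"
            if s > 0 and e == length:  # touches genomic-right edge
                return "AA" if strand == "+" else "AD"
    return "COMPLEX"


def hypergeom_tail_greater(table):
    """One-tailed (enrichment) Fisher p by direct hypergeometric summation."""
    (a, b), (c, d) = table
    r1, c1, ntot = a + b, a + c, a + b + c + d

    def pmf(k):
        return (
            math.comb(c1, k)
            * math.comb(ntot - c1, r1 - k)
            / math.comb(ntot, r1)
        )

    kmin, kmax = max(0, r1 + c1 - ntot), min(r1, c1)
    return sum(pmf(k) for k in range(a, kmax + 1)), pmf, (kmin, kmax)


def mwu_exact_enumeration(x, y, alternative):
    """Exact Mann-Whitney p by enumerating all rank assignments (tie-free)."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle needs tie-free data"
    n1, n2 = len(x), len(y)

    def u_of(first_idx):
        ranks = [i + 1 for i in sorted(first_idx)]
        r1 = sum(ranks)
        return r1 - n1 * (n1 + 1) / 2

    obs_idx = [pooled.index(v) for v in x]
    u_obs = u_of(obs_idx)
    us = [u_of(c) for c in combinations(range(n1 + n2), n1)]
    total = len(us)
    if alternative == "less":
        return sum(1 for u in us if u <= u_obs) / total
    if alternative == "greater":
        return sum(1 for u in us if u >= u_obs) / total
    lo = sum(1 for u in us if u <= u_obs) / total
    hi = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2 * min(lo, hi))


def bh_stepup(pvals):
    """Hand-coded Benjamini-Hochberg step-up adjustment."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj
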