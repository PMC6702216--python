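"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or base-level
bookkeeping, staying independent of the implementation path it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from itrpred.regions import GenomicInterval


def merge_by_components(intervals: list[GenomicInterval]) -> list[tuple[str, int, int]]:
    """Connected components of the >=1-shared-base overlap graph, via an
    explicit adjacency search."""
    n = len(intervals)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    out = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            k = stack.pop()
            comp.append(k)
            for m in adj[k]:
                if not seen[m]:
                    seen[m] = True
                    stack.append(m)
        out.append(
            (
                intervals[i].chrom,
                min(intervals[k].start for k in comp),
                max(intervals[k].end for k in comp),
            )
        )
    return sorted(out)


def classify_base_by_base(
    region: GenomicInterval,
    exon_bases: set[tuple[str, int]],
    intron_bases: set[tuple[str, int]],
    pseudo_bases: set[tuple[str, int]],
) -> str:
    """Priority classification by checking every base of the region."""
    bases = {(region.chrom, p) for p in range(region.start, region.end)}
    if bases & exon_bases:
        return "exon"
    if bases & intron_bases:
        return "intron"
    if bases & pseudo_bases:
        return "pseudogene"
    return "intergenic"


def f1_at_threshold(pos: list[int], neg: list[int], t: int) -> float:
    tp = sum(1 for x in pos if x >= t)
    fp = sum(1 for x in neg if x >= t)
    fn = len(pos) - tp
    return 0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn)


def f1_threshold_exhaustive(pos: list[int], neg: list[int]) -> tuple[int, float]:
    """Best >=t threshold by scanning every integer between the extremes;
    returns (threshold, F1)."""
    lo = min(pos + neg)
    hi = max(pos + neg) + 1
    best_t, best_f1 = lo, -1.0
    for t in range(lo, hi + 1):
        f1 = f1_at_threshold(pos, neg, t)
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return best_t, best_f1


def expected_commonality_uniform(b1: int, b2: int, n_tissues: int = 5) -> float:
    """Exact expected % commonality for uniform random tissue sets of sizes
    b1 and b2, by enumerating every subset pair."""
    universe = list(range(n_tissues))
    total = 0.0
    count = 0
    for a in combinations(universe, b1):
        for b in combinations(universe, b2):
            sa, sb = set(a), set(b)
            total += 100.0 * len(sa & sb) / len(sa | sb)
            count += 1
    return total / count


def auc_by_pair_counting(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the probability a positive outranks a negative (ties 0.5)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
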