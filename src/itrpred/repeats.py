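"""Protein-coding and repetitive flagging of transcribed regions.

A transcribed region is called likely protein-coding when it carries a known
protein domain or a significant translated match to a plant protein.  It is
called highly repetitive when it carries a protein domain enriched among
interspersed repeats, or when its within-species duplicate count reaches a
threshold chosen by F-measure maximization against benchmark repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SimilarityEvidence",
    "call_protein_coding",
    "repeat_domain_enrichment",
    "duplicate_count_threshold",
    "call_repetitive",
]


@dataclass(frozen=True)
class SimilarityEvidence:
    """Similarity evidence for one region: best translated-protein E-value,
    protein/RNA domain content, and within-species duplicate count."""

    region_id: str
    protein_evalue: float | None = None
    protein_domains: frozenset = frozenset()
    rna_domains: frozenset = frozenset()
    duplicate_count: int = 0

    def __post_init__(self) -> None:
        if self.protein_evalue is not None and not (0 <= self.protein_evalue <= 1):
            raise ValueError("E-value must lie in [0, 1]")
        if self.duplicate_count < 0:
            raise ValueError("duplicate_count must be non-negative")
        object.__setattr__(self, "protein_domains", frozenset(self.protein_domains))
        object.__setattr__(self, "rna_domains", frozenset(self.rna_domains))


def call_protein_coding(
    evidence: SimilarityEvidence, e_cutoff: float = 1e-5
) -> bool:
    """Likely protein-coding: any protein domain in a translated frame, or a
    translated protein match with E-value below the cutoff."""
    if evidence.protein_domains:
        return True
    return evidence.protein_evalue is not None and evidence.protein_evalue < e_cutoff


def repeat_domain_enrichment(
    domain_counts_in_repeats: Mapping[str, int],
    n_repeats: int,
    domain_counts_in_exon_trs: Mapping[str, int],
    n_exon_trs: int,
    fdr: float = 0.05,
) -> set[str]:
    """Protein domains enriched among benchmark interspersed repeats relative
    to exon transcribed regions.

    One-sided (greater in repeats) Fisher's exact test per domain,
    Benjamini-Hochberg adjusted across every domain observed in either group;
    returns domains with adjusted p < ``fdr``.
    """
    if n_repeats <= 0 or n_exon_trs <= 0:
        raise ValueError("group sizes must be positive")
    domains = sorted(set(domain_counts_in_repeats) | set(domain_counts_in_exon_trs))
    if not domains:
        return set()
    pvalues = []
    for d in domains:
        a = domain_counts_in_repeats.get(d, 0)
        b = domain_counts_in_exon_trs.get(d, 0)
        if a > n_repeats or b > n_exon_trs:
            raise ValueError(f"domain {d} count exceeds group size")
        table = [[a, n_repeats - a], [b, n_exon_trs - b]]
        pvalues.append(fisher_exact(table, alternative="greater")[1])
    reject = multipletests(pvalues, alpha=fdr, method="fdr_bh")[1] < fdr
    return {d for d, r in zip(domains, reject) if r}


def duplicate_count_threshold(
    pos_counts: Sequence[int], neg_counts: Sequence[int]
) -> int:
    """Duplicate-count threshold maximizing F1 of "repetitive iff count >= t".

    Positives are benchmark repeats (long terminal repeats in the original
    analysis), negatives exon transcribed regions.  All distinct observed
    counts plus max+1 are scanned; ties break toward the smallest threshold.
    """
    if not pos_counts or not neg_counts:
        raise ValueError("both count lists must be non-empty")
    pos = np.asarray(pos_counts)
    neg = np.asarray(neg_counts)
    candidates = sorted(set(pos.tolist()) | set(neg.tolist()))
    candidates.append(max(candidates) + 1)
    best_t, best_f1 = candidates[0], -1.0
    for t in candidates:
        tp = int((pos >= t).sum())
        fp = int((neg >= t).sum())
        fn = len(pos) - tp
        f1 = 0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn)
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return int(best_t)


def call_repetitive(
    evidence: SimilarityEvidence,
    enriched_domains: set[str],
    threshold: int,
) -> bool:
    """Highly repetitive: carries a repeat-enriched protein domain, or has a
    duplicate count at or above the F-measure-optimized threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if evidence.protein_domains & set(enriched_domains):
        return True
    return evidence.duplicate_count >= threshold
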