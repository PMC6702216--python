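"""Syntenic-block dating and syntenic duplicate/ortholog identification.

Syntenic blocks arrive as ordered anchor-gene pairs with per-anchor
synonymous substitution rates (Ks).  A block's median Ks dates it: blocks at
or above 0.7 derive from the ancient rho/sigma whole-genome duplications
shared by the grasses, while maize blocks below 0.7 derive from the ~12 MYA
maize-lineage WGD.  Genic transcribed regions find their syntenic partner
through the anchor gene that contains them; intergenic regions through the
interval circumscribed by the flanking anchor pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import MatchRecord, best_match
from .regions import GenomicInterval

__all__ = [
    "AnchorPair",
    "SyntenicBlock",
    "assign_wgd",
    "syntenic_match",
    "retention_summary",
    "RetentionSummary",
]

KS_WGD_BOUNDARY = 0.7


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    interval_a: GenomicInterval
    gene_b: str
    interval_b: GenomicInterval
    ks: float

    def __post_init__(self) -> None:
        if self.ks < 0:
            raise ValueError("Ks must be >= 0")


@dataclass(frozen=True)
class SyntenicBlock:
    """An ordered run of collinear anchor-gene pairs between two genomes
    (within- or cross-species)."""

    block_id: str
    species_a: str
    species_b: str
    anchors: tuple[AnchorPair, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchors", tuple(self.anchors))
        if not self.anchors:
            raise ValueError("block must contain at least one anchor pair")
        starts_a = [a.interval_a.start for a in self.anchors]
        if starts_a != sorted(starts_a):
            raise ValueError("anchors must be ordered along genome A")
        starts_b = [a.interval_b.start for a in self.anchors]
        asc = starts_b == sorted(starts_b)
        desc = starts_b == sorted(starts_b, reverse=True)
        if not (asc or desc):
            raise ValueError("anchor positions must be monotonic along genome B")

    @property
    def median_ks(self) -> float:
        return float(np.median([a.ks for a in self.anchors]))

    @property
    def span_a(self) -> GenomicInterval:
        return GenomicInterval(
            self.anchors[0].interval_a.chrom,
            self.anchors[0].interval_a.start,
            self.anchors[-1].interval_a.end,
        )


def assign_wgd(block: SyntenicBlock, species: str) -> str:
    """Date a within-species block by its median anchor Ks.

    median Ks >= 0.7 -> ``rho_sigma`` (ancient shared WGDs); maize blocks
    below 0.7 -> ``maize_wgd``; blocks below 0.7 in other species lack a
    WGD assignment (``none``) and are excluded from WGD summaries.
    """
    if not block.anchors:
        raise ValueError("block has no anchor Ks values")
    med = block.median_ks
    if med >= KS_WGD_BOUNDARY:
        return "rho_sigma"
    if species == "maize":
        return "maize_wgd"
    return "none"


def _flanking_gap(
    block: SyntenicBlock, region: GenomicInterval
) -> tuple[int, int] | None:
    """Index of the anchor pair (i, i+1) whose inter-anchor interval on
    genome A holds the majority of the region's bases; ties break upstream."""
    best = None
    for i in range(len(block.anchors) - 1):
        gap_start = block.anchors[i].interval_a.end
        gap_end = block.anchors[i + 1].interval_a.start
        if gap_start >= gap_end:
            continue
        overlap = min(region.end, gap_end) - max(region.start, gap_start)
        if overlap > 0 and (best is None or overlap > best[1]):
            best = (i, overlap)
    if best is None:
        return None
    return best[0], best[0] + 1


def syntenic_match(
    region: GenomicInterval,
    region_class: str,
    block: SyntenicBlock,
    matches: Sequence[MatchRecord],
) -> MatchRecord | None:
    """Syntenic duplicate/ortholog of a region within a block.

    Exon and intron regions: the best hit overlapping the partner of the
    anchor gene containing the region.  Intergenic regions (ITRs and random
    intergenic sequences): the best hit lying strictly within the genome-B
    interval circumscribed by the partners of the flanking anchor pair.
    """
    span = block.span_a
    if region.chrom != span.chrom or not span.overlaps(region):
        raise ValueError(f"region {region} outside block {block.block_id} span")
    if region_class in ("exon", "intron"):
        host = None
        for anchor in block.anchors:
            if region.overlaps(anchor.interval_a):
                host = anchor
                break
        if host is None:
            return None
        pool = [
            m
            for m in matches
            if m.subject_interval.overlaps(host.interval_b)
        ]
        return best_match(pool)
    # intergenic: circumscribed interval between flanking anchor partners
    gap = _flanking_gap(block, region)
    if gap is None:
        return None
    i, j = gap
    b1 = block.anchors[i].interval_b
    b2 = block.anchors[j].interval_b
    if b1.chrom != b2.chrom:
        return None
    left, right = (b1, b2) if b1.start <= b2.start else (b2, b1)
    if left.end >= right.start:
        return None
    pool = [
        m
        for m in matches
        if m.subject_chrom == left.chrom
        and m.subject_start >= left.end
        and m.subject_end <= right.start
    ]
    return best_match(pool)


@dataclass
class RetentionSummary:
    """Per-class syntenic-duplicate retention and expression of partners.

    ``retention``: rows (region_class, wgd_label) with counts and the
    fraction of regions with a syntenic duplicate.  ``expression``: rows
    (region_class, k_bin) with the fraction of duplicates whose partner
    locus is overlapped by a transcribed region.
    """

    retention: pd.DataFrame
    expression: pd.DataFrame


def retention_summary(
    regions: Sequence[tuple[str, GenomicInterval, str]],
    blocks: Sequence[SyntenicBlock],
    matches_by_region: Mapping[str, Sequence[MatchRecord]],
    species: str,
    transcribed_partner: Sequence[GenomicInterval] = (),
    k_bins: Sequence[float] = (0.0, 0.08 / 3, 2 * 0.08 / 3, 0.08),
) -> RetentionSummary:
    """Summarize syntenic duplicate retention and partner expression.

    ``regions`` are (region_id, interval, region_class) triples on genome A;
    each region is assigned to the first block whose span contains it.
    Partner expression asks whether the duplicate's subject interval is
    overlapped by any transcribed region of the partner genome.  K bins
    default to three equal-width bins over the [0, 0.08] range where
    retained duplicates concentrate.
    """
    ret_counts: dict[tuple[str, str], list[int]] = {}
    expr_counts: dict[tuple[str, str], list[int]] = {}
    edges = list(k_bins)
    for region_id, interval, region_class in regions:
        block = None
        for b in blocks:
            if b.span_a.chrom == interval.chrom and b.span_a.overlaps(interval):
                block = b
                break
        if block is None:
            continue
        label = assign_wgd(block, species)
        key = (region_class, label)
        n, n_dup = ret_counts.get(key, [0, 0])
        match = syntenic_match(
            interval, region_class, block, matches_by_region.get(region_id, ())
        )
        ret_counts[key] = [n + 1, n_dup + (1 if match is not None else 0)]
        if match is None or match.k is None:
            continue
        for lo, hi in zip(edges, edges[1:]):
            if lo <= match.k < hi or (hi == edges[-1] and match.k == hi):
                bin_label = f"[{lo:.4g},{hi:.4g})"
                expressed = any(
                    t.overlaps(match.subject_interval) for t in transcribed_partner
                )
                nd, ne = expr_counts.get((region_class, bin_label), [0, 0])
                expr_counts[(region_class, bin_label)] = [
                    nd + 1,
                    ne + (1 if expressed else 0),
                ]
                break
    ret_rows = [
        {
            "region_class": cls,
            "wgd_label": label,
            "n": n,
            "n_duplicated": nd,
            "retention": nd / n if n else float("nan"),
        }
        for (cls, label), (n, nd) in sorted(ret_counts.items())
    ]
    expr_rows = [
        {
            "region_class": cls,
            "k_bin": b,
            "n_duplicates": nd,
            "n_expressed": ne,
            "expressed_fraction": ne / nd if nd else float("nan"),
        }
        for (cls, b), (nd, ne) in sorted(expr_counts.items())
    ]
    return RetentionSummary(
        retention=pd.DataFrame(
            ret_rows,
            columns=["region_class", "wgd_label", "n", "n_duplicated", "retention"],
        ),
        expression=pd.DataFrame(
            expr_rows,
            columns=[
                "region_class",
                "k_bin",
                "n_duplicates",
                "n_expressed",
                "expressed_fraction",
            ],
        ),
    )
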