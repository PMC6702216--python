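"""Genomic interval model: fragment merging, priority classification, and
interval summaries for transcribed-region analysis.

All coordinates are 0-based, half-open ``[start, end)``.  GFF3 input/output
(1-based, inclusive) is converted at the I/O boundary.  Merging and
classification are strand-agnostic: transcript fragments from different
RNA-seq datasets are pooled without regard to strand before being compared
with annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Gene",
    "AnnotationSet",
    "TranscribedRegion",
    "merge_fragments",
    "classify_region",
    "find_unmappable",
    "sample_random_intergenic",
    "nearest_gene_distance",
    "space_coverage",
    "gene_bridging_fraction",
]

REGION_CLASSES = ("exon", "intron", "pseudogene", "intergenic")

_VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Gene:
    """A gene as a sorted chain of pairwise-disjoint exons.

    Introns are derived as the gaps between consecutive exons.
    """

    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"gene {self.gene_id} spans chromosomes {chroms}")
        ordered = tuple(sorted(self.exons, key=lambda e: e.start))
        for a, b in zip(ordered, ordered[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id} has overlapping exons")
        object.__setattr__(self, "exons", ordered)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end < b.start:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)


class AnnotationSet:
    """Gene/pseudogene/unmappable annotation over a set of chromosomes."""

    def __init__(
        self,
        chrom_lengths: Mapping[str, int],
        genes: Sequence[Gene] = (),
        pseudogenes: Sequence[GenomicInterval] = (),
        unmappable: Sequence[GenomicInterval] = (),
    ) -> None:
        self.chrom_lengths = dict(chrom_lengths)
        self.genes = list(genes)
        self.pseudogenes = list(pseudogenes)
        self.unmappable = list(unmappable)
        for gene in self.genes:
            length = self.chrom_lengths.get(gene.chrom)
            if length is None:
                raise ValueError(f"gene {gene.gene_id} on unknown chromosome")
            if gene.span.end > length:
                raise ValueError(f"gene {gene.gene_id} exceeds chromosome bounds")
        for iv in list(self.pseudogenes) + list(self.unmappable):
            length = self.chrom_lengths.get(iv.chrom)
            if length is None or iv.end > length:
                raise ValueError(f"interval {iv} outside chromosome bounds")
        self._exon_trees = _build_trees(
            e for g in self.genes for e in g.exons
        )
        self._intron_trees = _build_trees(
            i for g in self.genes for i in g.introns
        )
        self._pseudo_trees = _build_trees(self.pseudogenes)
        self._unmap_trees = _build_trees(self.unmappable)
        self._gene_span_trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            tree = self._gene_span_trees.setdefault(g.chrom, IntervalTree())
            tree.addi(g.span.start, g.span.end, g)

    # -- overlap helpers -------------------------------------------------
    def _overlaps(self, trees: dict, region: GenomicInterval) -> bool:
        tree = trees.get(region.chrom)
        return bool(tree is not None and tree.overlap(region.start, region.end))

    def overlaps_exon(self, region: GenomicInterval) -> bool:
        return self._overlaps(self._exon_trees, region)

    def overlaps_intron(self, region: GenomicInterval) -> bool:
        return self._overlaps(self._intron_trees, region)

    def overlaps_pseudogene(self, region: GenomicInterval) -> bool:
        return self._overlaps(self._pseudo_trees, region)

    def overlaps_unmappable(self, region: GenomicInterval) -> bool:
        return self._overlaps(self._unmap_trees, region)

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    def genes_overlapping(self, region: GenomicInterval) -> list[Gene]:
        tree = self._gene_span_trees.get(region.chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(region.start, region.end)]

    # -- space arrays ----------------------------------------------------
    def space_labels(self, chrom: str) -> np.ndarray:
        """Per-base space label: 1 exon, 2 intron, 3 pseudogene, 0 intergenic,
        -1 unmappable.  Priority exon > intron > pseudogene; unmappable
        overrides everything (excluded from all mappable space)."""
        n = self.chrom_lengths[chrom]
        labels = np.zeros(n, dtype=np.int8)
        for iv in self.pseudogenes:
            if iv.chrom == chrom:
                labels[iv.start : iv.end] = 3
        for g in self.genes:
            if g.chrom != chrom:
                continue
            for i in g.introns:
                labels[i.start : i.end] = 2
        for g in self.genes:
            if g.chrom != chrom:
                continue
            for e in g.exons:
                labels[e.start : e.end] = 1
        for iv in self.unmappable:
            if iv.chrom == chrom:
                labels[iv.start : iv.end] = -1
        return labels


def _build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


@dataclass
class TranscribedRegion:
    """A merged transcript fragment with class label and expression evidence."""

    interval: GenomicInterval
    region_class: str
    presence: dict[str, bool] = field(default_factory=dict)
    fpkm: dict[str, float] = field(default_factory=dict)
    coding_like: bool = False
    repetitive: bool = False
    region_id: str = ""

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        for dataset, value in self.fpkm.items():
            if value < 0:
                raise ValueError(f"negative FPKM in dataset {dataset}")
        if not self.region_id:
            iv = self.interval
            self.region_id = f"{iv.chrom}:{iv.start}-{iv.end}"

    def fpkm_in(self, dataset: str) -> float:
        """FPKM respecting the presence flag (absent => 0)."""
        if not self.presence.get(dataset, False):
            return 0.0
        return self.fpkm.get(dataset, 0.0)


def merge_fragments(
    fragments: Sequence[GenomicInterval],
    sources: Sequence[str] | None = None,
) -> tuple[list[GenomicInterval], list[set]]:
    """Merge transcript fragments that share at least one base.

    Fragments from all datasets are pooled; any two fragments overlapping by
    >= 1 nucleotide end up in the same merged region.  Bookended half-open
    intervals (``[a,b)``/``[b,c)``) share no base and are NOT merged.

    Returns the merged intervals (sorted, pairwise disjoint per chromosome)
    and, parallel to them, the set of contributing source labels (fragment
    indices when ``sources`` is None).
    """
    if sources is None:
        sources = [str(i) for i in range(len(fragments))]
    if len(sources) != len(fragments):
        raise ValueError("sources must parallel fragments")
    order = sorted(range(len(fragments)), key=lambda i: (fragments[i].chrom, fragments[i].start, fragments[i].end))
    merged: list[GenomicInterval] = []
    provenance: list[set] = []
    for i in order:
        frag = fragments[i]
        if (
            merged
            and merged[-1].chrom == frag.chrom
            and frag.start < merged[-1].end  # >= 1 shared base
        ):
            prev = merged[-1]
            merged[-1] = GenomicInterval(
                prev.chrom, prev.start, max(prev.end, frag.end)
            )
            provenance[-1].add(sources[i])
        else:
            merged.append(GenomicInterval(frag.chrom, frag.start, frag.end))
            provenance.append({sources[i]})
    return merged, provenance


def classify_region(region: GenomicInterval, annotation: AnnotationSet) -> str:
    """Classify a region against annotation: exon > intron > pseudogene >
    intergenic.  A single shared base with an exon suffices for the exon
    call, regardless of additional intron/pseudogene overlap."""
    length = annotation.chrom_lengths.get(region.chrom)
    if length is None:
        raise KeyError(f"unknown chromosome {region.chrom!r}")
    if region.end > length:
        raise ValueError(f"region {region} exceeds chromosome bounds")
    if annotation.overlaps_exon(region):
        return "exon"
    if annotation.overlaps_intron(region):
        return "intron"
    if annotation.overlaps_pseudogene(region):
        return "pseudogene"
    return "intergenic"


_N_RUN = re.compile(r"N{40,}")
_VALID_SEQ = re.compile(r"^[ACGTN]*$")


def find_unmappable(
    sequence: str, chrom: str = "chr", min_run: int = 40
) -> list[GenomicInterval]:
    """Maximal runs of >= ``min_run`` ambiguous nucleotides (Ns).

    Runs of Ns at least as long as the sequencing read length cannot anchor
    a read and are treated as likely-unmappable space.
    """
    seq = sequence.upper()
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    pattern = re.compile("N{%d,}" % min_run) if min_run != 40 else _N_RUN
    return [
        GenomicInterval(chrom, m.start(), m.end()) for m in pattern.finditer(seq)
    ]


def sample_random_intergenic(
    annotation: AnnotationSet,
    lengths: Sequence[int],
    transcribed: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    seed: int,
    max_retries: int = 10_000,
) -> list[GenomicInterval]:
    """Sample random intergenic intervals matched to a length list.

    Rejection sampling with uniform starts: sampled intervals are pairwise
    disjoint, intergenic (outside genes and pseudogenes), outside transcribed
    and likely-unmappable regions.  A post-hoc filter then drops intervals
    containing any ambiguous nucleotide, so the output lengths are a
    sub-multiset of the request.
    """
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    rng = np.random.default_rng(seed)
    allowed: dict[str, np.ndarray] = {}
    for chrom in annotation.chrom_lengths:
        mask = annotation.space_labels(chrom) == 0  # intergenic & mappable
        allowed[chrom] = mask
    for iv in transcribed:
        if iv.chrom in allowed:
            allowed[iv.chrom][iv.start : iv.end] = False
    chroms = sorted(annotation.chrom_lengths)
    weights = np.array([annotation.chrom_lengths[c] for c in chroms], dtype=float)
    if not any(allowed[c].any() for c in chroms):
        raise RuntimeError("no intergenic space available for sampling")
    weights /= weights.sum()
    placed: list[GenomicInterval] = []
    for length in lengths:
        ok = False
        for _ in range(max_retries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            limit = annotation.chrom_lengths[chrom] - length
            if limit < 0:
                continue
            start = int(rng.integers(0, limit + 1))
            if allowed[chrom][start : start + length].all():
                placed.append(GenomicInterval(chrom, start, start + length))
                allowed[chrom][start : start + length] = False
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place a random intergenic interval of length {length}"
            )
    # post-hoc ambiguous-nucleotide filter
    kept = []
    for iv in placed:
        seq = genome[iv.chrom][iv.start : iv.end].upper()
        if "N" not in seq:
            kept.append(iv)
    return kept


def nearest_gene_distance(
    region: GenomicInterval, genes: Sequence[GenomicInterval] | Sequence[Gene]
) -> int:
    """Distance in bases to the nearest gene on the same chromosome.

    0 when overlapping; otherwise the number of bases strictly between the
    closest interval ends.
    """
    spans = [g.span if isinstance(g, Gene) else g for g in genes]
    spans = [s for s in spans if s.chrom == region.chrom]
    if not spans:
        raise ValueError(f"no gene on chromosome {region.chrom}")
    best = None
    for s in spans:
        if region.overlaps(s):
            return 0
        if s.end <= region.start:
            d = region.start - s.end
        else:
            d = s.start - region.end
        best = d if best is None else min(best, d)
    return int(best)


def space_coverage(
    transcribed: Sequence[TranscribedRegion], annotation: AnnotationSet
) -> dict[str, float | None]:
    """Percent of each annotated space covered by transcribed regions of the
    matching class.  Unmappable bases are excluded from denominators; a
    zero-size space yields None (undefined), not 0."""
    class_code = {"intergenic": 0, "exon": 1, "intron": 2, "pseudogene": 3}
    covered_bases = {c: 0 for c in REGION_CLASSES}
    space_bases = {c: 0 for c in REGION_CLASSES}
    for chrom in annotation.chrom_lengths:
        labels = annotation.space_labels(chrom)
        covered = {c: np.zeros(len(labels), dtype=bool) for c in REGION_CLASSES}
        for tr in transcribed:
            if tr.interval.chrom == chrom:
                covered[tr.region_class][tr.interval.start : tr.interval.end] = True
        for cls, code in class_code.items():
            in_space = labels == code
            space_bases[cls] += int(in_space.sum())
            covered_bases[cls] += int((in_space & covered[cls]).sum())
    out: dict[str, float | None] = {}
    for cls in REGION_CLASSES:
        if space_bases[cls] == 0:
            out[cls] = None
        else:
            out[cls] = 100.0 * covered_bases[cls] / space_bases[cls]
    return out


def gene_bridging_fraction(
    multi_exon_transcripts: Sequence[Sequence[GenomicInterval]],
    itrs: Sequence[GenomicInterval],
    genes: Sequence[Gene] | Sequence[GenomicInterval],
    max_dist: int = 500,
) -> float:
    """Fraction of gene-proximal ITRs bridged to their nearest gene by a
    multi-exon transcript chain.

    An ITR within ``max_dist`` of a gene counts as bridged when some chain
    overlaps both the ITR and that nearest gene, evidence that the intergenic
    transcript is part of a larger genic transcriptional unit."""
    spans = [g.span if isinstance(g, Gene) else g for g in genes]
    proximal = 0
    bridged = 0
    for itr in itrs:
        same_chrom = [s for s in spans if s.chrom == itr.chrom]
        if not same_chrom:
            continue
        dists = []
        for s in same_chrom:
            if itr.overlaps(s):
                dists.append((0, s))
            elif s.end <= itr.start:
                dists.append((itr.start - s.end, s))
            else:
                dists.append((s.start - itr.end, s))
        dist, nearest = min(dists, key=lambda t: t[0])
        if dist > max_dist:
            continue
        proximal += 1
        for chain in multi_exon_transcripts:
            hits_itr = any(e.overlaps(itr) for e in chain)
            hits_gene = any(e.overlaps(nearest) for e in chain)
            if hits_itr and hits_gene:
                bridged += 1
                break
    if proximal == 0:
        return 0.0
    return bridged / proximal
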