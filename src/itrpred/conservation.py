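"""Cross-species conservation calling against an empirical null.

A sequence is called conserved when its best cross-species match is more
significant than the 95th-percentile best-hit significance of random,
unexpressed intergenic sequences.  Because 5% of null sequences exceed their
own 95th percentile by construction, 5 percentage points are subtracted from
final conserved proportions.  Per-base substitution rates between a query
and its best within-species match serve as a proxy for duplicate age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .regions import GenomicInterval, TranscribedRegion

__all__ = [
    "MatchRecord",
    "ConservedBlock",
    "significance",
    "best_match",
    "empirical_conservation_threshold",
    "call_conserved",
    "adjust_conserved_proportion",
    "estimate_substitution_rate",
    "SubstitutionRate",
    "cnb_expression_summary",
]

#: -log10 significance assigned to a reported E-value of exactly 0.
SIGNIFICANCE_CAP = 180.0


@dataclass(frozen=True)
class MatchRecord:
    """A similarity hit: query id, subject location, E-value, and optionally
    a bitscore and a per-base substitution rate K."""

    query: str
    subject_chrom: str
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float | None = None
    k: float | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        if self.k is not None and self.k < 0:
            raise ValueError("K must be >= 0 when present")

    @property
    def subject_interval(self) -> GenomicInterval:
        return GenomicInterval(self.subject_chrom, self.subject_start, self.subject_end)


def significance(evalue: float | None) -> float:
    """Best-hit significance on the -log10(E) scale.

    Hitless sequences score 0 so that the empirical percentile is computed
    over the full null set; E = 0 is capped at 180.
    """
    if evalue is None:
        return 0.0
    if evalue <= 0:
        return SIGNIFICANCE_CAP
    return min(-math.log10(evalue), SIGNIFICANCE_CAP)


def best_match(
    matches: Iterable[MatchRecord], query: str | None = None
) -> MatchRecord | None:
    """Most significant hit: minimum E-value, ties broken by maximum
    bitscore, then lexicographic subject location."""
    pool = [m for m in matches if query is None or m.query == query]
    if not pool:
        return None
    return min(
        pool,
        key=lambda m: (
            m.evalue,
            -(m.bitscore if m.bitscore is not None else -math.inf),
            (m.subject_chrom, m.subject_start, m.subject_end),
        ),
    )


def empirical_conservation_threshold(
    null_best: Sequence[float | None], percentile: float = 95.0
) -> float:
    """Empirical E-value threshold from random unexpressed sequences.

    Each null sequence contributes its best-hit significance (hitless -> 0);
    the ascending nearest-rank percentile of those significances defines the
    threshold, returned on the E-value scale.  When most nulls are hitless
    the threshold collapses to the search reporting cutoff, as observed for
    compact genomes; repeat-rich genomes yield far more stringent thresholds.
    """
    if len(null_best) == 0:
        raise ValueError("null set must be non-empty")
    sigs = sorted(significance(e) for e in null_best)
    rank = math.ceil(percentile / 100.0 * len(sigs))
    rank = min(max(rank, 1), len(sigs))
    s_thr = sigs[rank - 1]
    return 10.0 ** (-s_thr)


def call_conserved(query_best: float | None, threshold: float) -> bool:
    """True iff a hit exists and is strictly more significant than the
    empirical threshold."""
    if query_best is None:
        return False
    return significance(query_best) > significance(threshold)


def adjust_conserved_proportion(p_raw: float) -> float:
    """Subtract the 5% expected false-positive rate from a raw conserved
    proportion, flooring at zero."""
    if not (0.0 <= p_raw <= 1.0):
        raise ValueError("proportion must lie in [0, 1]")
    return max(p_raw - 0.05, 0.0)


@dataclass(frozen=True)
class SubstitutionRate:
    k: float
    p_distance: float
    aligned_columns: int


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("NUC.4.4")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def estimate_substitution_rate(query_seq: str, subject_seq: str) -> SubstitutionRate:
    """Per-base substitution rate K between a query and its match.

    The two sequences are globally aligned (EDNAFULL scoring, affine gaps:
    open 10, extend 0.5); p is the mismatch fraction over aligned non-gap
    columns and K applies the Jukes-Cantor multiple-hit correction
    ``K = -(3/4) ln(1 - 4p/3)``, undefined for p >= 0.75.
    """
    q = query_seq.upper()
    s = subject_seq.upper()
    if not q or not s:
        raise ValueError("sequences must be non-empty")
    if set(q) - set("ACGT") or set(s) - set("ACGT"):
        raise ValueError("sequences must be over {A, C, G, T}")
    aligner = _make_aligner()
    aln = aligner.align(q, s)[0]
    cols = 0
    mismatches = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        cols += qe - qs
        for i in range(qe - qs):
            if q[qs + i] != s[ss + i]:
                mismatches += 1
    if cols == 0:
        raise ValueError("empty alignment: no aligned columns")
    p = mismatches / cols
    if p >= 0.75:
        raise ValueError(f"p-distance {p:.3f} >= 0.75: correction undefined")
    k = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    return SubstitutionRate(k=k, p_distance=p, aligned_columns=cols)


@dataclass(frozen=True)
class ConservedBlock:
    """A nucleotide block conserved across all species, with a per-species
    interval and region class and per-base conservation scores on the
    reference genome."""

    block_id: str
    spans: Mapping[str, tuple[GenomicInterval, str]]
    scores: tuple[float, ...]
    reference: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "spans", dict(self.spans))
        object.__setattr__(self, "scores", tuple(self.scores))
        if self.reference not in self.spans:
            raise ValueError("reference species missing from spans")
        ref_iv, _ = self.spans[self.reference]
        if len(self.scores) != ref_iv.length:
            raise ValueError("score length must equal reference block length")
        if any(not (0.0 <= x <= 1.0) for x in self.scores):
            raise ValueError("scores must lie in [0, 1]")
        for species, (_, cls) in self.spans.items():
            if cls not in {"exon", "intron", "intergenic", "other"}:
                raise ValueError(f"invalid class {cls!r} for {species}")

    @property
    def common_class(self) -> str:
        classes = {cls for _, cls in self.spans.values()}
        return classes.pop() if len(classes) == 1 else "mixed"


def cnb_expression_summary(
    blocks: Sequence[ConservedBlock],
    transcribed: Mapping[str, Sequence[TranscribedRegion]],
) -> pd.DataFrame:
    """Count conserved blocks by the number of species in which they are
    expressed, stratified by block class.

    A block is expressed in a species when its interval there is overlapped
    by at least one transcribed region of the matching class.  Rows are block
    classes, columns the number of expressing species (0..n_species); counts
    sum to the number of blocks.
    """
    n_species = max((len(b.spans) for b in blocks), default=0)
    counts: dict[str, np.ndarray] = {}
    for block in blocks:
        n_expr = 0
        for species, (iv, cls) in block.spans.items():
            regs = transcribed.get(species, ())
            hit = any(
                tr.region_class == cls and tr.interval.overlaps(iv) for tr in regs
            )
            if hit:
                n_expr += 1
        row = counts.setdefault(
            block.common_class, np.zeros(n_species + 1, dtype=int)
        )
        row[n_expr] += 1
    frame = pd.DataFrame(
        {cls: row for cls, row in counts.items()}
    ).T.sort_index()
    frame.columns = list(range(n_species + 1))
    return frame
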