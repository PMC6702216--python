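"""Synthetic-data generation with planted ground truth.

Every pipeline input — annotation and genome sequence, per-dataset
transcript fragments and FPKM matrices, similarity tables with an empirical
null, syntenic blocks with planted duplicates, histone peaks, bisulfite
counts, and benchmark feature tables — can be generated with known truth
labels, so each analysis stage is testable without external downloads.

Class structure follows the directions observed in real data: exon-like
regions are longer, expressed at higher levels and in more tissues, more
often conserved, and more often gene-body methylated than ITR-like or
pseudogene-like regions; transcribed miRNAs sit between the two on
expression but score low on protein-level conservation.  All draws flow
from a per-stage generator derived deterministically from one scenario
seed, so stages can be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import MatchRecord
from .expression import RICE_LAYOUT, TissueLayout
from .features import (
    DEFAULT_MARKS,
    METHYLATION_CONTEXTS,
    METHYLATION_TISSUES,
    PeakSet,
    feature_registry,
)
from .regions import (
    AnnotationSet,
    Gene,
    GenomicInterval,
    TranscribedRegion,
    find_unmappable,
)
from .synteny import AnchorPair, SyntenicBlock

__all__ = [
    "ScenarioConfig",
    "generate_annotation",
    "generate_transcription",
    "generate_match_tables",
    "generate_feature_table",
    "generate_methylation",
    "generate_peaks",
    "generate_synteny",
    "SimulatedTranscription",
    "SimulatedMatches",
    "SimulatedMethylation",
    "SimulatedSynteny",
]

BENCHMARK_CLASSES = ("phenotype_exon", "transcribed_pseudogene", "transcribed_miRNA")

# stage tags for deriving independent per-stage generators from one seed
_STAGES = {
    "annotation": 1,
    "transcription": 2,
    "matches": 3,
    "features": 4,
    "methylation": 5,
    "peaks": 6,
    "synteny": 7,
}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STAGES[stage]])


@dataclass
class ScenarioConfig:
    """Default scenario: a ~1 Mbp two-chromosome genome with a few hundred
    genes, sized so the full pipeline runs in minutes on one CPU."""

    # genome / annotation
    n_chromosomes: int = 2
    chromosome_length: int = 600_000
    n_genes: int = 300
    mean_exons_per_gene: float = 4.0
    exon_length_range: tuple[int, int] = (120, 500)
    intron_length_range: tuple[int, int] = (60, 400)
    n_pseudogenes: int = 60
    pseudogene_length_range: tuple[int, int] = (300, 1500)
    n_runs_per_chromosome: int = 5
    n_run_length_range: tuple[int, int] = (40, 200)
    # transcription
    layout: TissueLayout = field(default_factory=lambda: RICE_LAYOUT)
    n_itrs: int = 300
    transcribed_gene_fraction: float = 0.7
    transcribed_intron_fraction: float = 0.15
    transcribed_pseudogene_fraction: float = 0.5
    exon_fragment_length: tuple[float, float] = (5.5, 0.5)  # lognormal mu, sigma
    itr_fragment_length: tuple[float, float] = (4.8, 0.5)
    exon_level_log: tuple[float, float] = (2.0, 0.8)
    itr_level_log: tuple[float, float] = (0.3, 0.8)
    exon_breadth_mean: float = 7.0
    itr_breadth_mean: float = 2.0
    # conservation null & planting
    n_null: int = 1000
    null_hit_prob: float = 0.4
    null_sig_min: float = 5.0
    null_sig_scale: float = 3.0
    conserved_fraction: Mapping[str, float] = field(
        default_factory=lambda: {
            "exon": 0.75,
            "intron": 0.20,
            "pseudogene": 0.35,
            "intergenic": 0.13,
        }
    )
    # duplicates / K mixture
    duplicate_fraction: float = 0.5
    k_recent_log: tuple[float, float] = (np.log(0.02), 0.5)
    k_ancient_log: tuple[float, float] = (np.log(0.7), 0.25)
    ancient_weight: float = 0.25
    # benchmark feature table
    n_benchmark_per_class: Mapping[str, int] = field(
        default_factory=lambda: {
            "phenotype_exon": 300,
            "transcribed_pseudogene": 300,
            "transcribed_miRNA": 60,
        }
    )
    feature_effect: Mapping[str, float] = field(
        default_factory=lambda: {
            "transcription": 1.0,
            "conservation": 1.0,
            "chromatin": 1.0,
            "methylation": 1.0,
        }
    )
    missingness: float = 0.05
    # methylation
    gbm_fraction: float = 0.3
    meth_coverage_ok_fraction: float = 0.9
    meth_background: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.25, "CHG": 0.10, "CHH": 0.04}
    )
    gbm_cg_level: float = 0.60
    # synteny
    n_anchor_pairs: int = 12
    planted_retention: float = 0.25
    partner_expressed_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name, p in [
            ("null_hit_prob", self.null_hit_prob),
            ("duplicate_fraction", self.duplicate_fraction),
            ("ancient_weight", self.ancient_weight),
            ("missingness", self.missingness),
            ("gbm_fraction", self.gbm_fraction),
            ("planted_retention", self.planted_retention),
        ]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for cls, p in self.conserved_fraction.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"conserved fraction for {cls} out of range")


# ---------------------------------------------------------------------------
# annotation + genome


def generate_annotation(
    config: ScenarioConfig, seed: int
) -> tuple[AnnotationSet, dict[str, str]]:
    """Generate an annotated genome: genes with exon/intron structure laid
    out left to right with random intergenic gaps, pseudogenes dropped into
    remaining intergenic space, and runs of Ns inserted as likely-unmappable
    regions (recovered from the sequence, not asserted separately)."""
    rng = _stage_rng(seed, "annotation")
    chrom_lengths = {
        f"chr{i + 1}": config.chromosome_length for i in range(config.n_chromosomes)
    }
    genes: list[Gene] = []
    gaps: list[GenomicInterval] = []
    genes_per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    placed = 0
    for chrom, length in chrom_lengths.items():
        pos = 0
        on_chrom = 0
        while placed < config.n_genes and on_chrom < genes_per_chrom:
            gap = int(rng.integers(500, 2500))
            n_exons = 1 + int(rng.poisson(config.mean_exons_per_gene - 1))
            exon_lens = rng.integers(*config.exon_length_range, size=n_exons)
            intron_lens = (
                rng.integers(*config.intron_length_range, size=n_exons - 1)
                if n_exons > 1
                else np.array([], dtype=int)
            )
            gene_len = int(exon_lens.sum() + intron_lens.sum())
            start = pos + gap
            if start + gene_len > length:
                break
            if gene_len > length:
                raise RuntimeError("gene longer than chromosome: infeasible packing")
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            cursor = start
            for i, el in enumerate(exon_lens):
                exons.append(GenomicInterval(chrom, cursor, cursor + int(el), strand))
                cursor += int(el)
                if i < len(intron_lens):
                    cursor += int(intron_lens[i])
            gene = Gene(f"gene_{placed + 1:04d}", tuple(exons))
            genes.append(gene)
            if gap > 0:
                gaps.append(GenomicInterval(chrom, pos, start))
            pos = cursor
            placed += 1
            on_chrom += 1
        if pos < length:
            gaps.append(GenomicInterval(chrom, pos, length))
    if placed < config.n_genes:
        raise RuntimeError("infeasible packing: genes exceed chromosome space")
    # pseudogenes into intergenic gaps with room
    pseudogenes: list[GenomicInterval] = []
    big_gaps = [g for g in gaps if g.length > config.pseudogene_length_range[1] + 100]
    for i in range(config.n_pseudogenes):
        gap = big_gaps[int(rng.integers(0, len(big_gaps)))]
        ln = int(rng.integers(*config.pseudogene_length_range))
        start = int(rng.integers(gap.start, gap.end - ln))
        iv = GenomicInterval(gap.chrom, start, start + ln)
        if any(iv.overlaps(p) for p in pseudogenes):
            continue
        pseudogenes.append(iv)
    # genome sequence with N runs in intergenic space
    genome: dict[str, str] = {}
    occupied: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        mask = np.zeros(length, dtype=bool)
        for g in genes:
            if g.chrom == chrom:
                mask[g.span.start : g.span.end] = True
        for p in pseudogenes:
            if p.chrom == chrom:
                mask[p.start : p.end] = True
        occupied[chrom] = mask
    for chrom, length in chrom_lengths.items():
        seq = rng.choice(list("ACGT"), size=length)
        inserted = 0
        attempts = 0
        while inserted < config.n_runs_per_chromosome and attempts < 1000:
            attempts += 1
            run_len = int(rng.integers(*config.n_run_length_range))
            start = int(rng.integers(0, length - run_len))
            if occupied[chrom][start : start + run_len].any():
                continue
            seq[start : start + run_len] = "N"
            occupied[chrom][start : start + run_len] = True
            inserted += 1
        genome[chrom] = "".join(seq)
    unmappable = [
        iv
        for chrom, seq in genome.items()
        for iv in find_unmappable(seq, chrom=chrom)
    ]
    annotation = AnnotationSet(chrom_lengths, genes, pseudogenes, unmappable)
    return annotation, genome


# ---------------------------------------------------------------------------
# transcription


@dataclass
class SimulatedTranscription:
    regions: list[TranscribedRegion]
    fragments: dict[str, list[GenomicInterval]]
    fpkm: pd.DataFrame
    presence: pd.DataFrame
    truth: pd.Series  # region_id -> planted class


def _expression_for(
    rng: np.random.Generator,
    layout: TissueLayout,
    breadth_mean: float,
    level_log: tuple[float, float],
) -> tuple[dict[str, float], dict[str, bool]]:
    datasets = list(layout.datasets)
    tissues = list(layout.tissues)
    n_tissues = int(np.clip(round(rng.normal(breadth_mean, 1.2)), 0, len(tissues)))
    chosen = (
        set(rng.choice(tissues, size=n_tissues, replace=False)) if n_tissues else set()
    )
    fpkm: dict[str, float] = {}
    presence: dict[str, bool] = {}
    for d in datasets:
        tissue = layout.dataset_tissue[d]
        if tissue in chosen and rng.random() < 0.9:
            presence[d] = True
            fpkm[d] = float(np.exp(rng.normal(*level_log)))
        else:
            presence[d] = False
            fpkm[d] = 0.0
    if chosen and not any(presence.values()):
        d = layout.datasets_for(sorted(chosen)[0])[0]
        presence[d] = True
        fpkm[d] = float(np.exp(rng.normal(*level_log)))
    return fpkm, presence


def generate_transcription(
    annotation: AnnotationSet,
    genome: Mapping[str, str],
    config: ScenarioConfig,
    seed: int,
) -> SimulatedTranscription:
    """Plant transcribed regions of each class and emit per-dataset
    fragments plus FPKM/presence matrices.

    Exon-derived regions are longer, expressed higher and in more tissues
    than ITRs; intron and pseudogene regions sit in between.  Per-dataset
    fragments are random sub-intervals of the region so that merging the
    fragments reconstructs the region extents."""
    rng = _stage_rng(seed, "transcription")
    layout = config.layout
    regions: list[TranscribedRegion] = []

    def add_region(iv: GenomicInterval, cls: str, breadth_mean, level_log) -> None:
        fpkm, presence = _expression_for(rng, layout, breadth_mean, level_log)
        regions.append(
            TranscribedRegion(
                interval=iv,
                region_class=cls,
                presence=presence,
                fpkm=fpkm,
            )
        )

    genes = list(annotation.genes)
    rng.shuffle(genes)
    n_tx = int(config.transcribed_gene_fraction * len(genes))
    for g in genes[:n_tx]:
        exon = g.exons[int(rng.integers(0, len(g.exons)))]
        ln = int(np.clip(np.exp(rng.normal(*config.exon_fragment_length)), 30, exon.length))
        start = int(rng.integers(exon.start, exon.end - ln + 1))
        add_region(
            GenomicInterval(exon.chrom, start, start + ln),
            "exon",
            config.exon_breadth_mean,
            config.exon_level_log,
        )
    introns = [i for g in genes for i in g.introns if i.length >= 60]
    rng.shuffle(introns)
    for intron in introns[: int(config.transcribed_intron_fraction * len(introns))]:
        ln = int(np.clip(np.exp(rng.normal(*config.itr_fragment_length)), 30, intron.length))
        start = int(rng.integers(intron.start, intron.end - ln + 1))
        add_region(
            GenomicInterval(intron.chrom, start, start + ln),
            "intron",
            (config.exon_breadth_mean + config.itr_breadth_mean) / 2,
            config.itr_level_log,
        )
    pseudos = list(annotation.pseudogenes)
    rng.shuffle(pseudos)
    for p in pseudos[: int(config.transcribed_pseudogene_fraction * len(pseudos))]:
        ln = int(np.clip(np.exp(rng.normal(*config.itr_fragment_length)), 30, p.length))
        start = int(rng.integers(p.start, p.end - ln + 1))
        add_region(
            GenomicInterval(p.chrom, start, start + ln),
            "pseudogene",
            config.itr_breadth_mean + 1,
            config.itr_level_log,
        )
    # ITRs in free intergenic space
    allowed = {c: annotation.space_labels(c) == 0 for c in annotation.chrom_lengths}
    for r in regions:
        iv = r.interval
        allowed[iv.chrom][iv.start : iv.end] = False
    chroms = sorted(annotation.chrom_lengths)
    placed = 0
    attempts = 0
    while placed < config.n_itrs and attempts < 100 * config.n_itrs:
        attempts += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        ln = int(np.clip(np.exp(rng.normal(*config.itr_fragment_length)), 30, 5000))
        limit = annotation.chrom_lengths[chrom] - ln
        start = int(rng.integers(0, limit))
        if not allowed[chrom][start : start + ln].all():
            continue
        iv = GenomicInterval(chrom, start, start + ln)
        add_region(iv, "intergenic", config.itr_breadth_mean, config.itr_level_log)
        allowed[chrom][start : start + ln] = False
        placed += 1
    if placed < config.n_itrs:
        raise RuntimeError("could not place the requested number of ITRs")
    # fragments: a jittered sub-interval of the region in each present dataset
    fragments: dict[str, list[GenomicInterval]] = {d: [] for d in layout.datasets}
    for r in regions:
        iv = r.interval
        for d in layout.datasets:
            if not r.presence[d]:
                continue
            trim_left = int(rng.integers(0, max(1, iv.length // 10)))
            trim_right = int(rng.integers(0, max(1, iv.length // 10)))
            start = iv.start + trim_left
            end = max(start + 1, iv.end - trim_right)
            fragments[d].append(GenomicInterval(iv.chrom, start, end))
    ids = [r.region_id for r in regions]
    fpkm = pd.DataFrame(
        [[r.fpkm[d] for d in layout.datasets] for r in regions],
        index=ids,
        columns=list(layout.datasets),
    )
    presence = pd.DataFrame(
        [[r.presence[d] for d in layout.datasets] for r in regions],
        index=ids,
        columns=list(layout.datasets),
    )
    truth = pd.Series([r.region_class for r in regions], index=ids)
    return SimulatedTranscription(regions, fragments, fpkm, presence, truth)


# ---------------------------------------------------------------------------
# similarity / conservation


@dataclass
class SimulatedMatches:
    null_best: list[float | None]
    query_best: dict[str, float | None]
    planted_conserved: set[str]
    duplicates: pd.DataFrame  # region_id, k, is_ancient
    truth: pd.Series


def draw_null_best_evalue(rng: np.random.Generator, config: ScenarioConfig) -> float | None:
    """Best-hit E-value of a random unexpressed sequence: usually hitless,
    otherwise just past the search reporting cutoff with an exponentially
    decaying significance tail."""
    if rng.random() >= config.null_hit_prob:
        return None
    s = config.null_sig_min + rng.exponential(config.null_sig_scale)
    return 10.0 ** (-s)


def generate_match_tables(
    config: ScenarioConfig,
    region_classes: pd.Series,
    seed: int,
) -> SimulatedMatches:
    """Best cross-species hits with a planted conserved subset, plus
    within-species duplicates with a recent/ancient K mixture.

    Null (random unexpressed) sequences draw from the null match process
    only.  A per-class fraction of query regions receives a planted hit well
    above the null 95th percentile; the rest draw from the null process."""
    rng = _stage_rng(seed, "matches")
    null_best = [draw_null_best_evalue(rng, config) for _ in range(config.n_null)]
    query_best: dict[str, float | None] = {}
    planted: set[str] = set()
    for region_id, cls in region_classes.items():
        p_c = config.conserved_fraction.get(cls, 0.0)
        if rng.random() < p_c:
            s = 30.0 + rng.exponential(15.0)
            query_best[region_id] = 10.0 ** (-min(s, 175.0))
            planted.add(region_id)
        else:
            query_best[region_id] = draw_null_best_evalue(rng, config)
    dup_rows = []
    for region_id in region_classes.index:
        if rng.random() >= config.duplicate_fraction:
            continue
        ancient = rng.random() < config.ancient_weight
        mu, sigma = config.k_ancient_log if ancient else config.k_recent_log
        dup_rows.append(
            {
                "region_id": region_id,
                "k": float(np.exp(rng.normal(mu, sigma))),
                "is_ancient": ancient,
            }
        )
    duplicates = pd.DataFrame(dup_rows, columns=["region_id", "k", "is_ancient"])
    return SimulatedMatches(
        null_best=null_best,
        query_best=query_best,
        planted_conserved=planted,
        duplicates=duplicates,
        truth=region_classes,
    )


# ---------------------------------------------------------------------------
# benchmark feature table


def _beta(rng: np.random.Generator, mean: float, conc: float = 8.0) -> float:
    mean = float(np.clip(mean, 0.02, 0.98))
    return float(rng.beta(mean * conc, (1 - mean) * conc))


#: class-direction multipliers per feature family (exon-like high).
_CLASS_DELTA = {
    "phenotype_exon": {
        "transcription": 1.0,
        "conservation": 1.0,
        "chromatin": 1.0,
        "methylation": 1.0,
    },
    "transcribed_miRNA": {
        "transcription": 0.0,
        "conservation": -0.6,
        "chromatin": 0.0,
        "methylation": -0.5,
    },
    "transcribed_pseudogene": {
        "transcription": -0.8,
        "conservation": -1.0,
        "chromatin": -1.0,
        "methylation": 0.2,
    },
}


def generate_feature_table(
    labels: pd.Series,
    config: ScenarioConfig,
    seed: int,
) -> pd.DataFrame:
    """Class-conditional 44-feature table for benchmark regions.

    Families shift between classes by the configured effect sizes: phenotype
    exons score high on expression, conservation, activation chromatin, and
    gene-body methylation; transcribed pseudogenes low; transcribed miRNAs
    intermediate on expression and low on protein-level conservation.
    Missingness is applied to methylation features at the configured rate.
    With all effect sizes at zero the classes are indistinguishable.
    """
    rng = _stage_rng(seed, "features")
    layout = config.layout
    eff = config.feature_effect
    registry = feature_registry(layout)
    rows = []
    for region_id, cls in labels.items():
        if cls not in _CLASS_DELTA:
            raise ValueError(f"unknown benchmark class {cls!r}")
        delta = _CLASS_DELTA[cls]
        row: dict[str, float] = {}
        # transcription: tissue levels + derived max / median / breadth.
        # Shifts are mild: any single feature separates the classes only
        # weakly; discrimination comes from combining all families.
        d_tx = eff["transcription"] * delta["transcription"]
        breadth_mean = 4.0 + 1.2 * d_tx
        n_tissues = int(np.clip(round(rng.normal(breadth_mean, 1.8)), 0, 9))
        tissues = list(layout.tissues)
        chosen = (
            set(rng.choice(tissues, size=n_tissues, replace=False))
            if n_tissues
            else set()
        )
        mu = 0.8 + 0.5 * d_tx
        levels = {
            t: float(np.exp(rng.normal(mu, 1.0))) if t in chosen else 0.0
            for t in tissues
        }
        for t in tissues:
            row[f"expr_{t}"] = levels[t]
        expressed = [v for v in levels.values() if v > 0]
        row["expr_max"] = max(expressed) if expressed else 0.0
        row["expr_median_expressed"] = float(np.median(expressed)) if expressed else 0.0
        row["expr_breadth"] = float(
            len({layout.breadth_group[t] for t in chosen})
        )
        # conservation
        d_cons = eff["conservation"] * delta["conservation"]
        p_hit = float(np.clip(0.45 + 0.15 * d_cons, 0.02, 0.98))
        if rng.random() < p_hit:
            row["cons_logE"] = float(np.clip(rng.normal(25 + 10 * d_cons, 15), 5, 180))
        else:
            row["cons_logE"] = 0.0
        cnb_mean = 0.35 + 0.12 * d_cons
        if cls == "transcribed_miRNA":
            # conserved RNA structure: block overlap despite weak
            # protein-level similarity
            cnb_mean = 0.45
        prop = _beta(rng, cnb_mean, 4.0) if rng.random() < 0.6 + 0.12 * d_cons else 0.0
        row["cons_cnb_prop"] = prop
        phast_mean = 0.5 + 0.15 * d_cons
        if cls == "transcribed_miRNA":
            phast_mean = 0.7
        row["cons_phastcons"] = _beta(rng, phast_mean, 10.0) if prop > 0 else 0.0
        # chromatin
        d_chr = eff["chromatin"] * delta["chromatin"]
        n_act = 0
        n_rep = 0
        for mark, mark_class in DEFAULT_MARKS.items():
            direction = d_chr if mark_class == "activation" else -d_chr
            p_over = float(np.clip(0.45 + 0.15 * direction, 0.02, 0.98))
            if rng.random() < p_over:
                cov = _beta(rng, 0.55 + 0.08 * direction, 5.0)
                if mark_class == "activation":
                    n_act += 1
                else:
                    n_rep += 1
            else:
                cov = 0.0
            row[f"hist_cov_{mark}"] = cov
        row["hist_n_activation"] = float(n_act)
        row["hist_n_repression"] = float(n_rep)
        row["mnase_depth"] = float(rng.gamma(4.0, 1.0 + 0.2 * max(-d_chr, 0.0)))
        # methylation
        d_me = eff["methylation"] * delta["methylation"]
        gbm_rate = float(np.clip(0.2 + 0.12 * d_me, 0.01, 0.95))
        for t in METHYLATION_TISSUES:
            gbm = rng.random() < gbm_rate
            if gbm:
                cg, chg, chh = 0.6, 0.06, 0.04
            else:
                cg = 0.2
                chg = 0.12 + 0.05 * max(-d_me, 0.0)
                chh = 0.05 + 0.03 * max(-d_me, 0.0)
            row[f"meth_{t}_CG"] = _beta(rng, cg, 10.0)
            row[f"meth_{t}_CHG"] = _beta(rng, chg, 10.0)
            row[f"meth_{t}_CHH"] = _beta(rng, chh, 10.0)
            row[f"gbm_{t}"] = float(gbm)
        rows.append(row)
    table = pd.DataFrame(rows, index=labels.index)[registry]
    if config.missingness > 0:
        meth_cols = [c for c in registry if c.startswith(("meth_", "gbm_"))]
        mask = rng.random((len(table), len(meth_cols))) < config.missingness
        values = table[meth_cols].values
        values[mask] = np.nan
        table[meth_cols] = values
    return table


# ---------------------------------------------------------------------------
# methylation counts


@dataclass
class SimulatedMethylation:
    counts: pd.DataFrame
    gbm_true: set[str]


def generate_methylation(
    region_ids: Sequence[str],
    config: ScenarioConfig,
    seed: int,
) -> SimulatedMethylation:
    """Bisulfite read counts with a designated gene-body-methylated subset.

    GBM-true regions draw CG methylated-read counts above the genome
    background with CHG/CHH at background; all other regions draw every
    context at background.  A configured fraction of regions has read and
    site counts above the level minimums; the rest fall below and yield
    missing levels."""
    rng = _stage_rng(seed, "methylation")
    gbm_true = {
        rid for rid in region_ids if rng.random() < config.gbm_fraction
    }
    rows = []
    for rid in region_ids:
        for tissue in METHYLATION_TISSUES:
            ok = rng.random() < config.meth_coverage_ok_fraction
            for context in METHYLATION_CONTEXTS:
                if ok:
                    total = int(30 + rng.poisson(20))
                    sites = int(10 + rng.poisson(10))
                else:
                    # coverage below the 5-read / 5-site level minimums
                    total = min(int(rng.poisson(1.5)), 4)
                    sites = min(int(rng.poisson(1.5)), 4)
                bg = config.meth_background[context]
                p = (
                    config.gbm_cg_level
                    if (rid in gbm_true and context == "CG")
                    else bg
                )
                meth = int(rng.binomial(total, p)) if total else 0
                rows.append(
                    {
                        "region_id": rid,
                        "tissue": tissue,
                        "context": context,
                        "methylated": meth,
                        "total": total,
                        "sites": sites,
                    }
                )
    return SimulatedMethylation(counts=pd.DataFrame(rows), gbm_true=gbm_true)


# ---------------------------------------------------------------------------
# peaks


def generate_peaks(
    regions: Sequence[tuple[str, GenomicInterval, str]],
    config: ScenarioConfig,
    seed: int,
) -> list[PeakSet]:
    """Histone peak sets with class-dependent overlap probabilities: exon
    regions are covered by activation-mark peaks most of the time, ITR-like
    regions rarely; repression marks invert the direction."""
    rng = _stage_rng(seed, "peaks")
    overlap_p = {
        ("exon", "activation"): 0.8,
        ("exon", "repression"): 0.1,
        ("intron", "activation"): 0.5,
        ("intron", "repression"): 0.2,
        ("pseudogene", "activation"): 0.2,
        ("pseudogene", "repression"): 0.5,
        ("intergenic", "activation"): 0.25,
        ("intergenic", "repression"): 0.35,
    }
    peaksets = []
    for mark, mark_class in DEFAULT_MARKS.items():
        intervals = []
        for _, iv, cls in regions:
            p = overlap_p.get((cls, mark_class), 0.3)
            if rng.random() < p:
                frac = rng.uniform(0.3, 1.0)
                ln = max(1, int(frac * iv.length))
                start = int(rng.integers(iv.start, iv.end - ln + 1))
                intervals.append(GenomicInterval(iv.chrom, start, start + ln))
        peaksets.append(PeakSet(mark=mark, intervals=tuple(intervals), mark_class=mark_class))
    return peaksets


# ---------------------------------------------------------------------------
# synteny


@dataclass
class SimulatedSynteny:
    blocks: list[SyntenicBlock]
    regions: list[tuple[str, GenomicInterval, str]]
    matches_by_region: dict[str, list[MatchRecord]]
    transcribed_partner: list[GenomicInterval]
    planted_retention: float
    retained: set[str]


def generate_synteny(
    config: ScenarioConfig,
    seed: int,
    species: str = "rice",
    ancient: bool = True,
) -> SimulatedSynteny:
    """A within-species syntenic block with planted intergenic duplicates.

    One block of ``n_anchor_pairs`` anchors is laid out on a query and a
    partner chromosome; one ITR sits in each inter-anchor interval, and a
    planted fraction receives a match inside the corresponding partner
    interval (its K drawn from the recent/ancient mixture).  A fraction of
    planted partner loci is overlapped by a transcribed region."""
    rng = _stage_rng(seed, "synteny")
    n = config.n_anchor_pairs
    gene_len, gap_len = 2000, 4000
    anchors = []
    ks_mu = 0.85 if ancient else 0.3
    for i in range(n):
        a_start = 10_000 + i * (gene_len + gap_len)
        b_start = 20_000 + i * (gene_len + gap_len)
        ks = float(np.clip(rng.normal(ks_mu, 0.05), 0.05, 3.0))
        anchors.append(
            AnchorPair(
                gene_a=f"geneA_{i}",
                interval_a=GenomicInterval("chrA", a_start, a_start + gene_len),
                gene_b=f"geneB_{i}",
                interval_b=GenomicInterval("chrB", b_start, b_start + gene_len),
                ks=ks,
            )
        )
    block = SyntenicBlock("block_1", species, species, tuple(anchors))
    regions = []
    matches: dict[str, list[MatchRecord]] = {}
    n_gaps = n - 1
    n_retained = int(round(config.planted_retention * n_gaps))
    retained_idx = set(
        rng.choice(n_gaps, size=n_retained, replace=False).tolist()
    )
    retained: set[str] = set()
    transcribed_partner = []
    for i in range(n_gaps):
        gap_a_start = anchors[i].interval_a.end
        mid = gap_a_start + gap_len // 2
        iv = GenomicInterval("chrA", mid - 150, mid + 150)
        rid = f"itr_{i}"
        regions.append((rid, iv, "intergenic"))
        if i in retained_idx:
            gap_b_start = anchors[i].interval_b.end
            mid_b = gap_b_start + gap_len // 2
            is_ancient = rng.random() < config.ancient_weight
            mu, sigma = (
                config.k_ancient_log if is_ancient else config.k_recent_log
            )
            record = MatchRecord(
                query=rid,
                subject_chrom="chrB",
                subject_start=mid_b - 150,
                subject_end=mid_b + 150,
                evalue=1e-30,
                bitscore=200.0,
                k=float(np.exp(rng.normal(mu, sigma))),
            )
            matches[rid] = [record]
            retained.add(rid)
            if rng.random() < config.partner_expressed_fraction:
                transcribed_partner.append(
                    GenomicInterval("chrB", mid_b - 100, mid_b + 100)
                )
    return SimulatedSynteny(
        blocks=[block],
        regions=regions,
        matches_by_region=matches,
        transcribed_partner=transcribed_partner,
        planted_retention=n_retained / n_gaps,
        retained=retained,
    )
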