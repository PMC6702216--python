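"""Construction of the 44-feature vector used for functional prediction.

Five feature families describe each region: transcription activity (9
tissue expression levels, the maximum and median-of-expressed FPKM, and
expression breadth — 12 features), sequence conservation (best cross-species
hit significance, conserved-block overlap proportion, and median phastCons
score — 3), chromatin (fractional coverage by each of 10 histone-mark peak
sets, counts of overlapping activation and repression marks, and mean
MNase-seq depth — 13), and DNA methylation (CG/CHG/CHH levels in four
tissues plus a gene-body-methylation flag per tissue — 16).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .expression import (
    RICE_LAYOUT,
    ExpressionProfile,
    TissueLayout,
    expression_breadth,
    tissue_level,
)
from .regions import GenomicInterval

__all__ = [
    "PeakSet",
    "MethylationCounts",
    "DEFAULT_MARKS",
    "METHYLATION_TISSUES",
    "METHYLATION_CONTEXTS",
    "feature_registry",
    "transcription_features",
    "conservation_features",
    "chromatin_features",
    "methylation_level",
    "gbm_calls",
    "gbm_call",
    "assemble_feature_vector",
]

LOG_EVALUE_CAP = 180.0

#: Default histone marks and their activation/repression assignment
#: (8 activation-associated, 2 repression-associated).
DEFAULT_MARKS: dict[str, str] = {
    "H3K4me1": "activation",
    "H3K4me3": "activation",
    "H3K9ac": "activation",
    "H3K23ac": "activation",
    "H3K27ac": "activation",
    "H3K36me3": "activation",
    "H4K12ac": "activation",
    "H3K4ac": "activation",
    "H3K9me2": "repression",
    "H3K27me3": "repression",
}

METHYLATION_TISSUES = ("embryo", "endosperm", "leaf", "panicle")
METHYLATION_CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class PeakSet:
    """Peak intervals for one histone mark."""

    mark: str
    intervals: tuple[GenomicInterval, ...]
    mark_class: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        if self.mark_class not in {"activation", "repression"}:
            raise ValueError(f"invalid mark class {self.mark_class!r}")


@dataclass(frozen=True)
class MethylationCounts:
    """Bisulfite read counts for one region x tissue x context cell."""

    region_id: str
    tissue: str
    context: str
    methylated: int
    total: int
    sites: int

    def __post_init__(self) -> None:
        if self.context not in METHYLATION_CONTEXTS:
            raise ValueError(f"invalid context {self.context!r}")
        if not (0 <= self.methylated <= self.total):
            raise ValueError("need 0 <= methylated <= total")
        if self.sites < 0:
            raise ValueError("sites must be >= 0")


def feature_registry(
    layout: TissueLayout = RICE_LAYOUT,
    marks: Mapping[str, str] = DEFAULT_MARKS,
    meth_tissues: Sequence[str] = METHYLATION_TISSUES,
) -> list[str]:
    """The canonical ordered list of the 44 feature names."""
    names = [f"expr_{t}" for t in layout.tissues]
    names += ["expr_max", "expr_median_expressed", "expr_breadth"]
    names += ["cons_logE", "cons_cnb_prop", "cons_phastcons"]
    names += [f"hist_cov_{m}" for m in marks]
    names += ["hist_n_activation", "hist_n_repression", "mnase_depth"]
    names += [
        f"meth_{t}_{c}" for t in meth_tissues for c in METHYLATION_CONTEXTS
    ]
    names += [f"gbm_{t}" for t in meth_tissues]
    return names


def transcription_features(profile: ExpressionProfile) -> dict[str, float]:
    """12 transcription features: per-tissue level, max over datasets,
    median among expressed datasets (0 when expressed nowhere), breadth."""
    layout = profile.layout
    out = {f"expr_{t}": tissue_level(profile, t) for t in layout.tissues}
    expressed = [
        profile.value(d) for d in layout.datasets if profile.expressed_in(d)
    ]
    out["expr_max"] = float(max(expressed)) if expressed else 0.0
    out["expr_median_expressed"] = float(np.median(expressed)) if expressed else 0.0
    out["expr_breadth"] = float(expression_breadth(profile))
    return out


def conservation_features(
    best_evalue: float | None,
    cnb_overlap: int,
    region_length: int,
    scores: Sequence[float] = (),
) -> dict[str, float]:
    """3 conservation features: -log10 of the best cross-species E-value
    (no significant match -> 0; E = 0 -> 180), proportion of the region
    overlapping a conserved nucleotide block, and the median per-base
    phastCons score over that overlap (0 without overlap)."""
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    if not (0 <= cnb_overlap <= region_length):
        raise ValueError("cnb_overlap must lie in [0, region_length]")
    if best_evalue is None:
        log_e = 0.0
    elif best_evalue <= 0:
        log_e = LOG_EVALUE_CAP
    else:
        log_e = min(max(-math.log10(best_evalue), 0.0), LOG_EVALUE_CAP)
    phast = float(np.median(scores)) if cnb_overlap > 0 and len(scores) else 0.0
    return {
        "cons_logE": log_e,
        "cons_cnb_prop": cnb_overlap / region_length,
        "cons_phastcons": phast,
    }


def chromatin_features(
    region: GenomicInterval,
    peaksets: Sequence[PeakSet],
    mnase_depth: float,
) -> dict[str, float]:
    """13 chromatin features: per-mark fractional peak coverage, counts of
    activation/repression marks with any overlap, and mean MNase depth."""
    out: dict[str, float] = {}
    n_act = 0
    n_rep = 0
    for ps in peaksets:
        covered = np.zeros(region.length, dtype=bool)
        for iv in ps.intervals:
            if iv.chrom != region.chrom:
                continue
            lo = max(iv.start, region.start) - region.start
            hi = min(iv.end, region.end) - region.start
            if hi > lo:
                covered[lo:hi] = True
        cov = float(covered.mean())
        out[f"hist_cov_{ps.mark}"] = cov
        if cov > 0:
            if ps.mark_class == "activation":
                n_act += 1
            else:
                n_rep += 1
    out["hist_n_activation"] = float(n_act)
    out["hist_n_repression"] = float(n_rep)
    out["mnase_depth"] = float(mnase_depth)
    return out


def methylation_level(
    methylated: int,
    total: int,
    sites: int,
    min_reads: int = 5,
    min_sites: int = 5,
) -> float | None:
    """Methylation level (methylated reads / total reads), or None when
    coverage falls below the read or cytosine-site minimums."""
    if not (0 <= methylated <= total):
        raise ValueError("need 0 <= methylated <= total")
    if total < min_reads or sites < min_sites:
        return None
    return methylated / total


def gbm_calls(
    counts: pd.DataFrame,
    background: Mapping[str, float],
    fdr: float = 0.05,
    min_reads: int = 5,
    min_sites: int = 5,
) -> pd.DataFrame:
    """Gene-body-methylation calls per region and tissue.

    ``counts`` columns: region_id, tissue, context, methylated, total,
    sites.  Per context and tissue, each region's methylated-read count is
    tested against the genome-background level with a one-sided binomial
    test, BH-adjusted across all regions tested in that context x tissue
    family.  A region is gene-body methylated (flag 1) when CG is
    significantly enriched while neither CHG nor CHH is; the flag is missing
    (NaN) when the CG level itself is missing.
    """
    for ctx, level in background.items():
        if not (0.0 < level < 1.0):
            raise ValueError(f"background level for {ctx} must lie in (0, 1)")
    required = {"region_id", "tissue", "context", "methylated", "total", "sites"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    sig: dict[tuple[str, str, str], bool] = {}
    measured: dict[tuple[str, str, str], bool] = {}
    for (tissue, context), grp in counts.groupby(["tissue", "context"], sort=True):
        bg = background[context]
        tested_idx = []
        pvalues = []
        for idx, row in grp.iterrows():
            level = methylation_level(
                int(row.methylated), int(row.total), int(row.sites),
                min_reads, min_sites,
            )
            key = (str(row.region_id), tissue, context)
            measured[key] = level is not None
            if level is None:
                continue
            tested_idx.append(key)
            pvalues.append(
                binomtest(
                    int(row.methylated), int(row.total), bg, alternative="greater"
                ).pvalue
            )
        if pvalues:
            padj = multipletests(pvalues, alpha=fdr, method="fdr_bh")[1]
            for key, p in zip(tested_idx, padj):
                sig[key] = bool(p <= fdr)
    regions = counts["region_id"].astype(str).unique()
    tissues = counts["tissue"].unique()
    flags = pd.DataFrame(index=regions, columns=tissues, dtype=float)
    for r in regions:
        for t in tissues:
            if not measured.get((r, t, "CG"), False):
                flags.loc[r, t] = np.nan
                continue
            cg = sig.get((r, t, "CG"), False)
            chg = sig.get((r, t, "CHG"), False)
            chh = sig.get((r, t, "CHH"), False)
            flags.loc[r, t] = float(cg and not chg and not chh)
    return flags


def gbm_call(
    cells: Sequence[MethylationCounts],
    background: Mapping[str, float],
    fdr: float = 0.05,
    min_reads: int = 5,
    min_sites: int = 5,
) -> dict[str, float]:
    """Single-region GBM flag per tissue (a one-region BH family)."""
    frame = pd.DataFrame(
        [
            {
                "region_id": c.region_id,
                "tissue": c.tissue,
                "context": c.context,
                "methylated": c.methylated,
                "total": c.total,
                "sites": c.sites,
            }
            for c in cells
        ]
    )
    flags = gbm_calls(frame, background, fdr, min_reads, min_sites)
    region = frame["region_id"].iloc[0]
    return {t: flags.loc[region, t] for t in flags.columns}


def assemble_feature_vector(
    *parts: Mapping[str, float],
    registry: Sequence[str] | None = None,
) -> pd.Series:
    """Merge feature-family dicts into the canonical 44-value vector.

    Duplicate or unknown feature names raise; features absent from every
    part (e.g. low-coverage methylation cells) propagate as NaN for
    downstream imputation.
    """
    if registry is None:
        registry = feature_registry()
    known = set(registry)
    merged: dict[str, float] = {}
    for part in parts:
        for name, value in part.items():
            if name not in known:
                raise KeyError(f"unknown feature name {name!r}")
            if name in merged:
                raise KeyError(f"duplicate feature name {name!r}")
            merged[name] = value
    values = [merged.get(name, np.nan) for name in registry]
    return pd.Series(values, index=list(registry), dtype=float)
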