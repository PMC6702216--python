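"""Tissue-level expression summaries and expression-conservation statistics.

Expression evidence arrives as a per-dataset FPKM value plus a presence
flag.  Replicate datasets collapse to a tissue for expression levels; for
expression breadth, developmental series (the two seed stages and the two
inflorescence stages) further collapse to a single tissue.  Percent
commonality between a pair of homologous regions is the fraction of their
jointly expressed tissues that are shared, computed over the five tissues
common to all species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "TissueLayout",
    "RICE_LAYOUT",
    "COMMONALITY_TISSUES",
    "ExpressionProfile",
    "tissue_level",
    "expression_breadth",
    "percent_commonality",
    "breadth_matched_exon_commonality",
    "random_commonality",
    "RegionExpression",
    "neighbor_expression_correlation",
]

#: Tissues shared by all four species, the universe for % commonality.
COMMONALITY_TISSUES = ("embryo", "endosperm", "seed", "leaf", "anther")


@dataclass(frozen=True)
class TissueLayout:
    """Dataset -> tissue grouping, plus the tissue -> breadth-group collapse.

    ``dataset_tissue`` maps every RNA-seq dataset to its tissue (replicates
    share a tissue); ``breadth_group`` maps each tissue to the collapsed
    group used for expression-breadth counting.
    """

    dataset_tissue: Mapping[str, str]
    breadth_group: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dataset_tissue", dict(self.dataset_tissue))
        object.__setattr__(self, "breadth_group", dict(self.breadth_group))
        missing = set(self.dataset_tissue.values()) - set(self.breadth_group)
        if missing:
            raise ValueError(f"tissues missing from breadth_group: {missing}")

    @property
    def datasets(self) -> tuple[str, ...]:
        return tuple(self.dataset_tissue)

    @property
    def tissues(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.dataset_tissue.values():
            seen.setdefault(t)
        return tuple(seen)

    @property
    def breadth_groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.tissues:
            seen.setdefault(self.breadth_group[t])
        return tuple(seen)

    def datasets_for(self, tissue: str) -> list[str]:
        if tissue not in self.breadth_group:
            raise KeyError(f"unknown tissue {tissue!r}")
        return [d for d, t in self.dataset_tissue.items() if t == tissue]


def _default_rice_layout() -> TissueLayout:
    # 11 datasets over 9 tissues; leaf and endosperm have replicates.
    dataset_tissue = {
        "leaf_1": "leaf",
        "leaf_2": "leaf",
        "endosperm_1": "endosperm",
        "endosperm_2": "endosperm",
        "embryo": "embryo",
        "anther": "anther",
        "seed_5dap": "seed_5dap",
        "seed_10dap": "seed_10dap",
        "inflorescence_early": "inflorescence_early",
        "inflorescence_emerging": "inflorescence_emerging",
        "root": "root",
    }
    breadth_group = {
        "leaf": "leaf",
        "endosperm": "endosperm",
        "embryo": "embryo",
        "anther": "anther",
        "seed_5dap": "seed",
        "seed_10dap": "seed",
        "inflorescence_early": "inflorescence",
        "inflorescence_emerging": "inflorescence",
        "root": "root",
    }
    return TissueLayout(dataset_tissue, breadth_group)


RICE_LAYOUT = _default_rice_layout()


@dataclass
class ExpressionProfile:
    """Per-dataset FPKM and presence for one region under a tissue layout."""

    region_id: str
    fpkm: dict[str, float]
    presence: dict[str, bool]
    layout: TissueLayout = field(default_factory=lambda: RICE_LAYOUT)

    def __post_init__(self) -> None:
        known = set(self.layout.datasets)
        for d, v in self.fpkm.items():
            if d not in known:
                raise KeyError(f"dataset {d!r} not in layout")
            if v < 0:
                raise ValueError(f"negative FPKM for dataset {d}")
        for d in self.presence:
            if d not in known:
                raise KeyError(f"dataset {d!r} not in layout")

    @classmethod
    def from_fpkm(
        cls, region_id: str, fpkm: Mapping[str, float], layout: TissueLayout = RICE_LAYOUT
    ) -> "ExpressionProfile":
        """Build a profile from an FPKM matrix row; presence proxied by
        FPKM > 0 when no assembled-fragment evidence is supplied."""
        fpkm = dict(fpkm)
        return cls(region_id, fpkm, {d: v > 0 for d, v in fpkm.items()}, layout)

    def expressed_in(self, dataset: str) -> bool:
        return bool(self.presence.get(dataset, False))

    def value(self, dataset: str) -> float:
        return self.fpkm.get(dataset, 0.0)


def tissue_level(profile: ExpressionProfile, tissue: str) -> float:
    """Expression level of a tissue: mean FPKM over replicate datasets with
    presence evidence; the single value when only one replicate is expressed;
    0 when the region is expressed in none."""
    datasets = profile.layout.datasets_for(tissue)
    values = [profile.value(d) for d in datasets if profile.expressed_in(d)]
    if not values:
        return 0.0
    return float(np.mean(values))


def expression_breadth(profile: ExpressionProfile) -> int:
    """Number of distinct collapsed tissues with presence in at least one
    constituent dataset."""
    groups = set()
    for d in profile.layout.datasets:
        if profile.expressed_in(d):
            tissue = profile.layout.dataset_tissue[d]
            groups.add(profile.layout.breadth_group[tissue])
    return len(groups)


def expressed_tissue_set(
    profile: ExpressionProfile, universe: Sequence[str] = COMMONALITY_TISSUES
) -> set[str]:
    """Collapsed tissues (restricted to the shared universe) with presence
    evidence in at least one dataset."""
    groups = set()
    for d in profile.layout.datasets:
        if profile.expressed_in(d):
            tissue = profile.layout.dataset_tissue[d]
            groups.add(profile.layout.breadth_group[tissue])
    return groups & set(universe)


def percent_commonality(tissues_a: set[str], tissues_b: set[str]) -> float:
    """Shared expressed tissues as a percent of all expressed tissues for the
    pair (union denominator, so the statistic is symmetric and bounded)."""
    if not tissues_a or not tissues_b:
        raise ValueError("both tissue sets must be non-empty")
    union = tissues_a | tissues_b
    return 100.0 * len(tissues_a & tissues_b) / len(union)


def breadth_matched_exon_commonality(
    query_breadths: Sequence[tuple[int, int]],
    exon_pairs: Sequence[tuple[set[str], set[str]]],
    per_query: int = 2,
    seed: int | None = None,
) -> list[float]:
    """Percent commonality of exon control pairs breadth-matched to query
    pairs.

    For each query pair's unordered breadths (b1, b2), ``per_query`` exon
    pairs with identical unordered breadths are sampled without replacement
    and their % commonality returned.  Queries with no matching exon pair are
    skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    pool: dict[tuple[int, int], list[int]] = {}
    for i, (a, b) in enumerate(exon_pairs):
        key = tuple(sorted((len(a), len(b))))
        pool.setdefault(key, []).append(i)
    out: list[float] = []
    for b1, b2 in query_breadths:
        key = tuple(sorted((int(b1), int(b2))))
        candidates = pool.get(key, [])
        if not candidates:
            logger.warning("no breadth-matched exon pair for breadths %s", key)
            continue
        take = min(per_query, len(candidates))
        chosen = rng.choice(len(candidates), size=take, replace=False)
        for j in chosen:
            a, b = exon_pairs[candidates[int(j)]]
            # matched pairs preserve the query breadth by construction
            assert tuple(sorted((len(a), len(b)))) == key
            out.append(percent_commonality(a, b))
    return out


def random_commonality(
    breadth_pair: tuple[int, int],
    tissue_freqs: Mapping[str, float],
    n: int = 25,
    seed: int | None = None,
) -> list[float]:
    """Random expectation of % commonality for a breadth pair.

    For each of ``n`` replicates, two random tissue sets of sizes b1 and b2
    are drawn without replacement with probabilities proportional to how
    often each tissue appears among expression-conserved regions.
    """
    b1, b2 = breadth_pair
    tissues = list(tissue_freqs)
    weights = np.array([tissue_freqs[t] for t in tissues], dtype=float)
    if (weights <= 0).any():
        raise ValueError("tissue weights must be positive")
    if not (1 <= b1 <= len(tissues)) or not (1 <= b2 <= len(tissues)):
        raise ValueError("breadth exceeds tissue universe")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        a = set(rng.choice(tissues, size=b1, replace=False, p=weights))
        b = set(rng.choice(tissues, size=b2, replace=False, p=weights))
        out.append(percent_commonality(a, b))
    return out


@dataclass(frozen=True)
class RegionExpression:
    """A region with its interval, kind, strand, and tissue-level expression
    vector, as used for neighbor-correlation profiles."""

    region_id: str
    interval: GenomicInterval
    kind: str  # gene | pseudogene | itr
    expression: tuple[float, ...]
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"gene", "pseudogene", "itr"}:
            raise ValueError(f"invalid kind {self.kind!r}")


def _pair_category(a: RegionExpression, b: RegionExpression) -> str | None:
    left, right = (a, b) if a.interval.start <= b.interval.start else (b, a)
    kinds = {a.kind, b.kind}
    if a.kind == "gene" and b.kind == "gene":
        if a.gene_id is not None and a.gene_id == b.gene_id:
            return "within_gene"
        if left.interval.strand == right.interval.strand:
            return "gene_gene_tandem"
        if left.interval.strand == "-" and right.interval.strand == "+":
            return "gene_gene_head_to_head"
        return "gene_gene_tail_to_tail"
    if kinds == {"gene", "itr"} or kinds == {"gene", "pseudogene"}:
        gene, other = (a, b) if a.kind == "gene" else (b, a)
        other_kind = "itr" if other.kind == "itr" else "pseudo"
        if gene.interval.strand == "-":
            upstream = other.interval.start >= gene.interval.end
        else:
            upstream = other.interval.end <= gene.interval.start
        side = "up" if upstream else "down"
        return f"gene_{other_kind}_{side}"
    if kinds == {"itr"}:
        return "itr_itr"
    return None


def _pcc(x: Sequence[float], y: Sequence[float]) -> float | None:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def neighbor_expression_correlation(
    regions: Sequence[RegionExpression],
    distance_bins: Sequence[int] = (0, 500, 2000, 10_000),
    n_random: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Median expression correlation between neighboring region pairs.

    Adjacent regions along each chromosome form pairs, categorized as
    within-gene, gene/gene (tandem, head-to-head, tail-to-tail), gene/ITR
    (up/downstream), gene/pseudogene (up/downstream), or ITR/ITR, and binned
    by the gap between them.  Pairs with a zero-variance expression vector
    are excluded.  A ``random`` bin holds the median over up to ``n_random``
    randomly drawn pairs of the same category.
    """
    rng = np.random.default_rng(seed)
    edges = list(distance_bins) + [np.inf]
    rows: list[dict] = []
    by_chrom: dict[str, list[RegionExpression]] = {}
    for r in regions:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    pcc_by_cat_bin: dict[tuple[str, str], list[float]] = {}
    categories: set[str] = set()
    for chrom_regions in by_chrom.values():
        ordered = sorted(chrom_regions, key=lambda r: (r.interval.start, r.interval.end))
        for a, b in zip(ordered, ordered[1:]):
            cat = _pair_category(a, b)
            if cat is None:
                continue
            categories.add(cat)
            pcc = _pcc(a.expression, b.expression)
            if pcc is None:
                continue
            gap = max(0, b.interval.start - a.interval.end)
            for lo, hi in zip(edges, edges[1:]):
                if lo <= gap < hi:
                    label = f"[{lo},{hi})"
                    break
            pcc_by_cat_bin.setdefault((cat, label), []).append(pcc)
    # random baseline: same-category pairs drawn from the full region set
    all_regions = list(regions)
    for cat in sorted(categories):
        values: list[float] = []
        attempts = 0
        while len(values) < n_random and attempts < 10 * n_random:
            attempts += 1
            i, j = rng.integers(0, len(all_regions), size=2)
            if i == j:
                continue
            a, b = all_regions[int(i)], all_regions[int(j)]
            if _pair_category(a, b) != cat:
                continue
            pcc = _pcc(a.expression, b.expression)
            if pcc is not None:
                values.append(pcc)
        if values:
            pcc_by_cat_bin[(cat, "random")] = values
    for (cat, label), values in sorted(pcc_by_cat_bin.items()):
        rows.append(
            {
                "category": cat,
                "bin": label,
                "n_pairs": len(values),
                "median_pcc": float(np.median(values)),
            }
        )
    return pd.DataFrame(rows, columns=["category", "bin", "n_pairs", "median_pcc"])
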