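import numpy as np
import pandas as pd
import pytest

from itrpred.conservation import (
    call_conserved,
    empirical_conservation_threshold,
)
from itrpred.features import feature_registry
from itrpred.regions import classify_region
from itrpred.simulate import (
    ScenarioConfig,
    generate_annotation,
    generate_feature_table,
    generate_match_tables,
    generate_methylation,
    generate_peaks,
    generate_transcription,
)


@pytest.fixture(scope="module")
def small_config() -> ScenarioConfig:
    return ScenarioConfig(
        n_chromosomes=1,
        chromosome_length=300_000,
        n_genes=80,
        n_pseudogenes=20,
        n_itrs=60,
        n_null=300,
    )


@pytest.fixture(scope="module")
def annotation_genome(small_config):
    return generate_annotation(small_config, seed=3)


class TestGenerateAnnotation:
    def test_requested_counts_and_invariants(self, small_config, annotation_genome):
        annotation, genome = annotation_genome
        assert len(annotation.genes) == small_config.n_genes
        assert len(annotation.pseudogenes) > 0
        for gene in annotation.genes:
            assert gene.span.end <= annotation.chrom_lengths[gene.chrom]
        assert len(genome["chr1"]) == small_config.chromosome_length

    def test_unmappable_derived_from_sequence(self, annotation_genome):
        annotation, genome = annotation_genome
        for iv in annotation.unmappable:
            run = genome[iv.chrom][iv.start : iv.end]
            assert set(run) == {"N"}
            assert iv.length >= 40

    def test_same_seed_reproduces_byte_identical_output(self, small_config):
        a1, g1 = generate_annotation(small_config, seed=5)
        a2, g2 = generate_annotation(small_config, seed=5)
        assert g1 == g2
        assert [g.exons for g in a1.genes] == [g.exons for g in a2.genes]

    def test_zero_genes_gives_pure_intergenic_genome(self):
        config = ScenarioConfig(
            n_chromosomes=1, chromosome_length=100_000, n_genes=0,
            n_pseudogenes=0, n_itrs=10,
        )
        annotation, _ = generate_annotation(config, seed=1)
        labels = annotation.space_labels("chr1")
        assert set(np.unique(labels)) <= {-1, 0}

    def test_infeasible_packing_errors(self):
        config = ScenarioConfig(
            n_chromosomes=1, chromosome_length=20_000, n_genes=500
        )
        with pytest.raises(RuntimeError):
            generate_annotation(config, seed=1)


@pytest.fixture(scope="module")
def tx(small_config, annotation_genome):
    annotation, genome = annotation_genome
    return generate_transcription(annotation, genome, small_config, seed=3)


class TestGenerateTranscription:
    def test_planted_classes_match_classifier(self, tx, annotation_genome):
        annotation, _ = annotation_genome
        for region in tx.regions:
            assert classify_region(region.interval, annotation) == region.region_class

    def test_itrs_shorter_than_exon_fragments(self, tx):
        lengths = pd.DataFrame(
            {
                "length": [r.interval.length for r in tx.regions],
                "cls": [r.region_class for r in tx.regions],
            }
        )
        medians = lengths.groupby("cls")["length"].median()
        assert medians["intergenic"] < medians["exon"]

    def test_itrs_narrower_and_lower_than_exons(self, tx):
        breadth = tx.presence.sum(axis=1)
        level = tx.fpkm.max(axis=1)
        cls = tx.truth
        assert breadth[cls == "intergenic"].mean() < breadth[cls == "exon"].mean()
        assert (
            level[cls == "intergenic"].median() < level[cls == "exon"].median()
        )

    def test_fragments_merge_back_to_regions(self, tx):
        from itrpred.regions import merge_fragments

        all_frags = [f for frags in tx.fragments.values() for f in frags]
        merged, _ = merge_fragments(all_frags)
        region_ivs = {
            (r.interval.chrom, r.interval.start, r.interval.end)
            for r in tx.regions
            if any(r.presence.values())
        }
        # every merged fragment lies within exactly one planted region
        for m in merged:
            hosts = [
                r
                for r in tx.regions
                if r.interval.chrom == m.chrom
                and r.interval.start <= m.start
                and m.end <= r.interval.end
            ]
            assert len(hosts) == 1
        assert len(merged) <= len(region_ivs) + 1

    def test_presence_false_implies_zero_fpkm(self, tx):
        assert ((tx.fpkm.values > 0) <= tx.presence.values).all()


class TestGenerateMatchTables:
    def test_planted_fraction_within_binomial_interval(self, small_config):
        classes = pd.Series(["intergenic"] * 2000, index=[f"q{i}" for i in range(2000)])
        config = ScenarioConfig(conserved_fraction={"intergenic": 0.30})
        sim = generate_match_tables(config, classes, seed=4)
        frac = len(sim.planted_conserved) / len(classes)
        # 3-sigma binomial interval around 0.30 at n = 2000
        assert abs(frac - 0.30) < 3 * np.sqrt(0.3 * 0.7 / 2000)

    def test_zero_fraction_plants_nothing(self):
        classes = pd.Series(["intergenic"] * 100)
        config = ScenarioConfig(conserved_fraction={"intergenic": 0.0})
        sim = generate_match_tables(config, classes, seed=4)
        assert sim.planted_conserved == set()

    def test_planted_hits_exceed_null_threshold(self, small_config):
        classes = pd.Series(["exon"] * 300, index=[f"q{i}" for i in range(300)])
        sim = generate_match_tables(small_config, classes, seed=6)
        thr = empirical_conservation_threshold(sim.null_best)
        for rid in sim.planted_conserved:
            assert call_conserved(sim.query_best[rid], thr)

    def test_ancient_weight_zero_keeps_k_recent(self):
        classes = pd.Series(["exon"] * 400)
        config = ScenarioConfig(ancient_weight=0.0, duplicate_fraction=1.0)
        sim = generate_match_tables(config, classes, seed=8)
        assert (sim.duplicates.k < 0.7).all()
        assert not sim.duplicates.is_ancient.any()


class TestGenerateFeatureTable:
    def test_registry_columns_and_missingness(self, small_config):
        labels = pd.Series(
            ["phenotype_exon"] * 50
            + ["transcribed_pseudogene"] * 50
            + ["transcribed_miRNA"] * 20,
            index=[f"b{i}" for i in range(120)],
        )
        table = generate_feature_table(labels, small_config, seed=2)
        assert list(table.columns) == feature_registry()
        meth_cols = [c for c in table.columns if c.startswith(("meth_", "gbm_"))]
        other_cols = [c for c in table.columns if c not in meth_cols]
        assert table[other_cols].notna().all().all()
        assert table[meth_cols].isna().any().any()

    def test_zero_missingness_gives_complete_table(self):
        config = ScenarioConfig(missingness=0.0)
        labels = pd.Series(["phenotype_exon"] * 30)
        table = generate_feature_table(labels, config, seed=2)
        assert table.notna().all().all()

    def test_class_directions_follow_configuration(self, small_config):
        labels = pd.Series(
            ["phenotype_exon"] * 200 + ["transcribed_pseudogene"] * 200,
            index=[f"b{i}" for i in range(400)],
        )
        table = generate_feature_table(labels, small_config, seed=2)
        exon = table[labels.values == "phenotype_exon"]
        pseudo = table[labels.values == "transcribed_pseudogene"]
        assert exon["expr_breadth"].mean() > pseudo["expr_breadth"].mean()
        assert exon["cons_logE"].mean() > pseudo["cons_logE"].mean()
        assert exon["hist_n_activation"].mean() > pseudo["hist_n_activation"].mean()

    def test_zero_effects_remove_class_differences(self):
        config = ScenarioConfig(
            feature_effect={
                "transcription": 0.0,
                "conservation": 0.0,
                "chromatin": 0.0,
                "methylation": 0.0,
            },
            missingness=0.0,
        )
        labels = pd.Series(
            ["phenotype_exon"] * 300 + ["transcribed_pseudogene"] * 300,
            index=[f"b{i}" for i in range(600)],
        )
        table = generate_feature_table(labels, config, seed=2)
        exon = table[labels.values == "phenotype_exon"]
        pseudo = table[labels.values == "transcribed_pseudogene"]
        diff = (exon.mean() - pseudo.mean()) / table.std().replace(0, 1)
        assert diff.abs().max() < 0.25  # no systematic separation

    def test_unknown_class_errors(self, small_config):
        with pytest.raises(ValueError):
            generate_feature_table(pd.Series(["exonic"]), small_config, seed=1)


class TestGenerateMethylation:
    def test_reads_below_minimum_yield_missing_levels(self):
        from itrpred.features import methylation_level

        config = ScenarioConfig(meth_coverage_ok_fraction=0.0)
        sim = generate_methylation([f"r{i}" for i in range(20)], config, seed=3)
        levels = [
            methylation_level(r.methylated, r.total, r.sites)
            for r in sim.counts.itertuples()
        ]
        assert all(lv is None for lv in levels)

    def test_gbm_subset_fraction(self):
        config = ScenarioConfig(gbm_fraction=0.3)
        ids = [f"r{i}" for i in range(1000)]
        sim = generate_methylation(ids, config, seed=3)
        frac = len(sim.gbm_true) / len(ids)
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 1000)


class TestGeneratePeaks:
    def test_extreme_overlap_probabilities(self, annotation_genome):
        from itrpred.features import chromatin_features

        regions = [
            (f"r{i}", iv, "exon")
            for i, iv in enumerate(
                [g.exons[0] for g in annotation_genome[0].genes[:20]]
            )
        ]
        config = ScenarioConfig()
        peaks = generate_peaks(regions, config, seed=1)
        # activation marks overlap exon regions at 0.8 per mark: nearly every
        # region is covered by at least one of the eight
        covered = 0
        for _, iv, _ in regions:
            feats = chromatin_features(iv, peaks, mnase_depth=0.0)
            if feats["hist_n_activation"] > 0:
                covered += 1
        assert covered >= len(regions) - 1

    def test_fixed_seed_reproducible(self, annotation_genome):
        regions = [("r0", annotation_genome[0].genes[0].exons[0], "exon")]
        config = ScenarioConfig()
        a = generate_peaks(regions, config, seed=9)
        b = generate_peaks(regions, config, seed=9)
        assert a == b
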