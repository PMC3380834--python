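"""Gene association, feature profiles, and expression analytics."""

import numpy as np
import pandas as pd
import pytest

from occudiff.annotate import (
    GeneModel,
    associate_regions_to_genes,
    closest_tss,
    closest_tss_table,
    expression_change_by_class,
    expression_profile,
    feature_masks,
    feature_profile,
    mean_change_by_geneset,
)
from occudiff.classify import ClassifiedRegion
from occudiff.peaks import BoundRegion


def gene(gene_id, tss, start=None, end=None, seq="chr", strand="+", **kw):
    if start is None:
        start = tss if strand == "+" else tss - 1999
    if end is None:
        end = start + 2000
    return GeneModel(
        gene_id=gene_id, seq=seq, strand=strand, tss=tss,
        start=start, end=end, **kw,
    )


def peak(center, seq="chr", value=3.0, half=200):
    return BoundRegion(seq, center - half, center + half, value, center, 5)


def classified(region, label, value_b=None, delta=None):
    vb = value_b if value_b is not None else region.peak_value
    d = delta if delta is not None else vb - region.peak_value
    return ClassifiedRegion(region, vb, d, label)


class TestClosestTss:
    def test_center_on_tss(self):
        genes = [gene("g1", 1000), gene("g2", 5000)]
        assert closest_tss(peak(1000), genes).gene_id == "g1"

    def test_nearest_wins(self):
        genes = [gene("g1", 1000), gene("g2", 5000)]
        assert closest_tss(peak(1400), genes).gene_id == "g1"
        assert closest_tss(peak(3500), genes).gene_id == "g2"

    def test_tie_goes_to_smaller_tss(self):
        genes = [gene("g2", 2000), gene("g1", 1000)]
        assert closest_tss(peak(1500), genes).gene_id == "g1"

    def test_no_gene_on_sequence(self):
        assert closest_tss(peak(1000, seq="chrX"), [gene("g1", 1000)]) is None

    def test_matches_exhaustive_scan_and_permutation_invariance(self):
        rng = np.random.default_rng(10)
        genes = [gene(f"g{i}", int(t))
                 for i, t in enumerate(sorted(rng.integers(2000, 500_000, 100)))]
        peaks = [peak(int(c)) for c in rng.integers(2000, 500_000, 100)]
        shuffled = list(genes)
        rng.shuffle(shuffled)
        for p in peaks:
            best = min(genes, key=lambda g: (abs(g.tss - p.peak_center), g.tss))
            assert closest_tss(p, genes).gene_id == best.gene_id
            assert closest_tss(p, shuffled).gene_id == best.gene_id

    def test_table_reports_signed_distance(self):
        tab = closest_tss_table([peak(1400)], [gene("g1", 1000)])
        assert tab.loc[0, "gene_id"] == "g1"
        assert tab.loc[0, "tss_distance"] == 400


TOY_GENOME = {"chr": 20_000}


def toy_genes():
    # two genes; g1 on + with one intron, g2 on - single exon
    g1 = GeneModel(
        "g1", "chr", "+", tss=2000, start=2000, end=5000,
        exons=((2000, 3000), (4000, 5000)), introns=((3000, 4000),),
        coding=((2200, 3000), (4000, 4800)),
        utr5=((2000, 2200),), utr3=((4800, 5000),),
    )
    g2 = GeneModel(
        "g2", "chr", "-", tss=11_999, start=10_000, end=12_000,
        exons=((10_000, 12_000),),
    )
    return [g1, g2]


class TestFeatureProfile:
    def test_masks_have_hand_computed_coverage(self):
        masks = feature_masks(toy_genes(), TOY_GENOME, 500)
        # promoters: [1500,2501) and [11499,12500) -> 2002 nt
        assert int(masks["promoter"]["chr"].sum()) == 2002
        assert int(masks["intron"]["chr"].sum()) == 1000
        assert int(masks["transcript"]["chr"].sum()) == 5000
        # intergenic = genome - (transcripts U promoters);
        # overlaps: promoter inside g1 span [2000,2501) = 501,
        # inside g2 span [11499,12000) = 501
        union = 5000 + 2002 - 1002
        assert int(masks["intergenic"]["chr"].sum()) == 20_000 - union

    def test_partition_of_genome(self):
        masks = feature_masks(toy_genes(), TOY_GENOME, 500)
        covered = (
            masks["promoter"]["chr"] | masks["exon"]["chr"]
            | masks["intron"]["chr"] | masks["intergenic"]["chr"]
        )
        assert covered.all()
        assert not (masks["intergenic"]["chr"] & masks["transcript"]["chr"]).any()

    def test_region_inside_intron_counts_for_intron_only(self):
        prof = feature_profile([peak(3500, half=100)], toy_genes(), TOY_GENOME)
        assert prof.loc["intron", "pct_regions"] == 100.0
        assert prof.loc["promoter", "pct_regions"] == 0.0
        assert prof.loc["intergenic", "pct_regions"] == 0.0

    def test_whole_genome_region_hits_every_feature(self):
        whole = BoundRegion("chr", 0, 20_000, 1.0, 100, 5)
        prof = feature_profile([whole], toy_genes(), TOY_GENOME)
        assert (prof["pct_regions"] == 100.0).all()

    def test_genome_fractions(self):
        prof = feature_profile([], toy_genes(), TOY_GENOME)
        assert prof.loc["intron", "genome_fraction"] == pytest.approx(0.05)
        assert prof.loc["promoter", "genome_fraction"] == pytest.approx(
            2002 / 20_000
        )

    def test_promoter_includes_both_endpoints(self):
        masks = feature_masks([gene("g1", 2000)], TOY_GENOME, 500)
        pm = masks["promoter"]["chr"]
        assert pm[1500] and pm[2500]
        assert not pm[1499] and not pm[2501]


class TestAssociateRegions:
    def test_overlap_and_gap_rules(self):
        g = gene("g1", 5000, start=5000, end=8000)
        near = BoundRegion("chr", 4100, 4600, 2.0, 4300, 5)   # 400 bp away
        far = BoundRegion("chr", 3999, 4499, 2.0, 4200, 5)    # 501 bp away
        inside = BoundRegion("chr", 6000, 6300, 2.0, 6100, 5)
        links = associate_regions_to_genes([near, far, inside], [g], 500)
        assert links["g1"] == [0, 2]

    def test_matches_bruteforce_distance_scan(self):
        rng = np.random.default_rng(21)
        genes = [
            gene(f"g{i}", int(s), start=int(s), end=int(s) + 1500)
            for i, s in enumerate(rng.integers(2000, 400_000, 60))
        ]
        regions = [peak(int(c)) for c in rng.integers(0, 400_000, 120)]
        links = associate_regions_to_genes(regions, genes, 500)
        for g in genes:
            expected = [
                i for i, r in enumerate(regions)
                if max(g.start - r.end, r.start - g.end, 0) <= 500
            ]
            assert links.get(g.gene_id, []) == expected


class TestExpressionProfile:
    def _setup(self, noise_rng=None):
        genes = [gene(f"g{i}", 1000 + 10_000 * i) for i in range(8)]
        trends = {
            "up": [8.0, 7.0], "unchanged": [7.0, 6.5],
            "down": [5.0, 6.0], "lost": [3.0, 5.0],
        }
        labels = ["up", "unchanged", "down", "lost"] * 2
        rows, classified_regions = {}, []
        for i, (g, label) in enumerate(zip(genes, labels)):
            rows[g.gene_id] = trends[label]
            classified_regions.append(
                classified(peak(g.tss + 100), label)
            )
        expr = pd.DataFrame.from_dict(
            rows, orient="index", columns=["T0", "T1"]
        )
        return classified_regions, genes, expr, trends

    def test_zero_noise_recovers_class_trends_exactly(self):
        classified_regions, genes, expr, trends = self._setup()
        prof = expression_profile(classified_regions, genes, expr)
        for label, (m0, m1) in trends.items():
            sub = prof[prof["label"] == label].set_index("timepoint")
            assert sub.loc["T0", "mean"] == pytest.approx(m0)
            assert sub.loc["T1", "mean"] == pytest.approx(m1)
            assert sub.loc["T0", "n_genes"] == 2

    def test_gene_counted_once_per_class(self):
        genes = [gene("g1", 1000)]
        expr = pd.DataFrame({"T0": [5.0]}, index=["g1"])
        regions = [
            classified(peak(900), "up"),
            classified(peak(1100), "up"),   # same closest gene, same class
        ]
        prof = expression_profile(regions, genes, expr)
        assert prof[prof["label"] == "up"]["n_genes"].iloc[0] == 1

    def test_single_gene_class_has_undefined_ci(self):
        genes = [gene("g1", 1000)]
        expr = pd.DataFrame({"T0": [5.0]}, index=["g1"])
        prof = expression_profile([classified(peak(1000), "down")], genes, expr)
        row = prof[(prof["label"] == "down")].iloc[0]
        assert row["n_genes"] == 1
        assert np.isnan(row["ci_low"])


class TestExpressionChange:
    def test_planted_signs_recovered(self):
        rng = np.random.default_rng(31)
        genes, regions, deltas = [], [], {}
        for i in range(120):
            label = ["up", "unchanged", "down", "lost"][i % 4]
            tss = 2000 + 3000 * i
            g = gene(f"g{i}", tss, start=tss, end=tss + 1000)
            genes.append(g)
            regions.append(classified(peak(tss + 500), label))
            shift = {"up": 1.0, "unchanged": 0.0, "down": -1.0, "lost": -1.0}
            deltas[g.gene_id] = shift[label] + rng.normal(0, 0.2)
        change = expression_change_by_class(
            regions, genes, pd.Series(deltas), 500
        )
        assert change.loc["up", "mean"] > 0.5
        assert abs(change.loc["unchanged", "mean"]) < 0.3
        assert change.loc["down", "mean"] < -0.5
        assert change.loc["up", "ci_low"] > change.loc["down", "ci_high"]

    def test_all_zero_changes(self):
        genes = [gene("g1", 1000), gene("g2", 8000, start=8000, end=9000)]
        regions = [classified(peak(1100), "up"), classified(peak(8200), "down")]
        delta = pd.Series({"g1": 0.0, "g2": 0.0})
        change = expression_change_by_class(regions, genes, delta, 500)
        assert change.loc["up", "mean"] == 0.0
        assert change.loc["down", "mean"] == 0.0


class TestMeanChangeByGeneset:
    def test_constant_delta_recovered(self):
        g = gene("g1", 5000, start=5000, end=6000)
        regions = [
            classified(peak(5200), "down", delta=-2.0),
            classified(peak(5800), "down", delta=-2.0),
        ]
        table = mean_change_by_geneset(regions, {"set1": ["g1"]}, [g], 500)
        assert table.loc["set1", "mean_delta"] == pytest.approx(-2.0)
        assert table.loc["set1", "n_regions"] == 2

    def test_opposite_sets_separate(self):
        rng = np.random.default_rng(41)
        genes, regions = [], []
        sets = {"gain": [], "loss": []}
        for i in range(100):
            tss = 2000 + 3000 * i
            g = gene(f"g{i}", tss, start=tss, end=tss + 1000)
            genes.append(g)
            if i % 2 == 0:
                sets["gain"].append(g.gene_id)
                d = 1.5 + rng.normal(0, 0.3)
            else:
                sets["loss"].append(g.gene_id)
                d = -1.5 + rng.normal(0, 0.3)
            regions.append(classified(peak(tss + 500), "unchanged", delta=d))
        table = mean_change_by_geneset(regions, sets, genes, 500)
        assert table.loc["gain", "mean_delta"] > 1.0
        assert table.loc["loss", "mean_delta"] < -1.0
        assert table.loc["gain", "ci_low"] > table.loc["loss", "ci_high"]

    def test_single_region_set_flagged(self):
        g = gene("g1", 5000, start=5000, end=6000)
        regions = [classified(peak(5200), "down", delta=-1.5)]
        table = mean_change_by_geneset(regions, {"s": ["g1"]}, [g], 500)
        assert np.isnan(table.loc["s", "ci_low"])

    def test_empty_set_flagged(self):
        table = mean_change_by_geneset([], {"s": ["gX"]}, [], 500)
        assert table.loc["s", "n_regions"] == 0
        assert np.isnan(table.loc["s", "mean_delta"])
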