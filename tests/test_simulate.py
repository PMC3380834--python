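"""Synthetic-data generator: coverage statistics, factor/HOT structure,
expression, and determinism."""

import numpy as np
import pytest

from occudiff.annotate import GeneModel
from occudiff.simulate import (
    ExpressionSpec,
    PlantedPeak,
    SimSpec,
    classes_from_planted,
    condition_b_spec,
    default_sim_spec,
    simulate_coverage,
    simulate_expression,
    simulate_expression_change,
    simulate_factor_sets,
    simulate_gene_models,
    write_artifacts,
)


def spec_100kb(seed=0, peaks=(), **kw):
    return SimSpec(
        genome_lengths={"chr": 100_000}, background_rate=10.0,
        planted_peaks=tuple(peaks), seed=seed, **kw,
    )


class TestCoverage:
    def test_background_means_near_rate(self):
        ip, inp = simulate_coverage(spec_100kb())
        assert ip.counts["chr"].mean() == pytest.approx(10.0, rel=0.05)
        assert inp.counts["chr"].mean() == pytest.approx(10.0, rel=0.05)

    def test_planted_ratio_matches_enrichment(self):
        peak = PlantedPeak("chr", 10_000, 11_000, 3.0)
        ip, inp = simulate_coverage(spec_100kb(peaks=[peak]))
        ratio = (
            ip.counts["chr"][10_000:11_000].mean()
            / inp.counts["chr"][10_000:11_000].mean()
        )
        assert ratio == pytest.approx(8.0, rel=0.2)

    def test_rectangular_profile_without_taper(self):
        peak = PlantedPeak("chr", 10_000, 11_000, 3.0)
        ip, _ = simulate_coverage(spec_100kb(peaks=[peak], summit_taper=0.0))
        inside = ip.counts["chr"][10_000:11_000]
        edge = inside[:100].mean()
        middle = inside[450:550].mean()
        assert edge == pytest.approx(middle, rel=0.2)

    def test_summit_taper_lowers_edges(self):
        peak = PlantedPeak("chr", 10_000, 20_000, 3.0)
        ip, _ = simulate_coverage(spec_100kb(peaks=[peak], summit_taper=1.0))
        inside = ip.counts["chr"][10_000:20_000]
        assert inside[:500].mean() < inside[4750:5250].mean()

    def test_same_seed_reproduces_bedgraph_bytes(self, tmp_path):
        from occudiff.io import write_bedgraph_coverage

        files = []
        for i in (1, 2):
            spec = default_sim_spec(42, genome_length=60_000, n_peaks=1)
            ip, _ = simulate_coverage(spec)
            path = tmp_path / f"ip{i}.bedgraph"
            write_bedgraph_coverage(ip, path)
            files.append(path.read_bytes())
        assert files[0] == files[1]

    def test_different_seeds_differ(self):
        a, _ = simulate_coverage(spec_100kb(seed=1))
        b, _ = simulate_coverage(spec_100kb(seed=2))
        assert not np.array_equal(a.counts["chr"], b.counts["chr"])

    def test_overlapping_planted_peaks_rejected(self):
        peaks = [
            PlantedPeak("chr", 1000, 2000, 3.0),
            PlantedPeak("chr", 1500, 2500, 3.0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            simulate_coverage(spec_100kb(peaks=peaks))

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="outside"):
            spec_100kb(peaks=[PlantedPeak("chr", 99_000, 101_000, 2.0)])
        with pytest.raises(ValueError, match="non-negative"):
            spec_100kb(peaks=[PlantedPeak("chr", 0, 100, -1.0)])
        with pytest.raises(ValueError, match="background_rate"):
            SimSpec(genome_lengths={"chr": 100}, background_rate=0.0)


class TestFactorSets:
    def test_independent_factors_overlap_near_random_expectation(self):
        from occudiff.overlap import percent_overlap

        pcts = []
        for seed in range(15):
            spec_s = SimSpec(
                genome_lengths={"chr": 1_000_000}, hotspot_fraction=0.0,
                n_factors=2, regions_per_factor=50, factor_region_width=200,
                seed=seed,
            )
            a, b = simulate_factor_sets(spec_s)[0][:2]
            pcts.append(percent_overlap(a, b))
        # P(one 200-bp region hits any of 50 others) ~ 1-(1-399/1e6)^50 ~ 2%
        expected = 100 * (1 - (1 - 399 / 1_000_000) ** 50)
        assert np.mean(pcts) == pytest.approx(expected, abs=2.0)

    def test_full_hotspot_fraction_makes_every_hot_region_deep(self):
        spec = SimSpec(
            genome_lengths={"chr": 500_000}, n_factors=5,
            regions_per_factor=20, hotspot_fraction=1.0, seed=3,
        )
        factors, hot, _ = simulate_factor_sets(spec)
        assert len(factors) == 5
        assert (hot.scores >= 5).all()

    def test_hotness_matches_bruteforce_recount(self):
        spec = SimSpec(
            genome_lengths={"chr": 30_000}, n_factors=3,
            regions_per_factor=8, factor_region_width=500,
            hotspot_fraction=0.5, seed=7,
        )
        factors, hot, _ = simulate_factor_sets(spec)
        cover = np.zeros(30_000, dtype=int)
        for fs in factors:
            for r in fs:
                cover[r.start: r.end] += 1
        for h in hot:
            segment = cover[h.start: h.end]
            assert (segment == h.score).all()
        # every covered nucleotide is inside some HOT region
        covered = np.zeros(30_000, dtype=bool)
        for h in hot:
            covered[h.start: h.end] = True
        assert np.array_equal(covered, cover >= 1)

    def test_truth_table_records_memberships(self):
        spec = SimSpec(
            genome_lengths={"chr": 200_000}, n_factors=4,
            regions_per_factor=10, hotspot_fraction=0.5, seed=1,
        )
        factors, _, truth = simulate_factor_sets(spec)
        assert len(truth) == 40
        assert truth["is_hotspot"].sum() == 4 * 5
        for fs in factors:
            sub = truth[truth["factor"] == fs.name]
            assert len(sub) == len(fs)


def toy_genes(n=50, spacing=4000):
    genes = []
    for i in range(n):
        s = 1000 + i * spacing
        genes.append(GeneModel(
            gene_id=f"g{i}", seq="chr", strand="+", tss=s, start=s, end=s + 2000,
        ))
    return genes


class TestExpression:
    def test_zero_noise_recovers_spec_exactly(self):
        espec = ExpressionSpec(
            timepoints=("T0", "T1"),
            class_means={"hi": (8.0, 6.0), "lo": (2.0, 4.0)},
            noise_sd=0.0,
        )
        spec = SimSpec(
            genome_lengths={"chr": 300_000}, expression_spec=espec, seed=5
        )
        table, truth = simulate_expression(spec, toy_genes())
        for gid, cls in truth.items():
            assert tuple(table.loc[gid]) == espec.class_means[cls]

    def test_sample_means_within_three_se(self):
        espec = ExpressionSpec(
            timepoints=("T0",), class_means={"only": (5.0,)}, noise_sd=0.5
        )
        spec = SimSpec(
            genome_lengths={"chr": 10_000_000}, expression_spec=espec, seed=6
        )
        genes = toy_genes(1000, spacing=6000)
        table, _ = simulate_expression(spec, genes)
        se = 0.5 / np.sqrt(1000)
        assert abs(table["T0"].mean() - 5.0) < 3 * se

    def test_separated_classes_have_disjoint_cis(self):
        from occudiff.annotate import mean_ci

        espec = ExpressionSpec(
            timepoints=("T0",),
            class_means={"a": (6.0,), "b": (4.0,)},
            noise_sd=0.1,
        )
        spec = SimSpec(
            genome_lengths={"chr": 2_000_000}, expression_spec=espec, seed=7
        )
        genes = toy_genes(200, spacing=6000)
        table, truth = simulate_expression(spec, genes)
        _, lo_a, _ = mean_ci(table.loc[truth[truth == "a"].index, "T0"].to_numpy())
        _, _, hi_b = mean_ci(table.loc[truth[truth == "b"].index, "T0"].to_numpy())
        assert lo_a > hi_b

    def test_missing_class_errors(self):
        spec = SimSpec(genome_lengths={"chr": 300_000}, seed=1)
        genes = toy_genes(3)
        with pytest.raises(ValueError, match="no expression class"):
            simulate_expression(spec, genes, classes={"g0": "up"})
        with pytest.raises(ValueError, match="unknown expression class"):
            simulate_expression(
                spec, genes,
                classes={g.gene_id: "nonesuch" for g in genes},
            )

    def test_change_follows_class_means(self):
        spec = SimSpec(genome_lengths={"chr": 300_000}, seed=2)
        classes = {"g1": "up", "g2": "down"}
        delta = simulate_expression_change(spec, classes)
        assert delta["g1"] > delta["g2"]


class TestConditionB:
    def test_class_shifts_applied(self):
        spec = default_sim_spec(0)
        spec_b = condition_b_spec(spec)
        by_label = {}
        for p in spec.planted_peaks:
            by_label.setdefault(p.label, []).append(p)
        b_spans = {(p.start, p.end): p for p in spec_b.planted_peaks}
        for p in by_label["lost"]:
            assert (p.start, p.end) not in b_spans
        for p in by_label["up"]:
            assert b_spans[(p.start, p.end)].log2_enrichment == \
                p.log2_enrichment + 2
        for p in by_label["down"]:
            assert b_spans[(p.start, p.end)].log2_enrichment == \
                p.log2_enrichment - 2
        for p in by_label["unchanged"]:
            assert b_spans[(p.start, p.end)].log2_enrichment == \
                p.log2_enrichment

    def test_condition_b_draws_are_independent(self):
        spec = default_sim_spec(0)
        ip_a, _ = simulate_coverage(spec)
        ip_b, _ = simulate_coverage(condition_b_spec(spec))
        bg = slice(0, 5000)  # before the first planted peak
        assert not np.array_equal(ip_a.counts["sim_chr"][bg],
                                  ip_b.counts["sim_chr"][bg])


class TestGeneModelsAndArtifacts:
    def test_gene_models_are_consistent(self):
        spec = SimSpec(genome_lengths={"chr": 400_000}, seed=9)
        genes = simulate_gene_models(spec, n_genes=40)
        assert len(genes) == 40
        for g in genes:
            tiled = sorted(g.exons + g.introns)
            assert tiled[0][0] == g.start and tiled[-1][1] == g.end
            for (s1, e1), (s2, e2) in zip(tiled, tiled[1:]):
                assert e1 == s2

    def test_classes_from_planted_uses_nearest_peak(self):
        spec = default_sim_spec(0)
        genes = simulate_gene_models(spec, n_genes=30)
        classes = classes_from_planted(spec, genes)
        for g in genes:
            nearest = min(
                spec.planted_peaks,
                key=lambda p: abs((p.start + p.end) // 2 - g.tss),
            )
            assert classes[g.gene_id] == nearest.label

    def test_write_artifacts_truth_pairing(self, tmp_path):
        spec = default_sim_spec(
            1, genome_length=80_000, n_peaks=2,
            n_factors=3, regions_per_factor=5,
        )
        paths = write_artifacts(spec, tmp_path)
        for key in ("ip", "input", "truth_peaks", "hot", "truth_factors",
                    "genes", "expression", "truth_expression", "genome"):
            assert key in paths
        import pandas as pd

        truth = pd.read_csv(paths["truth_peaks"], sep="\t")
        assert len(truth) == 2
        assert set(truth.columns) == {
            "seq", "start", "end", "log2_enrichment", "label"
        }
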