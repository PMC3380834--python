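"""End-to-end orchestration of the occupancy analysis on simulated data.

``run_pipeline`` composes every stage: simulate the two-condition
coverage pair, build and smooth the enrichment tracks, call bound
regions in condition A, requantify and classify them against condition
B, summarize classes against the simulated HOT regions, run the
factor-overlap analyses, and annotate regions with genes, features, and
expression. Every artifact is written under the output directory and
listed, with a SHA-256 content hash, in ``manifest.json`` — two runs of
the same configuration produce identical hashes.
"""

from __future__ import annotations

import hashlib
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as oio
from .annotate import (
    closest_tss_table,
    expression_change_by_class,
    expression_profile,
    feature_profile,
    mean_change_by_geneset,
)
from .classify import class_summary, classify_regions, foldchange_hotness_bins
from .config import PipelineConfig
from .overlap import RegionSet, cutoff_sweep, overlap_matrix, top_n
from .peaks import call_peaks
from .simulate import (
    SimSpec,
    classes_from_planted,
    condition_b_spec,
    default_sim_spec,
    planted_truth,
    simulate_coverage,
    simulate_expression,
    simulate_expression_change,
    simulate_factor_sets,
    simulate_gene_models,
)

logger = logging.getLogger("occudiff")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one full run needs."""

    outdir: Path
    sim: SimSpec
    cfg: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path, outdir: str | Path) -> "RunConfig":
        """Build from a TOML file with optional [pipeline] and [sim] tables."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        cfg = PipelineConfig(**data.get("pipeline", {}))
        sim_kwargs = dict(data.get("sim", {}))
        seed = int(sim_kwargs.pop("seed", 0))
        spec = default_sim_spec(seed=seed, **sim_kwargs)
        return cls(outdir=Path(outdir), sim=spec, cfg=cfg, seed=seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(run: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    outdir = Path(run.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = run.cfg
    logger.info("configuration: %s", cfg.to_dict())
    written: dict[str, Path] = {}

    def emit(name: str, filename: str) -> Path:
        p = outdir / filename
        written[name] = p
        return p

    def stage(name: str):
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        spec_a = run.sim
        spec_b = condition_b_spec(spec_a)
        ip_a, input_a = simulate_coverage(spec_a)
        ip_b, input_b = simulate_coverage(spec_b)
        oio.write_genome_lengths(spec_a.genome_lengths, emit("genome", "genome.tsv"))
        oio.write_bedgraph_coverage(ip_a, emit("ip_a", "condition_a_ip.bedgraph"))
        oio.write_bedgraph_coverage(input_a, emit("input_a", "condition_a_input.bedgraph"))
        oio.write_bedgraph_coverage(ip_b, emit("ip_b", "condition_b_ip.bedgraph"))
        oio.write_bedgraph_coverage(input_b, emit("input_b", "condition_b_input.bedgraph"))
        planted_truth(spec_a).to_csv(
            emit("truth_peaks", "truth_peaks.tsv"), sep="\t", index=False
        )

        stage("call-peaks")
        track_a, cutoff_a, regions_a = call_peaks(ip_a, input_a, cfg)
        track_b, cutoff_b, regions_b = call_peaks(ip_b, input_b, cfg)
        logger.info(
            "cutoffs: A=%.4f (%d regions), B=%.4f (%d regions)",
            cutoff_a, len(regions_a), cutoff_b, len(regions_b),
        )
        oio.write_bedgraph_ratio(track_a, emit("track_a", "condition_a_smoothed.bedgraph"))
        oio.write_bedgraph_ratio(track_b, emit("track_b", "condition_b_smoothed.bedgraph"))
        oio.write_peak_bed(regions_a, emit("peaks_a", "condition_a_peaks.bed"), "a")
        oio.write_peak_bed(regions_b, emit("peaks_b", "condition_b_peaks.bed"), "b")

        stage("classify")
        classified = classify_regions(regions_a, track_b, cfg)
        oio.write_classified_tsv(classified, emit("classified", "classified_regions.tsv"))
        # diagnostic: condition-B regions with no condition-A counterpart
        set_a = RegionSet.from_bound_regions("condition_a", regions_a)
        n_b_only = sum(
            not set_a.overlaps_any(r.seq, r.start, r.end) for r in regions_b
        )

        stage("overlap")
        factors, hot, factor_truth = simulate_factor_sets(spec_a)
        oio.write_hot_tsv(hot, emit("hot", "hot_regions.tsv"))
        factor_truth.to_csv(
            emit("truth_factors", "truth_factors.tsv"), sep="\t", index=False
        )
        summary = class_summary(classified, hot)
        summary.to_csv(emit("class_summary", "class_summary.tsv"), sep="\t")
        bins = foldchange_hotness_bins(classified, hot)
        bins.to_csv(emit("hotness_bins", "foldchange_hotness_bins.tsv"),
                    sep="\t", index=False)
        peak_set = RegionSet.from_bound_regions("peaks_a", regions_a)
        matrices = overlap_matrix([peak_set], factors, mode="top_n", cfg=cfg)
        matrices["query_in_target"].to_csv(
            emit("overlap_fwd", "overlap_peaks_in_factors.tsv"), sep="\t"
        )
        matrices["target_in_query"].to_csv(
            emit("overlap_rev", "overlap_factors_in_peaks.tsv"), sep="\t"
        )
        sweeps = []
        for fs in factors:
            target = top_n(fs, min(cfg.top_n, len(fs)))
            sw = cutoff_sweep(peak_set, target, cfg)
            sw.insert(0, "factor", fs.name)
            sweeps.append(sw)
        pd.concat(sweeps, ignore_index=True).to_csv(
            emit("sweeps", "cutoff_sweeps.tsv"), sep="\t", index=False
        )

        stage("annotate")
        genes = simulate_gene_models(spec_a)
        oio.write_gene_models_bed12(genes, emit("genes", "genes.bed"))
        gene_classes = classes_from_planted(spec_a, genes)
        expr, expr_truth = simulate_expression(spec_a, genes, classes=gene_classes)
        expr.to_csv(emit("expression", "expression.tsv"), sep="\t")
        expr_truth.to_csv(emit("truth_expression", "truth_expression.tsv"), sep="\t")
        tss_tab = closest_tss_table(regions_a, genes)
        oio.write_peak_table(regions_a, tss_tab, emit("peak_table", "peak_table.tsv"))
        features = feature_profile(
            regions_a, genes, spec_a.genome_lengths, cfg.promoter_halfwidth
        )
        features.to_csv(emit("features", "feature_profile.tsv"), sep="\t")
        profile = expression_profile(classified, genes, expr)
        profile.to_csv(emit("expr_profile", "expression_profile.tsv"),
                       sep="\t", index=False)
        delta_expr = simulate_expression_change(spec_a, gene_classes)
        change = expression_change_by_class(
            classified, genes, delta_expr, cfg.promoter_halfwidth
        )
        change.to_csv(emit("expr_change", "expression_change_by_class.tsv"), sep="\t")
        gene_sets = {
            "gain_class_genes": sorted(
                g for g, c in gene_classes.items() if c == "up"
            ),
            "loss_class_genes": sorted(
                g for g, c in gene_classes.items() if c in ("down", "lost")
            ),
        }
        geneset_change = mean_change_by_geneset(
            classified, gene_sets, genes, cfg.promoter_halfwidth
        )
        geneset_change.to_csv(
            emit("geneset_change", "occupancy_change_by_geneset.tsv"), sep="\t"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest = {
        "config": cfg.to_dict(),
        "seed": run.seed,
        "cutoff_a": cutoff_a,
        "cutoff_b": cutoff_b,
        "n_regions_a": len(regions_a),
        "n_regions_b": len(regions_b),
        "n_b_only_regions": n_b_only,
        "artifacts": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in sorted(written.items())
        },
    }
    oio.write_json(manifest, outdir / "manifest.json")
    return manifest
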