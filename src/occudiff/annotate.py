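"""Region annotation against genes, gene features, and expression.

Regions are tied to genes two ways, matching how the downstream analyses
use them: by the single closest transcription start site (TSS) to the
peak center (expression trajectories), and by span proximity — overlap
or a gap of at most 500 bp (expression-change comparisons). Gene
features are promoter (TSS +/- 500 bp, both endpoints included), intron,
coding, UTRs, and intergenic (the complement of transcript spans and
promoters); a region may overlap several features, so feature
percentages need not sum to 100. All confidence intervals are
normal-approximation 95% intervals (mean +/- 1.96 SE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import LABELS, ClassifiedRegion
from .peaks import BoundRegion

__all__ = [
    "GeneModel",
    "mean_ci",
    "closest_tss",
    "closest_tss_table",
    "feature_masks",
    "feature_profile",
    "associate_regions_to_genes",
    "expression_profile",
    "expression_change_by_class",
    "mean_change_by_geneset",
]

PLOTTED_FEATURES = ("promoter", "intron", "intergenic")

Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    """A gene with TSS, transcript span, and sub-features (0-based half-open)."""

    gene_id: str
    seq: str
    strand: str
    tss: int
    start: int
    end: int
    exons: tuple[Interval, ...] = ()
    introns: tuple[Interval, ...] = ()
    coding: tuple[Interval, ...] = ()
    utr5: tuple[Interval, ...] = ()
    utr3: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not self.start <= self.tss < self.end:
            raise ValueError(f"{self.gene_id}: TSS outside transcript span")
        for name in ("exons", "introns", "coding", "utr5", "utr3"):
            for s, e in getattr(self, name):
                if not (self.start <= s < e <= self.end):
                    raise ValueError(f"{self.gene_id}: {name} outside span")


def mean_ci(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, ci_low, ci_high); CI bounds NaN when n < 2."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.nan, np.nan, np.nan
    mean = float(values.mean())
    if values.size < 2:
        return mean, np.nan, np.nan
    se = float(values.std(ddof=1)) / np.sqrt(values.size)
    return mean, mean - 1.96 * se, mean + 1.96 * se


def closest_tss(region: BoundRegion, genes: list[GeneModel]) -> GeneModel | None:
    """The gene whose TSS is nearest the region's peak center.

    Distance is strand-independent; ties go to the smaller TSS
    coordinate. Returns None when no gene lies on the region's sequence.
    """
    candidates = [g for g in genes if g.seq == region.seq]
    if not candidates:
        return None
    return min(candidates, key=lambda g: (abs(g.tss - region.peak_center), g.tss))


def closest_tss_table(
    regions: list[BoundRegion], genes: list[GeneModel]
) -> pd.DataFrame:
    """Per-region closest gene and signed distance (center - TSS)."""
    rows = []
    for r in regions:
        g = closest_tss(r, genes)
        if g is None:
            rows.append((r.seq, r.start, r.end, r.peak_center, None, np.nan))
        else:
            rows.append(
                (r.seq, r.start, r.end, r.peak_center, g.gene_id,
                 r.peak_center - g.tss)
            )
    return pd.DataFrame(
        rows,
        columns=["seq", "start", "end", "peak_center", "gene_id", "tss_distance"],
    )


def _paint(mask: np.ndarray, intervals: list[Interval]) -> None:
    for s, e in intervals:
        mask[max(s, 0): min(e, mask.size)] = True


def feature_masks(
    genes: list[GeneModel],
    genome_lengths: dict[str, int],
    promoter_halfwidth: int = 500,
) -> dict[str, dict[str, np.ndarray]]:
    """Dense boolean masks per feature per sequence.

    Overlapping gene models are unioned. The promoter covers
    ``[TSS - halfwidth, TSS + halfwidth]`` inclusive (half-open
    ``[TSS-500, TSS+501)`` at defaults); ``intergenic`` is the complement
    of transcript spans and promoters.
    """
    features = ("promoter", "intron", "coding", "utr5", "utr3", "exon", "transcript")
    masks: dict[str, dict[str, np.ndarray]] = {
        f: {seq: np.zeros(n, dtype=bool) for seq, n in genome_lengths.items()}
        for f in features
    }
    for g in genes:
        if g.seq not in genome_lengths:
            raise ValueError(f"gene {g.gene_id} on unknown sequence {g.seq!r}")
        _paint(
            masks["promoter"][g.seq],
            [(g.tss - promoter_halfwidth, g.tss + promoter_halfwidth + 1)],
        )
        _paint(masks["transcript"][g.seq], [(g.start, g.end)])
        _paint(masks["intron"][g.seq], list(g.introns))
        _paint(masks["coding"][g.seq], list(g.coding))
        _paint(masks["utr5"][g.seq], list(g.utr5))
        _paint(masks["utr3"][g.seq], list(g.utr3))
        _paint(masks["exon"][g.seq], list(g.exons))
    masks["intergenic"] = {
        seq: ~(masks["transcript"][seq] | masks["promoter"][seq])
        for seq in genome_lengths
    }
    return masks


def feature_profile(
    regions: list[BoundRegion],
    genes: list[GeneModel],
    genome_lengths: dict[str, int],
    promoter_halfwidth: int = 500,
) -> pd.DataFrame:
    """Percent of regions overlapping each gene feature, plus genome baseline.

    ``pct_regions`` is the percent of regions overlapping the feature by
    at least one nucleotide (features are not mutually exclusive);
    ``genome_fraction`` is the feature's share of total genome length,
    the baseline expected for randomly placed regions. Coding and UTR
    rows are computed alongside the plotted promoter / intron /
    intergenic rows.
    """
    masks = feature_masks(genes, genome_lengths, promoter_halfwidth)
    total_len = sum(genome_lengths.values())
    rows = []
    for feature in ("promoter", "intron", "intergenic", "coding", "utr5", "utr3"):
        fmask = masks[feature]
        if regions:
            n_hit = sum(
                bool(fmask[r.seq][r.start: r.end].any()) for r in regions
            )
            pct = 100.0 * n_hit / len(regions)
        else:
            pct = np.nan
        frac = sum(int(m.sum()) for m in fmask.values()) / total_len
        rows.append((feature, pct, frac))
    return pd.DataFrame(
        rows, columns=["feature", "pct_regions", "genome_fraction"]
    ).set_index("feature")


def _gap(r_start: int, r_end: int, g_start: int, g_end: int) -> int:
    """Nucleotides separating two half-open intervals; 0 when overlapping."""
    if r_start < g_end and g_start < r_end:
        return 0
    return g_start - r_end if g_start >= r_end else r_start - g_end


def associate_regions_to_genes(
    regions: list[BoundRegion] | list[ClassifiedRegion],
    genes: list[GeneModel],
    max_distance: int = 500,
) -> dict[str, list[int]]:
    """gene_id -> indices of regions overlapping the gene span or within
    ``max_distance`` bp of it (strictly more than ``max_distance`` away is
    not linked)."""
    links: dict[str, list[int]] = {}
    for g in genes:
        hits = [
            i
            for i, r in enumerate(regions)
            if r.seq == g.seq and _gap(r.start, r.end, g.start, g.end) <= max_distance
        ]
        if hits:
            links[g.gene_id] = hits
    return links


def expression_profile(
    classified: list[ClassifiedRegion],
    genes: list[GeneModel],
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Mean log2 expression per class per time point, with 95% CI.

    Each region is associated with its closest TSS; a gene associated
    with several regions of the same class is counted once for that
    class (but contributes to every class that reaches it). Genes absent
    from the expression table are skipped. Columns: ``label``,
    ``timepoint``, ``n_genes``, ``mean``, ``ci_low``, ``ci_high``.
    """
    class_genes: dict[str, set[str]] = {label: set() for label in LABELS}
    for c in classified:
        g = closest_tss(c.region, genes)
        if g is not None and g.gene_id in expression.index:
            class_genes[c.label].add(g.gene_id)
    rows = []
    for label in LABELS:
        ids = sorted(class_genes[label])
        for tp in expression.columns:
            vals = expression.loc[ids, tp].to_numpy() if ids else np.empty(0)
            mean, lo, hi = mean_ci(vals)
            rows.append((label, tp, len(ids), mean, lo, hi))
    return pd.DataFrame(
        rows, columns=["label", "timepoint", "n_genes", "mean", "ci_low", "ci_high"]
    )


def expression_change_by_class(
    classified: list[ClassifiedRegion],
    genes: list[GeneModel],
    delta_expression: pd.Series,
    max_distance: int = 500,
) -> pd.DataFrame:
    """Mean expression change (95% CI) of genes linked to each region class.

    Genes are linked to regions by span overlap or proximity within
    ``max_distance`` bp; a gene linked to regions of several classes
    contributes to each. Columns: ``label``, ``n_genes``, ``mean``,
    ``ci_low``, ``ci_high``.
    """
    links = associate_regions_to_genes(classified, genes, max_distance)
    per_class: dict[str, list[float]] = {label: [] for label in LABELS}
    for gene_id, region_idx in links.items():
        if gene_id not in delta_expression.index:
            continue
        for label in {classified[i].label for i in region_idx}:
            per_class[label].append(float(delta_expression[gene_id]))
    rows = []
    for label in LABELS:
        vals = np.array(per_class[label])
        mean, lo, hi = mean_ci(vals)
        rows.append((label, vals.size, mean, lo, hi))
    return pd.DataFrame(
        rows, columns=["label", "n_genes", "mean", "ci_low", "ci_high"]
    ).set_index("label")


def mean_change_by_geneset(
    classified: list[ClassifiedRegion],
    gene_sets: dict[str, list[str]],
    genes: list[GeneModel],
    max_distance: int = 500,
) -> pd.DataFrame:
    """Mean occupancy change (95% CI) of regions linked to named gene sets.

    For each set, the log2 change ``delta`` of every region linked (by
    overlap or <= ``max_distance`` bp) to any of the set's genes is
    averaged; a region linked through several genes of the set counts
    once. Regions with non-finite delta (no condition-B signal) are
    excluded. Columns: ``geneset``, ``n_regions``, ``mean_delta``,
    ``ci_low``, ``ci_high``.
    """
    links = associate_regions_to_genes(classified, genes, max_distance)
    rows = []
    for name, ids in gene_sets.items():
        idx = sorted({i for gid in ids for i in links.get(gid, [])})
        deltas = np.array(
            [classified[i].delta for i in idx if np.isfinite(classified[i].delta)]
        )
        mean, lo, hi = mean_ci(deltas)
        rows.append((name, deltas.size, mean, lo, hi))
    return pd.DataFrame(
        rows, columns=["geneset", "n_regions", "mean_delta", "ci_low", "ci_high"]
    ).set_index("geneset")
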