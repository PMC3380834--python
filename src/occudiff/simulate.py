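"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, the data the analysis consumes:

* **Coverage.** Input-chromatin read counts are Poisson with a uniform
  background rate; IP counts are Poisson with the same rate outside
  planted peaks and ``rate * 2**e(x)`` inside a planted peak, where the
  log2 enrichment ``e(x)`` peaks at the summit and tapers slightly
  toward the edges. The method consumes per-nucleotide counts, so no
  read- or fragment-shape modelling is needed to exercise the rules.
* **Factor region sets.** Each of ``n_factors`` transcription factors
  contributes ``regions_per_factor`` scored regions; a fraction
  ``hotspot_fraction`` of each factor's regions sits at shared hotspot
  loci (identical coordinates across factors), the rest are uniform
  random. A HOT-region set is derived by counting, at every covered
  locus, how many factor regions cover it (HOTness, minimum 1).
* **Expression.** Each gene belongs to a trajectory class; its log2
  expression at each time point is the class mean plus Gaussian noise.

Every artifact pairs with a machine-readable truth table (planted
peaks, factor memberships, expression classes). One root seed feeds
independent per-artifact streams, so adding a factor set never perturbs
the coverage draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .overlap import RegionSet

__all__ = [
    "PlantedPeak",
    "ExpressionSpec",
    "SimSpec",
    "default_sim_spec",
    "condition_b_spec",
    "simulate_coverage",
    "simulate_factor_sets",
    "simulate_expression",
    "simulate_gene_models",
    "write_artifacts",
]

# independent child streams off the root seed
_STREAMS = {
    "coverage": 0, "factors": 1, "expression": 2, "genes": 3,
    "placement": 4, "expression_change": 5,
}

DEFAULT_TIMEPOINTS = (
    "E00-02", "E02-04", "E04-06", "E06-08",
    "E08-10", "E10-12", "E12-14", "E14-16",
)

# qualitative trajectory shapes for the four occupancy classes: regions
# gaining occupancy in condition B sit in genes expressed early and
# declining; lost regions in late-rising, initially silent genes
DEFAULT_CLASS_MEANS = {
    "up": (7.5, 7.2, 6.9, 6.6, 6.3, 6.0, 5.7, 5.5),
    "unchanged": (8.0, 7.8, 7.6, 7.4, 7.2, 7.0, 6.8, 6.5),
    "down": (5.0, 5.3, 5.6, 5.9, 6.2, 6.5, 6.8, 7.0),
    "lost": (3.0, 3.4, 3.9, 4.3, 4.7, 5.1, 5.6, 6.0),
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class PlantedPeak:
    seq: str
    start: int
    end: int
    log2_enrichment: float
    label: str | None = None  # intended cross-condition class, if any


# mean per-gene log2 expression change between the two simulated
# conditions, by trajectory class (genes near gained occupancy go up,
# genes near reduced or lost occupancy go down)
DEFAULT_CHANGE_MEANS = {"up": 1.0, "unchanged": 0.0, "down": -1.0, "lost": -1.0}


@dataclass(frozen=True)
class ExpressionSpec:
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    class_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MEANS)
    )
    change_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHANGE_MEANS)
    )
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for cls, means in self.class_means.items():
            if len(means) != len(self.timepoints):
                raise ValueError(
                    f"class {cls!r}: {len(means)} means for "
                    f"{len(self.timepoints)} time points"
                )


@dataclass(frozen=True)
class SimSpec:
    """Full description of one synthetic data set."""

    genome_lengths: dict[str, int]
    background_rate: float = 10.0
    planted_peaks: tuple[PlantedPeak, ...] = ()
    summit_taper: float = 0.5
    n_factors: int = 40
    regions_per_factor: int = 60
    factor_region_width: int = 400
    hotspot_fraction: float = 0.3
    expression_spec: ExpressionSpec = field(default_factory=ExpressionSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate <= 0:
            raise ValueError("background_rate must be positive")
        if self.summit_taper < 0:
            raise ValueError("summit_taper must be non-negative")
        if not 0.0 <= self.hotspot_fraction <= 1.0:
            raise ValueError("hotspot_fraction must lie in [0, 1]")
        if self.n_factors < 1:
            raise ValueError("n_factors must be at least 1")
        if self.regions_per_factor < 1 or self.factor_region_width < 1:
            raise ValueError("factor set dimensions must be positive")
        for p in self.planted_peaks:
            if p.seq not in self.genome_lengths:
                raise ValueError(f"planted peak on unknown sequence {p.seq!r}")
            if not 0 <= p.start < p.end <= self.genome_lengths[p.seq]:
                raise ValueError(
                    f"planted peak {p.seq}:{p.start}-{p.end} outside sequence"
                )
            if p.log2_enrichment < 0:
                raise ValueError("log2_enrichment must be non-negative")


CLASS_CYCLE = ("up", "unchanged", "down", "lost")
CLASS_SHIFTS = {"up": 2.0, "unchanged": 0.0, "down": -2.0, "lost": None}


def default_sim_spec(
    seed: int = 0,
    genome_length: int = 1_000_000,
    n_peaks: int = 20,
    enrichment: float = 3.5,
    width_range: tuple[int, int] = (550, 750),
    **kwargs,
) -> SimSpec:
    """The reference simulation: a 1-Mb genome at background rate 10 with
    20 planted peaks of summit log2 enrichment 3.5 and widths 550-750 bp.

    The peak density (~20/Mb) is of the order of a genome-wide call set
    of a few thousand peaks on a ~120-Mb genome. The summit enrichment
    is chosen so that the top-5% cutoff falls in the lower tail of the
    planted peak values (the regime the quantile rule is meant for: the
    cutoff below the bulk of true peak values) and so that every +/-2
    log2 rescaling of :func:`condition_b_spec` keeps the expected
    requantified value clear of both classification boundaries (the
    0.5-log2 lost floor and the +/-1 change band). Peaks are placed one
    per equal slot with random jitter, so they never overlap; each
    carries an intended cross-condition class (up/unchanged/down/lost,
    cycling).
    """
    rng = _rng(seed, "placement")
    slot = genome_length // n_peaks
    if slot < width_range[1] + 2:
        raise ValueError("genome too short for the requested peaks")
    peaks = []
    for i in range(n_peaks):
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        start = i * slot + int(rng.integers(0, slot - width))
        peaks.append(
            PlantedPeak(
                "sim_chr", start, start + width, enrichment,
                label=CLASS_CYCLE[i % 4],
            )
        )
    return SimSpec(
        genome_lengths={"sim_chr": genome_length},
        background_rate=10.0,
        planted_peaks=tuple(peaks),
        seed=seed,
        **kwargs,
    )


def condition_b_spec(spec: SimSpec) -> SimSpec:
    """Derive the second-condition spec from the planted class labels.

    Peaks labelled ``up``/``down`` have their log2 enrichment shifted by
    +2/-2 (floored at 0), ``unchanged`` keep it, and ``lost`` peaks are
    removed. The seed is bumped by one so the condition-B libraries are
    independent draws, as separately sequenced samples would be.
    """
    new_peaks = []
    for p in spec.planted_peaks:
        shift = CLASS_SHIFTS.get(p.label or "unchanged", 0.0)
        if shift is None:
            continue
        new_peaks.append(
            replace(p, log2_enrichment=max(p.log2_enrichment + shift, 0.0))
        )
    return replace(spec, planted_peaks=tuple(new_peaks), seed=spec.seed + 1)


def planted_truth(spec: SimSpec) -> pd.DataFrame:
    """Truth table for the planted peaks (0-based half-open)."""
    return pd.DataFrame(
        [
            (p.seq, p.start, p.end, p.log2_enrichment, p.label or "")
            for p in spec.planted_peaks
        ],
        columns=["seq", "start", "end", "log2_enrichment", "label"],
    )


def simulate_coverage(spec: SimSpec):
    """(IP, input) coverage pair with Poisson counts and planted peaks.

    Input counts are Poisson at the background rate everywhere. IP
    counts are Poisson at the background rate outside planted peaks and
    at ``rate * 2**e(x)`` inside, where the log2 enrichment ``e(x)``
    equals the peak's value at the summit (midpoint) and declines
    linearly by ``summit_taper`` toward the edges (floored at 0) —
    enrichment in chromatin immunoprecipitation is unimodal around the
    binding site, and a perfectly flat profile would leave the summit
    position unidentifiable. ``summit_taper=0`` gives rectangular peaks.

    Overlapping planted peaks on one sequence are an error — the planted
    truth must stay unambiguous.
    """
    from .tracks import CoverageTrack

    by_seq: dict[str, list[PlantedPeak]] = {}
    for p in spec.planted_peaks:
        by_seq.setdefault(p.seq, []).append(p)
    for seq, peaks in by_seq.items():
        peaks.sort(key=lambda p: p.start)
        for a, b in zip(peaks, peaks[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"planted peaks overlap on {seq}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
    rng = _rng(spec.seed, "coverage")
    ip_counts, in_counts = {}, {}
    for seq in spec.genome_lengths:
        length = spec.genome_lengths[seq]
        in_counts[seq] = rng.poisson(spec.background_rate, length).astype(float)
        rate = np.full(length, spec.background_rate)
        for p in by_seq.get(seq, ()):
            x = np.arange(p.start, p.end)
            center = (p.start + p.end - 1) / 2.0
            frac = np.abs(x - center) / ((p.end - p.start) / 2.0)
            e_x = np.maximum(p.log2_enrichment - spec.summit_taper * frac, 0.0)
            rate[p.start: p.end] *= 2.0**e_x
        ip_counts[seq] = rng.poisson(rate).astype(float)
    return CoverageTrack(ip_counts), CoverageTrack(in_counts)


def simulate_factor_sets(spec: SimSpec):
    """(factor sets, HOT set, truth table).

    ``round(hotspot_fraction * regions_per_factor)`` hotspot loci are
    drawn once; every factor places one region at each hotspot (exact
    coordinates) and the remainder uniformly at random. Scores are
    uniform on [1, 10). HOT regions are the maximal runs of constant
    factor-coverage >= 1, scored by that coverage (HOTness).
    """
    rng = _rng(spec.seed, "factors")
    width = spec.factor_region_width
    n_hot = round(spec.hotspot_fraction * spec.regions_per_factor)
    n_rand = spec.regions_per_factor - n_hot
    seqs = sorted(spec.genome_lengths)
    lengths = np.array([spec.genome_lengths[s] for s in seqs], dtype=float)
    seq_prob = lengths / lengths.sum()

    def random_interval():
        s = seqs[rng.choice(len(seqs), p=seq_prob)]
        max_start = spec.genome_lengths[s] - width
        if max_start <= 0:
            raise ValueError(f"sequence {s!r} shorter than factor_region_width")
        return s, int(rng.integers(0, max_start))

    hotspots = [random_interval() for _ in range(n_hot)]
    factors, truth_rows = [], []
    for f in range(spec.n_factors):
        name = f"factor_{f:02d}"
        rows = []
        for h, (s, start) in enumerate(hotspots):
            score = float(rng.uniform(1.0, 10.0))
            rows.append((s, start, start + width, score))
            truth_rows.append((name, s, start, start + width, score, True, h))
        for _ in range(n_rand):
            s, start = random_interval()
            score = float(rng.uniform(1.0, 10.0))
            rows.append((s, start, start + width, score))
            truth_rows.append((name, s, start, start + width, score, False, -1))
        factors.append(RegionSet(name, rows))

    hot_rows = []
    for s in seqs:
        cover = np.zeros(spec.genome_lengths[s], dtype=np.int64)
        for fs in factors:
            sub = fs.df[fs.df["seq"] == s]
            for start, end in zip(sub["start"], sub["end"]):
                cover[start:end] += 1
        changes = np.nonzero(np.diff(cover))[0] + 1
        starts = np.concatenate(([0], changes))
        ends = np.concatenate((changes, [cover.size]))
        for st, en in zip(starts, ends):
            if cover[st] >= 1:
                hot_rows.append((s, int(st), int(en), float(cover[st])))
    hot = RegionSet("HOT", hot_rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=["factor", "seq", "start", "end", "score", "is_hotspot", "hotspot_id"],
    )
    return factors, hot, truth


def simulate_expression(
    spec: SimSpec,
    genes: list[GeneModel],
    classes: dict[str, str] | None = None,
):
    """(expression table, per-gene class truth).

    Expression of gene g at time point t is
    ``class_mean[class(g)][t] + N(0, noise_sd)``. Classes are assigned
    uniformly at random unless ``classes`` maps every gene explicitly;
    a gene without a class, or with a class missing from the
    specification, is an error.
    """
    rng = _rng(spec.seed, "expression")
    espec = spec.expression_spec
    class_names = sorted(espec.class_means)
    assigned: dict[str, str] = {}
    for g in genes:
        if classes is not None:
            if g.gene_id not in classes:
                raise ValueError(f"gene {g.gene_id} has no expression class")
            cls = classes[g.gene_id]
        else:
            cls = class_names[int(rng.integers(len(class_names)))]
        if cls not in espec.class_means:
            raise ValueError(f"unknown expression class {cls!r}")
        assigned[g.gene_id] = cls
    values = np.empty((len(genes), len(espec.timepoints)))
    for i, g in enumerate(genes):
        means = np.array(espec.class_means[assigned[g.gene_id]])
        noise = (
            rng.normal(0.0, espec.noise_sd, means.size)
            if espec.noise_sd > 0
            else 0.0
        )
        values[i] = means + noise
    table = pd.DataFrame(
        values,
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=list(espec.timepoints),
    )
    truth = pd.Series(assigned, name="class")
    truth.index.name = "gene_id"
    return table, truth


def classes_from_planted(spec: SimSpec, genes: list[GeneModel]) -> dict[str, str]:
    """Assign each gene the class label of the nearest planted peak (by
    TSS-to-peak-midpoint distance), coupling expression structure to the
    planted occupancy structure. Peaks without a label are skipped; with
    no labelled peak on a gene's sequence the first class name is used."""
    class_names = sorted(spec.expression_spec.class_means)
    labelled = [p for p in spec.planted_peaks if p.label]
    out = {}
    for g in genes:
        candidates = [p for p in labelled if p.seq == g.seq]
        if not candidates:
            out[g.gene_id] = class_names[0]
            continue
        nearest = min(candidates, key=lambda p: abs((p.start + p.end) // 2 - g.tss))
        out[g.gene_id] = nearest.label
    return out


def simulate_expression_change(
    spec: SimSpec, classes: dict[str, str]
) -> pd.Series:
    """Per-gene log2 expression change between the two conditions:
    class change mean plus Gaussian noise of the expression noise SD."""
    rng = _rng(spec.seed, "expression_change")
    espec = spec.expression_spec
    values = {}
    for gene_id, cls in sorted(classes.items()):
        if cls not in espec.change_means:
            raise ValueError(f"no change mean for class {cls!r}")
        noise = rng.normal(0.0, espec.noise_sd) if espec.noise_sd > 0 else 0.0
        values[gene_id] = espec.change_means[cls] + noise
    out = pd.Series(values, name="delta_expression")
    out.index.name = "gene_id"
    return out


def simulate_gene_models(
    spec: SimSpec,
    n_genes: int = 150,
    span_range: tuple[int, int] = (2_000, 8_000),
) -> list[GeneModel]:
    """Random multi-exon gene models (overlaps between genes allowed)."""
    rng = _rng(spec.seed, "genes")
    seqs = sorted(spec.genome_lengths)
    lengths = np.array([spec.genome_lengths[s] for s in seqs], dtype=float)
    seq_prob = lengths / lengths.sum()
    genes = []
    for i in range(n_genes):
        seq = seqs[rng.choice(len(seqs), p=seq_prob)]
        span = int(rng.integers(span_range[0], span_range[1] + 1))
        start = int(rng.integers(0, spec.genome_lengths[seq] - span))
        end = start + span
        strand = "+" if rng.random() < 0.5 else "-"
        n_introns = int(rng.integers(1, 4))
        n_seg = 2 * n_introns + 1
        extra = rng.multinomial(span - 100 * n_seg, np.full(n_seg, 1.0 / n_seg))
        seg_lens = 100 + extra
        bounds = start + np.concatenate(([0], np.cumsum(seg_lens)))
        exons = [(int(bounds[k]), int(bounds[k + 1])) for k in range(0, n_seg, 2)]
        introns = [(int(bounds[k]), int(bounds[k + 1])) for k in range(1, n_seg, 2)]
        # coding core with UTR margins inside the first and last exon
        thick = (exons[0][0] + 50, exons[-1][1] - 50)
        coding, left_utr, right_utr = [], [], []
        for s, e in exons:
            if e > thick[0] and s < thick[1]:
                coding.append((max(s, thick[0]), min(e, thick[1])))
            if s < thick[0]:
                left_utr.append((s, min(e, thick[0])))
            if e > thick[1]:
                right_utr.append((max(s, thick[1]), e))
        utr5, utr3 = (left_utr, right_utr) if strand == "+" else (right_utr, left_utr)
        genes.append(
            GeneModel(
                gene_id=f"gene_{i:04d}", seq=seq, strand=strand,
                tss=start if strand == "+" else end - 1,
                start=start, end=end,
                exons=tuple(exons), introns=tuple(introns),
                coding=tuple(coding), utr5=tuple(utr5), utr3=tuple(utr3),
            )
        )
    return genes


def write_artifacts(spec: SimSpec, outdir: str | Path) -> dict[str, str]:
    """Write every simulated artifact plus its truth table; returns a
    name -> path manifest."""
    from . import io as oio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def register(name: str, filename: str) -> Path:
        p = outdir / filename
        paths[name] = str(p)
        return p

    oio.write_genome_lengths(
        spec.genome_lengths, register("genome", "genome.tsv")
    )
    ip, input_ = simulate_coverage(spec)
    oio.write_bedgraph_coverage(ip, register("ip", "ip.bedgraph"))
    oio.write_bedgraph_coverage(input_, register("input", "input.bedgraph"))
    planted_truth(spec).to_csv(
        register("truth_peaks", "truth_peaks.tsv"), sep="\t", index=False
    )

    factors, hot, factor_truth = simulate_factor_sets(spec)
    for fs in factors:
        oio.write_region_set(fs, register(fs.name, f"{fs.name}.bed"))
    oio.write_hot_tsv(hot, register("hot", "hot_regions.tsv"))
    factor_truth.to_csv(
        register("truth_factors", "truth_factors.tsv"), sep="\t", index=False
    )

    genes = simulate_gene_models(spec)
    oio.write_gene_models_bed12(genes, register("genes", "genes.bed"))
    expr, expr_truth = simulate_expression(spec, genes)
    expr.to_csv(register("expression", "expression.tsv"), sep="\t")
    expr_truth.to_csv(
        register("truth_expression", "truth_expression.tsv"), sep="\t"
    )
    return paths
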