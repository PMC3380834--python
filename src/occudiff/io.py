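"""Readers and writers for the text formats the pipeline touches.

Conventions: all coordinates are 0-based, half-open — internally, in BED
and bedGraph, and in every TSV artifact. GFF3, the one 1-based source,
is converted at the parser boundary only. Coverage bedGraphs are
run-length encoded; ratio-track bedGraphs carry one line per present
grid value, the interval ``[p, p + grid_step)`` holding the value
sampled at ``p``. BED scores round-trip to 6 decimals; the peak BED
carries the BED-legal integer score (0-1000, scaled to the track
maximum) in column 5 and the float peak value in column 7.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .classify import ClassifiedRegion
from .overlap import RegionSet
from .peaks import BoundRegion
from .tracks import CoverageTrack, RatioTrack, n_grid_points

__all__ = [
    "read_genome_lengths",
    "write_genome_lengths",
    "write_bedgraph_coverage",
    "read_bedgraph_coverage",
    "write_bedgraph_ratio",
    "read_bedgraph_ratio",
    "write_region_set",
    "read_bed_regions",
    "write_peak_bed",
    "read_peak_bed",
    "write_classified_tsv",
    "read_classified_tsv",
    "write_hot_tsv",
    "read_hot_tsv",
    "read_expression_tsv",
    "write_peak_table",
    "write_gene_models_bed12",
    "read_gene_models_bed12",
    "read_gene_models_gff3",
    "write_json",
]

HEADER_PREFIXES = ("track", "browser", "#")


def _fmt(x: float) -> str:
    return f"{x:.6f}".rstrip("0").rstrip(".")


def read_genome_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV: sequence name, length in bp."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(HEADER_PREFIXES):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}, line {i}: expected 'name<TAB>length'")
            lengths[parts[0]] = int(parts[1])
    return lengths


def write_genome_lengths(lengths: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq, n in lengths.items():
            fh.write(f"{seq}\t{n}\n")


def write_bedgraph_coverage(track: CoverageTrack, path: str | Path) -> None:
    """Run-length-encoded 4-column bedGraph of per-nucleotide counts."""
    with open(path, "w") as fh:
        for seq in track.counts:
            arr = track.counts[seq]
            if arr.size == 0:
                continue
            changes = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate(([0], changes))
            ends = np.concatenate((changes, [arr.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{seq}\t{s}\t{e}\t{_fmt(arr[s])}\n")


def _parse_bedgraph(path: str | Path):
    """Yield (line_no, seq, start, end, value), validating per-sequence
    sorted, non-overlapping intervals."""
    last: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(HEADER_PREFIXES):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}, line {i}: expected 4 columns")
            seq = parts[0]
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}, line {i}: {exc}") from None
            if start >= end:
                raise ValueError(f"{path}, line {i}: start >= end")
            if start < last.get(seq, 0):
                raise ValueError(
                    f"{path}, line {i}: overlapping or unsorted interval on {seq}"
                )
            last[seq] = end
            yield i, seq, start, end, value


def read_bedgraph_coverage(
    path: str | Path, genome_lengths: dict[str, int]
) -> CoverageTrack:
    """Dense coverage from a bedGraph; uncovered nucleotides are 0."""
    counts = {seq: np.zeros(n) for seq, n in genome_lengths.items()}
    for i, seq, start, end, value in _parse_bedgraph(path):
        if seq not in counts:
            raise ValueError(f"{path}, line {i}: unknown sequence {seq!r}")
        if end > genome_lengths[seq]:
            raise ValueError(f"{path}, line {i}: interval beyond {seq} length")
        counts[seq][start:end] = value
    return CoverageTrack(counts)


def write_bedgraph_ratio(track: RatioTrack, path: str | Path) -> None:
    """One line per present grid value: ``[p, p + grid_step)`` -> value."""
    step = track.grid_step
    with open(path, "w") as fh:
        for seq in track.values:
            arr = track.values[seq]
            length = track.genome_lengths[seq]
            for idx in np.nonzero(~np.isnan(arr))[0]:
                p = int(idx) * step
                fh.write(f"{seq}\t{p}\t{min(p + step, length)}\t{arr[idx]:.9g}\n")


def read_bedgraph_ratio(
    path: str | Path,
    genome_lengths: dict[str, int],
    grid_step: int = 35,
    kind: str = "smoothed",
) -> RatioTrack:
    """Grid-sparse ratio track; interval starts must sit on the grid."""
    values = {
        seq: np.full(n_grid_points(n, grid_step), np.nan)
        for seq, n in genome_lengths.items()
    }
    for i, seq, start, end, value in _parse_bedgraph(path):
        if seq not in values:
            raise ValueError(f"{path}, line {i}: unknown sequence {seq!r}")
        if start % grid_step:
            raise ValueError(
                f"{path}, line {i}: interval start {start} is off the "
                f"{grid_step}-bp grid"
            )
        values[seq][start // grid_step] = value
    return RatioTrack(
        grid_step=grid_step, genome_lengths=dict(genome_lengths),
        values=values, kind=kind,
    )


def write_region_set(regions: RegionSet, path: str | Path) -> None:
    """BED6 with the float score (6 decimals) in column 5."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(
                f"{r.seq}\t{r.start}\t{r.end}\t{regions.name}_{i}\t"
                f"{_fmt(r.score)}\t.\n"
            )


def read_bed_regions(
    path: str | Path,
    name: str | None = None,
    genome_lengths: dict[str, int] | None = None,
) -> RegionSet:
    """BED with at least 3 columns; column 5 (when present) is the score.

    Track/browser/comment header lines are skipped. With
    ``genome_lengths`` given, regions on unknown sequences are an error.
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(HEADER_PREFIXES):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}, line {i}: expected >= 3 columns")
            seq = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}, line {i}: {exc}") from None
            if start >= end:
                raise ValueError(f"{path}, line {i}: start >= end")
            if genome_lengths is not None and seq not in genome_lengths:
                raise ValueError(f"{path}, line {i}: unknown sequence {seq!r}")
            score = float(parts[4]) if len(parts) >= 5 and parts[4] != "." else 0.0
            rows.append((seq, start, end, score))
    return RegionSet(name or Path(path).stem, rows)


def write_peak_bed(
    regions: list[BoundRegion], path: str | Path, prefix: str = "peak"
) -> None:
    """BED6+3: name, scaled integer score, strand '.', then peak_value,
    peak_center, n_values. The integer score is
    ``round(1000 * peak_value / max peak_value)`` clamped to 0-1000."""
    track_max = max((r.peak_value for r in regions), default=0.0)
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            scaled = 0
            if track_max > 0:
                scaled = int(np.clip(round(1000 * r.peak_value / track_max), 0, 1000))
            fh.write(
                f"{r.seq}\t{r.start}\t{r.end}\t{prefix}_{i}\t{scaled}\t.\t"
                f"{r.peak_value:.6f}\t{r.peak_center}\t{r.n_values}\n"
            )


def read_peak_bed(path: str | Path) -> list[BoundRegion]:
    regions = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(HEADER_PREFIXES):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}, line {i}: expected 9 columns")
            regions.append(
                BoundRegion(
                    seq=parts[0], start=int(parts[1]), end=int(parts[2]),
                    peak_value=float(parts[6]), peak_center=int(parts[7]),
                    n_values=int(parts[8]),
                )
            )
    return regions


CLASSIFIED_COLUMNS = (
    "seq", "start", "end", "peak_center", "n_values",
    "value_a", "value_b", "delta", "label",
)


def write_classified_tsv(
    classified: list[ClassifiedRegion], path: str | Path
) -> None:
    rows = [
        (
            c.seq, c.start, c.end, c.region.peak_center, c.region.n_values,
            c.value_a, c.value_b, c.delta, c.label,
        )
        for c in classified
    ]
    pd.DataFrame(rows, columns=CLASSIFIED_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_classified_tsv(path: str | Path) -> list[ClassifiedRegion]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        region = BoundRegion(
            seq=row.seq, start=int(row.start), end=int(row.end),
            peak_value=float(row.value_a), peak_center=int(row.peak_center),
            n_values=int(row.n_values),
        )
        out.append(
            ClassifiedRegion(region, float(row.value_b), float(row.delta), row.label)
        )
    return out


def write_hot_tsv(hot: RegionSet, path: str | Path) -> None:
    hot.df.rename(columns={"score": "hotness"}).to_csv(path, sep="\t", index=False)


def read_hot_tsv(path: str | Path, name: str = "HOT") -> RegionSet:
    df = pd.read_csv(path, sep="\t").rename(columns={"hotness": "score"})
    return RegionSet(name, df)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Gene x time point log2 expression; first column is the gene ID."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: expression values must be finite")
    return df


def write_peak_table(
    regions: list[BoundRegion],
    tss_table: pd.DataFrame,
    path: str | Path,
) -> None:
    """Peak position, peak value, and distance to closest TSS, as TSV."""
    df = tss_table.copy()
    df.insert(4, "peak_value", [r.peak_value for r in regions])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_gene_models_bed12(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            exons = sorted(g.exons) or [(g.start, g.end)]
            coding = sorted(g.coding)
            thick_start = coding[0][0] if coding else g.start
            thick_end = coding[-1][1] if coding else g.start
            sizes = ",".join(str(e - s) for s, e in exons) + ","
            starts = ",".join(str(s - g.start) for s, _ in exons) + ","
            fh.write(
                f"{g.seq}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{thick_start}\t{thick_end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )


def _gene_from_exons(
    gene_id: str, seq: str, strand: str, start: int, end: int,
    exons: list[tuple[int, int]], thick: tuple[int, int] | None,
) -> GeneModel:
    exons = sorted(exons)
    introns = [
        (exons[i][1], exons[i + 1][0])
        for i in range(len(exons) - 1)
        if exons[i + 1][0] > exons[i][1]
    ]
    coding: list[tuple[int, int]] = []
    left_utr: list[tuple[int, int]] = []
    right_utr: list[tuple[int, int]] = []
    if thick is not None and thick[1] > thick[0]:
        ts, te = thick
        for s, e in exons:
            if e > ts and s < te:
                coding.append((max(s, ts), min(e, te)))
            if s < ts:
                left_utr.append((s, min(e, ts)))
            if e > te:
                right_utr.append((max(s, te), e))
    utr5, utr3 = (left_utr, right_utr) if strand == "+" else (right_utr, left_utr)
    tss = start if strand == "+" else end - 1
    return GeneModel(
        gene_id=gene_id, seq=seq, strand=strand, tss=tss, start=start, end=end,
        exons=tuple(exons), introns=tuple(introns), coding=tuple(coding),
        utr5=tuple(utr5), utr3=tuple(utr3),
    )


def read_gene_models_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(HEADER_PREFIXES):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}, line {i}: expected 12 columns")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}, line {i}: start >= end")
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(
                _gene_from_exons(
                    parts[3], parts[0], parts[5], start, end, exons,
                    (int(parts[6]), int(parts[7])),
                )
            )
    return genes


def read_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    """Gene models from GFF3 (1-based closed coordinates, converted here).

    Exons and CDS are pooled across the gene's transcripts; introns are
    the gaps between the merged exons.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = [(f.start - 1, f.end) for f in db.children(g, featuretype="exon")]
        cds = [(f.start - 1, f.end) for f in db.children(g, featuretype="CDS")]
        if not exons:
            exons = [(g.start - 1, g.end)]
        merged: list[tuple[int, int]] = []
        for s, e in sorted(exons):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
            else:
                merged.append((s, e))
        thick = (min(s for s, _ in cds), max(e for _, e in cds)) if cds else None
        genes.append(
            _gene_from_exons(
                g.id, g.seqid, g.strand, g.start - 1, g.end, merged, thick
            )
        )
    return genes


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
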