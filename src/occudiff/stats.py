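"""Statistical comparisons and ChIP-qPCR fold-enrichment arithmetic.

All t-tests are two-tailed and do not assume equal variances (Welch);
the paired test operates on per-region differences. qPCR enrichment
assumes perfect primer doubling per cycle (efficiency 2, configurable):
the raw enrichment of a locus is 2^(Ct_input - mean Ct_IP) times an
optional input-dilution correction, and reported values are normalized
to reference loci measured on the same plate (a single control locus or
the mean of two intergenic background sites). Histone-modification
measurements can additionally be normalized to total histone H3 at the
same locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "welch_t_test",
    "paired_t_test",
    "pooled_acetylation_compare",
    "QpcrPlate",
    "fold_enrichment",
]


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float
    undefined: bool = False


def welch_t_test(sample_a, sample_b) -> TTestResult:
    """Two-tailed t-test without assuming equal variances.

    Uses the Welch statistic with Welch-Satterthwaite degrees of
    freedom. Both samples need n >= 2 and at least one must have
    nonzero variance.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def paired_t_test(values_a, values_b) -> TTestResult:
    """Two-tailed paired t-test on per-pair differences (df = n - 1).

    Zero-variance differences (including identical inputs) make the
    statistic undefined; the result is flagged rather than reported as
    zero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    sd = d.std(ddof=1)
    n = d.size
    # identical differences up to float roundoff: statistic undefined
    if sd <= 1e-12 * max(1.0, float(np.abs(d).max())):
        return TTestResult(np.nan, float(n - 1), np.nan, undefined=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TTestResult(float(t), float(n - 1), float(p))


def pooled_acetylation_compare(
    measurements: dict[str, dict[str, np.ndarray]],
    genotype_a: str,
    genotype_b: str,
) -> TTestResult:
    """Welch test between genotypes pooling all marks' replicates.

    ``measurements`` maps mark name -> genotype -> replicate values.
    When several histone acetylations are compared between two
    genotypes, all replicates from every mark are concatenated into one
    sample per genotype before testing.
    """
    pooled_a, pooled_b = [], []
    for mark, per_genotype in measurements.items():
        if genotype_a in per_genotype:
            pooled_a.append(np.asarray(per_genotype[genotype_a], dtype=float))
        if genotype_b in per_genotype:
            pooled_b.append(np.asarray(per_genotype[genotype_b], dtype=float))
    if not pooled_a or not pooled_b:
        raise ValueError("no replicates found for one of the genotypes")
    return welch_t_test(np.concatenate(pooled_a), np.concatenate(pooled_b))


REQUIRED_PLATE_COLUMNS = (
    "antibody", "locus", "replicate", "ct_ip1", "ct_ip2", "ct_input"
)


@dataclass
class QpcrPlate:
    """ChIP-qPCR Ct measurements: one row per (antibody, locus, replicate).

    Columns ``ct_ip1``/``ct_ip2`` are the IP duplicates, ``ct_input``
    the input chromatin Ct. ``dilution`` is a plate-level input-dilution
    correction factor applied to raw enrichments; it cancels under
    reference-locus normalization, and the default of 1 is safe whenever
    only normalized values are reported. ``efficiency`` is the per-cycle
    amplification factor.
    """

    data: pd.DataFrame
    dilution: float = 1.0
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        missing = set(REQUIRED_PLATE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"plate table missing columns: {sorted(missing)}")
        cts = self.data[["ct_ip1", "ct_ip2", "ct_input"]].to_numpy(dtype=float)
        if not (cts > 0).all():
            raise ValueError("all Ct values must be positive")
        if self.dilution <= 0 or self.efficiency <= 1:
            raise ValueError("dilution must be > 0 and efficiency > 1")

    @classmethod
    def from_tsv(
        cls, path: str | Path, dilution: float = 1.0, efficiency: float = 2.0
    ) -> "QpcrPlate":
        return cls(pd.read_csv(path, sep="\t"), dilution=dilution, efficiency=efficiency)

    def raw_enrichment(self, antibody: str, locus: str) -> pd.Series:
        """Per-replicate raw fold enrichment over input for one locus.

        ``efficiency ** (ct_input - mean(ct_ip duplicates)) * dilution``,
        indexed by replicate.
        """
        sub = self.data[
            (self.data["antibody"] == antibody) & (self.data["locus"] == locus)
        ]
        if sub.empty:
            raise ValueError(f"no measurements for {antibody!r} at {locus!r}")
        d_ct = sub["ct_input"].to_numpy(dtype=float) - 0.5 * (
            sub["ct_ip1"].to_numpy(dtype=float) + sub["ct_ip2"].to_numpy(dtype=float)
        )
        values = self.efficiency**d_ct * self.dilution
        return pd.Series(values, index=sub["replicate"].to_numpy(), name=locus)


def fold_enrichment(
    plate: QpcrPlate,
    antibody: str,
    locus: str,
    reference: tuple[str, ...] = ("Mi-2",),
    h3_normalize: bool = False,
    h3_antibody: str = "H3",
) -> pd.Series:
    """Reference-normalized fold enrichment, per biological replicate.

    The raw locus enrichment is divided by the reference value on the
    same replicate: the single control locus, or the mean over two (or
    more) intergenic background sites. With ``h3_normalize`` (histone
    modifications), the value is further divided by the same ratio
    computed from the total-H3 measurements, correcting for nucleosome
    occupancy.
    """
    if not reference:
        raise ValueError("at least one reference locus is required")

    def normalized(ab: str) -> pd.Series:
        raw = plate.raw_enrichment(ab, locus)
        refs = pd.concat(
            [plate.raw_enrichment(ab, r) for r in reference], axis=1
        )
        ref = refs.mean(axis=1)
        joined = pd.concat([raw, ref], axis=1, join="inner")
        if joined.empty:
            raise ValueError(
                f"no replicate measures both {locus!r} and the reference loci"
            )
        return joined.iloc[:, 0] / joined.iloc[:, 1]

    result = normalized(antibody)
    if h3_normalize:
        h3 = normalized(h3_antibody)
        joined = pd.concat([result, h3], axis=1, join="inner")
        result = joined.iloc[:, 0] / joined.iloc[:, 1]
    return result.rename(f"{antibody}:{locus}")
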