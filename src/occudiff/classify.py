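"""Cross-condition classification of bound regions.

Regions called in condition A are requantified on the condition-B
enrichment track using the same top-five-consecutive scoring rule,
restricted to each region's original span. No cross-condition rescaling
is performed (the two tracks are assumed comparably normalized by their
own depth adjustment). Each region is then labelled:

* ``lost`` if the condition-B value is below ``lost_threshold`` (0.5 log2);
* otherwise by the log2 change ``delta = value_b - value_a``:
  ``up`` if delta > +1, ``down`` if delta < -1, ``unchanged`` in between
  (the band is closed: delta exactly +/-1 is unchanged).

Regions whose span holds no condition-B value at all receive a -inf
sentinel and are classified lost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .overlap import RegionSet
from .peaks import BoundRegion, score_region
from .tracks import RatioTrack

__all__ = [
    "LABELS",
    "ClassifiedRegion",
    "requantify",
    "classify",
    "classify_regions",
    "region_hotness",
    "class_summary",
    "foldchange_hotness_bins",
]

LABELS = ("up", "unchanged", "down", "lost")

NO_SIGNAL = float("-inf")


@dataclass(frozen=True)
class ClassifiedRegion:
    """A condition-A bound region with its condition-B value and label."""

    region: BoundRegion
    value_b: float
    delta: float
    label: str

    @property
    def seq(self) -> str:
        return self.region.seq

    @property
    def start(self) -> int:
        return self.region.start

    @property
    def end(self) -> int:
        return self.region.end

    @property
    def value_a(self) -> float:
        return self.region.peak_value


def requantify(
    regions: list[BoundRegion],
    track_b: RatioTrack,
    cfg: PipelineConfig | None = None,
) -> np.ndarray:
    """Condition-B peak value inside each condition-A region span.

    Applies the top-five-consecutive scoring to the condition-B track
    restricted to ``[start, end)``; spans with no present value get the
    ``-inf`` sentinel (classified lost downstream).
    """
    cfg = cfg or PipelineConfig()
    out = np.empty(len(regions))
    for i, r in enumerate(regions):
        try:
            out[i] = score_region(track_b, r.seq, r.start, r.end, cfg)[0]
        except ValueError:
            out[i] = NO_SIGNAL
    return out


def classify(
    regions: list[BoundRegion],
    values_b: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> list[ClassifiedRegion]:
    """Assign each region exactly one of up / unchanged / down / lost.

    ``lost`` takes precedence: any region whose condition-B value is
    strictly below ``lost_threshold`` is lost regardless of the change.
    """
    cfg = cfg or PipelineConfig()
    if len(values_b) != len(regions):
        raise ValueError("values_b length does not match regions")
    fc = cfg.fold_change_threshold
    out: list[ClassifiedRegion] = []
    for r, vb in zip(regions, values_b):
        vb = float(vb)
        delta = vb - r.peak_value
        if vb < cfg.lost_threshold:
            label = "lost"
        elif delta > fc:
            label = "up"
        elif delta < -fc:
            label = "down"
        else:
            label = "unchanged"
        out.append(ClassifiedRegion(r, vb, delta, label))
    return out


def classify_regions(
    regions: list[BoundRegion],
    track_b: RatioTrack,
    cfg: PipelineConfig | None = None,
) -> list[ClassifiedRegion]:
    """Requantify on the condition-B track and classify in one step."""
    cfg = cfg or PipelineConfig()
    return classify(regions, requantify(regions, track_b, cfg), cfg)


def region_hotness(region, hot_regions: RegionSet) -> float:
    """HOTness of a region: the maximum HOTness among overlapping HOT
    intervals, or NaN if the region overlaps none."""
    scores = hot_regions.overlapping_scores(region.seq, region.start, region.end)
    return float(scores.max()) if scores.size else float("nan")


def class_summary(
    classified: list[ClassifiedRegion], hot_regions: RegionSet
) -> pd.DataFrame:
    """Per-class table: count, HOT overlap, mean HOTness, mean peak value.

    ``pct_hot`` is the percent of class regions overlapping at least one
    HOT interval by >= 1 nt; ``mean_hotness`` averages the per-region
    HOTness (max over overlapping HOT intervals) across the overlapping
    regions only. Empty classes keep n = 0 with NaN means.
    """
    rows = []
    for label in LABELS:
        members = [c for c in classified if c.label == label]
        if not members:
            rows.append((label, 0, np.nan, np.nan, np.nan))
            continue
        hotness = np.array([region_hotness(c, hot_regions) for c in members])
        overlapping = hotness[~np.isnan(hotness)]
        pct_hot = 100.0 * overlapping.size / len(members)
        mean_hot = float(overlapping.mean()) if overlapping.size else np.nan
        mean_va = float(np.mean([c.value_a for c in members]))
        rows.append((label, len(members), pct_hot, mean_hot, mean_va))
    return pd.DataFrame(
        rows, columns=["label", "n", "pct_hot", "mean_hotness", "mean_peak_value"]
    ).set_index("label")


def foldchange_hotness_bins(
    classified: list[ClassifiedRegion],
    hot_regions: RegionSet,
    bin_width: float = 0.5,
) -> pd.DataFrame:
    """Mean HOTness (with 95% CI) of regions binned by log2 fold change.

    Regions are binned by ``delta``; within each bin the mean HOTness of
    HOT-overlapping regions is reported with a normal-approximation 95%
    confidence interval (mean +/- 1.96 SE). Regions with a non-finite
    delta (no condition-B signal) are excluded; bins with fewer than two
    HOTness values carry NaN CI bounds. Columns: ``bin_left``,
    ``bin_right``, ``n``, ``mean_hotness``, ``ci_low``, ``ci_high``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    usable = [c for c in classified if np.isfinite(c.delta)]
    if not usable:
        return pd.DataFrame(
            columns=["bin_left", "bin_right", "n", "mean_hotness", "ci_low", "ci_high"]
        )
    deltas = np.array([c.delta for c in usable])
    hotness = np.array([region_hotness(c, hot_regions) for c in usable])
    idx = np.floor(deltas / bin_width).astype(int)
    rows = []
    for b in range(idx.min(), idx.max() + 1):
        sel = hotness[idx == b]
        sel = sel[~np.isnan(sel)]
        if sel.size == 0:
            continue
        mean = float(sel.mean())
        if sel.size >= 2:
            se = float(sel.std(ddof=1)) / np.sqrt(sel.size)
            lo, hi = mean - 1.96 * se, mean + 1.96 * se
        else:
            lo = hi = np.nan
        rows.append((b * bin_width, (b + 1) * bin_width, sel.size, mean, lo, hi))
    return pd.DataFrame(
        rows, columns=["bin_left", "bin_right", "n", "mean_hotness", "ci_low", "ci_high"]
    )
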