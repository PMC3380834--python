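"""Quantile-threshold peak calling on a smoothed enrichment track.

Bound regions are defined directly from the smoothed grid: the cutoff is
the empirical quantile leaving the top 5% of present values (at defaults);
above-cutoff positions are clustered left to right, a cluster extending as
long as the next above-cutoff value lies within 200 bp of the previous
one; clusters spanning less than 200 bp are discarded. Each surviving
region is scored as the mean of the highest five consecutive present
values inside it, and the peak center is the grid position of the middle
value of that window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .tracks import CoverageTrack, RatioTrack, build_ratio_track, median_smooth

__all__ = [
    "BoundRegion",
    "determine_cutoff",
    "score_region",
    "call_regions",
    "call_peaks",
]

MIN_VALUES_FOR_CUTOFF = 20


@dataclass(frozen=True)
class BoundRegion:
    """A called bound region (0-based half-open coordinates)."""

    seq: str
    start: int
    end: int
    peak_value: float
    peak_center: int
    n_values: int

    def __post_init__(self) -> None:
        if not self.start <= self.peak_center < self.end:
            raise ValueError("peak_center must lie inside the region")
        if not np.isfinite(self.peak_value):
            raise ValueError("peak_value must be finite")

    @property
    def span(self) -> int:
        return self.end - self.start


def determine_cutoff(track: RatioTrack, cfg: PipelineConfig | None = None) -> float:
    """Enrichment cutoff leaving the top ``quantile`` fraction of values.

    Returns the (1 - quantile) empirical quantile (linear interpolation)
    of all present smoothed values.
    """
    cfg = cfg or PipelineConfig()
    present = track.present_values()
    if present.size < MIN_VALUES_FOR_CUTOFF:
        raise ValueError(
            f"need at least {MIN_VALUES_FOR_CUTOFF} present values to set a "
            f"cutoff, got {present.size}"
        )
    return float(np.quantile(present, 1.0 - cfg.quantile))


def score_region(
    track: RatioTrack,
    seq: str,
    start: int,
    end: int,
    cfg: PipelineConfig | None = None,
) -> tuple[float, int, int]:
    """Score ``[start, end)`` on ``track``: (peak_value, peak_center, n_values).

    Present values inside the span are taken in position order;
    "consecutive" means consecutive in that ordered list (missing grid
    points are skipped). The peak value is the maximum mean over windows
    of ``consec_for_score`` consecutive values; the center is the grid
    position of the window's middle value; ties go to the leftmost
    window. With fewer present values than the window size, the peak
    value is the mean of all of them and the center the middle one's
    position.
    """
    cfg = cfg or PipelineConfig()
    arr = track.values[seq]
    step = track.grid_step
    lo = -(-start // step)          # first grid index at or after start
    hi = -(-end // step)            # first grid index at or after end
    lo = max(lo, 0)
    hi = min(hi, arr.size)
    window = arr[lo:hi]
    mask = ~np.isnan(window)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no present values in {seq}:{start}-{end}")
    vals = window[mask]
    pos = (np.nonzero(mask)[0] + lo) * step
    k = cfg.consec_for_score
    if n < k:
        return float(vals.mean()), int(pos[(n - 1) // 2]), n
    means = np.convolve(vals, np.full(k, 1.0 / k), mode="valid")
    best = int(np.argmax(means))    # argmax is leftmost on ties
    return float(means[best]), int(pos[best + k // 2]), n


def call_regions(
    track: RatioTrack, threshold: float, cfg: PipelineConfig | None = None
) -> list[BoundRegion]:
    """Cluster above-threshold grid positions into scored bound regions.

    A cluster extends while the next above-threshold position is within
    ``max_gap`` bp of the previous one. The cluster span is
    ``[first, last + grid_step)``; spans shorter than ``min_region_len``
    are discarded (with ``span_includes_bin=False`` the length rule uses
    ``last - first`` instead). Output order follows the per-sequence
    scan; no sorting is applied here.
    """
    cfg = cfg or PipelineConfig()
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    step = track.grid_step
    regions: list[BoundRegion] = []
    for seq, arr in track.values.items():
        above = np.nonzero(arr >= threshold)[0] * step
        if above.size == 0:
            continue
        breaks = np.nonzero(np.diff(above) > cfg.max_gap)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [above.size - 1]))
        for i, j in zip(starts, ends):
            first, last = int(above[i]), int(above[j])
            span = (last + step - first) if cfg.span_includes_bin else (last - first)
            if span < cfg.min_region_len:
                continue
            start, end = first, last + step
            peak_value, peak_center, n_values = score_region(
                track, seq, start, end, cfg
            )
            regions.append(
                BoundRegion(seq, start, end, peak_value, peak_center, n_values)
            )
    return regions


def call_peaks(
    ip: CoverageTrack, input_: CoverageTrack, cfg: PipelineConfig | None = None
) -> tuple[RatioTrack, float, list[BoundRegion]]:
    """End-to-end: coverage pair -> (smoothed track, cutoff, sorted regions)."""
    cfg = cfg or PipelineConfig()
    raw = build_ratio_track(ip, input_, cfg)
    smoothed = median_smooth(raw, cfg)
    threshold = determine_cutoff(smoothed, cfg)
    regions = call_regions(smoothed, threshold, cfg)
    regions.sort(key=lambda r: (r.seq, r.start))
    return smoothed, threshold, regions
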