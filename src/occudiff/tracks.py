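"""Coverage and enrichment-ratio tracks.

A :class:`CoverageTrack` holds dense per-nucleotide read counts for the
immunoprecipitated (IP) and input chromatin libraries. From a matched
IP/input pair, :func:`build_ratio_track` derives a sparse log2(IP/input)
enrichment value on a fixed-step grid: positions where the IP count is
below the genome-wide IP mean are treated as unenriched and left missing,
input counts below the genome-wide input mean are floored to that mean
(so low-coverage input noise cannot inflate the ratio), and the result is
adjusted for the sequencing-depth difference between the two libraries.
The raw grid is then median-smoothed (:func:`median_smooth`) in centered
windows, discarding windows with too few data points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = [
    "CoverageTrack",
    "RatioTrack",
    "genome_mean",
    "build_ratio_track",
    "median_smooth",
]


@dataclass
class CoverageTrack:
    """Per-nucleotide read counts over named sequences.

    ``counts`` maps sequence name to a dense non-negative array, one entry
    per nucleotide. Fractional counts are allowed (e.g. after scaling).
    """

    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for seq, arr in self.counts.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"counts for {seq!r} must be 1-D")
            if arr.size and arr.min() < 0:
                raise ValueError(f"negative read count on {seq!r}")
            clean[seq] = arr
        self.counts = clean

    @property
    def genome_lengths(self) -> dict[str, int]:
        return {seq: int(arr.size) for seq, arr in self.counts.items()}

    @property
    def total_length(self) -> int:
        return int(sum(arr.size for arr in self.counts.values()))

    def same_layout(self, other: "CoverageTrack") -> bool:
        return self.genome_lengths == other.genome_lengths


def n_grid_points(length: int, step: int) -> int:
    """Number of grid positions 0, step, 2*step, ... inside ``[0, length)``."""
    return -(-length // step)


@dataclass
class RatioTrack:
    """Sparse log2 enrichment values on a fixed-step grid.

    ``values`` maps sequence name to an array with one entry per grid
    position (position ``i * grid_step``); NaN marks a missing value.
    ``kind`` records provenance: ``"raw"`` or ``"smoothed"``.
    """

    grid_step: int
    genome_lengths: dict[str, int]
    values: dict[str, np.ndarray]
    kind: str = "raw"

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.kind not in ("raw", "smoothed"):
            raise ValueError("kind must be 'raw' or 'smoothed'")
        if set(self.values) != set(self.genome_lengths):
            raise ValueError("values and genome_lengths name different sequences")
        for seq, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            n = n_grid_points(self.genome_lengths[seq], self.grid_step)
            if arr.size != n:
                raise ValueError(
                    f"{seq!r}: expected {n} grid values, got {arr.size}"
                )
            if np.isinf(arr).any():
                raise ValueError(f"non-finite (inf) value on {seq!r}")
            self.values[seq] = arr

    def positions(self, seq: str) -> np.ndarray:
        """Grid coordinates (bp) for ``seq``."""
        return np.arange(self.values[seq].size, dtype=np.int64) * self.grid_step

    def present_values(self) -> np.ndarray:
        """All non-missing values, concatenated over sequences (sorted name order)."""
        parts = [
            arr[~np.isnan(arr)] for _, arr in sorted(self.values.items())
        ]
        if not parts:
            return np.empty(0)
        return np.concatenate(parts)

    def n_present(self) -> int:
        return int(sum((~np.isnan(a)).sum() for a in self.values.values()))


def genome_mean(track: CoverageTrack) -> float:
    """Arithmetic mean read count per nucleotide over the whole genome.

    Zeros count; sequences are weighted by their length.
    """
    total_len = track.total_length
    if total_len == 0:
        raise ValueError("empty coverage track")
    total = sum(float(arr.sum()) for arr in track.counts.values())
    return total / total_len


def build_ratio_track(
    ip: CoverageTrack, input_: CoverageTrack, cfg: PipelineConfig | None = None
) -> RatioTrack:
    """Sample the depth-adjusted log2(IP/input) ratio on the grid.

    At each grid position ``p``:

    * if ``ip[p] < mean(ip)`` the position is missing (not enriched);
    * otherwise ``value = log2(ip[p]) - log2(max(input[p], mean(input))) - adj``

    where the adjustment ``adj`` normalizes for sequencing depth:
    ``log2(mean(ip)) - log2(mean(input))`` in the default ``"log2"`` mode,
    or the raw difference ``mean(ip) - mean(input)`` in ``"raw"`` mode.
    """
    cfg = cfg or PipelineConfig()
    if not ip.same_layout(input_):
        raise ValueError("IP and input tracks have different genome layouts")
    mu_ip = genome_mean(ip)
    mu_in = genome_mean(input_)
    if mu_ip == 0 or mu_in == 0:
        raise ValueError("degenerate library: zero mean read count")
    if cfg.adjust_mode == "log2":
        adj = math.log2(mu_ip) - math.log2(mu_in)
    else:
        adj = mu_ip - mu_in

    values: dict[str, np.ndarray] = {}
    for seq in ip.counts:
        c_ip = ip.counts[seq][:: cfg.grid_step]
        c_in = input_.counts[seq][:: cfg.grid_step]
        vals = np.full(c_ip.size, np.nan)
        present = c_ip >= mu_ip
        if present.any():
            floored = np.maximum(c_in[present], mu_in)
            vals[present] = np.log2(c_ip[present]) - np.log2(floored) - adj
        values[seq] = vals
    return RatioTrack(
        grid_step=cfg.grid_step,
        genome_lengths=ip.genome_lengths,
        values=values,
        kind="raw",
    )


def median_smooth(track: RatioTrack, cfg: PipelineConfig | None = None) -> RatioTrack:
    """Median-smooth a raw grid track in centered windows.

    The window at position ``p`` covers grid positions ``q`` with
    ``|q - p| <= smooth_window / 2`` (11 candidate points at defaults).
    The output at ``p`` is the median of the present values in the window
    if at least ``min_points_per_window`` are present, else missing; the
    position itself need not carry a raw value. Median of an even count is
    the mean of the two central values.
    """
    cfg = cfg or PipelineConfig()
    if track.grid_step != cfg.grid_step:
        raise ValueError("track grid step does not match configuration")
    half = cfg.smooth_half_steps
    window = 2 * half + 1
    values: dict[str, np.ndarray] = {}
    for seq, arr in track.values.items():
        if arr.size == 0:
            values[seq] = arr.copy()
            continue
        smoothed = (
            pd.Series(arr)
            .rolling(window, center=True, min_periods=cfg.min_points_per_window)
            .median()
            .to_numpy()
        )
        values[seq] = smoothed
    return RatioTrack(
        grid_step=track.grid_step,
        genome_lengths=dict(track.genome_lengths),
        values=values,
        kind="smoothed",
    )
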