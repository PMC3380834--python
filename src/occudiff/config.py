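"""Pipeline configuration.

Every numeric constant of the occupancy analysis lives in
:class:`PipelineConfig` so that a run is fully described by one object.
The defaults are the constants of the published method: enrichment values
sampled on a 35-bp grid, median-smoothed in 350-bp windows with at least
5 data points, peaks called at the top-5% quantile with a 200-bp minimum
length and 200-bp extension gap, scored as the mean of the best five
consecutive values, classified with a 0.5 log2 "lost" floor and a
+/-1 log2 "unchanged" band, promoters/gene association at +/-500 bp,
top-300 region selection, and 20-step overlap cutoff sweeps.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class PipelineConfig:
    """Numeric constants of the occupancy pipeline.

    Parameters
    ----------
    grid_step
        Spacing (bp) of the grid on which enrichment values are sampled.
    smooth_window
        Width (bp) of the centered median-smoothing window.
    min_points_per_window
        Minimum number of present values a smoothing window needs; windows
        with fewer are discarded (value becomes missing).
    quantile
        Top fraction of smoothed values used to set the peak-calling cutoff
        (0.05 means the 95th percentile).
    min_region_len
        Minimum span (bp) of a called bound region.
    max_gap
        Maximum distance (bp) between successive above-cutoff values for a
        region to keep extending.
    consec_for_score
        Number of consecutive values averaged to produce the peak value.
    lost_threshold
        Condition-B value (log2) below which occupancy is classed as lost.
    fold_change_threshold
        Half-width (log2) of the "unchanged" band around zero change.
    promoter_halfwidth
        Promoter half-width (bp) around the TSS; also the default
        region-to-gene association distance.
    top_n
        Number of highest-scoring regions used in top-N comparisons.
    sweep_steps
        Number of equal score steps in an overlap cutoff sweep.
    tail_fraction
        Sweep stop rule: stop once at most this fraction of regions remains.
    adjust_mode
        Depth adjustment of the ratio track: ``"log2"`` subtracts
        log2(mean IP) - log2(mean input) (the default, dimensionally
        consistent reading); ``"raw"`` subtracts the raw count difference.
    span_includes_bin
        If True (default), a region's span extends one ``grid_step`` past
        the last above-cutoff position (each value represents its bin), so
        six contiguous grid values at defaults span 210 bp and pass the
        200-bp rule. If False, span is measured between first and last
        positions only.
    """

    grid_step: int = 35
    smooth_window: int = 350
    min_points_per_window: int = 5
    quantile: float = 0.05
    min_region_len: int = 200
    max_gap: int = 200
    consec_for_score: int = 5
    lost_threshold: float = 0.5
    fold_change_threshold: float = 1.0
    promoter_halfwidth: int = 500
    top_n: int = 300
    sweep_steps: int = 20
    tail_fraction: float = 0.05
    adjust_mode: str = "log2"
    span_includes_bin: bool = True

    def __post_init__(self) -> None:
        positives = (
            "grid_step", "smooth_window", "min_points_per_window",
            "min_region_len", "max_gap", "consec_for_score",
            "promoter_halfwidth", "top_n", "sweep_steps",
            "fold_change_threshold",
        )
        for name in positives:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("quantile", "tail_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.lost_threshold < 0:
            raise ValueError("lost_threshold must be non-negative")
        if self.adjust_mode not in ("log2", "raw"):
            raise ValueError("adjust_mode must be 'log2' or 'raw'")

    @property
    def smooth_half_steps(self) -> int:
        """Grid steps on either side of a position inside the window."""
        return (self.smooth_window // 2) // self.grid_step

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_toml(cls, path: str | Path, section: str = "pipeline") -> "PipelineConfig":
        """Load overrides from a TOML file; absent keys keep their defaults."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        overrides = data.get(section, data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**overrides)
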