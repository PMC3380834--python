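import numpy as np
import pytest

from occudiff.config import PipelineConfig
from occudiff.tracks import CoverageTrack, RatioTrack


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


def make_ratio_track(
    values, grid_step: int = 35, seq: str = "chr", kind: str = "smoothed"
) -> RatioTrack:
    """RatioTrack from a value list; None entries become missing."""
    arr = np.array(
        [np.nan if v is None else float(v) for v in values], dtype=float
    )
    return RatioTrack(
        grid_step=grid_step,
        genome_lengths={seq: arr.size * grid_step},
        values={seq: arr},
        kind=kind,
    )


def make_coverage(counts_by_seq) -> CoverageTrack:
    return CoverageTrack(
        {seq: np.asarray(c, dtype=float) for seq, c in counts_by_seq.items()}
    )


def random_sparse_values(rng, n, missing_frac=0.3, scale=2.0):
    """Array of values with NaN holes, for randomized track tests."""
    vals = rng.normal(0.0, scale, n)
    holes = rng.random(n) < missing_frac
    vals[holes] = np.nan
    return vals
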