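"""Interval-set overlap statistics.

A :class:`RegionSet` is a scored collection of genomic intervals (0-based
half-open) supporting one-nucleotide overlap queries, top-N selection by
score, and increasing-cutoff overlap sweeps. Percent overlap is
direction-dependent (a long query region overlapping several targets
still counts once, and swapping query and target generally changes the
answer), so both directions are always computed explicitly and never
averaged.
"""

from __future__ import annotations

import warnings
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .config import PipelineConfig
from .peaks import BoundRegion

__all__ = [
    "RegionSet",
    "percent_overlap",
    "top_n",
    "cutoff_sweep",
    "three_bin_cutoffs",
    "overlap_matrix",
]


class Region(NamedTuple):
    seq: str
    start: int
    end: int
    score: float


class RegionSet:
    """A named, scored interval collection with an overlap index."""

    def __init__(self, name: str, regions: Iterable[tuple] | pd.DataFrame):
        if isinstance(regions, pd.DataFrame):
            df = regions.loc[:, ["seq", "start", "end", "score"]].copy()
        else:
            df = pd.DataFrame(list(regions), columns=["seq", "start", "end", "score"])
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["score"] = df["score"].astype(float)
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError(f"{name}: every region must satisfy start < end")
        if len(df) and ~np.isfinite(df["score"]).all():
            raise ValueError(f"{name}: scores must be finite")
        self.name = name
        self.df = df.sort_values(["seq", "start", "end"], kind="stable").reset_index(
            drop=True
        )
        self._trees: dict[str, IntervalTree] | None = None

    @classmethod
    def from_bound_regions(
        cls, name: str, regions: Iterable[BoundRegion]
    ) -> "RegionSet":
        return cls(
            name, [(r.seq, r.start, r.end, r.peak_value) for r in regions]
        )

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield Region(row.seq, int(row.start), int(row.end), float(row.score))

    @property
    def scores(self) -> np.ndarray:
        return self.df["score"].to_numpy()

    def _index(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            self._trees = {}
            for seq, sub in self.df.groupby("seq", sort=False):
                self._trees[seq] = IntervalTree.from_tuples(
                    zip(sub["start"], sub["end"], sub["score"])
                )
        return self._trees

    def overlaps_any(self, seq: str, start: int, end: int) -> bool:
        """True if ``[start, end)`` shares at least one nucleotide with the set."""
        tree = self._index().get(seq)
        return bool(tree is not None and tree.overlap(start, end))

    def overlapping_scores(self, seq: str, start: int, end: int) -> np.ndarray:
        """Scores of all set regions overlapping ``[start, end)`` by >= 1 nt."""
        tree = self._index().get(seq)
        if tree is None:
            return np.empty(0)
        return np.array(sorted(iv.data for iv in tree.overlap(start, end)))

    def filter_score(self, cutoff: float) -> "RegionSet":
        """Sub-set of regions with score >= cutoff."""
        return RegionSet(self.name, self.df[self.df["score"] >= cutoff])


def percent_overlap(query: RegionSet, target: RegionSet) -> float:
    """Percent of query regions overlapping >= 1 target region by >= 1 nt.

    Each query region counts at most once however many targets it hits.
    """
    if len(query) == 0:
        raise ValueError("empty query set")
    hits = sum(
        target.overlaps_any(r.seq, r.start, r.end) for r in query
    )
    return 100.0 * hits / len(query)


def top_n(regions: RegionSet, n: int) -> RegionSet:
    """The ``n`` highest-scoring regions, ties broken by (seq, start).

    Asking for more regions than exist returns the whole set with a warning.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(regions):
        warnings.warn(
            f"{regions.name}: requested top {n} of {len(regions)} regions; "
            "returning all",
            stacklevel=2,
        )
        n = len(regions)
    order = regions.df.sort_values(
        ["score", "seq", "start"], ascending=[False, True, True], kind="stable"
    )
    return RegionSet(regions.name, order.head(n))


def cutoff_sweep(
    query: RegionSet,
    target: RegionSet,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Percent overlap of the query in the target at increasing score cutoffs.

    Cutoffs run from the minimum to the maximum query score in
    ``sweep_steps`` equal steps (21 candidate cutoffs at defaults). At
    each cutoff, query regions scoring at least the cutoff are retained
    and their percent overlap with the target recorded; the sweep stops
    after the first cutoff at which at most ``tail_fraction`` of the
    query regions remain. Columns: ``cutoff``, ``n_retained``,
    ``percent_overlap`` (NaN when nothing is retained).
    """
    cfg = cfg or PipelineConfig()
    if len(query) == 0:
        raise ValueError("empty query set")
    smin = float(query.scores.min())
    smax = float(query.scores.max())
    if smin == smax:
        warnings.warn(
            f"{query.name}: constant scores; sweep degenerates to one cutoff",
            stacklevel=2,
        )
        cutoffs = [smin]
    else:
        cutoffs = [
            smin + k * (smax - smin) / cfg.sweep_steps
            for k in range(cfg.sweep_steps + 1)
        ]
    rows = []
    stop_at = cfg.tail_fraction * len(query)
    for c in cutoffs:
        retained = query.filter_score(c)
        pct = percent_overlap(retained, target) if len(retained) else np.nan
        rows.append((c, len(retained), pct))
        if len(retained) <= stop_at:
            break
    return pd.DataFrame(rows, columns=["cutoff", "n_retained", "percent_overlap"])


def three_bin_cutoffs(
    query: RegionSet, cfg: PipelineConfig | None = None
) -> tuple[float, float, float]:
    """The three summary cutoffs used for binned overlap plots.

    ``c1`` is no cutoff (the minimum score, all regions included), ``c3``
    the smallest sweep cutoff retaining at most ``tail_fraction`` of the
    regions (the ~5% most enriched), and ``c2`` their average. If no
    sweep cutoff reaches the tail (tiny sets), ``c3`` falls back to the
    maximum score with a warning.
    """
    cfg = cfg or PipelineConfig()
    if len(query) == 0:
        raise ValueError("empty query set")
    scores = query.scores
    smin, smax = float(scores.min()), float(scores.max())
    if smin == smax:
        return smin, smin, smin
    c3 = None
    for k in range(cfg.sweep_steps + 1):
        c = smin + k * (smax - smin) / cfg.sweep_steps
        if (scores >= c).sum() <= cfg.tail_fraction * len(query):
            c3 = c
            break
    if c3 is None:
        warnings.warn(
            f"{query.name}: no sweep cutoff reaches the {cfg.tail_fraction:.0%} "
            "tail; using the maximum score",
            stacklevel=2,
        )
        c3 = smax
    return smin, (smin + c3) / 2.0, c3


def overlap_matrix(
    queries: list[RegionSet],
    targets: list[RegionSet],
    mode: str = "all",
    cfg: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Pairwise percent-overlap tables in both directions.

    ``mode="top_n"`` restricts each target set to its ``top_n``
    highest-scoring regions before computing overlaps (the usual way
    factor compendia are normalized against each other). Returns
    ``{"query_in_target": ..., "target_in_query": ...}``; rows are query
    names and columns target names in both tables.
    """
    cfg = cfg or PipelineConfig()
    if mode not in ("all", "top_n"):
        raise ValueError("mode must be 'all' or 'top_n'")
    if mode == "top_n":
        targets = [top_n(t, min(cfg.top_n, len(t))) for t in targets]
    fwd = pd.DataFrame(
        {
            t.name: [percent_overlap(q, t) for q in queries]
            for t in targets
        },
        index=[q.name for q in queries],
    )
    rev = pd.DataFrame(
        {
            t.name: [percent_overlap(t, q) for q in queries]
            for t in targets
        },
        index=[q.name for q in queries],
    )
    return {"query_in_target": fwd, "target_in_query": rev}
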