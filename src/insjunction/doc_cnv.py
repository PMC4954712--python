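"""Windowed depth-of-coverage and fold-change copy-gain calling.

Depth counts aligned reference-consuming bases (CIGAR M/=/X), not read
starts.  An extra copy of an autosomal region (three copies against a
diploid background) is expected to raise depth by a factor of 1.5; the
default call threshold 1.35 is the midpoint between the no-gain (1.0)
and trisomy (1.5) expectations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignments import AlignmentRecord
from .core import GenomicInterval

TRISOMY_FOLD = 1.5


@dataclass
class DepthProfile:
    contig: str
    interval: GenomicInterval
    window_size: int
    window_starts: np.ndarray  # genome-agnostic 1-based positions
    window_means: np.ndarray
    per_base: np.ndarray  # per-base depth over the interval

    @property
    def mean(self) -> float:
        return float(self.per_base.mean())

    def to_frame(self) -> pd.DataFrame:
        ends = np.minimum(self.window_starts + self.window_size - 1, self.interval.end)
        return pd.DataFrame(
            {"contig": self.contig, "start": self.window_starts, "end": ends,
             "mean_depth": self.window_means}
        )


@dataclass
class CopyGainCall:
    region: GenomicInterval
    fold_change: float
    expected_fold: float
    gained: bool

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold change must be > 0")


def _aligned_spans(rec: AlignmentRecord) -> Iterable[tuple[int, int]]:
    pos = rec.pos
    for op, n in rec.cigar:
        if op in "M=X":
            yield pos, pos + n - 1
            pos += n
        elif op in "DN":
            pos += n


def windowed_depth(
    records: Iterable[AlignmentRecord],
    interval: GenomicInterval,
    window_size: int = 1000,
) -> DepthProfile:
    """Per-window mean depth over ``interval``: aligned-base count divided
    by window length.  The total aligned-base count is conserved across
    windows."""
    lo, hi = interval.start, interval.end
    diff = np.zeros(hi - lo + 2, dtype=np.int64)
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.contig != interval.contig:
            continue
        for s, e in _aligned_spans(rec):
            s, e = max(s, lo), min(e, hi)
            if s <= e:
                diff[s - lo] += 1
                diff[e - lo + 1] -= 1
    per_base = np.cumsum(diff[:-1])
    starts = np.arange(lo, hi + 1, window_size)
    means = np.empty(len(starts), dtype=float)
    for i, s in enumerate(starts):
        e = min(s + window_size - 1, hi)
        means[i] = per_base[s - lo : e - lo + 1].mean()
    return DepthProfile(interval.contig, interval, window_size, starts, means, per_base)


def region_summary(
    profile: DepthProfile, regions: Mapping[str, GenomicInterval]
) -> pd.DataFrame:
    """Mean and (sample) SD of per-window depth for each named region,
    over the windows fully contained in the region."""
    rows = []
    ends = np.minimum(profile.window_starts + profile.window_size - 1, profile.interval.end)
    for name, region in regions.items():
        if region.contig != profile.contig:
            raise ValueError(f"region {name!r} is on a different contig")
        mask = (profile.window_starts >= region.start) & (ends <= region.end)
        vals = profile.window_means[mask]
        if vals.size == 0:
            raise ValueError(f"region {name!r} contains no complete windows")
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append((name, region.start, region.end, float(vals.mean()), sd, int(vals.size)))
    return pd.DataFrame(rows, columns=["region", "start", "end", "mean", "sd", "n_windows"])


def fold_change_call(
    profile: DepthProfile,
    insert_region: GenomicInterval,
    flank_regions: Sequence[GenomicInterval],
    gain_threshold: float = 1.35,
) -> CopyGainCall:
    """Copy-gain call: insert-region mean depth over the mean of the flank
    means; gained when the fold change reaches ``gain_threshold``."""
    regions = {"insert": insert_region}
    regions.update({f"flank{i}": r for i, r in enumerate(flank_regions)})
    summary = region_summary(profile, regions).set_index("region")
    flank_means = summary.loc[[r for r in summary.index if r.startswith("flank")], "mean"]
    flank = float(flank_means.mean())
    if flank <= 0:
        raise ValueError("zero flank depth; cannot compute fold change")
    fold = float(summary.loc["insert", "mean"]) / flank
    return CopyGainCall(insert_region, fold, TRISOMY_FOLD, fold >= gain_threshold)


def merge_profiles(a: DepthProfile, b: DepthProfile) -> DepthProfile:
    """Depth is additive: the profile of merged alignments equals the sum
    of per-file profiles."""
    if (a.contig, a.window_size, a.interval) != (b.contig, b.window_size, b.interval):
        raise ValueError("profiles cover different grids")
    return DepthProfile(
        a.contig, a.interval, a.window_size, a.window_starts,
        a.window_means + b.window_means, a.per_base + b.per_base,
    )
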