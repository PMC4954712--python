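"""Discordant-pair and split-read structural-variant detection.

Two evidence classes drive interchromosomal-insertion discovery from
paired-end WGS:

* discordant pairs — high-quality read pairs whose mates map to
  different chromosomes, or to the same chromosome with an implied
  insert above a threshold (default 700 bp, twice the library mean);
  clustered in sliding windows (default 200 bp) with the local-maximum
  rearrangement position reported per cluster;
* split reads — reads where part of the read aligns at the anchor locus
  and the soft-clipped remainder maps elsewhere; the last aligned base
  adjacent to the clip marks the breakpoint at base resolution, and the
  mate's contig classifies the evidence (anchor on the acceptor vs the
  donor chromosome).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .alignments import AlignmentRecord, FilterPolicy, clip_structure, _occurrences
from .core import Contig, GenomicInterval

DEFAULT_INSERT_THRESHOLD = 700
DEFAULT_WINDOW = 200


@dataclass(frozen=True)
class DiscordantPair:
    qname: str
    locus_a: tuple[str, int]  # (contig, leftmost pos)
    locus_b: tuple[str, int]
    reason: str  # 'inter_chromosomal' | 'long_insert'
    insert_size: Optional[int] = None
    # junction-facing boundaries (read end for forward reads, start for
    # reverse), used for local-maximum clustering
    boundary_a: Optional[int] = None
    boundary_b: Optional[int] = None

    def __post_init__(self) -> None:
        if self.reason == "inter_chromosomal" and self.locus_a[0] == self.locus_b[0]:
            raise ValueError("inter_chromosomal pair on a single contig")


@dataclass
class DiscordantCluster:
    window: GenomicInterval
    partner_contig: str
    support: int
    peak_pos: int


@dataclass(frozen=True)
class SplitReadEvidence:
    qname: str
    contig: str  # anchored contig
    breakpoint_pos: int  # last aligned base adjacent to the clip
    clip_side: str  # 'left' | 'right'
    side: str  # 'proximal' | 'distal'
    clipped_seq: str
    clipped_locus: Optional[tuple[str, int, str]] = None  # (contig, pos, strand)
    mate_anchor: str = "unmapped"  # 'acceptor' | 'donor' | 'other' | 'unmapped'
    resolved_by: Optional[str] = None  # 'supplementary' | 'remap' | 'end_remap'
    ambiguous: bool = False


@dataclass
class EvidenceSummary:
    """Per-breakpoint evidence counts in the shape of a two-breakpoint
    split-read/discordant-pair summary table."""

    counts: pd.DataFrame  # index: breakpoint label; columns: evidence class

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


# ---------------------------------------------------------------------------
# discordant pairs
# ---------------------------------------------------------------------------


def _boundary(rec: AlignmentRecord) -> int:
    """Junction-facing boundary: rightmost aligned base for forward reads
    (mate lies to the right), leftmost for reverse reads."""
    return rec.pos if rec.is_reverse else rec.end


def find_discordant_pairs(
    records: Iterable[AlignmentRecord],
    policy: Optional[FilterPolicy] = None,
    insert_threshold: int = DEFAULT_INSERT_THRESHOLD,
) -> list[DiscordantPair]:
    """Pairs whose mates map to different contigs or whose insert size is
    strictly greater than ``insert_threshold``.  High-quality pairs only:
    both mates must pass the policy (default: primary, non-duplicate,
    MAPQ >= 20).  Each qname is reported at most once."""
    policy = policy or FilterPolicy()
    mates: dict[str, dict[bool, AlignmentRecord]] = defaultdict(dict)
    for rec in records:
        if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
            continue
        mates[rec.qname][rec.is_read2] = rec
    out: list[DiscordantPair] = []
    unpaired = 0
    for qname in mates:
        pair = mates[qname]
        if len(pair) != 2:
            unpaired += 1
            continue
        r1, r2 = pair[False], pair[True]
        if not (policy.passes(r1) and policy.passes(r2)):
            continue
        if r1.contig != r2.contig:
            out.append(
                DiscordantPair(
                    qname, (r1.contig, r1.pos), (r2.contig, r2.pos),
                    "inter_chromosomal", None, _boundary(r1), _boundary(r2),
                )
            )
        else:
            insert = abs(r1.tlen) if r1.tlen else abs(
                max(r1.end, r2.end) - min(r1.pos, r2.pos) + 1
            )
            if insert > insert_threshold:
                out.append(
                    DiscordantPair(
                        qname, (r1.contig, r1.pos), (r2.contig, r2.pos),
                        "long_insert", insert, _boundary(r1), _boundary(r2),
                    )
                )
    if unpaired:
        warnings.warn(f"{unpaired} qnames had no complete mate pair", stacklevel=2)
    return out


def cluster_discordant(
    pairs: Sequence[DiscordantPair],
    window_size: int = DEFAULT_WINDOW,
    min_support: int = 3,
    exclusion: Sequence[GenomicInterval] = (),
) -> list[DiscordantCluster]:
    """Sliding-window clustering (step = window/2) of discordant-pair
    boundaries, per (contig, partner contig).  Overlapping qualifying
    windows sharing a partner merge; the peak is the per-base position
    with the highest boundary count (leftmost on ties).  Clusters
    intersecting an exclusion region are dropped."""
    events: dict[tuple[str, str], list[int]] = defaultdict(list)
    for p in pairs:
        for (contig, _), boundary, (partner, _) in (
            (p.locus_a, p.boundary_a, p.locus_b),
            (p.locus_b, p.boundary_b, p.locus_a),
        ):
            if boundary is not None:
                events[(contig, partner)].append(boundary)
    clusters: list[DiscordantCluster] = []
    step = max(1, window_size // 2)
    for (contig, partner), positions in sorted(events.items()):
        positions = np.sort(np.asarray(positions))
        lo, hi = int(positions[0]), int(positions[-1])
        spans = []
        start = max(1, lo - window_size)
        while start <= hi:
            end = start + window_size - 1
            n = int(np.searchsorted(positions, end, "right") - np.searchsorted(positions, start, "left"))
            if n >= min_support:
                if spans and start <= spans[-1][1] + 1:
                    spans[-1] = (spans[-1][0], max(spans[-1][1], end))
                else:
                    spans.append((start, end))
            start += step
        for s, e in spans:
            inwin = positions[(positions >= s) & (positions <= e)]
            vals, counts = np.unique(inwin, return_counts=True)
            peak = int(vals[np.argmax(counts)])  # leftmost maximum
            window = GenomicInterval(contig, s, e)
            if any(window.overlaps(x) for x in exclusion):
                continue
            clusters.append(DiscordantCluster(window, partner, len(inwin), peak))
    return clusters


def poor_alignment_regions(
    records: Iterable[AlignmentRecord],
    window_size: int = DEFAULT_WINDOW,
    max_low_mapq_frac: float = 0.5,
    low_mapq: int = 20,
) -> list[GenomicInterval]:
    """Windows where poorly aligned records (MAPQ < ``low_mapq``) exceed
    the given fraction, merged when contiguous.  Records are assigned to
    the window containing their leftmost position."""
    totals: dict[tuple[str, int], int] = defaultdict(int)
    low: dict[tuple[str, int], int] = defaultdict(int)
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        key = (rec.contig, (rec.pos - 1) // window_size)
        totals[key] += 1
        if rec.mapq < low_mapq:
            low[key] += 1
    flagged = sorted(k for k in totals if low[k] / totals[k] > max_low_mapq_frac)
    merged: list[GenomicInterval] = []
    for contig, w in flagged:
        start, end = w * window_size + 1, (w + 1) * window_size
        if merged and merged[-1].contig == contig and merged[-1].end + 1 >= start:
            merged[-1] = GenomicInterval(contig, merged[-1].start, end)
        else:
            merged.append(GenomicInterval(contig, start, end))
    return merged


# ---------------------------------------------------------------------------
# split reads
# ---------------------------------------------------------------------------


def _resolve_clip(
    clip_seq: str,
    rec: AlignmentRecord,
    clip_side: str,
    reference: dict[str, Contig],
    supplementary: dict[tuple[str, bool], list[AlignmentRecord]],
    min_clip: int,
    min_distance: int,
):
    """Locate where a clipped subsequence maps: prefer the read's
    supplementary alignment, then a unique whole-clip exact match, then
    the longest uniquely matching clip prefix/suffix (the distal junction
    produces composite clips that never match whole)."""
    supps = supplementary.get((rec.qname, rec.is_read2), [])
    for s in supps:
        if s.contig != rec.contig or abs(s.pos - rec.pos) > min_distance:
            return (s.contig, s.pos, "-" if s.is_reverse else "+"), "supplementary", False
    hits = _occurrences(reference, clip_seq)
    hits = [
        (c, p, st)
        for c, p, st in hits
        if c != rec.contig or abs(p - rec.pos) > min_distance
    ]
    if len(hits) == 1:
        return (*hits[0][:2], hits[0][2]), "remap", False
    if len(hits) > 1:
        return None, "remap", True
    # composite clip: try the longest end-portions of the clip
    from .alignments import _longest_end_match

    for from_start in (True, False):
        length, ehits = _longest_end_match(reference, clip_seq, from_start)
        if length >= min_clip:
            ehits = [
                (c, p, st)
                for c, p, st in ehits
                if c != rec.contig or abs(p - rec.pos) > min_distance
            ]
            if len(ehits) == 1:
                return ehits[0], "end_remap", False
    return None, None, False


def find_split_reads(
    records: Sequence[AlignmentRecord],
    reference: dict[str, Contig],
    min_clip: int = 20,
    acceptor: Optional[str] = None,
    donor: Optional[str] = None,
    min_distance: int = 1000,
) -> list[SplitReadEvidence]:
    """Extract reads with a soft-clipped portion of at least ``min_clip``
    whose clipped subsequence maps away from the anchor ("did not map
    locally": on another contig or more than ``min_distance`` away).

    The breakpoint is the last aligned base adjacent to the clip; the
    mate's contig gives the evidence class (paired end maps to the
    acceptor vs donor chromosome).
    """
    supplementary: dict[tuple[str, bool], list[AlignmentRecord]] = defaultdict(list)
    for rec in records:
        if rec.is_supplementary:
            supplementary[(rec.qname, rec.is_read2)].append(rec)
    out: list[SplitReadEvidence] = []
    for rec in sorted(records, key=lambda r: (r.contig or "", r.pos, r.qname)):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        left, right, seqs = clip_structure(rec)
        for clip_side, seq in seqs.items():
            if len(seq) < min_clip:
                continue
            locus, how, ambiguous = _resolve_clip(
                seq, rec, clip_side, reference, supplementary, min_clip, min_distance
            )
            if how is None and not ambiguous:
                continue
            bp = rec.end if clip_side == "right" else rec.pos
            if rec.contig == acceptor or donor is None:
                side = "proximal" if clip_side == "right" else "distal"
            else:
                side = "proximal" if clip_side == "left" else "distal"
            mate = "unmapped"
            if rec.mate_contig is not None:
                if rec.mate_contig == acceptor:
                    mate = "acceptor"
                elif rec.mate_contig == donor:
                    mate = "donor"
                else:
                    mate = "other"
            out.append(
                SplitReadEvidence(
                    qname=rec.qname, contig=rec.contig, breakpoint_pos=bp,
                    clip_side=clip_side, side=side, clipped_seq=seq,
                    clipped_locus=locus, mate_anchor=mate, resolved_by=how,
                    ambiguous=ambiguous,
                )
            )
    return out


def summarize_evidence(
    splits: Sequence[SplitReadEvidence],
    clusters: Sequence[DiscordantCluster],
    breakpoints: Optional[dict[str, int]] = None,
    acceptor: Optional[str] = None,
    tolerance: int = 5,
) -> EvidenceSummary:
    """Count split reads (by mate anchor) and discordant pairs per
    breakpoint.  Breakpoints default to the modal split-read positions on
    the acceptor contig for each side."""
    if breakpoints is None:
        breakpoints = {}
        for side in ("proximal", "distal"):
            positions = [
                s.breakpoint_pos
                for s in splits
                if s.side == side and (acceptor is None or s.contig == acceptor)
            ]
            if positions:
                vals, counts = np.unique(positions, return_counts=True)
                breakpoints[side] = int(vals[np.argmax(counts)])
    rows = {}
    for side, bp in breakpoints.items():
        near = [
            s
            for s in splits
            if s.side == side
            and abs(s.breakpoint_pos - bp) <= tolerance
            and (acceptor is None or s.contig == acceptor)
        ]
        disc = sum(
            c.support
            for c in clusters
            if c.window.start - DEFAULT_WINDOW <= bp <= c.window.end + DEFAULT_WINDOW
            and (acceptor is None or c.window.contig == acceptor)
        )
        rows[f"{side} ({bp})"] = {
            "split_mate_acceptor": sum(s.mate_anchor == "acceptor" for s in near),
            "split_mate_donor": sum(s.mate_anchor == "donor" for s in near),
            "discordant_pairs": disc,
        }
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    if df.empty:
        df = pd.DataFrame(
            columns=["split_mate_acceptor", "split_mate_donor", "discordant_pairs"]
        ).astype(int)
    return EvidenceSummary(df)


def clusters_to_bed(clusters: Sequence[DiscordantCluster]) -> pd.DataFrame:
    """Clusters as 0-based half-open BED rows."""
    rows = [
        (*c.window.to_bed(), c.partner_contig, c.support, c.peak_pos) for c in clusters
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "partner", "support", "peak_pos"]
    )
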