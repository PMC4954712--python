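"""Base-resolution breakpoint junction characterization.

From split reads anchored at a candidate breakpoint this module builds a
positional-majority consensus across the junction, explains the consensus
as a tiling of reference segments (acceptor, donor, micro-insert,
inverted acceptor), and calls the junction micro-architecture signatures
of replicative repair (MMBIR/FoSTeS): microhomology shared by the two
references at the boundary, short foreign micro-inserts with overlap to
the donor end, small local inversions abutting the breakpoint, and
junction-adjacent SNVs/deletions.  The final event is emitted as an
insertion call with VCF 4.2 breakend records and derivative-chromosome
notation.

Segmentation strategy: the two ends of a junction consensus are anchored
by their maximal exact reference matches (long, hence unique); the short
gap between the anchors is then explained structurally — an edit-tolerant
acceptor extension for junction-adjacent variants, a reverse-strand
acceptor match abutting the resume point for inversions, and a
neighbor-overlap extension search for micro-inserts.  Two hypotheses
(with and without the variant extension) are compared and the one leaving
fewer unexplained bases wins, ties to the simpler one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from .core import Contig, GenomicInterval, revcomp, suffix_prefix_overlap
from .doc_cnv import CopyGainCall
from .sv_detect import EvidenceSummary
from .synthetic_data import (
    JunctionDeletion,
    JunctionSNV,
    JunctionSpec,
    MicroInsert,
)

MIN_MATCH = 10


# ---------------------------------------------------------------------------
# exact-match primitives
# ---------------------------------------------------------------------------


def _match_loci(reference: dict[str, Contig], query: str) -> list[tuple[str, int, str]]:
    """All exact occurrences of query, both strands, as (contig, 1-based
    local start on the forward strand, strand)."""
    out = []
    rc = revcomp(query)
    for name, c in reference.items():
        for q, strand in ((query, "+"), (rc, "-")):
            start = c.sequence.find(q)
            while start != -1:
                out.append((name, start + 1, strand))
                start = c.sequence.find(q, start + 1)
    return out


def _longest_match(
    reference: dict[str, Contig], seq: str, from_start: bool
) -> tuple[int, list[tuple[str, int, str]]]:
    """Longest prefix (from_start) or suffix of ``seq`` occurring exactly
    somewhere in the reference (either strand)."""
    lo, hi, best = 0, len(seq), 0
    while lo < hi:
        mid = (lo + hi + 1) // 2
        sub = seq[:mid] if from_start else seq[-mid:]
        if _match_loci(reference, sub):
            best, lo = mid, mid
        else:
            hi = mid - 1
    if best == 0:
        return 0, []
    sub = seq[:best] if from_start else seq[-best:]
    return best, _match_loci(reference, sub)


# ---------------------------------------------------------------------------
# consensus assembly
# ---------------------------------------------------------------------------


def assemble_junction(
    reads: Sequence[tuple[str, int]], min_support: int = 2, max_tie_frac: float = 0.10
) -> tuple[str, int, bool]:
    """Positional-majority consensus over reads sharing a junction anchor.

    ``reads`` holds (sequence, anchor_index) pairs where ``anchor_index``
    is the 0-based position within the sequence of the shared junction
    column.  Returns (consensus, anchor column within the consensus,
    low_confidence); low confidence means ties occurred at more than
    ``max_tie_frac`` of the columns.
    """
    if len(reads) < min_support:
        raise ValueError(f"need at least {min_support} supporting reads")
    lo = min(-a for _, a in reads)
    hi = max(len(s) - a for s, a in reads)
    width = hi - lo
    votes: list[dict[str, int]] = [dict() for _ in range(width)]
    for seq, anchor in reads:
        for i, base in enumerate(seq):
            col = i - anchor - lo
            votes[col][base] = votes[col].get(base, 0) + 1
    out = []
    ties = 0
    for v in votes:
        if not v:
            out.append("N")
            continue
        ranked = sorted(v.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            ties += 1
        out.append(ranked[0][0])
    low_conf = ties > max_tie_frac * width
    return "".join(out), -lo, low_conf


# ---------------------------------------------------------------------------
# junction segmentation
# ---------------------------------------------------------------------------


@dataclass
class JunctionSegment:
    source: str
    interval: GenomicInterval  # genome coordinates
    strand: str
    role: str  # acceptor_left | donor | micro_insert | inverted_acceptor | acceptor_right | unknown
    consensus_span: tuple[int, int]  # 1-based inclusive columns
    ambiguous: bool = False
    alt_loci: list = field(default_factory=list)


@dataclass
class MicroInsertCall:
    source: Optional[str]
    interval: Optional[GenomicInterval]
    length: int
    overlap_with_neighbor: int
    ambiguous: bool = False
    loci: list = field(default_factory=list)


@dataclass
class InversionCall:
    length: int
    interval: Optional[GenomicInterval] = None  # acceptor interval inverted


@dataclass
class BreakpointJunction:
    side: str  # proximal | distal
    consensus: str
    segments: list[JunctionSegment]
    microhomology_len: int = 0
    microhomology_seq: str = ""
    micro_insert: Optional[MicroInsertCall] = None
    inversion: Optional[InversionCall] = None
    snvs: list[JunctionSNV] = field(default_factory=list)
    deletions: list[JunctionDeletion] = field(default_factory=list)
    unexplained: int = 0
    low_confidence: bool = False


def _genome_interval(
    reference: dict[str, Contig], contig: str, local_start: int, length: int, strand: str
) -> GenomicInterval:
    off = reference[contig].offset
    return GenomicInterval(contig, off + local_start, off + local_start + length - 1, strand)


def _pick_locus(loci: list[tuple[str, int, str]], reference: dict[str, Contig]):
    """Deterministic tie-break: contig order in the reference dict, then
    forward strand before reverse (a reverse-strand tie is the mirror
    artifact inside inverted repeats), then leftmost; ambiguity retained
    in the remainder."""
    order = {name: i for i, name in enumerate(reference)}
    ranked = sorted(loci, key=lambda x: (order.get(x[0], 99), x[2] != "+", x[1]))
    return ranked[0], ranked[1:]


def detect_inversion(
    candidate: str, acceptor: Contig, resume_pos: int
) -> InversionCall:
    """Maximal k such that the last k candidate bases equal the reverse
    complement of the acceptor bases immediately left of ``resume_pos``
    (genome coordinate): a local inversion abutting the breakpoint."""
    best = 0
    lo_limit = min(len(candidate), resume_pos - acceptor.offset - 1)
    for k in range(1, lo_limit + 1):
        if candidate[-k:] == revcomp(acceptor.fetch(resume_pos - k, resume_pos - 1)):
            best = k
    if best == 0:
        return InversionCall(0, None)
    return InversionCall(
        best, GenomicInterval(acceptor.name, resume_pos - best, resume_pos - 1, "-")
    )


def detect_micro_insert(
    subseq: str,
    reference: dict[str, Contig],
    min_hit: int = MIN_MATCH,
    neighbor_tail: str = "",
    max_extension: int = 15,
) -> MicroInsertCall:
    """Identify the source of an unexplained junction subsequence.

    The candidate is extended leftwards into the neighboring (donor)
    segment, longest extension first, because template-switch fragments
    typically share their first bases with the donor end; the overlap is
    then reported as microhomology against the neighbor rather than an
    assignment of those bases to either source.  No unique hit of at
    least ``min_hit`` bases leaves the fragment of unknown origin.
    """
    for ext in range(min(max_extension, len(neighbor_tail)), -1, -1):
        candidate = (neighbor_tail[-ext:] if ext else "") + subseq
        if len(candidate) < min_hit:
            continue
        loci = _match_loci(reference, candidate)
        if not loci:
            continue
        (contig, pos, strand), rest = _pick_locus(loci, reference)
        interval = _genome_interval(reference, contig, pos, len(candidate), strand)
        overlap = suffix_prefix_overlap(neighbor_tail, candidate)
        return MicroInsertCall(
            source=contig, interval=interval, length=len(candidate),
            overlap_with_neighbor=overlap, ambiguous=len(loci) > 1, loci=loci,
        )
    return MicroInsertCall(
        source=None, interval=None, length=len(subseq),
        overlap_with_neighbor=0,
    )


def call_microhomology(
    left_seq_tail: str, right_seq_head: str
) -> tuple[int, str]:
    """Maximal k such that the k bases at the junction are identical in
    both source references at their respective boundaries: the last k of
    the left segment equal the first k of the right segment."""
    k = suffix_prefix_overlap(left_seq_tail, right_seq_head)
    return k, right_seq_head[:k]


def _segment_seq(reference: dict[str, Contig], seg: JunctionSegment) -> str:
    if seg.source not in reference:
        return ""
    c = reference[seg.source]
    s = c.fetch(seg.interval.start, seg.interval.end)
    return s if seg.strand == "+" else revcomp(s)


def _variant_extension(gap: str, acceptor: Contig, resume_genome: int,
                       edit_weight: int = 4, max_edit_frac: float = 0.25,
                       min_ext: int = 8):
    """Try to explain a suffix of the gap as acceptor sequence carrying a
    few junction-adjacent edits, right-anchored at ``resume_genome``-1.
    Returns (consumed gap bases, ref span, snvs, deletions) or None."""
    w = len(gap) + 10
    lo = max(acceptor.offset + 1, resume_genome - w)
    ref_win = acceptor.fetch(lo, resume_genome - 1)
    rt = ref_win[::-1]
    best = None
    for m in range(min_ext, len(gap) + 1):
        rg = gap[-m:][::-1]
        res = edlib.align(rg, rt, mode="SHW", task="distance")
        dist = res["editDistance"]
        if dist < 0 or dist > max(1, math.floor(m * max_edit_frac)):
            continue
        score = m - edit_weight * dist
        if score > 0 and (best is None or score > best[0]):
            best = (score, m)
    if best is None:
        return None
    m = best[1]
    rg = gap[-m:][::-1]
    res = edlib.align(rg, rt, mode="SHW", task="locations")
    span = res["locations"][0][1] + 1
    target = acceptor.fetch(resume_genome - span, resume_genome - 1)
    fwd = edlib.align(gap[-m:], target, mode="NW", task="path")
    snvs, deletions = [], []
    qpos = 0
    tpos = resume_genome - span
    num = ""
    for ch in fwd["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            qpos += n
            tpos += n
        elif ch == "X":
            for i in range(n):
                snvs.append(JunctionSNV(tpos + i, target[tpos + i - (resume_genome - span)], gap[len(gap) - m + qpos + i]))
            qpos += n
            tpos += n
        elif ch == "D":  # consumes target: bases deleted from the junction
            deletions.append(JunctionDeletion(tpos, n))
            tpos += n
        elif ch == "I":  # consumes query: junction-inserted bases; leave unexplained
            qpos += n
    return m, span, snvs, deletions


def segment_junction(
    consensus: str,
    reference: dict[str, Contig],
    min_match: int = MIN_MATCH,
    acceptor: Optional[str] = None,
    side: str = "proximal",
) -> BreakpointJunction:
    """Explain a junction consensus as an ordered tiling of reference
    segments and call the junction micro-architecture.

    The leftmost and rightmost maximal exact matches anchor the walk; the
    gap between them is resolved structurally (variants, inversion,
    micro-insert) as described in the module docstring.
    """
    n = len(consensus)
    left_len, left_loci = _longest_match(reference, consensus, True)
    if left_len < min_match or not left_loci:
        return BreakpointJunction(side, consensus, [], unexplained=n, low_confidence=True)
    (lc, lp, lstrand), lrest = _pick_locus(left_loci, reference)
    left_seg = JunctionSegment(
        source=lc, interval=_genome_interval(reference, lc, lp, left_len, lstrand),
        strand=lstrand, role="unknown", consensus_span=(1, left_len),
        ambiguous=len(left_loci) > 1, alt_loci=lrest,
    )
    if left_len >= n:  # single-source consensus
        left_seg.role = "acceptor_left" if lc == acceptor else "donor"
        return BreakpointJunction(side, consensus, [left_seg])

    right_len, right_loci = _longest_match(reference, consensus, False)
    right_len = min(right_len, n - left_len)  # anchors may not cross
    sub = consensus[-right_len:]
    right_loci = _match_loci(reference, sub) if right_len else []
    if right_len < min_match or not right_loci:
        left_seg.role = "acceptor_left" if lc == acceptor else "donor"
        return BreakpointJunction(
            side, consensus, [left_seg], unexplained=n - left_len, low_confidence=True
        )
    (rc, rp, rstrand), rrest = _pick_locus(right_loci, reference)
    right_seg = JunctionSegment(
        source=rc, interval=_genome_interval(reference, rc, rp, right_len, rstrand),
        strand=rstrand, role="unknown", consensus_span=(n - right_len + 1, n),
        ambiguous=len(right_loci) > 1, alt_loci=rrest,
    )
    left_seg.role = "acceptor_left" if lc == acceptor else "donor"
    right_seg.role = "acceptor_right" if rc == acceptor else "donor"

    segments = [left_seg]
    junction = BreakpointJunction(side, consensus, segments)
    gap = consensus[left_len : n - right_len]
    left_tail = _segment_seq(reference, left_seg)[-30:]

    snvs: list[JunctionSNV] = []
    deletions: list[JunctionDeletion] = []
    inversion = InversionCall(0, None)
    micro: Optional[MicroInsertCall] = None
    resume_genome = right_seg.interval.start if rstrand == "+" else None

    def analyze(gap_seq: str, resume: Optional[int]):
        """Explain gap bases right-to-left: inversion abutting the resume
        point, then micro-insert with neighbor overlap; returns
        (inversion, micro_insert, unexplained)."""
        inv = InversionCall(0, None)
        rest = gap_seq
        if resume is not None and rc == acceptor and rest:
            inv = detect_inversion(rest, reference[acceptor], resume)
            if inv.length:
                rest = rest[: -inv.length]
        mi = None
        unexplained = 0
        if rest:
            mi = detect_micro_insert(rest, reference, min_match, left_tail)
            if mi.source is None:
                unexplained = len(rest)
        return inv, mi, unexplained

    # hypothesis A: no junction-adjacent variants
    inv_a, mi_a, un_a = analyze(gap, resume_genome)
    best = ("A", inv_a, mi_a, un_a, [], [], 0, resume_genome)
    # hypothesis B: a gap suffix is acceptor sequence carrying small edits
    if rc == acceptor and rstrand == "+" and gap:
        ext = _variant_extension(gap, reference[acceptor], right_seg.interval.start)
        if ext is not None:
            m, span, snv_b, del_b = ext
            resume_b = right_seg.interval.start - span
            inv_b, mi_b, un_b = analyze(gap[:-m], resume_b)
            if un_b < un_a:
                best = ("B", inv_b, mi_b, un_b, snv_b, del_b, m, resume_b)
    _, inversion, micro, unexplained, snvs, deletions, consumed, resume_genome = best

    # gap occupies columns [left_len+1 .. left_len+len(gap)]; the last
    # `consumed` of those are the variant-carrying acceptor window
    resume_col = left_len + len(gap) - consumed  # last structural gap column
    inv_len = inversion.length
    if micro is not None:
        mlen = micro.length - micro.overlap_with_neighbor if micro.source else micro.length
        seg = JunctionSegment(
            source=micro.source or "unknown",
            interval=micro.interval
            or GenomicInterval("unknown", 1, max(1, micro.length)),
            strand=micro.interval.strand if micro.interval else "+",
            role="micro_insert" if micro.source else "unknown",
            consensus_span=(left_len + 1, max(left_len + 1, resume_col - inv_len)),
            ambiguous=micro.ambiguous, alt_loci=micro.loci[1:] if micro.loci else [],
        )
        segments.append(seg)
    if inv_len:
        segments.append(
            JunctionSegment(
                source=acceptor, interval=inversion.interval, strand="-",
                role="inverted_acceptor",
                consensus_span=(resume_col - inv_len + 1, resume_col),
            )
        )
    if resume_genome is not None and rc == acceptor and consumed:
        # extend the right anchor down to the resume point (variant window)
        right_seg.interval = GenomicInterval(
            rc, resume_genome, right_seg.interval.end, rstrand
        )
        right_seg.consensus_span = (resume_col + 1, n)
    segments.append(right_seg)

    # microhomology at the boundary between the left anchor and its
    # right-hand neighbor, read off the two source references
    head = _segment_seq(reference, segments[1])[:30]
    mh_len, mh_seq = call_microhomology(left_tail, head)
    junction.microhomology_len = mh_len
    junction.microhomology_seq = mh_seq
    junction.micro_insert = micro
    junction.inversion = inversion if inversion.length else None
    junction.snvs = snvs
    junction.deletions = deletions
    junction.unexplained = unexplained
    return junction


def call_junction_variants(
    consensus: str, acceptor: Contig, window: int = 50, min_match: int = MIN_MATCH
) -> tuple[list[JunctionSNV], list[JunctionDeletion]]:
    """SNVs and deletions on the acceptor side of a junction consensus:
    the acceptor-aligned right anchor is extended leftward with an
    edit-tolerant alignment over up to ``window`` bases, and mismatches /
    missing reference bases are reported against acceptor coordinates."""
    ref = {acceptor.name: acceptor}
    right_len, right_loci = _longest_match(ref, consensus, False)
    if right_len < min_match or not right_loci:
        return [], []
    (rc, rp, rstrand), _ = _pick_locus(right_loci, ref)
    if rstrand != "+":
        return [], []
    gap = consensus[: len(consensus) - right_len][-window:]
    if not gap:
        return [], []
    ext = _variant_extension(gap, acceptor, acceptor.offset + rp)
    if ext is None:
        return [], []
    _, _, snvs, deletions = ext
    return snvs, deletions


# ---------------------------------------------------------------------------
# palindrome / hairpin annotation
# ---------------------------------------------------------------------------


@dataclass
class PalindromeAnnotation:
    center: float  # genome coordinate of the hairpin-loop midpoint
    arm_len: int
    loop_seq: str
    breakpoint_distance: int


def annotate_palindrome(
    acceptor: Contig,
    breakpoint_pos: int,
    max_arm: int = 200,
    max_loop: int = 8,
    min_arm: int = 20,
) -> Optional[PalindromeAnnotation]:
    """Maximal inverted repeat (arms reverse-complementary, loop at most
    ``max_loop`` bases) whose span contains the breakpoint; hairpin loops
    of such palindromes are hotspots for double-strand breaks.  Returns
    None when no arm reaches ``min_arm``."""
    seq = acceptor.sequence
    bp = acceptor.to_local(breakpoint_pos)
    n = len(seq)
    best: Optional[tuple[int, float, str]] = None
    for loop in range(0, max_loop + 1):
        for c in range(max(1, bp - max_arm), min(n, bp + max_arm) + 1):
            # loop occupies local [c, c + loop - 1]
            arm = 0
            while (
                c - 1 - arm >= 1
                and c + loop + arm <= n
                and arm < max_arm
                and seq[c - 2 - arm] == revcomp(seq[c + loop + arm - 1])
            ):
                arm += 1
            if arm < min_arm:
                continue
            span_lo, span_hi = c - arm, c + loop + arm - 1
            if not span_lo <= bp <= span_hi:
                continue
            center = c + (loop - 1) / 2.0
            if best is None or arm > best[0]:
                best = (arm, center, seq[c - 1 : c - 1 + loop])
    if best is None:
        return None
    arm, center, loop_seq = best
    return PalindromeAnnotation(
        center=acceptor.offset + center,
        arm_len=arm,
        loop_seq=loop_seq,
        breakpoint_distance=int(abs(bp - center)),
    )


# ---------------------------------------------------------------------------
# final call and VCF emission
# ---------------------------------------------------------------------------


@dataclass
class InsertionCall:
    acceptor: str
    acceptor_pos: int  # insertion between acceptor_pos and acceptor_pos + 1
    donor_segment: GenomicInterval
    inserted_length: int
    microhomology_len: int = 0
    micro_insert: Optional[MicroInsertCall] = None
    inversion_len: int = 0
    snvs: list[JunctionSNV] = field(default_factory=list)
    deletions: list[JunctionDeletion] = field(default_factory=list)
    evidence: Optional[EvidenceSummary] = None
    copy_gain: Optional[CopyGainCall] = None
    notation: str = ""
    partial: bool = False

    def to_spec(self) -> JunctionSpec:
        """Reconstruct the junction specification implied by this call
        (used e.g. to rebuild the mutant haplotype for assay design)."""
        mi = None
        if self.micro_insert is not None and self.micro_insert.source:
            mi = MicroInsert(
                self.micro_insert.source,
                self.micro_insert.interval.start,
                self.micro_insert.length,
                self.micro_insert.overlap_with_neighbor,
            )
        return JunctionSpec(
            acceptor=self.acceptor,
            acceptor_break=self.acceptor_pos,
            donor_segment=self.donor_segment,
            microhomology=self.microhomology_len,
            micro_insert=mi,
            inversion_len=self.inversion_len,
            snv=self.snvs[0] if self.snvs else None,
            deletion=self.deletions[0] if self.deletions else None,
        )


def emit_call(
    proximal: BreakpointJunction,
    distal: Optional[BreakpointJunction],
    reference: dict[str, Contig],
    acceptor: str,
    evidence: Optional[EvidenceSummary] = None,
    copy_gain: Optional[CopyGainCall] = None,
    band_labels: tuple[str, str] = ("", ""),
) -> tuple[InsertionCall, str]:
    """Combine the two resolved junctions into the final insertion call
    plus VCF 4.2 text (four mate-paired breakend records and one symbolic
    insertion record).  Band labels are configuration metadata used only
    in the derivative-chromosome notation string."""
    acc_left = next((s for s in proximal.segments if s.role == "acceptor_left"), None)
    donor_prox = next((s for s in proximal.segments if s.role == "donor"), None)
    if acc_left is None or donor_prox is None:
        raise ValueError("proximal junction does not resolve acceptor -> donor")
    B = acc_left.interval.end
    dstrand = donor_prox.strand
    donor_contig = donor_prox.source
    donor_start = donor_prox.interval.start if dstrand == "+" else donor_prox.interval.end

    if distal is None:
        call = InsertionCall(
            acceptor=acceptor, acceptor_pos=B,
            donor_segment=donor_prox.interval, inserted_length=0,
            microhomology_len=proximal.microhomology_len,
            evidence=evidence, copy_gain=copy_gain, partial=True,
        )
        return call, _write_vcf(call, proximal, None, reference)

    donor_dist = next((s for s in distal.segments if s.role == "donor"), None)
    acc_right = next((s for s in distal.segments if s.role == "acceptor_right"), None)
    if donor_dist is None or acc_right is None:
        raise ValueError("distal junction does not resolve donor -> acceptor")
    if donor_dist.source != donor_contig:
        raise ValueError(
            f"composite event: junction donor contigs disagree "
            f"({donor_contig} vs {donor_dist.source})"
        )
    donor_end = donor_dist.interval.end if dstrand == "+" else donor_dist.interval.start
    lo, hi = min(donor_start, donor_end), max(donor_start, donor_end)
    donor_iv = GenomicInterval(donor_contig, lo, hi, dstrand)
    novel = 0
    if distal.micro_insert is not None and distal.micro_insert.source:
        novel = distal.micro_insert.length - distal.micro_insert.overlap_with_neighbor
    elif distal.micro_insert is not None:
        novel = distal.micro_insert.length
    deleted = sum(d.length for d in distal.deletions)
    inserted_length = len(donor_iv) + novel - deleted
    notation = (
        f"der({acceptor})dir ins({acceptor};{donor_contig})"
        f"({band_labels[0]};{band_labels[1]})"
    )
    call = InsertionCall(
        acceptor=acceptor, acceptor_pos=B, donor_segment=donor_iv,
        inserted_length=inserted_length,
        microhomology_len=proximal.microhomology_len,
        micro_insert=distal.micro_insert,
        inversion_len=distal.inversion.length if distal.inversion else 0,
        snvs=list(distal.snvs), deletions=list(distal.deletions),
        evidence=evidence, copy_gain=copy_gain, notation=notation,
    )
    return call, _write_vcf(call, proximal, distal, reference)


def _write_vcf(
    call: InsertionCall,
    proximal: BreakpointJunction,
    distal: Optional[BreakpointJunction],
    reference: dict[str, Contig],
) -> str:
    """VCF 4.2 with mate-paired BNDs (local contig coordinates, so the
    records validate against the contig lengths in the header) plus one
    symbolic INS record for the full event."""
    acc = reference[call.acceptor]
    don = reference[call.donor_segment.contig]
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Inserted length">',
        '##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Microhomology length">',
        '##INFO=<ID=EVENT,Number=1,Type=String,Description="Event id">',
    ]
    for c in reference.values():
        lines.append(f"##contig=<ID={c.name},length={len(c)}>")
        lines.append(f"##offset {c.name}={c.offset}")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    pB = acc.to_local(call.acceptor_pos)
    refB = acc.sequence[pB - 1]
    rows = []
    d = call.donor_segment
    plus = d.strand == "+"
    pS = don.to_local(d.start if plus else d.end)
    refS = don.sequence[pS - 1]
    alt_b1 = f"{refB}[{don.name}:{pS}[" if plus else f"{refB}]{don.name}:{pS}]"
    alt_b2 = f"]{acc.name}:{pB}]{refS}" if plus else f"[{acc.name}:{pB}[{refS}"
    rows.append((acc.name, pB, "bnd_prox_a", refB, alt_b1,
                 f"SVTYPE=BND;MATEID=bnd_prox_b;HOMLEN={call.microhomology_len};EVENT=ins1"))
    rows.append((don.name, pS, "bnd_prox_b", refS, alt_b2,
                 "SVTYPE=BND;MATEID=bnd_prox_a;EVENT=ins1"))

    if distal is not None:
        acc_right = next(s for s in distal.segments if s.role == "acceptor_right")
        pR = acc.to_local(acc_right.interval.start)
        refR = acc.sequence[pR - 1]
        pE = don.to_local(d.end if plus else d.start)
        refE = don.sequence[pE - 1]
        ins_bases = ""
        if distal.micro_insert is not None:
            mi = distal.micro_insert
            if mi.source and mi.interval:
                src = reference[mi.source]
                frag = src.fetch(mi.interval.start, mi.interval.end)
                if mi.interval.strand == "-":
                    frag = revcomp(frag)
                ins_bases += frag[mi.overlap_with_neighbor:]
        if distal.inversion is not None and distal.inversion.interval is not None:
            iv = distal.inversion.interval
            ins_bases += revcomp(acc.fetch(iv.start, iv.end))
        alt_d1 = (f"{refE}{ins_bases}[{acc.name}:{pR}[" if plus
                  else f"]{acc.name}:{pR}]{ins_bases}{refE}")
        alt_d2 = (f"]{don.name}:{pE}]{ins_bases}{refR}" if plus
                  else f"{refR}{ins_bases}[{don.name}:{pE}[")
        rows.append((don.name, pE, "bnd_dist_a", refE, alt_d1,
                     "SVTYPE=BND;MATEID=bnd_dist_b;EVENT=ins1"))
        rows.append((acc.name, pR, "bnd_dist_b", refR, alt_d2,
                     "SVTYPE=BND;MATEID=bnd_dist_a;EVENT=ins1"))
        rows.append((acc.name, pB, "ins1", refB, "<INS>",
                     f"SVTYPE=INS;END={pB};SVLEN={call.inserted_length};EVENT=ins1"))

    contig_order = {c: i for i, c in enumerate(reference)}
    rows.sort(key=lambda r: (contig_order.get(r[0], 99), r[1]))
    for chrom, pos, vid, ref, alt, info in rows:
        lines.append(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t{info}")
    return "\n".join(lines) + "\n"
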