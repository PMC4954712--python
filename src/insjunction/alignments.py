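"""SAM/BAM I/O, read-quality filtering, and a light exact-seed mapper.

The mapper exists so the pipeline can run end-to-end from raw FASTQ on
desk-scale references without an external aligner: it places reads by
unique full-length exact match and emits split (soft-clipped primary +
supplementary) alignments for chimeric reads whose prefix and suffix
match different loci.  It assumes error-free reads and exact matching;
see docs/methods.md for the resulting limitations on real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import pysam

from .core import Contig, revcomp

_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")
_OP_CODES = "MIDNSHP=X"


@dataclass
class AlignmentRecord:
    """A single alignment, 1-based leftmost reference position."""

    qname: str
    contig: Optional[str]
    pos: int
    mapq: int
    cigar: list[tuple[str, int]]
    seq: str
    is_paired: bool = False
    is_proper: bool = False
    is_reverse: bool = False
    is_read2: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    is_unmapped: bool = False
    mate_contig: Optional[str] = None
    mate_pos: Optional[int] = None
    tlen: int = 0

    def __post_init__(self) -> None:
        if not self.is_unmapped:
            if self.pos < 1:
                raise ValueError("pos must be >= 1")
            if not 0 <= self.mapq <= 60:
                raise ValueError("mapq must be in [0, 60]")
            qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
            if self.seq and qlen != len(self.seq):
                raise ValueError(
                    f"CIGAR query length {qlen} != sequence length {len(self.seq)}"
                )

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def end(self) -> int:
        """1-based inclusive rightmost aligned reference position."""
        return self.pos + self.ref_span - 1

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar) if self.cigar else "*"


@dataclass(frozen=True)
class FilterPolicy:
    """The read-quality policy applied before SV evidence collection:
    non-duplicate primary records with MAPQ at or above the cut-off
    (both mates, when applied pairwise)."""

    min_mapq: int = 20
    exclude_duplicates: bool = True
    exclude_secondary: bool = True
    keep_supplementary: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_mapq <= 60:
            raise ValueError("min_mapq must be in [0, 60]")

    def passes(self, rec: AlignmentRecord) -> bool:
        if rec.is_unmapped:
            return False
        if rec.mapq < self.min_mapq:
            return False
        if self.exclude_duplicates and rec.is_duplicate:
            return False
        if self.exclude_secondary and rec.is_secondary:
            return False
        if rec.is_supplementary and not self.keep_supplementary:
            return False
        return True


# ---------------------------------------------------------------------------
# pysam conversion and file I/O
# ---------------------------------------------------------------------------


def _from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = (
        [( _OP_CODES[op], n) for op, n in seg.cigartuples] if seg.cigartuples else []
    )
    return AlignmentRecord(
        qname=seg.query_name,
        contig=seg.reference_name if not seg.is_unmapped else None,
        pos=(seg.reference_start + 1) if not seg.is_unmapped else 0,
        mapq=seg.mapping_quality,
        cigar=cigar,
        seq=seg.query_sequence or "",
        is_paired=seg.is_paired,
        is_proper=seg.is_proper_pair,
        is_reverse=seg.is_reverse,
        is_read2=seg.is_read2,
        is_secondary=seg.is_secondary,
        is_supplementary=seg.is_supplementary,
        is_duplicate=seg.is_duplicate,
        is_unmapped=seg.is_unmapped,
        mate_contig=seg.next_reference_name if seg.next_reference_id >= 0 else None,
        mate_pos=(seg.next_reference_start + 1) if seg.next_reference_id >= 0 else None,
        tlen=seg.template_length,
    )


def _to_pysam(rec: AlignmentRecord, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = rec.qname
    seg.query_sequence = rec.seq or None
    seg.flag = (
        (0x1 if rec.is_paired else 0)
        | (0x2 if rec.is_proper else 0)
        | (0x4 if rec.is_unmapped else 0)
        | (0x10 if rec.is_reverse else 0)
        | (0x40 if rec.is_paired and not rec.is_read2 else 0)
        | (0x80 if rec.is_paired and rec.is_read2 else 0)
        | (0x100 if rec.is_secondary else 0)
        | (0x400 if rec.is_duplicate else 0)
        | (0x800 if rec.is_supplementary else 0)
    )
    if not rec.is_unmapped:
        seg.reference_id = header.get_tid(rec.contig)
        seg.reference_start = rec.pos - 1
        seg.mapping_quality = rec.mapq
        seg.cigartuples = [(_OP_CODES.index(op), n) for op, n in rec.cigar]
    if rec.mate_contig is not None:
        seg.next_reference_id = header.get_tid(rec.mate_contig)
        seg.next_reference_start = rec.mate_pos - 1
    seg.template_length = rec.tlen
    if rec.seq:
        seg.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
    return seg


def sam_header(reference: dict[str, Contig]) -> pysam.AlignmentHeader:
    """SAM header with @SQ lines for each contig; coordinate offsets are
    recorded as @CO comment lines."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c.name, "LN": len(c)} for c in reference.values()],
        "CO": [f"offset {c.name}={c.offset}" for c in reference.values()],
    }
    return pysam.AlignmentHeader.from_dict(header)


def write_alignments(
    records: Sequence[AlignmentRecord], path: str, reference: dict[str, Contig]
) -> None:
    """Write records to SAM (or BAM if the path ends in .bam), coordinate
    sorted."""
    header = sam_header(reference)
    order = {name: i for i, name in enumerate(reference)}
    mode = "wb" if str(path).endswith(".bam") else "w"
    recs = sorted(
        records, key=lambda r: (r.is_unmapped, order.get(r.contig, 1 << 30), r.pos)
    )
    with pysam.AlignmentFile(path, mode, header=header) as fh:
        for rec in recs:
            fh.write(_to_pysam(rec, header))


def read_alignments(
    path: str, policy: Optional[FilterPolicy] = None
) -> Iterator[AlignmentRecord]:
    """Stream records from SAM/BAM in file order, applying the filter
    policy record-wise (duplicates, secondaries, MAPQ)."""
    try:
        with pysam.AlignmentFile(path, check_sq=True) as fh:
            if not fh.header.get("SQ"):
                raise ValueError(f"{path}: missing @SQ header lines")
            for seg in fh:
                rec = _from_pysam(seg)
                if policy is None or policy.passes(rec):
                    yield rec
    except (ValueError, OSError) as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# clip structure
# ---------------------------------------------------------------------------


def clip_structure(rec: AlignmentRecord) -> tuple[int, int, dict[str, str]]:
    """Clip lengths at each end of the alignment plus the soft-clipped
    subsequences ({'left': ..., 'right': ...}; hard clips have no
    sequence)."""
    if not rec.cigar:
        raise ValueError("record has no CIGAR")
    left = right = 0
    i = 0
    ops = rec.cigar
    if i < len(ops) and ops[i][0] == "H":
        left += ops[i][1]
        i += 1
    left_soft = 0
    if i < len(ops) and ops[i][0] == "S":
        left_soft = ops[i][1]
        left += left_soft
    j = len(ops) - 1
    if j >= 0 and ops[j][0] == "H":
        right += ops[j][1]
        j -= 1
    right_soft = 0
    if j >= 0 and ops[j][0] == "S" and j != i - 1:
        right_soft = ops[j][1]
        right += right_soft
    subseqs: dict[str, str] = {}
    if rec.seq:
        if left_soft:
            subseqs["left"] = rec.seq[:left_soft]
        if right_soft:
            subseqs["right"] = rec.seq[len(rec.seq) - right_soft :]
    return left, right, subseqs


# ---------------------------------------------------------------------------
# light exact-seed mapper
# ---------------------------------------------------------------------------


class KmerIndex:
    """Exact k-mer index over the forward strands of a contig set."""

    def __init__(self, reference: dict[str, Contig], k: int = 31):
        total = sum(len(c) for c in reference.values())
        if total > 10_000_000:
            raise ValueError("reference too large to k-mer index in memory (> 10 Mb)")
        self.k = k
        self.reference = reference
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, c in reference.items():
            s = c.sequence
            for i in range(len(s) - k + 1):
                self.index.setdefault(s[i : i + k], []).append((name, i + 1))

    def seed_hits(self, seq: str) -> list[tuple[str, int]]:
        return self.index.get(seq[: self.k], [])


def _occurrences(reference: dict[str, Contig], query: str) -> list[tuple[str, int, str]]:
    """All exact occurrences of ``query`` on either strand, as
    (contig, 1-based local start on the forward strand, strand)."""
    out = []
    rc = revcomp(query)
    for name, c in reference.items():
        s = c.sequence
        for q, strand in ((query, "+"), (rc, "-")):
            start = s.find(q)
            while start != -1:
                out.append((name, start + 1, strand))
                start = s.find(q, start + 1)
    return out


def _longest_end_match(
    reference: dict[str, Contig], seq: str, from_start: bool
) -> tuple[int, list[tuple[str, int, str]]]:
    """Longest prefix (or suffix) of ``seq`` with at least one exact
    occurrence; binary search on length."""
    lo, hi, best = 0, len(seq), 0
    while lo < hi:
        mid = (lo + hi + 1) // 2
        sub = seq[:mid] if from_start else seq[-mid:]
        if _occurrences(reference, sub):
            best = mid
            lo = mid
        else:
            hi = mid - 1
    if best == 0:
        return 0, []
    sub = seq[:best] if from_start else seq[-best:]
    return best, _occurrences(reference, sub)


def map_reads(
    read_pairs: Iterable[tuple[str, str, str]],
    reference: dict[str, Contig],
    k: int = 31,
) -> list[AlignmentRecord]:
    """Map error-free reads by unique exact match.

    ``read_pairs`` yields (qname, seq1, seq2).  Full-length unique matches
    become full-match records at MAPQ 60; chimeric reads whose prefix and
    suffix match different loci become a soft-clipped primary plus a
    supplementary; ambiguous reads get MAPQ 0.
    """
    records: list[AlignmentRecord] = []
    idx = KmerIndex(reference, k)
    for qname, seq1, seq2 in read_pairs:
        if k > min(len(seq1), len(seq2)):
            raise ValueError("k exceeds read length")
        placed = [_map_single(reference, idx, s) for s in (seq1, seq2)]
        for mate, (runs, _) in enumerate(placed):
            other_runs, _ = placed[1 - mate]
            mate_primary = other_runs[0] if other_runs else None
            for ri, run in enumerate(runs):
                rec = run
                rec.qname = qname
                rec.is_paired = True
                rec.is_read2 = mate == 1
                rec.is_supplementary = ri > 0
                if mate_primary is not None and not mate_primary.is_unmapped:
                    rec.mate_contig = mate_primary.contig
                    rec.mate_pos = mate_primary.pos
                    if rec.contig == rec.mate_contig and not rec.is_unmapped:
                        lo = min(rec.pos, rec.mate_pos)
                        hi = max(rec.end, mate_primary.end)
                        rec.tlen = (hi - lo + 1) * (1 if rec.pos <= rec.mate_pos else -1)
                        rec.is_proper = abs(rec.tlen) <= 1000
                records.append(rec)
    order = {name: i for i, name in enumerate(reference)}
    records.sort(key=lambda r: (r.is_unmapped, order.get(r.contig, 1 << 30), r.pos))
    return records


def _map_single(reference, idx: KmerIndex, seq: str):
    n = len(seq)
    full_hits = []
    for query, strand in ((seq, "+"), (revcomp(seq), "-")):
        for name, pos in idx.seed_hits(query):
            c = reference[name]
            if c.sequence[pos - 1 : pos - 1 + n] == query:
                full_hits.append((name, pos, strand))
    full_hits = sorted(set(full_hits))
    if len(full_hits) == 1:
        name, pos, strand = full_hits[0]
        rec = AlignmentRecord(
            qname="", contig=name, pos=pos, mapq=60, cigar=[("M", n)],
            seq=seq if strand == "+" else revcomp(seq), is_reverse=strand == "-",
        )
        return [rec], "unique"
    if len(full_hits) > 1:
        name, pos, strand = full_hits[0]
        rec = AlignmentRecord(
            qname="", contig=name, pos=pos, mapq=0, cigar=[("M", n)],
            seq=seq if strand == "+" else revcomp(seq), is_reverse=strand == "-",
        )
        return [rec], "ambiguous"
    # split mapping: longest exact prefix and suffix
    plen, phits = _longest_end_match(reference, seq, True)
    slen, shits = _longest_end_match(reference, seq, False)
    recs = []
    for (length, hits, at_start) in ((plen, phits, True), (slen, shits, False)):
        if length < idx.k or len(hits) != 1:
            continue
        name, pos, strand = hits[0]
        clip = n - length
        sub = seq[:length] if at_start else seq[-length:]
        if strand == "+":
            cigar = [("M", length), ("S", clip)] if at_start else [("S", clip), ("M", length)]
            rseq = seq
        else:
            cigar = [("S", clip), ("M", length)] if at_start else [("M", length), ("S", clip)]
            rseq = revcomp(seq)
        recs.append(
            AlignmentRecord(
                qname="", contig=name, pos=pos, mapq=60, cigar=cigar, seq=rseq,
                is_reverse=strand == "-",
            )
        )
    if not recs:
        rec = AlignmentRecord(
            qname="", contig=None, pos=0, mapq=0, cigar=[], seq=seq, is_unmapped=True
        )
        return [rec], "unmapped"
    recs.sort(key=lambda r: -max(n for op, n in r.cigar if op == "M"))
    return recs, "split"
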