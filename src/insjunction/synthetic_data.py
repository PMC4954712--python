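"""Synthetic ground-truth generator for interchromosomal-insertion studies.

This module is the stand-in for unavailable patient genomes: it builds
reference contigs, plants a fully specified insertion junction
(microhomology, third-chromosome micro-insert with donor overlap, local
inversion, junction-adjacent SNV and deletion), simulates error-free
paired-end reads with per-read truth, projects those reads back onto the
reference as split/discordant alignments, and generates X-linked cohorts
and comparative-Ct tables.

The packaged ``cmtx3`` preset reproduces the published junction
micro-architecture of the 78 kb chr8q24.3 -> Xq27.1 insertion: acceptor
break at chrX:139,502,948, donor segment of 77,856 bp starting at
chr8:145,768,312, 2 bp microhomology (AA), a 19 bp chr12q13.12
micro-insert whose first 10 bp overlap the donor end, a 12 bp acceptor
inversion, an SNV (T>G) at chrX:139,502,968 and a 1 bp deletion at
chrX:139,502,976, with a 180 bp palindrome (TATC loop) spanning the
acceptor breakpoint.

Planted junctions are *identifiable by construction*: single reference
bases flanking each planted feature are adjusted so that the planted
parameters are the unique maximal-parsimony parse of the junction
sequence (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Contig, GenomicInterval, complement, revcomp, suffix_prefix_overlap

UNDETERMINED = "Undetermined"

# ---------------------------------------------------------------------------
# junction specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MicroInsert:
    """Short foreign fragment inserted at the distal junction.

    ``start`` is the genome coordinate (on ``source``) of the first base of
    the full ``length``-bp fragment; the first ``overlap_with_donor`` bases
    are shared with the donor-segment end (template-switch microhomology),
    so only ``length - overlap_with_donor`` novel bases appear in the
    mutant haplotype.
    """

    source: str
    start: int
    length: int
    overlap_with_donor: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("micro-insert length must be >= 1")
        if not 0 <= self.overlap_with_donor <= self.length:
            raise ValueError("overlap_with_donor must be in [0, length]")


@dataclass(frozen=True)
class JunctionSNV:
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("SNV ref and alt must differ")


@dataclass(frozen=True)
class JunctionDeletion:
    pos: int
    length: int = 1

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("deletion length must be >= 1")


@dataclass(frozen=True)
class JunctionSpec:
    """Complete description of a planted interchromosomal insertion.

    All coordinates are genome-scale (contig offset applied), 1-based.
    The donor segment is inserted directly after ``acceptor_break`` on the
    acceptor contig; ``donor_segment.strand`` gives its orientation.
    """

    acceptor: str
    acceptor_break: int
    donor_segment: GenomicInterval
    microhomology: int = 0
    micro_insert: Optional[MicroInsert] = None
    inversion_len: int = 0
    snv: Optional[JunctionSNV] = None
    deletion: Optional[JunctionDeletion] = None

    def __post_init__(self) -> None:
        if self.microhomology < 0:
            raise ValueError("microhomology length must be >= 0")
        if self.inversion_len < 0:
            raise ValueError("inversion length must be >= 0")
        resume = self.acceptor_break + self.inversion_len
        for v, what in ((self.snv, "SNV"), (self.deletion, "deletion")):
            if v is not None and v.pos <= resume:
                raise ValueError(
                    f"junction {what} at {v.pos} overlaps the inverted/junction "
                    f"region ending at {resume}"
                )
        if self.snv is not None and self.deletion is not None:
            dstart, dend = self.deletion.pos, self.deletion.pos + self.deletion.length - 1
            if dstart <= self.snv.pos <= dend:
                raise ValueError("SNV lies inside the deleted bases")

    @property
    def novel_insert_len(self) -> int:
        if self.micro_insert is None:
            return 0
        return self.micro_insert.length - self.micro_insert.overlap_with_donor

    @property
    def donor_length(self) -> int:
        return len(self.donor_segment)


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")

CMTX3_ACCEPTOR = "chrX_mini"
CMTX3_DONOR = "chr8_mini"
CMTX3_THIRD = "chr12_mini"


def cmtx3_spec() -> JunctionSpec:
    """The packaged preset: junction architecture of the 78 kb insertion."""
    donor_start = 145_768_312
    return JunctionSpec(
        acceptor=CMTX3_ACCEPTOR,
        acceptor_break=139_502_948,
        donor_segment=GenomicInterval(CMTX3_DONOR, donor_start, donor_start + 77_856 - 1, "+"),
        microhomology=2,
        micro_insert=MicroInsert(CMTX3_THIRD, 50_272_500, 19, 10),
        inversion_len=12,
        snv=JunctionSNV(139_502_968, "T", "G"),
        deletion=JunctionDeletion(139_502_976, 1),
    )


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def build_reference(config: dict) -> dict[str, Contig]:
    """Build named random reference contigs from a config dict.

    ``config`` holds ``seed`` and ``contigs``: a list of dicts with
    ``name``, ``length`` and ``offset``.  Alternatively ``{"preset":
    "cmtx3", "seed": s}`` returns the fully planted preset reference.
    Deterministic for a given seed.
    """
    if config.get("preset") == "cmtx3":
        refs, _ = cmtx3_reference(seed=config.get("seed", 0))
        return refs
    rng = np.random.default_rng(config["seed"])
    contigs: dict[str, Contig] = {}
    for entry in config["contigs"]:
        name = entry["name"]
        if name in contigs:
            raise ValueError(f"duplicate contig name {name!r}")
        offset = int(entry.get("offset", 0))
        if offset < 0:
            raise ValueError(f"contig {name!r}: offset would give non-positive coordinates")
        seq = _random_seq(rng, int(entry["length"])).tobytes().decode()
        contigs[name] = Contig(name, seq, offset)
    return contigs


class _Editable:
    """Mutable view of a contig set, addressed by genome coordinates."""

    def __init__(self, contigs: dict[str, Contig]):
        self.arrays = {n: bytearray(c.sequence, "ascii") for n, c in contigs.items()}
        self.offsets = {n: c.offset for n, c in contigs.items()}

    def get(self, name: str, pos: int) -> str:
        return chr(self.arrays[name][pos - self.offsets[name] - 1])

    def set(self, name: str, pos: int, base: str) -> None:
        self.arrays[name][pos - self.offsets[name] - 1] = ord(base)

    def fetch(self, name: str, start: int, end: int) -> str:
        off = self.offsets[name]
        return self.arrays[name][start - off - 1 : end - off].decode()

    def set_range(self, name: str, start: int, seq: str) -> None:
        off = self.offsets[name]
        self.arrays[name][start - off - 1 : start - off - 1 + len(seq)] = seq.encode()

    def contains(self, name: str, pos: int) -> bool:
        local = pos - self.offsets[name]
        return 1 <= local <= len(self.arrays[name])

    def to_contigs(self) -> dict[str, Contig]:
        return {
            n: Contig(n, arr.decode(), self.offsets[n]) for n, arr in self.arrays.items()
        }


def plant_palindrome(
    contig: Contig, center_pos: int, arm_len: int, loop: str = "TATC"
) -> Contig:
    """Plant a perfect inverted repeat (hairpin) with the given loop.

    ``center_pos`` is the genome coordinate of the first loop base.  The
    left arm occupies the ``arm_len`` bases immediately before the loop;
    the right arm is its reverse complement.
    """
    ed = _Editable({contig.name: contig})
    ed.set_range(contig.name, center_pos, loop)
    left = ed.fetch(contig.name, center_pos - arm_len, center_pos - 1)
    ed.set_range(contig.name, center_pos + len(loop), revcomp(left))
    return ed.to_contigs()[contig.name]


def _donor_mutant_seq(ed: _Editable, spec: JunctionSpec) -> str:
    d = spec.donor_segment
    seq = ed.fetch(d.contig, d.start, d.end)
    return seq if d.strand == "+" else revcomp(seq)


def plant_junction(
    contigs: dict[str, Contig], spec: JunctionSpec, seed: int = 0
) -> dict[str, Contig]:
    """Edit reference contigs so the junction architecture of ``spec`` is
    both *present* (shared microhomology/overlap bases really are shared)
    and *identifiable* (boundary bases adjacent to each planted feature
    are adjusted so the planted parameters are the unique maximal parse).

    Returns a new contig dict; inputs are not modified.
    """
    rng = np.random.default_rng(seed)
    ed = _Editable(contigs)
    acc, B = spec.acceptor, spec.acceptor_break
    d = spec.donor_segment
    h = spec.microhomology
    mi = spec.micro_insert
    inv = spec.inversion_len

    def pick_base(avoid: set[str]) -> str:
        choices = [b for b in "ACGT" if b not in avoid]
        return choices[int(rng.integers(0, len(choices)))]

    def replant() -> None:
        # microhomology: donor prefix (in inserted orientation) := acceptor tail
        if h > 0:
            tail = ed.fetch(acc, B - h + 1, B)
            if d.strand == "+":
                ed.set_range(d.contig, d.start, tail)
            else:
                ed.set_range(d.contig, d.end - h + 1, revcomp(tail))
        # micro-insert overlap: fragment prefix := donor tail (inserted orientation)
        if mi is not None and mi.overlap_with_donor > 0:
            dm = _donor_mutant_seq(ed, spec)
            ed.set_range(mi.source, mi.start, dm[-mi.overlap_with_donor :])
        if spec.snv is not None:
            ed.set(acc, spec.snv.pos, spec.snv.ref)

    for _ in range(300):
        replant()
        dm = _donor_mutant_seq(ed, spec)
        novel = (
            ed.fetch(mi.source, mi.start + mi.overlap_with_donor, mi.start + mi.length - 1)
            if mi is not None and spec.novel_insert_len > 0
            else ""
        )
        inv_seq = revcomp(ed.fetch(acc, B + 1, B + inv)) if inv > 0 else ""
        resume = B + inv + 1
        # first mutant base after the donor part / last before acceptor resume
        after_donor = (novel or inv_seq or ed.get(acc, resume))[0]
        before_resume = (inv_seq or novel or dm)[-1]
        before_inv = (novel or dm)[-1]

        edits: list[tuple[str, int, set[str]]] = []  # (contig, pos, avoid-bases)
        # K1: acceptor left-anchor match must stop exactly at the break
        if ed.get(acc, B + 1) == dm[0]:
            edits.append((acc, B + 1, {dm[0]}))
        # K2: proximal microhomology must scan to exactly h
        k = suffix_prefix_overlap(ed.fetch(acc, max(B - h - 20, 1), B), dm[: h + 20])
        if k != h:
            pos = d.start + h if d.strand == "+" else d.end - h
            edits.append((d.contig, pos, {ed.get(d.contig, pos)}))
        # K3: donor anchor must stop exactly at the donor end
        if d.strand == "+":
            if ed.contains(d.contig, d.end + 1) and ed.get(d.contig, d.end + 1) == after_donor:
                edits.append((d.contig, d.end + 1, {after_donor}))
        else:
            if ed.contains(d.contig, d.start - 1) and complement(
                ed.get(d.contig, d.start - 1)
            ) == after_donor:
                edits.append((d.contig, d.start - 1, {complement(after_donor)}))
        # K4: donor/micro-insert overlap must scan to exactly the planted value
        if mi is not None and spec.novel_insert_len > 0:
            frag = ed.fetch(mi.source, mi.start, mi.start + mi.length - 1)
            ov = suffix_prefix_overlap(dm[-(mi.overlap_with_donor + 20) :], frag)
            if ov != mi.overlap_with_donor:
                pos = mi.start + mi.overlap_with_donor
                edits.append((mi.source, pos, {ed.get(mi.source, pos)}))
        # K4b: the base before the fragment on its source contig must not
        # extend the donor-overlap scan (otherwise micro-insert detection
        # would report one extra shared base)
        if mi is not None and spec.novel_insert_len > 0 and mi.overlap_with_donor < len(dm):
            if ed.contains(mi.source, mi.start - 1) and ed.get(
                mi.source, mi.start - 1
            ) == dm[-(mi.overlap_with_donor + 1)]:
                edits.append((mi.source, mi.start - 1, {dm[-(mi.overlap_with_donor + 1)]}))
        # K5: donor right-anchor (proximal) must not extend left of the start
        if d.strand == "+":
            if ed.contains(d.contig, d.start - 1) and ed.get(d.contig, d.start - 1) == ed.get(
                acc, B
            ):
                edits.append((d.contig, d.start - 1, {ed.get(acc, B)}))
        else:
            if ed.contains(d.contig, d.end + 1) and complement(
                ed.get(d.contig, d.end + 1)
            ) == ed.get(acc, B):
                edits.append((d.contig, d.end + 1, {complement(ed.get(acc, B))}))
        # K6: the abutting reverse-strand scan must report exactly inv
        gap = novel + inv_seq
        kinv = 0
        for kk in range(1, len(gap) + 1):
            if gap[-kk:] == revcomp(ed.fetch(acc, resume - kk, resume - 1)):
                kinv = kk
        if kinv != inv and gap:
            # the k=kinv equality involves the base just left of the true
            # inversion; perturb the deepest offending gap base we own
            if inv > 0 and novel:
                pos = mi.start + mi.length - 1  # last novel fragment base
                edits.append((mi.source, pos, {novel[-1]}))
            elif inv > 0:
                pos = d.end if d.strand == "+" else d.start
                edits.append((d.contig, pos, {dm[-1]}))
            else:  # inv == 0 but scan found spurious inversion signal
                pos = (
                    mi.start + mi.length - 1
                    if novel
                    else (d.end if d.strand == "+" else d.start)
                )
                edits.append(
                    (mi.source if novel else d.contig, pos, {gap[-1]})
                )
        # K7: acceptor resume anchor must not extend left of the resume point
        if ed.get(acc, resume - 1) == before_resume and resume - 1 > B or (
            resume - 1 == B and ed.get(acc, B) == before_resume and (novel or dm)
        ):
            if resume - 1 > B:
                edits.append((acc, resume - 1, {before_resume}))
            elif novel:
                edits.append((mi.source, mi.start + mi.length - 1, {ed.get(acc, B)}))
            else:
                pos = d.end if d.strand == "+" else d.start
                edits.append((d.contig, pos, {ed.get(acc, B)}))
        if not edits:
            break
        name, pos, avoid = edits[0]
        avoid = set(avoid) | {ed.get(name, pos)}
        ed.set(name, pos, pick_base(avoid))
    else:
        raise RuntimeError("junction disambiguation did not converge")
    return ed.to_contigs()


def cmtx3_reference(seed: int = 0) -> tuple[dict[str, Contig], JunctionSpec]:
    """Preset reference: three mini-contigs carrying hg19-scale offsets,
    a 180 bp palindrome spanning the acceptor breakpoint, and the fully
    planted junction architecture."""
    spec = cmtx3_spec()
    config = {
        "seed": seed,
        "contigs": [
            # local position 100,000 <-> chrX:139,502,948 (acceptor break)
            {"name": CMTX3_ACCEPTOR, "length": 200_000, "offset": 139_402_948},
            # local position 1 <-> chr8:145,700,000 (DOC assessment interval start)
            {"name": CMTX3_DONOR, "length": 200_000, "offset": 145_699_999},
            {"name": CMTX3_THIRD, "length": 5_000, "offset": 50_270_000},
        ],
    }
    refs = build_reference(config)
    ed = _Editable(refs)
    # 180 bp palindrome: 88 bp arms around the TATC hairpin loop at
    # chrX:139,502,953-139,502,956, spanning the acceptor breakpoint.
    # Bases needed by later plants are chosen on the left arm first so the
    # mirrored right arm stays consistent where possible.
    ed.set_range(CMTX3_ACCEPTOR, 139_502_947, "AA")  # microhomology bases
    ed.set(CMTX3_ACCEPTOR, 139_502_949, "C")  # keeps the left-anchor stop clean
    ed.set(CMTX3_ACCEPTOR, 139_502_941, "A")  # mirrors to the SNV ref base T at 968
    refs = ed.to_contigs()
    refs[CMTX3_ACCEPTOR] = plant_palindrome(
        refs[CMTX3_ACCEPTOR], 139_502_953, arm_len=88, loop="TATC"
    )
    # break the mirror pair of the breakpoint base (948 <-> 961): inside a
    # perfect palindrome the acceptor-left junction flank would match the
    # far arm on the minus strand just as well as its own locus, leaving
    # the junction parse ambiguous; real identifiable junctions require
    # this imperfection (the published palindrome is likewise interrupted)
    ed = _Editable(refs)
    if ed.get(CMTX3_ACCEPTOR, 139_502_961) == complement(ed.get(CMTX3_ACCEPTOR, 139_502_948)):
        ed.set(CMTX3_ACCEPTOR, 139_502_961, "C")
    refs = ed.to_contigs()
    return plant_junction(refs, spec, seed=seed), spec


# ---------------------------------------------------------------------------
# mutant haplotype
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentBlock:
    """Maps a mutant-haplotype interval back to reference coordinates.

    ``hap_start``/``hap_end`` are 1-based local positions on the haplotype;
    ``ref_start``/``ref_end`` are genome coordinates on ``contig``.
    """

    hap_start: int
    hap_end: int
    contig: str
    ref_start: int
    ref_end: int
    strand: str = "+"


@dataclass
class Haplotype:
    contig: Contig
    blocks: list[SegmentBlock]

    @property
    def name(self) -> str:
        return self.contig.name


def reference_haplotype(contig: Contig) -> Haplotype:
    block = SegmentBlock(1, len(contig), contig.name, contig.offset + 1, contig.offset + len(contig))
    return Haplotype(contig, [block])


@dataclass
class TruthRecord:
    """Ground truth for one simulated haplotype: the spec that was planted
    and the segment map from haplotype to reference coordinates."""

    spec: JunctionSpec
    haplotype: str
    blocks: list[SegmentBlock]


def build_mutant_haplotype(
    reference: dict[str, Contig], spec: JunctionSpec, name: str = "mut_acceptor"
) -> tuple[Contig, TruthRecord]:
    """Assemble the mutant acceptor haplotype described by ``spec``.

    The references must already carry the shared microhomology/overlap
    bases (see :func:`plant_junction`); a spec whose shared bases are not
    actually shared in the references is rejected.  Returned haplotype
    length obeys::

        len(acceptor) + len(donor segment)
            + (micro-insert length - overlap_with_donor)
            - deletion length
    """
    for cname in {spec.acceptor, spec.donor_segment.contig} | (
        {spec.micro_insert.source} if spec.micro_insert else set()
    ):
        if cname not in reference:
            raise ValueError(f"spec references unknown contig {cname!r}")
    acc = reference[spec.acceptor]
    B = spec.acceptor_break
    d = spec.donor_segment
    donor = reference[d.contig].fetch(d.start, d.end)
    if d.strand == "-":
        donor = revcomp(donor)
    if spec.microhomology > 0:
        tail = acc.fetch(B - spec.microhomology + 1, B)
        if donor[: spec.microhomology] != tail:
            raise ValueError(
                "microhomology bases are not shared by the references; "
                "run plant_junction first"
            )
    novel = ""
    if spec.micro_insert is not None:
        mi = spec.micro_insert
        frag = reference[mi.source].fetch(mi.start, mi.start + mi.length - 1)
        if mi.overlap_with_donor > 0 and frag[: mi.overlap_with_donor] != donor[-mi.overlap_with_donor :]:
            raise ValueError(
                "micro-insert overlap bases are not shared with the donor end; "
                "run plant_junction first"
            )
        novel = frag[mi.overlap_with_donor :]
    inv_seq = revcomp(acc.fetch(B + 1, B + spec.inversion_len)) if spec.inversion_len else ""
    resume = B + spec.inversion_len + 1

    tail = acc.fetch(resume, acc.offset + len(acc))
    # apply SNV and deletion to the resumed acceptor sequence
    tail_arr = bytearray(tail, "ascii")
    if spec.snv is not None:
        i = spec.snv.pos - resume
        if tail_arr[i : i + 1].decode() != spec.snv.ref:
            raise ValueError("SNV ref base does not match the acceptor reference")
        tail_arr[i] = ord(spec.snv.alt)
    if spec.deletion is not None:
        i = spec.deletion.pos - resume
        del tail_arr[i : i + spec.deletion.length]
    tail = tail_arr.decode()

    left = acc.fetch(acc.offset + 1, B)
    seq = left + donor + novel + inv_seq + tail

    blocks: list[SegmentBlock] = []
    cursor = 1

    def add(length: int, contig: str, ref_start: int, ref_end: int, strand: str = "+") -> None:
        nonlocal cursor
        if length <= 0:
            return
        blocks.append(SegmentBlock(cursor, cursor + length - 1, contig, ref_start, ref_end, strand))
        cursor += length

    add(len(left), spec.acceptor, acc.offset + 1, B)
    add(len(donor), d.contig, d.start, d.end, d.strand)
    if novel:
        mi = spec.micro_insert
        add(len(novel), mi.source, mi.start + mi.overlap_with_donor, mi.start + mi.length - 1)
    add(len(inv_seq), spec.acceptor, B + 1, B + spec.inversion_len, "-")
    acc_end = acc.offset + len(acc)
    if spec.deletion is None:
        add(len(tail), spec.acceptor, resume, acc_end)
    else:
        dpos, dlen = spec.deletion.pos, spec.deletion.length
        add(dpos - resume, spec.acceptor, resume, dpos - 1)
        add(acc_end - (dpos + dlen) + 1, spec.acceptor, dpos + dlen, acc_end)

    expected = (
        len(acc)
        + len(donor)
        + (spec.micro_insert.length - spec.micro_insert.overlap_with_donor if spec.micro_insert else 0)
        - (spec.deletion.length if spec.deletion else 0)
    )
    assert len(seq) == expected, "mutant haplotype length formula violated"
    contig = Contig(name, seq, 0)
    return contig, TruthRecord(spec=spec, haplotype=name, blocks=blocks)


def mutant_haplotype(reference: dict[str, Contig], spec: JunctionSpec, name: str = "mut_acceptor") -> Haplotype:
    contig, truth = build_mutant_haplotype(reference, spec, name)
    return Haplotype(contig, truth.blocks)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadPlacement:
    """Truth placement of one sequenced read on its source haplotype."""

    qname: str
    mate: int  # 1 or 2
    haplotype: str
    start: int  # 1-based local start on the haplotype (leftmost base)
    strand: str  # '+' read equals the haplotype substring, '-' its revcomp
    seq: str


@dataclass
class SimulationTruth:
    haplotypes: dict[str, Haplotype]
    placements: list[ReadPlacement]
    read_len: int
    spec: Optional[JunctionSpec] = None


def simulate_reads(
    haplotypes: Sequence[Haplotype],
    coverage: float,
    read_len: int = 101,
    insert_mean: float = 350.0,
    insert_sd: float = 35.0,
    seed: int = 0,
    error_rate: float = 0.0,
) -> SimulationTruth:
    """Simulate forward-reverse paired-end reads at the given per-haplotype
    fold coverage.  Fragment lengths are Gaussian; reads are error-free by
    default so that truth projection stays exact.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if read_len < 20:
        raise ValueError("read_len must be >= 20")
    if insert_mean < 2 * read_len:
        raise ValueError("insert_mean must be at least twice the read length")
    rng = np.random.default_rng(seed)
    placements: list[ReadPlacement] = []
    hap_map: dict[str, Haplotype] = {}
    counter = 0
    spec = None
    for hi, hap in enumerate(haplotypes):
        key = hap.name if hap.name not in hap_map else f"{hap.name}#{hi}"
        hap_map[key] = hap
        L = len(hap.contig)
        n_pairs = max(1, int(round(coverage * L / (2 * read_len))))
        frags = rng.normal(insert_mean, insert_sd, size=n_pairs)
        frags = np.clip(np.rint(frags), 2 * read_len, L).astype(int)
        starts = (rng.random(n_pairs) * (L - frags + 1)).astype(int) + 1
        seq = hap.contig.sequence
        for j in range(n_pairs):
            s, f = int(starts[j]), int(frags[j])
            counter += 1
            qname = f"sim{counter}"
            r1 = seq[s - 1 : s - 1 + read_len]
            r2_start = s + f - read_len
            r2 = revcomp(seq[r2_start - 1 : r2_start - 1 + read_len])
            if error_rate > 0:
                r1 = _add_errors(r1, error_rate, rng)
                r2 = _add_errors(r2, error_rate, rng)
            placements.append(ReadPlacement(qname, 1, key, s, "+", r1))
            placements.append(ReadPlacement(qname, 2, key, r2_start, "-", r2))
    return SimulationTruth(hap_map, placements, read_len, spec)


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = bytearray(seq, "ascii")
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        cur = chr(arr[i])
        arr[i] = ord([b for b in "ACGT" if b != cur][int(rng.integers(0, 3))])
    return arr.decode()


def write_fastq(truth: SimulationTruth, path_r1: str, path_r2: str) -> None:
    qual = "I" * truth.read_len
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in truth.placements:
            out = f1 if p.mate == 1 else f2
            out.write(f"@{p.qname}/{p.mate}\n{p.seq}\n+\n{qual}\n")


def write_fasta(contigs: Iterable[Contig], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.name} offset={c.offset}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# truth projection (replaces an external aligner for simulated reads)
# ---------------------------------------------------------------------------


def project_alignments(truth: SimulationTruth, reference: dict[str, Contig], min_anchor: int = 20):
    """Project simulated reads onto the reference using the haplotype
    segment maps: reads inside one reference segment become full-match
    records; junction-spanning reads become a soft-clipped primary plus a
    supplementary record at the clipped portion's true locus.

    Returns a coordinate-sorted list of
    :class:`insjunction.alignments.AlignmentRecord`.
    """
    from .alignments import AlignmentRecord  # local import to avoid a cycle

    records: list[AlignmentRecord] = []
    by_qname: dict[str, dict[int, dict]] = {}
    for p in truth.placements:
        hap = truth.haplotypes.get(p.haplotype)
        if hap is None:
            raise ValueError(f"placement references unknown haplotype {p.haplotype!r}")
        runs = _project_read(hap, p.start, p.start + len(p.seq) - 1, reference)
        if not runs:
            raise ValueError("read does not overlap any reference segment")
        runs.sort(key=lambda r: r["qlen"], reverse=True)
        primary = runs[0]
        supp = next((r for r in runs[1:] if r["qlen"] >= min_anchor), None)
        by_qname.setdefault(p.qname, {})[p.mate] = {
            "placement": p,
            "primary": primary,
            "supp": supp,
        }
    for qname, mates in by_qname.items():
        for mate, info in mates.items():
            other = mates.get(3 - mate)
            p = info["placement"]
            for run, is_supp in ((info["primary"], False), (info["supp"], True)):
                if run is None:
                    continue
                rec = _run_to_record(qname, p, run, is_supp, other, reference)
                records.append(rec)
    order = {name: i for i, name in enumerate(reference)}
    records.sort(key=lambda r: (order.get(r.contig, 99), r.pos))
    return records


def _project_read(hap: Haplotype, rstart: int, rend: int, reference: dict[str, Contig]):
    """Decompose read interval [rstart, rend] (haplotype-local) into
    colinear reference runs; adjacent same-contig '+' blocks separated by
    small reference gaps merge into one run with internal deletions."""
    pieces = []
    for b in hap.blocks:
        lo, hi = max(rstart, b.hap_start), min(rend, b.hap_end)
        if lo > hi:
            continue
        if b.strand == "+":
            ref_lo = b.ref_start + (lo - b.hap_start)
            ref_hi = b.ref_start + (hi - b.hap_start)
        else:
            ref_hi = b.ref_end - (lo - b.hap_start)
            ref_lo = b.ref_end - (hi - b.hap_start)
        pieces.append(
            {"qs": lo - rstart, "qe": hi - rstart, "contig": b.contig,
             "ref_lo": ref_lo, "ref_hi": ref_hi, "strand": b.strand}
        )
    runs = []
    for piece in pieces:
        if (
            runs
            and runs[-1]["contig"] == piece["contig"]
            and runs[-1]["strand"] == piece["strand"] == "+"
            and piece["ref_lo"] > runs[-1]["ref_hi"]
            and piece["ref_lo"] - runs[-1]["ref_hi"] - 1 <= 10
            and piece["qs"] == runs[-1]["qe"] + 1
        ):
            run = runs[-1]
            run["ops"].append(("D", piece["ref_lo"] - run["ref_hi"] - 1))
            run["ops"].append(("M", piece["qe"] - piece["qs"] + 1))
            run["ref_hi"] = piece["ref_hi"]
            run["qe"] = piece["qe"]
            run["qlen"] = run["qe"] - run["qs"] + 1
        else:
            runs.append(
                {**piece, "ops": [("M", piece["qe"] - piece["qs"] + 1)],
                 "qlen": piece["qe"] - piece["qs"] + 1}
            )
    return runs


def _run_to_record(qname, placement, run, is_supp, other, reference):
    from .alignments import AlignmentRecord

    contig = reference[run["contig"]]
    pos_local = contig.to_local(run["ref_lo"])
    n = len(placement.seq)
    left_clip = run["qs"]
    right_clip = n - 1 - run["qe"]
    ops = list(run["ops"])
    hap_frag = placement.seq if placement.strand == "+" else revcomp(placement.seq)
    # hap_frag is the haplotype-forward fragment; for '-' runs the aligned
    # portion maps to the reference plus strand as its reverse complement
    if run["strand"] == "-":
        seq = revcomp(hap_frag)
        ops = ops[::-1]
        left_clip, right_clip = right_clip, left_clip
    else:
        seq = hap_frag
    cigar = []
    if left_clip:
        cigar.append(("S", left_clip))
    cigar.extend(ops)
    if right_clip:
        cigar.append(("S", right_clip))
    is_reverse = (placement.strand == "-") != (run["strand"] == "-")
    mate_contig = mate_pos = None
    tlen = 0
    if other is not None:
        oc = reference[other["primary"]["contig"]]
        mate_contig = oc.name
        mate_pos = oc.to_local(other["primary"]["ref_lo"])
        if mate_contig == contig.name:
            lo = min(pos_local, mate_pos)
            hi = max(
                contig.to_local(run["ref_hi"]),
                oc.to_local(other["primary"]["ref_hi"]),
            )
            tlen = hi - lo + 1
            if pos_local > mate_pos or (pos_local == mate_pos and placement.mate == 2):
                tlen = -tlen
    return AlignmentRecord(
        qname=qname,
        contig=contig.name,
        pos=pos_local,
        mapq=60,
        cigar=cigar,
        seq=seq,
        is_paired=other is not None,
        is_reverse=is_reverse,
        is_read2=placement.mate == 2,
        is_supplementary=is_supp,
        is_proper=(mate_contig == contig.name and abs(tlen) <= 1000),
        mate_contig=mate_contig,
        mate_pos=mate_pos,
        tlen=tlen,
    )


# ---------------------------------------------------------------------------
# cohorts under X-linked segregation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSample:
    sample_id: str
    sex: str  # 'male' | 'female'
    carrier_alleles: int
    affection: str  # 'affected' | 'carrier' | 'unaffected'
    haplotypes: list[str] = field(default_factory=list)  # haplotype labels

    def __post_init__(self) -> None:
        n_x = 1 if self.sex == "male" else 2
        if len(self.haplotypes) != n_x:
            raise ValueError("haplotype count inconsistent with sex")
        if self.carrier_alleles > n_x:
            raise ValueError("carrier_alleles exceeds X haplotype count")
        if self.sex == "male" and self.affection == "affected" and self.carrier_alleles != 1:
            raise ValueError("affected males carry exactly one mutant allele")


_STATUS_ALLELES = {"affected": 1, "carrier": 1, "unaffected": 0}


def simulate_cohort(
    pedigree: pd.DataFrame, spec: JunctionSpec, seed: int = 0
) -> list[SimulatedSample]:
    """Assign mutant-X genotypes to a pedigree table under X-linked
    transmission.  The table needs columns ``sample_id``, ``sex``
    (male/female) and ``status`` (affected/carrier/unaffected); optional
    ``father``/``mother`` columns are audited for transmission violations
    (an affected or carrier child whose mother is present and
    non-carrier, i.e. father-to-son transmission, is rejected).
    """
    del spec, seed  # genotypes are fully determined by the requested statuses
    samples: dict[str, SimulatedSample] = {}
    for row in pedigree.itertuples(index=False):
        status = row.status
        if status not in _STATUS_ALLELES:
            raise ValueError(f"unknown status {status!r}")
        alleles = _STATUS_ALLELES[status]
        if row.sex == "male" and status == "carrier":
            alleles = 1  # hemizygous carrier male: modelled, flagged downstream
        haps = (
            (["mutX"] if alleles else ["wtX"])
            if row.sex == "male"
            else (["mutX", "wtX"] if alleles == 1 else ["wtX", "wtX"])
        )
        samples[row.sample_id] = SimulatedSample(
            sample_id=row.sample_id,
            sex=row.sex,
            carrier_alleles=alleles,
            affection=status,
            haplotypes=haps,
        )
    has_links = {"father", "mother"} <= set(pedigree.columns)
    if has_links:
        for row in pedigree.itertuples(index=False):
            child = samples[row.sample_id]
            mother = samples.get(row.mother) if isinstance(row.mother, str) else None
            if child.carrier_alleles >= 1 and mother is not None and mother.carrier_alleles == 0:
                raise ValueError(
                    f"X-linked transmission violated: carrier child {child.sample_id} "
                    "with a non-carrier mother"
                )
    return samples_list(samples)


def samples_list(samples: dict[str, SimulatedSample]) -> list[SimulatedSample]:
    return list(samples.values())


def random_pedigree(n_families: int, seed: int = 0, children_per_family: int = 4) -> pd.DataFrame:
    """Random two-generation X-linked genealogies: each family has a
    carrier mother and an unaffected father; children inherit the mutant X
    from the mother with probability 1/2, giving affected sons and carrier
    daughters.  Statuses are therefore transmission-consistent by
    construction."""
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(n_families):
        mo, fa = f"F{f}_mother", f"F{f}_father"
        rows.append((mo, "", "", "female", "carrier"))
        rows.append((fa, "", "", "male", "unaffected"))
        for c in range(children_per_family):
            sex = "male" if rng.random() < 0.5 else "female"
            inherits = rng.random() < 0.5
            if sex == "male":
                status = "affected" if inherits else "unaffected"
            else:
                status = "carrier" if inherits else "unaffected"
            rows.append((f"F{f}_child{c}", fa, mo, sex, status))
    return pd.DataFrame(rows, columns=["sample_id", "father", "mother", "sex", "status"])


# ---------------------------------------------------------------------------
# comparative-Ct tables
# ---------------------------------------------------------------------------


def simulate_ct_table(
    samples: Sequence[str],
    genes: Sequence[str],
    fold_changes: dict,
    housekeeping_ct: float = 15.0,
    noise_sd: float = 0.15,
    seed: int = 0,
    housekeeping_gene: str = "18S",
    target_base_ct: float = 25.0,
    n_extractions: int = 3,
    n_tech: int = 3,
) -> pd.DataFrame:
    """Emit a long-format Ct table with 3 RNA extractions x 3 technical
    replicates per sample/gene.  ``fold_changes[(sample, gene)]`` gives the
    true expression fold relative to the table's baseline (fold 1); the
    string ``"not_detected"`` plants the undetermined sentinel for all
    wells of that sample/gene."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for sample in samples:
        for gene in list(genes) + [housekeeping_gene]:
            if gene == housekeeping_gene:
                base = housekeeping_ct
            else:
                fold = fold_changes.get((sample, gene), 1.0)
                if fold == "not_detected":
                    base = None
                else:
                    fold = float(fold)
                    if fold <= 0:
                        raise ValueError("fold changes must be > 0 or 'not_detected'")
                    base = target_base_ct - math.log2(fold)
            for ext in range(1, n_extractions + 1):
                for tech in range(1, n_tech + 1):
                    ct = (
                        UNDETERMINED
                        if base is None
                        else round(base + rng.normal(0.0, noise_sd), 4)
                    )
                    rows.append((sample, gene, ext, tech, ct))
    return pd.DataFrame(rows, columns=["sample", "gene", "extraction", "tech_rep", "ct"])
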