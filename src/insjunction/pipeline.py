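"""End-to-end drivers: simulate -> detect -> resolve -> call.

These compose the per-module operations into the full insertion-discovery
workflow and are what the analysis scripts, the acceptance checks, and
the recovery property suite run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import sv_detect
from .alignments import AlignmentRecord, FilterPolicy, clip_structure
from .core import Contig, GenomicInterval, revcomp
from .junction import (
    BreakpointJunction,
    InsertionCall,
    assemble_junction,
    emit_call,
    segment_junction,
)
from .sv_detect import SplitReadEvidence, find_split_reads
from .synthetic_data import (
    Haplotype,
    JunctionSpec,
    SimulationTruth,
    cmtx3_reference,
    mutant_haplotype,
    project_alignments,
    reference_haplotype,
    simulate_reads,
)


@dataclass
class ResolutionResult:
    proximal: Optional[BreakpointJunction]
    distal: Optional[BreakpointJunction]
    call: Optional[InsertionCall]
    vcf: str
    splits: list[SplitReadEvidence]
    clusters: list
    summary: object
    modal_proximal: Optional[int]  # genome coordinate on the acceptor
    modal_distal: Optional[int]


def _modal(positions) -> Optional[int]:
    if not positions:
        return None
    vals, counts = np.unique(np.asarray(positions), return_counts=True)
    return int(vals[np.argmax(counts)])


def _anchor_index(rec: AlignmentRecord, clip_side: str) -> int:
    """0-based read index of the junction column: the first clipped base
    for right clips, the first aligned base for left clips."""
    left, right, _ = clip_structure(rec)
    if clip_side == "right":
        return len(rec.seq) - right
    return left


def _cluster_consensus(
    records_by_read: dict,
    splits: list[SplitReadEvidence],
    contig: str,
    bp: int,
    clip_side: str,
    tolerance: int = 5,
    min_support: int = 2,
):
    """Consensus over the reads of one split-read cluster, aligned on the
    shared clip boundary."""
    reads = []
    for ev in splits:
        if ev.contig != contig or ev.clip_side != clip_side:
            continue
        if abs(ev.breakpoint_pos - bp) > tolerance:
            continue
        rec = records_by_read.get((ev.qname, ev.contig, ev.breakpoint_pos, clip_side))
        if rec is None:
            continue
        reads.append((rec.seq, _anchor_index(rec, clip_side)))
    if len(reads) < min_support:
        return None
    consensus, anchor_col, low_conf = assemble_junction(reads, min_support)
    return consensus, low_conf, len(reads)


def _classify_resolution(jx: BreakpointJunction, acceptor: str) -> Optional[str]:
    """A junction reading acceptor -> (donor contig) is the proximal side
    of an insertion; donor -> acceptor is the distal side."""
    if not jx.segments:
        return None
    first, last = jx.segments[0], jx.segments[-1]
    if first.role == "acceptor_left" and any(
        s.role == "donor" for s in jx.segments
    ):
        return "proximal"
    if first.role == "donor" and last.role == "acceptor_right":
        return "distal"
    return None


def resolve_insertion(
    records: list[AlignmentRecord],
    reference: dict[str, Contig],
    acceptor: str,
    donor: Optional[str] = None,
    policy: Optional[FilterPolicy] = None,
    min_clip: int = 20,
    insert_threshold: int = 700,
    window_size: int = 200,
    band_labels: tuple[str, str] = ("", ""),
) -> ResolutionResult:
    """Full junction resolution from alignments: split-read detection,
    discordant clustering, modal breakpoints on the acceptor, consensus
    assembly per junction side, segmentation, and the final insertion
    call with VCF output.  Output is invariant to record order (records
    are sorted internally)."""
    policy = policy or FilterPolicy()
    records = [r for r in records if policy.passes(r)]
    splits = find_split_reads(records, reference, min_clip, acceptor=acceptor, donor=donor)
    pairs = sv_detect.find_discordant_pairs(records, policy, insert_threshold)
    exclusion = sv_detect.poor_alignment_regions(records, window_size)
    clusters = sv_detect.cluster_discordant(pairs, window_size, exclusion=exclusion)

    acc_off = reference[acceptor].offset
    modal_prox = _modal(
        [s.breakpoint_pos for s in splits if s.contig == acceptor and s.clip_side == "right"]
    )
    modal_dist = _modal(
        [s.breakpoint_pos for s in splits if s.contig == acceptor and s.clip_side == "left"]
    )

    records_by_read = {}
    for rec in records:
        if rec.is_supplementary or rec.is_secondary or rec.is_unmapped:
            continue
        left, right, seqs = clip_structure(rec)
        for clip_side in seqs:
            bp = rec.end if clip_side == "right" else rec.pos
            records_by_read[(rec.qname, rec.contig, bp, clip_side)] = rec

    # consensus per split-read cluster, then classify each resolved
    # junction as the proximal or distal side of the insertion; every
    # well-supported cluster (acceptor- or donor-anchored) is a candidate,
    # so a junction remains resolvable when one anchor class is sparse
    cluster_keys: dict[tuple[str, int, str], int] = {}
    for ev in splits:
        key = (ev.contig, ev.breakpoint_pos, ev.clip_side)
        cluster_keys[key] = cluster_keys.get(key, 0) + 1
    proximal = distal = None
    best_support = {"proximal": 0, "distal": 0}
    for (contig, bp, clip_side), support in sorted(
        cluster_keys.items(), key=lambda kv: -kv[1]
    )[:12]:
        if support < 2:
            continue
        got = _cluster_consensus(records_by_read, splits, contig, bp, clip_side)
        if got is None:
            continue
        consensus, low_conf, n_reads = got
        jx = segment_junction(consensus, reference, acceptor=acceptor)
        # canonical orientation: the acceptor flank reads forward; a
        # donor-anchored cluster sees the same junction reverse-complemented
        acc_strands = [
            s.strand
            for s in jx.segments
            if s.source == acceptor and s.role in ("acceptor_left", "acceptor_right")
        ]
        if acc_strands and all(st == "-" for st in acc_strands):
            jx = segment_junction(revcomp(consensus), reference, acceptor=acceptor)
        side = _classify_resolution(jx, acceptor)
        if side is None or n_reads <= best_support[side]:
            continue
        jx.side = side
        jx.low_confidence = jx.low_confidence or low_conf
        best_support[side] = n_reads
        if side == "proximal":
            proximal = jx
        else:
            distal = jx

    summary = sv_detect.summarize_evidence(splits, clusters, acceptor=acceptor)
    call, vcf = None, ""
    if proximal is not None and any(s.role == "donor" for s in proximal.segments):
        call, vcf = emit_call(
            proximal, distal, reference, acceptor,
            evidence=summary, band_labels=band_labels,
        )
    return ResolutionResult(
        proximal=proximal, distal=distal, call=call, vcf=vcf,
        splits=splits, clusters=clusters, summary=summary,
        modal_proximal=None if modal_prox is None else modal_prox + acc_off,
        modal_distal=None if modal_dist is None else modal_dist + acc_off,
    )


def run_simulation(
    reference: dict[str, Contig],
    spec: JunctionSpec,
    coverage: float = 40.0,
    seed: int = 1,
    with_donor_diploid: bool = False,
) -> tuple[SimulationTruth, list[AlignmentRecord], Haplotype]:
    """Simulate an affected hemizygous male: one mutant acceptor
    haplotype (optionally plus the two native donor-chromosome copies for
    depth analyses) and project the reads back onto the reference."""
    mut = mutant_haplotype(reference, spec)
    haps = [mut]
    if with_donor_diploid:
        donor = reference[spec.donor_segment.contig]
        haps += [reference_haplotype(donor), reference_haplotype(donor)]
    truth = simulate_reads(haps, coverage=coverage, seed=seed)
    records = project_alignments(truth, reference)
    return truth, records, mut


def random_junction_spec(
    rng: np.random.Generator,
    acceptor: str = "accA",
    donor: str = "donB",
    third: str = "thrC",
    with_variants: bool = False,
) -> JunctionSpec:
    """Draw a random identifiable junction architecture for the recovery
    property suite: microhomology 0-6, micro-insert absent or 12-25 bp
    with 0-10 bp donor overlap (shorter overlapping inserts are not
    identifiable from sequence even in principle), inversion 0-15 bp."""
    from .synthetic_data import (
        JunctionDeletion,
        JunctionSNV,
        MicroInsert,
    )

    B = int(rng.integers(2000, 4000))
    dlen = int(rng.integers(800, 1500))
    dstart = int(rng.integers(30, 3000 - dlen - 30))
    strand = "+" if rng.random() < 0.8 else "-"
    mh = int(rng.integers(0, 7))
    micro = None
    if rng.random() < 0.5:
        mlen = int(rng.integers(12, 26))
        ov = int(rng.integers(0, min(10, mlen - 2) + 1))
        mstart = int(rng.integers(30, 1500 - mlen - 30))
        micro = MicroInsert(third, 3_000_000 + mstart, mlen, ov)
    inv = int(rng.integers(0, 16))
    snv = deletion = None
    if with_variants and rng.random() < 0.5:
        resume = B + inv
        spos = resume + int(rng.integers(8, 31))
        dpos = spos + int(rng.integers(3, 16))
        snv = JunctionSNV(1_000_000 + spos, "A", "G")  # ref/alt fixed after planting
        deletion = JunctionDeletion(1_000_000 + dpos, 1)
    return JunctionSpec(
        acceptor=acceptor,
        acceptor_break=1_000_000 + B,
        donor_segment=GenomicInterval(donor, 2_000_000 + dstart, 2_000_000 + dstart + dlen - 1, strand),
        microhomology=mh,
        micro_insert=micro,
        inversion_len=inv,
        snv=snv,
        deletion=deletion,
    )


def recovery_trial(seed: int, coverage: float = 40.0, with_variants: bool = False) -> dict:
    """One randomized round trip: draw a junction spec, plant it on small
    random contigs, simulate reads at the given coverage, resolve, and
    compare the recovered parameters with the planted truth."""
    from .synthetic_data import JunctionSNV, build_reference, plant_junction

    rng = np.random.default_rng(seed)
    config = {
        "seed": int(rng.integers(0, 2**31 - 1)),
        "contigs": [
            {"name": "accA", "length": 6000, "offset": 1_000_000},
            {"name": "donB", "length": 3000, "offset": 2_000_000},
            {"name": "thrC", "length": 1500, "offset": 3_000_000},
        ],
    }
    spec = random_junction_spec(rng, with_variants=with_variants)
    reference = build_reference(config)
    if spec.snv is not None:
        ref_base = reference["accA"].fetch(spec.snv.pos, spec.snv.pos)
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref_base]
        spec = __import__("dataclasses").replace(
            spec, snv=JunctionSNV(spec.snv.pos, ref_base, alt)
        )
    reference = plant_junction(reference, spec, seed=int(rng.integers(0, 2**31 - 1)))
    _, records, _ = run_simulation(reference, spec, coverage=coverage, seed=int(rng.integers(0, 2**31 - 1)))
    result = resolve_insertion(records, reference, acceptor="accA", donor="donB")
    call = result.call
    recovered = {
        "acceptor_break": call.acceptor_pos if call else None,
        "donor_start": call.donor_segment.start if call else None,
        "donor_end": call.donor_segment.end if call and not call.partial else None,
        "microhomology": call.microhomology_len if call else None,
        "micro_insert_len": (
            call.micro_insert.length if call and call.micro_insert and call.micro_insert.source else 0
        )
        if call and not call.partial
        else None,
        "inversion_len": call.inversion_len if call and not call.partial else None,
    }
    truth = {
        "acceptor_break": spec.acceptor_break,
        "donor_start": spec.donor_segment.start,
        "donor_end": spec.donor_segment.end,
        "microhomology": spec.microhomology,
        "micro_insert_len": spec.micro_insert.length if spec.micro_insert else 0,
        "inversion_len": spec.inversion_len,
    }
    return {"spec": spec, "recovered": recovered, "truth": truth,
            "exact": recovered == truth, "result": result}


def run_cmtx3(
    coverage: float = 40.0, seed: int = 1, ref_seed: int = 0,
    with_donor_diploid: bool = False,
) -> dict:
    """The packaged preset end-to-end: build the planted reference,
    simulate an affected male at the requested coverage, and resolve the
    insertion.  Returns all intermediate artifacts keyed by name."""
    reference, spec = cmtx3_reference(seed=ref_seed)
    truth, records, mut = run_simulation(
        reference, spec, coverage=coverage, seed=seed,
        with_donor_diploid=with_donor_diploid,
    )
    result = resolve_insertion(
        records, reference, acceptor=spec.acceptor,
        donor=spec.donor_segment.contig, band_labels=("q27.1", "q24.3"),
    )
    return {
        "reference": reference, "spec": spec, "truth": truth,
        "records": records, "mutant": mut, "result": result,
    }
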