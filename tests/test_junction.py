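"""Junction consensus, segmentation, micro-architecture calls, palindrome
annotation, and VCF emission."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from insjunction.core import Contig, GenomicInterval, revcomp
from insjunction.junction import (
    annotate_palindrome,
    assemble_junction,
    call_junction_variants,
    call_microhomology,
    detect_inversion,
    detect_micro_insert,
    segment_junction,
)
from insjunction.synthetic_data import build_reference

DNA = st.text(alphabet="ACGT", min_size=0, max_size=20)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestAssembleJunction:
    def test_identical_reads_give_the_read(self):
        reads = [("ACGTACGTAC", 4)] * 5
        consensus, col, low = assemble_junction(reads)
        assert consensus == "ACGTACGTAC" and col == 4 and not low

    def test_offset_reads_tile_consensus(self):
        full = "ACGTACGTACGTACGTACGT"
        reads = [(full[i : i + 10], 8 - i) for i in range(4)]
        consensus, col, low = assemble_junction(reads)
        assert consensus == full[:13]

    def test_single_read_rejected(self):
        with pytest.raises(ValueError, match="supporting reads"):
            assemble_junction([("ACGT", 0)])

    def test_conflicting_columns_flag_low_confidence(self):
        reads = [("AAAAAAAAAA", 0), ("CCCCCCCCCC", 0)]
        _, _, low = assemble_junction(reads)
        assert low


class TestMicrohomology:
    def test_published_example(self):
        # acceptor ends ...GCAA, donor starts AAGT -> 2 bp overlap "AA"
        k, seq = call_microhomology("TTTTGCAA", "AAGTCCCC")
        assert (k, seq) == (2, "AA")

    def test_no_shared_bases(self):
        k, _ = call_microhomology("AAAC", "GTTT")
        assert k == 0

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(left=DNA, right=DNA)
    def test_matches_exhaustive_overlap_scan(self, left, right):
        k, seq = call_microhomology(left, right)
        best = 0
        for j in range(1, min(len(left), len(right)) + 1):
            if left[-j:] == right[:j]:
                best = j
        assert k == best
        assert seq == right[:k]

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(left=DNA, right=DNA)
    def test_symmetric_under_role_swap(self, left, right):
        """Reverse-complementing the junction and swapping the segment
        roles reports the same overlap length."""
        k1, _ = call_microhomology(left, right)
        k2, _ = call_microhomology(revcomp(right), revcomp(left))
        assert k1 == k2


class TestMicroInsert:
    def _refs(self):
        return build_reference({"seed": 17, "contigs": [
            {"name": "a", "length": 4000, "offset": 0},
            {"name": "c12", "length": 1500, "offset": 0}]})

    def test_planted_fragment_with_overlap(self, cmtx3):
        refs, spec = cmtx3
        mi = spec.micro_insert
        frag = refs[mi.source].fetch(mi.start, mi.start + mi.length - 1)
        donor_tail = refs[spec.donor_segment.contig].fetch(
            spec.donor_segment.end - 29, spec.donor_segment.end
        )
        got = detect_micro_insert(frag[mi.overlap_with_donor:], refs,
                                  neighbor_tail=donor_tail)
        assert got.source == mi.source
        assert got.length == 19 and got.overlap_with_neighbor == 10

    def test_absent_fragment_unknown_origin(self):
        refs = self._refs()
        rng = np.random.default_rng(1)
        for _ in range(20):
            frag = random_dna(rng, 19)
            if frag not in refs["a"].sequence and frag not in refs["c12"].sequence:
                break
        got = detect_micro_insert(frag, refs)
        assert got.source is None and got.length == 19

    def test_palindromic_fragment_ambiguous(self):
        rng = np.random.default_rng(4)
        arm = random_dna(rng, 300)
        pal = arm + revcomp(arm)
        refs = {"p": Contig("p", pal)}
        frag = pal[100:115]  # inside the left arm: present on both strands
        got = detect_micro_insert(frag, refs)
        assert got.ambiguous
        assert len(got.loci) == 2


class TestInversion:
    def test_planted_preset_inversion(self, cmtx3):
        refs, spec = cmtx3
        acc = refs[spec.acceptor]
        B = spec.acceptor_break
        inv_seq = revcomp(acc.fetch(B + 1, B + 12))
        got = detect_inversion(inv_seq, acc, B + 13)
        assert got.length == 12
        assert got.interval == GenomicInterval(spec.acceptor, B + 1, B + 12, "-")

    def test_empty_candidate(self, cmtx3):
        refs, spec = cmtx3
        got = detect_inversion("", refs[spec.acceptor], spec.acceptor_break + 1)
        assert got.length == 0

    def test_randomized_planted_inversions_recover_exactly(self):
        """Planted inversion lengths 5-30 recover exactly across seeds,
        with a mismatching sentinel base guarding each flank."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = 3000
            seq = random_dna(rng, n)
            resume = int(rng.integers(1000, 2000))
            k = int(rng.integers(5, 31))
            acc = Contig("a", seq)
            inv = revcomp(seq[resume - k - 1 : resume - 1])
            # prepend a base that cannot extend the scan
            lead = next(b for b in "ACGT" if b != revcomp(seq[resume - k - 2]))
            got = detect_inversion(lead + inv, acc, resume)
            assert got.length == k


class TestSegmentation:
    def test_single_source_consensus(self, cmtx3):
        refs, spec = cmtx3
        acc = refs[spec.acceptor]
        consensus = acc.fetch(139_450_000, 139_450_160)
        jx = segment_junction(consensus, refs, acceptor=spec.acceptor)
        assert len(jx.segments) == 1
        assert jx.segments[0].role == "acceptor_left"

    def test_planted_proximal_junction(self, cmtx3):
        refs, spec = cmtx3
        acc, don = refs[spec.acceptor], refs[spec.donor_segment.contig]
        consensus = acc.fetch(spec.acceptor_break - 80, spec.acceptor_break) + don.fetch(
            spec.donor_segment.start, spec.donor_segment.start + 80
        )
        jx = segment_junction(consensus, refs, acceptor=spec.acceptor)
        roles = [s.role for s in jx.segments]
        assert roles == ["acceptor_left", "donor"]
        assert jx.segments[0].interval.end == 139_502_948
        assert jx.segments[1].interval.start == 145_768_312
        assert jx.microhomology_len == 2 and jx.microhomology_seq == "AA"

    def test_planted_distal_junction(self, cmtx3, cmtx3_run):
        jx = cmtx3_run["result"].distal
        roles = [s.role for s in jx.segments]
        assert roles == ["donor", "micro_insert", "inverted_acceptor", "acceptor_right"]
        assert jx.micro_insert.length == 19
        assert jx.micro_insert.overlap_with_neighbor == 10
        assert jx.inversion.length == 12


class TestJunctionVariants:
    def test_reference_consensus_is_variant_free(self, cmtx3):
        refs, spec = cmtx3
        acc = refs[spec.acceptor]
        consensus = acc.fetch(139_460_000, 139_460_150)
        snvs, dels = call_junction_variants(consensus, acc)
        assert snvs == [] and dels == []

    def test_preset_variants_at_planted_coordinates(self, cmtx3_run):
        call = cmtx3_run["result"].call
        assert [s.pos for s in call.snvs] == [139_502_968]
        assert call.snvs[0].ref == "T" and call.snvs[0].alt == "G"
        assert [(d.pos, d.length) for d in call.deletions] == [(139_502_976, 1)]

    def test_randomized_single_edits_match_brute_force_diff(self):
        rng = np.random.default_rng(23)
        refs = build_reference({"seed": 31, "contigs": [{"name": "a", "length": 5000, "offset": 0}]})
        acc = refs["a"]
        for _ in range(30):
            pos = int(rng.integers(2000, 2500))
            window = list(acc.fetch(pos - 60, pos + 80))
            edit_at = int(rng.integers(12, 45))
            ref_base = window[60 - edit_at]
            alt = next(b for b in "ACGT" if b != ref_base)
            window[60 - edit_at] = alt
            consensus = "".join(window)
            snvs, dels = call_junction_variants(consensus, acc)
            assert dels == []
            assert [(s.pos, s.ref, s.alt) for s in snvs] == [(pos - edit_at, ref_base, alt)]


class TestPalindrome:
    def test_constructed_hairpin_with_central_loop(self):
        rng = np.random.default_rng(3)
        arm = random_dna(rng, 88)
        seq = random_dna(rng, 150) + arm + "TATC" + revcomp(arm) + random_dna(rng, 150)
        c = Contig("x", seq)
        ann = annotate_palindrome(c, 150 + 90)
        assert ann is not None
        assert ann.loop_seq == "TATC"
        assert ann.arm_len == 88
        assert ann.breakpoint_distance == 0

    def test_random_sequence_has_no_annotation(self):
        rng = np.random.default_rng(5)
        c = Contig("x", random_dna(rng, 600))
        assert annotate_palindrome(c, 300) is None

    def test_arm_length_matches_quadratic_oracle(self):
        """Planted arms 20-60 agree with an O(n^2) exhaustive
        inverted-repeat scan."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            arm_len = int(rng.integers(20, 61))
            loop_len = int(rng.integers(0, 9))
            arm = random_dna(rng, arm_len)
            loop = random_dna(rng, loop_len)
            seq = random_dna(rng, 80) + arm + loop + revcomp(arm) + random_dna(rng, 80)
            c = Contig("x", seq)
            bp = 80 + arm_len  # breakpoint at the loop edge
            ann = annotate_palindrome(c, bp, min_arm=15)
            # oracle: maximal arm over all (center, loop<=8) containing bp
            best = 0
            n = len(seq)
            for loop_l in range(0, 9):
                for center in range(1, n + 1):
                    a = 0
                    while (
                        center - 1 - a >= 1
                        and center + loop_l + a <= n
                        and seq[center - 2 - a] == revcomp(seq[center + loop_l + a - 1])
                    ):
                        a += 1
                    if a >= 15 and center - a <= bp <= center + loop_l + a - 1:
                        best = max(best, a)
            assert ann is not None and ann.arm_len == best


class TestEmitCall:
    def test_vcf_breakend_mate_reciprocity(self, cmtx3_run, tmp_path):
        vcf = cmtx3_run["result"].vcf
        path = tmp_path / "call.vcf"
        path.write_text(vcf)
        recs = {r.id: r for r in pysam.VariantFile(str(path))}
        bnds = {k: v for k, v in recs.items() if v.info["SVTYPE"] == "BND"}
        assert len(bnds) == 4
        for rid, rec in bnds.items():
            mate = bnds[rec.info["MATEID"]]
            assert mate.info["MATEID"] == rid
            # the mate's locus appears inside this record's ALT string
            assert f"{mate.chrom}:{mate.pos}" in rec.alts[0]
        ins = recs["ins1"]
        assert ins.info["SVTYPE"] == "INS"
        assert ins.info["SVLEN"] == 77_856 + 9 - 1

    def test_partial_call_without_distal_junction(self, cmtx3):
        from insjunction.junction import emit_call

        refs, spec = cmtx3
        acc, don = refs[spec.acceptor], refs[spec.donor_segment.contig]
        consensus = acc.fetch(spec.acceptor_break - 80, spec.acceptor_break) + don.fetch(
            spec.donor_segment.start, spec.donor_segment.start + 80
        )
        prox = segment_junction(consensus, refs, acceptor=spec.acceptor)
        call, vcf = emit_call(prox, None, refs, spec.acceptor)
        assert call.partial
        assert "<INS>" not in vcf

    def test_notation_string(self, cmtx3_run):
        call = cmtx3_run["result"].call
        assert call.notation == "der(chrX_mini)dir ins(chrX_mini;chr8_mini)(q27.1;q24.3)"
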