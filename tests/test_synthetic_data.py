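"""Generator tests: reference construction, junction planting, read
simulation, truth projection, cohorts, and Ct tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from insjunction.core import Contig, GenomicInterval
from insjunction.synthetic_data import (
    JunctionDeletion,
    JunctionSNV,
    JunctionSpec,
    MicroInsert,
    UNDETERMINED,
    build_mutant_haplotype,
    build_reference,
    mutant_haplotype,
    plant_junction,
    random_pedigree,
    reference_haplotype,
    simulate_cohort,
    simulate_ct_table,
    simulate_reads,
    write_fastq,
)


class TestBuildReference:
    def test_deterministic_for_seed(self):
        cfg = {"seed": 1, "contigs": [{"name": "a", "length": 1000, "offset": 0},
                                      {"name": "b", "length": 1000, "offset": 5}]}
        r1, r2 = build_reference(cfg), build_reference(cfg)
        assert r1["a"].sequence == r2["a"].sequence
        assert r1["b"].sequence == r2["b"].sequence
        assert len(r1["a"]) == 1000

    def test_rejects_duplicate_names_and_bad_offsets(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_reference({"seed": 0, "contigs": [
                {"name": "a", "length": 10, "offset": 0},
                {"name": "a", "length": 10, "offset": 0}]})
        with pytest.raises(ValueError):
            build_reference({"seed": 0, "contigs": [{"name": "a", "length": 10, "offset": -5}]})

    def test_preset_coordinates(self, cmtx3):
        refs, spec = cmtx3
        acc = refs[spec.acceptor]
        # acceptor junction coordinate is carried by offset + local break
        assert spec.acceptor_break == 139_502_948
        assert acc.to_local(spec.acceptor_break) + acc.offset == 139_502_948
        assert spec.donor_segment.start == 145_768_312
        assert len(spec.donor_segment) == 77_856


class TestMutantHaplotype:
    def test_hand_concatenation(self):
        refs = {
            "acc": Contig("acc", "AAAAAAAAAACCCCCCCCCC"),
            "don": Contig("don", "TTGGGGTT"),
        }
        spec = JunctionSpec("acc", 10, GenomicInterval("don", 3, 6, "+"))
        mut, truth = build_mutant_haplotype(refs, spec)
        assert mut.sequence == "AAAAAAAAAA" + "GGGG" + "CCCCCCCCCC"
        assert [b.contig for b in truth.blocks] == ["acc", "don", "acc"]

    def test_empty_donor_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("don", 5, 4, "+")

    def test_preset_truth_matches_spec(self, cmtx3):
        refs, spec = cmtx3
        mut, truth = build_mutant_haplotype(refs, spec)
        assert truth.spec.microhomology == 2
        assert truth.spec.micro_insert.length == 19
        assert truth.spec.micro_insert.overlap_with_donor == 10
        assert truth.spec.inversion_len == 12
        expected = 200_000 + 77_856 + (19 - 10) - 1
        assert len(mut) == expected

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        mh=st.integers(0, 6),
        dlen=st.integers(50, 400),
        inv=st.integers(0, 15),
        milen=st.sampled_from([0, 12, 15, 19, 25]),
        ov=st.integers(0, 10),
        dele=st.integers(0, 3),
    )
    def test_length_formula_property(self, mh, dlen, inv, milen, ov, dele):
        """Mutant length = acceptor + donor + (micro-insert - overlap) - deletion."""
        cfg = {"seed": 3, "contigs": [
            {"name": "acc", "length": 3000, "offset": 0},
            {"name": "don", "length": 1500, "offset": 0},
            {"name": "thr", "length": 500, "offset": 0}]}
        micro = None
        if milen:
            ov = min(ov, milen - 2)
            micro = MicroInsert("thr", 100, milen, ov)
        spec = JunctionSpec(
            "acc", 1500, GenomicInterval("don", 500, 500 + dlen - 1, "+"),
            microhomology=mh, micro_insert=micro, inversion_len=inv,
            deletion=JunctionDeletion(1500 + inv + 40, dele) if dele else None,
        )
        refs = plant_junction(build_reference(cfg), spec, seed=9)
        mut, _ = build_mutant_haplotype(refs, spec)
        expected = 3000 + dlen + (milen - (micro.overlap_with_donor if micro else 0) if milen else 0) - dele
        assert len(mut) == expected

    def test_unknown_contig_and_overlapping_edits_rejected(self):
        refs = {"acc": Contig("acc", "ACGT" * 100), "don": Contig("don", "ACGT" * 50)}
        with pytest.raises(ValueError, match="unknown contig"):
            build_mutant_haplotype(
                refs, JunctionSpec("nope", 10, GenomicInterval("don", 1, 10, "+"))
            )
        with pytest.raises(ValueError, match="inside the deleted"):
            JunctionSpec(
                "acc", 100, GenomicInterval("don", 1, 10, "+"),
                snv=JunctionSNV(150, "A", "C"), deletion=JunctionDeletion(149, 3),
            )


class TestSimulateReads:
    def test_read_length_and_determinism(self, small_genome, tmp_path):
        refs, spec = small_genome
        hap = mutant_haplotype(refs, spec)
        t1 = simulate_reads([hap], coverage=2, read_len=101, seed=4)
        t2 = simulate_reads([hap], coverage=2, read_len=101, seed=4)
        assert all(len(p.seq) == 101 for p in t1.placements)
        f1a, f1b = tmp_path / "a1.fq", tmp_path / "a2.fq"
        f2a, f2b = tmp_path / "b1.fq", tmp_path / "b2.fq"
        write_fastq(t1, str(f1a), str(f1b))
        write_fastq(t2, str(f2a), str(f2b))
        assert f1a.read_bytes() == f2a.read_bytes()
        assert f1b.read_bytes() == f2b.read_bytes()

    def test_fastq_parseable(self, small_genome, tmp_path):
        from Bio import SeqIO

        refs, spec = small_genome
        hap = reference_haplotype(refs["accA"])
        truth = simulate_reads([hap], coverage=1, seed=2)
        write_fastq(truth, str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq"))
        recs = list(SeqIO.parse(str(tmp_path / "r1.fq"), "fastq"))
        assert len(recs) == sum(p.mate == 1 for p in truth.placements)
        assert all(len(r.seq) == 101 for r in recs)

    def test_invalid_parameters_rejected(self, small_genome):
        refs, _ = small_genome
        hap = reference_haplotype(refs["accA"])
        with pytest.raises(ValueError):
            simulate_reads([hap], coverage=0)
        with pytest.raises(ValueError, match="twice the read length"):
            simulate_reads([hap], coverage=10, read_len=101, insert_mean=150)

    def test_mean_depth_against_interval_oracle(self, small_genome):
        """Realized depth within 10% of target, checked by brute-force
        per-base counting of truth placements."""
        refs, _ = small_genome
        hap = reference_haplotype(refs["accA"])  # 20 kb
        truth = simulate_reads([hap], coverage=30, seed=7)
        cov = np.zeros(len(hap.contig) + 1)
        for p in truth.placements:
            cov[p.start - 1 : p.start - 1 + 101] += 1
        mean = cov[:-1].mean()
        assert 27 <= mean <= 33


class TestProjection:
    def test_interior_reads_full_match(self, small_sim):
        refs, spec, truth, records, mut = small_sim
        donor_interior = [
            r for r in records
            if r.contig == "donB" and not r.is_supplementary and r.cigar_string() == "101M"
        ]
        assert donor_interior, "expected full-match donor-interior records"

    def test_junction_read_against_substring_oracle(self, small_sim):
        """Soft-clipped primaries and their supplementaries sit exactly
        where exhaustive substring search places the read portions."""
        refs, spec, truth, records, mut = small_sim
        checked = 0
        for r in records:
            if r.is_supplementary or "S" not in r.cigar_string():
                continue
            ops = dict((op, n) for op, n in r.cigar)
            m = ops.get("M", 0)
            if m < 25:
                continue
            aligned = (
                r.seq[: m] if r.cigar[0][0] == "M" else r.seq[len(r.seq) - m :]
            )
            hit = refs[r.contig].sequence.find(aligned)
            assert hit != -1 and hit + 1 == r.pos
            checked += 1
            if checked >= 25:
                break
        assert checked >= 10

    def test_pair_straddling_junction_is_discordant(self, small_sim):
        refs, spec, truth, records, mut = small_sim
        by_q = {}
        for r in records:
            if not r.is_supplementary:
                by_q.setdefault(r.qname, []).append(r)
        straddlers = [
            q for q, rs in by_q.items()
            if len(rs) == 2 and rs[0].contig != rs[1].contig
        ]
        assert straddlers, "junction-straddling pairs should map to two contigs"
        q = straddlers[0]
        assert by_q[q][0].mate_contig == by_q[q][1].contig


class TestCohort:
    def test_affected_males_carry_one_allele(self, cmtx3):
        _, spec = cmtx3
        ped = pd.DataFrame(
            [(f"m{i}", "male", "affected") for i in range(25)],
            columns=["sample_id", "sex", "status"],
        )
        cohort = simulate_cohort(ped, spec)
        assert len(cohort) == 25
        assert all(s.carrier_alleles == 1 for s in cohort)

    def test_empty_cohort(self, cmtx3):
        _, spec = cmtx3
        ped = pd.DataFrame(columns=["sample_id", "sex", "status"])
        assert simulate_cohort(ped, spec) == []

    def test_transmission_audit_over_random_genealogies(self, cmtx3):
        """Every affected son's mother is a carrier in generated
        genealogies (brute-force pedigree walk, 300 random families)."""
        _, spec = cmtx3
        ped = random_pedigree(300, seed=3)
        cohort = {s.sample_id: s for s in simulate_cohort(ped, spec)}
        rows = ped.set_index("sample_id")
        checked = 0
        for sid, row in rows.iterrows():
            s = cohort[sid]
            if s.sex == "male" and s.affection == "affected" and row["mother"]:
                assert cohort[row["mother"]].carrier_alleles >= 1
                checked += 1
        assert checked > 50

    def test_inconsistent_pedigree_rejected(self, cmtx3):
        _, spec = cmtx3
        ped = pd.DataFrame(
            [("mo", "", "", "female", "unaffected"),
             ("son", "fa", "mo", "male", "affected")],
            columns=["sample_id", "father", "mother", "sex", "status"],
        )
        with pytest.raises(ValueError, match="transmission"):
            simulate_cohort(ped, spec)


class TestCtTable:
    def test_noise_free_folds_are_exact(self):
        tab = simulate_ct_table(["a", "b"], ["G"], {("b", "G"): 3.0}, noise_sd=0.0, seed=0)
        g = tab[tab.gene == "G"]
        cts_a = g[g["sample"] == "a"].ct.astype(float)
        cts_b = g[g["sample"] == "b"].ct.astype(float)
        assert cts_a.nunique() == 1 and cts_b.nunique() == 1
        # planted fold 3: target Ct lower by log2(3) cycles
        # Ct values are emitted at 4-decimal precision
        assert cts_a.iloc[0] - cts_b.iloc[0] == pytest.approx(np.log2(3), abs=1e-3)

    def test_replicate_structure(self):
        tab = simulate_ct_table(["s"], ["G"], {}, seed=1)
        g = tab[(tab["sample"] == "s") & (tab.gene == "G")]
        assert len(g) == 9  # 3 extractions x 3 technical replicates
        assert set(g.extraction) == {1, 2, 3} and set(g.tech_rep) == {1, 2, 3}

    def test_not_detected_sentinel(self):
        tab = simulate_ct_table(["s"], ["G"], {("s", "G"): "not_detected"}, seed=1)
        g = tab[tab.gene == "G"]
        assert (g.ct == UNDETERMINED).all()

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_ct_table(["s"], ["G"], {}, noise_sd=-1)
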