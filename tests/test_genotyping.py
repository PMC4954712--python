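"""Multiplex-assay placement, in-silico PCR, genotype logic, segregation,
and panel accounting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from insjunction.core import revcomp
from insjunction.genotyping import (
    Amplicon,
    PCRTemplate,
    Primer,
    call_genotype,
    genotype_cohort,
    insilico_pcr,
    place_assay,
    sample_templates,
    screen_panel,
    segregation_check,
)
from insjunction.synthetic_data import mutant_haplotype, simulate_cohort


@pytest.fixture(scope="module")
def assay(cmtx3):
    refs, spec = cmtx3
    return place_assay(spec, refs)


@pytest.fixture(scope="module")
def haplotypes(cmtx3):
    refs, spec = cmtx3
    return refs[spec.acceptor], mutant_haplotype(refs, spec)


class TestPlaceAssay:
    def test_published_sizes_verified_by_pcr(self, cmtx3, assay, haplotypes):
        refs, spec = cmtx3
        wt, mut = haplotypes
        ped = pd.DataFrame(
            [("aff", "male", "affected"), ("car", "female", "carrier"),
             ("non", "male", "unaffected")],
            columns=["sample_id", "sex", "status"],
        )
        for sample in simulate_cohort(ped, spec):
            tmpls = sample_templates(sample, wt, mut, spec)
            amps = insilico_pcr(tmpls, assay.primers)
            sizes = sorted({(a.spans, a.length) for a in amps})
            if sample.sample_id == "aff":
                assert sizes == [("distal_junction", 235), ("proximal_junction", 595)]
            elif sample.sample_id == "car":
                assert sizes == [("distal_junction", 235), ("proximal_junction", 595),
                                 ("wild_type", 340)]
            else:
                assert sizes == [("wild_type", 340)]

    def test_tiny_wild_type_product_rejected(self, cmtx3):
        refs, spec = cmtx3
        with pytest.raises(ValueError, match="shorter than two primers"):
            place_assay(spec, refs, size_spec=(30, 595, 235))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        wt=st.integers(120, 400),
        prox_extra=st.integers(30, 300),
        dist_extra=st.integers(60, 300),
    )
    def test_randomized_size_specs_solve_then_verify(self, cmtx3, wt, prox_extra, dist_extra):
        """Emitted primer sites always reproduce the requested product
        lengths when run through in-silico PCR."""
        refs, spec = cmtx3
        prox = wt // 2 + 21 + prox_extra
        dist = wt // 2 + 60 + dist_extra
        assay = place_assay(spec, refs, size_spec=(wt, prox, dist))
        wt_acc = refs[spec.acceptor]
        mut = mutant_haplotype(refs, spec)
        B_local = wt_acc.to_local(spec.acceptor_break)
        tmpl_wt = PCRTemplate("wt", wt_acc.sequence, insertion_site=B_local)
        dist_pos = B_local + len(spec.donor_segment) + spec.novel_insert_len + spec.inversion_len
        tmpl_mut = PCRTemplate("mut", mut.contig.sequence, proximal_pos=B_local,
                               distal_pos=dist_pos)
        amps = insilico_pcr([tmpl_wt, tmpl_mut], assay.primers, max_product=2000)
        got = {(a.spans, a.length) for a in amps}
        assert ("wild_type", wt) in got
        assert ("proximal_junction", prox) in got
        assert ("distal_junction", dist) in got


class TestInsilicoPCR:
    def test_no_binding_no_product(self):
        tmpl = PCRTemplate("t", "A" * 500)
        primers = [Primer("p", "ACGTACGTACGTACGTACG", "acceptor")]
        assert insilico_pcr([tmpl], primers) == []

    def test_single_planted_pair_matches_brute_force(self):
        rng = np.random.default_rng(13)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        fwd = seq[100:121]
        rev = revcomp(seq[480:501])
        primers = [Primer("F", fwd, "acceptor"), Primer("R", rev, "acceptor")]
        amps = insilico_pcr([PCRTemplate("t", seq)], primers)
        products = [(a.start, a.end, a.length) for a in amps]
        # oracle: scan all occurrences of both primers
        assert seq.find(fwd) == 100 and seq.find(revcomp(rev)) == 480
        assert products == [(101, 501, 401)]

    def test_product_count_invariant_under_revcomp(self, cmtx3, assay, haplotypes):
        _, mut = haplotypes
        t_fwd = PCRTemplate("f", mut.contig.sequence)
        t_rev = PCRTemplate("r", revcomp(mut.contig.sequence))
        n_fwd = len(insilico_pcr([t_fwd], assay.primers))
        n_rev = len(insilico_pcr([t_rev], assay.primers))
        assert n_fwd == n_rev > 0

    def test_primer_validation(self):
        with pytest.raises(ValueError):
            Primer("p", "ACGT", "acceptor")  # too short
        with pytest.raises(ValueError):
            Primer("p", "ACGTNACGTACGTACGTACGT", "acceptor")  # non-ACGT


class TestGenotypeLogic:
    def _amp(self, span):
        return Amplicon("F", "R", "t", 1, 400, 400, span)

    def test_legend_table_exhaustive(self):
        """Genotype is a pure function of (sex, amplicon span set):
        exhaustive enumeration of the 2 x 8 input space."""
        spans = ["wild_type", "proximal_junction", "distal_junction"]
        for sex in ("male", "female"):
            for mask in itertools.product([0, 1], repeat=3):
                present = frozenset(s for s, m in zip(spans, mask) if m)
                amps = [self._amp(s) for s in present]
                call = call_genotype(amps, sex).call
                if present == {"wild_type"}:
                    assert call == "non_carrier"
                elif present == {"proximal_junction", "distal_junction"} and sex == "male":
                    assert call == "affected_hemizygous"
                elif present == {"wild_type", "proximal_junction", "distal_junction"} and sex == "female":
                    assert call == "carrier_female"
                else:
                    assert call == "inconsistent"

    def test_male_with_all_three_inconsistent(self):
        amps = [self._amp(s) for s in ("wild_type", "proximal_junction", "distal_junction")]
        assert call_genotype(amps, "male").call == "inconsistent"


class TestSegregation:
    def _genotyped_cohort(self, cmtx3, haplotypes, ped):
        refs, spec = cmtx3
        wt, mut = haplotypes
        from insjunction.genotyping import place_assay

        assay = place_assay(spec, refs)
        cohort = simulate_cohort(ped, spec)
        return genotype_cohort(cohort, assay, wt, mut, spec)

    def test_full_study_composition_concordant(self, cmtx3, haplotypes):
        """25 affected males + 30 carrier females + 50 unaffected
        non-carriers: 105 concordant, 0 discordant."""
        rows = (
            [(f"am{i}", "male", "affected") for i in range(25)]
            + [(f"cf{i}", "female", "carrier") for i in range(30)]
            + [(f"um{i}", "male", "unaffected") for i in range(30)]
            + [(f"uf{i}", "female", "unaffected") for i in range(20)]
        )
        ped = pd.DataFrame(rows, columns=["sample_id", "sex", "status"])
        genotypes = self._genotyped_cohort(cmtx3, haplotypes, ped)
        report = segregation_check(genotypes, ped)
        assert report["n_concordant"] == 105
        assert report["n_discordant"] == 0
        assert report["transmission_violations"] == []

    def test_empty_cohort(self):
        ped = pd.DataFrame(columns=["sample_id", "sex", "status"])
        report = segregation_check([], ped)
        assert report["n_concordant"] == report["n_discordant"] == 0

    def test_father_to_son_transmission_flagged(self):
        from insjunction.genotyping import GenotypeCall

        ped = pd.DataFrame(
            [("fa", "", "", "male", "affected"),
             ("mo", "", "", "female", "unaffected"),
             ("son", "fa", "mo", "male", "affected")],
            columns=["sample_id", "father", "mother", "sex", "status"],
        )
        genotypes = [
            GenotypeCall("fa", "male", frozenset(), "affected_hemizygous"),
            GenotypeCall("mo", "female", frozenset(), "non_carrier"),
            GenotypeCall("son", "male", frozenset(), "affected_hemizygous"),
        ]
        report = segregation_check(genotypes, ped)
        assert len(report["transmission_violations"]) == 1
        assert report["transmission_violations"][0]["sample"] == "son"

    def test_pedigree_cycle_rejected(self):
        ped = pd.DataFrame(
            [("a", "b", "", "male", "unaffected"),
             ("b", "a", "", "male", "unaffected")],
            columns=["sample_id", "father", "mother", "sex", "status"],
        )
        with pytest.raises(ValueError, match="cycle"):
            segregation_check([], ped)


class TestScreenPanel:
    def test_published_composition(self):
        from insjunction.genotyping import GenotypeCall

        genotypes = [
            GenotypeCall(f"f{i}", "female", frozenset(), "non_carrier") for i in range(252)
        ] + [GenotypeCall(f"m{i}", "male", frozenset(), "non_carrier") for i in range(123)]
        report = screen_panel(genotypes)
        assert report["x_chromosomes"] == 627
        assert report["carrier_x_chromosomes"] == 0

    def test_empty_panel(self):
        report = screen_panel([])
        assert report["x_chromosomes"] == 0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(n_f=st.integers(0, 300), n_m=st.integers(0, 300))
    def test_counts_match_arithmetic_oracle(self, n_f, n_m):
        from insjunction.genotyping import GenotypeCall

        genotypes = [
            GenotypeCall(f"f{i}", "female", frozenset(), "non_carrier") for i in range(n_f)
        ] + [GenotypeCall(f"m{i}", "male", frozenset(), "non_carrier") for i in range(n_m)]
        assert screen_panel(genotypes)["x_chromosomes"] == 2 * n_f + n_m
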