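"""In-silico multiplex PCR genotyping of the insertion and X-linked
segregation analysis.

The assay follows the published three-amplicon design: one wild-type
amplicon across the insertion point (acceptor forward + acceptor
reverse), and two junction-crossing amplicons pairing an acceptor primer
with a donor-internal primer (acceptor-F + donor-R over the proximal
junction; donor-F + acceptor-R over the distal junction).  Unaffected
hemizygous males and homozygous reference females give the single
wild-type product; affected hemizygous males give the two junction
products; carrier females give all three.

Because the published primer genomic coordinates are not printed, primer
sites on synthetic genomes are solved exactly from the published product
sizes and then verified by in-silico PCR.  Primer binding is exact-match
(no mismatches), convergent orientation, inclusive product length
between the outermost primer 5' ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .core import Contig, revcomp
from .junction import InsertionCall
from .synthetic_data import (
    Haplotype,
    JunctionSpec,
    SimulatedSample,
    build_mutant_haplotype,
)

DEFAULT_SIZES = (340, 595, 235)  # wild-type, proximal-junction, distal-junction
PRIMER_LEN = 21


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str
    side: str  # intended template side: 'acceptor' | 'donor'

    def __post_init__(self) -> None:
        if not 18 <= len(self.sequence) <= 30:
            raise ValueError("primer length must be 18-30 nt")
        if not set(self.sequence) <= set("ACGT"):
            raise ValueError("primer sequence must be over A/C/G/T")


@dataclass(frozen=True)
class PCRTemplate:
    """A haplotype sequence plus the junction geometry needed to label
    amplicons: ``insertion_site`` for a wild-type acceptor (the base after
    which the insertion would land) and the two junction positions (last
    base before the junction, template-local) for a mutant acceptor."""

    name: str
    sequence: str
    insertion_site: Optional[int] = None
    proximal_pos: Optional[int] = None
    distal_pos: Optional[int] = None


@dataclass(frozen=True)
class Amplicon:
    forward: str  # primer name
    reverse: str
    template: str
    start: int  # 1-based position of the forward primer 5' end
    end: int  # 1-based position of the reverse primer 5' end
    length: int
    spans: str  # 'wild_type' | 'proximal_junction' | 'distal_junction' | 'none'


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    sex: str
    amplicon_spans: frozenset
    call: str  # non_carrier | affected_hemizygous | carrier_female | inconsistent


# ---------------------------------------------------------------------------
# assay placement
# ---------------------------------------------------------------------------


@dataclass
class AssayDesign:
    primers: list[Primer]
    sizes: tuple[int, int, int]
    sites: pd.DataFrame  # primer site table

    def primer(self, name: str) -> Primer:
        return next(p for p in self.primers if p.name == name)


def place_assay(
    call: InsertionCall | JunctionSpec,
    reference: dict[str, Contig],
    size_spec: tuple[int, int, int] = DEFAULT_SIZES,
    primer_len: int = PRIMER_LEN,
) -> AssayDesign:
    """Solve primer sites from the three target product lengths.

    On the wild-type acceptor, X.F/X.R flank the insertion point and give
    ``size_spec[0]``; on the mutant haplotype X.F + donor-internal 8.R
    give ``size_spec[1]`` across the proximal junction and donor-internal
    8.F + X.R give ``size_spec[2]`` across the distal junction.  Site
    offsets are solved exactly from the length equations and verified by
    in-silico PCR downstream.
    """
    wt_len, prox_len, dist_len = size_spec
    if wt_len < 2 * primer_len:
        raise ValueError("wild-type product shorter than two primers")
    spec = call.to_spec() if isinstance(call, InsertionCall) else call
    acc = reference[spec.acceptor]
    B = spec.acceptor_break
    mutant, truth = build_mutant_haplotype(reference, spec, name="assay_mutant")

    # X.F fully left of the junction, X.R fully right, product = wt_len
    f5 = B - wt_len // 2 + 1
    f5 = min(max(f5, B - wt_len + primer_len), B - primer_len + 1)
    r5 = f5 + wt_len - 1
    if r5 - primer_len + 1 <= B:
        raise ValueError("wild-type product cannot span the insertion point")
    xf = acc.fetch(f5, f5 + primer_len - 1)
    xr = revcomp(acc.fetch(r5 - primer_len + 1, r5))

    # locate haplotype-local coordinates via the truth segment map
    def mutant_pos_of_acceptor(pos: int) -> int:
        for b in truth.blocks:
            if b.contig == spec.acceptor and b.strand == "+" and b.ref_start <= pos <= b.ref_end:
                return b.hap_start + (pos - b.ref_start)
        raise ValueError(f"acceptor position {pos} absent from the mutant haplotype")

    donor_len = len(spec.donor_segment)
    mut_f5 = mutant_pos_of_acceptor(f5)
    # proximal product: X.F ... donor-internal reverse primer
    dr_mut = mut_f5 + prox_len - 1
    dr_off = dr_mut - mutant_pos_of_acceptor(B)  # offset into the donor part
    if not primer_len <= dr_off <= donor_len:
        raise ValueError("donor segment shorter than the proximal primer offset")
    er = revcomp(mutant.sequence[dr_mut - primer_len : dr_mut])

    # distal product: donor-internal forward primer ... X.R
    mut_r5 = mutant_pos_of_acceptor(r5)
    df_mut = mut_r5 - dist_len + 1
    df_off = df_mut - mutant_pos_of_acceptor(B)
    if not 1 <= df_off <= donor_len - primer_len + 1:
        raise ValueError("donor segment shorter than the distal primer offset")
    ef = mutant.sequence[df_mut - 1 : df_mut - 1 + primer_len]

    primers = [
        Primer("X.F", xf, "acceptor"),
        Primer("X.R", xr, "acceptor"),
        Primer("8.F", ef, "donor"),
        Primer("8.R", er, "donor"),
    ]
    sites = pd.DataFrame(
        [
            ("X.F", spec.acceptor, f5, "+"),
            ("X.R", spec.acceptor, r5, "-"),
            ("8.F", spec.donor_segment.contig, df_off, "+"),
            ("8.R", spec.donor_segment.contig, dr_off, "-"),
        ],
        columns=["primer", "contig", "five_prime", "strand"],
    )
    return AssayDesign(primers, size_spec, sites)


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------


def _sites(template: str, primer: Primer):
    fwd, rev = [], []
    p, rc = primer.sequence, revcomp(primer.sequence)
    i = template.find(p)
    while i != -1:
        fwd.append(i + 1)  # 5' end = leftmost base
        i = template.find(p, i + 1)
    i = template.find(rc)
    while i != -1:
        rev.append(i + len(rc))  # 5' end = rightmost base
        i = template.find(rc, i + 1)
    return fwd, rev


def insilico_pcr(
    templates: Sequence[PCRTemplate],
    primers: Sequence[Primer],
    max_product: int = 2000,
) -> list[Amplicon]:
    """All convergent primer-pair placements with product length at most
    ``max_product``.  Product length is the inclusive distance between the
    outermost primer 5' ends."""
    out: list[Amplicon] = []
    for tmpl in templates:
        hits = {p.name: _sites(tmpl.sequence, p) for p in primers}
        seen = set()
        for pf in primers:
            for pr in primers:
                for s in hits[pf.name][0]:
                    for e in hits[pr.name][1]:
                        length = e - s + 1
                        if length < len(pf.sequence) + len(pr.sequence):
                            continue
                        if length > max_product:
                            continue
                        key = (tmpl.name, s, e)
                        if key in seen:
                            continue
                        seen.add(key)
                        out.append(
                            Amplicon(
                                pf.name, pr.name, tmpl.name, s, e, length,
                                _classify_span(tmpl, s, e),
                            )
                        )
    return out


def _classify_span(tmpl: PCRTemplate, s: int, e: int) -> str:
    if tmpl.proximal_pos is not None and s <= tmpl.proximal_pos < e:
        return "proximal_junction"
    if tmpl.distal_pos is not None and s <= tmpl.distal_pos < e:
        return "distal_junction"
    if tmpl.insertion_site is not None and s <= tmpl.insertion_site < e:
        return "wild_type"
    return "none"


def sample_templates(
    sample: SimulatedSample,
    wild_acceptor: Contig,
    mutant: Haplotype,
    spec: JunctionSpec,
) -> list[PCRTemplate]:
    """PCR templates for a simulated sample's X haplotypes."""
    B_local = wild_acceptor.to_local(spec.acceptor_break)
    donor_len = len(spec.donor_segment)
    prox = B_local
    dist = B_local + donor_len + spec.novel_insert_len + spec.inversion_len
    out = []
    for i, label in enumerate(sample.haplotypes):
        if label == "mutX":
            out.append(
                PCRTemplate(f"{sample.sample_id}_hap{i}", mutant.contig.sequence,
                            proximal_pos=prox, distal_pos=dist)
            )
        else:
            out.append(
                PCRTemplate(f"{sample.sample_id}_hap{i}", wild_acceptor.sequence,
                            insertion_site=B_local)
            )
    return out


# ---------------------------------------------------------------------------
# genotype calls
# ---------------------------------------------------------------------------


def call_genotype(amplicons: Sequence[Amplicon], sex: str, sample_id: str = "") -> GenotypeCall:
    """Genotype from the set of amplicon span classes: the single
    wild-type product marks a non-carrier; the two junction products in a
    male mark an affected hemizygote; all three in a female mark a
    carrier; any other combination is inconsistent."""
    spans = frozenset(a.spans for a in amplicons) - {"none"}
    if spans == {"wild_type"}:
        call = "non_carrier"
    elif spans == {"proximal_junction", "distal_junction"} and sex == "male":
        call = "affected_hemizygous"
    elif spans == {"wild_type", "proximal_junction", "distal_junction"} and sex == "female":
        call = "carrier_female"
    else:
        call = "inconsistent"
    return GenotypeCall(sample_id, sex, spans, call)


def genotype_cohort(
    samples: Sequence[SimulatedSample],
    assay: AssayDesign,
    wild_acceptor: Contig,
    mutant: Haplotype,
    spec: JunctionSpec,
    max_product: int = 2000,
) -> list[GenotypeCall]:
    calls = []
    for sample in samples:
        templates = sample_templates(sample, wild_acceptor, mutant, spec)
        amps = insilico_pcr(templates, assay.primers, max_product)
        calls.append(call_genotype(amps, sample.sex, sample.sample_id))
    return calls


# ---------------------------------------------------------------------------
# segregation and panel screening
# ---------------------------------------------------------------------------

_CARRIER_CALLS = {"affected_hemizygous", "carrier_female"}


def segregation_check(
    genotypes: Sequence[GenotypeCall],
    pedigree: pd.DataFrame,
    model: str = "x_linked",
) -> dict:
    """Concordance of genotypes with affection status under X-linked
    inheritance (affected males carry the insertion; unaffected males do
    not; carrier females are asymptomatic) plus a transmission audit over
    parent-child links (no father-to-son transmission of the mutant X)."""
    if model != "x_linked":
        raise ValueError(f"unknown segregation model {model!r}")
    by_id = {g.sample_id: g for g in genotypes}
    ped = pedigree.set_index("sample_id")
    _check_cycles(ped)
    concordant, discordant = [], []
    for sid, row in ped.iterrows():
        g = by_id.get(sid)
        if g is None:
            continue
        carrier = g.call in _CARRIER_CALLS
        status = row["status"]
        ok = (
            (status == "affected" and g.sex == "male" and carrier)
            or (status == "unaffected" and not carrier)
            or (status == "carrier" and g.sex == "female" and carrier)
        )
        (concordant if ok else discordant).append(sid)
    violations = []
    has_links = {"father", "mother"} <= set(pedigree.columns)
    if has_links:
        for sid, row in ped.iterrows():
            g = by_id.get(sid)
            if g is None or g.call not in _CARRIER_CALLS:
                continue
            mother = by_id.get(row["mother"]) if isinstance(row["mother"], str) else None
            father = by_id.get(row["father"]) if isinstance(row["father"], str) else None
            if g.sex == "male" and mother is not None and mother.call not in _CARRIER_CALLS:
                violations.append(
                    {"sample": sid, "problem": "carrier son of a non-carrier mother "
                     "(father-to-son transmission is impossible for X-linked loci)"}
                )
            if (
                g.sex == "female"
                and mother is not None
                and father is not None
                and mother.call not in _CARRIER_CALLS
                and father.call not in _CARRIER_CALLS
            ):
                violations.append(
                    {"sample": sid, "problem": "carrier daughter of two non-carrier parents"}
                )
    return {
        "model": model,
        "n_concordant": len(concordant),
        "n_discordant": len(discordant),
        "discordant_samples": discordant,
        "transmission_violations": violations,
    }


def _check_cycles(ped: pd.DataFrame) -> None:
    def parents(sid):
        if sid not in ped.index:
            return []
        row = ped.loc[sid]
        return [p for p in (row.get("father"), row.get("mother")) if isinstance(p, str) and p]

    for start in ped.index:
        seen = {start}
        frontier = parents(start)
        depth = 0
        while frontier and depth < 1000:
            nxt = []
            for p in frontier:
                if p in seen:
                    raise ValueError(f"pedigree cycle involving {p!r}")
                seen.add(p)
                nxt.extend(parents(p))
            frontier = nxt
            depth += 1


def screen_panel(genotypes: Sequence[GenotypeCall]) -> dict:
    """Control-panel accounting: X chromosomes screened = 2 per female +
    1 per male; carrier X chromosomes counted from the genotype calls."""
    n_f = sum(g.sex == "female" for g in genotypes)
    n_m = sum(g.sex == "male" for g in genotypes)
    carriers = sum(g.call in _CARRIER_CALLS for g in genotypes)
    return {
        "n_females": n_f,
        "n_males": n_m,
        "x_chromosomes": 2 * n_f + n_m,
        "carrier_x_chromosomes": carriers,
    }
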