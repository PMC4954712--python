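#!/usr/bin/env python
"""Build the planted ground-truth genome and simulate the affected male.

Writes reference FASTA, paired FASTQ, and the truth-projected SAM under
scratch/ (large, regenerable), and a small genome summary under results/.
"""

import json
import os

from insjunction.alignments import write_alignments
from insjunction.pipeline import run_simulation
from insjunction.synthetic_data import cmtx3_reference, write_fasta, write_fastq

os.makedirs("scratch", exist_ok=True)
os.makedirs("results", exist_ok=True)

reference, spec = cmtx3_reference(seed=0)
truth, records, mut = run_simulation(reference, spec, coverage=40, seed=1)

write_fasta(reference.values(), "scratch/reference.fa")
write_fasta([mut.contig], "scratch/mutant_haplotype.fa")
write_fastq(truth, "scratch/reads_R1.fastq", "scratch/reads_R2.fastq")
write_alignments(records, "scratch/affected_male.sam", reference)

summary = {
    "contigs": {n: {"length": len(c), "offset": c.offset} for n, c in reference.items()},
    "acceptor_break": spec.acceptor_break,
    "donor_segment": [spec.donor_segment.contig, spec.donor_segment.start,
                      spec.donor_segment.end],
    "donor_length": len(spec.donor_segment),
    "microhomology": spec.microhomology,
    "micro_insert": {"source": spec.micro_insert.source, "length": spec.micro_insert.length,
                     "overlap_with_donor": spec.micro_insert.overlap_with_donor},
    "inversion_len": spec.inversion_len,
    "snv": [spec.snv.pos, spec.snv.ref, spec.snv.alt],
    "deletion": [spec.deletion.pos, spec.deletion.length],
    "mutant_haplotype_length": len(mut.contig),
    "n_reads": len(truth.placements),
    "coverage": 40,
}
with open("results/genome_summary.json", "w") as fh:
    json.dump(summary, fh, indent=2)

print(f"simulated {len(truth.placements)} reads ({summary['n_reads'] * 101 / 1e6:.1f} Mb)"
      f" from a {len(mut.contig):,} bp mutant haplotype")
print(f"planted junction: break chrX:{spec.acceptor_break:,}, donor "
      f"chr8:{spec.donor_segment.start:,}-{spec.donor_segment.end:,} "
      f"({len(spec.donor_segment):,} bp)")
print("outputs: scratch/{reference.fa,mutant_haplotype.fa,reads_R*.fastq,affected_male.sam}")
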