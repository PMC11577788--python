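"""Design a knockout oligo and its MAMA screening primers for a gene.

A 5-nt block of adjacent mismatches (the size that evades mismatch repair
in L. reuteri) converts an interior codon to a stop; MAMA PCR then
distinguishes recombinants (short allele-specific band) from wild type
(outer-primer band only).
"""

from barcodeq import design_mama_primers, design_stop_oligo
from barcodeq._seq import revcomp
from barcodeq.simulate import gen_cds_fixture

cds = gen_cds_fixture(400, seed=7)  # synthetic 400-codon gene
oligo = design_stop_oligo(cds, gene_strand="+", lagging_strand="-",
                          target_residues=[200])
print(f"CDS length: {len(cds)} nt ({len(cds)//3 - 1} sense codons)")
print(f"oligo ({len(oligo.sequence)} nt, lagging strand): {oligo.sequence}")
print(f"mismatch block (oligo coords): {oligo.mismatch_block}")
print(f"annotated mutations: {oligo.mutations}")

# screen design: embed the mutant CDS in a genomic context
pad = gen_cds_fixture(250, seed=8)
a, b = oligo.block_cds
mutant_locus = pad + cds[:a] + revcomp(oligo.sequence)[38:43] + cds[b:] + pad
site = len(pad) + a
primers = design_mama_primers(mutant_locus, site, (site, site + 5))
print(f"\nfwd outer: {primers.fwd_outer}")
print(f"rev outer: {primers.rev_outer}")
print(f"MAMA:      {primers.mama_primer}")
print(f"wild-type band: ~{primers.predicted_wt_band_bp} bp (always amplifies)")
print(f"recombinant band: ~{primers.predicted_mut_band_bp} bp (mutant allele only)")
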