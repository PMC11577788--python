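"""Simulate amplicon sequencing of a nine-strain mixture and demultiplex it.

Reads are merged by overlap consensus, filtered at Emax = 1 expected
errors, and assigned to strains by exact flank-anchored barcode lookup.
The estimated composition is compared with the generating truth.
"""

import numpy as np

from barcodeq import demux_sample, parse_template
from barcodeq import reference as ref
from barcodeq.simulate import SimConfig, gen_read_pairs

template = parse_template(ref.BARCODE_TEMPLATE_OLIGO)
whitelist = ref.strain_whitelist()  # barcode -> strain, nine tagged mutants
strains = sorted(set(whitelist.values()))
props = {s: 1 / len(strains) for s in strains}

cfg = SimConfig(seed=11, read_depth=10_000, per_base_error_rate=0.001)
pairs, truth = gen_read_pairs(cfg, whitelist, props, template)
counts, log = demux_sample(pairs, template, whitelist)

print("pipeline log:", log)
print(f"\n{'strain':8s} {'true %':>8s} {'est %':>8s}")
est = counts.percentages()
for _, row in truth.iterrows():
    s = row["strain"]
    print(f"{s:8s} {100 * row['true_proportion']:8.2f} {est[s]:8.2f}")
print(
    "\nEstimated percentages track the truth to within binomial sampling "
    "error; reads losing\ntheir flanks to sequencing error are 'unassigned', "
    "barcode-position errors go 'offlist'."
)
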