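"""Enumerate the functional barcode space of the degenerate repair oligo.

The barcoding oligo writes six random bases into the cat locus while
repairing an in-frame stop codon. Positions 2-4 replace the stop codon and
are read on the reverse complement (cat is on the opposite strand), so
only barcodes whose replacement codon is a sense codon restore
chloramphenicol resistance and survive selection.
"""

from barcodeq import enumerate_space, parse_template
from barcodeq import reference as ref

template = parse_template(ref.BARCODE_TEMPLATE_OLIGO)
print(f"template: {template.sequence}")
print(f"degenerate positions (0-based): {template.degenerate_offsets}")

space = enumerate_space(template)
print(f"\nall barcodes:          {space.all_barcodes}")
print(f"functional barcodes:   {space.functional_count}")
print(f"nonfunctional:         {space.nonfunctional_count}")
print(
    "\nThe 4,096 6-mers split into 4^3 x 61 = 3,904 selectable tags "
    "(sense replacement codon)\nand 4^3 x 3 = 192 tags that leave a stop "
    "codon in place and are never recovered."
)
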