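"""Published oligonucleotide designs for the *L. reuteri* cat-locus barcoding system.

These are the published sequences of the degenerate barcoding oligo (oVPL3848),
the nine strain-specific barcoded repair oligos used to tag the adhesin
mutants, the residue-level mutation annotations of the stop-codon
recombineering oligos, and one worked MAMA screening set. They serve as
reference inputs for validation and as a ready-made whitelist for the
competition analysis.
"""

from __future__ import annotations

# Degenerate barcoding oligo targeting the inactivated cat gene (cat*).
# Written antisense to the cat coding strand; the six N's are the barcode:
# one wobble base, the three bases replacing the in-frame stop codon, and
# two further wobble bases (codons A138, S140, S142 on the coding strand).
BARCODE_TEMPLATE_OLIGO = (
    "gtttcccaaaacacctatacctgaaaatgcNttttcNNNNtcNattattcc"
    "ttggacttcatttactgggtttaacttaa"
)

# Strain-specific barcoded repair oligos (oligo id -> sequence). Uppercase
# bases in the published designs mark the barcode positions.
BARCODED_OLIGOS: dict[str, str] = {
    "oVPL3996": "gtttcccaaaacacctatacctgaaaatgcTttttcGACGtcTattattccttggacttcatttactgggtttaacttaa",
    "oVPL3997": "gtttcccaaaacacctatacctgaaaatgcTttttcTTGCtcGattattccttggacttcatttactgggtttaacttaa",
    "oVPL3998": "gtttcccaaaacacctatacctgaaaatgcGttttcTATTtcTattattccttggacttcatttactgggtttaacttaa",
    "oVPL3999": "gtttcccaaaacacctatacctgaaaatgcCttttcGACAtcTattattccttggacttcatttactgggtttaacttaa",
    "oVPL4000": "gtttcccaaaacacctatacctgaaaatgcTttttcCTTAtcCattattccttggacttcatttactgggtttaacttaa",
    "oVPL4001": "gtttcccaaaacacctatacctgaaaatgcGttttcTATCtcTattattccttggacttcatttactgggtttaacttaa",
    "oVPL4002": "gtttcccaaaacacctatacctgaaaatgcTttttcAGCAtcTattattccttggacttcatttactgggtttaacttaa",
    "oVPL4003": "gtttcccaaaacacctatacctgaaaatgcTttttcAGTTtcAattattccttggacttcatttactgggtttaacttaa",
    "oVPL4005": "gtttcccaaaacacctatacctgaaaatgcTttttcGTGTtcTattattccttggacttcatttactgggtttaacttaa",
}

# Strain carried by each barcoded oligo.
OLIGO_STRAIN: dict[str, str] = {
    "oVPL3996": "dcmbA",
    "oVPL3997": "dauto",
    "oVPL3998": "dapf1",
    "oVPL3999": "d11993",
    "oVPL4000": "dfbpA",
    "oVPL4001": "dsrtA",
    "oVPL4002": "dslpA",
    "oVPL4003": "dpilP",
    "oVPL4005": "dcidi",
}

# Residue-level mutation strings of the published stop-codon recombineering
# oligos (oligo id -> annotation; '*' marks a nonsense substitution).
MUTATION_STRINGS: dict[str, str] = {
    "oVPL236": "H488R",
    "oVPL449": "K150*V151Q",
    "oVPL1670": "Y38*Q39SM40L",
    "oVPL3694": "Q211RG212*",
    "oVPL3763": "N68*P69*",
    "oVPL3796": "P282*N283D",
    "oVPL3802": "P58*Q59*",
    "oVPL3808": "N162*Q163*",
    "oVPL3814": "V102*Q103*",
    "oVPL3850": "D82E G83* E84*",
    "oVPL3856": "P99* K100*",
    "oVPL3939": "M76RG77*",
}

# srtA stop-codon oligo (K150*V151Q) with its published MAMA screening set.
# The gene frame runs on the reverse complement of the oligo; anchoring
# residue 138 at region offset 2 places the introduced stop at residue 150.
SRTA_STOP_OLIGO = (
    "aaacgcgatccatgttggtgatataaatcatctgccctTGTCA"
    "agcatgatagtacaatggagaaaagaggattttgctcc"
)
SRTA_FRAME_ANCHOR = (2, 138)  # (region offset on gene strand, residue index)
SRTA_MAMA_OLIGO = "ttggtgatataaatcatctgccctTGTC"


def strain_whitelist() -> dict[str, str]:
    """Barcode -> strain mapping for the nine published tagged mutants."""
    # extracted lazily to avoid an import cycle with barcode_model
    from .barcode_model import extract_barcode, parse_template

    template = parse_template(BARCODE_TEMPLATE_OLIGO)
    out: dict[str, str] = {}
    for oligo_id, seq in BARCODED_OLIGOS.items():
        bc = extract_barcode(seq, template)
        assert bc is not None
        out[bc] = OLIGO_STRAIN[oligo_id]
    return out
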