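"""Standard genetic code as a small lookup object.

The barcode design hinges on a single sense/stop decision per codon, so the
table is exposed as a plain ``codon -> amino acid`` mapping (stop = ``'*'``)
built from Biopython's standard table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable as _BioCodonTable

from ._seq import DNA_BASES, check_dna


@dataclass(frozen=True)
class CodonTable:
    """Codon -> single-letter amino acid mapping with an explicit stop set."""

    forward: dict[str, str]
    stop_codons: frozenset[str]
    sense_codons: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.forward) != 64:
            raise ValueError(f"codon table must cover 64 codons, got {len(self.forward)}")
        object.__setattr__(
            self, "sense_codons", frozenset(self.forward) - self.stop_codons
        )

    def translate_codon(self, codon: str) -> str:
        """Amino acid for one codon; ``'*'`` for a stop codon."""
        c = check_dna(codon, what="codon")
        if len(c) != 3:
            raise ValueError(f"codon must have length 3, got {c!r}")
        return self.forward[c]

    def translate(self, seq: str) -> str:
        s = check_dna(seq, what="CDS")
        if len(s) % 3:
            raise ValueError(f"sequence length {len(s)} not divisible by 3")
        return "".join(self.forward[s[i : i + 3]] for i in range(0, len(s), 3))

    def is_stop(self, codon: str) -> bool:
        return self.translate_codon(codon) == "*"


def standard_table() -> CodonTable:
    """The standard genetic code: 61 sense codons, 3 stops (TAA/TAG/TGA)."""
    bio = _BioCodonTable.unambiguous_dna_by_id[1]
    forward = {c: bio.forward_table[c] for c in bio.forward_table}
    for stop in bio.stop_codons:
        forward[stop] = "*"
    # forward_table omits stops; fill any remaining combination defensively
    for codon in ("".join(p) for p in itertools.product(DNA_BASES, repeat=3)):
        forward.setdefault(codon, "*")
    return CodonTable(forward=forward, stop_codons=frozenset(bio.stop_codons))


STANDARD_TABLE = standard_table()
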