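"""Small shared sequence helpers (uppercase canonical form throughout)."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_BASES = ("A", "C", "G", "T")


def canon(seq: str) -> str:
    """Uppercase canonical form of a DNA string."""
    return seq.upper()


def revcomp(seq: str) -> str:
    return canon(seq).translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, *, allow_n: bool = False, what: str = "sequence") -> str:
    """Validate alphabet and return the canonical (uppercase) form."""
    s = canon(seq)
    allowed = set("ACGTN") if allow_n else set("ACGT")
    bad = set(s) - allowed
    if bad:
        raise ValueError(
            f"{what} contains non-{'IUPAC' if allow_n else 'ACGT'} "
            f"character(s): {sorted(bad)}"
        )
    return s
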