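"""Design of stop-codon recombineering oligos and MAMA screening primers.

ssDNA recombineering incorporates a short oligo at the replication fork of
the lagging strand. A block of five adjacent mismatches evades mismatch
repair in *L. reuteri*, so each knockout oligo carries exactly one 5-nt
replacement block that converts one or more interior codons of the target
CDS into stop codons, flanked by long homology arms (default 38 nt, giving
an ~81-nt oligo). Recombinants are then screened by mismatch amplification
mutation assay (MAMA) PCR: two outer primers 500 bp either side of the
edited site yield an ~1-kb product from any template, while an
allele-specific primer whose 3' end sits on the mismatch block amplifies
only the recombinant allele, producing a diagnostic ~0.5-kb band.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

from ._seq import DNA_BASES, check_dna, revcomp
from .codon import STANDARD_TABLE, CodonTable

AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY*")

MISMATCH_BLOCK_LEN = 5
DEFAULT_ARM_LENGTH = 38

_MUTATION_TOKEN = re.compile(r"([A-Z])(\d+)([A-Z*])")


class DesignInfeasibleError(ValueError):
    """No admissible replacement block achieves the requested stops."""


@dataclass(frozen=True)
class Substitution:
    """One residue-level change, e.g. ``K150*`` = Lys150 to stop."""

    residue_index: int  # 1-based
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_LETTERS or self.wt_aa == "*":
            raise ValueError(f"invalid wild-type amino acid {self.wt_aa!r}")
        if self.mut_aa not in AA_LETTERS:
            raise ValueError(f"invalid mutant amino acid {self.mut_aa!r}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"substitution at {self.residue_index} is synonymous")
        if self.residue_index < 1:
            raise ValueError("residue indices are 1-based")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.residue_index}{self.mut_aa}"


@dataclass(frozen=True)
class MutationSpec:
    """Ordered residue-level annotation, e.g. ``K150*V151Q``."""

    substitutions: tuple[Substitution, ...]

    def __post_init__(self) -> None:
        idxs = [s.residue_index for s in self.substitutions]
        if any(b < a for a, b in zip(idxs, idxs[1:])):
            raise ValueError("residue indices must be non-decreasing")

    def __str__(self) -> str:
        return "".join(str(s) for s in self.substitutions)

    def __len__(self) -> int:
        return len(self.substitutions)

    @property
    def introduces_stop(self) -> bool:
        return any(s.mut_aa == "*" for s in self.substitutions)


def parse_mutation_string(text: str) -> MutationSpec:
    """Parse a concatenated annotation like ``"K150*V151Q"``.

    Whitespace between tokens is tolerated; the canonical formatted form
    (``str(spec)``) is space-free.
    """
    compact = "".join(text.split())
    pos = 0
    subs: list[Substitution] = []
    for m in _MUTATION_TOKEN.finditer(compact):
        if m.start() != pos:
            raise ValueError(f"malformed mutation string near {compact[pos:]!r}")
        subs.append(Substitution(int(m.group(2)), m.group(1), m.group(3)))
        pos = m.end()
    if pos != len(compact) or not subs:
        raise ValueError(f"malformed mutation string {text!r}")
    return MutationSpec(substitutions=tuple(subs))


def format_mutation_spec(spec: MutationSpec) -> str:
    return str(spec)


@dataclass(frozen=True)
class RecombineeringOligo:
    """A lagging-strand knockout oligo with its 5-nt mismatch block.

    ``mismatch_block`` is the half-open interval of mismatching bases in
    oligo coordinates; ``block_cds`` the same interval in CDS coordinates.
    """

    sequence: str
    target_strand: str  # always "lagging"
    mismatch_block: tuple[int, int]
    block_cds: tuple[int, int]
    arms: tuple[int, int]
    mutations: MutationSpec
    target_locus: str = ""

    def __post_init__(self) -> None:
        if self.mismatch_block[1] - self.mismatch_block[0] != MISMATCH_BLOCK_LEN:
            raise ValueError("mismatch block must span exactly 5 nt")
        if min(self.arms) < 35:
            raise ValueError("homology arms must be >= 35 nt")
        if not self.mutations.introduces_stop:
            raise ValueError("oligo must introduce at least one stop codon")


def _validate_cds(cds: str, table: CodonTable) -> str:
    s = check_dna(cds, what="CDS")
    if len(s) % 3:
        raise ValueError(f"CDS length {len(s)} not divisible by 3")
    if s[:3] not in ("ATG", "GTG", "TTG"):
        raise ValueError(f"CDS must begin with a start codon, got {s[:3]}")
    if not table.is_stop(s[-3:]):
        raise ValueError(f"CDS must end with a stop codon, got {s[-3:]}")
    return s


def _aa_changes(
    wt_codons: str, mut_codons: str, first_residue: int, table: CodonTable
) -> list[Substitution]:
    wt_aa = table.translate(wt_codons)
    mut_aa = table.translate(mut_codons)
    return [
        Substitution(first_residue + i, a, b)
        for i, (a, b) in enumerate(zip(wt_aa, mut_aa))
        if a != b
    ]


def design_stop_oligo(
    cds: str,
    gene_strand: str = "+",
    lagging_strand: str = "-",
    target_residues: list[int] | None = None,
    arm_length: int = DEFAULT_ARM_LENGTH,
    table: CodonTable = STANDARD_TABLE,
    target_locus: str = "",
) -> RecombineeringOligo:
    """Design a lagging-strand oligo converting target residues to stops.

    Candidate 5-nt blocks overlapping the target codons are scored by how
    many requested residues become stops (every block base must mismatch
    wild type, so the block evades mismatch repair); ties go to the
    5'-most placement on the oligo. The returned :class:`MutationSpec`
    annotates every amino-acid change the block causes, including
    collateral changes at flanking residues.
    """
    s = _validate_cds(cds, table)
    n_codons = len(s) // 3
    if not target_residues:
        raise ValueError("at least one target residue is required")
    for r in target_residues:
        if not 1 < r < n_codons:
            raise ValueError(
                f"target residue {r} must be interior (2..{n_codons - 1})"
            )
    if gene_strand not in "+-" or lagging_strand not in "+-":
        raise ValueError("strands must be '+' or '-'")
    oligo_is_sense = gene_strand == lagging_strand

    target_set = set(target_residues)
    # candidate block start positions: any 5-nt window touching a target codon
    starts: set[int] = set()
    for r in target_residues:
        lo, hi = 3 * (r - 1), 3 * r  # codon interval, half-open
        starts.update(range(max(0, lo - MISMATCH_BLOCK_LEN + 1), hi))
    best: tuple | None = None  # (score, -n_changes, oligo_5p_key, repl, start)
    for start in sorted(starts):
        end = start + MISMATCH_BLOCK_LEN
        if end > len(s):
            continue
        wt_block = s[start:end]
        res_lo, res_hi = start // 3 + 1, (end - 1) // 3 + 1  # residues touched
        for repl in itertools.product(*[
            [b for b in DNA_BASES if b != w] for w in wt_block
        ]):
            mut = s[: start] + "".join(repl) + s[end:]
            changes = _aa_changes(
                s[3 * (res_lo - 1) : 3 * res_hi],
                mut[3 * (res_lo - 1) : 3 * res_hi],
                res_lo,
                table,
            )
            stops = sum(
                1 for c in changes if c.mut_aa == "*" and c.residue_index in target_set
            )
            if stops == 0:
                continue
            # 5'-most on the oligo: small start if sense, large start if antisense
            oligo_5p_key = -start if oligo_is_sense else start
            cand = (stops, oligo_5p_key, -len(changes), "".join(repl), start)
            if best is None or cand > best:
                best = cand
    if best is None:
        raise DesignInfeasibleError(
            f"no 5-nt block creates a stop at residues {sorted(target_set)}"
        )
    _, _, _, repl, start = best
    end = start + MISMATCH_BLOCK_LEN
    if start - arm_length < 0 or end + arm_length > len(s):
        raise ValueError(
            "homology arms extend beyond the CDS; choose a more interior "
            "target or a shorter arm_length"
        )
    mut_cds = s[:start] + repl + s[end:]
    res_lo, res_hi = start // 3 + 1, (end - 1) // 3 + 1
    mutations = MutationSpec(
        tuple(
            _aa_changes(
                s[3 * (res_lo - 1) : 3 * res_hi],
                mut_cds[3 * (res_lo - 1) : 3 * res_hi],
                res_lo,
                table,
            )
        )
    )
    window = mut_cds[start - arm_length : end + arm_length]
    if oligo_is_sense:
        oligo_seq = window
        block = (arm_length, arm_length + MISMATCH_BLOCK_LEN)
    else:
        oligo_seq = revcomp(window)
        block = (arm_length, arm_length + MISMATCH_BLOCK_LEN)  # symmetric arms
    return RecombineeringOligo(
        sequence=oligo_seq,
        target_strand="lagging",
        mismatch_block=block,
        block_cds=(start, end),
        arms=(arm_length, arm_length),
        mutations=mutations,
        target_locus=target_locus,
    )


def annotate_oligo_mutations(
    oligo: str,
    wt_region: str,
    frame_anchor: tuple[int, int],
    gene_strand_relative_to_oligo: str = "+",
    table: CodonTable = STANDARD_TABLE,
) -> MutationSpec | None:
    """Residue-level differences between an oligo and its wild-type region.

    ``wt_region`` is given in gene orientation and must align end-to-end
    with the (possibly reverse-complemented) oligo. ``frame_anchor =
    (region_offset, residue_index)`` states that the codon starting at
    ``region_offset`` encodes residue ``residue_index``. Returns ``None``
    for a perfect match (empty annotation).
    """
    wt = check_dna(wt_region, what="wild-type region")
    o = check_dna(oligo, what="oligo")
    if gene_strand_relative_to_oligo == "-":
        o = revcomp(o)
    elif gene_strand_relative_to_oligo != "+":
        raise ValueError("gene_strand_relative_to_oligo must be '+' or '-'")
    if len(o) != len(wt):
        raise ValueError(
            f"oligo ({len(o)} nt) and wild-type region ({len(wt)} nt) must align end-to-end"
        )
    mismatches = [i for i, (a, b) in enumerate(zip(o, wt)) if a != b]
    if not mismatches:
        return None
    span = mismatches[-1] - mismatches[0] + 1
    if span > MISMATCH_BLOCK_LEN:
        raise ValueError(
            f"mismatches span {span} nt; a single block of <= {MISMATCH_BLOCK_LEN} is required"
        )
    offset, residue0 = frame_anchor
    # codon grid anchored so the codon at `offset` encodes residue `residue0`
    first = offset % 3
    usable = len(wt) - first - ((len(wt) - first) % 3)
    wt_fr = wt[first : first + usable]
    mut_fr = o[first : first + usable]
    first_residue = residue0 + (first - offset) // 3
    subs = _aa_changes(wt_fr, mut_fr, first_residue, table)
    return MutationSpec(tuple(subs)) if subs else None


@dataclass(frozen=True)
class MAMAPrimerSet:
    """Outer primer pair plus mutant-specific MAMA primer with band sizes."""

    fwd_outer: str
    rev_outer: str
    mama_primer: str
    fwd_outer_start: int
    rev_outer_5p: int
    mama_5p: int
    predicted_wt_band_bp: int
    predicted_mut_band_bp: int


def design_mama_primers(
    locus: str,
    mutation_site: int,
    mismatch_block: tuple[int, int],
    outer_offset: int = 500,
    outer_primer_len: int = 25,
    mama_primer_len: int = 26,
) -> MAMAPrimerSet:
    """Design a MAMA screening set around an edited site.

    ``locus`` must be the *recombinant* sequence so the MAMA primer's
    3' bases match the mutant allele. The forward outer primer starts
    ``outer_offset`` bp upstream of the site, the reverse outer primer
    ``outer_offset`` bp downstream; the MAMA primer runs in the forward
    direction and 3'-terminates on the mismatch block. The wild-type
    diagnostic band is the outer-pair amplicon (~2x outer_offset); the
    recombinant band is the MAMA/reverse-outer amplicon (~outer_offset).
    """
    seq = check_dna(locus, what="locus")
    bstart, bend = mismatch_block
    if not (0 <= bstart < bend <= len(seq)):
        raise ValueError("mismatch_block outside locus")
    if not (bstart <= mutation_site < bend):
        raise ValueError("mutation_site must lie inside the mismatch block")
    fwd_start = mutation_site - outer_offset
    rev_5p = mutation_site + outer_offset
    if fwd_start < 0 or rev_5p >= len(seq):
        raise ValueError(
            f"site must be >= {outer_offset} bp from both locus ends"
        )
    fwd_outer = seq[fwd_start : fwd_start + outer_primer_len]
    rev_outer = revcomp(seq[rev_5p - outer_primer_len + 1 : rev_5p + 1])
    mama_3p = bend - 1  # last base of the block
    mama_5p = mama_3p - mama_primer_len + 1
    if mama_5p < 0:
        raise ValueError("locus too short for the MAMA primer")
    mama = seq[mama_5p : mama_3p + 1]
    wt_band = rev_5p - fwd_start + 1
    mut_band = rev_5p - mama_5p + 1
    return MAMAPrimerSet(
        fwd_outer=fwd_outer,
        rev_outer=rev_outer,
        mama_primer=mama,
        fwd_outer_start=fwd_start,
        rev_outer_5p=rev_5p,
        mama_5p=mama_5p,
        predicted_wt_band_bp=wt_band,
        predicted_mut_band_bp=mut_band,
    )
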