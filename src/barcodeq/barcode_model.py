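"""Degenerate-barcode model for the stop-codon-repairing cat oligo.

The barcoding oligo repairs an engineered in-frame stop codon in a
chromosomal chloramphenicol-resistance gene (*cat*) while writing six random
bases into the locus. Because the oligo is antisense to the *cat* coding
strand, the three bases replacing the stop codon (barcode positions 2-4)
are read as a codon on the reverse complement; a barcode is *functional* -
i.e. restores Cat and survives chloramphenicol selection - exactly when
that replacement codon is a sense codon. The remaining three positions sit
on wobble bases (codons A138, S140, S142) and are unconstrained.

This module parses the degenerate template, enumerates and classifies the
barcode space (3 stop codons reverse-complement to 3 of the 64 replacement
codons, so 4^3 x 61 = 3,904 of the 4,096 barcodes are functional),
instantiates and extracts concrete barcodes, and provides the
collision/diversity arithmetic used to assess library complexity.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import DNA_BASES, check_dna, revcomp
from .codon import STANDARD_TABLE, CodonTable

BARCODE_LENGTH = 6
FLANK_LENGTH = 12

#: Role of each 1-based barcode position: positions 2-4 replace the stop
#: codon; positions 1, 5 and 6 are wobble bases.
ROLE_MAP: dict[int, str] = {
    1: "wobble",
    2: "codon1",
    3: "codon2",
    4: "codon3",
    5: "wobble",
    6: "wobble",
}

#: Offsets of the codon positions within a 6-base barcode (0-based).
CODON_SLICE = slice(1, 4)


class TemplateFormatError(ValueError):
    """Degenerate template does not match the expected N arrangement."""


@dataclass(frozen=True)
class BarcodeTemplate:
    """A degenerate repair oligo with six N positions and fixed flanks.

    ``sequence`` is the canonical uppercase oligo (antisense to the *cat*
    coding strand), ``degenerate_offsets`` the 0-based N positions in
    ascending order, and ``flank_left``/``flank_right`` the 12-nt constant
    anchors immediately outside the degenerate block, used for extraction.
    """

    sequence: str
    degenerate_offsets: tuple[int, ...]
    flank_left: str
    flank_right: str
    role_map: Mapping[int, str] = field(default_factory=lambda: dict(ROLE_MAP))
    orientation: str = "antisense"  # relative to the cat coding strand

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Barcode:
    """A concrete 6-base tag with its functionality call."""

    bases: str
    functional: bool
    replacement_aa: str  # amino acid encoded by revcomp of positions 2-4

    @property
    def replacement_codon(self) -> str:
        return revcomp(self.bases[CODON_SLICE])


@dataclass(frozen=True)
class BarcodeSpace:
    """Exhaustive classification of all 4^6 barcodes for one template."""

    template: BarcodeTemplate
    all_barcodes: int
    functional: tuple[str, ...]
    nonfunctional_count: int

    @property
    def functional_count(self) -> int:
        return len(self.functional)


@dataclass(frozen=True)
class DiversityStats:
    """Summary of an observed barcode library.

    ``position_frequency`` is a 6x4 count table (rows = barcode positions
    1-6, columns = A/C/G/T); ``information_content`` is per-position
    2 - H bits, the height of a sequence-logo column.
    """

    k: int
    N: int
    expected_unique: float
    observed_unique: int
    position_frequency: pd.DataFrame
    information_content: np.ndarray
    aa_spectrum: dict[str, int]


def parse_template(sequence: str) -> BarcodeTemplate:
    """Parse a degenerate barcoding oligo into a :class:`BarcodeTemplate`.

    The six N's must be arranged as ``N xxxxx NNNN xx N`` (one wobble, five
    fixed bases, the stop-replacement codon plus one wobble, two fixed
    bases, one wobble), matching the published design. Flank anchors are
    the 12 bases immediately left of the first N and right of the last N.
    """
    seq = check_dna(sequence, allow_n=True, what="template")
    offsets = tuple(i for i, b in enumerate(seq) if b == "N")
    if len(offsets) != BARCODE_LENGTH:
        raise TemplateFormatError(
            f"template must contain exactly {BARCODE_LENGTH} N positions, "
            f"found {len(offsets)}"
        )
    expected_gaps = (6, 1, 1, 1, 3)
    gaps = tuple(b - a for a, b in zip(offsets, offsets[1:]))
    if gaps != expected_gaps:
        raise TemplateFormatError(
            f"N arrangement must be N/5 fixed/NNNN/2 fixed/N "
            f"(offset gaps {expected_gaps}), got gaps {gaps}"
        )
    first, last = offsets[0], offsets[-1]
    if first < FLANK_LENGTH or last + 1 + FLANK_LENGTH > len(seq):
        raise TemplateFormatError(
            f"degenerate block must be flanked by at least {FLANK_LENGTH} "
            f"constant bases on each side"
        )
    flank_left = seq[first - FLANK_LENGTH : first]
    flank_right = seq[last + 1 : last + 1 + FLANK_LENGTH]
    for name, flank in (("left", flank_left), ("right", flank_right)):
        if seq.count(flank) != 1:
            raise TemplateFormatError(f"{name} flank {flank!r} is not unique in template")
    return BarcodeTemplate(
        sequence=seq,
        degenerate_offsets=offsets,
        flank_left=flank_left,
        flank_right=flank_right,
    )


def classify_barcode(
    bases: str, template: BarcodeTemplate | None = None, table: CodonTable = STANDARD_TABLE
) -> Barcode:
    """Classify a 6-base barcode as functional (sense replacement) or not.

    The template is antisense to the coding strand, so the replacement
    codon is the reverse complement of barcode positions 2-4.
    """
    b = check_dna(bases, what="barcode")
    if len(b) != BARCODE_LENGTH:
        raise ValueError(f"barcode must have length {BARCODE_LENGTH}, got {len(b)}")
    aa = table.translate_codon(revcomp(b[CODON_SLICE]))
    return Barcode(bases=b, functional=aa != "*", replacement_aa=aa)


def enumerate_space(
    template: BarcodeTemplate,
    table: CodonTable = STANDARD_TABLE,
    codon_whitelist: Iterable[str] | None = None,
) -> BarcodeSpace:
    """Exhaustively enumerate and classify all 4^6 barcodes.

    ``codon_whitelist`` optionally restricts functionality to a subset of
    sense replacement codons (e.g. codons encoding amino acids observed to
    restore activity); functionality then requires membership in that set.
    """
    whitelist: frozenset[str] | None = None
    if codon_whitelist is not None:
        whitelist = frozenset(check_dna(c, what="codon") for c in codon_whitelist)
        for c in whitelist:
            if len(c) != 3:
                raise ValueError(f"whitelist entries must be codons, got {c!r}")
            if table.is_stop(c):
                raise ValueError(f"whitelist codon {c} is a stop codon")
    functional: list[str] = []
    nonfunctional = 0
    for combo in itertools.product(DNA_BASES, repeat=BARCODE_LENGTH):
        bases = "".join(combo)
        bc = classify_barcode(bases, template, table)
        ok = bc.functional
        if ok and whitelist is not None:
            ok = bc.replacement_codon in whitelist
        if ok:
            functional.append(bases)
        else:
            nonfunctional += 1
    return BarcodeSpace(
        template=template,
        all_barcodes=4**BARCODE_LENGTH,
        functional=tuple(functional),
        nonfunctional_count=nonfunctional,
    )


def instantiate_oligo(template: BarcodeTemplate, bases: str) -> str:
    """Fill the template's N positions with the barcode bases, in order."""
    b = check_dna(bases, what="barcode")
    if len(b) != len(template.degenerate_offsets):
        raise ValueError(
            f"barcode length {len(b)} does not match "
            f"{len(template.degenerate_offsets)} degenerate positions"
        )
    seq = list(template.sequence)
    for base, off in zip(b, template.degenerate_offsets):
        seq[off] = base
    return "".join(seq)


def _find_exact(haystack: str, needle: str, max_mismatches: int) -> list[int]:
    if max_mismatches == 0:
        hits, start = [], 0
        while (i := haystack.find(needle, start)) != -1:
            hits.append(i)
            start = i + 1
        return hits
    n = len(needle)
    return [
        i
        for i in range(len(haystack) - n + 1)
        if sum(a != b for a, b in zip(haystack[i : i + n], needle)) <= max_mismatches
    ]


def extract_barcode(
    read_sequence: str,
    template: BarcodeTemplate,
    max_flank_mismatches: int = 0,
) -> str | None:
    """Pull the 6 barcode bases out of a read by anchoring on both flanks.

    Both the read and its reverse complement are searched. Returns ``None``
    (unassigned) unless exactly one flank pair with the template's spacing
    is found across both strands.
    """
    seq = check_dna(read_sequence, allow_n=True, what="read")
    offs = template.degenerate_offsets
    inner_len = offs[-1] - offs[0] + 1  # window between the two flanks
    rel = [o - offs[0] for o in offs]
    hits: list[tuple[str, int]] = []  # (strand sequence, window start)
    for strand in (seq, revcomp(seq)):
        lefts = _find_exact(strand, template.flank_left, max_flank_mismatches)
        rights = set(_find_exact(strand, template.flank_right, max_flank_mismatches))
        for li in lefts:
            start = li + FLANK_LENGTH
            if start + inner_len in rights:
                hits.append((strand, start))
    if len(hits) != 1:
        return None
    strand, start = hits[0]
    return "".join(strand[start + r] for r in rel)


def expected_unique_barcodes(k: int, N: int) -> float:
    """Expected number of distinct barcodes after k uniform draws from N.

    Classic occupancy result: ``N * (1 - (1 - 1/N)^k)``.
    """
    if N < 1:
        raise ValueError(f"library size N must be >= 1, got {N}")
    if k < 0:
        raise ValueError(f"draw count k must be >= 0, got {k}")
    return N * (1.0 - (1.0 - 1.0 / N) ** k)


def simulate_unique_barcodes(
    k: int,
    N: int,
    trials: int = 10_000,
    seed: int | None = None,
    position_weights: np.ndarray | None = None,
    template: BarcodeTemplate | None = None,
    table: CodonTable = STANDARD_TABLE,
) -> dict[str, float]:
    """Monte-Carlo distribution of the unique-barcode count after k draws.

    With ``position_weights`` (a 6x4 row-stochastic matrix over A/C/G/T)
    draws are made from the *functional* barcode space under per-position
    bias (rejection sampling of stop replacements); otherwise draws are
    uniform over N equally likely barcodes. Returns mean, sd and quantiles.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    if position_weights is None:
        draws = rng.integers(0, N, size=(trials, k))
        uniques = np.array([len(np.unique(row)) for row in draws])
    else:
        w = np.asarray(position_weights, dtype=float)
        if w.shape != (BARCODE_LENGTH, 4) or np.any(w < 0):
            raise ValueError("position_weights must be a nonnegative 6x4 matrix")
        sums = w.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("each position's weights must sum to 1")
        uniques = np.empty(trials, dtype=int)
        for t in range(trials):
            barcodes = _sample_functional(k, w, rng, table)
            uniques[t] = len(set(barcodes))
    qs = np.quantile(uniques, [0.025, 0.25, 0.5, 0.75, 0.975])
    return {
        "mean": float(uniques.mean()),
        "sd": float(uniques.std(ddof=1)) if trials > 1 else 0.0,
        "q2.5": float(qs[0]),
        "q25": float(qs[1]),
        "median": float(qs[2]),
        "q75": float(qs[3]),
        "q97.5": float(qs[4]),
    }


def _sample_functional(
    k: int, weights: np.ndarray, rng: np.random.Generator, table: CodonTable
) -> list[str]:
    """Draw k functional barcodes under per-position base bias."""
    out: list[str] = []
    while len(out) < k:
        idx = [rng.choice(4, p=weights[j]) for j in range(BARCODE_LENGTH)]
        bases = "".join(DNA_BASES[i] for i in idx)
        if not table.is_stop(revcomp(bases[CODON_SLICE])):
            out.append(bases)
    return out


def diversity_stats(
    barcodes: Sequence[str],
    N: int = 3904,
    table: CodonTable = STANDARD_TABLE,
    small_sample_correction: bool = False,
) -> DiversityStats:
    """Positional base usage, logo information content and amino-acid spectrum.

    ``information_content[j] = 2 - H_j`` bits with ``H_j`` the Shannon
    entropy of position j. The optional small-sample correction subtracts
    the Miller-Madow bias term ``(|A|-1) / (2 ln 2 k)`` from each column's
    information content (clipped at 0).
    """
    if len(barcodes) == 0:
        raise ValueError("barcode list must be nonempty")
    clean = [classify_barcode(b, table=table).bases for b in barcodes]
    k = len(clean)
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(1, BARCODE_LENGTH + 1, name="position"), columns=list(DNA_BASES)
    )
    for b in clean:
        for j, base in enumerate(b, start=1):
            counts.loc[j, base] += 1
    freqs = counts.to_numpy(dtype=float) / k
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = 2.0 - entropy
    if small_sample_correction:
        ic = np.clip(ic - (len(DNA_BASES) - 1) / (2.0 * math.log(2) * k), 0.0, 2.0)
    spectrum = Counter(classify_barcode(b, table=table).replacement_aa for b in clean)
    return DiversityStats(
        k=k,
        N=N,
        expected_unique=expected_unique_barcodes(k, N),
        observed_unique=len(set(clean)),
        position_frequency=counts,
        information_content=ic,
        aa_spectrum=dict(spectrum),
    )
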