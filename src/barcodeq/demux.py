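"""Amplicon demultiplexing: merge pairs, filter by expected errors, count barcodes.

The sequencing readout of a pooled competition is a short *cat*-locus
amplicon carrying the 6-base strain barcode. Paired 150-bp reads fully
overlap the amplicon, so mates are merged by overlap consensus, merged
reads are filtered on the expected number of errors E = sum(10^(-Q/10))
with a default cutoff Emax = 1, and each surviving read is assigned to a
whitelisted strain by exact flank-anchored barcode extraction. Reads whose
barcode is structurally valid but absent from the whitelist ("offlist")
are tallied separately and excluded from relative-abundance percentages.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from ._seq import check_dna, revcomp
from .barcode_model import BarcodeTemplate, extract_barcode

PHRED_OFFSET = 33
QUAL_CAP = 41

#: Sentinel assignment values
OFFLIST = "__offlist__"
UNASSIGNED = "__unassigned__"


@dataclass(frozen=True)
class ReadPair:
    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class MergedRead:
    id: str
    seq: str
    qual: str
    overlap_len: int
    expected_errors: float


@dataclass
class FilterLog:
    n_input: int = 0
    n_removed: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed


def _quals(qual: str) -> np.ndarray:
    q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - PHRED_OFFSET
    if q.size and q.min() < 0:
        raise ValueError("quality string contains characters below '!' (not Phred+33)")
    return q


def expected_errors(qual: str) -> float:
    """Expected number of sequencing errors: sum of 10^(-Q/10) per base."""
    q = _quals(qual)
    return float(np.sum(10.0 ** (-q / 10.0))) if q.size else 0.0


def merge_pair(
    pair: ReadPair,
    min_overlap: int = 10,
    min_identity: float = 0.9,
) -> MergedRead | None:
    """Merge a read pair by overlap consensus; ``None`` means rejected.

    Mate 2 is reverse-complemented, every overlap length >= ``min_overlap``
    is scored by matches - mismatches, and the best-scoring overlap with
    identity >= ``min_identity`` wins (ties go to the longer overlap).
    Consensus takes the higher-quality base; agreeing positions get
    ``min(q1+q2, 41)``, disagreeing ones ``max-min`` floored at 2.
    """
    s1 = np.frombuffer(check_dna(pair.seq1, allow_n=True).encode(), dtype=np.uint8)
    q1 = _quals(pair.qual1)
    s2 = np.frombuffer(revcomp(pair.seq2).encode(), dtype=np.uint8)
    q2 = _quals(pair.qual2)[::-1]
    n1, n2 = s1.size, s2.size
    best: tuple[int, int] | None = None  # (score, overlap)
    for o in range(min_overlap, min(n1, n2) + 1):
        a = s1[n1 - o :]
        b = s2[:o]
        matches = int(np.count_nonzero(a == b))
        if matches / o < min_identity:
            continue
        score = 2 * matches - o  # matches - mismatches
        if best is None or (score, o) > best:
            best = (score, o)
    if best is None:
        return None
    _, o = best
    left = s1[: n1 - o]
    right = s2[o:]
    a1, a2 = s1[n1 - o :], s2[:o]
    qa1, qa2 = q1[n1 - o :], q2[:o]
    agree = a1 == a2
    cons = np.where(qa1 >= qa2, a1, a2)
    cons_q = np.where(
        agree,
        np.minimum(qa1 + qa2, QUAL_CAP),
        np.maximum(np.abs(qa1 - qa2), 2),
    )
    seq = (left.tobytes() + cons.tobytes() + right.tobytes()).decode()
    qual_arr = np.concatenate([q1[: n1 - o], cons_q, q2[o:]])
    qual = (qual_arr.astype(np.uint8) + PHRED_OFFSET).tobytes().decode()
    ee = float(np.sum(10.0 ** (-qual_arr / 10.0)))
    return MergedRead(
        id=pair.id, seq=seq, qual=qual, overlap_len=o, expected_errors=ee
    )


def filter_merged(
    reads: Iterable[MergedRead], emax: float = 1.0
) -> tuple[list[MergedRead], FilterLog]:
    """Retain merged reads with expected_errors <= emax (order preserved)."""
    log = FilterLog()
    kept: list[MergedRead] = []
    for r in reads:
        log.n_input += 1
        if r.expected_errors <= emax:
            kept.append(r)
        else:
            log.n_removed += 1
    return kept, log


def check_whitelist(whitelist: Mapping[str, str]) -> None:
    """Validate a barcode -> strain mapping (distinct, well-formed barcodes)."""
    from .barcode_model import classify_barcode

    strains = Counter(whitelist.values())
    for bc in whitelist:
        classify_barcode(bc)  # raises on bad alphabet/length
    dup_strains = [s for s, n in strains.items() if n > 1]
    if dup_strains:
        raise ValueError(f"strains mapped by multiple barcodes: {dup_strains}")


def assign_barcode(
    read: MergedRead,
    template: BarcodeTemplate,
    whitelist: Mapping[str, str],
) -> str:
    """Assign a merged read to a strain, ``OFFLIST`` or ``UNASSIGNED``."""
    bc = extract_barcode(read.seq, template)
    if bc is None:
        return UNASSIGNED
    return whitelist.get(bc, OFFLIST)


@dataclass
class SampleCounts:
    """Per-strain read tallies for one sample."""

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    unassigned_reads: int = 0
    offlist_reads: int = 0

    @property
    def whitelist_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def total_filtered_reads(self) -> int:
        return self.whitelist_reads + self.unassigned_reads + self.offlist_reads

    def percentages(self) -> dict[str, float]:
        """Relative percentages over whitelist reads only.

        Raises if the sample has no whitelist reads (percentages undefined).
        """
        total = self.whitelist_reads
        if total == 0:
            raise ValueError(
                f"sample {self.sample_id}: no whitelist reads, percentages undefined"
            )
        return {s: 100.0 * n / total for s, n in self.counts.items()}


def tally_sample(
    assignments: Iterable[str],
    sample_id: str = "sample",
    strains: Iterable[str] | None = None,
) -> SampleCounts:
    """Tally an assignment stream into :class:`SampleCounts`.

    ``strains`` optionally pre-seeds zero counts so absent strains appear
    explicitly in the table.
    """
    sc = SampleCounts(sample_id=sample_id)
    if strains is not None:
        sc.counts = {s: 0 for s in strains}
    for a in assignments:
        if a == UNASSIGNED:
            sc.unassigned_reads += 1
        elif a == OFFLIST:
            sc.offlist_reads += 1
        else:
            sc.counts[a] = sc.counts.get(a, 0) + 1
    return sc


def demux_sample(
    pairs: Iterable[ReadPair],
    template: BarcodeTemplate,
    whitelist: Mapping[str, str],
    sample_id: str = "sample",
    emax: float = 1.0,
    min_overlap: int = 10,
    min_identity: float = 0.9,
) -> tuple[SampleCounts, dict[str, int]]:
    """Full per-sample pipeline: merge -> Emax filter -> assign -> tally.

    Returns the counts plus a run log with merge/filter statistics.
    """
    check_whitelist(whitelist)
    n_pairs = n_unmerged = 0

    def merged_stream() -> Iterator[MergedRead]:
        nonlocal n_pairs, n_unmerged
        for p in pairs:
            n_pairs += 1
            m = merge_pair(p, min_overlap=min_overlap, min_identity=min_identity)
            if m is None:
                n_unmerged += 1
            else:
                yield m

    kept, flog = filter_merged(merged_stream(), emax=emax)
    sc = tally_sample(
        (assign_barcode(r, template, whitelist) for r in kept),
        sample_id=sample_id,
        strains=sorted(set(whitelist.values())),
    )
    log = {
        "read_pairs": n_pairs,
        "unmerged": n_unmerged,
        "merged": flog.n_input,
        "emax_removed": flog.n_removed,
        "filtered": flog.n_retained,
        "whitelist": sc.whitelist_reads,
        "offlist": sc.offlist_reads,
        "unassigned": sc.unassigned_reads,
    }
    return sc, log
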