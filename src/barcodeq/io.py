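"""File-format helpers: FASTA/FASTQ via Biopython, whitelists and tables via pandas."""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .demux import ReadPair, SampleCounts


def _open_text(path: str | Path, mode: str = "rt"):
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, mode)
    return open(p, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {record id: uppercase sequence}."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Stream matched records from two (optionally gzipped) FASTQ files."""
    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for (id1, s1, q1), (id2, s2, q2) in zip(it1, it2, strict=True):
            if id1.split()[0].rstrip("/12") != id2.split()[0].rstrip("/12"):
                raise ValueError(f"mate id mismatch: {id1!r} vs {id2!r}")
            yield ReadPair(id=id1.split()[0], seq1=s1, qual1=q1, seq2=s2, qual2=q2)


def write_fastq_pairs(
    pairs: Iterable[ReadPair], r1_path: str | Path, r2_path: str | Path
) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def read_whitelist(path: str | Path) -> dict[str, str]:
    """Barcode whitelist: one barcode per line, or 2-column TSV (strain, barcode).

    Returns barcode -> strain; bare-barcode files use the barcode itself as
    the strain id. Duplicate barcodes are a configuration error.
    """
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                strain, barcode = fields[0], fields[0]
            elif len(fields) == 2:
                strain, barcode = fields
            else:
                raise ValueError(f"whitelist line has {len(fields)} columns: {line!r}")
            if barcode.upper() in out:
                raise ValueError(f"duplicate whitelist barcode {barcode!r}")
            out[barcode.upper()] = strain
    return out


def write_counts_tsv(counts: SampleCounts, path: str | Path) -> None:
    """Tidy per-strain counts with percentages over whitelist reads."""
    total = counts.whitelist_reads
    rows = [
        {
            "sample_id": counts.sample_id,
            "strain_id": s,
            "reads": n,
            "percent": (100.0 * n / total) if total else float("nan"),
        }
        for s, n in sorted(counts.counts.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    """Threshold/config file in YAML or JSON."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
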