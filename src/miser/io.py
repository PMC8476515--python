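"""File-format plumbing: FASTA/FASTQ, TSV tables, BED export, run logs.

TSV is the interchange format for every table: tab-separated, one header
row, ``#`` comment lines allowed.  Residue coordinates in TSV files are
1-based inclusive; BED exports are 0-based half-open nucleotide intervals.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import DeletionVariant, OrfRecord, validate_orf

__all__ = [
    "read_orf",
    "write_fasta",
    "iter_fastq",
    "write_fastq",
    "variants_to_frame",
    "write_tsv",
    "read_tsv",
    "read_pool_table",
    "regions_to_bed",
    "sha256_file",
    "write_run_log",
]

_GZIP_MAGIC = b"\x1f\x8b"


def _open_text(path: "str | Path", mode: str = "rt") -> IO[str]:
    """Open a text file, transparently un-gzipping by magic bytes."""
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == _GZIP_MAGIC:
            return gzip.open(path, mode)
        return open(path, mode)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_orf(path: "str | Path", record_id: str | None = None) -> OrfRecord:
    """Read and validate the first (or named) record of a FASTA file."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if record_id is None or rec.id == record_id:
                return validate_orf(str(rec.seq), id=rec.id)
    raise FileNotFoundError(f"no FASTA record {record_id or ''!r} in {path}")


def write_fasta(records: Iterable[tuple[str, str]], path: "str | Path") -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def iter_fastq(path: "str | Path") -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ file (plain or gzip)."""
    with _open_text(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq


def write_fastq(reads: Iterable[tuple[str, str, str]], path: "str | Path") -> int:
    """Write (read_id, sequence, quality) triples; returns the read count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def variants_to_frame(
    variants: Iterable[DeletionVariant], n_codons: int | None = None
) -> pd.DataFrame:
    """Serialize variants as the standard TSV row layout."""
    rows = []
    for v in variants:
        span = v.deleted_span
        rows.append(
            {
                "variant_id": f"del_{v.a}_{v.b}_{v.scar_type}",
                "a": v.a,
                "b": v.b,
                "k": v.k,
                "scar_type": v.scar_type,
                "deleted_start": span[0] if span else 0,
                "deleted_end": span[1] if span else 0,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["variant_id", "a", "b", "k", "scar_type", "deleted_start", "deleted_end"],
    )
    if n_codons is not None:
        frame["orf_bp"] = 3 * (n_codons - frame["k"]) + 6
    return frame


def write_tsv(frame: pd.DataFrame, path: "str | Path", index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_pool_table(path: "str | Path") -> dict[tuple[int, int], int]:
    """Read a count TSV (a, b, count_total or count columns) into a dict."""
    frame = read_tsv(path)
    if "count_total" in frame.columns:
        col = "count_total"
    elif "count" in frame.columns:
        col = "count"
    else:
        raise ValueError(f"{path}: no count_total/count column")
    return {
        (int(r.a), int(r.b)): int(getattr(r, col)) for r in frame.itertuples()
    }


def regions_to_bed(regions, orf_id: str) -> pd.DataFrame:
    """Convert residue regions (1-based inclusive) to BED (0-based half-open, nt)."""
    rows = [
        {
            "chrom": orf_id,
            "start": 3 * (r.start - 1),
            "end": 3 * r.end,
            "name": f"tolerated_{r.start}_{r.end}",
            "score": round(1000 * max(0.0, min(1.0, r.mean_score))),
            "strand": "+",
        }
        for r in regions
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def sha256_file(path: "str | Path") -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_log(
    path: "str | Path",
    command: str,
    params: dict,
    inputs: "Iterable[str | Path]" = (),
) -> None:
    """Write a JSON run log: parameter echo plus input checksums."""
    log = {
        "command": command,
        "params": {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()},
        "inputs": {str(p): sha256_file(p) for p in inputs if Path(p).exists()},
    }
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
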