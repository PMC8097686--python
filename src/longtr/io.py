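"""Sequence input and call reporting.

Reads FASTA or FASTQ, plain or gzipped, with format auto-detection;
qualities are discarded.  Non-ACGT letters (N, IUPAC ambiguity codes,
lower case soft masking) are uppercased and any residual ambiguity is
replaced by a seeded random base so the 4-letter coding stays dense; the
number of replacements is logged.

Calls are written as TSV (0-based half-open coordinates, matching the
inter-base position convention) with an optional BED6 mirror.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

from .chaining import RepeatCall
from .kmers import BASES, Read

logger = logging.getLogger(__name__)

__all__ = ["read_sequences", "sanitize_seq", "write_calls", "read_calls"]

TSV_COLUMNS = [
    "read_id",
    "start",
    "end",
    "repeat_len",
    "unit_len",
    "unit_seq",
    "copies",
    "sigma",
    "identity",
    "k_used",
    "w_used",
]


def sanitize_seq(seq: str, rng: np.random.Generator) -> tuple[str, int]:
    """Uppercase, map U to T, replace anything non-ACGT by a random base.

    Returns the clean sequence and the number of replaced characters.
    """
    s = seq.upper().replace("U", "T")
    chars = list(s)
    replaced = 0
    for i, c in enumerate(chars):
        if c not in BASES:
            chars[i] = BASES[int(rng.integers(0, 4))]
            replaced += 1
    return "".join(chars), replaced


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: Path) -> str:
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            raise ValueError(f"{path}: not FASTA or FASTQ (first byte {line[0]!r})")
    return "fasta"  # empty file: an empty stream of either format


def read_sequences(path: str | Path, seed: int = 0) -> Iterator[Read]:
    """Stream sanitized reads from a FASTA/FASTQ file (gzip-aware)."""
    path = Path(path)
    fmt = _sniff_format(path)
    rng = np.random.default_rng(seed)
    total_replaced = 0
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            seq, replaced = sanitize_seq(str(rec.seq), rng)
            total_replaced += replaced
            if replaced:
                logger.info(
                    "read %s: replaced %d ambiguous bases", rec.id, replaced
                )
            if seq:
                yield Read(rec.id, seq)
    if total_replaced:
        logger.info("total ambiguous bases replaced: %d", total_replaced)


def write_calls(
    calls: list[RepeatCall], path: str | Path, bed_path: str | Path | None = None
) -> None:
    """Write final calls as TSV, with an optional BED6 mirror.

    BED name is ``<unit_len>x<copies>``; the BED score is sigma capped
    at 1000.
    """
    rows = [
        {
            "read_id": c.read_id,
            "start": c.s,
            "end": c.e,
            "repeat_len": c.span,
            "unit_len": len(c.unit),
            "unit_seq": c.unit,
            "copies": round(c.copies, 2),
            "sigma": c.sigma,
            "identity": round(c.identity, 4),
            "k_used": c.k_used,
            "w_used": c.w_used,
        }
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for c in calls:
                name = f"{len(c.unit)}x{round(c.copies)}"
                score = min(1000, max(0, c.sigma))
                fh.write(
                    f"{c.read_id}\t{c.s}\t{c.e}\t{name}\t{score}\t+\n"
                )


def read_calls(path: str | Path) -> list[RepeatCall]:
    """Parse a TSV written by :func:`write_calls`."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            RepeatCall(
                read_id=row.read_id,
                s=int(row.start),
                e=int(row.end),
                unit=str(row.unit_seq),
                sigma=int(row.sigma),
                copies=float(row.copies),
                identity=float(row.identity),
                k_used=int(row.k_used),
                w_used=int(row.w_used),
            )
        )
    return calls
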