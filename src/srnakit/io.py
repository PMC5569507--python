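"""Readers and writers for the plain-text formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython; this module adds the
collapsed-FASTA count convention (``>id_count`` headers), RNA-alphabet
normalization and validation, and deterministic TSV output (UTF-8, LF,
fixed column order).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO

from ._seq import to_rna, validate_rna


class ParseError(ValueError):
    """Raised when an input file violates the expected grammar."""


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(record_id, rna_sequence), ...]``.

    Sequences are uppercased and T is converted to U.  Duplicate ids and
    non-ACGTUN characters are errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = to_rna(str(rec.seq))
        try:
            validate_rna(seq, name=f"record {rec.id!r}")
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        records.append((rec.id, seq))
    return records


def read_collapsed_fasta(path: str | os.PathLike) -> dict[str, int]:
    """Read a collapsed FASTA (``>id_count`` headers) into ``{seq: count}``.

    Counts of identical sequences appearing under several ids are summed.
    """
    counts: dict[str, int] = {}
    for rec_id, seq in read_fasta(path):
        head, sep, tail = rec_id.rpartition("_")
        if not sep or not tail.isdigit():
            raise ParseError(
                f"{path}: header {rec_id!r} does not follow the '>id_count' convention"
            )
        count = int(tail)
        if count < 1:
            raise ParseError(f"{path}: record {rec_id!r} has non-positive count")
        counts[seq] = counts.get(seq, 0) + count
    return counts


def write_collapsed_fasta(counts: dict[str, int], path: str | os.PathLike,
                          prefix: str = "r") -> None:
    """Write ``{seq: count}`` as collapsed FASTA, most abundant first."""
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, (seq, count) in enumerate(ordered, start=1):
            fh.write(f">{prefix}{i}_{count}\n{seq}\n")


def read_fastq(path: str | os.PathLike) -> dict[str, int]:
    """Read FASTQ (qualities ignored) into ``{seq: count}``."""
    counts: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = to_rna(str(rec.seq))
        try:
            validate_rna(seq, name=f"record {rec.id!r}")
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        counts[seq] = counts.get(seq, 0) + 1
    return counts


def read_reads(path: str | os.PathLike) -> dict[str, int]:
    """Dispatch on extension: .fastq/.fq -> FASTQ, otherwise collapsed FASTA."""
    name = str(path).lower()
    if name.endswith((".fastq", ".fq")):
        return read_fastq(path)
    return read_collapsed_fasta(path)


def write_fastq(counts: dict[str, int], path: str | os.PathLike,
                prefix: str = "r") -> None:
    """Expand ``{seq: count}`` to FASTQ with constant 'I' qualities."""
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        n = 0
        for seq, count in ordered:
            for _ in range(count):
                n += 1
                fh.write(f"@{prefix}{n}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n{seq}\n")


def write_tsv(path: str | os.PathLike, header: Sequence[str],
              rows: Iterable[Sequence]) -> None:
    """Write a TSV with a header row, UTF-8, LF line endings."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_tsv(path: str | os.PathLike) -> tuple[list[str], list[list[str]]]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty TSV")
    header = lines[0].split("\t")
    return header, [ln.split("\t") for ln in lines[1:]]


def write_yaml(obj, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True, default_flow_style=False)


def read_yaml(path: str | os.PathLike):
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
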