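"""Sequence and genotype file I/O.

FASTA/FASTQ are detected by content (leading '>' vs '@'), never by file
extension, and gzip is detected by magic bytes; parsing is delegated to
Biopython's SeqIO.  Sequences are uppercased and validated against ACGTN.

The genotype dialect is a GenAlEx-like CSV: an ``individual`` column
followed by two columns per locus (the locus name repeated), integer
allele sizes in bp, with 0 or blank meaning missing.  Reader and writer
round-trip losslessly.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .popgen import GenotypeTable

__all__ = [
    "SequenceFormatError",
    "GenotypeDialectError",
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "read_genotypes",
    "write_genotypes",
]

_ALPHABET = set("ACGTN")


class SequenceFormatError(ValueError):
    pass


class GenotypeDialectError(ValueError):
    pass


def _open_text(path) -> _io.TextIOBase:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(path) -> Iterator[tuple[str, str]]:
    """Stream ``(record_id, sequence)`` from FASTA or FASTQ (gzip
    transparent).  Uppercases and validates the ACGTN alphabet; a bad
    record raises SequenceFormatError naming it."""
    handle = _open_text(path)
    try:
        first = handle.read(1)
        while first and first.isspace():
            first = handle.read(1)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        elif not first:
            return
        else:
            raise SequenceFormatError(f"{path}: neither FASTA nor FASTQ (starts with {first!r})")
        handle.seek(0)
        for number, record in enumerate(SeqIO.parse(handle, fmt), start=1):
            seq = str(record.seq).upper()
            bad = set(seq) - _ALPHABET
            if bad:
                raise SequenceFormatError(
                    f"{path}: record {number} ({record.id}) has invalid characters {sorted(bad)}"
                )
            yield record.id, seq
    finally:
        handle.close()


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(records: Iterable[tuple[str, str]], path, quality_char: str = "I") -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_genotypes(path) -> GenotypeTable:
    """Read the genotype CSV dialect (two columns per locus, 0/blank =
    missing)."""
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise GenotypeDialectError(f"{path}: empty genotype file")
    header = [c.strip() for c in lines[0].split(",")]
    if header[0].lower() != "individual":
        raise GenotypeDialectError(f"{path}: first column must be 'individual'")
    locus_cols = header[1:]
    if len(locus_cols) % 2 != 0:
        raise GenotypeDialectError(f"{path}: odd number of allele columns")
    loci: list[str] = []
    for i in range(0, len(locus_cols), 2):
        if locus_cols[i] != locus_cols[i + 1]:
            raise GenotypeDialectError(
                f"{path}: locus columns must come in named pairs "
                f"({locus_cols[i]!r} vs {locus_cols[i + 1]!r})"
            )
        loci.append(locus_cols[i])
    individuals: list[str] = []
    table = GenotypeTable(individuals=individuals, loci=loci)
    for lineno, line in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in line.split(",")]
        if len(cells) != len(header):
            raise GenotypeDialectError(f"{path}: line {lineno} has {len(cells)} cells, expected {len(header)}")
        ind = cells[0]
        individuals.append(ind)
        for li, locus in enumerate(loci):
            a_raw, b_raw = cells[1 + 2 * li], cells[2 + 2 * li]
            missing_a = a_raw in ("", "0")
            missing_b = b_raw in ("", "0")
            if missing_a != missing_b:
                raise GenotypeDialectError(
                    f"{path}: line {lineno}, locus {locus}: half-missing call"
                )
            if missing_a:
                table.set_call(ind, locus, None)
            else:
                try:
                    table.set_call(ind, locus, (int(a_raw), int(b_raw)))
                except ValueError as exc:
                    raise GenotypeDialectError(
                        f"{path}: line {lineno}, locus {locus}: non-integer allele"
                    ) from exc
    return table


def write_genotypes(table: GenotypeTable, path) -> None:
    with open(path, "w") as fh:
        header = ["individual"]
        for locus in table.loci:
            header.extend([locus, locus])
        fh.write(",".join(header) + "\n")
        for ind in table.individuals:
            cells = [ind]
            for locus in table.loci:
                call = table.get(ind, locus)
                if call is None:
                    cells.extend(["0", "0"])
                else:
                    cells.extend([str(call[0]), str(call[1])])
            fh.write(",".join(cells) + "\n")
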