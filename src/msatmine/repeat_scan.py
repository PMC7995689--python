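"""Detection of perfect short tandem repeats (STRs) in sequencing reads.

A microsatellite allele is a perfect tandem array of a 2-4 bp motif.  Motifs
are reduced to a *canonical* representative that is invariant under cyclic
rotation and reverse complementation, so that hits written as "(AC)n",
"(CA)n" and "(GT)n" all co-cluster downstream.  Only full repeat units are
counted: a reported array always satisfies ``end - start == unit_count *
len(unit)``; trailing partial units belong to the flank.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "MotifError",
    "RepeatMotif",
    "STRHit",
    "revcomp",
    "is_valid_motif",
    "canonical_motif",
    "scan_read",
    "scan_reads",
    "write_hits_tsv",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Unit lengths handled by the scanner (di-, tri-, tetranucleotide).
UNIT_LENGTHS = (2, 3, 4)


class MotifError(ValueError):
    """Raised for motifs outside the 2-4 bp ACGT, non-degenerate class."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_valid_motif(unit: str) -> bool:
    """True iff ``unit`` is a 2-4 bp ACGT motif that is not a whole-number
    repetition of a shorter unit (e.g. ``ATAT`` == (AT)x2 and any
    homopolymer are invalid)."""
    n = len(unit)
    if n < 2 or n > 4:
        return False
    if any(b not in "ACGT" for b in unit):
        return False
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def canonical_motif(unit: str) -> str:
    """Canonical representative of a repeat motif class.

    The representative is the lexicographically smallest string over all
    cyclic rotations of ``unit`` and of its reverse complement, which makes
    it invariant under strand flips and phase shifts.  Idempotent.

    Raises
    ------
    MotifError
        If ``unit`` is not a valid 2-4 bp non-degenerate ACGT motif.
    """
    unit = unit.upper()
    if not is_valid_motif(unit):
        raise MotifError(f"invalid repeat motif: {unit!r}")
    rc = revcomp(unit)
    n = len(unit)
    return min(
        min(unit[i:] + unit[:i] for i in range(n)),
        min(rc[i:] + rc[:i] for i in range(n)),
    )


@dataclass(frozen=True)
class RepeatMotif:
    """A repeat unit together with its canonical class representative."""

    unit: str
    canonical: str

    @classmethod
    def from_unit(cls, unit: str) -> "RepeatMotif":
        return cls(unit=unit.upper(), canonical=canonical_motif(unit))


@dataclass
class STRHit:
    """One perfect tandem array found in one read.

    ``left_flank``/``right_flank`` are the read sequence abutting the array,
    reported up to the read ends (they may contain N).  ``strand_as_read``
    is always "+" at scan time; orientation is resolved in locus_builder.
    """

    read_id: str
    motif: RepeatMotif
    start: int
    end: int
    unit_count: int
    left_flank: str
    right_flank: str
    strand_as_read: str = "+"

    @property
    def span(self) -> int:
        """Array length in bp (== unit_count * unit length)."""
        return self.end - self.start


def _periodic_runs(arr: np.ndarray, valid: np.ndarray, lag: int):
    """Yield (start, length) of maximal stretches where arr[k] == arr[k-lag]
    over ACGT bases only.  `length` is the periodic region length in bases
    (>= lag + 1 matched positions means length > lag)."""
    eq = (arr[lag:] == arr[:-lag]) & valid[lag:] & valid[:-lag]
    if not eq.any():
        return
    # boundaries of True runs in eq
    padded = np.concatenate(([False], eq, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        # periodic region covers seq[s : e + lag]
        yield int(s), int(e - s + lag)


def scan_read(seq: str, min_units: int = 4, read_id: str = "read") -> list[STRHit]:
    """Find every maximal perfect 2-4 bp tandem array with >= ``min_units``
    full units.

    Overlapping representations are resolved leftmost-longest: the longer
    array wins, ties broken by smaller start, then shorter unit.  Reported
    hits are non-overlapping.  N bases never match and terminate arrays.

    Parameters
    ----------
    seq : str
        Read sequence (ACGTN; lowercase accepted).
    min_units : int
        Minimum number of full repeat units (>= 3).
    read_id : str
        Identifier recorded on each hit.
    """
    if min_units < 3:
        raise ValueError("min_units must be >= 3")
    seq = seq.upper()
    n = len(seq)
    if n == 0:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))

    candidates: list[tuple[int, int, int, str]] = []  # (span, start, ulen, unit)
    for u in UNIT_LENGTHS:
        if n <= u:
            continue
        for start, length in _periodic_runs(arr, valid, u):
            unit_count = length // u
            if unit_count < min_units:
                continue
            unit = seq[start : start + u]
            if not is_valid_motif(unit):
                continue
            candidates.append((unit_count * u, start, u, unit))

    # leftmost-longest selection: longer span first, then smaller start,
    # then shorter unit; greedily keep non-overlapping arrays.
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    taken: list[tuple[int, int]] = []
    hits: list[STRHit] = []
    for span, start, u, unit in candidates:
        end = start + span
        if any(start < t_end and t_start < end for t_start, t_end in taken):
            continue
        taken.append((start, end))
        hits.append(
            STRHit(
                read_id=read_id,
                motif=RepeatMotif.from_unit(unit),
                start=start,
                end=end,
                unit_count=span // u,
                left_flank=seq[:start],
                right_flank=seq[end:],
            )
        )
    hits.sort(key=lambda h: h.start)
    return hits


def scan_reads(records: Iterable[tuple[str, str]], min_units: int = 4) -> list[STRHit]:
    """Scan an iterable of ``(read_id, sequence)`` records."""
    out: list[STRHit] = []
    for read_id, seq in records:
        out.extend(scan_read(seq, min_units=min_units, read_id=read_id))
    return out


def write_hits_tsv(hits: Iterable[STRHit], path, header_comment: str | None = None) -> None:
    """Write hits as TSV: read_id, canonical_motif, unit, start, end,
    unit_count, left_flank, right_flank."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(
            "read_id\tcanonical_motif\tunit\tstart\tend\tunit_count\tleft_flank\tright_flank\n"
        )
        for h in hits:
            fh.write(
                f"{h.read_id}\t{h.motif.canonical}\t{h.motif.unit}\t{h.start}\t{h.end}"
                f"\t{h.unit_count}\t{h.left_flank}\t{h.right_flank}\n"
            )
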