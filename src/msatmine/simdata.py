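"""Synthetic truth sets for the discovery pipeline.

Emulates the study design the toolkit targets: a small number of diploid
individuals (two by default, i.e. four chromosomes), genomes carrying
planted di-/tri-/tetranucleotide STR loci with known per-haplotype allele
lengths, uniform shotgun reads from both strands with optional substitution
errors, and fecal-style genotype degradation (allelic dropout, false
alleles, missing calls).

Every planted locus records its flanks and alleles in a truth table, so
each pipeline stage can be scored against ground truth.  Generation is
fully deterministic given the seed.

Deliberately idealised relative to real data: uniform base composition,
substitution-only read errors (keeping allele-length truth exact), no
adapters, duplicates or contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .popgen import GenotypeTable
from .repeat_scan import is_valid_motif, revcomp

__all__ = [
    "SimConfig",
    "PlantedLocus",
    "SimulatedGenomes",
    "simulate_genomes",
    "simulate_reads",
    "simulate_genotype_table",
    "degrade_genotypes",
    "individual_of_read",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-condition parameters of the simulated experiment.

    Defaults mirror the discovery design: 2 individuals (4 chromosomes),
    MiSeq-like 300 bp reads at 30x per haplotype, error-free unless stated.
    """

    seed: int
    n_individuals: int = 2
    genome_length: int = 30_000
    n_loci: int = 24
    fraction_polymorphic: float = 0.75
    motif_length_weights: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.5, 3: 0.25, 4: 0.25}
    )
    flank_length: int = 80
    min_allele_units: int = 8
    max_allele_units: int = 13
    coverage: float = 30.0
    read_length: int = 300
    error_rate: float = 0.0
    anchor_k: int = 12


@dataclass
class PlantedLocus:
    locus_id: str
    unit: str
    canonical: str
    flank_left: str
    flank_right: str
    allele_units: dict[str, int]  # haplotype id -> unit count
    polymorphic: bool

    def allele_bp(self, haplotype: str) -> int:
        return self.allele_units[haplotype] * len(self.unit)


@dataclass
class SimulatedGenomes:
    haplotypes: dict[str, str]  # "ind1_h1" -> sequence
    loci: list[PlantedLocus]
    truth: pd.DataFrame


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_motif(rng: np.random.Generator, length: int) -> str:
    while True:
        unit = _random_seq(rng, length)
        if is_valid_motif(unit):
            return unit


def _fix_boundaries(block: str, prev_unit: str | None, next_unit: str | None,
                    rng: np.random.Generator) -> str:
    """Ensure a background block never extends an adjoining repeat array:
    its first base must differ from the following array's unit[0] read
    back-to-front... concretely, the base left of an array must not equal
    unit[-1] and the base right of an array must not equal unit[0]."""
    chars = list(block)
    if prev_unit is not None and chars and chars[0] == prev_unit[0]:
        choices = [b for b in "ACGT" if b != prev_unit[0]]
        chars[0] = choices[int(rng.integers(0, 3))]
    if next_unit is not None and chars and chars[-1] == next_unit[-1]:
        choices = [b for b in "ACGT" if b != next_unit[-1]]
        chars[-1] = choices[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_genomes(config: SimConfig) -> SimulatedGenomes:
    """Build per-haplotype genomes with planted STR loci and a truth table.

    The genome is a chain of random background blocks with one repeat array
    inserted between consecutive blocks per locus.  Bases abutting each
    array are resampled so the array never extends into the flank, making
    planted allele length equal the maximal perfect-array span exactly.
    Planted anchor k-mers are verified unique within each haplotype
    (offending blocks are resampled).

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    hap_ids = [
        f"ind{i + 1}_h{h + 1}"
        for i in range(config.n_individuals)
        for h in range(2)
    ]
    block_len = config.genome_length // (config.n_loci + 1)
    if block_len < 2 * config.flank_length + 10:
        raise ValueError(
            "genome_length too small for n_loci with the requested flank_length"
        )

    lengths = np.array(sorted(config.motif_length_weights))
    weights = np.array([config.motif_length_weights[l] for l in lengths], dtype=float)
    weights /= weights.sum()

    n_poly = int(round(config.fraction_polymorphic * config.n_loci))
    poly_flags = np.zeros(config.n_loci, dtype=bool)
    poly_flags[:n_poly] = True
    rng.shuffle(poly_flags)

    for attempt in range(30):
        build_rng = np.random.default_rng(rng.integers(0, 2**31))
        loci: list[PlantedLocus] = []
        units: list[str] = []
        for li in range(config.n_loci):
            ulen = int(build_rng.choice(lengths, p=weights))
            unit = _random_motif(build_rng, ulen)
            base_units = int(
                build_rng.integers(config.min_allele_units, config.max_allele_units + 1)
            )
            if poly_flags[li]:
                while True:
                    alleles = {
                        h: base_units + int(build_rng.integers(0, 3)) for h in hap_ids
                    }
                    if len(set(alleles.values())) >= 2:
                        break
            else:
                alleles = {h: base_units for h in hap_ids}
            from .repeat_scan import canonical_motif

            loci.append(
                PlantedLocus(
                    locus_id=f"locus{li + 1:03d}",
                    unit=unit,
                    canonical=canonical_motif(unit),
                    flank_left="",
                    flank_right="",
                    allele_units=alleles,
                    polymorphic=bool(poly_flags[li]),
                )
            )
            units.append(unit)

        blocks = []
        for bi in range(config.n_loci + 1):
            prev_unit = units[bi - 1] if bi > 0 else None
            next_unit = units[bi] if bi < config.n_loci else None
            blocks.append(
                _fix_boundaries(_random_seq(build_rng, block_len), prev_unit, next_unit, build_rng)
            )
        for li, locus in enumerate(loci):
            locus.flank_left = blocks[li][-config.flank_length :]
            locus.flank_right = blocks[li + 1][: config.flank_length]

        haplotypes = {}
        for h in hap_ids:
            parts = [blocks[0]]
            for li, locus in enumerate(loci):
                parts.append(locus.unit * locus.allele_units[h])
                parts.append(blocks[li + 1])
            haplotypes[h] = "".join(parts)

        # anchor uniqueness check within one haplotype genome
        k = config.anchor_k
        genome = haplotypes[hap_ids[0]]
        ok = True
        for locus in loci:
            for anchor in (locus.flank_left[-k:], locus.flank_right[:k]):
                if genome.count(anchor) != 1 or genome.count(revcomp(anchor)) != 0:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            break
    else:
        raise RuntimeError("could not generate genomes with unique anchors")

    rows = []
    for locus in loci:
        row = {
            "locus_id": locus.locus_id,
            "unit": locus.unit,
            "canonical": locus.canonical,
            "polymorphic": locus.polymorphic,
            "flank_left": locus.flank_left,
            "flank_right": locus.flank_right,
        }
        for h in hap_ids:
            row[f"allele_bp_{h}"] = locus.allele_bp(h)
        rows.append(row)
    return SimulatedGenomes(haplotypes=haplotypes, loci=loci, truth=pd.DataFrame(rows))


def simulate_reads(
    haplotypes: Mapping[str, str],
    coverage: float,
    read_length: int = 300,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Uniform shotgun reads from both strands.

    Per haplotype the read count is Poisson(coverage * L / read_length);
    start positions are uniform, strand is fair, and substitution errors
    occur independently per base at ``error_rate``.  Returns
    ``(records, origin)`` where records are ``(read_id, sequence)`` and the
    origin table maps each read to (haplotype, start, end, strand).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    origin_rows = []
    for hap in sorted(haplotypes):
        seq = haplotypes[hap]
        if read_length > len(seq):
            raise ValueError(f"read_length {read_length} exceeds haplotype {hap} length")
        n_reads = int(rng.poisson(coverage * len(seq) / read_length))
        starts = rng.integers(0, len(seq) - read_length + 1, size=n_reads)
        strands = rng.random(n_reads) < 0.5
        for i in range(n_reads):
            s = int(starts[i])
            fragment = seq[s : s + read_length]
            if error_rate > 0:
                frag = np.frombuffer(fragment.encode(), dtype=np.uint8).copy()
                hitpos = np.flatnonzero(rng.random(read_length) < error_rate)
                for pos in hitpos:
                    current = chr(frag[pos])
                    options = [b for b in "ACGT" if b != current]
                    frag[pos] = ord(options[int(rng.integers(0, 3))])
                fragment = frag.tobytes().decode()
            strand = "-" if strands[i] else "+"
            if strand == "-":
                fragment = revcomp(fragment)
            rid = f"{hap}:{i}"
            records.append((rid, fragment))
            origin_rows.append(
                {"read_id": rid, "haplotype": hap, "start": s, "end": s + read_length, "strand": strand}
            )
    return records, pd.DataFrame(origin_rows)


def individual_of_read(read_id: str) -> str:
    """Individual id from a simulated read id ('ind1_h2:17' -> 'ind1')."""
    return read_id.split(":")[0].split("_h")[0]


def simulate_genotype_table(
    locus_freqs: Mapping[str, Mapping[int, float]],
    n_individuals: int,
    seed: int = 0,
) -> GenotypeTable:
    """Sample a diploid genotype table under Hardy-Weinberg equilibrium
    with the given per-locus allele frequencies."""
    rng = np.random.default_rng(seed)
    individuals = [f"sim{i + 1:04d}" for i in range(n_individuals)]
    loci = list(locus_freqs)
    table = GenotypeTable(individuals=individuals, loci=loci)
    for locus in loci:
        alleles = np.array(sorted(locus_freqs[locus]))
        p = np.array([locus_freqs[locus][a] for a in alleles], dtype=float)
        p = p / p.sum()
        draws = rng.choice(alleles, size=(n_individuals, 2), p=p)
        for ind, (a, b) in zip(individuals, draws):
            table.set_call(ind, locus, (int(a), int(b)))
    return table


def degrade_genotypes(
    table: GenotypeTable,
    dropout_rate: float = 0.0,
    false_allele_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeTable:
    """Fecal-style genotype degradation.

    Independently per call: with ``missing_rate`` the call is lost; with
    ``dropout_rate`` a heterozygous call loses one allele (becomes
    homozygous); with ``false_allele_rate`` one allele is replaced by a
    novel label absent from the locus.  Deterministic given seed.
    """
    for name, rate in (
        ("dropout_rate", dropout_rate),
        ("false_allele_rate", false_allele_rate),
        ("missing_rate", missing_rate),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = GenotypeTable(individuals=list(table.individuals), loci=list(table.loci))
    novel_label: dict[str, int] = {}
    for locus in table.loci:
        labels = [
            a
            for ind in table.individuals
            if (call := table.get(ind, locus)) is not None
            for a in call
        ]
        novel_label[locus] = (max(labels) + 2) if labels else 999
    for ind in table.individuals:
        for locus in table.loci:
            call = table.get(ind, locus)
            if call is None:
                out.set_call(ind, locus, None)
                continue
            if rng.random() < missing_rate:
                out.set_call(ind, locus, None)
                continue
            a, b = call
            if a != b and rng.random() < dropout_rate:
                keep = a if rng.random() < 0.5 else b
                a = b = keep
            if rng.random() < false_allele_rate:
                novel = novel_label[locus]
                if rng.random() < 0.5:
                    a = novel
                else:
                    b = novel
            out.set_call(ind, locus, (a, b))
    return out
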