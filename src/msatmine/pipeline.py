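"""End-to-end marker discovery: reads -> STR hits -> locus clusters ->
polymorphism calls -> exclusion filters -> primer design -> in-silico PCR
validation.

The discovery stages operate on combined reads from all individuals (the
polymorphism signal is across all sequenced chromosomes); per-individual
provenance, when available, is carried through for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

from . import insilico_pcr, locus_builder, locus_filter, primer_design, repeat_scan
from .config import PipelineConfig
from .locus_builder import LocusCluster, PolymorphismCall
from .locus_filter import ContaminantIndex, FilterOutcome
from .insilico_pcr import MarkerValidation
from .primer_design import PrimerPair

__all__ = ["CandidateMarker", "DiscoveryResult", "discover_markers"]

NO_PRIMERS = "NO_PRIMERS"


@dataclass
class CandidateMarker:
    """A filtered polymorphic locus with its designed primer pair and
    validation status."""

    cluster: LocusCluster
    call: PolymorphismCall
    filter_outcome: FilterOutcome
    primer_pair: PrimerPair | None = None
    validation: MarkerValidation | None = None
    reasons: set[str] = field(default_factory=set)

    @property
    def accepted(self) -> bool:
        return (
            self.filter_outcome.passed
            and self.primer_pair is not None
            and self.validation is not None
            and self.validation.status == "single_product_polymorphic"
        )


@dataclass
class DiscoveryResult:
    clusters: list[LocusCluster]
    calls: list[PolymorphismCall]
    candidates: list[CandidateMarker]

    @property
    def accepted(self) -> list[CandidateMarker]:
        return [c for c in self.candidates if c.accepted]


def discover_markers(
    reads: Iterable[tuple[str, str]],
    config: PipelineConfig | None = None,
    validation_templates: Mapping[str, str] | None = None,
    contaminant_index: ContaminantIndex | None = None,
    individual_of: Callable[[str], str] | None = None,
) -> DiscoveryResult:
    """Run the full discovery pipeline on combined reads.

    ``validation_templates`` (e.g. the individuals' genomes, or assembled
    consensus sequences) drive the in-silico PCR validation step; without
    them, designed markers are validated against each cluster's own
    consensus alleles.
    """
    config = config or PipelineConfig()
    hits = repeat_scan.scan_reads(reads, min_units=config.scan.min_units)
    clusters, _ = locus_builder.cluster_hits(
        hits,
        anchor_k=config.cluster.anchor_k,
        min_flank=config.cluster.min_flank,
        max_mismatch=config.cluster.max_mismatch,
        individual_of=individual_of,
    )
    calls = [locus_builder.call_alleles(c, min_support=config.cluster.min_support) for c in clusters]
    anchor_counts = locus_filter.anchor_usage(clusters, anchor_k=config.cluster.anchor_k)

    candidates: list[CandidateMarker] = []
    for cluster, call in zip(clusters, calls):
        if call.status != "polymorphic":
            continue
        outcome = locus_filter.filter_locus(
            cluster,
            config=config.filter,
            contaminant_index=contaminant_index,
            anchor_counts=anchor_counts,
            call=call,
            anchor_k=config.cluster.anchor_k,
        )
        cand = CandidateMarker(
            cluster=cluster, call=call, filter_outcome=outcome, reasons=set(outcome.reasons)
        )
        candidates.append(cand)
        if not outcome.passed:
            continue
        consensus, rep_start, rep_end = locus_builder.consensus_sequence(cluster)
        alleles = [a for a, _ in call.supported_alleles]
        pairs = primer_design.design_primers(
            consensus, rep_start, rep_end, alleles, constraints=config.primer
        )
        if not pairs:
            cand.reasons.add(NO_PRIMERS)
            continue
        cand.primer_pair = pairs[0]
        templates = validation_templates
        if templates is None:
            left, right = consensus[:rep_start], consensus[rep_end:]
            templates = {
                f"{cluster.cluster_id}:{a}": left
                + _allele_array(cluster, a)
                + right
                for a in alleles
            }
        products = insilico_pcr.amplify(
            cand.primer_pair,
            templates,
            max_mismatch=config.ipcress.max_mismatch,
            three_prime_exact=config.ipcress.three_prime_exact,
            max_product=config.ipcress.max_product,
        )
        cand.validation = insilico_pcr.classify_marker(products, config=config.ipcress)
        if cand.validation.status != "single_product_polymorphic":
            cand.reasons.add(cand.validation.status)
    return DiscoveryResult(clusters=clusters, calls=calls, candidates=candidates)


def _allele_array(cluster: LocusCluster, allele: int) -> str:
    arrays = sorted(
        m.array_seq for m in cluster.members if m.span == allele and m.full_array
    )
    if arrays:
        return arrays[0]
    return cluster.canonical_motif * (allele // cluster.unit_len)
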