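"""Exclusion rules for polymorphic STR clusters.

Candidate loci are rejected when the repeat is too short (< 6 tandem units
at the longest allele), the allele size range is too broad for reliable
scoring, the flanks look like repetitive elements (low-complexity sequence
or anchors shared across many clusters), the flanks closely match a
user-supplied contaminant set (e.g. human), or the flanks are too short to
design primers in.  All failing rules are reported, not just the first.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .locus_builder import LocusCluster, PolymorphismCall, call_alleles
from .repeat_scan import revcomp

__all__ = [
    "FilterConfig",
    "FilterOutcome",
    "ScoreUndefinedError",
    "EmptyIndexError",
    "low_complexity_score",
    "ContaminantIndex",
    "contaminant_similarity",
    "anchor_usage",
    "filter_locus",
    "write_filter_report",
]

logger = logging.getLogger(__name__)

TOO_FEW_REPEATS = "TOO_FEW_REPEATS"
BROAD_RANGE = "BROAD_RANGE"
REPETITIVE = "REPETITIVE"
CONTAMINANT_LIKE = "CONTAMINANT_LIKE"
FLANKS_TOO_SHORT = "FLANKS_TOO_SHORT"


@dataclass
class FilterConfig:
    """Thresholds for the locus exclusion rules.

    min_unit_count : longest allele must reach this many tandem units.
    max_allele_range_bp : maximal allowed (max - min) allele span.
    low_complexity_threshold : DUST-like triplet score above which a flank
        counts as repetitive; window is the score's sliding-window size.
    max_shared_anchor_clusters : an anchor k-mer seen in more clusters than
        this marks a multi-copy (repetitive-element) region.
    contaminant_identity_threshold / contaminant_min_span : minimal local
        identity and matched span for a contaminant call.
    min_flank_bp : consensus flanks shorter than this cannot host primers.
    max_amplicon_bp : retained for pipeline-level bookkeeping.
    """

    min_unit_count: int = 6
    max_allele_range_bp: int = 20
    low_complexity_threshold: float = 1.5
    low_complexity_window: int = 36
    max_shared_anchor_clusters: int = 2
    contaminant_identity_threshold: float = 0.90
    contaminant_min_span: int = 30
    min_flank_bp: int = 20
    max_amplicon_bp: int = 150


@dataclass
class FilterOutcome:
    passed: bool
    reasons: set[str] = field(default_factory=set)
    metrics: dict = field(default_factory=dict)


class ScoreUndefinedError(ValueError):
    """Sequence too short for the requested low-complexity window."""


class EmptyIndexError(ValueError):
    """Contaminant index contains no sequence (distinct from 'no match')."""


def low_complexity_score(seq: str, window: int = 36) -> float:
    """DUST-like low-complexity score.

    For each sliding window of length ``window`` the score is
    ``sum_t c_t(c_t-1)/2 / (n-1)`` over triplet counts ``c_t`` (``n`` =
    window - 2 triplets); the maximum over windows is returned.  A window
    with all-distinct triplets scores 0; a homopolymer scores the maximal
    ``n/2`` for its window.  Monotonically non-decreasing in any triplet's
    count.
    """
    seq = seq.upper()
    if len(seq) < window:
        raise ScoreUndefinedError(f"sequence length {len(seq)} < window {window}")
    if window < 4:
        raise ValueError("window must be >= 4")
    best = 0.0
    n = window - 2
    counts: Counter[str] = Counter(seq[i : i + 3] for i in range(n))
    best = sum(c * (c - 1) // 2 for c in counts.values()) / (n - 1)
    for i in range(1, len(seq) - window + 1):
        counts[seq[i - 1 : i + 2]] -= 1
        counts[seq[i + window - 3 : i + window]] += 1
        score = sum(c * (c - 1) // 2 for c in counts.values()) / (n - 1)
        if score > best:
            best = score
    return best


class ContaminantIndex:
    """Seed k-mer index over a contaminant sequence set (e.g. a human decoy
    FASTA); both strands are searched via the query."""

    def __init__(self, sequences: Mapping[str, str], k: int = 12):
        self.k = k
        self.sequences = {name: s.upper() for name, s in sequences.items()}
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        for name, s in self.sequences.items():
            for i in range(len(s) - k + 1):
                self.kmers.setdefault(s[i : i + k], []).append((name, i))

    def __len__(self) -> int:
        return len(self.sequences)

    @classmethod
    def from_fasta(cls, path, k: int = 12) -> "ContaminantIndex":
        from .io import read_sequences

        return cls({rid: seq for rid, seq in read_sequences(path)}, k=k)


def _extend(query: str, target: str, qi: int, ti: int, k: int) -> tuple[int, int]:
    """Greedy ungapped X-drop extension around a seed match; returns
    (matches, span) of the best-scoring ungapped segment."""
    MATCH, MISMATCH, XDROP = 1, -2, 6
    # right extension
    score = k
    best_score = k
    right_len = k
    i, j = qi + k, ti + k
    length = k
    while i < len(query) and j < len(target):
        score += MATCH if query[i] == target[j] else MISMATCH
        length += 1
        i += 1
        j += 1
        if score > best_score:
            best_score, right_len = score, length
        if best_score - score > XDROP:
            break
    # left extension
    score = best_score
    total_best = best_score
    left_ext = 0
    i, j = qi - 1, ti - 1
    ext = 0
    while i >= 0 and j >= 0:
        score += MATCH if query[i] == target[j] else MISMATCH
        ext += 1
        i -= 1
        j -= 1
        if score > total_best:
            total_best, left_ext = score, ext
        if total_best - score > XDROP:
            break
    span = right_len + left_ext
    # score = matches - 2*mismatches and span = matches + mismatches
    mismatches = (span - total_best) // 3
    matches = span - mismatches
    return matches, span


def contaminant_similarity(
    flank: str, index: ContaminantIndex, min_span: int = 30
) -> tuple[float, int]:
    """Best ungapped seed-and-extend local identity of ``flank`` (either
    strand) against the index.

    Returns ``(identity, span)`` of the best hit, preferring hits whose
    span reaches ``min_span``; ``(0.0, 0)`` when no seed matches.
    Deterministic.
    """
    if len(index) == 0:
        raise EmptyIndexError("contaminant index is empty")
    flank = flank.upper()
    k = index.k
    best = (0.0, 0)
    best_long = (0.0, 0)
    for query in (flank, revcomp(flank)):
        seen: set[tuple[str, int, int]] = set()
        for qi in range(len(query) - k + 1):
            for name, ti in index.kmers.get(query[qi : qi + k], ()):  # noqa: B905
                key = (name, ti - qi, qi // k)
                if key in seen:
                    continue
                seen.add(key)
                matches, span = _extend(query, index.sequences[name], qi, ti, k)
                ident = matches / span
                if span >= min_span and (ident, span) > best_long:
                    best_long = (ident, span)
                if (ident, span) > best:
                    best = (ident, span)
    return best_long if best_long[1] else best


def anchor_usage(clusters: Iterable[LocusCluster], anchor_k: int = 12) -> Counter:
    """Count, per anchor k-mer adjoining the repeat, how many distinct
    clusters use it (multi-copy / repetitive-element signal)."""
    usage: Counter[str] = Counter()
    for c in clusters:
        anchors = set()
        if len(c.consensus_left) >= anchor_k:
            anchors.add(c.consensus_left[-anchor_k:])
        if len(c.consensus_right) >= anchor_k:
            anchors.add(c.consensus_right[:anchor_k])
        for a in anchors:
            usage[a] += 1
    return usage


def filter_locus(
    cluster: LocusCluster,
    config: FilterConfig | None = None,
    contaminant_index: ContaminantIndex | None = None,
    anchor_counts: Mapping[str, int] | None = None,
    call: PolymorphismCall | None = None,
    anchor_k: int = 12,
) -> FilterOutcome:
    """Apply all exclusion rules to one polymorphic cluster.

    All failing rules accumulate in ``reasons`` (order-independent set).
    Without a contaminant index the contaminant check is skipped with a
    logged warning and ``metrics['contaminant_checked'] = False`` — never
    silently reported as checked.
    """
    config = config or FilterConfig()
    call = call or call_alleles(cluster)
    alleles = [a for a, _ in call.supported_alleles] or sorted(cluster.allele_support)
    if not alleles:
        alleles = sorted({m.span for m in cluster.members})
    reasons: set[str] = set()
    metrics: dict = {}

    max_units = max(alleles) // cluster.unit_len
    metrics["max_unit_count"] = max_units
    if max_units < config.min_unit_count:
        reasons.add(TOO_FEW_REPEATS)

    allele_range = max(alleles) - min(alleles)
    metrics["allele_range_bp"] = allele_range
    if allele_range > config.max_allele_range_bp:
        reasons.add(BROAD_RANGE)

    if min(len(cluster.consensus_left), len(cluster.consensus_right)) < config.min_flank_bp:
        reasons.add(FLANKS_TOO_SHORT)

    scores = []
    for flank in (cluster.consensus_left, cluster.consensus_right):
        w = min(config.low_complexity_window, len(flank))
        if w >= 12:
            scores.append(low_complexity_score(flank, window=w))
    metrics["low_complexity"] = max(scores) if scores else None
    if scores and max(scores) > config.low_complexity_threshold:
        reasons.add(REPETITIVE)
    if anchor_counts is not None:
        shared = 0
        if len(cluster.consensus_left) >= anchor_k:
            shared = max(shared, anchor_counts.get(cluster.consensus_left[-anchor_k:], 0))
        if len(cluster.consensus_right) >= anchor_k:
            shared = max(shared, anchor_counts.get(cluster.consensus_right[:anchor_k], 0))
        metrics["max_anchor_clusters"] = shared
        if shared > config.max_shared_anchor_clusters:
            reasons.add(REPETITIVE)

    if contaminant_index is not None:
        best = (0.0, 0)
        for flank in (cluster.consensus_left, cluster.consensus_right):
            if len(flank) >= contaminant_index.k:
                ident, span = contaminant_similarity(
                    flank, contaminant_index, min_span=config.contaminant_min_span
                )
                if (ident, span) > best:
                    best = (ident, span)
        metrics["contaminant_identity"], metrics["contaminant_span"] = best
        metrics["contaminant_checked"] = True
        if (
            best[0] >= config.contaminant_identity_threshold
            and best[1] >= config.contaminant_min_span
        ):
            reasons.add(CONTAMINANT_LIKE)
    else:
        metrics["contaminant_checked"] = False
        logger.warning(
            "cluster %s: no contaminant index supplied; contaminant check skipped",
            cluster.cluster_id,
        )
        warnings.warn(
            f"cluster {cluster.cluster_id}: contaminant check skipped (no index)",
            stacklevel=2,
        )

    return FilterOutcome(passed=not reasons, reasons=reasons, metrics=metrics)


def write_filter_report(rows: Iterable[tuple[str, FilterOutcome]], path, header_comment=None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("cluster_id\tpassed\treasons\tmetrics\n")
        for cid, outcome in rows:
            reasons = ",".join(sorted(outcome.reasons)) or "."
            metrics = ";".join(f"{k}={v}" for k, v in sorted(outcome.metrics.items()))
            fh.write(f"{cid}\t{int(outcome.passed)}\t{reasons}\t{metrics}\n")
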