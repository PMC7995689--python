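"""Grouping of STR hits from many reads into per-locus clusters.

Shotgun reads are unassembled and come from both strands, so hits from one
genomic locus are recognised purely by their flanking sequence.  Each hit is
first flipped into a deterministic canonical orientation; hits then cluster
when they share the canonical motif, an exact anchor k-mer immediately
adjoining the repeat on at least one side, and near-identical flanks
overall (union-find transitive closure).

Allele lengths are read off as the bp span of the repeat array, using only
reads in which the array is fully contained with at least one flank base on
both sides; reads whose array touches a read end still support clustering
but cannot yield a length.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .repeat_scan import RepeatMotif, STRHit, revcomp

__all__ = [
    "OrientedHit",
    "LocusCluster",
    "PolymorphismCall",
    "orient_hit",
    "cluster_hits",
    "call_alleles",
    "consensus_sequence",
    "write_clusters_tsv",
    "write_consensus_fasta",
]


@dataclass
class OrientedHit:
    """An STRHit flipped into canonical orientation.

    The orientation keeping the lexicographically smaller
    ``left_flank + right_flank`` concatenation wins; ties keep the as-read
    orientation.  ``full_array`` marks hits whose array is flanked on both
    sides (usable for allele-length calling).
    """

    read_id: str
    canonical: str
    unit_len: int
    span: int
    left_flank: str
    right_flank: str
    array_seq: str
    flipped: bool
    full_array: bool
    individual: str | None = None


def orient_hit(hit: STRHit | OrientedHit, individual: str | None = None) -> OrientedHit:
    """Deterministically orient a hit; idempotent, and a hit and its
    reverse-complement mate produce identical oriented records.

    The comparison reads the flanks outward from the repeat boundary
    (right flank vs reverse-complemented left flank, truncated to equal
    length), so reads of one locus truncated at different depths still
    orient identically.  On a tie (palindromic flank geometry) the as-read
    orientation is kept.
    """
    if isinstance(hit, OrientedHit):
        fwd = (hit.left_flank, hit.right_flank, hit.array_seq, hit.flipped)
        canonical, unit_len, span = hit.canonical, hit.unit_len, hit.span
        read_id = hit.read_id
        individual = individual or hit.individual
    else:
        fwd = (hit.left_flank, hit.right_flank, _array_seq(hit), False)
        canonical, unit_len, span = hit.motif.canonical, len(hit.motif.unit), hit.span
        read_id = hit.read_id
    left, right, arr, flipped = fwd
    outward_right = right
    outward_left = revcomp(left)
    t = min(len(outward_right), len(outward_left))
    if outward_left[:t] < outward_right[:t]:
        left, right, arr, flipped = revcomp(right), revcomp(left), revcomp(arr), not flipped
    return OrientedHit(
        read_id=read_id,
        canonical=canonical,
        unit_len=unit_len,
        span=span,
        left_flank=left,
        right_flank=right,
        array_seq=arr,
        flipped=flipped,
        full_array=len(left) > 0 and len(right) > 0,
        individual=individual,
    )


def _array_seq(hit: STRHit) -> str:
    return hit.motif.unit * hit.unit_count


@dataclass
class LocusCluster:
    """A set of oriented hits inferred to come from one genomic locus."""

    cluster_id: str
    canonical_motif: str
    unit_len: int
    members: list[OrientedHit]
    consensus_left: str
    consensus_right: str
    allele_support: dict[int, int] = field(default_factory=dict)
    source_individuals: dict[int, set[str]] = field(default_factory=dict)
    non_multiple_warning: bool = False

    @property
    def n_reads(self) -> int:
        return len(self.members)


@dataclass
class PolymorphismCall:
    """Allele spectrum of a cluster after read-support filtering."""

    status: str  # polymorphic | monomorphic | ambiguous
    supported_alleles: list[tuple[int, int]]  # (allele bp, read count)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _flank_mismatches(a: OrientedHit, b: OrientedHit, cap: int) -> int:
    """Substitution count over the overlapping flank regions (both sides,
    aligned at the repeat boundary).  Early-exits once `cap` is exceeded."""
    total = 0
    la, lb = a.left_flank, b.left_flank
    m = min(len(la), len(lb))
    sa, sb = la[len(la) - m :], lb[len(lb) - m :]
    if sa != sb:
        for x, y in zip(sa, sb):
            if x != y:
                total += 1
                if total > cap:
                    return total
    ra, rb = a.right_flank, b.right_flank
    m = min(len(ra), len(rb))
    sa, sb = ra[:m], rb[:m]
    if sa != sb:
        for x, y in zip(sa, sb):
            if x != y:
                total += 1
                if total > cap:
                    return total
    return total


def _consensus(strings: Sequence[str], from_right: bool) -> str:
    """Per-column majority consensus; columns aligned at the repeat boundary
    (i.e. right-aligned for left flanks).  Ties break to the
    lexicographically smallest base for determinism."""
    if not strings:
        return ""
    n = max(len(s) for s in strings)
    out = []
    for col in range(n):
        counts: Counter[str] = Counter()
        for s in strings:
            if col < len(s):
                base = s[len(s) - 1 - col] if from_right else s[col]
                counts[base] += 1
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        out.append(best)
    if from_right:
        out.reverse()
    return "".join(out)


def cluster_hits(
    hits: Iterable[STRHit | OrientedHit],
    anchor_k: int = 12,
    min_flank: int = 20,
    max_mismatch: int = 2,
    individual_of: Callable[[str], str] | None = None,
) -> tuple[list[LocusCluster], list[OrientedHit]]:
    """Cluster hits into loci by flanking-sequence identity.

    Two hits join when they share the canonical motif, their anchor k-mers
    (the ``anchor_k`` flank bases adjoining the repeat) match exactly on at
    least one side, and the overlapping flank regions differ by at most
    ``max_mismatch`` substitutions in total.  Clustering is a union-find
    transitive closure, so it is invariant to input order and strand.

    Hits with either flank shorter than ``min_flank`` are returned
    separately as unclusterable.

    Returns
    -------
    (clusters, unclusterable)
        Clusters sorted by (motif, consensus flanks) with deterministic ids.
    """
    if anchor_k > min_flank:
        raise ValueError("anchor_k must be <= min_flank")
    oriented: list[OrientedHit] = []
    unclusterable: list[OrientedHit] = []
    for h in hits:
        oh = orient_hit(h)
        if oh.individual is None and individual_of is not None:
            oh.individual = individual_of(oh.read_id)
        if len(oh.left_flank) < min_flank or len(oh.right_flank) < min_flank:
            unclusterable.append(oh)
        else:
            oriented.append(oh)

    # canonical input order so that union-find tie-breaks are order-free
    oriented.sort(key=lambda o: (o.canonical, o.left_flank[-min_flank:], o.right_flank[:min_flank], o.read_id))

    uf = _UnionFind(len(oriented))
    buckets: dict[tuple, list[int]] = defaultdict(list)
    for i, oh in enumerate(oriented):
        buckets[(oh.canonical, "L", oh.left_flank[-anchor_k:])].append(i)
        buckets[(oh.canonical, "R", oh.right_flank[:anchor_k])].append(i)
    for members in buckets.values():
        for ai in range(len(members)):
            i = members[ai]
            for bi in range(ai + 1, len(members)):
                j = members[bi]
                if uf.find(i) == uf.find(j):
                    continue
                if _flank_mismatches(oriented[i], oriented[j], max_mismatch) <= max_mismatch:
                    uf.union(i, j)

    groups: dict[int, list[OrientedHit]] = defaultdict(list)
    for i, oh in enumerate(oriented):
        groups[uf.find(i)].append(oh)

    clusters: list[LocusCluster] = []
    for members in groups.values():
        cons_left = _consensus([m.left_flank for m in members], from_right=True)
        cons_right = _consensus([m.right_flank for m in members], from_right=False)
        support: dict[int, int] = defaultdict(int)
        sources: dict[int, set[str]] = defaultdict(set)
        for m in members:
            if m.full_array:
                support[m.span] += 1
                if m.individual is not None:
                    sources[m.span].add(m.individual)
        unit_len = members[0].unit_len
        warn = any(
            (a - b) % unit_len != 0 for a in support for b in support if a > b
        )
        clusters.append(
            LocusCluster(
                cluster_id="",
                canonical_motif=members[0].canonical,
                unit_len=unit_len,
                members=members,
                consensus_left=cons_left,
                consensus_right=cons_right,
                allele_support=dict(sorted(support.items())),
                source_individuals={k: set(v) for k, v in sources.items()},
                non_multiple_warning=warn,
            )
        )
    clusters.sort(key=lambda c: (c.canonical_motif, c.consensus_left, c.consensus_right))
    for idx, c in enumerate(clusters, start=1):
        c.cluster_id = f"cl{idx:05d}"
    return clusters, unclusterable


def call_alleles(cluster: LocusCluster, min_support: int = 2) -> PolymorphismCall:
    """Call the allele-length spectrum of a cluster.

    Alleles with fewer than ``min_support`` supporting full-array reads are
    dropped (guards against single-read sequencing error with only ~4
    chromosomes sampled).  Status is polymorphic with >= 2 surviving
    alleles, monomorphic with exactly 1, ambiguous with 0.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    surviving = sorted(
        (length, count)
        for length, count in cluster.allele_support.items()
        if count >= min_support
    )
    if len(surviving) >= 2:
        status = "polymorphic"
    elif len(surviving) == 1:
        status = "monomorphic"
    else:
        status = "ambiguous"
    return PolymorphismCall(status=status, supported_alleles=surviving)


def consensus_sequence(cluster: LocusCluster, allele: int | None = None) -> tuple[str, int, int]:
    """Consensus locus sequence (left flank + repeat array + right flank).

    Uses the most-supported allele's array by default (ties to the shorter
    allele).  Returns ``(sequence, repeat_start, repeat_end)`` with the
    repeat coordinates on the returned sequence.
    """
    if allele is None:
        if cluster.allele_support:
            allele = min(
                cluster.allele_support,
                key=lambda a: (-cluster.allele_support[a], a),
            )
        else:
            allele = max(m.span for m in cluster.members)
    arrays = sorted(m.array_seq for m in cluster.members if m.span == allele and m.full_array)
    if not arrays:
        arrays = sorted(m.array_seq for m in cluster.members if m.span == allele)
    array = arrays[0] if arrays else cluster.canonical_motif * (allele // cluster.unit_len)
    left = cluster.consensus_left
    seq = left + array + cluster.consensus_right
    return seq, len(left), len(left) + len(array)


def write_clusters_tsv(clusters, calls, path, header_comment: str | None = None) -> None:
    """Cluster table TSV: id, motif, n_reads, consensus flanks, allele
    support pairs and polymorphism status."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(
            "cluster_id\tmotif\tn_reads\tconsensus_left\tconsensus_right\talleles\tstatus\n"
        )
        for c, call in zip(clusters, calls):
            alleles = ",".join(f"{a}:{n}" for a, n in sorted(c.allele_support.items()))
            fh.write(
                f"{c.cluster_id}\t{c.canonical_motif}\t{c.n_reads}\t{c.consensus_left}"
                f"\t{c.consensus_right}\t{alleles}\t{call.status}\n"
            )


def write_consensus_fasta(clusters, path) -> None:
    """Consensus locus sequences as FASTA for downstream primer design."""
    with open(path, "w") as fh:
        for c in clusters:
            seq, s, e = consensus_sequence(c)
            fh.write(f">{c.cluster_id} motif={c.canonical_motif} repeat={s}-{e}\n{seq}\n")
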