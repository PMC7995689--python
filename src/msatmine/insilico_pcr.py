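"""In-silico PCR: primer binding-site search and product enumeration.

A primer binds wherever its Hamming distance to the template window is at
most ``max_mismatch`` *and* its 3'-most ``three_prime_exact`` bases match
exactly (polymerase extension requires a matched 3' end).  Products arise
where two sites on opposite strands face each other within
``max_product`` bp.  The mismatch model is substitutions only — no indels.

Used both for validating designed markers on the discovery individuals and
for cross-species specificity checks (e.g. tapir, human templates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .primer_design import PrimerPair
from .repeat_scan import revcomp

__all__ = [
    "BindingSite",
    "Amplicon",
    "MarkerValidation",
    "PcrConfig",
    "find_binding_sites",
    "amplify",
    "classify_marker",
    "write_product_tsv",
]


@dataclass
class PcrConfig:
    max_mismatch: int = 2
    three_prime_exact: int = 3
    max_product: int = 1000
    # classification
    max_size_range: int = 20
    expected_size_window: tuple[int, int] | None = None


@dataclass(frozen=True)
class BindingSite:
    """One primer binding location.  ``start``/``end`` are 0-based half-open
    template coordinates; strand '+' means the primer anneals to the minus
    strand and extends rightward, '-' the converse."""

    strand: str
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int
    end: int
    fwd_mismatches: int
    rev_mismatches: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _hamming_scan(primer: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Mismatch count of the primer against every template window."""
    k = len(primer)
    if len(template) < k:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(template, k)
    return (windows != primer).sum(axis=1)


def find_binding_sites(
    primer: str,
    template: str,
    max_mismatch: int = 2,
    three_prime_exact: int = 3,
) -> list[BindingSite]:
    """All binding sites of ``primer`` on both strands of ``template``.

    A '+' site is a match of the primer itself (3' end = site end); a '-'
    site is a match of its reverse complement (3' end = site start).
    Sites are returned sorted by (start, strand); deterministic.
    """
    if three_prime_exact < 1:
        raise ValueError("three_prime_exact must be >= 1")
    if len(primer) >= len(template):
        return []
    t = _encode(template)
    k = len(primer)
    sites: list[BindingSite] = []

    p = _encode(primer)
    mm = _hamming_scan(p, t)
    tail = _hamming_scan(p[-three_prime_exact:], t)  # 3'-seed windows at every position
    for pos in np.flatnonzero(mm <= max_mismatch):
        if tail[pos + k - three_prime_exact] == 0:
            sites.append(BindingSite("+", int(pos), int(pos + k), int(mm[pos])))

    prc = _encode(revcomp(primer))
    mm = _hamming_scan(prc, t)
    head = _hamming_scan(prc[:three_prime_exact], t)
    for pos in np.flatnonzero(mm <= max_mismatch):
        if head[pos] == 0:
            sites.append(BindingSite("-", int(pos), int(pos + k), int(mm[pos])))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def amplify(
    pair: PrimerPair,
    templates: Mapping[str, str],
    max_mismatch: int = 2,
    three_prime_exact: int = 3,
    max_product: int = 1000,
) -> dict[str, list[Amplicon]]:
    """Enumerate all products of a primer pair over a template set.

    Both orientations are considered: forward primer on '+' with reverse
    primer on '-' (product strand '+'), and the converse (strand '-').
    Every facing site pair with 0 < length <= max_product is reported.
    """
    out: dict[str, list[Amplicon]] = {}
    for tid, template in templates.items():
        f_sites = find_binding_sites(pair.forward, template, max_mismatch, three_prime_exact)
        r_sites = find_binding_sites(pair.reverse, template, max_mismatch, three_prime_exact)
        products: list[Amplicon] = []
        for left, right, strand in (
            (pair.forward, pair.reverse, "+"),
            (pair.reverse, pair.forward, "-"),
        ):
            lefts = f_sites if strand == "+" else r_sites
            rights = r_sites if strand == "+" else f_sites
            for ls in lefts:
                if ls.strand != "+":
                    continue
                for rs in rights:
                    if rs.strand != "-":
                        continue
                    length = rs.end - ls.start
                    if 0 < length <= max_product:
                        fmm = ls.mismatches if strand == "+" else rs.mismatches
                        rmm = rs.mismatches if strand == "+" else ls.mismatches
                        products.append(
                            Amplicon(tid, ls.start, rs.end, fmm, rmm, strand)
                        )
        products.sort(key=lambda a: (a.start, a.end, a.strand))
        out[tid] = products
    return out


@dataclass
class MarkerValidation:
    """Classification of a candidate marker from its per-template product
    lists; exclusion statuses mirror the discovery-stage rejection
    reasons."""

    status: str  # single_product_polymorphic | monomorphic | multiple_products | no_product | broad_range
    products: dict[str, list[Amplicon]] = field(default_factory=dict)
    sizes: dict[str, list[int]] = field(default_factory=dict)


def classify_marker(
    products: Mapping[str, list[Amplicon]] | Mapping[str, list[int]],
    config: PcrConfig | None = None,
) -> MarkerValidation:
    """Classify a marker from products per individual/template.

    no_product : every template empty.
    multiple_products : some template yields more than one product where the
        extras fall outside the expected-size window (a diploid's two
        in-window alleles are not secondary bands); without a window, any
        >1-product template qualifies.
    broad_range : product size spread across templates exceeds the cap.
    monomorphic : all templates yield one identical product size.
    single_product_polymorphic : otherwise.
    """
    if not products:
        raise ValueError("at least one template is required")
    config = config or PcrConfig()
    sizes: dict[str, list[int]] = {}
    for tid, plist in products.items():
        sizes[tid] = sorted(p.length if isinstance(p, Amplicon) else int(p) for p in plist)
    prods = {
        tid: list(plist) if plist and isinstance(plist[0], Amplicon) else []
        for tid, plist in products.items()
    }

    def build(status: str) -> MarkerValidation:
        return MarkerValidation(status=status, products=prods, sizes=sizes)

    if all(not s for s in sizes.values()):
        return build("no_product")
    window = config.expected_size_window
    for tid, s in sizes.items():
        if len(s) > 1:
            if window is None or any(not (window[0] <= x <= window[1]) for x in s):
                return build("multiple_products")
    observed = sorted({x for s in sizes.values() for x in s})
    if max(observed) - min(observed) > config.max_size_range:
        return build("broad_range")
    if len(observed) == 1:
        return build("monomorphic")
    return build("single_product_polymorphic")


def write_product_tsv(rows, path, header_comment=None) -> None:
    """Product table TSV: template, marker, start, end, length, mismatches,
    strand."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("template\tmarker\tstart\tend\tlength\tfwd_mm\trev_mm\tstrand\n")
        for marker, tid, amp in rows:
            fh.write(
                f"{tid}\t{marker}\t{amp.start}\t{amp.end}\t{amp.length}"
                f"\t{amp.fwd_mismatches}\t{amp.rev_mismatches}\t{amp.strand}\n"
            )
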