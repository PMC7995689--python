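"""Short-amplicon primer design in STR consensus flanks.

Degraded template (fecal DNA) demands short products: every amplicon,
including the longest allele, must stay within ``max_amplicon_bp`` (150 bp
by default), with the two primer lengths jointly in the 36-44 bp window.
Fluorescent genotyping uses an M13-tailed forward primer, so reported size
ranges add the 18 bp universal tail; the tail never participates in
binding-site search.

Melting temperatures are available as the Wallace rule (2AT + 4GC) or a
nearest-neighbor model using the unified dinucleotide parameter table of
SantaLucia (1998) with explicit monovalent-salt and primer concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "M13_FORWARD_TAIL",
    "DesignConstraints",
    "PrimerPair",
    "melting_temperature",
    "gc_fraction",
    "max_homopolymer",
    "primer_violations",
    "design_primers",
    "reported_size_range",
    "write_primer_tsv",
]

#: Universal M13(-21) forward tail prepended for fluorescent genotyping.
M13_FORWARD_TAIL = "TGTAAAACGACGGCCAGT"

# Unified nearest-neighbor parameters (SantaLucia 1998): dH kcal/mol, dS cal/(mol K)
_NN_DH = {
    "AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2,
    "CA": -8.5, "TG": -8.5, "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
    "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0,
}
_NN_DS = {
    "AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3,
    "CA": -22.7, "TG": -22.7, "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0, "GA": -22.2, "TC": -22.2,
    "CG": -27.2, "GC": -24.4, "GG": -19.9, "CC": -19.9,
}
_INIT_GC = (0.1, -2.8)  # terminal G/C initiation dH, dS
_INIT_AT = (2.3, 4.1)   # terminal A/T initiation dH, dS
_R = 1.987  # gas constant, cal/(mol K)


@dataclass
class DesignConstraints:
    """All numeric design bounds; every value lives here, not in code."""

    min_primer_len: int = 18
    max_primer_len: int = 22
    min_total_len: int = 36
    max_total_len: int = 44
    gc_min: float = 0.40
    gc_max: float = 0.60
    tm_min: float = 54.0
    tm_max: float = 62.0
    max_tm_diff: float = 3.0
    max_homopolymer: int = 4  # no run of 5+
    gc_clamp_3prime: bool = True  # 3'-terminal base must be G or C
    max_gc_last5: int = 3
    max_amplicon_bp: int = 150
    tm_method: str = "nn"
    na_mM: float = 50.0
    primer_nM: float = 250.0  # per-strand concentration


@dataclass
class PrimerPair:
    """A candidate primer pair on a consensus locus.

    ``reverse`` is given 5'->3' on the opposite strand.  ``fwd_start`` and
    ``rev_end`` are 0-based coordinates on the consensus sequence;
    ``product_size_by_allele`` maps allele length (bp) to untailed amplicon
    size.
    """

    forward: str
    reverse: str
    fwd_start: int
    rev_end: int
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float
    product_size_by_allele: dict[int, int] = field(default_factory=dict)

    @property
    def m13_tailed_forward(self) -> str:
        return M13_FORWARD_TAIL + self.forward


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def melting_temperature(
    primer: str,
    method: str = "nn",
    na_mM: float = 50.0,
    primer_nM: float = 250.0,
) -> float:
    """Primer melting temperature in deg C.

    wallace : 2*(A+T) + 4*(G+C).
    nn : nearest-neighbor with the unified SantaLucia (1998) table, entropic
        salt correction 0.368*(N-1)*ln[Na+], and
        Tm = 1000*dH / (dS' + R*ln(Ct/4)) - 273.15 with total strand
        concentration Ct = 2 * primer_nM (non-self-complementary duplex).
    """
    primer = primer.upper()
    if len(primer) < 10:
        raise ValueError("primer must be at least 10 bases")
    if any(b not in "ACGT" for b in primer):
        raise ValueError("ambiguity codes are not supported")
    if method == "wallace":
        at = primer.count("A") + primer.count("T")
        gc = primer.count("G") + primer.count("C")
        return 2.0 * at + 4.0 * gc
    if method != "nn":
        raise ValueError(f"unknown Tm method: {method}")
    dh = 0.0
    ds = 0.0
    for i in range(len(primer) - 1):
        pair = primer[i : i + 2]
        dh += _NN_DH[pair]
        ds += _NN_DS[pair]
    for terminal in (primer[0], primer[-1]):
        init = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += init[0]
        ds += init[1]
    ds += 0.368 * (len(primer) - 1) * math.log(na_mM / 1000.0)
    ct = 2.0 * primer_nM * 1e-9
    return 1000.0 * dh / (ds + _R * math.log(ct / 4.0)) - 273.15


def primer_violations(seq: str, c: DesignConstraints, tm: float | None = None) -> list[str]:
    """Constraint check for a single primer; returns the list of violated
    rules (empty = acceptable).  Shared by the designer and by independent
    re-validation."""
    v = []
    if not (c.min_primer_len <= len(seq) <= c.max_primer_len):
        v.append("length")
    gc = gc_fraction(seq)
    if not (c.gc_min <= gc <= c.gc_max):
        v.append("gc")
    if tm is None:
        tm = melting_temperature(seq, c.tm_method, c.na_mM, c.primer_nM)
    if not (c.tm_min <= tm <= c.tm_max):
        v.append("tm")
    if max_homopolymer(seq) > c.max_homopolymer:
        v.append("homopolymer")
    if c.gc_clamp_3prime and seq[-1] not in "GC":
        v.append("clamp")
    if sum(1 for b in seq[-5:] if b in "GC") > c.max_gc_last5:
        v.append("gc_last5")
    return v


_RC = str.maketrans("ACGT", "TGCA")


def design_primers(
    consensus: str,
    repeat_start: int,
    repeat_end: int,
    allele_lengths: list[int],
    constraints: DesignConstraints | None = None,
    max_pairs: int | None = 20,
) -> list[PrimerPair]:
    """Enumerate and rank all primer pairs satisfying the constraints.

    The repeat array occupies ``consensus[repeat_start:repeat_end]`` and
    represents one allele; products for other alleles differ by the allele
    length difference.  The product for the *largest* allele must fit in
    ``max_amplicon_bp``.  Primers never overlap the repeat array.  Ranking
    is deterministic: (|dTm|, product size at largest allele, fwd_start,
    rev_end).  An empty list means no satisfying pair exists.
    """
    c = constraints or DesignConstraints()
    consensus = consensus.upper()
    rep_len = repeat_end - repeat_start
    if not allele_lengths:
        raise ValueError("allele_lengths must be non-empty")
    max_allele = max(allele_lengths)
    extra = max_allele - rep_len

    def tm(seq: str) -> float:
        return melting_temperature(seq, c.tm_method, c.na_mM, c.primer_nM)

    fwd: list[tuple[int, str, float]] = []  # (start, seq, tm)
    # product at largest allele = (rev_end - fwd_start) + extra <= cap, so
    # the forward start cannot be further than cap from the repeat start.
    min_fwd_start = max(0, repeat_start + rep_len + extra - c.max_amplicon_bp)
    for ln in range(c.min_primer_len, c.max_primer_len + 1):
        for start in range(min_fwd_start, repeat_start - ln + 1):
            seq = consensus[start : start + ln]
            if "N" in seq:
                continue
            t = tm(seq)
            if not primer_violations(seq, c, tm=t):
                fwd.append((start, seq, t))
    rev: list[tuple[int, str, float]] = []  # (rev_end, seq, tm)
    max_rev_end = min(len(consensus), repeat_end + c.max_amplicon_bp)
    for ln in range(c.min_primer_len, c.max_primer_len + 1):
        for s in range(repeat_end, max_rev_end - ln + 1):
            window = consensus[s : s + ln]
            if "N" in window:
                continue
            seq = window.translate(_RC)[::-1]
            t = tm(seq)
            if not primer_violations(seq, c, tm=t):
                rev.append((s + ln, seq, t))

    pairs: list[PrimerPair] = []
    for f_start, f_seq, f_tm in fwd:
        for r_end, r_seq, r_tm in rev:
            total = len(f_seq) + len(r_seq)
            if not (c.min_total_len <= total <= c.max_total_len):
                continue
            if abs(f_tm - r_tm) > c.max_tm_diff:
                continue
            product_rep = r_end - f_start
            if product_rep + extra > c.max_amplicon_bp:
                continue
            sizes = {a: product_rep + (a - rep_len) for a in sorted(allele_lengths)}
            if min(sizes.values()) <= total:
                continue  # degenerate: product shorter than the primers
            pairs.append(
                PrimerPair(
                    forward=f_seq,
                    reverse=r_seq,
                    fwd_start=f_start,
                    rev_end=r_end,
                    tm_f=f_tm,
                    tm_r=r_tm,
                    gc_f=gc_fraction(f_seq),
                    gc_r=gc_fraction(r_seq),
                    product_size_by_allele=sizes,
                )
            )
    pairs.sort(
        key=lambda p: (
            abs(p.tm_f - p.tm_r),
            max(p.product_size_by_allele.values()),
            p.fwd_start,
            p.rev_end,
        )
    )
    return pairs[:max_pairs] if max_pairs else pairs


def reported_size_range(pair: PrimerPair, alleles: list[int] | None = None) -> tuple[int, int]:
    """Product size range across alleles with the 18 bp M13 tail added to
    each, matching how fluorescent fragment sizes are reported."""
    sizes = (
        [pair.product_size_by_allele[a] for a in alleles]
        if alleles is not None
        else list(pair.product_size_by_allele.values())
    )
    tail = len(M13_FORWARD_TAIL)
    return min(sizes) + tail, max(sizes) + tail


def write_primer_tsv(rows, path, header_comment=None) -> None:
    """Primer table: locus, untailed F/R sequences, allele count, tailed
    size range, design metrics."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(
            "locus\tforward\treverse\tn_alleles\tsize_min\tsize_max\ttm_f\ttm_r\tgc_f\tgc_r\n"
        )
        for locus, pair in rows:
            lo, hi = reported_size_range(pair)
            fh.write(
                f"{locus}\t{pair.forward}\t{pair.reverse}\t{len(pair.product_size_by_allele)}"
                f"\t{lo}\t{hi}\t{pair.tm_f:.2f}\t{pair.tm_r:.2f}\t{pair.gc_f:.2f}\t{pair.gc_r:.2f}\n"
            )
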