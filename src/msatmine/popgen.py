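"""Marker-panel population-genetic statistics.

Per-locus statistics for a diploid genotype table: allele count A, observed
heterozygosity H_O, expected heterozygosity H_E (plain 1 - sum p_i^2 and
the unbiased 2n/(2n-1) correction), inbreeding coefficient F_IS (both the
simple 1 - H_O/H_E form and the Weir & Cockerham 1984 single-population f
from variance components), and the probabilities of identity of Waits et
al. (2001):

    P_ID      = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2
    P_ID(sib) = 0.25 + 0.5 sum p_i^2 + 0.5 (sum p_i^2)^2 - 0.25 sum p_i^4

Panel-level power multiplies per-locus P_ID across loci, most informative
(lowest) first, and reports the minimal panel size whose cumulative product
drops below a threshold.  A paired-table concordance report classifies
genotype disagreements into allelic dropout, false alleles and other
mismatches — the error modes of low-template (fecal) genotyping.

Missing data are handled by locus-wise complete observations (pairwise
deletion), as in FSTAT/GenAlEx.  Internal arithmetic is full precision;
``round_half_up`` provides the 2-decimal display convention of marker
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NoDataError",
    "MonomorphicLocusError",
    "GenotypeTable",
    "AlleleFrequencies",
    "LocusSummary",
    "PanelSummary",
    "ConcordanceReport",
    "allele_frequencies",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "pid",
    "pid_sib",
    "fis",
    "locus_summary",
    "summarize_panel",
    "panel_power",
    "genotype_concordance",
    "round_half_up",
]


class NoDataError(ValueError):
    """Locus has no non-missing calls."""


class MonomorphicLocusError(ValueError):
    """F_IS is undefined at a monomorphic locus (not zero)."""


Call = tuple[int, int] | None


@dataclass
class GenotypeTable:
    """Individuals x loci matrix of unordered diploid allele pairs.

    Allele labels are integers (bp sizes) comparable within a locus only;
    ``None`` marks a missing call.
    """

    individuals: list[str]
    loci: list[str]
    calls: dict[tuple[str, str], Call] = field(default_factory=dict)

    def get(self, individual: str, locus: str) -> Call:
        return self.calls.get((individual, locus))

    def set_call(self, individual: str, locus: str, call: Call) -> None:
        if call is not None:
            a, b = call
            call = (int(a), int(b)) if a <= b else (int(b), int(a))
        self.calls[(individual, locus)] = call

    def typed(self, locus: str) -> list[tuple[str, tuple[int, int]]]:
        """(individual, call) pairs with a non-missing call at ``locus``."""
        out = []
        for ind in self.individuals:
            call = self.calls.get((ind, locus))
            if call is not None:
                out.append((ind, call))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        data = {}
        for locus in self.loci:
            col1, col2 = [], []
            for ind in self.individuals:
                call = self.calls.get((ind, locus))
                col1.append(call[0] if call else pd.NA)
                col2.append(call[1] if call else pd.NA)
            data[f"{locus}.1"] = col1
            data[f"{locus}.2"] = col2
        return pd.DataFrame(data, index=self.individuals)


@dataclass
class AlleleFrequencies:
    locus: str
    freqs: dict[int, float]
    n_typed: int


def _probs(freqs) -> np.ndarray:
    """Accept AlleleFrequencies, a mapping label->p, or a plain sequence."""
    if isinstance(freqs, AlleleFrequencies):
        p = np.array(list(freqs.freqs.values()), dtype=float)
    elif isinstance(freqs, Mapping):
        p = np.array(list(freqs.values()), dtype=float)
    else:
        p = np.asarray(list(freqs), dtype=float)
    if p.size == 0:
        raise NoDataError("no allele frequencies")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"allele frequencies must sum to 1 (got {p.sum()})")
    return p


def allele_frequencies(table: GenotypeTable, locus: str) -> AlleleFrequencies:
    """Counting estimator p_i = count_i / (2 n_typed) over non-missing
    calls only."""
    typed = table.typed(locus)
    if not typed:
        raise NoDataError(f"locus {locus}: all calls missing")
    counts: dict[int, int] = {}
    for _, (a, b) in typed:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    n = len(typed)
    freqs = {allele: c / (2 * n) for allele, c in sorted(counts.items())}
    return AlleleFrequencies(locus=locus, freqs=freqs, n_typed=n)


def observed_heterozygosity(table: GenotypeTable, locus: str) -> float:
    """Fraction of non-missing individuals carrying two distinct alleles."""
    typed = table.typed(locus)
    if not typed:
        raise NoDataError(f"locus {locus}: all calls missing")
    return sum(1 for _, (a, b) in typed if a != b) / len(typed)


def expected_heterozygosity(freqs, unbiased: bool = False, n_typed: int | None = None) -> float:
    """H_E = 1 - sum p_i^2; the unbiased form multiplies by 2n/(2n-1)."""
    p = _probs(freqs)
    he = 1.0 - float(np.sum(p**2))
    if not unbiased:
        return he
    if n_typed is None:
        if isinstance(freqs, AlleleFrequencies):
            n_typed = freqs.n_typed
        else:
            raise ValueError("unbiased H_E requires n_typed")
    if n_typed == 0:
        raise NoDataError("unbiased H_E undefined for n_typed = 0")
    return he * (2 * n_typed) / (2 * n_typed - 1)


def pid(freqs) -> float:
    """Probability that two unrelated individuals share a genotype
    (Waits et al. 2001): sum p_i^4 + sum_{i<j} (2 p_i p_j)^2."""
    p = _probs(freqs)
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    # sum_{i<j} (2 p_i p_j)^2 = 2 * ((sum p^2)^2 - sum p^4)
    return s4 + 2.0 * (s2 * s2 - s4)


def pid_sib(freqs) -> float:
    """Probability that two full siblings share a genotype
    (Waits et al. 2001): 0.25 + 0.5 S2 + 0.5 S2^2 - 0.25 S4."""
    p = _probs(freqs)
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 0.25 + 0.5 * s2 + 0.5 * s2 * s2 - 0.25 * s4


def fis(table: GenotypeTable, locus: str, estimator: str = "weir_cockerham") -> float:
    """Inbreeding coefficient F_IS.

    simple : 1 - H_O / H_E(unbiased).
    weir_cockerham : single-population f of Weir & Cockerham (1984) from
        per-allele variance components
        b_A = n/(n-1) [p(1-p) - (2n-1)/(4n) hbar_A], c_A = hbar_A/2,
        f = 1 - sum c / sum (b + c),
    where hbar_A is the observed frequency of heterozygotes carrying A.
    """
    freqs = allele_frequencies(table, locus)
    if len(freqs.freqs) < 2:
        raise MonomorphicLocusError(f"locus {locus} is monomorphic")
    typed = table.typed(locus)
    n = len(typed)
    if n < 2:
        raise NoDataError(f"locus {locus}: need >= 2 typed individuals")
    if estimator == "simple":
        ho = observed_heterozygosity(table, locus)
        he = expected_heterozygosity(freqs, unbiased=True)
        return 1.0 - ho / he
    if estimator != "weir_cockerham":
        raise ValueError(f"unknown F_IS estimator: {estimator}")
    sum_b = 0.0
    sum_c = 0.0
    for allele, p in freqs.freqs.items():
        hbar = sum(1 for _, (a, b) in typed if (a == allele) != (b == allele)) / n
        b_comp = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * hbar)
        c_comp = hbar / 2.0
        sum_b += b_comp
        sum_c += c_comp
    denom = sum_b + sum_c
    if denom == 0:
        raise MonomorphicLocusError(f"locus {locus}: zero variance components")
    return 1.0 - sum_c / denom


@dataclass
class LocusSummary:
    locus: str
    n_typed: int
    A: int
    Ho: float
    He_plain: float
    He_unbiased: float
    Fis_simple: float | None
    Fis_wc: float | None
    PID: float
    PIDsib: float


def locus_summary(table: GenotypeTable, locus: str) -> LocusSummary:
    freqs = allele_frequencies(table, locus)
    ho = observed_heterozygosity(table, locus)
    polymorphic = len(freqs.freqs) >= 2
    fis_simple = fis_wc = None
    if polymorphic:
        try:
            fis_simple = fis(table, locus, "simple")
            fis_wc = fis(table, locus, "weir_cockerham")
        except (MonomorphicLocusError, NoDataError):
            pass
    return LocusSummary(
        locus=locus,
        n_typed=freqs.n_typed,
        A=len(freqs.freqs),
        Ho=ho,
        He_plain=expected_heterozygosity(freqs),
        He_unbiased=expected_heterozygosity(freqs, unbiased=True),
        Fis_simple=fis_simple,
        Fis_wc=fis_wc,
        PID=pid(freqs),
        PIDsib=pid_sib(freqs),
    )


def summarize_panel(table: GenotypeTable) -> pd.DataFrame:
    """Per-locus statistics for every locus with data, as a DataFrame."""
    rows = []
    for locus in table.loci:
        try:
            s = locus_summary(table, locus)
        except NoDataError:
            continue
        rows.append(vars(s))
    return pd.DataFrame(rows).set_index("locus")


@dataclass
class PanelSummary:
    criterion: str
    threshold: float
    ordering: list[str]
    per_locus: list[float]
    cumulative: list[float]
    min_loci: int | None  # None = threshold never reached


def panel_power(
    per_locus: Mapping[str, float] | Sequence[LocusSummary],
    criterion: str = "PID",
    threshold: float = 1e-4,
) -> PanelSummary:
    """Cumulative identity power of a marker panel.

    Loci are sorted ascending by the chosen per-locus probability (most
    informative first; ties by locus id), running products taken, and the
    minimal panel size reported as the first m with product < threshold.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    if isinstance(per_locus, Mapping):
        items = dict(per_locus)
    else:
        attr = {"PID": "PID", "PIDsib": "PIDsib"}[criterion]
        items = {s.locus: getattr(s, attr) for s in per_locus}
    if not items:
        raise ValueError("at least one locus required")
    ordered = sorted(items.items(), key=lambda kv: (kv[1], kv[0]))
    values = [v for _, v in ordered]
    cumulative = list(np.cumprod(values))
    min_loci = next((i + 1 for i, c in enumerate(cumulative) if c < threshold), None)
    return PanelSummary(
        criterion=criterion,
        threshold=threshold,
        ordering=[k for k, _ in ordered],
        per_locus=values,
        cumulative=cumulative,
        min_loci=min_loci,
    )


@dataclass
class ConcordanceReport:
    n_compared: int
    n_het_in_a: int
    counts: dict[str, int]
    detail: pd.DataFrame
    match_rate: float
    dropout_rate: float  # per heterozygous call in table A
    false_allele_rate: float  # per compared call


def genotype_concordance(table_a: GenotypeTable, table_b: GenotypeTable) -> ConcordanceReport:
    """Compare genotypes of shared (individual, locus) pairs across two
    tables (e.g. blood-derived vs fecal-derived).

    match : identical unordered pairs.
    allelic_dropout : A heterozygous, B homozygous for one of A's alleles.
    false_allele : B contains an allele absent from A.
    other_mismatch : any remaining disagreement.

    A call hit by both error modes presents as false_allele, so the raw
    dropout fraction underestimates the per-heterozygote dropout
    probability by the factor (1 - false-allele rate); ``dropout_rate``
    divides that factor out.
    """
    shared_inds = [i for i in table_a.individuals if i in set(table_b.individuals)]
    shared_loci = [l for l in table_a.loci if l in set(table_b.loci)]
    rows = []
    counts = {"match": 0, "allelic_dropout": 0, "false_allele": 0, "other_mismatch": 0}
    n_het_a = 0
    for ind in shared_inds:
        for locus in shared_loci:
            ca = table_a.get(ind, locus)
            cb = table_b.get(ind, locus)
            if ca is None or cb is None:
                continue
            set_a, set_b = set(ca), set(cb)
            if ca[0] != ca[1]:
                n_het_a += 1
            if set_a == set_b:
                cls = "match"
            elif set_b - set_a:
                cls = "false_allele"
            elif ca[0] != ca[1] and cb[0] == cb[1] and cb[0] in set_a:
                cls = "allelic_dropout"
            else:
                cls = "other_mismatch"
            counts[cls] += 1
            rows.append({"individual": ind, "locus": locus, "call_a": ca, "call_b": cb, "class": cls})
    n = sum(counts.values())
    if n == 0:
        raise NoDataError("no overlapping non-missing (individual, locus) pairs")
    false_rate = counts["false_allele"] / n
    if n_het_a:
        dropout_rate = counts["allelic_dropout"] / n_het_a / max(1.0 - false_rate, 1e-12)
    else:
        dropout_rate = float("nan")
    return ConcordanceReport(
        n_compared=n,
        n_het_in_a=n_het_a,
        counts=counts,
        detail=pd.DataFrame(rows),
        match_rate=counts["match"] / n,
        dropout_rate=dropout_rate,
        false_allele_rate=false_rate,
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding used for report display (marker tables
    print 2 decimals; banker's rounding would disagree on exact halves)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
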