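"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: repeat arrays are
found by direct string comparison at every (start, unit length), identity
probabilities by exhaustive genotype enumeration, and binding sites by
naive per-position Hamming loops.
"""

from __future__ import annotations

from itertools import combinations_with_replacement, product

_RC = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def brute_canonical(unit: str) -> str:
    """Minimum over explicitly enumerated rotations of unit and rc(unit)."""
    forms = []
    for s in (unit, rc(unit)):
        for i in range(len(s)):
            forms.append(s[i:] + s[:i])
    return min(forms)


def brute_valid_motif(unit: str) -> bool:
    if not (2 <= len(unit) <= 4) or set(unit) - set("ACGT"):
        return False
    return all(
        unit != unit[:d] * (len(unit) // d)
        for d in range(1, len(unit))
        if len(unit) % d == 0
    )


def brute_scan(seq: str, min_units: int = 4):
    """Every maximal perfect tandem array by testing every (start, unit
    length, extension); then the leftmost-longest non-overlap convention.
    Returns [(start, end, canonical, unit_count)] sorted by start."""
    candidates = []
    n = len(seq)
    for u in (2, 3, 4):
        for i in range(n - u + 1):
            unit = seq[i : i + u]
            if not brute_valid_motif(unit):
                continue
            if i >= u and seq[i - u : i] == unit:
                continue  # not leftmost in phase
            count = 1
            while seq[i + count * u : i + (count + 1) * u] == unit:
                count += 1
            if count >= min_units:
                candidates.append((count * u, i, u, unit))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    taken = []
    hits = []
    for span, start, u, unit in candidates:
        end = start + span
        if any(start < te and ts < end for ts, te in taken):
            continue
        taken.append((start, end))
        hits.append((start, end, brute_canonical(unit), span // u))
    return sorted(hits)


def brute_pid(freqs) -> float:
    """P(two unrelated individuals share a genotype) by summing squared
    Hardy-Weinberg genotype probabilities over all unordered genotypes."""
    p = list(freqs)
    k = len(p)
    total = 0.0
    for i, j in combinations_with_replacement(range(k), 2):
        prob = p[i] ** 2 if i == j else 2 * p[i] * p[j]
        total += prob * prob
    return total


def brute_pid_sib(freqs) -> float:
    """P(two full sibs share a genotype) by exhaustive enumeration of
    parental ordered genotypes and sib allele transmissions."""
    p = list(freqs)
    k = len(p)
    total = 0.0
    for ma, mb, fa, fb in product(range(k), repeat=4):
        parent_prob = p[ma] * p[mb] * p[fa] * p[fb]
        child_geno: dict[tuple[int, int], float] = {}
        for from_m, from_f in product((ma, mb), (fa, fb)):
            g = (min(from_m, from_f), max(from_m, from_f))
            child_geno[g] = child_geno.get(g, 0.0) + 0.25
        total += parent_prob * sum(q * q for q in child_geno.values())
    return total


def brute_binding_sites(primer: str, template: str, max_mismatch: int, three_prime_exact: int):
    """Naive per-position site search on both strands.
    Returns [(strand, start, end, mismatches)]."""
    k = len(primer)
    sites = []
    for pos in range(len(template) - k + 1):
        window = template[pos : pos + k]
        mm = sum(1 for a, b in zip(primer, window) if a != b)
        if mm <= max_mismatch and primer[-three_prime_exact:] == window[-three_prime_exact:]:
            sites.append(("+", pos, pos + k, mm))
        rcw = rc(window)
        mm = sum(1 for a, b in zip(primer, rcw) if a != b)
        if mm <= max_mismatch and primer[-three_prime_exact:] == rcw[-three_prime_exact:]:
            sites.append(("-", pos, pos + k, mm))
    return sites


def brute_products(fwd: str, rev: str, template: str, max_mismatch: int,
                   three_prime_exact: int, max_product: int):
    """All facing site combinations of the two primers; returns sorted
    product lengths."""
    f_sites = brute_binding_sites(fwd, template, max_mismatch, three_prime_exact)
    r_sites = brute_binding_sites(rev, template, max_mismatch, three_prime_exact)
    lengths = []
    for a_sites, b_sites in ((f_sites, r_sites), (r_sites, f_sites)):
        for sa in a_sites:
            if sa[0] != "+":
                continue
            for sb in b_sites:
                if sb[0] != "-":
                    continue
                length = sb[2] - sa[1]
                if 0 < length <= max_product:
                    lengths.append(length)
    return sorted(lengths)


def brute_triplet_score(seq: str, window: int) -> float:
    """Max over windows of sum C(c_t, 2) / (n_triplets - 1)."""
    best = 0.0
    for i in range(len(seq) - window + 1):
        w = seq[i : i + window]
        counts: dict[str, int] = {}
        for j in range(len(w) - 2):
            t = w[j : j + 3]
            counts[t] = counts.get(t, 0) + 1
        n = len(w) - 2
        score = sum(c * (c - 1) // 2 for c in counts.values()) / (n - 1)
        best = max(best, score)
    return best
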