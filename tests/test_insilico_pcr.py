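"""In-silico PCR: binding-site search vs a naive per-position oracle, the
3'-exact rule, product enumeration, strand symmetry, monotonicity, and
marker classification."""

import numpy as np
import pytest

from msatmine.insilico_pcr import (
    Amplicon,
    PcrConfig,
    amplify,
    classify_marker,
    find_binding_sites,
)
from msatmine.primer_design import PrimerPair
from msatmine.repeat_scan import revcomp

from oracles import brute_binding_sites, brute_products


def _pair(fwd, rev):
    return PrimerPair(forward=fwd, reverse=rev, fwd_start=0, rev_end=0,
                      tm_f=0, tm_r=0, gc_f=0, gc_r=0)


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def test_planted_primer_found_exactly(rng):
    template = _random_seq(rng, 400)
    primer = template[100:120]
    sites = find_binding_sites(primer, template, max_mismatch=0)
    plus = [s for s in sites if s.strand == "+"]
    assert any(s.start == 100 and s.mismatches == 0 for s in plus)


def test_three_prime_mismatch_blocks_binding(rng):
    template = _random_seq(rng, 200)
    primer = list(template[50:70])
    # internal substitution tolerated
    primer_internal = primer.copy()
    primer_internal[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[primer_internal[5]]
    found = find_binding_sites("".join(primer_internal), template, max_mismatch=1)
    assert any(s.start == 50 for s in found if s.strand == "+")
    # 3'-terminal substitution never binds
    primer_3p = primer.copy()
    primer_3p[-1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[primer_3p[-1]]
    found = find_binding_sites("".join(primer_3p), template, max_mismatch=1)
    assert not any(s.start == 50 for s in found if s.strand == "+")


def test_random_primer_never_hits_random_template(rng):
    """Expected exact-match count for a random 20-mer on 100 kb is
    ~2e5/4^20 ~ 2e-7; across 20 trials zero hits."""
    for _ in range(20):
        template = _random_seq(rng, 100_000)
        primer = _random_seq(rng, 20)
        assert find_binding_sites(primer, template, max_mismatch=0) == []


def test_binding_sites_match_naive_oracle(rng):
    for _ in range(20):
        template = _random_seq(rng, 300)
        # half the trials plant the primer (possibly reverse-complemented)
        primer = _random_seq(rng, 12)
        if rng.random() < 0.7:
            pos = int(rng.integers(0, 280))
            planted = primer if rng.random() < 0.5 else revcomp(primer)
            template = template[:pos] + planted + template[pos + 12 :]
        got = [(s.strand, s.start, s.end, s.mismatches)
               for s in find_binding_sites(primer, template, max_mismatch=2, three_prime_exact=3)]
        assert sorted(got) == sorted(brute_binding_sites(primer, template, 2, 3))


def test_amplify_reproduces_planted_diploid_alleles(rng):
    left = _random_seq(rng, 80)
    right = _random_seq(rng, 80)
    fwd = left[-20:]
    rev = revcomp(right[:20])
    hap1 = _random_seq(rng, 500) + left + "AC" * 10 + right + _random_seq(rng, 500)
    hap2 = _random_seq(rng, 300) + left + "AC" * 12 + right + _random_seq(rng, 700)
    products = amplify(_pair(fwd, rev), {"h1": hap1, "h2": hap2}, max_product=200)
    assert [a.length for a in products["h1"]] == [60]
    assert [a.length for a in products["h2"]] == [64]


def test_amplify_strand_symmetric(rng):
    left, right = _random_seq(rng, 60), _random_seq(rng, 60)
    template = left + "ACAC" * 6 + right
    pair = _pair(left[-20:], revcomp(right[:20]))
    fwd_products = amplify(pair, {"t": template})["t"]
    rev_products = amplify(pair, {"t": revcomp(template)})["t"]
    assert sorted(a.length for a in fwd_products) == sorted(a.length for a in rev_products)


def test_amplify_matches_allpairs_enumeration_oracle(rng):
    """Oracle equivalence with a naive all-pairs site-combination
    enumerator on templates <= 5 kb, including multi-site templates."""
    for _ in range(10):
        template = _random_seq(rng, 2000)
        fwd = _random_seq(rng, 15)
        rev = _random_seq(rng, 15)
        # plant several sites to force multiple products
        for planted in (fwd, revcomp(rev), fwd, revcomp(rev)):
            pos = int(rng.integers(0, 1900))
            template = template[:pos] + planted + template[pos + 15 :]
        got = sorted(
            a.length for a in amplify(_pair(fwd, rev), {"t": template},
                                      max_mismatch=1, max_product=1000)["t"]
        )
        assert got == brute_products(fwd, rev, template, 1, 3, 1000)


def test_mismatch_and_product_monotonicity(rng):
    template = _random_seq(rng, 3000)
    fwd, rev = _random_seq(rng, 16), _random_seq(rng, 16)
    template = template[:500] + fwd + template[516:1200] + revcomp(rev) + template[1216:]
    sites0 = find_binding_sites(fwd, template, max_mismatch=0)
    sites2 = find_binding_sites(fwd, template, max_mismatch=2)
    assert set(sites0) <= set(sites2)
    long_products = amplify(_pair(fwd, rev), {"t": template}, max_product=2000)["t"]
    short_products = amplify(_pair(fwd, rev), {"t": template}, max_product=500)["t"]
    assert set(short_products) <= set(long_products)


def _amp(length):
    return Amplicon("t", 0, length, 0, 0)


def test_classify_marker_statuses():
    assert classify_marker({"i1": [_amp(120)], "i2": [_amp(124)]}).status == "single_product_polymorphic"
    assert classify_marker({"i1": [_amp(120)], "i2": [_amp(120)]}).status == "monomorphic"
    assert classify_marker({"i1": [_amp(120), _amp(412)]}).status == "multiple_products"
    assert classify_marker({"i1": [], "i2": []}).status == "no_product"
    broad = classify_marker({"i1": [_amp(100)], "i2": [_amp(150)]}, PcrConfig(max_size_range=20))
    assert broad.status == "broad_range"
    with pytest.raises(ValueError):
        classify_marker({})


def test_classify_marker_diploid_two_alleles_within_window_not_secondary():
    cfg = PcrConfig(expected_size_window=(110, 140))
    val = classify_marker({"i1": [_amp(120), _amp(124)], "i2": [_amp(120)]}, cfg)
    assert val.status == "single_product_polymorphic"
    # an extra band outside the window is a secondary product
    val = classify_marker({"i1": [_amp(120), _amp(412)], "i2": [_amp(124)]}, cfg)
    assert val.status == "multiple_products"


def test_cross_species_off_size_product_flagged(rng):
    """A distant second binding geometry on another species' template
    yields a product far outside the expected window (the specificity
    signal for contaminating tapir/human DNA)."""
    left, right = _random_seq(rng, 60), _random_seq(rng, 60)
    pair = _pair(left[-20:], revcomp(right[:20]))
    rhino = left + "AC" * 10 + right
    tapir = left[-20:] + _random_seq(rng, 380) + right[:20]
    products = amplify(pair, {"rhino": rhino, "tapir": tapir}, max_product=1000)
    assert [a.length for a in products["rhino"]] == [60]
    assert [a.length for a in products["tapir"]] == [420]
    val = classify_marker(products, PcrConfig(expected_size_window=(50, 80)))
    assert val.status == "broad_range" or val.status == "multiple_products"
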