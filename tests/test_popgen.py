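"""Panel statistics: heterozygosity, F_IS, probability-of-identity
formulas against exhaustive-enumeration oracles, cumulative panel power,
and paired-sample concordance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msatmine.popgen import (
    GenotypeTable,
    MonomorphicLocusError,
    NoDataError,
    allele_frequencies,
    expected_heterozygosity,
    fis,
    genotype_concordance,
    locus_summary,
    observed_heterozygosity,
    panel_power,
    pid,
    pid_sib,
    round_half_up,
)
from msatmine.simdata import degrade_genotypes, simulate_genotype_table

from oracles import brute_pid, brute_pid_sib


def table_from(calls_per_individual, locus="L1"):
    individuals = [f"i{n}" for n in range(1, len(calls_per_individual) + 1)]
    t = GenotypeTable(individuals=individuals, loci=[locus])
    for ind, call in zip(individuals, calls_per_individual):
        t.set_call(ind, locus, call)
    return t


def test_allele_frequencies_counting_and_missing():
    t = table_from([(1, 1), (1, 1), (1, 1), (1, 1), (1, 2)])
    f = allele_frequencies(t, "L1")
    assert f.freqs == {1: 0.9, 2: 0.1}
    assert f.n_typed == 5

    het_only = allele_frequencies(table_from([(1, 2)]), "L1")
    assert het_only.freqs == {1: 0.5, 2: 0.5}

    with_missing = table_from([(1, 1), (1, 2), None, (2, 2), (1, 1), (1, 2)])
    f = allele_frequencies(with_missing, "L1")
    assert f.n_typed == 5  # denominator 10 alleles, not 12
    assert f.freqs[1] == pytest.approx(6 / 10)

    with pytest.raises(NoDataError):
        allele_frequencies(table_from([None, None]), "L1")


def test_observed_heterozygosity():
    assert observed_heterozygosity(
        table_from([(1, 1), (1, 1), (1, 1), (1, 1), (1, 2)]), "L1"
    ) == pytest.approx(0.20)
    assert observed_heterozygosity(table_from([(1, 2), (1, 3), (2, 3)]), "L1") == 1.0
    assert observed_heterozygosity(table_from([(1, 1), (2, 2)]), "L1") == 0.0


def test_expected_heterozygosity_plain_and_unbiased():
    assert expected_heterozygosity([0.5, 0.5]) == pytest.approx(0.5)
    # 9:1 with n=5: (10/9) * (1 - 0.82) = 0.2 exactly
    assert expected_heterozygosity({1: 0.9, 2: 0.1}, unbiased=True, n_typed=5) == pytest.approx(0.2)
    # 4:3:2:1 with n=5: (10/9) * 0.70
    assert expected_heterozygosity(
        [0.4, 0.3, 0.2, 0.1], unbiased=True, n_typed=5
    ) == pytest.approx(10 / 9 * 0.7)
    with pytest.raises(ValueError):
        expected_heterozygosity([0.5, 0.5], unbiased=True)


def test_pid_closed_forms():
    assert pid([0.5, 0.5]) == pytest.approx(0.375)
    assert pid([0.9, 0.1]) == pytest.approx(0.6886)
    assert pid([0.4, 0.3, 0.2, 0.1]) == pytest.approx(0.1446)


def test_pid_sib_closed_forms():
    assert pid_sib([0.5, 0.5]) == pytest.approx(0.59375)
    assert pid_sib([0.9, 0.1]) == pytest.approx(0.83215)
    assert pid_sib([0.4, 0.3, 0.2, 0.1]) == pytest.approx(0.43615)


simplex = st.integers(2, 6).flatmap(
    lambda k: st.lists(st.floats(0.05, 1.0), min_size=k, max_size=k)
)


@given(simplex)
@settings(derandomize=True, max_examples=150)
def test_pid_formulas_match_exhaustive_enumeration(weights):
    """The closed forms equal exhaustive genotype enumeration (unrelated
    pairs) and parental-transmission enumeration (sib pairs)."""
    p = np.array(weights) / np.sum(weights)
    assert pid(p) == pytest.approx(brute_pid(p), abs=1e-12)
    if len(p) <= 4:
        assert pid_sib(p) == pytest.approx(brute_pid_sib(p), abs=1e-12)


@given(simplex)
@settings(derandomize=True, max_examples=150)
def test_pid_sib_dominates_pid(weights):
    p = np.array(weights) / np.sum(weights)
    assert pid_sib(p) >= pid(p)


def test_pid_minimized_at_uniform_frequencies(rng):
    for k in range(2, 7):
        uniform = np.full(k, 1.0 / k)
        base_pid, base_sib = pid(uniform), pid_sib(uniform)
        for _ in range(200):
            w = rng.dirichlet(np.ones(k))
            assert pid(w) >= base_pid - 1e-12
            assert pid_sib(w) >= base_sib - 1e-12


def test_fis_fixed_heterozygote_deficit():
    # polymorphic but zero observed heterozygosity -> F_IS = 1 both ways
    t = table_from([(1, 1), (1, 1), (2, 2), (1, 1), (2, 2)])
    assert fis(t, "L1", "simple") == pytest.approx(1.0)
    assert fis(t, "L1", "weir_cockerham") == pytest.approx(1.0)


def test_fis_near_zero_at_hardy_weinberg(rng):
    freqs = {"L1": {100: 0.5, 104: 0.5}}
    t = simulate_genotype_table(freqs, n_individuals=2000, seed=5)
    assert abs(fis(t, "L1", "simple")) < 0.05
    assert abs(fis(t, "L1", "weir_cockerham")) < 0.05


def test_fis_weir_cockerham_hand_computed_oracle():
    """Genotypes A/A, A/A, B/B, C/C, B/D (n=5).  Per-allele components by
    hand: sum c = 0.2, sum (b+c) = 0.85, f = 1 - 0.2/0.85 = 0.764705...;
    the simple estimator gives 1 - 0.2/0.7778 = 0.742857..."""
    t = table_from([(1, 1), (1, 1), (2, 2), (3, 3), (2, 4)])
    assert fis(t, "L1", "weir_cockerham") == pytest.approx(1 - 0.2 / 0.85, abs=1e-9)
    assert fis(t, "L1", "simple") == pytest.approx(1 - 0.2 / (10 / 9 * 0.7), abs=1e-9)
    assert round_half_up(fis(t, "L1", "weir_cockerham")) == 0.76


def test_fis_negative_for_heterozygote_excess():
    t = table_from([(1, 2), (1, 2), (1, 2), (1, 2)])
    assert fis(t, "L1", "simple") < 0
    assert fis(t, "L1", "weir_cockerham") < 0


def test_fis_undefined_for_monomorphic_locus():
    t = table_from([(1, 1), (1, 1), (1, 1)])
    with pytest.raises(MonomorphicLocusError):
        fis(t, "L1")


def test_locus_summary_reconstructed_marker_rows():
    """Two reconstructed marker configurations: a 9:1 biallelic locus with
    one heterozygote in five, and a 4:3:2:1 four-allele locus; all printed
    statistics reproduce after half-up 2-decimal rounding."""
    biallelic = table_from([(154, 154)] * 4 + [(154, 156)])
    s = locus_summary(biallelic, "L1")
    assert (s.A, round_half_up(s.Ho), round_half_up(s.He_unbiased)) == (2, 0.2, 0.2)
    assert round_half_up(s.PID) == 0.69
    assert round_half_up(s.PIDsib) == 0.83

    four_allele = table_from([(98, 98), (98, 98), (106, 106), (114, 114), (106, 126)])
    s = locus_summary(four_allele, "L1")
    assert (s.A, round_half_up(s.Ho), round_half_up(s.He_unbiased)) == (4, 0.2, 0.78)
    assert round_half_up(s.PID) == 0.14
    assert round_half_up(s.PIDsib) == 0.44
    assert round_half_up(s.Fis_wc) == 0.76


def test_panel_power_brute_force_and_sentinel():
    values = {"a": 0.1, "b": 0.5, "c": 0.2, "d": 0.05}
    power = panel_power(values, threshold=1e-3)
    assert power.ordering == ["d", "a", "c", "b"]
    expected = np.cumprod([0.05, 0.1, 0.2, 0.5])
    assert power.cumulative == pytest.approx(list(expected))
    assert power.min_loci == 4  # 0.05*0.1*0.2 = 1e-3 is not strictly below
    # naive loop oracle
    running, count = 1.0, None
    for i, v in enumerate(sorted(values.values())):
        running *= v
        if running < 1e-3 and count is None:
            count = i + 1
    assert power.min_loci == count

    assert panel_power({"only": 0.5}, threshold=1e-4).min_loci is None
    with pytest.raises(ValueError):
        panel_power(values, threshold=2.0)


def test_statistics_recover_generating_frequencies():
    """n=500 simulated diploids under HWE: H_O, H_E and PID match the
    generating values within 3 standard errors."""
    true = {100: 0.5, 104: 0.3, 108: 0.2}
    t = simulate_genotype_table({"L1": true}, n_individuals=500, seed=42)
    p = np.array(list(true.values()))
    he_true = 1 - np.sum(p**2)
    n = 500
    se_ho = np.sqrt(he_true * (1 - he_true) / n)
    assert abs(observed_heterozygosity(t, "L1") - he_true) < 3 * se_ho
    f = allele_frequencies(t, "L1")
    assert expected_heterozygosity(f) == pytest.approx(he_true, abs=3 * se_ho)
    assert pid(f) == pytest.approx(pid(p), abs=0.05)


def test_concordance_identical_tables():
    t = table_from([(1, 2), (1, 1), (2, 2)])
    rep = genotype_concordance(t, t)
    assert rep.match_rate == 1.0
    assert rep.counts["allelic_dropout"] == 0


def test_concordance_classification_rules():
    a = GenotypeTable(["i1", "i2", "i3", "i4"], ["L1"])
    b = GenotypeTable(["i1", "i2", "i3", "i4"], ["L1"])
    a.set_call("i1", "L1", (120, 124)); b.set_call("i1", "L1", (120, 120))  # dropout
    a.set_call("i2", "L1", (120, 124)); b.set_call("i2", "L1", (120, 128))  # false allele
    a.set_call("i3", "L1", (120, 124)); b.set_call("i3", "L1", (124, 120))  # match
    a.set_call("i4", "L1", (120, 120)); b.set_call("i4", "L1", None)        # skipped
    rep = genotype_concordance(a, b)
    assert rep.n_compared == 3
    assert rep.counts == {"match": 1, "allelic_dropout": 1, "false_allele": 1, "other_mismatch": 0}


def test_concordance_requires_overlap():
    a = GenotypeTable(["i1"], ["L1"], {("i1", "L1"): (1, 2)})
    b = GenotypeTable(["i2"], ["L1"], {("i2", "L1"): (1, 2)})
    with pytest.raises(NoDataError):
        genotype_concordance(a, b)


def test_concordance_recovers_simulated_error_rates():
    """Closed loop: degrade 10^4 calls at known dropout/false-allele rates
    and recover both within their binomial 95% CIs."""
    from scipy.stats import binom

    freqs = {f"L{j}": {100: 0.5, 104: 0.5} for j in range(20)}
    clean = simulate_genotype_table(freqs, n_individuals=500, seed=7)
    dirty = degrade_genotypes(clean, dropout_rate=0.2, false_allele_rate=0.05, seed=8)
    rep = genotype_concordance(clean, dirty)
    assert rep.n_compared == 10_000

    lo, hi = binom.ppf([0.025, 0.975], rep.n_het_in_a, 0.2) / rep.n_het_in_a
    assert lo <= rep.dropout_rate <= hi
    lo, hi = binom.ppf([0.025, 0.975], rep.n_compared, 0.05) / rep.n_compared
    assert lo <= rep.false_allele_rate <= hi


def test_round_half_up_display_convention():
    assert round_half_up(0.125) == 0.13
    assert round_half_up(0.6886) == 0.69
    assert round_half_up(-0.145) == -0.15
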