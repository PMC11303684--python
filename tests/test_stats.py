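import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from chitosim import (
    ChainPopulation,
    ChitosanChain,
    Fragment,
    FragmentSet,
    GeneratorParams,
    PRESETS,
    analytic_aachio_mean_dp,
    analytic_aachio_pmf,
    block_sizes_direct,
    block_sizes_from_profile,
    composition_profile,
    diad_triad_frequencies,
    digest_population,
    dp_distribution,
    generate_patterned,
    generate_random,
    make_ideal_repeat,
    pa_value,
    population_pattern_stats,
    triad_strength,
)


def frag_set_from(*seqs: str) -> FragmentSet:
    frags = [Fragment(ChitosanChain.from_string(s).units) for s in seqs]
    total = sum(f.dp for f in frags)
    return FragmentSet(frags, n_bonds_total=total - 1, n_bonds_cut=len(frags) - 1)


def test_dp_distribution_molar_and_mass():
    fs = frag_set_from("DA", "ADA", "DDA")
    molar = dp_distribution(fs, "molar").relative
    assert molar[2] == pytest.approx(1 / 3)
    assert molar[3] == pytest.approx(2 / 3)
    mass = dp_distribution(fs, "mass").relative
    assert mass[2] == pytest.approx(0.25)
    assert mass[3] == pytest.approx(0.75)
    with pytest.raises(ValueError):
        dp_distribution(FragmentSet([], 0, 0))
    with pytest.raises(ValueError):
        dp_distribution(fs, "ri")


def test_triad_strength_examples():
    assert triad_strength({2: 1, 3: 1, 4: 1, 5: 1, 6: 1}) == pytest.approx(2 / 3)
    assert triad_strength({2: 1, 3: 3, 4: 1, 5: 0, 6: 1}) == pytest.approx(2.0)
    # DPs outside 2..6 are ignored
    assert triad_strength({1: 99, 2: 1, 3: 1, 4: 1, 5: 1, 6: 1, 7: 99}) == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        triad_strength({3: 5, 6: 2})


def test_triad_strength_of_random_digest_matches_closed_form():
    dist = analytic_aachio_pmf(0.5)
    assert triad_strength(dist) == pytest.approx((0.25 + 0.078125) / (0.25 + 0.1875 + 0.125))


def test_composition_profile():
    prof = composition_profile(frag_set_from("DA", "ADA", "DDA"))
    assert prof.counts == {(1, 1): 1.0, (2, 1): 1.0, (1, 2): 1.0}
    assert prof.total_units == 8
    # M counts as D
    prof = composition_profile(frag_set_from("DM"))
    assert prof.counts == {(0, 2): 1.0}


def test_block_sizes_from_profile_examples():
    prof = composition_profile(frag_set_from("DA", "ADA", "DDA"))
    assert block_sizes_from_profile(prof) == (pytest.approx(4 / 3), pytest.approx(4 / 3))
    # ideal (DDA) digest: pure (1,2) products
    pop = ChainPopulation([make_ideal_repeat("DDA", 999)])
    prof = composition_profile(digest_population(pop, PRESETS["AaChio"]))
    assert block_sizes_from_profile(prof) == (pytest.approx(1, abs=0.01),
                                              pytest.approx(2, abs=0.01))


def test_block_sizes_direct_examples():
    pop = ChainPopulation([ChitosanChain.from_string("DAADADDA")])
    assert block_sizes_direct(pop) == (pytest.approx(4 / 3), pytest.approx(4 / 3))
    pop = ChainPopulation([make_ideal_repeat("DDA", 9)])
    assert block_sizes_direct(pop) == (1.0, 2.0)
    mean_a, mean_d = block_sizes_direct(ChainPopulation([make_ideal_repeat("A", 5)]))
    assert mean_a == 5.0 and mean_d is None


@pytest.mark.parametrize("s", [0.0, 0.5])
def test_block_size_estimator_agrees_with_run_lengths(random_pop_032, s):
    """Profile-based block sizes track the direct run-length oracle (2%)."""
    if s == 0.0:
        pop = random_pop_032
    else:
        pop = generate_patterned(GeneratorParams(500, 1000, 0.32, s=s, seed=13))
    prof = composition_profile(digest_population(pop, PRESETS["AaChio"]))
    a_prof, d_prof = block_sizes_from_profile(prof)
    a_dir, d_dir = block_sizes_direct(pop)
    assert a_prof == pytest.approx(a_dir, rel=0.02)
    assert d_prof == pytest.approx(d_dir, rel=0.02)


def test_random_block_sizes_follow_geometric_law(random_pop_032):
    mean_a, mean_d = block_sizes_direct(random_pop_032)
    assert mean_a == pytest.approx(1 / 0.68, rel=0.02)
    assert mean_d == pytest.approx(1 / 0.32, rel=0.02)


def test_diad_triad_hand_counts():
    stats = diad_triad_frequencies(ChainPopulation([ChitosanChain.from_string("ADADAD")]))
    assert stats.diads == pytest.approx({"AD": 3 / 5, "DA": 2 / 5, "AA": 0, "DD": 0})
    stats = diad_triad_frequencies(ChainPopulation([ChitosanChain.from_string("AAAA")]))
    assert stats.diads["AA"] == 1.0
    stats = diad_triad_frequencies(ChainPopulation([ChitosanChain.from_string("DDADDA")]))
    assert stats.triads["DDA"] == pytest.approx(2 / 4)
    assert stats.triads["DAD"] == pytest.approx(1 / 4)
    assert stats.triads["ADD"] == pytest.approx(1 / 4)
    with pytest.raises(ValueError):
        diad_triad_frequencies(ChainPopulation([ChitosanChain.from_string("A")]))


def test_pa_value_anchors(dda_pop):
    # alternating → exactly 2 for any n
    for n in (2, 10, 1000):
        stats = diad_triad_frequencies(ChainPopulation([make_ideal_repeat("AD", n)]))
        assert pa_value(stats) == pytest.approx(2.0)
    # block-wise mixture → exactly 0
    mix = ChainPopulation(
        [make_ideal_repeat("A", 100, id=f"a{i}") for i in range(5)]
        + [make_ideal_repeat("D", 100, id=f"d{i}") for i in range(5)]
    )
    assert pa_value(diad_triad_frequencies(mix)) == 0.0
    # ideal (DDA) → 1.5 up to O(1/DP)
    assert pa_value(diad_triad_frequencies(dda_pop)) == pytest.approx(1.5, abs=0.01)
    # homopolymer → undefined
    with pytest.raises(ValueError):
        pa_value(diad_triad_frequencies(ChainPopulation([make_ideal_repeat("A", 10)])))


def test_pa_monotone_in_pattern_strength():
    """PA and triad strength rise with s at FA 0.32 (up to sampling error)."""
    pas, tss = [], []
    for i, s in enumerate((0.0, 0.25, 0.5, 0.75, 1.0)):
        pop = generate_patterned(GeneratorParams(300, 999, 0.32, s=s, seed=40 + i))
        pas.append(pa_value(diad_triad_frequencies(pop)))
        dist = dp_distribution(digest_population(pop, PRESETS["AaChio"]))
        tss.append(triad_strength(dist))
    eps = 0.01
    assert all(b > a - eps for a, b in zip(pas[:-1], pas[1:]))
    assert all(b > a for a, b in zip(tss[:-1], tss[1:]))


@given(st.lists(st.text(alphabet="AD", min_size=2, max_size=40), min_size=1, max_size=8))
def test_diad_stationarity(seqs):
    """|F_AD − F_DA| ≤ n_chains / total diads: each chain contributes at most
    one excess transition."""
    pop = ChainPopulation([ChitosanChain.from_string(s) for s in seqs])
    stats = diad_triad_frequencies(pop)
    total_diads = sum(c.dp - 1 for c in pop)
    assert abs(stats.diads["AD"] - stats.diads["DA"]) <= len(seqs) / total_diads + 1e-12


def brute_force_interior_pmf(fa: float, max_dp: int) -> dict[int, float]:
    """Enumerate interior DA|XX fragments A^x D^y A directly."""
    q = 1.0 - fa
    pmf: dict[int, float] = {}
    for n in range(2, max_dp + 1):
        total = 0.0
        for x in range(0, n - 1):
            y = n - 1 - x
            if y >= 1:
                total += fa**x * q**y * fa  # x leading As, y Ds, terminal A
        pmf[n] = total
    return pmf


@pytest.mark.parametrize("fa", [0.2, 0.32, 0.5])
def test_analytic_pmf_matches_enumeration_and_sums_to_one(fa):
    dist = analytic_aachio_pmf(fa, max_dp=40)
    brute = brute_force_interior_pmf(fa, 40)
    for n in range(2, 21):
        assert dist.get(n) == pytest.approx(brute[n], abs=1e-12)
    big = analytic_aachio_pmf(fa, max_dp=400)
    assert big.counts.sum() == pytest.approx(1.0, abs=1e-9)
    mean = float((big.counts * big.counts.index).sum())
    assert mean == pytest.approx(analytic_aachio_mean_dp(fa), rel=1e-6)


def test_analytic_pmf_values_at_half():
    dist = analytic_aachio_pmf(0.5)
    assert dist.get(2) == pytest.approx(0.25)
    assert dist.get(3) == pytest.approx(0.25)
    assert dist.get(4) == pytest.approx(0.1875)
    with pytest.raises(ValueError):
        analytic_aachio_pmf(0.0)


def test_simulated_digest_matches_analytic_oracle(random_pop_032):
    """Empirical DA|XX fragment-DP law vs the closed form (dev < 0.01)."""
    frag_set = digest_population(random_pop_032, PRESETS["AaChio"])
    emp = dp_distribution(frag_set).relative
    ana = analytic_aachio_pmf(0.32, max_dp=40).relative
    for n in range(2, 21):
        assert abs(float(emp.get(n, 0.0)) - float(ana.get(n, 0.0))) < 0.01
    mean_emp = frag_set.total_units / len(frag_set)
    assert mean_emp == pytest.approx(analytic_aachio_mean_dp(0.32), rel=0.01)


def test_population_pattern_stats_bundle(random_pop_032):
    stats = population_pattern_stats(random_pop_032)
    assert stats.pa == pytest.approx(1.0, abs=0.01)
    assert stats.fa_observed == pytest.approx(0.32, abs=0.005)
    assert stats.mean_d_block == pytest.approx(1 / 0.32, rel=0.02)
    assert sum(stats.triads.values()) == pytest.approx(1.0)
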