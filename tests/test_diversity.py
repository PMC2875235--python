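"""Diversity statistics and neutrality tests against independent oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest

from mthaplopop.diversity import (
    compute_diversity,
    fus_fs,
    haplotype_diversity,
    mean_pairwise_differences,
    neutrality_pvalues,
    stirling1_unsigned,
    tajimas_d,
)
from mthaplopop.notation import DistancePolicy, HVRI
from mthaplopop.simulate import simulate_coalescent_sample


# ---------------------------------------------------------------------------
# haplotype diversity
# ---------------------------------------------------------------------------

def test_haplotype_diversity_examples():
    h, _ = haplotype_diversity([2, 2])
    assert h == pytest.approx(2 / 3, abs=1e-12)  # (4/3)(1 - 1/2)
    n = 10
    h, _ = haplotype_diversity([1] * n)
    assert h == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        haplotype_diversity([1])


def test_haplotype_diversity_order_invariance():
    a = haplotype_diversity([5, 3, 2, 1, 1])
    b = haplotype_diversity([1, 2, 1, 3, 5])
    assert a == b


# ---------------------------------------------------------------------------
# mean pairwise differences
# ---------------------------------------------------------------------------

def test_mpd_trivial_cases():
    haps = simulate_coalescent_sample(4, S=0, seed=0)
    mpd, _, s = mean_pairwise_differences(haps)
    assert (mpd, s) == (0.0, 0)

    two = simulate_coalescent_sample(2, S=3, seed=1)
    mpd, _, s = mean_pairwise_differences(two)
    assert mpd == 3.0 and s == 3


def test_mpd_reorder_invariance(eljadida, policy):
    mpd_a, _, s_a = mean_pairwise_differences(eljadida, policy)
    rev = list(reversed(eljadida))
    mpd_b, _, s_b = mean_pairwise_differences(rev, policy)
    assert mpd_a == mpd_b and s_a == s_b


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def _tajima_oracle(S, mpd, n):
    # independent direct transcription of the textbook constants
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    var = (c1 / a1) * S + (c2 / (a1**2 + a2)) * S * (S - 1)
    return (mpd - S / a1) / np.sqrt(var)


def test_tajimas_d_matches_oracle_on_random_triples():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(4, 200))
        S = int(rng.integers(1, 100))
        mpd = float(rng.uniform(0, 20))
        assert tajimas_d(S, mpd, n) == pytest.approx(_tajima_oracle(S, mpd, n), abs=1e-9)


def test_tajimas_d_zero_when_mpd_equals_watterson():
    n, S = 10, 5
    a1 = sum(1 / i for i in range(1, n))
    assert tajimas_d(S, S / a1, n) == pytest.approx(0.0, abs=1e-12)


def test_tajimas_d_undefined_without_segregating_sites():
    assert math.isnan(tajimas_d(0, 0.0, 10))


# ---------------------------------------------------------------------------
# Fu's Fs
# ---------------------------------------------------------------------------

def _ewens_tail_oracle(n, k_obs, theta: Fraction) -> Fraction:
    """Pr(K >= k_obs) by summing the Ewens sampling formula over all
    integer partitions of n -- an enumeration completely independent of the
    Stirling-number route."""
    from sympy.utilities.iterables import partitions

    rising = Fraction(1)
    for i in range(n):
        rising *= theta + i
    total = Fraction(0)
    for part in partitions(n):
        k = sum(part.values())
        if k < k_obs:
            continue
        prob = Fraction(math.factorial(n)) / rising
        for j, a_j in part.items():
            prob *= (theta / j) ** a_j / math.factorial(a_j)
        total += prob
    return total


@pytest.mark.parametrize("n,k_obs,theta", [(4, 4, 1), (5, 3, 2), (6, 4, Fraction(7, 2)),
                                           (7, 2, Fraction(1, 3)), (8, 6, 5)])
def test_fus_fs_matches_partition_enumeration(n, k_obs, theta):
    sp = _ewens_tail_oracle(n, k_obs, Fraction(theta))
    expected = math.log(Fraction(sp) / (1 - Fraction(sp)))
    assert fus_fs(n, k_obs, float(theta)) == pytest.approx(expected, abs=1e-9)


def test_fus_fs_closed_form_small_case():
    # |s(4, k)| = 6, 11, 6, 1; theta=1 => S' = 1/24, Fs = ln(1/23)
    assert stirling1_unsigned(4) == (0, 6, 11, 6, 1)
    assert fus_fs(4, 4, 1.0) == pytest.approx(math.log(1 / 23), abs=1e-12)


def test_fus_fs_k1_is_certain():
    assert fus_fs(10, 1, 2.0) == math.inf


def test_fus_fs_input_validation():
    with pytest.raises(ValueError):
        fus_fs(1, 1, 1.0)
    with pytest.raises(ValueError):
        fus_fs(10, 11, 1.0)
    with pytest.raises(ValueError):
        fus_fs(10, 5, 0.0)


def test_stirling_row_recurrence_against_sympy():
    from sympy.functions.combinatorial.numbers import stirling

    for n in (5, 12, 30):
        row = stirling1_unsigned(n)
        for k in range(n + 1):
            assert row[k] == stirling(n, k, kind=1, signed=False)


# ---------------------------------------------------------------------------
# simulation p-values
# ---------------------------------------------------------------------------

def test_pvalues_deterministic_under_seed():
    a = neutrality_pvalues(20, 10, -1.5, -5.0, reps=200, seed=7)
    b = neutrality_pvalues(20, 10, -1.5, -5.0, reps=200, seed=7)
    assert a == b


def test_pvalue_of_null_median_is_central():
    # D_obs at the null median should give p around 0.5
    n, S = 25, 12
    pv = neutrality_pvalues(n, S, 0.0, 0.0, reps=400, seed=3)
    # D=0 sits near the centre of the neutral distribution
    assert 0.25 < pv.p_D < 0.75


# ---------------------------------------------------------------------------
# end-to-end summary
# ---------------------------------------------------------------------------

def test_compute_diversity_pi_consistency(eljadida, policy):
    res = compute_diversity(eljadida, policy)
    assert res.pi == pytest.approx(res.mpd / res.window_length, rel=1e-12)
    assert res.k <= res.n
    assert 0 <= res.H <= 1
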