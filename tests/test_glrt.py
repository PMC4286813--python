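"""The randomization GLRT: statistic, p-values, exact oracle and calibration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from rootstage import (
    ValidationError,
    calibrate,
    exact_pvalue,
    glr_statistic,
    multinomial_loglik_kernel,
    randomization_test,
)
from rootstage.glrt import StateSpaceTooLarge


def pad(levels):
    return list(levels) + [0] * (8 - len(levels))


# --- log-likelihood kernel ------------------------------------------------

def test_kernel_hand_value():
    ll = multinomial_loglik_kernel(pad([1, 1]), pad([0.5, 0.5]))
    assert ll == pytest.approx(math.log(0.25), abs=1e-12)


def test_kernel_zero_counts_and_impossible_observation():
    assert multinomial_loglik_kernel([0] * 8, pad([1.0])) == 0.0
    with pytest.raises(ValidationError):
        multinomial_loglik_kernel(pad([2]), pad([0.0, 1.0]))


# --- G statistic -----------------------------------------------------------

def test_statistic_zero_for_identical_tables():
    t, pooled = glr_statistic(pad([5, 5]), pad([5, 5]))
    assert t == 0.0
    assert pooled.sum() == pytest.approx(1.0)


def test_statistic_disjoint_support_closed_form():
    # 2x2 table with E = 5 everywhere: T = 2 * 4 * 10 ln 2 / 2 = 40 ln 2
    t, _ = glr_statistic(pad([10, 0]), pad([0, 10]))
    assert t == pytest.approx(40 * math.log(2), abs=1e-10)


def test_statistic_matches_scipy_g_test(rng):
    """Independent oracle: scipy's log-likelihood-ratio contingency statistic."""
    for _ in range(300):
        k = rng.integers(2, 9)
        probs = rng.dirichlet(np.ones(k))
        a = np.zeros(8, dtype=int)
        b = np.zeros(8, dtype=int)
        a[:k] = rng.multinomial(int(rng.integers(1, 60)), probs)
        b[:k] = rng.multinomial(int(rng.integers(1, 60)), probs)
        t, _ = glr_statistic(a, b)
        table = np.vstack([a, b])
        table = table[:, table.sum(axis=0) > 0]
        ref = stats.chi2_contingency(table, correction=False, lambda_="log-likelihood")
        assert t == pytest.approx(ref.statistic, abs=1e-10)


@given(
    st.lists(st.integers(0, 20), min_size=8, max_size=8).filter(lambda c: sum(c) > 0),
    st.integers(1, 5),
)
def test_statistic_zero_iff_equal_frequencies(counts, k):
    t, _ = glr_statistic(counts, [k * c for c in counts])
    assert t == pytest.approx(0.0, abs=1e-10)


@given(
    st.lists(st.integers(0, 15), min_size=8, max_size=8).filter(lambda c: sum(c) > 0),
    st.lists(st.integers(0, 15), min_size=8, max_size=8).filter(lambda c: sum(c) > 0),
)
def test_statistic_nonnegative_and_symmetric(a, b):
    t_ab, _ = glr_statistic(a, b)
    t_ba, _ = glr_statistic(b, a)
    assert t_ab >= 0.0
    assert t_ab == pytest.approx(t_ba, abs=1e-10)


def test_statistic_label_invariance(rng):
    a = rng.multinomial(40, np.full(8, 1 / 8))
    b = rng.multinomial(30, np.full(8, 1 / 8))
    t, _ = glr_statistic(a, b)
    perm = rng.permutation(8)
    t_perm, _ = glr_statistic(a[perm], b[perm])
    assert t == pytest.approx(t_perm, abs=1e-10)


def test_statistic_requires_nonempty_groups():
    with pytest.raises(ValidationError):
        glr_statistic([0] * 8, pad([3]))


# --- randomization test ----------------------------------------------------

def test_randomization_degenerate_null_p_is_one():
    res = randomization_test(pad([3, 3, 3]), pad([3, 3, 3]), B=500, seed=4)
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_randomization_extreme_table_small_p():
    res = randomization_test(pad([10, 0]), pad([0, 10]), B=10_000, seed=1)
    assert res.p_value <= 0.001


def test_randomization_determinism():
    a, b = pad([4, 2, 1]), pad([1, 2, 4])
    r1 = randomization_test(a, b, B=200, seed=7)
    r2 = randomization_test(a, b, B=200, seed=7)
    assert r1.p_value == r2.p_value
    assert np.array_equal(r1.null_statistics, r2.null_statistics)
    r3 = randomization_test(a, b, B=200, seed=8)
    assert not np.array_equal(r1.null_statistics, r3.null_statistics)


def test_tie_rules_consistent():
    a, b = pad([4, 2, 1]), pad([1, 2, 4])
    geq = randomization_test(a, b, B=1000, seed=3, tie_rule="geq")
    strict = randomization_test(a, b, B=1000, seed=3, tie_rule="strict")
    plus = randomization_test(a, b, B=1000, seed=3, tie_rule="plus_one")
    assert strict.p_value <= geq.p_value
    assert plus.p_value == pytest.approx((1 + geq.p_value * 1000) / 1001)


def test_randomization_rejects_tiny_b():
    with pytest.raises(ValidationError):
        randomization_test(pad([2, 1]), pad([1, 2]), B=10, seed=0)


def test_result_summary_and_row():
    res = randomization_test(pad([4, 2]), pad([2, 4]), B=500, seed=0)
    assert "G statistic" in res.summary()
    row = res.to_row()
    assert row["B"] == 500 and 0 <= row["p_value"] <= 1


# --- exact enumeration oracle ----------------------------------------------

def brute_force_exact(a, b):
    """Independent enumeration: itertools over per-level counts, scipy pmf."""
    a, b = np.asarray(a), np.asarray(b)
    n_a, n_b = a.sum(), b.sum()
    t_obs, pooled = glr_statistic(a, b)
    active = np.flatnonzero(pooled > 0)
    p = pooled[active]

    def outcomes(n):
        for combo in itertools.product(range(n + 1), repeat=len(active) - 1):
            if sum(combo) <= n:
                yield np.array(list(combo) + [n - sum(combo)])

    total = 0.0
    for xa in outcomes(int(n_a)):
        pa = stats.multinomial.pmf(xa, int(n_a), p)
        for xb in outcomes(int(n_b)):
            fa, fb = np.zeros(8, dtype=int), np.zeros(8, dtype=int)
            fa[active], fb[active] = xa, xb
            t, _ = glr_statistic(fa, fb) if xa.sum() and xb.sum() else (0.0, None)
            if t >= t_obs - 1e-9 * max(1.0, t_obs):
                total += pa * stats.multinomial.pmf(xb, int(n_b), p)
    return total


@pytest.mark.parametrize(
    "a,b",
    [
        (pad([3, 0]), pad([0, 3])),
        (pad([2, 2]), pad([2, 2])),
        (pad([3, 1, 0]), pad([0, 1, 3])),
    ],
)
def test_exact_pvalue_against_independent_enumeration(a, b):
    assert exact_pvalue(a, b) == pytest.approx(brute_force_exact(a, b), abs=1e-12)


def test_exact_pvalue_degenerate_statistic():
    assert exact_pvalue(pad([2, 2]), pad([2, 2])) == pytest.approx(1.0)


def test_exact_pvalue_refuses_large_state_space():
    with pytest.raises(StateSpaceTooLarge):
        exact_pvalue(pad([30, 30, 30, 30]), pad([30, 30, 30, 30]), max_states=100)


def test_exact_pvalue_invariant_under_group_swap():
    a, b = pad([4, 1, 0]), pad([1, 2, 2])
    assert exact_pvalue(a, b) == pytest.approx(exact_pvalue(b, a), abs=1e-12)


def test_randomization_converges_to_exact():
    a, b = pad([3, 2]), pad([0, 5])
    pe = exact_pvalue(a, b)
    for B in (1000, 10_000):
        pr = randomization_test(a, b, B=B, seed=12).p_value
        bound = 4 * math.sqrt(pe * (1 - pe) / B)
        assert abs(pr - pe) <= bound


# --- calibration -----------------------------------------------------------

def test_calibrate_alt_equals_null_regimes():
    probs = pad([0.25, 0.25, 0.25, 0.25])
    null = calibrate(probs, 30, 30, reps=30, B=1000, seed=5)
    alt = calibrate(probs, 30, 30, alt_probs=probs, reps=30, B=1000, seed=5)
    assert null.regime == "null" and alt.regime == "alternative"
    assert null.rejection_rate == alt.rejection_rate  # identical draws, same seed


def test_calibrate_report_invariants():
    rep = calibrate(pad([0.5, 0.5]), 20, 20, reps=40, B=1000, seed=6)
    lo, hi = rep.binom_ci95
    assert 0 <= lo <= rep.rejection_rate <= hi <= 1


def test_power_increases_with_effect_size():
    null = np.array(pad([0.25, 0.25, 0.25, 0.25]))
    rates = []
    for shift in (0.0, 0.1, 0.2):
        alt = null.copy()
        alt[0] += shift
        alt[3] = 0.25 - shift
        rep = calibrate(null, 60, 60, alt_probs=alt, reps=60, B=1000, seed=9)
        rates.append(rep.rejection_rate)
    assert rates[0] < rates[1] < rates[2]
    assert rates[2] > 0.9
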