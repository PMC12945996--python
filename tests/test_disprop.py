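"""Disproportionality statistics against hand computations and oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from tpopv.disprop import (ContingencyTable, association_test,
                           bcpnn_posterior_mc, build_contingency,
                           classify_tier, compute_bcpnn, compute_prr,
                           compute_ror, compute_signal_stats, gate_signal,
                           scan_all_signals)
from tests.conftest import tiny_clean

cells = st.integers(min_value=1, max_value=500)


# --- contingency construction ---------------------------------------------

def test_build_contingency_enumeration():
    clean = tiny_clean(
        [("1", "D", "target"), ("2", "D", "target"),
         ("3", None, "background"), ("4", None, "background")],
        [("1", "Pulmonary embolism", "venous"),
         ("3", "Pulmonary embolism", "venous")])
    t = build_contingency(clean, "D", "Pulmonary embolism")
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)


def test_build_contingency_category_level():
    clean = tiny_clean(
        [("1", "D", "target"), ("2", "D", "target"), ("3", None, "background")],
        [("1", "Pulmonary embolism", "venous"),
         ("2", "Deep vein thrombosis", "venous")])
    t = build_contingency(clean, "D", "venous")
    assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 1)


def test_build_contingency_empty_dataset_errors():
    clean = tiny_clean([], [])
    with pytest.raises(ValueError):
        build_contingency(clean, "D", "Pulmonary embolism")


def test_build_contingency_absent_drug_flagged():
    clean = tiny_clean([("1", None, "background")],
                       [("1", "Pulmonary embolism", "venous")])
    t = build_contingency(clean, "Nonexistent", "Pulmonary embolism")
    assert t.a == 0 and t.b == 0


def test_repeated_pt_rows_count_once():
    clean = tiny_clean(
        [("1", "D", "target"), ("2", None, "background")],
        [("1", "Pulmonary embolism", "venous"),
         ("1", "Pulmonary embolism", "venous")])
    t = build_contingency(clean, "D", "Pulmonary embolism")
    assert t.a == 1


def test_cells_match_ground_truth_tallies(clean_planted, planted_dataset):
    """Generator bookkeeping is an exact oracle for the a-cell."""
    truth = planted_dataset.truth.cases
    tpo = {"Avatrombopag", "Eltrombopag", "Romiplostim"}
    analysed = clean_planted.analysis_cases
    t = build_contingency(clean_planted, "Avatrombopag", "Deep vein thrombosis")
    expect_a = truth[(truth.drug == "Avatrombopag") & (truth.role == "PS")
                     & truth.smq_pts.str.contains("Deep vein thrombosis")]
    assert t.a == len(expect_a)
    assert t.n == len(analysed)


# --- ROR -------------------------------------------------------------------

def test_ror_symmetric_about_one():
    ror, lo, hi = compute_ror(ContingencyTable(10, 10, 10, 10))
    assert ror == 1.0
    assert lo * hi == pytest.approx(1.0)


def test_ror_hand_example():
    ror, lo, hi = compute_ror(ContingencyTable(10, 20, 30, 240))
    assert ror == pytest.approx(4.0)
    se = math.sqrt(1 / 10 + 1 / 20 + 1 / 30 + 1 / 240)
    assert lo == pytest.approx(4.0 * math.exp(-1.959963984540054 * se))
    assert hi == pytest.approx(4.0 * math.exp(+1.959963984540054 * se))


def test_ror_published_style_counts_round_to_2dp():
    ror, _, _ = compute_ror(ContingencyTable(4812, 27788, 143, 4011))
    assert round(ror, 2) == 4.86


def test_ror_zero_cell_undefined_and_not_positive():
    t = ContingencyTable(5, 0, 3, 10)
    ror, lo, hi = compute_ror(t)
    assert np.isnan(ror) and np.isnan(lo)
    stats = compute_signal_stats(t)
    assert not stats.positive_ror and not stats.positive_all


@given(cells, cells, cells, cells)
def test_ror_transposition_inverts(a, b, c, d):
    ror, _, _ = compute_ror(ContingencyTable(a, b, c, d))
    swapped, _, _ = compute_ror(ContingencyTable(c, d, a, b))
    assert swapped == pytest.approx(1.0 / ror)


# --- PRR and chi-square ----------------------------------------------------

def test_prr_independence():
    prr, lo, hi, chi2 = compute_prr(ContingencyTable(10, 90, 20, 180))
    assert prr == pytest.approx(1.0)
    assert chi2 == pytest.approx(0.0)


def test_prr_hand_example():
    prr, _, _, chi2 = compute_prr(ContingencyTable(10, 90, 10, 890))
    assert prr == pytest.approx(9.0)
    # independent Pearson sum over (O-E)^2/E
    obs = np.array([[10, 90], [10, 890]])
    exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    assert chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum())


@given(cells, cells, cells, cells)
def test_chi2_matches_scipy(a, b, c, d):
    _, _, _, chi2 = compute_prr(ContingencyTable(a, b, c, d))
    ref = sps.chi2_contingency([[a, b], [c, d]], correction=False)[0]
    assert chi2 == pytest.approx(ref, rel=1e-10)


def test_prr_zero_c_undefined():
    prr, lo, hi, _ = compute_prr(ContingencyTable(5, 5, 0, 10))
    assert np.isnan(prr)


@given(cells, cells, cells, cells)
def test_ror_at_least_prr_when_positive(a, b, c, d):
    ror, _, _ = compute_ror(ContingencyTable(a, b, c, d))
    prr, _, _, _ = compute_prr(ContingencyTable(a, b, c, d))
    if ror > 1:
        assert ror >= prr - 1e-12


# --- BCPNN -----------------------------------------------------------------

def test_bcpnn_independence_limit():
    e_ic, v_ic, _ = compute_bcpnn(ContingencyTable(100, 900, 900, 8100))
    assert abs(e_ic) < 0.05
    assert v_ic > 0


def test_bcpnn_closed_form_example():
    e_ic, v_ic, ic2sd = compute_bcpnn(ContingencyTable(25, 75, 75, 825))
    assert e_ic == pytest.approx(1.22, abs=0.005)
    assert ic2sd == pytest.approx(e_ic - 2 * math.sqrt(v_ic))


def test_bcpnn_monte_carlo_agreement():
    e_ic, _, _ = compute_bcpnn(ContingencyTable(25, 75, 75, 825))
    mc = bcpnn_posterior_mc(ContingencyTable(25, 75, 75, 825),
                            n_draws=400_000, rng=0)
    assert mc == pytest.approx(e_ic, abs=0.02)


bulk_cells = st.integers(min_value=10, max_value=500)


@given(bulk_cells, bulk_cells, bulk_cells, bulk_cells)
def test_bcpnn_shrinks_toward_zero(a, b, c, d):
    """Away from the tiny-count regime (all cells >= 10, where the
    independence-calibrated prior can dominate), E(IC) never exceeds the
    raw observed-vs-expected information by more than a small margin."""
    t = ContingencyTable(a, b, c, d)
    e_ic, _, _ = compute_bcpnn(t)
    raw_ic = math.log2(a * t.n / ((a + b) * (a + c)))
    assert abs(e_ic) <= abs(raw_ic) + 0.1


@given(cells, cells, cells, cells)
def test_bcpnn_converges_to_raw_ic_with_scale(a, b, c, d):
    """Scaling every cell by 1000 drives E(IC) to the raw information
    component of the original proportions (the prior washes out)."""
    k = 1000
    big = ContingencyTable(a * k, b * k, c * k, d * k)
    e_ic, _, _ = compute_bcpnn(big)
    raw_ic = math.log2(a * (a + b + c + d) / ((a + b) * (a + c)))
    assert abs(e_ic - raw_ic) <= 0.02 + 0.03 * abs(raw_ic)


@pytest.mark.parametrize("k", [10, 100, 1000])
def test_bcpnn_variance_vanishes_with_scale(k):
    base = ContingencyTable(5, 20, 30, 100)
    big = ContingencyTable(5 * k, 20 * k, 30 * k, 100 * k)
    _, v_base, _ = compute_bcpnn(base)
    _, v_big, _ = compute_bcpnn(big)
    assert v_big < v_base
    assert v_big < 10.0 / k


# --- tiers and gate --------------------------------------------------------

@pytest.mark.parametrize("e_ic,tier", [
    (-0.5, "-"), (0.0, "-"), (0.4, "+"), (1.5, "+"),
    (1.51, "++"), (3.0, "++"), (3.2, "+++")])
def test_tier_thresholds(e_ic, tier):
    assert classify_tier(e_ic) == tier


def test_gate_requires_a_at_least_3():
    t = ContingencyTable(2, 1, 1, 1000)  # huge ROR but a=2
    s = compute_signal_stats(t)
    assert s.ror > 100
    assert not s.positive_ror and not s.positive_all


def test_gate_independence_all_false():
    s = compute_signal_stats(ContingencyTable(50, 450, 100, 900))
    assert not (s.positive_ror or s.positive_prr or s.positive_bcpnn)


def test_gate_conservative_bcpnn_option():
    t = ContingencyTable(4, 96, 100, 9800)
    s_e = compute_signal_stats(t, bcpnn_gate="e_ic")
    s_c = compute_signal_stats(t, bcpnn_gate="ic_minus_2sd")
    assert s_e.positive_bcpnn or not s_c.positive_bcpnn  # conservative gate is stricter


# --- association test ------------------------------------------------------

def test_small_expected_uses_fisher():
    p, method = association_test(ContingencyTable(1, 9, 2, 8))
    assert method == "fisher"


def test_large_balanced_uses_chi2_p_one():
    p, method = association_test(ContingencyTable(50, 50, 50, 50))
    assert method == "chi2"
    assert p == pytest.approx(1.0)


def _fisher_bruteforce(a, b, c, d):
    """Exhaustive two-sided Fisher p over tables with fixed margins."""
    from math import comb
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: comb(r1, x) * comb(r2, c1 - x) / denom for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


def test_fisher_equals_bruteforce_example():
    p, method = association_test(ContingencyTable(3, 7, 2, 18))
    assert method == "fisher"
    assert p == pytest.approx(_fisher_bruteforce(3, 7, 2, 18), rel=1e-9)


def test_fisher_close_to_chi2_for_large_expected():
    """The exact and asymptotic tests agree for very large cells.  (At
    expected counts of only ~10^2 the two-sided definitions can still gap
    by ~0.05 near p = 1, so the check uses cells of several hundred.)"""
    rng = np.random.default_rng(0)
    for _ in range(20):
        a, b, c, d = rng.integers(500, 2000, size=4)
        t = ContingencyTable(int(a), int(b), int(c), int(d))
        p_f = sps.fisher_exact([[t.a, t.b], [t.c, t.d]])[1]
        p_c, method = association_test(t)
        assert method == "chi2"
        assert abs(p_f - p_c) < 0.02


# --- scanning --------------------------------------------------------------

def test_scan_single_pair():
    clean = tiny_clean([("1", "D", "target"), ("2", None, "background")],
                       [("1", "Pulmonary embolism", "venous")])
    df = scan_all_signals(clean)
    assert len(df) == 1
    assert df.loc[0, "a"] == 1


def test_scan_row_count_matches_truth(clean_planted, planted_dataset):
    df = scan_all_signals(clean_planted)
    truth = planted_dataset.truth.cases
    clean_ids = set(clean_planted.analysis_cases["case_id"])
    tpo = {"Avatrombopag", "Eltrombopag", "Romiplostim"}
    pairs = 0
    for drug in sorted(tpo):
        sub = truth[(truth.drug == drug) & (truth.role == "PS")
                    & truth.case_id.isin(clean_ids)]
        pts = set()
        for s in sub.smq_pts:
            if s:
                pts.update(s.split("|"))
        pairs += len(pts)
    assert len(df) == pairs


def test_scan_deterministic_and_sorted(clean_planted):
    d1 = scan_all_signals(clean_planted)
    d2 = scan_all_signals(clean_planted)
    assert d1.to_csv() == d2.to_csv()
    for _, grp in d1.groupby("drug"):
        assert (grp["a"].diff().dropna() <= 0).all()
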