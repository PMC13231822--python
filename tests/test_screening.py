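import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from _oracles import mann_whitney_u_bruteforce
from frailbn import fixtures
from frailbn.screening import (
    DegenerateSampleError,
    DegenerateTableError,
    SampleSizeSpec,
    mann_whitney,
    pearson_chi2,
    required_sample_size,
    screen,
    screening_frame,
    two_sample_t,
)
from frailbn.synthetic import Cohort


# ---------------------------------------------------------------- chi-square


def test_polypharmacy_chi2():
    assert pearson_chi2([[224, 61], [164, 231]]).chi2 == pytest.approx(92.887, abs=0.01)


def test_social_support_chi2():
    assert pearson_chi2([[3, 38], [93, 159], [292, 95]]).chi2 == pytest.approx(
        136.615, abs=0.01
    )


def test_identical_rows_give_zero():
    assert pearson_chi2([[10, 10], [20, 20]]).chi2 == 0.0


@pytest.mark.parametrize(
    "variable",
    [v for v in fixtures.TABLE1 if v not in fixtures.CHI2_FROM_COUNTS_DIFFERS],
)
def test_all_printed_chi2_reproduce(variable):
    fx = fixtures.TABLE1[variable]
    assert pearson_chi2(fx.counts).chi2 == pytest.approx(fx.printed_chi2, abs=0.01)


def test_depression_printed_value_is_inconsistent():
    # the published 13.294 does not follow from the published counts;
    # the recomputed statistic is asserted instead
    fx = fixtures.TABLE1["depression"]
    recomputed = pearson_chi2(fx.counts).chi2
    assert recomputed == pytest.approx(24.498, abs=0.01)
    assert abs(recomputed - fx.printed_chi2) > 10


def test_expected_margins_match_observed():
    ct = pearson_chi2([[5, 9, 1], [7, 2, 11]])
    np.testing.assert_allclose(ct.expected.sum(axis=1), ct.counts.sum(axis=1), atol=1e-9)
    np.testing.assert_allclose(ct.expected.sum(axis=0), ct.counts.sum(axis=0), atol=1e-9)
    assert ct.expected.sum() == pytest.approx(ct.counts.sum())


def test_agrees_with_scipy():
    counts = [[73, 123], [215, 160], [100, 9]]
    ours = pearson_chi2(counts)
    ref = chi2_contingency(np.asarray(counts), correction=False)
    assert ours.chi2 == pytest.approx(ref.statistic, abs=1e-10)
    assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)
    assert ours.df == ref.dof


def test_2x2_shortcut_formula():
    a, b, c, d = 224, 61, 164, 231
    n = a + b + c + d
    shortcut = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    assert pearson_chi2([[a, b], [c, d]]).chi2 == pytest.approx(shortcut, abs=1e-9)


@settings(max_examples=50, deadline=None)
@given(
    counts=st.lists(
        st.lists(st.integers(1, 200), min_size=2, max_size=4),
        min_size=2,
        max_size=5,
    ).filter(lambda rows: len({len(r) for r in rows}) == 1),
    seed=st.integers(0, 10_000),
)
def test_permutation_invariance(counts, seed):
    rng = np.random.default_rng(seed)
    arr = np.asarray(counts)
    base = pearson_chi2(arr).chi2
    shuffled = arr[rng.permutation(arr.shape[0])][:, rng.permutation(arr.shape[1])]
    assert pearson_chi2(shuffled).chi2 == pytest.approx(base, abs=1e-9)


def test_zero_column_rejected():
    with pytest.raises(DegenerateTableError):
        pearson_chi2([[1, 0], [2, 0]])


def test_negative_counts_rejected():
    with pytest.raises(DegenerateTableError):
        pearson_chi2([[1, -1], [2, 3]])


def test_too_small_table_rejected():
    with pytest.raises(DegenerateTableError):
        pearson_chi2([[1, 2]])


# --------------------------------------------------------------------- t test


def test_t_zero_for_identical_samples():
    res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == 0.0
    assert res.p == pytest.approx(1.0)


def test_pooled_t_hand_computed():
    res = two_sample_t([1, 2, 3], [4, 5, 6], variant="pooled")
    assert res.statistic == pytest.approx(-3.674, abs=1e-3)
    assert res.df == 4


def test_summary_form_near_printed_value():
    # published summaries are rounded, so only a loose match is possible
    res = two_sample_t(summary=((2.23, 0.81, 388), (2.12, 0.85, 292)), variant="pooled")
    assert res.statistic == pytest.approx(1.8, abs=0.15)
    assert res.df == 678


def test_welch_t_differs_under_heteroscedasticity():
    x = [1.0, 2.0, 3.0, 4.0]
    y = [10.0, 30.0, 50.0, 70.0]
    pooled = two_sample_t(x, y, variant="pooled")
    welch = two_sample_t(x, y, variant="welch")
    assert welch.df < pooled.df


def test_zero_variance_rejected():
    with pytest.raises(DegenerateSampleError):
        two_sample_t([2.0, 2.0], [2.0, 2.0])


def test_unknown_variant_rejected():
    with pytest.raises(ValueError):
        two_sample_t([1, 2], [3, 4], variant="bogus")


# --------------------------------------------------------------- mann-whitney


def test_complete_separation_u_zero():
    res = mann_whitney([1, 2], [3, 4])
    assert res.u == 0.0


def test_identical_samples_z_zero():
    res = mann_whitney([1, 2, 3], [1, 2, 3])
    assert res.statistic == 0.0


def test_tied_example_matches_bruteforce():
    x, y = [1, 2, 3, 4], [2, 3, 4, 5]
    res = mann_whitney(x, y)
    assert res.u == mann_whitney_u_bruteforce(x, y)


@settings(max_examples=100, deadline=None)
@given(
    x=st.lists(st.integers(0, 5), min_size=1, max_size=8),
    y=st.lists(st.integers(0, 5), min_size=1, max_size=8),
)
def test_u_equals_pair_counting(x, y):
    if len(set(x) | set(y)) == 1:
        with pytest.raises(DegenerateSampleError):
            mann_whitney(x, y)
        return
    assert mann_whitney(x, y).u == pytest.approx(mann_whitney_u_bruteforce(x, y))


def test_all_tied_rejected():
    with pytest.raises(DegenerateSampleError):
        mann_whitney([1, 1], [1, 1])


def test_empty_group_rejected():
    with pytest.raises(DegenerateSampleError):
        mann_whitney([], [1, 2])


# ---------------------------------------------------------------- sample size


def test_published_sample_size():
    spec = SampleSizeSpec(pi=0.412, alpha=0.05, delta=0.05, dropout=0.20)
    assert required_sample_size(spec) == 467


def test_sample_size_without_dropout():
    assert required_sample_size(SampleSizeSpec(pi=0.412)) == 373


def test_sample_size_half_prevalence():
    assert required_sample_size(SampleSizeSpec(pi=0.5)) == 385


def test_sample_size_validation():
    with pytest.raises(ValueError):
        SampleSizeSpec(pi=0.4, delta=0.0)
    with pytest.raises(ValueError):
        SampleSizeSpec(pi=1.5)


# --------------------------------------------------------------------- screen


def _cohort_from_fixture_counts():
    """Expand the published contingency counts into a patient-level table."""
    columns = {}
    outcome = ["no"] * fixtures.GROUP_SIZES[0] + ["yes"] * fixtures.GROUP_SIZES[1]
    columns["oral_frailty"] = outcome
    for name, fx in fixtures.TABLE1.items():
        non_case, case = [], []
        for label, (a, b) in zip(fx.row_labels, fx.counts):
            non_case += [label] * a
            case += [label] * b
        columns[name] = non_case + case
    return Cohort(pd.DataFrame(columns))


def test_screen_reproduces_published_selection():
    cohort = _cohort_from_fixture_counts()
    results = {r.variable: r for r in screen(cohort, "oral_frailty", alpha=0.05)}
    significant = {v for v, r in results.items() if r.selected}
    expected = {v for v, fx in fixtures.TABLE1.items() if fx.significant}
    assert significant == expected
    assert "polypharmacy" in significant
    assert "sex" not in significant
    assert results["sex"].statistic == pytest.approx(0.836, abs=0.01)


def test_screen_alpha_one_selects_everything():
    cohort = _cohort_from_fixture_counts()
    assert all(r.selected for r in screen(cohort, "oral_frailty", alpha=1.0))


def test_screen_skips_single_state_column(caplog):
    frame = pd.DataFrame(
        {"oral_frailty": ["no", "yes"] * 10, "constant": ["x"] * 20}
    )
    with caplog.at_level(logging.WARNING):
        results = screen(Cohort(frame), "oral_frailty")
    assert "constant" not in {r.variable for r in results}
    assert any("single observed state" in m for m in caplog.messages)


def test_screen_routes_continuous_by_normality(rng):
    n = 400
    outcome = np.where(rng.random(n) < 0.5, "yes", "no")
    normal = rng.normal(0, 1, n) + (outcome == "yes") * 0.5
    skewed = rng.exponential(1, n) * (1 + (outcome == "yes"))
    frame = pd.DataFrame(
        {"oral_frailty": outcome, "normal_var": normal, "skewed_var": skewed}
    )
    tests = {r.variable: r.test for r in screen(Cohort(frame), "oral_frailty")}
    assert tests["normal_var"] == "pooled-t"
    assert tests["skewed_var"] == "mann-whitney"


def test_screen_unknown_outcome():
    with pytest.raises(KeyError):
        screen(Cohort(pd.DataFrame({"a": ["x", "y"]})), "missing")


def test_screening_frame_columns():
    cohort = _cohort_from_fixture_counts()
    frame = screening_frame(screen(cohort, "oral_frailty"))
    assert list(frame.columns) == ["variable", "test", "statistic", "df", "p", "selected"]
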