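"""Statistical battery primitives: t-tests, correlations, sex-adjusted
regression, and the battery report."""

import numpy as np
import pytest
from scipy import stats as sps

from vtamap.errors import DegenerateInputError, ParameterError, ValidationError
from vtamap.stats import (
    pearson,
    regression_adjusting_sex,
    run_paper_battery,
    spearman,
    ttest_from_summary,
    ttest_two_sample,
)
from vtamap.synthetic import CohortSpec, cohort_table, make_cohort


def test_ttest_hand_computed_pooled_variance():
    res = ttest_two_sample([1, 2, 3], [4, 5, 6], variant="student")
    assert res.statistic == pytest.approx(-3.674, abs=5e-4)
    assert res.df == 4


def test_ttest_identical_groups_and_variant_agreement():
    res = ttest_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], variant="welch")
    assert res.statistic == 0.0
    assert res.p_two_sided == pytest.approx(1.0)
    # equal n and equal variances: Student and Welch coincide
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 12)
    b = a + 0.7  # same sample variance by construction
    s = ttest_two_sample(a, b, variant="student")
    w = ttest_two_sample(a, b, variant="welch")
    assert s.statistic == pytest.approx(w.statistic, abs=1e-12)


def test_ttest_from_summary_consistency_with_raw():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, 15)
    b = rng.normal(0.4, 1.3, 12)
    for variant in ("welch", "student"):
        raw = ttest_two_sample(a, b, variant=variant)
        summ = ttest_from_summary(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size, variant=variant
        )
        assert summ.statistic == pytest.approx(raw.statistic, abs=1e-10)
        assert summ.p_two_sided == pytest.approx(raw.p_two_sided, abs=1e-10)
    eq = ttest_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
    assert eq.statistic == 0.0 and eq.p_two_sided == pytest.approx(1.0)


def test_published_age_row_p_value_from_summaries():
    """Group-comparison p reconstructed from printed cohort summaries
    (31.37 +/- 8.92, n=22 vs 30.73 +/- 8.84, n=21) is ~0.816."""
    res = ttest_from_summary(31.37, 8.92, 22, 30.73, 8.84, 21, variant="student")
    assert res.p_two_sided == pytest.approx(0.816, abs=0.01)


def test_pearson_and_spearman_basics():
    x = np.arange(10.0)
    assert pearson(x, 2 * x + 1).estimate == pytest.approx(1.0)
    r = spearman([1, 2, 3, 4], [1, 3, 2, 4])
    assert r.estimate == pytest.approx(0.8)
    # rank invariance under monotone transforms
    y = np.array([0.3, 2.0, 1.1, 5.0, 4.2, 7.7])
    a = spearman(np.arange(6.0), y)
    b = spearman(np.arange(6.0), np.exp(y))
    assert a.estimate == pytest.approx(b.estimate)
    with pytest.raises(DegenerateInputError):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_spearman_equals_pearson_on_ranks():
    rng = np.random.default_rng(3)
    x = rng.permutation(20).astype(float)
    y = rng.permutation(20).astype(float)
    rho = spearman(x, y).estimate
    r_on_ranks = pearson(sps.rankdata(x), sps.rankdata(y)).estimate
    assert rho == pytest.approx(r_on_ranks, abs=1e-12)


def test_spearman_exact_small_n_matches_enumeration():
    """For n=5 the exact two-sided permutation p equals a brute-force
    enumeration over all 120 pairings."""
    import itertools

    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
    res = spearman(x, y)
    assert res.method == "spearman_exact"
    rho_obs = sps.spearmanr(x, y).statistic
    count = 0
    for perm in itertools.permutations(range(5)):
        rho = sps.spearmanr(x, y[list(perm)]).statistic
        count += int(abs(rho) >= abs(rho_obs) - 1e-12)
    assert res.p_two_sided == pytest.approx(count / 120, abs=1e-12)
    # large n takes the t-approximation branch
    rng = np.random.default_rng(0)
    big = spearman(rng.normal(size=30), rng.normal(size=30))
    assert big.method == "spearman_tapprox"


def test_regression_matches_statsmodels_and_residual_identity():
    statsmodels_api = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(4)
    n = 40
    sex = rng.integers(0, 2, n)
    x = rng.normal(size=n) + 0.5 * sex
    y = 0.4 * x - 0.8 * sex + rng.normal(size=n)
    res = regression_adjusting_sex(y, x, np.where(sex == 1, "M", "F"))

    X = statsmodels_api.add_constant(np.column_stack([x, sex == 1]).astype(float))
    sm_fit = statsmodels_api.OLS(y, X).fit()
    assert res.statistic == pytest.approx(sm_fit.tvalues[1], abs=1e-10)
    assert res.p_two_sided == pytest.approx(sm_fit.pvalues[1], abs=1e-10)
    assert res.extras["coef"] == pytest.approx(sm_fit.params[1], abs=1e-10)

    # partial correlation via residual-on-residual Pearson
    S = statsmodels_api.add_constant((sex == 1).astype(float))
    rx = x - S @ np.linalg.lstsq(S, x, rcond=None)[0]
    ry = y - S @ np.linalg.lstsq(S, y, rcond=None)[0]
    r_resid = np.corrcoef(rx, ry)[0, 1]
    # the regression-derived partial correlation uses df = n-3 while the
    # raw residual correlation has no df adjustment; identical up to sign
    # and within numerical agreement of the t-based identity
    t_from_r = r_resid * np.sqrt((n - 3) / (1 - r_resid**2))
    assert res.statistic == pytest.approx(t_from_r, abs=1e-10)
    assert res.estimate == pytest.approx(r_resid, abs=1e-10)


def test_regression_orthogonal_sex_reduces_to_pearson():
    rng = np.random.default_rng(5)
    n = 200
    sex = np.tile([0, 1], n // 2)
    x = rng.normal(size=n)
    x = x - np.polyfit(sex, x, 1)[0] * (sex - sex.mean())  # orthogonalize
    y = 0.5 * x + rng.normal(size=n)
    y = y - np.polyfit(sex, y, 1)[0] * (sex - sex.mean())
    res = regression_adjusting_sex(y, x, sex)
    assert res.estimate == pytest.approx(pearson(x, y).estimate, abs=1e-10)


def test_regression_errors():
    with pytest.raises(ParameterError):
        regression_adjusting_sex([1, 2, 3, 4], [1, 2, 3, 4], ["F", "F", "F", "F"])


def test_battery_reports_all_tests_and_missing_columns():
    table = cohort_table(make_cohort(CohortSpec(seed=0)))
    report = run_paper_battery(table)
    assert report.n_tests == 15
    assert set(report.significant) == set(report.results)
    assert {"group_vta_intensity_norm", "group_sn_intensity", "intensity_on_bias_external_z"} <= set(report.results)
    with pytest.raises(ValidationError, match="vta_intensity_norm"):
        run_paper_battery(table.drop(columns=["vta_intensity_norm"]))


def test_battery_bh_correction_is_monotone():
    table = cohort_table(make_cohort(CohortSpec(seed=1)))
    rep = run_paper_battery(table, correction="bh")
    for name, res in rep.results.items():
        assert rep.p_adjusted[name] >= res.p_two_sided - 1e-12
        assert rep.p_adjusted[name] <= 1.0


def test_battery_sidedness_flag():
    table = cohort_table(make_cohort(CohortSpec(seed=2)))
    two = run_paper_battery(table, sided="two")
    one = run_paper_battery(table, sided="one")
    name = "group_vta_intensity_norm"
    assert one.results[name].p("one") == pytest.approx(two.results[name].p_two_sided / 2)
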