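"""p-value formulas, multiple-testing procedures and findings reporting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from longcontrast.calibration import calibrate_lambda
from longcontrast.regression import RegressionFit, fit_gene_regression
from longcontrast.testing import (
    GeneTestTable,
    alternative_pvalue,
    bh_reject,
    bonferroni_reject,
    evaluate_hypotheses,
    null_intercept_pvalue,
    report_findings,
)


def _fit_with_t(t, df=10):
    """A minimal non-degenerate fit with a prescribed intercept t statistic."""
    return RegressionFit(
        slope=0.0, intercept=t, intercept_se=1.0, t_intercept=t,
        r_squared=0.5, rss=1.0, tss=2.0, n=df + 2, df=df, degenerate=False,
    )


def test_null_pvalue_at_zero_statistic():
    assert null_intercept_pvalue(_fit_with_t(0.0)) == pytest.approx(1.0)


def test_null_pvalue_at_t_quantile():
    t975 = stats.t.ppf(0.975, df=20)
    assert null_intercept_pvalue(_fit_with_t(t975, df=20)) == pytest.approx(0.05)
    assert null_intercept_pvalue(_fit_with_t(-t975, df=20)) == pytest.approx(0.05)


def test_null_pvalue_worked_fit(worked_fit):
    """t = 0.75 / 0.6614... = 1.1339 on 2 df gives p close to 0.374."""
    p = null_intercept_pvalue(worked_fit)
    assert p == pytest.approx(2 * stats.t.cdf(-abs(worked_fit.t_intercept), df=2))
    assert p == pytest.approx(0.374, abs=5e-3)


def test_degenerate_fits_give_unit_pvalues():
    deg = fit_gene_regression(np.full(4, 3.0), np.array([0.0, 1.0, 2.0, 3.0]))
    assert null_intercept_pvalue(deg) == 1.0
    assert alternative_pvalue(deg, 0.0) == 1.0


def test_alternative_pvalue_at_level_equal_intercept(worked_fit):
    assert alternative_pvalue(worked_fit, worked_fit.intercept) == pytest.approx(0.5)


def test_alternative_pvalue_limits(worked_fit):
    assert alternative_pvalue(worked_fit, -1e12) == pytest.approx(0.0, abs=1e-12)
    assert alternative_pvalue(worked_fit, 1e12) == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError, match="finite"):
        alternative_pvalue(worked_fit, np.inf)


def test_alternative_pvalue_chained_on_calibration(worked_fit):
    lam = calibrate_lambda(worked_fit, pi=0.35, direction="below").lam
    t_shift = (worked_fit.intercept - lam) / worked_fit.intercept_se
    assert alternative_pvalue(worked_fit, lam) == pytest.approx(
        1.0 - stats.t.cdf(t_shift, df=2)
    )


def test_alternative_pvalue_zero_se():
    perfect = fit_gene_regression(np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0]))
    assert perfect.intercept_se == 0.0
    assert alternative_pvalue(perfect, 0.5) == 0.0  # intercept 1 above the level
    assert alternative_pvalue(perfect, 2.0) == 1.0
    assert alternative_pvalue(perfect, 1.0) == pytest.approx(0.5)


def test_lower_tail_option_is_complement(worked_fit):
    up = alternative_pvalue(worked_fit, 0.2, tail="upper")
    lo = alternative_pvalue(worked_fit, 0.2, tail="lower")
    assert up + lo == pytest.approx(1.0)


def test_bonferroni_examples():
    assert bonferroni_reject([0.9, 0.9], 0.025) == frozenset()
    assert bonferroni_reject([0.01, 0.9, 0.002], 0.025) == frozenset({2})
    assert bonferroni_reject([0.0, 0.0, 0.0], 0.025) == frozenset({0, 1, 2})
    assert bonferroni_reject([], 0.025) == frozenset()


def test_bh_examples():
    assert bh_reject([0.001, 0.013, 0.04, 0.9], 0.05) == frozenset({0, 1})
    assert bh_reject([1.0, 1.0, 1.0], 0.05) == frozenset()
    assert bh_reject([0.04], 0.05) == frozenset({0})
    assert bh_reject([], 0.05) == frozenset()


def _bh_brute(p, level):
    """Exhaustive step-up rule, independent of the implementation."""
    p = np.asarray(p, float)
    m = p.size
    order = np.sort(p)
    kmax = 0
    for k in range(1, m + 1):
        if order[k - 1] <= k * level / m:
            kmax = k
    if kmax == 0:
        return frozenset()
    crit = order[kmax - 1]
    return frozenset(np.flatnonzero(p <= crit).tolist())


def test_bh_matches_brute_force_with_ties_and_zeros():
    rng = np.random.default_rng(17)
    for _ in range(300):
        m = int(rng.integers(1, 21))
        p = np.round(rng.uniform(0, 1, m), 2)  # rounding forces ties
        p[rng.uniform(size=m) < 0.1] = 0.0
        level = float(rng.uniform(0.01, 0.2))
        ours = bh_reject(p, level)
        assert ours == _bh_brute(p, level)
        assert bonferroni_reject(p, level) <= ours  # Bonferroni never rejects more


@settings(deadline=None, max_examples=60, derandomize=True)
@given(seed=st.integers(0, 2**16))
def test_rejection_sets_monotone_under_pvalue_decrease(seed):
    """Shrinking any one p-value never removes rejections."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, 15))
    p = rng.uniform(0, 1, m)
    j = int(rng.integers(0, m))
    q = p.copy()
    q[j] = p[j] * rng.uniform(0, 1)
    for reject in (bonferroni_reject, bh_reject):
        assert reject(p, 0.05) <= reject(q, 0.05)


def _table(p_null, p_alt):
    m = len(p_null)
    return GeneTestTable(
        [f"g{j}" for j in range(m)], np.asarray(p_null), np.asarray(p_alt), np.zeros(m)
    )


def test_evaluate_uses_half_alpha_per_family():
    table = _table([0.02, 0.5], [0.6, 0.012])
    sets = evaluate_hypotheses(table, alpha=0.05, correction="bonferroni")
    # per family: bonferroni at 0.025 over m=2 -> threshold 0.0125
    assert sets.rejected_null == bonferroni_reject(table.p_null, 0.025)
    assert sets.rejected_alt == bonferroni_reject(table.p_alt, 0.025)
    assert sets.rejected_alt == frozenset({1})


def test_evaluate_all_ones_rejects_nothing():
    table = _table([1.0] * 4, [1.0] * 4)
    for corr in ("bonferroni", "bh"):
        sets = evaluate_hypotheses(table, 0.05, corr)
        assert sets.rejected_null == sets.rejected_alt == frozenset()


def test_evaluate_matches_per_family_oracle():
    rng = np.random.default_rng(23)
    table = _table(rng.uniform(0, 1, 5) ** 3, rng.uniform(0, 1, 5) ** 3)
    for corr, fn in (("bonferroni", bonferroni_reject), ("bh", bh_reject)):
        sets = evaluate_hypotheses(table, 0.05, corr)
        assert sets.rejected_null == fn(table.p_null, 0.025)
        assert sets.rejected_alt == fn(table.p_alt, 0.025)


def test_findings_are_sorted_intersection():
    table = _table([0.001, 0.001, 0.9, 0.001], [0.9, 0.0001, 0.0001, 0.0001])
    sets = evaluate_hypotheses(table, 0.05, "bh")
    found = report_findings(sets, table)
    expected = sorted(
        table.gene_names[j] for j in sets.rejected_null & sets.rejected_alt
    )
    assert list(found.genes) == expected
    assert set(found.genes) <= {table.gene_names[j] for j in sets.rejected_null}
    assert set(found.genes) <= {table.gene_names[j] for j in sets.rejected_alt}
    assert found.procedure_label == "FDR"


def test_disjoint_rejections_yield_empty_findings():
    table = _table([0.0001, 0.9], [0.9, 0.0001])
    found = report_findings(evaluate_hypotheses(table, 0.05, "bonferroni"), table)
    assert found.genes == () and found.procedure_label == "FWER"


def test_pvalue_bounds_enforced():
    with pytest.raises(ValueError, match="outside"):
        _table([1.2, 0.5], [0.5, 0.5])
    with pytest.raises(ValueError, match="level"):
        bonferroni_reject([0.5], 1.5)
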