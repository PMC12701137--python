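"""Two-way ANOVA and Tukey HSD against independent linear-model and quadrature oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from leukoselect.errors import DesignError
from leukoselect.stats import tukey_hsd, two_way_anova


def anova_ls_oracle(y):
    """Effect SS via explicit design-matrix least squares (sum-to-zero coding).

    For a balanced design the coding blocks are orthogonal, so each effect's
    SS is the squared norm of its fitted component.
    """
    a, b, r = y.shape
    obs = y.reshape(-1)

    def contrasts(levels):
        # sum-to-zero contrast columns for one factor
        C = np.zeros((levels, levels - 1))
        C[:-1, :] = np.eye(levels - 1)
        C[-1, :] = -1.0
        return C

    Ca, Cb = contrasts(a), contrasts(b)
    rows_a = np.repeat(np.arange(a), b * r)
    rows_b = np.tile(np.repeat(np.arange(b), r), a)
    Xa = Ca[rows_a]
    Xb = Cb[rows_b]
    Xab = np.einsum("ni,nj->nij", Xa, Xb).reshape(len(obs), -1)
    intercept = np.ones((len(obs), 1))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, obs, rcond=None)
        resid = obs - X @ beta
        return float(resid @ resid)

    full = np.hstack([intercept, Xa, Xb, Xab])
    ss_err = rss(full)
    ss_a = rss(np.hstack([intercept, Xb, Xab])) - ss_err
    ss_b = rss(np.hstack([intercept, Xa, Xab])) - ss_err
    ss_ab = rss(np.hstack([intercept, Xa, Xb])) - ss_err
    ss_tot = rss(intercept)
    return ss_a, ss_b, ss_ab, ss_err, ss_tot


def studentized_range_sf_oracle(q, k, df):
    """P(Q > q) by direct double quadrature of the studentized range distribution."""
    z = np.linspace(-8.5, 8.5, 3001)
    phi = sps.norm.pdf(z)
    Phi = sps.norm.cdf(z)

    def cdf_given_scale(qs):
        inner = k * phi * (Phi - sps.norm.cdf(z - qs)) ** (k - 1)
        return np.trapezoid(inner, z)

    from scipy.special import gammaln

    s = np.linspace(1e-6, 4.0, 2001)
    # density of S = sqrt(chi2_df / df)
    log_density = (
        (df / 2.0) * np.log(df)
        - gammaln(df / 2.0)
        - (df / 2.0 - 1.0) * np.log(2.0)
        + (df - 1.0) * np.log(s)
        - df * s**2 / 2.0
    )
    fs = np.exp(log_density)
    cdf_vals = np.array([cdf_given_scale(q * si) for si in s])
    return 1.0 - float(np.trapezoid(fs * cdf_vals, s))


class TestTwoWayAnova:
    def test_all_equal_observations_have_no_available_f(self):
        table = two_way_anova(np.full((3, 2, 3), 7.0))
        for source in ("Columns", "Rows", "Interaction"):
            row = table[source]
            assert row.ss == 0.0 and row.f is None and row.p is None

    def test_translation_invariance_of_sums_of_squares(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(3, 2, 3))
        t1 = two_way_anova(y)
        t2 = two_way_anova(y + 100.0)
        for source in ("Columns", "Rows", "Interaction", "Error", "Total"):
            assert t2[source].ss == pytest.approx(t1[source].ss, abs=1e-8)

    def test_hand_decomposed_three_by_two_design(self):
        # cell means (10, 12) in every column-level; residuals (-1, 0, 1) per cell
        cell_means = np.array([[10.0, 12.0]] * 3)
        resid = np.array([-1.0, 0.0, 1.0])
        y = cell_means[:, :, None] + resid[None, None, :]
        table = two_way_anova(y)
        assert table["Columns"].ss == pytest.approx(0.0, abs=1e-12)
        assert table["Rows"].ss == pytest.approx(18.0)
        assert table["Interaction"].ss == pytest.approx(0.0, abs=1e-12)
        assert table["Error"].ss == pytest.approx(12.0)
        assert (
            table["Columns"].df,
            table["Rows"].df,
            table["Interaction"].df,
            table["Error"].df,
            table["Total"].df,
        ) == (2, 1, 2, 12, 17)

    def test_sum_of_squares_decomposition_closes(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(4, 3, 2))
        t = two_way_anova(y)
        parts = sum(t[s].ss for s in ("Columns", "Rows", "Interaction", "Error"))
        assert parts == pytest.approx(t["Total"].ss, abs=1e-9)

    def test_agrees_with_design_matrix_least_squares_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a, b, r = rng.integers(2, 5, size=3)
            y = rng.normal(scale=rng.uniform(0.5, 3.0), size=(a, b, r)) + rng.uniform(-5, 5)
            table = two_way_anova(y)
            ss_a, ss_b, ss_ab, ss_err, ss_tot = anova_ls_oracle(y)
            assert table["Columns"].ss == pytest.approx(ss_a, abs=1e-8)
            assert table["Rows"].ss == pytest.approx(ss_b, abs=1e-8)
            assert table["Interaction"].ss == pytest.approx(ss_ab, abs=1e-8)
            assert table["Error"].ss == pytest.approx(ss_err, abs=1e-8)
            assert table["Total"].ss == pytest.approx(ss_tot, abs=1e-8)

    def test_agrees_with_statsmodels(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(7)
        y = rng.normal(size=(3, 2, 3))
        a, b, r = y.shape
        df = pd.DataFrame(
            {
                "value": y.reshape(-1),
                "A": np.repeat(np.arange(a), b * r).astype(str),
                "B": np.tile(np.repeat(np.arange(b), r), a).astype(str),
            }
        )
        sm_table = sm.stats.anova_lm(ols("value ~ C(A) * C(B)", data=df).fit(), typ=2)
        ours = two_way_anova(y)
        assert ours["Columns"].ss == pytest.approx(sm_table.loc["C(A)", "sum_sq"])
        assert ours["Rows"].ss == pytest.approx(sm_table.loc["C(B)", "sum_sq"])
        assert ours["Interaction"].ss == pytest.approx(sm_table.loc["C(A):C(B)", "sum_sq"])
        assert ours["Interaction"].p == pytest.approx(sm_table.loc["C(A):C(B)", "PR(>F)"])

    def test_ragged_design_rejected(self):
        with pytest.raises(DesignError):
            two_way_anova([[[1.0, 2.0], [3.0]], [[1.0], [2.0]]])


class TestTukeyHsd:
    def test_identical_groups_are_null(self):
        g = np.arange(6, dtype=float)
        result = tukey_hsd([g, g.copy()])
        c = result.comparisons[0]
        assert c.difference == 0.0
        assert c.p_value >= 0.999

    def test_interval_symmetric_about_difference(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(m, 1.0, size=8) for m in (0.0, 1.0, 3.0)]
        for c in tukey_hsd(groups).comparisons:
            assert (c.upper - c.difference) == pytest.approx(c.difference - c.lower, abs=1e-9)

    def test_unequal_sizes_rejected(self):
        with pytest.raises(DesignError):
            tukey_hsd([np.zeros(4), np.zeros(5)])

    def test_significance_pattern_and_quadrature_oracle(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(m, 1.0, size=6) for m in (0.0, 0.0, 5.0)]
        result = tukey_hsd(groups)
        by_pair = {(c.group_a, c.group_b): c for c in result.comparisons}
        assert by_pair[(1, 3)].p_value < 0.05
        assert by_pair[(2, 3)].p_value < 0.05
        assert by_pair[(1, 2)].p_value >= 0.05
        se = np.sqrt(result.ms_within / 6)
        for c in result.comparisons:
            oracle_p = studentized_range_sf_oracle(abs(c.difference) / se, 3, result.df_within)
            assert c.p_value == pytest.approx(oracle_p, abs=1e-4)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1.0, size=7) for m in (0.0, 1.0, 2.5)]
        ours = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        for c in ours.comparisons:
            i, j = c.group_a - 1, c.group_b - 1
            assert c.difference == pytest.approx(ref.statistic[i, j], abs=1e-12)
            assert c.p_value == pytest.approx(float(ref.pvalue[i, j]), abs=1e-6)
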