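import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phosphodiff import (
    ConfigurationError,
    anova_across_lines,
    benjamini_hochberg,
    common_oncogenic_markers,
    presence_absence_rescue,
    resistance_markers,
    up_down_sets,
    vs_reference,
    log2_zscore,
)
from phosphodiff.differential import oneway_f, two_sample_t
from .conftest import make_table


def bh_exhaustive(p):
    """Literal step-up definition: q_i = min over j>=rank(i) of n*p_(j)/j."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    for rank, i in enumerate(order, start=1):
        q[i] = min(
            min(n * p[order[j - 1]] / j for j in range(rank, n + 1)), 1.0
        )
    return q


class TestBenjaminiHochberg:
    def test_hand_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5]
        )

    def test_all_ones_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([1, 1, 1]), [1, 1, 1])

    def test_matches_exhaustive_definition_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(1, 50))
            p = rng.random(n)
            q = benjamini_hochberg(p)
            np.testing.assert_allclose(q, bh_exhaustive(list(p)), atol=1e-12)
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    def test_monotone_in_p(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p - 1e-15).all()

    @pytest.mark.parametrize("bad", [[-0.1], [1.5], [np.nan]])
    def test_rejects_invalid_pvalues(self, bad):
        with pytest.raises(ConfigurationError):
            benjamini_hochberg(bad)


class TestStatisticOracles:
    def test_f_statistic_matches_scipy_on_random_samples(self):
        rng = np.random.default_rng(0)
        n_trials = 2000
        X = rng.normal(size=(n_trials, 12))
        groups = [np.arange(0, 3), np.arange(3, 6), np.arange(6, 9), np.arange(9, 12)]
        F, p, ok = oneway_f(X, groups)
        assert ok.all()
        for i in range(n_trials):
            ref = stats.f_oneway(*(X[i, g] for g in groups))
            assert F[i] == pytest.approx(ref.statistic, abs=1e-10)
            assert p[i] == pytest.approx(ref.pvalue, abs=1e-10)

    @pytest.mark.parametrize("flavor,equal_var", [("welch", False), ("student", True)])
    def test_t_statistic_matches_scipy(self, flavor, equal_var):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2000, 8))
        t, p, diff, ok = two_sample_t(X, np.arange(0, 4), np.arange(4, 8), flavor=flavor)
        ref = stats.ttest_ind(X[:, :4], X[:, 4:], axis=1, equal_var=equal_var)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-10)
        np.testing.assert_allclose(p, ref.pvalue, atol=1e-10)

    def test_nan_aware_against_scipy_omit(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(500, 10))
        X[rng.random((500, 10)) < 0.2] = np.nan
        t, p, diff, ok = two_sample_t(X, np.arange(0, 5), np.arange(5, 10), "welch")
        for i in np.nonzero(ok)[0][:200]:
            a = X[i, :5][~np.isnan(X[i, :5])]
            b = X[i, 5:][~np.isnan(X[i, 5:])]
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t[i] == pytest.approx(ref.statistic, abs=1e-10)


class TestAnovaAcrossLines:
    def test_textbook_f_on_toy_matrix(self, design4):
        values = np.exp2(np.array([[1., 2, 1.5, 5, 6, 5.5, 0, 1, 0.5, 3, 3.5, 2.5]]))
        table = make_table(values, design4)
        norm = log2_zscore(table, axis="feature")
        frame = anova_across_lines(norm)
        X = norm.values.to_numpy()[0]
        ref = stats.f_oneway(X[:3], X[3:6], X[6:9], X[9:])
        assert frame["statistic"].iloc[0] == pytest.approx(ref.statistic)

    def test_equal_group_means_not_significant(self, design4):
        base = np.array([1.0, 2.0, 3.0] * 4)
        values = np.exp2(np.tile(base, (5, 1)) + np.random.default_rng(0).normal(0, 1e-6, (5, 12)))
        frame = anova_across_lines(log2_zscore(make_table(values, design4), "feature"))
        assert not frame["significant"].any()

    def test_feature_with_underfilled_group_skipped(self, design4):
        values = np.exp(np.random.default_rng(3).normal(size=(3, 12)))
        values[0, 0:2] = np.nan  # BEN has 1 valid value
        frame = anova_across_lines(log2_zscore(make_table(values, design4), "feature"))
        assert np.isnan(frame.loc["P000", "p"])
        assert frame.loc["P000", "significant"] == False  # noqa: E712


class TestDirectionLabels:
    def test_directions_flip_under_negation(self, design4):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(120, 12))
        values[:30, 3:6] += 2.0
        frame_a = {}
        for sign, store in ((1.0, "pos"), (-1.0, "neg")):
            norm = pd.DataFrame(sign * values, columns=design4.samples,
                                index=[f"P{i}" for i in range(120)])
            from phosphodiff import NormalizedTable
            nt = NormalizedTable(values=norm, design=design4, layer="proteome", axis="sample")
            frame_a[store] = vs_reference(nt)["CSL"]
        up_pos, down_pos = up_down_sets(frame_a["pos"])
        up_neg, down_neg = up_down_sets(frame_a["neg"])
        assert up_pos == down_neg and down_pos == up_neg


class TestResistanceRule:
    def test_single_comparison_hit_excluded(self, design4):
        rng = np.random.default_rng(6)
        values = rng.normal(scale=0.1, size=(40, 12))
        values[0, 6:9] += 5.0   # CRA only
        values[1, 6:12] += 5.0  # both CR lines
        from phosphodiff import NormalizedTable
        nt = NormalizedTable(
            values=pd.DataFrame(values, columns=design4.samples,
                                index=[f"P{i:02d}" for i in range(40)]),
            design=design4, layer="proteome", axis="sample")
        cr_up, cr_down, frames = resistance_markers(nt)
        assert "P01" in cr_up
        assert "P00" not in cr_up and "P00" not in cr_down

    def test_mixed_direction_excluded(self, design4):
        rng = np.random.default_rng(7)
        values = rng.normal(scale=0.1, size=(40, 12))
        values[0, 6:9] += 5.0
        values[0, 9:12] -= 5.0
        from phosphodiff import NormalizedTable
        nt = NormalizedTable(
            values=pd.DataFrame(values, columns=design4.samples,
                                index=[f"P{i:02d}" for i in range(40)]),
            design=design4, layer="proteome", axis="sample")
        cr_up, cr_down, _ = resistance_markers(nt)
        assert "P00" not in cr_up and "P00" not in cr_down


def test_common_markers_toy_sets():
    up = {"L1": ["A", "B"], "L2": ["B", "C"], "L3": ["B"]}
    down = {"L1": ["X"], "L2": ["Y"], "L3": ["Z"]}
    common_up, common_down = common_oncogenic_markers(up, down)
    assert common_up == ["B"]
    assert common_down == []


class TestPresenceAbsenceRescue:
    def test_rule_by_hand(self, design4):
        values = np.full((3, 12), np.nan)
        # P000: 2 valid in CR, none in CS -> CR_only
        values[0, 6:8] = 1.0
        # P001: 2 valid CR but 1 CS value -> excluded
        values[1, 6:8] = 1.0
        values[1, 3] = 1.0
        # P002: 2 valid CS, none CR -> CS_only (benign values irrelevant)
        values[2, 3:5] = 1.0
        values[2, 0] = 1.0
        table = make_table(values, design4)
        cr_only, cs_only = presence_absence_rescue(table)
        assert cr_only == ["P000"]
        assert cs_only == ["P002"]

    def test_quantification_filtered_features_never_qualify(self, design4):
        from phosphodiff import valid_value_filter
        rng = np.random.default_rng(8)
        values = np.exp(rng.normal(size=(50, 12)))
        values[rng.random((50, 12)) < 0.5] = np.nan
        table = make_table(values, design4)
        kept, removed = valid_value_filter(table)
        cr_only, cs_only = presence_absence_rescue(table)  # run on everything
        assert set(cr_only).isdisjoint(kept.feature_ids)
        assert set(cs_only).isdisjoint(kept.feature_ids)
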