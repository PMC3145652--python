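"""Welch ANOVA, B&H adjustment, fold conventions and cohort eligibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from barrex import cohort_stats as cs
from barrex import preprocess as pp
from barrex import synthetic_cohorts as sc
from barrex.expression_io import ABSENT, NONSIGNIFICANT, FIXTURE_THRESHOLDS


def welch_anova_oracle(groups):
    """Textbook Welch formula, written scalar-by-scalar and independently of
    the vectorized implementation under test."""
    k = len(groups)
    n = [len(g) for g in groups]
    m = [float(np.mean(g)) for g in groups]
    v = [float(np.var(g, ddof=1)) for g in groups]
    w = [n[j] / v[j] for j in range(k)]
    W = sum(w)
    grand = sum(w[j] * m[j] for j in range(k)) / W
    A = sum(w[j] * (m[j] - grand) ** 2 for j in range(k)) / (k - 1)
    lam = sum((1 - w[j] / W) ** 2 / (n[j] - 1) for j in range(k))
    F = A / (1 + 2 * (k - 2) / (k ** 2 - 1) * lam)
    df2 = (k ** 2 - 1) / (3 * lam)
    return F, df2, float(sps.f.sf(F, k - 1, df2))


class TestWelchAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        res = cs.welch_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_textbook_oracle_on_heteroscedastic_draws(self, rng):
        for _ in range(25):
            k = int(rng.integers(2, 5))
            groups = [rng.normal(rng.uniform(-2, 2), rng.uniform(0.2, 3),
                                 int(rng.integers(3, 30))) for _ in range(k)]
            res = cs.welch_anova(groups)
            F, df2, p = welch_anova_oracle(groups)
            assert res.F == pytest.approx(F, abs=1e-10)
            assert res.df2 == pytest.approx(df2, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_matches_published_library_implementation(self, rng):
        pg = pytest.importorskip("pingouin")
        groups = [rng.normal(0, s, n) for s, n in ((1, 8), (2, 12), (0.5, 10))]
        res = cs.welch_anova(groups)
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat([0, 1, 2], [8, 12, 10])})
        ref = pg.welch_anova(df, dv="y", between="g")
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-12)
        assert res.df2 == pytest.approx(float(ref["ddof2"].iloc[0]), rel=1e-12)

    def test_two_groups_reduce_to_welch_t(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, int(rng.integers(4, 20)))
            b = rng.normal(0.5, 2.5, int(rng.integers(4, 20)))
            res = cs.welch_anova([a, b])
            t = sps.ttest_ind(a, b, equal_var=False)
            assert res.p == pytest.approx(t.pvalue, rel=1e-9)
            assert res.F == pytest.approx(t.statistic ** 2, rel=1e-9)

    def test_location_and_scale_invariance(self, rng):
        groups = [rng.normal(0, s, 10) for s in (1, 2, 3)]
        base = cs.welch_anova(groups)
        shifted = cs.welch_anova([g + 17.3 for g in groups])
        scaled = cs.welch_anova([g * 4.2 for g in groups])
        assert shifted.F == pytest.approx(base.F, rel=1e-9)
        assert scaled.F == pytest.approx(base.F, rel=1e-9)

    def test_zero_variance_group_flagged_not_crashed(self):
        res = cs.welch_anova([[1.0, 1.0, 1.0], [1, 2, 3], [4, 5, 6]])
        assert np.isnan(res.p) and np.isnan(res.F)

    def test_matrix_path_agrees_with_scalar_path(self, rng):
        matrix = pd.DataFrame(rng.normal(0, 1, size=(20, 12)),
                              columns=[f"s{i}" for i in range(12)])
        labels = pd.Series(["S"] * 4 + ["BE"] * 4 + ["EAC"] * 4,
                           index=matrix.columns)
        table = cs.welch_anova_matrix(matrix, labels)
        for i in rng.choice(20, size=5, replace=False):
            row = matrix.iloc[int(i)]
            res = cs.welch_anova([row[:4], row[4:8], row[8:]])
            assert table["p"].iloc[int(i)] == pytest.approx(res.p, abs=1e-12)


class TestBhAdjust:
    def test_hand_evaluated_step_up(self):
        np.testing.assert_allclose(cs.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_equal_values(self):
        assert cs.bh_adjust([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(cs.bh_adjust([0.3, 0.3, 0.3]), [0.3] * 3)

    def test_nan_passthrough(self):
        out = cs.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], cs.bh_adjust([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_monotone_on_sorted_p_and_permutation_invariant(self, p):
        q = cs.bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = cs.bh_adjust(np.asarray(p)[perm])
        np.testing.assert_allclose(q_perm, q[perm])


class TestGroupFold:
    @pytest.mark.parametrize("a, b, expected", [
        (1.0, 2.0, 2.0),
        (2.0, 1.0, -2.0),
        (3.0, 3.0, 1.0),
    ])
    def test_signed_display_convention(self, a, b, expected):
        assert cs.group_fold(a, b) == pytest.approx(expected)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(0.01, 1e4), st.floats(0.01, 1e4))
    def test_antisymmetry(self, a, b):
        f, g = cs.group_fold(a, b), cs.group_fold(b, a)
        assert abs(f) == pytest.approx(abs(g), rel=1e-9)
        if abs(a / b - 1) > 1e-9:
            assert np.sign(f) == -np.sign(g)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            cs.group_fold(0.0, 1.0)


class TestPassCount:
    thresholds = FIXTURE_THRESHOLDS

    @pytest.mark.parametrize("cells, expected", [
        # printed peak-table rows: all present/passing; one blank; one absent
        ({"SDH": 1.3e-10, "GOMES": 0.0004, "GREENAWALT": 2.9e-07,
          "HAO": 0.009}, (4, 4)),
        ({"SDH": 7.8e-11, "GOMES": NONSIGNIFICANT, "GREENAWALT": 6.8e-14,
          "HAO": 0.043}, (3, 4)),
        ({"SDH": 9.4e-05, "GOMES": ABSENT, "GREENAWALT": 1.5e-06,
          "HAO": 0.002}, (3, 3)),
    ])
    def test_printed_examples(self, cells, expected):
        assert cs.pass_count(cells, self.thresholds) == expected


class TestTukey:
    def test_identical_groups_zero_statistic(self):
        means, res = cs.tukey_hsd([[1, 2, 3], [1, 2, 3]])
        assert res.statistic[0, 1] == pytest.approx(0.0)

    def test_group_means_are_plain_arithmetic_means(self, rng):
        groups = [rng.normal(0, 1, 6) for _ in range(3)]
        means, _ = cs.tukey_hsd(groups)
        np.testing.assert_allclose(means, [g.mean() for g in groups])

    def test_two_group_relation_to_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        _, res = cs.tukey_hsd([a, b])
        t = sps.ttest_ind(a, b, equal_var=True)
        # p of the studentized-range test with k=2 equals the pooled t-test p
        assert res.pvalue[0, 1] == pytest.approx(t.pvalue, rel=1e-6)


class TestCohortEligibility:
    def test_null_cohort_ineligible(self):
        cfg = sc.SimulationConfig(n_cohorts=1, group_sizes=(8, 8, 8),
                                  master_gene_count=600, platform_overlap=1.0,
                                  contamination_rate=0.0, multimap_rate=0.0,
                                  unmapped_rate=0.0, seed=11)
        cohort = sc.generate_cohorts(cfg)[0][0]
        eligible, n = cs.cohort_eligible(pp.normalize_cohort(cohort))
        assert not eligible
        assert n < 250

    def test_strongly_planted_cohort_eligible(self):
        sigs = sc.plant_signatures(range(1, 301), "S_BE", 4.0)
        cfg = sc.SimulationConfig(n_cohorts=3, group_sizes=(20, 20, 20),
                                  master_gene_count=600, platform_overlap=1.0,
                                  signatures=sigs, contamination_rate=0.0,
                                  multimap_rate=0.0, unmapped_rate=0.0, seed=11)
        cohort = sc.generate_cohorts(cfg)[0][0]
        eligible, n = cs.cohort_eligible(pp.normalize_cohort(cohort))
        assert eligible
        assert n >= 250

    def test_boundary_is_at_least(self):
        thr = cs.CohortThresholds()
        assert thr.eligibility_min_genes == 250  # "at least 250" is inclusive
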