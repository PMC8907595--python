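"""Statistics: summaries, ANOVA/t oracles, library cross-checks, CV report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from faceswell import (
    anova_oneway,
    build_report,
    deviation_report,
    pairwise_day_tests,
    summarize,
    ttest_two_sample,
)
from faceswell.stats import StatsDomainError


def table_of(values_by_group_day):
    rows = []
    for (group, day), values in values_by_group_day.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "rat_id": f"{group}{i}",
                    "group": group,
                    "day": day,
                    "S_raw": v,
                    "S_le": v,
                    "S_rot": v,
                    "S_final": v,
                }
            )
    return pd.DataFrame(rows)


class TestSummarize:
    def test_hand_computed_mean_sd(self):
        t = table_of({("model", 7): [2.0, 4.0, 6.0]})
        s = summarize(t, "final")
        assert s.loc[0, ["n", "mean", "sd"]].tolist() == [3, 4.0, 2.0]
        assert s.loc[0, "cv"] == pytest.approx(0.5)

    def test_single_observation_sd_zero(self):
        s = summarize(table_of({("control", 1): [5.0]}), "raw")
        assert s.loc[0, "sd"] == 0.0

    def test_row_permutation_invariant(self):
        t = table_of({("model", 7): [1.0, 5.0, 9.0], ("control", 7): [2.0, 2.0]})
        shuffled = t.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(summarize(t), summarize(shuffled))

    def test_unknown_stage_rejected(self):
        with pytest.raises(StatsDomainError):
            summarize(table_of({("model", 7): [1.0]}), "bogus")


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        r = anova_oneway([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert (r.statistic, r.p_value) == (0.0, 1.0)
        assert not r.significant

    def test_zero_within_variance_convention(self):
        r = anova_oneway([[0.0, 0.0], [10.0, 10.0]])
        assert np.isinf(r.statistic) and r.p_value == 0.0 and r.degenerate

    def test_hand_computed_three_by_three(self):
        """Means 5/8/11, grand mean 8: SS_between = 3·18 = 54 (df 2),
        SS_within = 3·8 = 24 (df 6) → F = 27/4 = 6.75."""
        r = anova_oneway([[3, 5, 7], [6, 8, 10], [9, 11, 13]])
        assert r.statistic == pytest.approx(6.75, abs=1e-12)
        assert r.df == (2.0, 6.0)

    def test_matches_scipy_on_random_inputs(self, rng):
        for _ in range(20):
            groups = [rng.normal(size=rng.integers(3, 12)) for _ in range(rng.integers(2, 5))]
            ours = anova_oneway(groups)
            ref = sps.f_oneway(*groups)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(StatsDomainError):
            anova_oneway([[1.0, 2.0]])
        with pytest.raises(StatsDomainError):
            anova_oneway([[1.0], [2.0, 3.0]])


class TestTTest:
    def test_identical_samples(self):
        r = ttest_two_sample([1, 2, 3], [1, 2, 3])
        assert (r.statistic, r.p_value) == (0.0, 1.0)

    def test_hand_computed_pooled_t(self):
        """Pooled SD 1, SE = sqrt(2/3): t = −3/0.8165 ≈ −3.674, df 4."""
        r = ttest_two_sample([1, 2, 3], [4, 5, 6])
        assert r.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert r.df == 4.0

    def test_antisymmetric_under_swap(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 6.0, 7.0, 9.0]
        r1, r2 = ttest_two_sample(a, b), ttest_two_sample(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_scipy_student_and_welch(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 15))
            b = rng.normal(1.0, 2.0, size=rng.integers(3, 15))
            ours = ttest_two_sample(a, b)
            ref = sps.ttest_ind(a, b)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)
            ours_w = ttest_two_sample(a, b, welch=True)
            ref_w = sps.ttest_ind(a, b, equal_var=False)
            assert ours_w.statistic == pytest.approx(ref_w.statistic, rel=1e-10)
            assert ours_w.p_value == pytest.approx(ref_w.pvalue, rel=1e-10)

    def test_zero_variance_conventions(self):
        assert ttest_two_sample([2.0, 2.0], [2.0, 2.0]).p_value == 1.0
        r = ttest_two_sample([2.0, 2.0], [5.0, 5.0])
        assert r.p_value == 0.0 and r.degenerate

    # rounding avoids denormal-underflow corner cases where SS terms
    # vanish in one formula but not the other
    @given(
        a=st.lists(st.floats(-50, 50).map(lambda v: round(v, 3)), min_size=3, max_size=10),
        b=st.lists(st.floats(-50, 50).map(lambda v: round(v, 3)), min_size=3, max_size=10),
    )
    @settings(max_examples=80, derandomize=True)
    def test_two_group_anova_equals_t_squared(self, a, b):
        t = ttest_two_sample(a, b)
        f = anova_oneway([a, b])
        if t.degenerate or f.degenerate:
            assert t.p_value == f.p_value
        else:
            assert f.statistic == pytest.approx(t.statistic**2, rel=1e-9, abs=1e-12)
            assert f.p_value == pytest.approx(t.p_value, rel=1e-9, abs=1e-12)

    def test_null_p_values_are_uniform(self):
        """KS test on pooled-t p-values from 2000 null normal samples."""
        gen = np.random.default_rng(123)
        ps = [
            ttest_two_sample(gen.normal(size=6), gen.normal(size=6)).p_value
            for _ in range(2000)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestPairwiseDayTests:
    def test_holm_never_more_liberal(self):
        gen = np.random.default_rng(5)
        t = table_of(
            {
                ("control", 7): gen.normal(0, 1, 6),
                ("model", 7): gen.normal(2, 1, 6),
                ("positive", 7): gen.normal(1, 1, 6),
            }
        )
        raw = pairwise_day_tests(t, "final")
        holm = pairwise_day_tests(t, "final", adjust="holm")
        pairs = raw.comparison.str.startswith("t:")
        assert (holm[pairs].p_value.values >= raw[pairs].p_value.values - 1e-12).all()

    def test_within_group_permutation_invariant(self):
        t = table_of({("control", 7): [1.0, 3.0, 5.0], ("model", 7): [2.0, 4.0, 9.0]})
        perm = t.iloc[[2, 0, 1, 5, 4, 3]].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            pairwise_day_tests(t, "final"), pairwise_day_tests(perm, "final")
        )


class TestDeviationReport:
    def _repeats(self, noise):
        gen = np.random.default_rng(8)
        rows = []
        for rat in ("a", "b"):
            base = gen.uniform(1e5, 2e5)
            for rep in range(30):
                rows.append(
                    {
                        "rat_id": rat,
                        "S_raw": base * (1 + noise[0] * gen.normal()),
                        "S_le": base * (1 + noise[1] * gen.normal()),
                        "S_rot": base * (1 + noise[2] * gen.normal()),
                        "S_final": base * (1 + noise[3] * gen.normal()),
                    }
                )
        return pd.DataFrame(rows)

    def test_nuisance_free_cvs_are_zero(self):
        rep = deviation_report(self._repeats((0, 0, 0, 0)))
        assert rep.per_rat[["raw", "le", "rot", "final"]].to_numpy() == pytest.approx(
            0.0, abs=1e-12
        )
        assert not rep.monotone_decreasing  # flat, not strictly decreasing

    def test_flags_monotone_reduction(self):
        rep = deviation_report(self._repeats((0.20, 0.05, 0.03, 0.01)))
        assert rep.monotone_decreasing
        assert rep.mean_cv["raw"] > rep.mean_cv["final"]

    def test_insufficient_repeats_rejected(self):
        df = self._repeats((0.1, 0.1, 0.1, 0.1)).iloc[[0]]
        with pytest.raises(StatsDomainError):
            deviation_report(df)


class TestBuildReport:
    def test_tidy_shapes_and_flags(self):
        gen = np.random.default_rng(3)
        t = table_of(
            {
                ("control", 7): gen.normal(10, 1, 6),
                ("model", 7): gen.normal(18, 1, 5),
                ("control", 12): gen.normal(10, 1, 6),
                ("model", 12): gen.normal(17, 1, 5),
            }
        )
        summaries, tests = build_report(t)
        assert set(summaries.stage) == {"raw", "le", "rot", "final"}
        assert len(summaries) == 4 * 4  # 4 stages × (2 groups × 2 days)
        day7 = tests[(tests.day == 7) & (tests.stage == "final")]
        assert set(day7.comparison) == {"anova:control/model", "t:control-vs-model"}
        assert bool(day7[day7.comparison == "t:control-vs-model"].significant.iloc[0])
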