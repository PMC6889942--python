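"""Statistics layer: explicit-SS ANOVA vs brute-force and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from redoxwound.errors import DesignError, MetricError
from redoxwound.stats import (pearson, percent_difference, repeated_anova,
                              summarize_cohort, tukey_posthoc)


def balanced_table(n_per_group=4, days=(0, 1, 2), seed=0, effects=True):
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("control", "diabetic"):
        for s in range(n_per_group):
            subj_eff = rng.normal(0, 0.5)
            for d in days:
                mu = (0.3 * d if (effects and g == "diabetic") else 0.0)
                rows.append({"subject": f"{g[0]}{s}", "group": g, "day": d,
                             "y": mu + subj_eff + rng.normal(0, 1)})
    return pd.DataFrame(rows)


def brute_force_ss(df):
    """Independent decomposition by explicit loops over cells."""
    y = df.set_index(["subject", "day"]).y
    subjects = sorted({s for s, _ in y.index})
    days = sorted({d for _, d in y.index})
    group_of = df.drop_duplicates("subject").set_index("subject").group
    grand = np.mean([y[s, d] for s in subjects for d in days])
    ss_total = sum((y[s, d] - grand) ** 2 for s in subjects for d in days)
    subj_mean = {s: np.mean([y[s, d] for d in days]) for s in subjects}
    ss_subj = len(days) * sum((subj_mean[s] - grand) ** 2 for s in subjects)
    groups = sorted(set(group_of))
    gmean = {g: np.mean([y[s, d] for s in subjects if group_of[s] == g for d in days])
             for g in groups}
    ng = {g: sum(group_of[s] == g for s in subjects) for g in groups}
    ss_group = len(days) * sum(ng[g] * (gmean[g] - grand) ** 2 for g in groups)
    dmean = {d: np.mean([y[s, d] for s in subjects]) for d in days}
    ss_day = len(subjects) * sum((dmean[d] - grand) ** 2 for d in days)
    ss_gd = 0.0
    for g in groups:
        for d in days:
            cell = np.mean([y[s, d] for s in subjects if group_of[s] == g])
            ss_gd += ng[g] * (cell - gmean[g] - dmean[d] + grand) ** 2
    return dict(total=ss_total, subjects=ss_subj, group=ss_group, day=ss_day,
                gd=ss_gd, sw=ss_subj - ss_group,
                err=ss_total - ss_subj - ss_day - ss_gd)


class TestRepeatedAnova:
    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_matches_brute_force_decomposition(self, seed):
        df = balanced_table(n_per_group=3, days=(0, 2, 4), seed=seed)
        res = repeated_anova(df, "y")
        ss = brute_force_ss(df)
        assert res.effects["group"].ss == pytest.approx(ss["group"], rel=1e-9)
        assert res.effects["day"].ss == pytest.approx(ss["day"], rel=1e-9)
        assert res.effects["group:day"].ss == pytest.approx(ss["gd"], rel=1e-9)
        assert res.errors["subjects_within_group"].ss == pytest.approx(
            ss["sw"], rel=1e-9)
        assert res.errors["day_x_subjects_within_group"].ss == pytest.approx(
            ss["err"], rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 3, 11, 19])
    def test_ss_decomposition_identity(self, seed):
        df = balanced_table(seed=seed)
        res = repeated_anova(df, "y")
        parts = (sum(e.ss for e in res.effects.values())
                 + sum(e.ss for e in res.errors.values()))
        assert parts == pytest.approx(res.ss_total, rel=1e-9)

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        df = balanced_table(n_per_group=5, seed=2)
        res = repeated_anova(df, "y")
        ref = pg.mixed_anova(df, dv="y", within="day", subject="subject",
                             between="group").set_index("Source")
        assert res.effects["group"].F == pytest.approx(ref.loc["group", "F"])
        assert res.effects["day"].F == pytest.approx(ref.loc["day", "F"])
        assert res.effects["group:day"].F == pytest.approx(
            ref.loc["Interaction", "F"])
        assert res.effects["day"].p == pytest.approx(ref.loc["day", "p_unc"])
        # epsilon estimators differ in pooling convention but stay close
        assert 1 / (3 - 1) <= res.gg_epsilon <= 1.0
        assert res.gg_epsilon == pytest.approx(ref.loc["day", "eps"], abs=0.1)

    def test_all_identical_is_no_variance_case(self):
        df = balanced_table(seed=0)
        df["y"] = 2.5
        res = repeated_anova(df, "y")
        assert res.ss_total == 0.0
        assert res.effects["group"].ss == 0.0
        assert np.isnan(res.effects["group:day"].F)
        assert "no-variance" in res.note

    def test_planted_group_effect_zero_noise(self):
        """Pure group shift: group SS equals closed form, error SS zero."""
        df = balanced_table(seed=0)
        df["y"] = np.where(df.group == "diabetic", 2.0, 1.0)
        res = repeated_anova(df, "y")
        n, d = 4, 3
        grand = 1.5
        closed = d * n * ((2.0 - grand) ** 2 + (1.0 - grand) ** 2)
        assert res.effects["group"].ss == pytest.approx(closed, rel=1e-12)
        assert res.errors["subjects_within_group"].ss == pytest.approx(0, abs=1e-12)
        assert res.effects["group"].F == np.inf and res.effects["group"].p == 0.0

    def test_unbalanced_design_lists_missing_cells(self):
        df = balanced_table().query("~(subject == 'c0' and day == 2)")
        with pytest.raises(DesignError, match=r"c0.*2"):
            repeated_anova(df, "y")


class TestTukey:
    def test_identical_groups_not_significant(self):
        df = balanced_table(seed=1, effects=False)
        df["y"] = np.tile([1.0, 2.0, 3.0, 4.0], 6)
        df.loc[df.group == "diabetic", "y"] = df.loc[df.group == "control", "y"].values
        for c in tukey_posthoc(df, "y"):
            assert c.mean_diff == pytest.approx(0.0)
            assert c.p_adj > 0.9 and not c.significant

    def test_extreme_separation_significant(self, rng):
        rows = []
        for g, mu in (("control", 0.0), ("diabetic", 10.0)):
            for s in range(6):
                rows.append({"subject": f"{g}{s}", "group": g, "day": 0,
                             "y": mu + rng.normal(0, 1)})
        (c,) = tukey_posthoc(pd.DataFrame(rows), "y")
        assert c.significant and c.p_adj < 0.001

    def test_q_statistic_formula(self):
        """q = mean diff / sqrt(MSE/n) with equal group sizes."""
        rows = []
        for g, vals in (("a", [1.0, 2.0, 3.0]), ("b", [4.0, 6.0, 8.0])):
            for s, v in enumerate(vals):
                rows.append({"subject": f"{g}{s}", "group": g, "day": 0, "y": v})
        (c,) = tukey_posthoc(pd.DataFrame(rows), "y")
        mse = (np.var([1, 2, 3], ddof=1) + np.var([4, 6, 8], ddof=1)) / 2
        assert c.q == pytest.approx(abs(2 - 6) / np.sqrt(mse / 3), rel=1e-12)

    def test_matches_statsmodels_tukeyhsd(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        rows = []
        for g in ("a", "b"):
            for s in range(5):
                rows.append({"subject": f"{g}{s}", "group": g, "day": 0,
                             "y": rng.normal((g == "b") * 1.2, 1)})
        df = pd.DataFrame(rows)
        (c,) = tukey_posthoc(df, "y")
        ref = sm.pairwise_tukeyhsd(df["y"], df["group"])
        assert c.p_adj == pytest.approx(float(ref.pvalues[0]), rel=1e-6)

    def test_single_group_rejected(self):
        df = balanced_table().query("group == 'control'")
        with pytest.raises(DesignError):
            tukey_posthoc(df, "y")


class TestPearson:
    def test_exact_negative_line(self):
        x = np.arange(10.0)
        res = pearson(x, -2 * x + 3)
        assert res.r == -1.0 and res.r_squared == 1.0
        assert res.slope == pytest.approx(-2.0) and res.intercept == pytest.approx(3.0)
        assert res.p == 0.0

    def test_independent_near_zero(self, rng):
        x = rng.permutation(2000).astype(float)
        y = rng.permutation(2000).astype(float)
        assert abs(pearson(x, y).r) < 0.08

    def test_five_point_fixture_matches_loop_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.1, 2.9, 4.2, 5.5, 6.8])
        res = pearson(x, y)
        mx, my = x.mean(), y.mean()
        num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
        den = np.sqrt(sum((xi - mx) ** 2 for xi in x)
                      * sum((yi - my) ** 2 for yi in y))
        assert res.r == pytest.approx(num / den, rel=1e-12)

    @given(st.floats(0.1, 5.0), st.floats(-3.0, 3.0))
    @settings(max_examples=20)
    def test_symmetry_and_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        assert pearson(x, y).r == pytest.approx(pearson(y, x).r, rel=1e-12)
        assert pearson(scale * x + shift, y).r_squared == pytest.approx(
            pearson(x, y).r_squared, rel=1e-9)

    def test_matches_scipy(self, rng):
        from scipy import stats as sps
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        res = pearson(x, y)
        ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(MetricError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(MetricError):
            pearson([1.0, 2.0], [1.0, 2.0])


class TestPercentDifference:
    def test_equal_means_zero(self):
        assert percent_difference(1.2, 1.2) == 0.0

    def test_reported_effect_sizes(self):
        # diabetic surface RR 1.2 -> 0.468 is a 61% drop; volumetric
        # 1.2 vs 0.408 is a 66% group difference
        assert percent_difference(1.2, 0.468) == pytest.approx(61.0)
        assert percent_difference(1.2, 0.408) == pytest.approx(66.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(MetricError):
            percent_difference(0.0, 1.0)


class TestSummary:
    def test_mean_and_se_by_hand(self):
        rows = [{"subject": f"s{i}", "group": "control", "day": 0,
                 "surface_rr": v} for i, v in enumerate([1.0, 2.0, 3.0])]
        rows += [{"subject": f"d{i}", "group": "diabetic", "day": 0,
                  "surface_rr": v} for i, v in enumerate([1.0, 2.0, 3.0])]
        s = summarize_cohort(pd.DataFrame(rows), markers=("surface_rr",))
        cell = s[(s.group == "control")].iloc[0]
        assert cell["mean"] == 2.0
        assert cell["se"] == pytest.approx(1.0 / np.sqrt(3), rel=1e-9)

    def test_single_subject_se_absent(self):
        rows = [{"subject": "a", "group": "control", "day": 0, "surface_rr": 1.0},
                {"subject": "b", "group": "diabetic", "day": 0, "surface_rr": 2.0}]
        s = summarize_cohort(pd.DataFrame(rows), markers=("surface_rr",))
        assert s["se"].isna().all()
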