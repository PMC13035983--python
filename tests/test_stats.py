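"""Statistical battery: PTA, ANOVA with post hoc, Spearman, duration t-tests,
demographic summaries.  Closed-form oracles are computed in-test."""

import numpy as np
import pandas as pd
import pytest

from labyrinthometry import (
    CohortSpec,
    duration_stratified_tests,
    eh_correlations,
    pta,
    simulate_cohort,
    summarize_cohort,
    three_group_comparison,
)


def frame(groups_values):
    rows = []
    for g, vals in groups_values.items():
        for v in vals:
            rows.append({"group": g, "metric": v})
    return pd.DataFrame(rows)


class TestPta:
    def test_mean_of_four(self):
        assert pta((60, 65, 70, 65)) == 65.0
        assert pta((0, 0, 0, 0)) == 0.0
        assert pta((20, 25, 25, 24.56)) == pytest.approx(23.64)

    def test_missing_or_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pta((60, 65, 70))
        with pytest.raises(ValueError):
            pta((60, 65, 70, np.nan))


def anova_oracle(samples):
    """Brute-force one-way ANOVA from sums of squares."""
    allv = np.concatenate(samples)
    grand = allv.mean()
    ss_between = sum(len(x) * (x.mean() - grand) ** 2 for x in samples)
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in samples)
    df_b = len(samples) - 1
    df_w = len(allv) - len(samples)
    return (ss_between / df_b) / (ss_within / df_w)


class TestThreeGroupComparison:
    def test_matches_sum_of_squares_oracle(self):
        # textbook-style 3 x 5 layout
        data = {
            "MDAE": np.array([4.1, 4.3, 4.0, 4.2, 4.4]),
            "MDUE": np.array([4.0, 4.1, 3.9, 4.2, 4.0]),
            "HC": np.array([3.8, 4.0, 3.9, 3.7, 4.1]),
        }
        res = three_group_comparison(frame(data), "metric")
        assert res.f_statistic == pytest.approx(anova_oracle(list(data.values())), abs=1e-6)

    def test_posthoc_pairs_and_range(self, rng):
        data = {
            g: rng.normal(loc, 0.2, 30)
            for g, loc in [("MDAE", 4.1), ("MDUE", 4.0), ("HC", 3.9)]
        }
        res = three_group_comparison(frame(data), "metric")
        assert set(res.posthoc) == {("MDAE", "MDUE"), ("MDAE", "HC"), ("MDUE", "HC")}
        assert all(0.0 <= p <= 1.0 for p in res.posthoc.values())

    def test_tukey_mode(self, rng):
        data = {g: rng.normal(4.0, 0.2, 25) for g in ("MDAE", "MDUE", "HC")}
        res = three_group_comparison(frame(data), "metric", posthoc="tukey")
        assert set(res.posthoc) == {("MDAE", "MDUE"), ("MDAE", "HC"), ("MDUE", "HC")}

    def test_zero_variance_everywhere_rejected(self):
        data = {g: np.full(5, 4.0) for g in ("MDAE", "MDUE", "HC")}
        with pytest.raises(ValueError, match="zero variance"):
            three_group_comparison(frame(data), "metric")

    def test_empty_group_rejected(self):
        data = {"MDAE": np.array([1.0, 2.0]), "MDUE": np.array([1.0, 2.0]), "HC": np.array([])}
        with pytest.raises(ValueError, match="HC"):
            three_group_comparison(frame(data), "metric")

    def test_type_one_error_calibration_quick(self, rng):
        # small version of the null-calibration experiment
        hits = 0
        reps = 200
        for _ in range(reps):
            data = {g: rng.normal(0, 1, 40) for g in ("MDAE", "MDUE", "HC")}
            res = three_group_comparison(frame(data), "metric")
            hits += res.p_value < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.04)

    def test_shuffling_labels_destroys_effect(self, rng):
        # permutation sanity: with labels shuffled, a large injected effect
        # no longer produces small p-values systematically
        data = {
            "MDAE": rng.normal(1.0, 1.0, 50),
            "MDUE": rng.normal(0.0, 1.0, 50),
            "HC": rng.normal(0.0, 1.0, 50),
        }
        df = frame(data)
        res = three_group_comparison(df, "metric")
        assert res.p_value < 0.01
        hits = 0
        for _ in range(100):
            shuffled = df.assign(group=rng.permutation(df["group"].to_numpy()))
            hits += three_group_comparison(shuffled, "metric").p_value < 0.05
        assert hits <= 15


class TestEhCorrelations:
    def test_hand_ranked_toy_set(self):
        df = pd.DataFrame(
            {"metric": [1.0, 2.0, 3.0, 4.0], "grade": [1, 3, 2, 4]}
        )
        res = eh_correlations(df, "grade", ["metric"])[0]
        assert res.spearman_r == pytest.approx(0.8)

    def test_monotone_metric_gives_r_one(self):
        df = pd.DataFrame({"metric": [1.0, 2.5, 7.0, 9.0], "grade": [0, 1, 2, 3]})
        res = eh_correlations(df, "grade", ["metric"])[0]
        assert res.spearman_r == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=50)
        g = rng.integers(0, 4, 50)
        df = pd.DataFrame({"metric": x, "grade": g})
        df2 = pd.DataFrame({"metric": np.exp(3 * x), "grade": g})
        r1 = eh_correlations(df, "grade", ["metric"])[0].spearman_r
        r2 = eh_correlations(df2, "grade", ["metric"])[0].spearman_r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_null_metric_small_r(self, rng):
        small = 0
        for _ in range(100):
            df = pd.DataFrame(
                {"metric": rng.normal(size=105), "grade": rng.integers(0, 4, 105)}
            )
            r = eh_correlations(df, "grade", ["metric"])[0].spearman_r
            small += abs(r) < 0.2
        assert small >= 95

    def test_constant_grade_rejected(self):
        df = pd.DataFrame({"metric": [1.0, 2.0, 3.0], "grade": [1, 1, 1]})
        with pytest.raises(ValueError, match="constant"):
            eh_correlations(df, "grade", ["metric"])


def t_oracle(a, b):
    """Pooled two-sample t from the closed form."""
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


class TestDurationTests:
    def _records(self, short, long_):
        return pd.DataFrame(
            {
                "duration_years": np.concatenate(
                    [np.full(len(short), 2.0), np.full(len(long_), 8.0)]
                ),
                "vestibular_volume_mm3": np.concatenate([short, long_]),
            }
        )

    def test_matches_closed_form(self, rng):
        a = rng.normal(52, 7, 47)
        b = rng.normal(55, 7, 58)
        res = duration_stratified_tests(
            self._records(a, b), metrics=["vestibular_volume_mm3"]
        )
        assert res.loc["vestibular_volume_mm3", "t"] == pytest.approx(
            t_oracle(a, b), abs=1e-9
        )

    def test_identical_strata_t_zero_p_one(self):
        a = np.array([50.0, 52.0, 54.0, 56.0])
        res = duration_stratified_tests(
            self._records(a, a), metrics=["vestibular_volume_mm3"]
        )
        assert res.loc["vestibular_volume_mm3", "t"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["vestibular_volume_mm3", "p"] == pytest.approx(1.0)

    def test_power_at_reference_effect_scale(self, rng):
        # +2.7 shift at sd 7, n = 47/58: analytic power ~0.5 at alpha 0.05
        hits = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(0.0, 7.0, 47)
            b = rng.normal(2.7, 7.0, 58)
            res = duration_stratified_tests(
                self._records(a, b), metrics=["vestibular_volume_mm3"]
            )
            hits += res.loc["vestibular_volume_mm3", "p"] < 0.05
        assert hits / reps == pytest.approx(0.50, abs=0.08)

    def test_small_stratum_rejected(self):
        df = self._records(np.array([1.0]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="stratum"):
            duration_stratified_tests(df, metrics=["vestibular_volume_mm3"])


class TestSummarizeCohort:
    def test_reference_percentages(self):
        # 60 female of 105 -> 57.14%; 59 left of 105 -> 56.19%
        sexes = ["F"] * 60 + ["M"] * 45
        sides = ["L"] * 59 + ["R"] * 46
        df = pd.DataFrame(
            {
                "group": "MDAE",
                "sex": sexes,
                "ear_side": sides,
                "age_years": 57.0,
                "duration_years": 3.0,
                "pta_db": 65.0,
            }
        )
        s = summarize_cohort(df)
        assert s["sex"]["Female"] == (60, 57.14)
        assert s["laterality"]["Left"] == (59, 56.19)

    def test_empty_category_zero_percent(self):
        df = pd.DataFrame(
            {
                "group": "MDAE",
                "sex": ["F"] * 4,
                "ear_side": ["L"] * 4,
                "age_years": 50.0,
                "duration_years": 2.0,
                "pta_db": 60.0,
            }
        )
        s = summarize_cohort(df)
        assert s["sex"]["Male"] == (0, 0.0)

    def test_percentages_sum_to_100(self):
        df = simulate_cohort(CohortSpec(seed=4))
        s = summarize_cohort(df)
        for field in ("sex", "laterality", "duration"):
            total = sum(p for _, p in s[field].values())
            assert total == pytest.approx(100.0, abs=0.05)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_cohort(pd.DataFrame())
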