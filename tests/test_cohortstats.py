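from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from snapia.cohortstats import (
    area_model,
    chi2_independence,
    included_cohort,
    logistic_presence,
    normality_screen,
    prevalence_summary,
    rank_compare,
    weighted_percentage,
)
from snapia.phantom import CohortGenParams, generate_cohort


def chi2_oracle(table):
    """Textbook Pearson statistic via the independent E-formula."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    E = row @ col / table.sum()
    return float(((table - E) ** 2 / E).sum())


class TestChi2:
    def test_reconstructed_sex_prevalence_table(self):
        """Counts rebuilt from 84.4% of 154 females and 69.8% of 149 males
        reproduce the published Pearson statistic of 9.2."""
        table = [[130, 24], [104, 45]]
        stat, dof, p = chi2_independence(table)
        assert dof == 1
        assert stat == pytest.approx(9.2, abs=0.05)
        assert p == pytest.approx(0.002, abs=0.001)

    def test_proportional_table_is_zero(self):
        stat, _, p = chi2_independence([[20, 40], [10, 20]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_textbook_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        r, c = rng.integers(2, 5, size=2)
        table = rng.integers(1, 60, size=(r, c))
        stat, dof, _ = chi2_independence(table)
        assert stat == pytest.approx(chi2_oracle(table))
        assert dof == (r - 1) * (c - 1)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_independence([[0, 0], [5, 3]])

    def test_continuity_correction_shrinks_2x2_statistic(self):
        plain, _, _ = chi2_independence([[130, 24], [104, 45]])
        corrected, _, _ = chi2_independence([[130, 24], [104, 45]], continuity_correction=True)
        assert corrected < plain


class TestPrevalenceSummary:
    def _cohort(self):
        rows = []
        groups = {"A": (45, 0.756), "B": (121, 0.843), "C": (137, 0.715)}
        i = 0
        for g, (n, pct) in groups.items():
            n_present = round(n * pct)
            for j in range(n):
                rows.append(
                    {
                        "subject_id": f"{g}{j}",
                        "status": "present" if j < n_present else "absent",
                        "variant": "simple" if j % 4 else "broad",
                        "bilobar": False,
                        "mean_adjusted_area_mm2": 20.0 if j < n_present else np.nan,
                        "group": g,
                    }
                )
                i += 1
        return pd.DataFrame(rows)

    def test_weighted_total_row(self):
        summary = prevalence_summary(self._cohort())
        assert summary.loc["TOTAL", "n"] == 303
        assert round(float(summary.loc["TOTAL", "pct_presence"]), 1) == 77.2

    def test_weighted_percentage_hand_check(self):
        assert weighted_percentage([45, 121, 137], [75.6, 84.3, 71.5]) == pytest.approx(
            77.2, abs=0.05
        )
        assert weighted_percentage([45, 121, 137], [17.2, 24.5, 23.0]) == pytest.approx(
            22.7, abs=0.05
        )

    def test_single_group_total_equals_group(self):
        df = self._cohort()
        df = df[df["group"] == "A"]
        summary = prevalence_summary(df)
        assert summary.loc["TOTAL", "pct_presence"] == pytest.approx(
            summary.loc["A", "pct_presence"]
        )

    def test_all_present_cohort_is_100(self):
        df = self._cohort()
        df = df[df["status"] == "present"]
        summary = prevalence_summary(df)
        assert summary.loc["TOTAL", "pct_presence"] == pytest.approx(100.0)

    def test_excluded_rows_dropped_from_inference(self):
        df = self._cohort()
        df.loc[df.index[:11], "status"] = "ambiguous_kissing"
        assert len(included_cohort(df)) == len(df) - 11

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            prevalence_summary(pd.DataFrame(columns=["status", "group"]))


class TestLogisticPresence:
    def test_recovers_generative_male_odds_ratio(self):
        df = generate_cohort(2000, seed=7)
        fit = logistic_presence(df, ["sex", "age"])
        assert 0.35 <= fit.extra["odds_ratios"]["sex[M]"] <= 0.7

    def test_null_covariate_ci_covers_one(self):
        params = CohortGenParams(presence_or_male=1.0)
        covered = 0
        n_rep = 60
        for seed in range(n_rep):
            df = generate_cohort(300, params, seed=100 + seed)
            try:
                fit = logistic_presence(df, ["sex"])
            except ValueError:
                continue
            lo, hi = fit.extra["odds_ratio_ci"]["sex[M]"]
            covered += lo <= 1.0 <= hi
        assert covered / n_rep >= 0.9

    def test_all_present_raises_separation_error(self):
        df = generate_cohort(100, CohortGenParams(presence_p_female=1 - 1e-12,
                                                  presence_or_male=1.0), seed=1)
        df["status"] = "present"
        with pytest.raises(ValueError):
            logistic_presence(df, ["sex"])


class TestAreaModel:
    def test_recovers_generative_age_slope(self):
        df = generate_cohort(1000, seed=11)
        fit = area_model(df, ["age", "sex"])
        assert -0.35 <= fit.params["age"] <= -0.15
        assert fit.extra["omega_squared"]["age"] > 0

    def test_zero_slope_ci_covers_zero(self):
        params = CohortGenParams(area_age_slope=0.0)
        covered = 0
        n_rep = 60
        for seed in range(n_rep):
            df = generate_cohort(300, params, seed=200 + seed)
            fit = area_model(df, ["age", "sex"])
            lo, hi = fit.conf_int.loc["age"]
            covered += lo <= 0.0 <= hi
        assert covered / n_rep >= 0.9

    def test_two_point_cohort_interpolates_exactly(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "status": ["present", "present"],
                "mean_adjusted_area_mm2": [20.0, 30.0],
                "age": [30.0, 50.0],
            }
        )
        fit = area_model(df, ["age"])
        assert fit.params["age"] == pytest.approx(0.5)
        assert fit.params["const"] == pytest.approx(5.0)

    def test_collinear_design_rejected(self):
        df = generate_cohort(200, seed=3)
        df["age2"] = df["age"]
        with pytest.raises(ValueError, match="[Cc]ollinear|rank"):
            area_model(df, ["age", "age2"])


def mannwhitney_exact_oracle(a, b):
    """Exhaustive enumeration of the U null distribution (no ties)."""
    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = pd.Series(pooled).rank().values

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n * (n + 1) / 2

    observed = u_of(range(n))
    us = [u_of(c) for c in combinations(range(len(pooled)), n)]
    us = np.array(us)
    mean_u = len(a) * len(b) / 2
    p = np.mean(np.abs(us - mean_u) >= abs(observed - mean_u) - 1e-12)
    return observed, float(p)


class TestRankCompare:
    def test_matches_exhaustive_enumeration_small_n(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            a = rng.normal(size=5)
            b = rng.normal(size=4)
            u, p = rank_compare(a, b)
            u_oracle, p_oracle = mannwhitney_exact_oracle(a, b)
            assert u == pytest.approx(u_oracle)
            assert p == pytest.approx(p_oracle, abs=1e-9)

    def test_direction_sanity(self):
        a = np.array([10.0, 11, 12, 13])
        b = np.array([1.0, 2, 3, 4])
        u, p = rank_compare(a, b)
        assert u == 16.0  # every a beats every b
        assert p < 0.05

    def test_shifted_groups_detected_at_cohort_scale(self):
        """A 4 mm² shift at n = 150 per group is detected at alpha = 0.01 in
        most replicates."""
        rng_master = np.random.default_rng(23)
        sd = CohortGenParams().area_sd
        hits = 0
        n_rep = 25
        for _ in range(n_rep):
            a = rng_master.normal(24.5, sd, size=150)
            b = rng_master.normal(20.5, sd, size=150)
            _, p = rank_compare(a, b)
            hits += p < 0.01
        assert hits / n_rep >= 0.8

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_compare([], [1.0])


class TestNormalityScreen:
    def test_gaussian_passes_heavy_skew_fails(self):
        rng = np.random.default_rng(5)
        assert normality_screen(rng.normal(size=200))
        assert not normality_screen(np.exp(rng.normal(size=200) * 2))
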