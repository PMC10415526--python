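"""Group statistics: grouping, outliers, mixed ANOVA, post-hocs."""

import numpy as np
import pandas as pd
import pytest

from betasw.stats import (CELLS, check_assumptions, demographic_tests,
                          detect_extreme_outliers, make_sw_table,
                          mixed_anova, posthoc_pairwise)
from betasw.subjects import classify_fatigue


# ---------------------------------------------------------------------------
# helpers / oracles
# ---------------------------------------------------------------------------


def _long_table(wide: pd.DataFrame) -> pd.DataFrame:
    """wide: columns subject, fatigue_group, sex, then the 4 cell values."""
    rows = []
    for _, r in wide.iterrows():
        for net, hemi in CELLS:
            rows.append({"subject": r["subject"],
                         "fatigue_group": r["fatigue_group"],
                         "sex": r["sex"], "network": net,
                         "hemisphere": hemi, "Sw": r[(net, hemi)],
                         "excluded": False, "exclusion_reason": ""})
    return pd.DataFrame(rows)


def oracle_mixed_anova_balanced(wide: pd.DataFrame) -> dict:
    """Independent cell-means sums-of-squares oracle for balanced designs.

    Works stratum by stratum on hand-computed contrast scores: for each
    within-subject stratum z, the 2x2 between design with n0 subjects per
    group gives SS(contrast of group means) = n0 * L^2 for L built from
    half-sum coefficients, and the error SS is the within-group scatter.
    """
    Y = {c: wide[c].to_numpy() for c in CELLS}
    z = {
        "average": (Y[CELLS[0]] + Y[CELLS[1]] + Y[CELLS[2]] + Y[CELLS[3]]) / 2,
        "network": (-Y[CELLS[0]] - Y[CELLS[1]] + Y[CELLS[2]] + Y[CELLS[3]]) / 2,
        "hemisphere": (-Y[CELLS[0]] + Y[CELLS[1]] - Y[CELLS[2]] + Y[CELLS[3]]) / 2,
        "network:hemisphere":
            (Y[CELLS[0]] - Y[CELLS[1]] - Y[CELLS[2]] + Y[CELLS[3]]) / 2,
    }
    fat = wide["fatigue_group"].to_numpy()
    sex = wide["sex"].to_numpy()
    groups = [("high", "female"), ("high", "male"),
              ("low", "female"), ("low", "male")]
    n0 = len(wide) // 4
    df_err = len(wide) - 4
    out = {}
    for stratum, zv in z.items():
        means = {g: zv[(fat == g[0]) & (sex == g[1])].mean() for g in groups}
        sse = sum(((zv[(fat == g[0]) & (sex == g[1])] - means[g]) ** 2).sum()
                  for g in groups)
        mse = sse / df_err
        grand = np.mean(list(means.values()))
        L_fat = (means[("high", "female")] + means[("high", "male")]
                 - means[("low", "female")] - means[("low", "male")]) / 2
        L_sex = (means[("high", "female")] - means[("high", "male")]
                 + means[("low", "female")] - means[("low", "male")]) / 2
        L_int = (means[("high", "female")] - means[("high", "male")]
                 - means[("low", "female")] + means[("low", "male")]) / 2
        ss = {"grand": 4 * n0 * grand**2, "fat": n0 * L_fat**2,
              "sex": n0 * L_sex**2, "int": n0 * L_int**2}
        out[stratum] = {k: v / mse for k, v in ss.items()}
    F = {
        "fatigue": out["average"]["fat"],
        "sex": out["average"]["sex"],
        "fatigue:sex": out["average"]["int"],
        "network": out["network"]["grand"],
        "network:fatigue": out["network"]["fat"],
        "network:sex": out["network"]["sex"],
        "network:fatigue:sex": out["network"]["int"],
        "hemisphere": out["hemisphere"]["grand"],
        "hemisphere:fatigue": out["hemisphere"]["fat"],
        "network:hemisphere": out["network:hemisphere"]["grand"],
        "network:hemisphere:fatigue:sex": out["network:hemisphere"]["int"],
    }
    return F


def _balanced_wide(n0=2, seed=0, effects=None):
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for fat in ("low", "high"):
        for sex in ("male", "female"):
            for _ in range(n0):
                base = {c: 1.0 + 0.1 * rng.normal() for c in CELLS}
                if effects:
                    for c in CELLS:
                        base[c] += effects(fat, sex, c)
                rows.append({"subject": f"S{k}", "fatigue_group": fat,
                             "sex": sex,
                             "fss7": 5.5 if fat == "high" else 2.0, **base})
                k += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


class TestClassification:
    @pytest.mark.parametrize("fss,expected", [(5.6, "high"), (2.1, "low"),
                                              (4.0, "low"), (4.01, "high"),
                                              (1.0, "low"), (7.0, "high")])
    def test_threshold_rule(self, fss, expected):
        assert classify_fatigue(fss) == expected

    @pytest.mark.parametrize("bad", [0.5, 7.5, -1.0])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            classify_fatigue(bad)

    def test_make_sw_table_validates_grouping(self):
        wide = _balanced_wide()
        long = _long_table(wide)
        subjects = wide[["subject", "fatigue_group", "sex", "fss7"]].copy()
        subjects = subjects.rename(columns={"subject": "id"})
        subjects.loc[0, "fss7"] = 6.0  # low-group subject with high score
        with pytest.raises(ValueError, match="inconsistent"):
            make_sw_table(long.drop(columns=["excluded",
                                             "exclusion_reason"]), subjects)


class TestOutliers:
    def _table(self, values):
        rows = [{"subject": f"S{k}", "fatigue_group": "low", "sex": "male",
                 "network": "motor", "hemisphere": "right", "Sw": v,
                 "excluded": False, "exclusion_reason": ""}
                for k, v in enumerate(values)]
        return pd.DataFrame(rows)

    def test_clean_cell_unflagged(self):
        out = detect_extreme_outliers(self._table([1, 1.1, 0.9, 1.05]))
        assert not out["excluded"].any()

    def test_extreme_value_flagged(self):
        out = detect_extreme_outliers(self._table([1, 1.1, 0.9, 1.05, 9.0]))
        assert out.loc[out["Sw"] == 9.0, "excluded"].all()
        assert out["excluded"].sum() == 1

    def test_identical_cell_unflagged(self):
        out = detect_extreme_outliers(self._table([1.0] * 5))
        assert not out["excluded"].any()

    def test_small_cell_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            detect_extreme_outliers(self._table([1.0, 2.0, 3.0]))


class TestAssumptions:
    def test_gaussian_cells_pass_at_nominal_rate(self):
        rng = np.random.default_rng(0)
        passes = []
        for _ in range(100):
            rows = []
            for k in range(14):
                for grp in ("low", "high"):
                    rows.append({"subject": f"{grp}{k}",
                                 "fatigue_group": grp, "sex": "male",
                                 "network": "motor", "hemisphere": "left",
                                 "Sw": rng.normal(), "excluded": False})
            rep = check_assumptions(pd.DataFrame(rows))
            passes.extend(rep["shapiro"]["normal"].tolist())
        rate = np.mean(passes)
        assert 0.88 < rate < 0.99

    def test_skewed_cells_fail_often(self):
        rng = np.random.default_rng(1)
        fails = []
        for _ in range(60):
            rows = [{"subject": f"S{k}", "fatigue_group": "low",
                     "sex": "male", "network": "motor", "hemisphere": "left",
                     "Sw": rng.exponential() ** 2, "excluded": False}
                    for k in range(14)]
            rep = check_assumptions(pd.DataFrame(rows))
            fails.append(not rep["shapiro"]["normal"].iloc[0])
        assert np.mean(fails) > 0.5

    def test_constant_cell_not_assessable(self):
        rows = [{"subject": f"S{k}", "fatigue_group": "low", "sex": "male",
                 "network": "motor", "hemisphere": "left", "Sw": 1.0,
                 "excluded": False} for k in range(6)]
        rep = check_assumptions(pd.DataFrame(rows))
        assert not rep["shapiro"]["assessable"].iloc[0]


class TestMixedAnova:
    def test_matches_brute_force_oracle_on_balanced_toy(self):
        wide = _balanced_wide(n0=2, seed=3)
        result = mixed_anova(_long_table(wide))
        table = result.table.set_index("effect")
        oracle = oracle_mixed_anova_balanced(wide)
        for effect, F in oracle.items():
            assert table.loc[effect, "F"] == pytest.approx(F, abs=1e-10), \
                effect
        assert result.n_subjects == 8
        assert (table["df_den"] == 4).all()

    def test_matches_statsmodels_between_stratum(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        wide = _balanced_wide(n0=3, seed=4)
        result = mixed_anova(_long_table(wide)).table.set_index("effect")
        avg = wide[list(CELLS)].mean(axis=1) * 2.0  # orthonormal average
        df = pd.DataFrame({"z": avg, "fat": wide["fatigue_group"],
                           "sex": wide["sex"]})
        model = smf.ols(
            "z ~ C(fat, Sum) * C(sex, Sum)", data=df).fit()
        aov = sm.stats.anova_lm(model, typ=3)
        assert result.loc["fatigue", "F"] == pytest.approx(
            aov.loc["C(fat, Sum)", "F"], rel=1e-8)
        assert result.loc["sex", "F"] == pytest.approx(
            aov.loc["C(sex, Sum)", "F"], rel=1e-8)
        assert result.loc["fatigue:sex", "F"] == pytest.approx(
            aov.loc["C(fat, Sum):C(sex, Sum)", "F"], rel=1e-8)

    def test_planted_interaction_detected(self):
        def eff(fat, sex, cell):
            net = cell[0]
            if fat == "high":
                return 0.5 if net == "sensory" else -0.5
            return 0.0

        wide = _balanced_wide(n0=4, seed=5, effects=eff)
        table = mixed_anova(_long_table(wide)).table.set_index("effect")
        assert table.loc["network:fatigue", "p"] < 0.001
        assert table.loc["network:fatigue", "ges"] > 0.1

    def test_gg_is_identity_for_two_level_factors(self):
        result = mixed_anova(_long_table(_balanced_wide(n0=2, seed=6)))
        assert "epsilon = 1" in result.sphericity
        assert np.allclose(result.table["p"], result.table["p_gg"])

    def test_small_between_cell_is_an_error(self):
        wide = _balanced_wide(n0=2, seed=7)
        wide = wide[~((wide["fatigue_group"] == "high")
                      & (wide["sex"] == "female"))].copy()
        with pytest.raises(ValueError, match=">= 2 subjects"):
            mixed_anova(_long_table(wide))

    def test_incomplete_subjects_dropped_listwise(self):
        wide = _balanced_wide(n0=3, seed=8)
        long = _long_table(wide)
        long.loc[(long["subject"] == "S0")
                 & (long["network"] == "motor")
                 & (long["hemisphere"] == "right"), "excluded"] = True
        result = mixed_anova(long)
        assert result.dropped_subjects == ["S0"]
        assert result.n_subjects == 11

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(9)
        hits = 0
        n_sims = 200
        for _ in range(n_sims):
            wide = _balanced_wide(n0=4, seed=int(rng.integers(2**31)))
            table = mixed_anova(_long_table(wide)).table.set_index("effect")
            hits += table.loc["network:fatigue", "p"] < 0.05
        assert 0.02 <= hits / n_sims <= 0.10


class TestPosthoc:
    def test_identical_groups_adjusted_p_is_one(self):
        wide = _balanced_wide(n0=3, seed=10)
        # make the groups exactly identical within each cell
        for c in CELLS:
            vals = wide.loc[wide["fatigue_group"] == "low", [c]].to_numpy()
            wide.loc[wide["fatigue_group"] == "high", [c]] = vals
        out = posthoc_pairwise(_long_table(wide))
        fam = out[out["family"] == "group"]
        assert (fam["p_bonf"] == 1.0).all()

    def test_bonferroni_arithmetic_and_monotonicity(self):
        wide = _balanced_wide(n0=4, seed=11)
        out = posthoc_pairwise(_long_table(wide))
        ok = out.dropna(subset=["p_raw"])
        assert np.allclose(ok["p_bonf"],
                           np.minimum(1.0, ok["p_raw"] * ok["m"]))
        assert (ok["p_bonf"] >= ok["p_raw"] - 1e-15).all()
        assert (ok["p_bonf"] <= 1.0).all()

    def test_small_cells_skipped_with_reason(self):
        wide = _balanced_wide(n0=2, seed=12)
        wide = wide[~((wide["fatigue_group"] == "high")
                      & (wide["sex"] == "female"))]
        out = posthoc_pairwise(_long_table(wide))
        stratified = out[(out["family"] == "group_by_sex")
                         & (out["sex"] == "female")]
        assert stratified["note"].str.contains("skipped").all()

    def test_planted_single_cell_effect_found_where_planted(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(30):
            def eff(fat, sex, cell):
                if fat == "high" and cell == ("sensory", "right"):
                    return 0.6
                return 0.0
            wide = _balanced_wide(n0=4, seed=int(rng.integers(2**31)),
                                  effects=eff)
            out = posthoc_pairwise(_long_table(wide))
            fam = out[out["family"] == "group"].set_index(
                ["network", "hemisphere"])
            hits += fam["p_bonf"].idxmin() == ("sensory", "right")
        assert hits >= 24  # >= 80%


class TestDemographics:
    def _subjects(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        fss = np.linspace(1.5, 6.5, n)
        return pd.DataFrame({
            "id": [f"S{k}" for k in range(n)],
            "fss7": fss,
            "age": rng.normal(60, 5, n),
            "grip_pct": rng.normal(95, 5, n),
            "nhpt_pct": rng.normal(90, 5, n),
            "hads_anx": rng.integers(0, 10, n),
            "hads_dep": rng.integers(0, 10, n),
            "time_post_stroke": rng.uniform(1, 10, n),
            "sex": ["male", "female"] * (n // 2),
            "hemisphere_affected": ["left"] * (n // 2) + ["right"] * (n // 2),
            "stroke_type": ["ischaemic"] * (n - 2) + ["hemorrhagic"] * 2,
            "vascular_territory": ["MCA"] * (n - 1) + [None],
        })

    def test_perfect_monotone_association(self):
        subjects = self._subjects()
        subjects["age"] = subjects["fss7"] * 2 + 1
        rep = demographic_tests(subjects)
        row = rep["spearman"].set_index("variable").loc["age"]
        assert row["rho"] == pytest.approx(1.0)
        subjects["age"] = -subjects["fss7"]
        rep = demographic_tests(subjects)
        row = rep["spearman"].set_index("variable").loc["age"]
        assert row["rho"] == pytest.approx(-1.0)

    def test_exact_ranksum_three_vs_three(self):
        subjects = self._subjects(n=6)
        subjects["sex"] = ["male"] * 3 + ["female"] * 3
        subjects["fss7"] = [1.1, 1.3, 1.6, 5.0, 5.5, 6.0]  # disjoint
        rep = demographic_tests(subjects)
        row = rep["categorical"].set_index("variable").loc["sex"]
        assert row["p"] == pytest.approx(0.1, abs=1e-12)
        assert row["r"] > 0

    def test_kruskal_skipped_when_sparse(self):
        subjects = self._subjects()
        subjects.loc[:, "vascular_territory"] = (
            ["MCA"] * 8 + ["PCA", None])
        rep = demographic_tests(subjects)
        assert "skipped" in rep["kruskal_vascular"]["note"]

    def test_kruskal_eta_squared_computed(self):
        subjects = self._subjects(n=12, seed=2)
        subjects["vascular_territory"] = (["MCA"] * 4 + ["PCA"] * 4
                                          + ["Brainstem/Cerebellum"] * 4)
        rep = demographic_tests(subjects)
        kw = rep["kruskal_vascular"]
        expected = (kw["H"] - 3 + 1) / (12 - 3)
        assert kw["eta2"] == pytest.approx(expected)

    def test_all_tied_not_assessable(self):
        subjects = self._subjects()
        subjects["age"] = 50.0
        rep = demographic_tests(subjects)
        row = rep["spearman"].set_index("variable").loc["age"]
        assert not row["assessable"]
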