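"""Group-level statistics on the small-world index.

The inferential stage mirrors a classical mixed-design analysis:

* grouping by trait fatigue (FSS-7 > 4),
* per-cell extreme-outlier exclusion (3 x IQR fences),
* assumption checks (Shapiro-Wilk normality, Levene homogeneity),
* a three-way mixed ANOVA on Sw with two between-subject factors
  (fatigue, sex) and two within-subject factors (network, hemisphere),
* Bonferroni-adjusted post-hoc t-tests,
* Spearman / Wilcoxon rank-sum / Kruskal-Wallis demographics tests.

With two-level within factors, sphericity holds trivially (epsilon = 1), so
the Greenhouse-Geisser adjustment leaves the p-values unchanged; this is
reported explicitly.  The ANOVA is computed by the orthonormal-contrast
decomposition: the four within-cell responses of each subject are rotated
into (average, network contrast, hemisphere contrast, interaction
contrast), and each rotated variable is analysed as a univariate 2 x 2
between-subjects regression with Type III partial sums of squares.  Effect
sizes are generalized eta squared (SS_effect over SS_effect plus all
subject-related error SS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .subjects import classify_fatigue

__all__ = [
    "make_sw_table",
    "detect_extreme_outliers",
    "check_assumptions",
    "mixed_anova",
    "AnovaResult",
    "posthoc_pairwise",
    "demographic_tests",
]

#: fixed cell order for the within-subject design
CELLS = (("motor", "left"), ("motor", "right"),
         ("sensory", "left"), ("sensory", "right"))

#: orthonormal within-subject contrasts over CELLS (rows have unit norm)
_CONTRASTS = {
    "average": np.array([1, 1, 1, 1]) / 2.0,
    "network": np.array([-1, -1, 1, 1]) / 2.0,       # sensory - motor
    "hemisphere": np.array([-1, 1, -1, 1]) / 2.0,    # right - left
    "network:hemisphere": np.array([1, -1, -1, 1]) / 2.0,
}

_EFFECT_NAMES = {
    "average": ("fatigue", "sex", "fatigue:sex"),
    "network": ("network", "network:fatigue", "network:sex",
                "network:fatigue:sex"),
    "hemisphere": ("hemisphere", "hemisphere:fatigue", "hemisphere:sex",
                   "hemisphere:fatigue:sex"),
    "network:hemisphere": ("network:hemisphere", "network:hemisphere:fatigue",
                           "network:hemisphere:sex",
                           "network:hemisphere:fatigue:sex"),
}


def make_sw_table(metrics: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Long-format Sw table: one row per subject x network x hemisphere.

    ``metrics`` needs columns (subject, network, hemisphere, Sw); group and
    sex are joined from the subject table and the stored fatigue group is
    validated against the FSS-7 > 4 rule.
    """
    sub = subjects.rename(columns={"id": "subject"})
    for _, row in sub.iterrows():
        if classify_fatigue(row["fss7"]) != row["fatigue_group"]:
            raise ValueError(
                f"subject {row['subject']}: stored group inconsistent with FSS-7"
            )
    out = metrics.merge(sub[["subject", "fatigue_group", "sex", "fss7"]],
                        on="subject", how="left")
    if out["fatigue_group"].isna().any():
        missing = out.loc[out["fatigue_group"].isna(), "subject"].unique()
        raise ValueError(f"subjects missing from the subject table: {missing}")
    out["excluded"] = False
    out["exclusion_reason"] = ""
    return out


def detect_extreme_outliers(sw: pd.DataFrame, k: float = 3.0) -> pd.DataFrame:
    """Flag Sw values outside [Q1 - k*IQR, Q3 + k*IQR] within each cell.

    Cells are network x hemisphere strata (pooled over groups); k = 3 gives
    the conventional 'extreme outlier' fences.  Flagged rows are marked
    ``excluded`` with a reason and left in the table.
    """
    out = sw.copy()
    for (net, hemi), grp in out.groupby(["network", "hemisphere"]):
        vals = grp["Sw"].to_numpy()
        if len(vals) < 4:
            raise ValueError(
                f"cell {net}/{hemi} has {len(vals)} values; need >= 4"
            )
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        bad = (vals < lo) | (vals > hi)
        idx = grp.index[bad]
        out.loc[idx, "excluded"] = True
        out.loc[idx, "exclusion_reason"] = (
            f"extreme outlier in {net}/{hemi} (outside [{lo:.4g}, {hi:.4g}])"
        )
    return out


def check_assumptions(sw: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk per cell and Levene per factor, on non-excluded rows."""
    df = sw.loc[~sw["excluded"]]
    shapiro_rows = []
    for (net, hemi, grp), cell in df.groupby(
            ["network", "hemisphere", "fatigue_group"]):
        vals = cell["Sw"].to_numpy()
        if len(vals) < 3 or np.ptp(vals) == 0:
            shapiro_rows.append({"network": net, "hemisphere": hemi,
                                 "fatigue_group": grp, "n": len(vals),
                                 "p": np.nan, "assessable": False,
                                 "normal": None})
            continue
        p = float(sps.shapiro(vals).pvalue)
        shapiro_rows.append({"network": net, "hemisphere": hemi,
                             "fatigue_group": grp, "n": len(vals), "p": p,
                             "assessable": True, "normal": p > alpha})
    levene_rows = []
    for (net, hemi), cell in df.groupby(["network", "hemisphere"]):
        for factor in ("fatigue_group", "sex"):
            groups = [g["Sw"].to_numpy() for _, g in cell.groupby(factor)]
            if len(groups) < 2 or any(len(g) < 2 for g in groups):
                levene_rows.append({"network": net, "hemisphere": hemi,
                                    "factor": factor, "p": np.nan,
                                    "assessable": False, "homogeneous": None})
                continue
            p = float(sps.levene(*groups).pvalue)
            levene_rows.append({"network": net, "hemisphere": hemi,
                                "factor": factor, "p": p, "assessable": True,
                                "homogeneous": p > alpha})
    return {"shapiro": pd.DataFrame(shapiro_rows),
            "levene": pd.DataFrame(levene_rows)}


@dataclass
class AnovaResult:
    table: pd.DataFrame
    n_subjects: int
    dropped_subjects: list
    sphericity: str = ("both within factors have 2 levels: sphericity holds "
                       "trivially (Greenhouse-Geisser epsilon = 1); "
                       "adjusted and unadjusted p coincide")


def _wide_sw(sw: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Subject x 4-cell wide table, listwise-dropping incomplete subjects."""
    df = sw.loc[~sw["excluded"]]
    wide = df.pivot_table(index=["subject", "fatigue_group", "sex"],
                          columns=["network", "hemisphere"], values="Sw",
                          aggfunc="first")
    cols = [c for c in CELLS if c in wide.columns]
    if len(cols) < 4:
        raise ValueError("missing whole network x hemisphere cells")
    complete = wide[list(CELLS)].dropna()
    dropped = sorted(set(wide.index.get_level_values("subject"))
                     - set(complete.index.get_level_values("subject")))
    return complete.reset_index(), dropped


def mixed_anova(sw: pd.DataFrame) -> AnovaResult:
    """Three-way mixed ANOVA on Sw: (fatigue, sex) between, (network,
    hemisphere) within.

    Subjects with any missing cell (e.g. excluded outliers) are dropped
    listwise.  Returns F, df, p and generalized eta squared for all 15
    effects.  Raises if any fatigue x sex cell has fewer than 2 subjects.
    """
    wide, dropped = _wide_sw(sw)
    n = len(wide)
    counts = wide.groupby(["fatigue_group", "sex"]).size()
    if len(counts) < 4 or counts.min() < 2:
        raise ValueError(
            f"each fatigue x sex cell needs >= 2 subjects, got\n{counts}"
        )
    Y = wide[list(CELLS)].to_numpy()  # (n, 4)
    f = np.where(wide["fatigue_group"] == "high", 1.0, -1.0)
    s = np.where(wide["sex"] == "female", 1.0, -1.0)
    X = np.column_stack([np.ones(n), f, s, f * s])
    XtX_inv = np.linalg.inv(X.T @ X)
    df_err = n - 4

    strata = {}
    for cname, c in _CONTRASTS.items():
        z = Y @ c
        beta = XtX_inv @ (X.T @ z)
        resid = z - X @ beta
        sse = float(resid @ resid)
        # Type III partial SS for each single-df term
        ss_terms = beta**2 / np.diag(XtX_inv)
        strata[cname] = (ss_terms, sse)

    total_error_ss = sum(sse for _, sse in strata.values())
    rows = []
    for cname, (ss_terms, sse) in strata.items():
        mse = sse / df_err
        # term 0 is the intercept: a real effect only in the contrast strata
        term_idx = (1, 2, 3) if cname == "average" else (0, 1, 2, 3)
        names = _EFFECT_NAMES[cname]
        for name, j in zip(names, term_idx):
            ss = float(ss_terms[j])
            F = ss / mse
            p = float(sps.f.sf(F, 1, df_err))
            ges = ss / (ss + total_error_ss)
            rows.append({"effect": name, "F": F, "df_num": 1,
                         "df_den": df_err, "p": p, "p_gg": p, "ges": ges,
                         "error_SS": sse, "effect_SS": ss})
    order = ["fatigue", "sex", "fatigue:sex", "network", "hemisphere",
             "network:hemisphere", "network:fatigue", "network:sex",
             "hemisphere:fatigue", "hemisphere:sex",
             "network:fatigue:sex", "hemisphere:fatigue:sex",
             "network:hemisphere:fatigue", "network:hemisphere:sex",
             "network:hemisphere:fatigue:sex"]
    table = (pd.DataFrame(rows).set_index("effect").loc[order].reset_index())
    return AnovaResult(table=table, n_subjects=n, dropped_subjects=dropped)


def _t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b)
    return float(t), float(p)


def posthoc_pairwise(sw: pd.DataFrame) -> pd.DataFrame:
    """Bonferroni-adjusted low-vs-high t-tests per network x hemisphere.

    Two families are kept separate: the 4 pooled group contrasts
    (m = 4), and the 8 sex-stratified contrasts (m = 8).  Cells with
    fewer than 2 subjects per group are skipped with a reason.
    """
    df = sw.loc[~sw["excluded"]]
    rows = []
    for family, strata in (("group", [None]), ("group_by_sex",
                                               ["male", "female"])):
        combos = [(net, hemi, sex) for net, hemi in CELLS for sex in strata]
        m = len(combos)
        for net, hemi, sex in combos:
            cell = df[(df["network"] == net) & (df["hemisphere"] == hemi)]
            if sex is not None:
                cell = cell[cell["sex"] == sex]
            lo = cell.loc[cell["fatigue_group"] == "low", "Sw"].to_numpy()
            hi = cell.loc[cell["fatigue_group"] == "high", "Sw"].to_numpy()
            row = {"family": family, "network": net, "hemisphere": hemi,
                   "sex": sex or "all", "n_low": len(lo), "n_high": len(hi),
                   "m": m}
            if len(lo) < 2 or len(hi) < 2:
                row.update({"t": np.nan, "p_raw": np.nan, "p_bonf": np.nan,
                            "note": "skipped: fewer than 2 per group"})
            else:
                t, p = _t_test(lo, hi)
                row.update({"t": t, "p_raw": p,
                            "p_bonf": min(1.0, p * m), "note": ""})
            rows.append(row)
    return pd.DataFrame(rows)


def _ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Two-sided Wilcoxon rank-sum: p (exact when feasible), z, r = |z|/sqrt(n)."""
    n1, n2 = len(x), len(y)
    ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    method = "exact" if (not ties and max(n1, n2) <= 25) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    nt = n1 + n2
    tie_term = (counts**3 - counts).sum() / (nt * (nt - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * (nt + 1 - tie_term))
    z = 0.0 if sigma == 0 else (u - mu) / sigma
    return float(res.pvalue), z, abs(z) / np.sqrt(nt)


def demographic_tests(subjects: pd.DataFrame) -> dict:
    """Associations between FSS-7 and demographic / clinical covariates.

    Spearman rank correlation for continuous covariates; Wilcoxon rank-sum
    (with effect size r = |z| / sqrt(n)) for two-level categorical
    covariates; Kruskal-Wallis (with rank eta squared) for vascular
    territory, skipped when any territory has fewer than 2 subjects.
    Missing values are dropped pairwise per test.
    """
    fss = subjects["fss7"]
    spearman_rows = []
    for var in ("age", "grip_pct", "nhpt_pct", "hads_anx", "hads_dep",
                "time_post_stroke"):
        mask = subjects[var].notna() & fss.notna()
        x, y = fss[mask].to_numpy(), subjects.loc[mask, var].to_numpy()
        if mask.sum() < 5:
            spearman_rows.append({"variable": var, "n": int(mask.sum()),
                                  "rho": np.nan, "p": np.nan,
                                  "assessable": False})
            continue
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            spearman_rows.append({"variable": var, "n": int(mask.sum()),
                                  "rho": np.nan, "p": np.nan,
                                  "assessable": False})
            continue
        rho, p = sps.spearmanr(x, y)
        spearman_rows.append({"variable": var, "n": int(mask.sum()),
                              "rho": float(rho), "p": float(p),
                              "assessable": True})

    cat_rows = []
    for var in ("sex", "hemisphere_affected", "stroke_type"):
        mask = subjects[var].notna() & fss.notna()
        levels = sorted(subjects.loc[mask, var].unique())
        if len(levels) != 2:
            cat_rows.append({"variable": var, "p": np.nan, "r": np.nan,
                             "note": f"needs 2 levels, has {len(levels)}"})
            continue
        a = fss[mask & (subjects[var] == levels[0])].to_numpy()
        b = fss[mask & (subjects[var] == levels[1])].to_numpy()
        if min(len(a), len(b)) < 2:
            cat_rows.append({"variable": var, "p": np.nan, "r": np.nan,
                             "note": "skipped: fewer than 2 per level"})
            continue
        p, z, r = _ranksum(a, b)
        cat_rows.append({"variable": var, "levels": "/".join(levels),
                         "n": len(a) + len(b), "p": p, "z": z, "r": r,
                         "note": ""})

    terr = subjects.dropna(subset=["vascular_territory", "fss7"])
    groups = [g["fss7"].to_numpy()
              for _, g in terr.groupby("vascular_territory")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        kw = {"test": "kruskal", "p": np.nan, "eta2": np.nan,
              "note": "skipped: too few subjects in some territory"}
    else:
        H, p = sps.kruskal(*groups)
        k, ntot = len(groups), sum(len(g) for g in groups)
        kw = {"test": "kruskal", "H": float(H), "p": float(p),
              "eta2": float((H - k + 1) / (ntot - k)), "note": ""}
    return {"spearman": pd.DataFrame(spearman_rows),
            "categorical": pd.DataFrame(cat_rows),
            "kruskal_vascular": kw}
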