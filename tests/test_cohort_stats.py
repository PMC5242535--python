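"""Grubbs screening, factorial ANOVA, Bonferroni correlations, post-hocs."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from neuropheno.cohort_stats import (
    bonferroni_alpha,
    bonferroni_correlations,
    factorial_anova,
    grubbs_critical,
    grubbs_screen,
    posthoc_bonferroni,
)
from neuropheno.types import InsufficientDataError


def test_grubbs_symmetric_small_set_no_outlier():
    assert not grubbs_screen([1.0, 2.0, 3.0]).is_outlier


def test_grubbs_hand_case():
    """{1,1,1,10}: G = 6.75/4.5 = 1.5 > critical ~1.481 at alpha=0.05."""
    res = grubbs_screen([1.0, 1.0, 1.0, 10.0])
    assert res.g == pytest.approx(1.5)
    assert res.critical == pytest.approx(1.4813, abs=1e-3)
    assert res.outlier_index == 3
    # the critical value comes from the t-quantile formula
    t = stats.t.ppf(1 - 0.05 / 8, 2)
    assert res.critical == pytest.approx(3 / 2 * math.sqrt(t**2 / (2 + t**2)))


def test_grubbs_vanishing_alpha_never_flags():
    assert not grubbs_screen([1.0, 2.0, 3.0, 10.0], alpha=1e-12).is_outlier
    # {1,1,1,10} attains the maximal G = (n-1)/sqrt(n); in the alpha -> 0
    # limit the criterion tends to that supremum and nothing is flagged
    assert not grubbs_screen([1.0, 1.0, 1.0, 10.0], alpha=1e-320).is_outlier


def test_grubbs_zero_variance_is_no_outlier():
    assert not grubbs_screen([5.0, 5.0, 5.0, 5.0]).is_outlier


def test_grubbs_needs_three_values():
    with pytest.raises(InsufficientDataError):
        grubbs_screen([1.0, 2.0])


@settings(derandomize=True, max_examples=30)
@given(shift=st.floats(-100, 100), scale=st.floats(0.01, 100))
def test_grubbs_affine_invariance(shift, scale):
    base = np.array([1.0, 2.0, 2.5, 3.0, 9.0])
    r1 = grubbs_screen(base)
    r2 = grubbs_screen(base * scale + shift)
    assert r1.outlier_index == r2.outlier_index
    assert r1.g == pytest.approx(r2.g, rel=1e-9)


def balanced_2x2(cell_means, n=4, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for (g, s), mu in cell_means.items():
        for _ in range(n):
            rows.append({"genotype": g, "sex": s,
                         "value": mu + rng.normal(0, noise) if noise else mu})
    return pd.DataFrame(rows)


def test_anova_constant_response_gives_zero_f():
    df = balanced_2x2({("WT", "M"): 5.0, ("WT", "F"): 5.0,
                       ("HD", "M"): 5.0, ("HD", "F"): 5.0})
    res = factorial_anova(df, ["genotype", "sex"])
    assert res.f("genotype") == 0.0
    assert res.f("genotype:sex") == 0.0
    assert res.p("sex") == 1.0


def textbook_two_way(df):
    """Independent oracle: classical balanced two-way decomposition."""
    cells = df.groupby(["genotype", "sex"])["value"]
    n = cells.count().iloc[0]
    grand = df["value"].mean()
    a_means = df.groupby("genotype")["value"].mean()
    b_means = df.groupby("sex")["value"].mean()
    ss_a = n * 2 * ((a_means - grand) ** 2).sum()
    ss_b = n * 2 * ((b_means - grand) ** 2).sum()
    cell_means = cells.mean()
    ss_cells = n * ((cell_means - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    sse = ((df["value"] - df.merge(
        cell_means.rename("cm"), on=["genotype", "sex"])["cm"]) ** 2).sum()
    dfe = len(df) - 4
    return {"genotype": (ss_a / 1) / (sse / dfe),
            "sex": (ss_b / 1) / (sse / dfe),
            "genotype:sex": (ss_ab / 1) / (sse / dfe)}


def test_anova_balanced_matches_textbook_decomposition():
    df = balanced_2x2({("WT", "M"): 10.0, ("WT", "F"): 12.0,
                       ("HD", "M"): 7.0, ("HD", "F"): 11.0},
                      n=5, noise=1.0, seed=4)
    res = factorial_anova(df, ["genotype", "sex"])
    oracle = textbook_two_way(df)
    assert res.f("genotype") == pytest.approx(oracle["genotype"], rel=1e-6)
    assert res.f("sex") == pytest.approx(oracle["sex"], rel=1e-6)
    assert res.f("genotype:sex") == pytest.approx(oracle["genotype:sex"], rel=1e-6)


def test_anova_effect_grows_with_planted_difference():
    fs = []
    for effect in (0.0, 1.0, 3.0):
        df = balanced_2x2({("WT", "M"): 10.0, ("WT", "F"): 10.0,
                           ("HD", "M"): 10.0 - effect, ("HD", "F"): 10.0 - effect},
                          n=8, noise=1.0, seed=1)
        fs.append(factorial_anova(df, ["genotype", "sex"]).f("genotype"))
    assert fs[0] < fs[1] < fs[2]


def test_anova_three_way_on_cohort_table():
    from neuropheno.synthetic import default_trajectory_config, generate_cohort

    traj = default_trajectory_config(missing_rate=0.05, outlier_rate=0.0)
    table = generate_cohort(traj, n_per_cell=6, ages=[36, 94], seed=3)
    loco = table[table["measure"] == "locomotor_distance"]
    res = factorial_anova(loco, ["genotype", "sex", "age_weeks"])
    assert res.f("genotype") > 0
    assert res.p("genotype") < 0.05  # the configured deficit is detectable


def test_anova_empty_level_raises():
    df = balanced_2x2({("WT", "M"): 10.0, ("WT", "F"): 12.0,
                       ("HD", "M"): 7.0, ("HD", "F"): 11.0})
    df.loc[df["genotype"] == "HD", "value"] = np.nan
    with pytest.raises(InsufficientDataError):
        factorial_anova(df, ["genotype", "sex"])


def test_bonferroni_adjusted_alpha_values():
    """6 measures -> alpha 0.05/15 = 0.0033; 7 -> 0.05/21 = 0.0024."""
    assert round(bonferroni_alpha(6), 4) == 0.0033
    assert round(bonferroni_alpha(7), 4) == 0.0024
    assert bonferroni_alpha(2) == 0.05


def test_correlation_plan_structure_and_psd():
    rng = np.random.default_rng(2)
    base = rng.normal(size=(40, 1))
    wide = pd.DataFrame(
        base + 0.5 * rng.normal(size=(40, 4)),
        columns=["a", "b", "c", "d"])
    plan = bonferroni_correlations(wide)
    r = plan.r.to_numpy()
    assert np.allclose(r, r.T)
    assert np.allclose(np.diag(r), 1.0)
    assert np.abs(r).max() <= 1.0
    assert np.linalg.eigvalsh(r).min() > -1e-10
    assert plan.n_comparisons == 6
    assert plan.adjusted_alpha == pytest.approx(0.05 / 6)
    # strongly shared signal should survive the Bonferroni gate
    assert plan.significant.to_numpy().any()


def test_correlation_insufficient_pairs_omitted():
    wide = pd.DataFrame({"a": [1.0, 2.0, np.nan, np.nan],
                         "b": [np.nan, np.nan, 1.0, 2.0],
                         "c": [1.0, 2.0, 3.0, 4.0]})
    with pytest.warns(RuntimeWarning):
        plan = bonferroni_correlations(wide)
    assert np.isnan(plan.r.loc["a", "b"])


def test_posthoc_identical_groups_not_flagged():
    df = pd.DataFrame({"group": ["a"] * 6 + ["b"] * 6,
                       "value": [5.0, 5.1, 4.9, 5.0, 5.2, 4.8] * 2})
    res = posthoc_bonferroni(df, "group")
    assert (res["p_adjusted"] > 0.5).all()


def test_posthoc_three_groups_triple_raw_p():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "group": np.repeat(["a", "b", "c"], 8),
        "value": rng.normal(size=24)})
    res = posthoc_bonferroni(df, "group")
    assert len(res) == 3
    assert np.allclose(res["p_adjusted"],
                       np.minimum(1.0, res["p_raw"] * 3))


def test_posthoc_planted_pair_detected():
    """Only the truly different pair is flagged in >=90% of repeats."""
    hits, false = 0, 0
    n_rep = 40
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "group": np.repeat(["a", "b", "c"], 10),
            "value": np.concatenate([
                rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                rng.normal(2.5, 1, 10)])})
        res = posthoc_bonferroni(df, "group").set_index(["group_a", "group_b"])
        if res.loc[("a", "c"), "p_adjusted"] < 0.05 \
                and res.loc[("b", "c"), "p_adjusted"] < 0.05:
            hits += 1
        if res.loc[("a", "b"), "p_adjusted"] < 0.05:
            false += 1
    assert hits / n_rep >= 0.9
    assert false / n_rep <= 0.15
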