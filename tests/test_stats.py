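"""Normalization, fold changes, dose-response correlation, group comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from inflamnet import (
    MissingControlError,
    compare_groups,
    dose_response_correlation,
    et_ratio_to_dose,
    log_fold_change,
    normalize_teer,
    normalize_to_control,
    stars,
)
from inflamnet.stats import _dunn_test, results_to_frame


def make_dataset(rng, analytes=("IL-6", "TNF-a"), conditions=("media", "LPS", "ccm"),
                 n_exp=3, n_rep=3, scale=None):
    rows = []
    for an, cond, e, r in itertools.product(
        analytes, conditions, range(1, n_exp + 1), range(1, n_rep + 1)
    ):
        base = {"media": 10, "LPS": 100, "ccm": 50}[cond]
        val = base * float(rng.lognormal(0, 0.1))
        if scale:
            val *= scale.get(e, 1.0)
        rows.append({"analyte": an, "condition": cond, "experiment": e,
                     "replicate": r, "concentration": val})
    return pd.DataFrame(rows)


# ------------------------------------------------------------ normalization


def test_control_normalizes_to_one(rng):
    df = make_dataset(rng)
    norm = normalize_to_control(df, "LPS")
    ctrl_means = (
        norm[norm.condition == "LPS"]
        .groupby(["analyte", "experiment"])["concentration"].mean()
    )
    assert np.allclose(ctrl_means, 1.0)


def test_double_control_value_maps_to_two(rng):
    df = pd.DataFrame({
        "analyte": "IL-6", "condition": ["LPS"] * 3 + ["ccm"],
        "experiment": 1, "replicate": [1, 2, 3, 1],
        "concentration": [10.0, 10.0, 10.0, 20.0],
    })
    norm = normalize_to_control(df, "LPS")
    assert norm.loc[norm.condition == "ccm", "concentration"].item() == 2.0


def test_normalization_groupby_oracle_and_scale_invariance(rng):
    df = make_dataset(rng, scale={1: 1.0, 2: 3.7, 3: 0.2})
    norm = normalize_to_control(df, "LPS")
    # independent group-by oracle
    for (an, e), grp in df.groupby(["analyte", "experiment"]):
        ctrl_mean = grp.loc[grp.condition == "LPS", "concentration"].mean()
        got = norm[(norm.analyte == an) & (norm.experiment == e)]
        np.testing.assert_allclose(
            got["concentration"], got["concentration_raw"] / ctrl_mean
        )
    # multiplying one experiment's raw values by any constant changes nothing
    df2 = df.copy()
    mask = df2.experiment == 2
    df2.loc[mask, "concentration"] *= 123.4
    norm2 = normalize_to_control(df2, "LPS")
    np.testing.assert_allclose(norm["concentration"], norm2["concentration"])


def test_missing_control_names_orphan(rng):
    df = make_dataset(rng)
    df = df[~((df.analyte == "TNF-a") & (df.experiment == 2)
              & (df.condition == "LPS"))]
    with pytest.raises(MissingControlError, match="TNF-a"):
        normalize_to_control(df, "LPS")
    with pytest.raises(MissingControlError):
        normalize_to_control(df, "nonexistent")


def test_teer_normalization(rng):
    df = pd.DataFrame({
        "condition": ["media"] * 3 + ["ccm"] * 3,
        "experiment": 1,
        "resistance": [200.0, 200.0, 200.0, 100.0, 100.0, 100.0],
    })
    norm = normalize_teer(df, "media")
    assert np.allclose(norm.loc[norm.condition == "media", "resistance"], 1.0)
    assert np.allclose(norm.loc[norm.condition == "ccm", "resistance"], 0.5)


# ------------------------------------------------------------- fold change


def test_lfc_trivial_values():
    df = pd.DataFrame({
        "analyte": "IL-6",
        "condition": ["media"] * 3 + ["same"] * 3 + ["quad"] * 3,
        "concentration": [10.0] * 3 + [10.0] * 3 + [40.0] * 3,
    })
    lfc = log_fold_change(df, "media", pseudocount=0)
    d = dict(zip(lfc.condition, lfc.lfc))
    assert d["same"] == pytest.approx(0.0)
    assert d["quad"] == pytest.approx(2.0)


def test_lfc_antisymmetry(rng):
    df = make_dataset(rng, conditions=("media", "ccm"))
    fwd = log_fold_change(df, "media", pseudocount=0)
    rev = log_fold_change(df, "ccm", pseudocount=0)
    merged = fwd.merge(rev, on="analyte", suffixes=("_f", "_r"))
    np.testing.assert_allclose(merged["lfc_f"], -merged["lfc_r"])


def test_lfc_recovers_programmed_fold_changes(rng):
    prog = {"half": 0.5, "same": 1.0, "eight": 8.0}
    rows = []
    for cond, fold in [("media", 1.0)] + list(prog.items()):
        for r in range(30):
            rows.append({"analyte": "x", "condition": cond,
                         "concentration": 100 * fold * float(rng.lognormal(0, 0.05))})
    lfc = log_fold_change(pd.DataFrame(rows), "media", pseudocount=0)
    d = dict(zip(lfc.condition, lfc.lfc))
    assert d["half"] == pytest.approx(-1.0, abs=0.1)
    assert d["same"] == pytest.approx(0.0, abs=0.1)
    assert d["eight"] == pytest.approx(3.0, abs=0.1)


def test_lfc_zero_baseline_requires_pseudocount():
    df = pd.DataFrame({
        "analyte": "x", "condition": ["media", "ccm"] * 2,
        "concentration": [0.0, 0.0, 0.0, 0.0],
    })
    with pytest.raises(ValueError, match="pseudocount"):
        log_fold_change(df, "media", pseudocount=0)


# ------------------------------------------------------------ dose response


def test_dose_proportional_gives_r_one():
    df = pd.DataFrame({
        "analyte": "IL-6", "dose": [0.2, 1.0, 5.0] * 3,
        "concentration": [c * 7.0 for c in [0.2, 1.0, 5.0] * 3],
    })
    out = dose_response_correlation(df)
    assert out.loc[0, "r"] == pytest.approx(1.0)
    assert not out.loc[0, "undefined"]


def test_dose_constant_flagged_undefined():
    df = pd.DataFrame({
        "analyte": "IL-6", "dose": [0.2, 1.0, 5.0] * 3, "concentration": 4.2,
    })
    out = dose_response_correlation(df)
    assert bool(out.loc[0, "undefined"])


def test_dose_correlation_formula_oracle(rng):
    doses = np.repeat([0.2, 1.0, 5.0], 9)
    conc = 3 * doses + rng.normal(0, 1, doses.size)
    df = pd.DataFrame({"analyte": "x", "dose": doses, "concentration": conc})
    out = dose_response_correlation(df)
    r_hand = (
        np.mean(doses * conc) - doses.mean() * conc.mean()
    ) / (doses.std() * conc.std())
    assert out.loc[0, "r"] == pytest.approx(r_hand, abs=1e-12)


def test_too_few_doses_raises():
    df = pd.DataFrame({"analyte": "x", "dose": [1, 1, 2], "concentration": [1, 2, 3]})
    with pytest.raises(ValueError, match="3 distinct"):
        dose_response_correlation(df)


def test_et_ratio_mapping():
    assert et_ratio_to_dose("1:5") == pytest.approx(0.2)
    assert et_ratio_to_dose("1:1") == 1.0
    assert et_ratio_to_dose("5:1") == 5.0


# -------------------------------------------------------- group comparison


def _groups_df(groups: dict[str, np.ndarray], analyte="x") -> pd.DataFrame:
    rows = [
        {"analyte": analyte, "condition": g, "concentration": float(v)}
        for g, vals in groups.items() for v in vals
    ]
    return pd.DataFrame(rows)


def test_identical_groups_not_significant(rng):
    base = rng.normal(10, 1, 9)
    res = compare_groups(_groups_df({"a": base, "b": base.copy()}))
    omnibus = res[0]
    assert omnibus.p > 0.9 and omnibus.stars == "ns"


def test_huge_effect_four_stars(rng):
    g1 = rng.normal(0, 1, 9)
    g2 = rng.normal(5, 1, 9)
    res = compare_groups(_groups_df({"a": g1, "b": g2}))
    posthoc = [r for r in res if r.test in ("Tukey HSD", "Dunn")]
    assert all(r.stars == "****" for r in posthoc)
    # cross-check the omnibus against a direct F computation
    omnibus = res[0]
    if omnibus.test == "one-way ANOVA":
        f_direct, p_direct = sps.f_oneway(g1, g2)
        assert omnibus.statistic == pytest.approx(float(f_direct))
        assert omnibus.p == pytest.approx(float(p_direct))


def test_bonferroni_is_min_one_m_times_p(rng):
    """3-group fixture: adjusted post-hoc p equals min(1, 3 * p_raw)."""
    groups = {g: rng.normal(m, 1, 9) for g, m in [("a", 0), ("b", 0.8), ("c", 5)]}
    res = compare_groups(_groups_df(groups))
    posthoc = [r for r in res if r.test in ("Tukey HSD", "Dunn")]
    assert len(posthoc) == 3
    for r in posthoc:
        assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p))
        assert r.p_adjusted >= r.p


def test_nonnormal_data_routes_to_kruskal(rng):
    g1 = rng.lognormal(0, 2, 30) ** 2  # wildly non-normal
    g2 = rng.lognormal(2, 2, 30) ** 2
    res = compare_groups(_groups_df({"a": g1, "b": g2}))
    assert res[0].test == "Kruskal-Wallis"
    assert any(r.test == "Dunn" for r in res)


def test_constant_group_routes_nonparametric(rng):
    res = compare_groups(
        _groups_df({"a": np.full(5, 3.0), "b": rng.normal(8, 1, 5)})
    )
    assert res[0].test == "Kruskal-Wallis"


def test_all_zero_variance_flagged():
    res = compare_groups(
        _groups_df({"a": np.full(5, 3.0), "b": np.full(5, 3.0)})
    )
    assert res[0].flagged and res[0].stars == "ns"


def test_dunn_hand_computation():
    """Dunn z for two small groups equals the textbook rank formula."""
    groups = {"a": np.array([1.0, 2.0, 3.0, 4.0]), "b": np.array([5.0, 6.0, 7.0, 8.0])}
    (g1, g2, z, p), = _dunn_test(groups)
    n = 8
    ranks_a, ranks_b = [1, 2, 3, 4], [5, 6, 7, 8]
    se = np.sqrt((n * (n + 1) / 12) * (1 / 4 + 1 / 4))  # no ties
    z_hand = (np.mean(ranks_a) - np.mean(ranks_b)) / se
    assert z == pytest.approx(z_hand)
    assert p == pytest.approx(2 * sps.norm.sf(abs(z_hand)))


def test_min_group_size_enforced(rng):
    df = _groups_df({"a": rng.normal(0, 1, 2), "b": rng.normal(0, 1, 9)})
    with pytest.raises(ValueError, match=">=3 observations"):
        compare_groups(df)


def test_star_thresholds():
    assert stars(0.2) == "ns"
    assert stars(0.049) == "*"
    assert stars(0.009) == "**"
    assert stars(0.0009) == "***"
    assert stars(0.00009) == "****"


def test_results_frame_columns(rng):
    res = compare_groups(_groups_df({"a": rng.normal(0, 1, 5),
                                     "b": rng.normal(1, 1, 5)}))
    df = results_to_frame(res)
    assert {"analyte", "comparison", "test", "p", "p_adjusted", "stars"} <= set(df.columns)
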