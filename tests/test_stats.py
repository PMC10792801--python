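import numpy as np
import pandas as pd
import pytest

from cvmstage import (
    compare_cohort,
    compare_three_groups,
    icc,
    letter_grouping,
    normality_triage,
)
from cvmstage.synthetic import SyntheticConfig, generate_cohort


# ---------------------------------------------------------------------------
# normality triage


def test_large_normal_samples_route_parametric(rng):
    groups = {s: rng.normal(10, 2, 200) for s in "abc"}
    assert normality_triage(groups) == "parametric"


def test_point_mass_group_routes_non_parametric(rng):
    groups = {"pre": np.zeros(59), "pub": rng.normal(1.5, 0.5, 220),
              "post": rng.normal(2.0, 0.5, 115)}
    assert normality_triage(groups) == "non-parametric"


def test_skewed_group_routes_non_parametric(rng):
    groups = {"a": rng.normal(0, 1, 200), "b": rng.exponential(1.0, 200),
              "c": rng.normal(0, 1, 200)}
    assert normality_triage(groups) == "non-parametric"


def test_tiny_groups_rejected():
    with pytest.raises(ValueError):
        normality_triage({"a": [1.0, 2.0], "b": [1, 2, 3], "c": [1, 2, 3]})


# ---------------------------------------------------------------------------
# three-group comparison


def test_zero_within_variance_gives_full_effect():
    comp = compare_three_groups({"g1": [1, 1], "g2": [2, 2], "g3": [3, 3]},
                                route="anova")
    assert comp.effect_size == pytest.approx(1.0)
    assert comp.p_value == 0.0
    assert [comp.letters[g] for g in ("g1", "g2", "g3")] == ["C", "B", "A"]


def test_identical_groups_share_a_letter():
    comp = compare_three_groups({"g1": [1, 2, 3], "g2": [1, 2, 3], "g3": [1, 2, 3]},
                                route="anova")
    assert comp.effect_size == pytest.approx(0.0)
    assert [comp.letters[g] for g in ("g1", "g2", "g3")] == ["A", "A", "A"]


def test_anova_matches_hand_computed_sums_of_squares():
    groups = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([2.0, 4.0, 6.0]),
              "c": np.array([5.0, 5.0, 8.0])}
    allx = np.concatenate(list(groups.values()))
    grand = allx.mean()
    ssb = sum(3 * (g.mean() - grand) ** 2 for g in groups.values())
    sst = ((allx - grand) ** 2).sum()
    ssw = sst - ssb
    f_expected = (ssb / 2) / (ssw / 6)
    comp = compare_three_groups(groups, route="anova")
    assert comp.statistic == pytest.approx(f_expected, rel=1e-12)
    assert comp.effect_size == pytest.approx(ssb / sst, rel=1e-12)


def test_effect_size_invariant_under_shift_and_scale(rng):
    groups = {s: rng.normal(m, 1.0, 40) for s, m in zip("abc", (0, 1, 2))}
    base = compare_three_groups(groups, route="anova").effect_size
    shifted = compare_three_groups(
        {s: np.asarray(v) + 100.0 for s, v in groups.items()}, route="anova"
    ).effect_size
    scaled = compare_three_groups(
        {s: np.asarray(v) * 3.5 for s, v in groups.items()}, route="anova"
    ).effect_size
    assert 0.0 <= base <= 1.0
    assert shifted == pytest.approx(base, rel=1e-9)
    assert scaled == pytest.approx(base, rel=1e-9)


def test_kruskal_route_invariant_under_monotone_transform(rng):
    groups = {s: rng.normal(m, 1.0, 50) for s, m in zip("abc", (0, 0.8, 1.6))}
    base = compare_three_groups(groups, route="kw")
    warped = compare_three_groups(
        {s: np.exp(np.asarray(v)) for s, v in groups.items()}, route="kw"
    )
    assert warped.statistic == pytest.approx(base.statistic, rel=1e-12)
    assert warped.effect_size == pytest.approx(base.effect_size, rel=1e-12)
    assert warped.pairwise["p_adj"].to_numpy() == pytest.approx(
        base.pairwise["p_adj"].to_numpy(), rel=1e-9)


def test_auto_route_follows_triage(rng):
    normal_groups = {s: rng.normal(m, 1.0, 120) for s, m in zip("abc", (0, 1, 2))}
    assert compare_three_groups(normal_groups, route="auto").test_used in (
        "anova", "kruskal-wallis")
    point_mass = {"a": np.zeros(50), "b": rng.normal(1, 0.3, 50),
                  "c": rng.normal(2, 0.3, 50)}
    assert compare_three_groups(point_mass, route="auto").test_used == "kruskal-wallis"


def test_dunn_separation_monotone(rng):
    """Larger group separation gives smaller Dunn p-values."""
    near = {s: rng.normal(m, 1.0, 60) for s, m in zip("abc", (0, 0.2, 0.4))}
    far = {s: rng.normal(m, 1.0, 60) for s, m in zip("abc", (0, 2.0, 4.0))}
    p_near = compare_three_groups(near, route="kw").pairwise["p_adj"].min()
    p_far = compare_three_groups(far, route="kw").pairwise["p_adj"].max()
    assert p_far < p_near


def test_two_groups_rejected():
    with pytest.raises(ValueError):
        compare_three_groups({"a": [1, 2], "b": [3, 4]})


# ---------------------------------------------------------------------------
# compact letter display


def test_letter_patterns():
    loc = {"pre": 12.39, "pub": 13.49, "post": 12.65}

    def sig(**pairs):
        return {frozenset(k.split("_")): v for k, v in pairs.items()}

    # all pairs differ: descending locations get A, B, C
    letters = letter_grouping({"a": 3, "b": 2, "c": 1},
                              sig(a_b=True, a_c=True, b_c=True))
    assert letters == {"a": "A", "b": "B", "c": "C"}
    # nothing differs
    letters = letter_grouping({"a": 3, "b": 2, "c": 1}, {})
    assert letters == {"a": "A", "b": "A", "c": "A"}
    # pre ~ post, both differ from pubertal (the published BW C3 pattern)
    letters = letter_grouping(loc, sig(pre_pub=True, pub_post=True, pre_post=False))
    assert (letters["pre"], letters["pub"], letters["post"]) == ("B", "A", "B")
    # pubertal bridges the extremes (the published CD C2 pattern)
    letters = letter_grouping({"pre": 1.0, "pub": 1.5, "post": 2.0},
                              sig(pre_post=True))
    assert (letters["pre"], letters["pub"], letters["post"]) == ("B", "AB", "A")


# ---------------------------------------------------------------------------
# intraclass correlation


def test_identical_raters_give_perfect_agreement(rng):
    col = rng.normal(0, 1, 20)
    ratings = np.column_stack([col, col, col])
    for model in ("icc2_1", "icc3_1"):
        res = icc(ratings, model=model)
        assert res.value == pytest.approx(1.0)
        assert res.ci95[0] <= res.value <= res.ci95[1]


def test_icc_matches_independent_reference_implementation(rng):
    pg = pytest.importorskip("pingouin")
    n, k = 12, 4
    y = (rng.normal(0, 3, (n, 1)) + rng.normal(0, 1, (n, k))
         + np.array([0.0, 0.5, 1.0, -0.3]))
    long = pd.DataFrame({
        "subj": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": y.ravel(),
    })
    table = pg.intraclass_corr(long, "subj", "rater", "score").set_index("Type")
    for model, label in (("icc2_1", "ICC(A,1)"), ("icc3_1", "ICC(C,1)")):
        mine = icc(y, model=model)
        ref_row = table.loc[label]
        assert mine.value == pytest.approx(float(ref_row["ICC"]), abs=1e-9)
        lo, hi = ref_row["CI95"]
        assert mine.ci95[0] == pytest.approx(lo, abs=0.01)
        assert mine.ci95[1] == pytest.approx(hi, abs=0.01)


def test_icc_recovers_generative_variance_ratio():
    """Subject variance 9, noise variance 1: expected ICC = 0.9."""
    rng = np.random.default_rng(314)
    n, k = 1000, 2
    y = rng.normal(0, 3, (n, 1)) + rng.normal(0, 1, (n, k))
    res = icc(y, model="icc2_1")
    assert res.value == pytest.approx(0.9, abs=0.02)


def test_rater_offset_orders_the_two_forms(rng):
    n, k = 50, 3
    base = rng.normal(0, 2, (n, 1)) + rng.normal(0, 1, (n, k))
    offset = base + np.array([0.0, 1.5, 3.0])
    assert icc(offset, "icc2_1").value < icc(offset, "icc3_1").value
    aligned = icc(base, "icc2_1").value
    assert aligned == pytest.approx(icc(base, "icc3_1").value, abs=0.05)


def test_incomplete_or_tiny_matrices_rejected(rng):
    with pytest.raises(ValueError):
        icc(rng.normal(size=(3, 2)))
    bad = rng.normal(size=(10, 2))
    bad[4, 1] = np.nan
    with pytest.raises(ValueError, match="incomplete"):
        icc(bad)


# ---------------------------------------------------------------------------
# cohort pipeline


def test_cohort_comparison_report_structure():
    cohort, _ = generate_cohort(SyntheticConfig(
        stage_counts={"pre-pubertal": 30, "pubertal": 60, "post-pubertal": 40},
        seed=8, landmarks=False))
    report = compare_cohort(cohort.table)
    assert set(report.outcomes) == {
        "swia_c3", "swia_c4", "cd_c2", "cd_c3", "cd_c4",
        "bw_c3", "bw_c4", "bh_c3", "bh_c4", "bs_c3", "bs_c4"}
    frame = report.to_frame()
    assert {"test", "p_value", "eta_squared"} <= set(frame.columns)
    # CDs contain a point-mass group, so they must route non-parametrically
    assert report.outcomes["cd_c3"].test_used == "kruskal-wallis"
    assert report.outcomes["cd_c4"].test_used == "kruskal-wallis"
    cell = report.outcomes["bh_c3"].cell("post-pubertal")
    assert "(" in cell and report.outcomes["bh_c3"].letters["post-pubertal"] in cell
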