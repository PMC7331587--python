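import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import coexscreen as cs


def _matrix(rows):
    rows = np.asarray(rows, dtype=float)
    return cs.AbundanceMatrix(
        [f"P{i}" for i in range(rows.shape[0])],
        [f"S{j}" for j in range(rows.shape[1])],
        rows,
        "normalized",
    )


def _design(sizes=(2, 2, 2)):
    status = (
        ["EX19DEL"] * sizes[0] + ["L858R"] * sizes[1] + ["NONE"] * sizes[2]
    )
    return cs.TraitDesign([f"S{i}" for i in range(sum(sizes))], status)


def test_anova_identical_group_means_gives_f_zero():
    m = _matrix([[1, 2, 1, 2, 1, 2]])
    out = cs.anova_per_protein(m, _design())
    assert out.F.iloc[0] == pytest.approx(0.0)
    assert out.anova_p.iloc[0] == pytest.approx(1.0)


def test_anova_closed_form_sums_of_squares():
    m = _matrix([[0, 1, 10, 11, 20, 21]])
    out = cs.anova_per_protein(m, _design())
    # hand computation: group means 0.5/10.5/20.5, grand 10.5
    ssb = 2 * ((0.5 - 10.5) ** 2 + 0 + (20.5 - 10.5) ** 2)
    ssw = 6 * 0.25
    f_expected = (ssb / 2) / (ssw / 3)
    assert out.F.iloc[0] == pytest.approx(f_expected, abs=1e-10)
    assert out.anova_p.iloc[0] == pytest.approx(stats.f.sf(f_expected, 2, 3), abs=1e-12)


def test_anova_matches_scipy_f_oneway_on_random_data():
    rng = np.random.default_rng(0)
    vals = rng.gamma(4.0, 2.0, size=(20, 12))
    m = _matrix(vals)
    d = _design((4, 4, 4))
    out = cs.anova_per_protein(m, d)
    for i in range(20):
        ref = stats.f_oneway(vals[i, :4], vals[i, 4:8], vals[i, 8:])
        assert out.F.iloc[i] == pytest.approx(ref.statistic, abs=1e-10)
        assert out.anova_p.iloc[i] == pytest.approx(ref.pvalue, abs=1e-10)


def test_anova_zero_variance_protein_is_nan():
    m = _matrix([[5, 5, 5, 5, 5, 5]])
    out = cs.anova_per_protein(m, _design())
    assert np.isnan(out.anova_p.iloc[0])


def test_anova_and_posthoc_match_r_reference():
    """Frozen values from R: anova(lm(x ~ g)) and pairwise.t.test(...,
    p.adjust.method='holm', pool.sd=TRUE) on the same 10-sample vector."""
    x = [0, 0.1, 0.2, 0.4, 5, 5.1, 4.8, 0.3, 0.2, 0.1]
    m = _matrix([x])
    d = _design((3, 4, 3))
    av = cs.anova_per_protein(m, d)
    assert av.F.iloc[0] == pytest.approx(7.21664282308, abs=1e-9)
    assert av.anova_p.iloc[0] == pytest.approx(0.0199082235253, abs=1e-10)
    ph = cs.pairwise_posthoc(m, d, adjust="holm")
    assert ph["p_ex19del_vs_none"].iloc[0] == pytest.approx(0.9371660953815, abs=1e-10)
    assert ph["p_l858r_vs_none"].iloc[0] == pytest.approx(0.0419525971189, abs=1e-10)
    assert ph["p_ex19del_vs_l858r"].iloc[0] == pytest.approx(0.0419525971189, abs=1e-10)
    assert ph["sign_l858r_vs_none"].iloc[0] == 1.0


def test_posthoc_equal_group_means_all_one():
    m = _matrix([[1, 2, 1, 2, 1, 2]])
    ph = cs.pairwise_posthoc(m, _design())
    for col in ("p_ex19del_vs_none", "p_l858r_vs_none", "p_ex19del_vs_l858r"):
        assert ph[col].iloc[0] == pytest.approx(1.0)


def test_posthoc_dominant_third_group_hand_formula():
    x = np.array([0, 0.1, 0, 0.1, 5, 5.1])
    m = _matrix([x])
    d = _design()
    ph = cs.pairwise_posthoc(m, d, adjust="holm")
    # pooled SD from all three groups, df = 3
    s2 = (3 * 0.005) / 3
    t_far = (0.05 - 5.05) / math.sqrt(s2 * (1 / 2 + 1 / 2))
    p_raw = 2 * stats.t.sf(abs(t_far), 3)
    # two large contrasts: holm multiplies smallest by 3, next by 2
    padj = sorted(
        ph[["p_ex19del_vs_none", "p_l858r_vs_none", "p_ex19del_vs_l858r"]].iloc[0]
    )
    assert padj[0] == pytest.approx(min(1, 3 * p_raw), rel=1e-9)
    assert padj[1] == pytest.approx(min(1, 3 * p_raw), rel=1e-9)  # holm monotonicity
    assert ph["p_ex19del_vs_l858r"].iloc[0] == pytest.approx(1.0)


def _diff_frame(anova_p, p_ex, s_ex, p_l8, s_l8):
    return pd.DataFrame(
        {
            "F": [1.0],
            "anova_p": [anova_p],
            "p_ex19del_vs_none": [p_ex],
            "sign_ex19del_vs_none": [s_ex],
            "p_l858r_vs_none": [p_l8],
            "sign_l858r_vs_none": [s_l8],
            "p_ex19del_vs_l858r": [0.001],
            "sign_ex19del_vs_l858r": [1.0],
        },
        index=["P1"],
    )


def test_classify_patterns_anova_gate():
    pats = cs.classify_patterns(_diff_frame(0.5, 0.001, 1, 0.001, 1), alpha=0.05)
    assert pats.pattern.iloc[0] == 0
    assert pats.direction_ex19del.iloc[0] == "ns"


@pytest.mark.parametrize(
    "p_ex,s_ex,p_l8,s_l8,expected",
    [
        (0.01, 1, 0.5, 1, 1),   # up under Ex19del only
        (0.01, -1, 0.5, 1, 2),  # down under Ex19del only
        (0.5, 1, 0.01, 1, 3),   # up under L858R only
        (0.01, 1, 0.01, 1, 5),  # up under both
        (0.01, -1, 0.01, -1, 6),  # down under both
        (0.01, 1, 0.01, -1, 7),
        (0.5, 1, 0.5, -1, 0),   # only the Ex19del-vs-L858R contrast: no pattern
    ],
)
def test_classify_patterns_direction_combinations(p_ex, s_ex, p_l8, s_l8, expected):
    pats = cs.classify_patterns(_diff_frame(0.001, p_ex, s_ex, p_l8, s_l8), alpha=0.05)
    assert pats.pattern.iloc[0] == expected


def test_classify_patterns_recovers_planted_directions(default_run):
    m, design, truth, result = default_run
    pats = result.patterns
    planted = dict(zip(truth.protein_ids, truth.pattern))
    de = [p for p in pats.index if planted[p] > 0]
    hits = sum(pats.loc[p, "pattern"] == planted[p] for p in de)
    assert hits / len(de) >= 0.8
    # no recovered direction contradicts the planted one
    from coexscreen.simulate import PATTERN_DIRECTIONS

    for p in de:
        det = pats.loc[p, "pattern"]
        if det == 0:
            continue
        for got, want in zip(PATTERN_DIRECTIONS[det], PATTERN_DIRECTIONS[planted[p]]):
            assert got == "ns" or want == "ns" or got == want


def _hypergeom_tail(k, N, K, n):
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
        for x in range(k, min(K, n) + 1)
    )


def test_overlap_screen_hypergeometric_oracle():
    universe = {f"P{i}" for i in range(364)}
    module = {f"P{i}" for i in range(10)}
    group = {f"P{i}" for i in range(8)} | {f"P{i}" for i in range(350, 362)}
    labels = np.array([1 if f"P{i}" in module else 0 for i in range(364)])
    part = cs.ModulePartition([f"P{i}" for i in range(364)], labels, 5, 4)
    pats = pd.DataFrame(
        {"pattern": [1 if f"P{i}" in group else 0 for i in range(364)]},
        index=[f"P{i}" for i in range(364)],
    )
    tab = cs.overlap_screen(part, pats, universe)
    row = tab.iloc[0]
    assert row.overlap == 8
    assert row.p == pytest.approx(_hypergeom_tail(8, 364, 20, 10), rel=1e-12)
    assert row.q >= row.p


def test_overlap_screen_degenerate_cells():
    ids = [f"P{i}" for i in range(20)]
    labels = np.array([1] * 5 + [0] * 15)
    part = cs.ModulePartition(ids, labels, 5, 4)
    # group = universe -> p = 1
    pats = pd.DataFrame({"pattern": [2] * 20}, index=ids)
    tab = cs.overlap_screen(part, pats, set(ids))
    assert tab.p.iloc[0] == pytest.approx(1.0)
    # group disjoint from module -> P(X >= 0) = 1
    pats2 = pd.DataFrame({"pattern": [0] * 5 + [3] * 4 + [0] * 11}, index=ids)
    tab2 = cs.overlap_screen(part, pats2, set(ids))
    assert tab2.overlap.iloc[0] == 0
    assert tab2.p.iloc[0] == pytest.approx(1.0)


def test_overlap_screen_best_q_and_selection(default_run):
    _, _, _, result = default_run
    tab = result.screen
    for module, sub in tab.groupby("module"):
        assert (sub.best_q == sub.q.min()).all()
        assert (sub.selected == (sub.best_q < 0.05)).all()
    assert (tab.q >= tab.p - 1e-15).all()


def test_benjamini_hochberg_examples():
    np.testing.assert_allclose(cs.benjamini_hochberg([0.2, 0.2, 0.2]), [0.2] * 3)
    np.testing.assert_allclose(
        cs.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
    )
    np.testing.assert_allclose(cs.benjamini_hochberg([0.3]), [0.3])
    with pytest.raises(ValueError):
        cs.benjamini_hochberg([0.5, 1.5])


def test_benjamini_hochberg_properties_hypothesis():
    from hypothesis import given, settings, strategies as st

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def check(pvals):
        p = np.asarray(pvals)
        q = cs.benjamini_hochberg(p)
        assert ((q >= p - 1e-12) & (q <= 1.0)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()
        # the smallest q never exceeds m * min(p)
        assert q.min() <= min(1.0, p.min() * p.size + 1e-12)

    check()


def test_benjamini_hochberg_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(6)
    p = rng.random(50)
    q = cs.benjamini_hochberg(p)
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(q, ref, atol=1e-12)
    # monotone in sorted order and never below p
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()
    assert (q >= p - 1e-15).all()


def test_covariate_comparison_reproduces_clinical_table():
    comp = cs.covariate_group_comparison(cs.egfr_cohort_traits())

    def cell(cov, grp):
        return comp[(comp.covariate == cov) & (comp.group == grp)].iloc[0]

    assert cell("age_years", "EX19DEL")["mean"] == pytest.approx(67.0, abs=0.05)
    assert cell("age_years", "L858R")["mean"] == pytest.approx(70.9, abs=0.05)
    assert cell("age_years", "NONE")["mean"] == pytest.approx(65.7, abs=0.05)
    assert cell("age_years", "L858R")["sd"] == pytest.approx(4.2, abs=0.05)
    assert cell("ct_size_mm", "L858R")["mean"] == pytest.approx(33.6, abs=0.05)
    assert cell("age_years", "EX19DEL")["anova_p"] == pytest.approx(0.517, abs=5e-4)
    assert cell("ct_size_mm", "EX19DEL")["anova_p"] == pytest.approx(0.333, abs=5e-4)
    assert cell("path_size_mm", "EX19DEL")["anova_p"] == pytest.approx(0.439, abs=5e-4)


def test_covariate_comparison_constant_covariate():
    t = cs.TraitDesign(
        [f"S{i}" for i in range(6)],
        ["EX19DEL", "EX19DEL", "L858R", "L858R", "NONE", "NONE"],
        pd.DataFrame({"flat": [3.0] * 6}),
    )
    comp = cs.covariate_group_comparison(t)
    assert (comp.sd == 0).all()
    assert comp.anova_p.isna().all()


def test_null_type_one_error_rate():
    m, design, _ = cs.generate_null_dataset(n_proteins=200, seed=0)
    logm = cs.log_transform(cs.normalize(m))
    out = cs.anova_per_protein(logm, design)
    frac = float((out.anova_p < 0.05).mean())
    assert 0.02 <= frac <= 0.09
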