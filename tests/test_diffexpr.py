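import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import ifliver as il
from ifliver import diffexpr
from ifliver.errors import DesignError, ValidationError


def _expr(values, arrays):
    df = pd.DataFrame(
        np.atleast_2d(values), columns=arrays,
        index=[f"g{i}" for i in range(np.atleast_2d(values).shape[0])],
    )
    df.attrs["log2"] = True
    return df


def test_fit_hand_example(tiny_sheet):
    # groups {1,3}, {2,4}, {0,0}, {0,0}: means 2,3,0,0; pooled s2 = 4/4 = 1
    values = [[1.0, 3.0, 2.0, 4.0, 0.0, 0.0, 0.0, 0.0]]
    expr = _expr(values, tiny_sheet.index)
    fit = il.fit_linear_model(expr, tiny_sheet)
    assert fit.means.loc["g0"].to_dict() == {"AL": 2.0, "CR": 3.0, "F2": 0.0, "SK": 0.0}
    assert fit.df_residual == 4
    assert fit.s2["g0"] == pytest.approx(1.0)


def test_fit_constant_gene(tiny_sheet):
    expr = _expr([[5.0] * 8], tiny_sheet.index)
    fit = il.fit_linear_model(expr, tiny_sheet)
    assert (fit.means.loc["g0"] == 5.0).all()
    assert fit.s2["g0"] == 0.0


def test_fit_requires_two_arrays_per_group(tiny_sheet):
    sheet = tiny_sheet.drop("F2_2")
    expr = _expr([np.arange(7.0)], sheet.index)
    with pytest.raises(DesignError):
        il.fit_linear_model(expr, sheet)


def test_prior_equal_variances_gives_infinite_d0(tiny_sheet, rng):
    # all gene variances exactly equal -> no excess dispersion
    base = rng.normal(0, 1, 8)
    base = (base - base.mean()) / base.std(ddof=0)
    values = np.stack([8.0 + 0.5 * base for _ in range(300)])
    expr = _expr(values, tiny_sheet.index)
    fit = il.fit_linear_model(expr, tiny_sheet)
    prior = il.estimate_variance_prior(fit)
    assert np.isinf(prior.d0)
    moderated = prior.moderate(fit.s2, fit.df_residual)
    assert np.allclose(moderated, prior.s0sq)


def test_prior_recovery_from_scaled_inv_chisq(rng):
    # direct draw from the generative model: sigma2 ~ inv-chisq(4, 0.05),
    # s2 ~ sigma2 * chi2_d / d
    d0_true, s0sq_true, d, g = 4.0, 0.05, 18, 5000
    sigma2 = d0_true * s0sq_true / rng.chisquare(d0_true, g)
    s2 = sigma2 * rng.chisquare(d, g) / d
    fit = il.GroupFit(
        means=pd.DataFrame(
            0.0, index=range(g), columns=list(il.TREATMENTS)
        ),
        s2=pd.Series(s2),
        df_residual=d,
        n_per_group={"AL": 6, "CR": 6, "F2": 4, "SK": 6},
    )
    prior = il.estimate_variance_prior(fit)
    assert 2.5 <= prior.d0 <= 7.0
    assert abs(prior.s0sq - s0sq_true) / s0sq_true < 0.20


def test_ordinary_mode_is_identity():
    prior = il.VariancePrior(d0=0.0, s0sq=123.0)
    s2 = pd.Series([0.1, 0.5, 2.0])
    assert prior.moderate(s2, 18).equals(s2)


def test_moderated_variance_between_prior_and_sample():
    prior = il.VariancePrior(d0=4.0, s0sq=0.05)
    s2 = pd.Series([0.01, 0.05, 0.3])
    mod = prior.moderate(s2, 18)
    lo = np.minimum(s2, prior.s0sq)
    hi = np.maximum(s2, prior.s0sq)
    assert ((mod >= lo - 1e-15) & (mod <= hi + 1e-15)).all()


def test_contrast_hand_computation():
    # two groups n=3, means 1 and 0, moderated s2 = 0.25, df_total = 18:
    # t = 1 / sqrt(0.25 * (1/3 + 1/3)) = 2.449
    fit = il.GroupFit(
        means=pd.DataFrame(
            {"AL": [0.0], "CR": [0.0], "F2": [1.0], "SK": [0.0]}, index=["g"]
        ),
        s2=pd.Series([0.25], index=["g"]),
        df_residual=14,
        n_per_group={"AL": 3, "CR": 3, "F2": 3, "SK": 3},
    )
    prior = il.VariancePrior(d0=4.0, s0sq=0.25)
    table = il.pairwise_contrasts(fit, prior)
    row = table[(table.pair == "F2_vs_AL")].iloc[0]
    assert row.t == pytest.approx(1.0 / np.sqrt(0.25 * (2 / 3)), rel=1e-12)
    assert row.t == pytest.approx(2.449, abs=5e-4)
    assert row.p == pytest.approx(2 * stats.t.sf(row.t, 18), rel=1e-12)


def test_equal_means_give_t_zero_p_one(tiny_sheet):
    expr = _expr([[3.0, 4.0] * 4], tiny_sheet.index)
    fit = il.fit_linear_model(expr, tiny_sheet)
    table = il.pairwise_contrasts(fit, il.VariancePrior(0.0, 0.0))
    assert np.allclose(table["t"], 0.0)
    assert np.allclose(table["p"], 1.0)


def test_pair_reversal_antisymmetry(tiny_sheet, rng):
    # relabeling two treatments swaps the sign of t but not p
    expr = _expr(rng.normal(8, 1, (40, 8)), tiny_sheet.index)
    fit = il.fit_linear_model(expr, tiny_sheet)
    prior = il.estimate_variance_prior(fit)
    table = il.pairwise_contrasts(fit, prior)
    swapped_sheet = tiny_sheet.copy()
    swapped_sheet["treatment"] = swapped_sheet["treatment"].map(
        {"F2": "AL", "AL": "F2", "CR": "CR", "SK": "SK"}
    )
    fit2 = il.fit_linear_model(expr, swapped_sheet)
    table2 = il.pairwise_contrasts(fit2, prior)
    a = table[table.pair == "F2_vs_AL"].set_index("gene")
    b = table2[table2.pair == "F2_vs_AL"].set_index("gene")
    assert np.allclose(a["t"], -b["t"])
    assert np.allclose(a["p"], b["p"])


def test_moderated_with_d0_zero_equals_ordinary_t(tiny_sheet, rng):
    expr = _expr(rng.normal(8, 1, (50, 8)), tiny_sheet.index)
    fit = il.fit_linear_model(expr, tiny_sheet)
    table = il.pairwise_contrasts(fit, il.VariancePrior(d0=0.0, s0sq=99.0))
    sub = table[table.pair == "SK_vs_CR"].set_index("gene")
    delta = fit.means["SK"] - fit.means["CR"]
    t_ref = delta / np.sqrt(fit.s2 * (1 / 2 + 1 / 2))
    assert np.allclose(sub["t"], t_ref, rtol=0, atol=1e-13)


def test_bh_hand_examples():
    assert np.allclose(
        il.adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    assert np.allclose(il.adjust_bh([1.0, 1.0, 1.0]), 1.0)
    assert il.adjust_bh([0.37]) == pytest.approx([0.37])
    with pytest.raises(ValidationError):
        il.adjust_bh([0.5, 1.5])


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200)
)
def test_bh_matches_statsmodels(pvec):
    ours = il.adjust_bh(pvec)
    theirs = multipletests(pvec, method="fdr_bh")[1]
    assert np.allclose(ours, theirs, atol=1e-12)


def test_filter_monotone_in_delta(default_run):
    # doubling a passing gene's group separation cannot remove it
    params = il.AnalysisParams()
    table = default_run["contrasts"]
    deg = default_run["deg"]
    boosted = table.copy()
    mask = boosted["gene"].isin(deg)
    boosted.loc[mask, "delta_log2"] *= 2
    boosted.loc[mask, "fold_change"] = np.exp2(
        boosted.loc[mask, "delta_log2"].abs()
    )
    boosted.loc[mask, "p"] /= 2
    boosted.loc[mask, "p_adj"] /= 2
    assert deg <= il.filter_de(boosted, params)


def test_updown_union_counts():
    rows = []
    for pair, delta, passes in [
        ("F2_vs_AL", 1.0, True),
        ("SK_vs_AL", -1.0, True),
        ("CR_vs_AL", 0.1, False),
        ("F2_vs_CR", 0.1, False),
        ("SK_vs_CR", 0.1, False),
        ("F2_vs_SK", 0.1, False),
    ]:
        rows.append(
            {
                "gene": "g1", "pair": pair, "delta_log2": delta,
                "fold_change": 2 ** abs(delta),
                "p": 0.001 if passes else 0.9,
                "p_adj": 0.001 if passes else 0.9,
            }
        )
    table = pd.DataFrame(rows)
    counts = il.updown_counts(table).set_index("pair")
    # one gene up in one pair and down in another appears in both unions
    assert counts.loc["union", "up"] == 1
    assert counts.loc["union", "down"] == 1
    assert counts.loc["F2_vs_AL", "up"] == 1
    assert counts.loc["SK_vs_AL", "down"] == 1


def test_type_one_error_control_on_null_data():
    # all-null simulations: BH-adjusted inclusion stays below alpha * G
    total_included, total_genes = 0, 0
    for seed in range(30, 50):
        cfg = il.SimConfig(seed=seed, n_probesets=400,
                           class_proportions={"null": 1.0})
        probes, pmap, sheet, _ = il.simulate_dataset(cfg)
        from ifliver import preprocess
        expr = preprocess.summarize_probesets(probes, pmap)
        fit = il.fit_linear_model(expr, sheet)
        prior = il.estimate_variance_prior(fit)
        table = il.pairwise_contrasts(fit, prior)
        total_included += len(il.filter_de(table))
        total_genes += cfg.n_probesets
    assert total_included <= 0.01 * total_genes


def test_permuting_arrays_within_treatment_changes_nothing(default_run):
    expr = default_run["expr"]
    sheet = default_run["sheet"]
    perm_cols = list(expr.columns)
    # swap two AL arrays and two SK arrays
    i, j = perm_cols.index("AL_1"), perm_cols.index("AL_5")
    perm_cols[i], perm_cols[j] = perm_cols[j], perm_cols[i]
    i, j = perm_cols.index("SK_2"), perm_cols.index("SK_6")
    perm_cols[i], perm_cols[j] = perm_cols[j], perm_cols[i]
    fit2 = il.fit_linear_model(expr[perm_cols], sheet)
    pd.testing.assert_frame_equal(default_run["fit"].means, fit2.means)
    pd.testing.assert_series_equal(default_run["fit"].s2, fit2.s2)
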