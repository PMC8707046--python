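"""Variance components against a brute-force sums-of-squares oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lenspue import (BroadSenseHeritability, anova_combined,
                     anova_gxp_subset, anova_single_condition, heritability,
                     heritability_combined)
from lenspue.exceptions import (DataValidationError, DomainError,
                                UnbalancedDesignError)
from lenspue.heritability import VarianceComponents

from conftest import balanced_table, make_long_frame
from lenspue import PhenotypeTable


# -- independent oracle: explicit-loop sums of squares -------------------


def brute_force_oneway(values: np.ndarray) -> dict:
    """One-way decomposition of a (genotype, rep) array by explicit loops."""
    g, r = values.shape
    grand = values.mean()
    ss_g = sum(r * (values[i].mean() - grand) ** 2 for i in range(g))
    ss_e = sum((values[i, k] - values[i].mean()) ** 2
               for i in range(g) for k in range(r))
    ms_g = ss_g / (g - 1)
    ms_e = ss_e / (g * (r - 1))
    return {"ms_g": ms_g, "ms_e": ms_e,
            "s2g": max(0.0, (ms_g - ms_e) / r), "s2e": ms_e}


def brute_force_twoway(values: np.ndarray) -> dict:
    """Two-way crossed decomposition of a (genotype, level, rep) array."""
    g, e, r = values.shape
    grand = values.mean()
    gm = values.mean(axis=(1, 2))     # genotype means
    tm = values.mean(axis=(0, 2))     # level means
    cm = values.mean(axis=2)          # cell means
    ss_g = e * r * sum((gm[i] - grand) ** 2 for i in range(g))
    ss_t = g * r * sum((tm[j] - grand) ** 2 for j in range(e))
    ss_ge = r * sum((cm[i, j] - gm[i] - tm[j] + grand) ** 2
                    for i in range(g) for j in range(e))
    ss_e = sum((values[i, j, k] - cm[i, j]) ** 2
               for i in range(g) for j in range(e) for k in range(r))
    ms_g = ss_g / (g - 1)
    ms_ge = ss_ge / ((g - 1) * (e - 1))
    ms_e = ss_e / (g * e * (r - 1))
    return {"ss_g": ss_g, "ss_t": ss_t, "ss_ge": ss_ge, "ss_e": ss_e,
            "ms_g": ms_g, "ms_t": ss_t / (e - 1), "ms_ge": ms_ge,
            "ms_e": ms_e, "s2e": ms_e,
            "s2ge": max(0.0, (ms_ge - ms_e) / r),
            "s2g": max(0.0, (ms_g - ms_ge) / (r * e))}


# -- single condition ----------------------------------------------------


def test_single_condition_noiseless():
    # genotype means 10/20/30, zero within-genotype noise, r = 2
    values = np.array([[10.0, 10], [20, 20], [30, 30]])[:, None, :]
    vc = anova_single_condition(balanced_table(values, treatments=("SP",)),
                                "SP", "SDW")
    assert vc.ms_E == 0.0
    assert vc.sigma2_G == pytest.approx(100.0)   # MS_G/r = 200/2
    assert np.isnan(vc.F_G)


def test_single_condition_all_equal_degenerate():
    values = np.full((3, 1, 2), 7.0)
    vc = anova_single_condition(balanced_table(values, treatments=("SP",)),
                                "SP", "SDW")
    assert vc.sigma2_G == 0.0 and vc.ms_E == 0.0


def test_single_condition_truncation_when_noise_dominates():
    rng = np.random.default_rng(0)
    # no genotype signal, large noise: MS_G < MS_E happens for some seeds
    for seed in range(20):
        values = np.random.default_rng(seed).normal(
            100, 10, size=(3, 1, 3)) + 0
        vc = anova_single_condition(
            balanced_table(np.abs(values), treatments=("SP",)), "SP", "SDW")
        assert vc.sigma2_G >= 0.0


@pytest.mark.parametrize("g,r,seed", [(2, 2, 0), (3, 3, 1), (4, 2, 2),
                                      (4, 3, 3)])
def test_single_condition_matches_oracle(g, r, seed):
    values = np.random.default_rng(seed).integers(
        0, 31, size=(g, 1, r)).astype(float)
    vc = anova_single_condition(balanced_table(values, treatments=("SP",)),
                                "SP", "SDW")
    oracle = brute_force_oneway(values[:, 0, :])
    assert vc.ms_G == pytest.approx(oracle["ms_g"], abs=1e-8)
    assert vc.ms_E == pytest.approx(oracle["ms_e"], abs=1e-8)
    assert vc.sigma2_G == pytest.approx(oracle["s2g"], abs=1e-8)


def test_unbalanced_design_refused(tiny_table):
    df = tiny_table.data
    unbal = PhenotypeTable(df.drop(df.index[0]))
    with pytest.raises(UnbalancedDesignError, match="balance or subsample"):
        anova_single_condition(unbal, "SP", "SDW")


# -- combined model ------------------------------------------------------


def test_combined_toy_matches_hand_oracle():
    values = np.array([[[3.0, 5], [10, 12]],
                       [[20, 22], [30, 28]]])   # 2 genotypes x 2 levels x 2
    vc = anova_combined(balanced_table(values), "SDW")
    oracle = brute_force_twoway(values)
    for got, want in ((vc.ms_G, "ms_g"), (vc.ms_GE, "ms_ge"),
                      (vc.ms_E, "ms_e"), (vc.sigma2_G, "s2g"),
                      (vc.sigma2_GE, "s2ge"), (vc.sigma2_e, "s2e")):
        assert got == pytest.approx(oracle[want], abs=1e-8)


def test_combined_zero_interaction_and_error():
    # purely additive genotype + level effects, no noise
    gvals = np.array([0.0, 10.0, 20.0])
    tvals = np.array([0.0, 5.0])
    values = (gvals[:, None, None] + tvals[None, :, None]
              + np.zeros((3, 2, 2)))
    vc = anova_combined(balanced_table(values), "SDW")
    assert vc.sigma2_GE == 0.0
    assert vc.sigma2_e == 0.0
    assert vc.sigma2_G > 0


def test_combined_ss_decomposition_is_exact():
    rng = np.random.default_rng(12)
    values = rng.integers(0, 31, size=(4, 2, 3)).astype(float)
    oracle = brute_force_twoway(values)
    ss_total = ((values - values.mean()) ** 2).sum()
    parts = oracle["ss_g"] + oracle["ss_t"] + oracle["ss_ge"] + oracle["ss_e"]
    assert parts == pytest.approx(ss_total, rel=1e-10)


def test_combined_arms_agree_with_single_on_noiseless_data():
    gvals = np.array([5.0, 15.0, 40.0, 60.0])
    values = np.repeat(gvals[:, None, None], 2, axis=1).repeat(3, axis=2)
    vc_c = anova_combined(balanced_table(values), "SDW")
    vc_s = anova_single_condition(balanced_table(values), "SP", "SDW")
    assert vc_c.sigma2_G == pytest.approx(vc_s.sigma2_G, rel=1e-10)


# -- heritability formulas -----------------------------------------------


def _vc(s2g, s2e, r=3, scope="SP", s2ge=None, e=1):
    return VarianceComponents(
        trait="SDW", scope=scope, sigma2_G=s2g, sigma2_GE=s2ge,
        sigma2_e=s2e, r=r, e=e, ms_G=np.nan, ms_GE=None, ms_E=np.nan,
        F_G=np.nan, p_G=np.nan, F_GE=None, p_GE=None)


@pytest.mark.parametrize("s2g,s2e,expected", [
    (5.0, 0.0, 1.0),
    (0.0, 4.0, 0.0),
    (170.06, 104.5, 0.830),   # inversion-consistent published pair
])
def test_heritability_single(s2g, s2e, expected):
    assert heritability(_vc(s2g, s2e)) == pytest.approx(expected, abs=1e-3)


@pytest.mark.parametrize("s2g,s2ge,s2e,expected", [
    (2.0, 1.0, 3.0, 2.0 / 3.0),
    (4.0, 0.0, 0.0, 1.0),
    (0.0, 1.0, 2.0, 0.0),
])
def test_heritability_combined_formula(s2g, s2ge, s2e, expected):
    vc = _vc(s2g, s2e, scope="combined", s2ge=s2ge, e=2)
    assert heritability_combined(vc) == pytest.approx(expected, abs=1e-4)


def test_heritability_all_zero_is_domain_error():
    with pytest.raises(DomainError):
        heritability(_vc(0.0, 0.0))


@given(s2g=st.floats(0.01, 1e4), s2e=st.floats(0.01, 1e4),
       bump=st.floats(0.01, 1e3))
@settings(max_examples=100, deadline=None)
def test_heritability_monotonicity(s2g, s2e, bump):
    h = heritability(_vc(s2g, s2e))
    assert heritability(_vc(s2g + bump, s2e)) >= h - 1e-12
    assert heritability(_vc(s2g, s2e + bump)) <= h + 1e-12
    assert heritability(_vc(s2g, s2e, r=4)) >= h - 1e-12


# -- subset fixed-effects ANOVA ------------------------------------------


def test_subset_anova_matches_oracle():
    values = np.array([[[3.0, 5], [10, 12]],
                       [[20, 22], [30, 28]]])
    table = balanced_table(values)
    out = anova_gxp_subset(table, ["G1", "G2"], "SDW")
    oracle = brute_force_twoway(values)
    assert out.loc["Genotypes (G)", "mean_sq"] == \
        pytest.approx(oracle["ms_g"], abs=1e-8)
    assert out.loc["Phosphorus (P)", "mean_sq"] == \
        pytest.approx(oracle["ms_t"], abs=1e-8)
    assert out.loc["G x P", "mean_sq"] == \
        pytest.approx(oracle["ms_ge"], abs=1e-8)


def test_subset_anova_identical_genotypes_zero_msg():
    values = np.tile(np.array([[[4.0, 4], [9, 9]]]), (3, 1, 1))
    out = anova_gxp_subset(balanced_table(values), ["G1", "G2", "G3"], "SDW")
    assert out.loc["Genotypes (G)", "mean_sq"] == pytest.approx(0.0, abs=1e-10)


def test_subset_anova_single_genotype_errors(tiny_table):
    with pytest.raises(DataValidationError, match=">= 2 genotypes"):
        anova_gxp_subset(tiny_table, ["G1"], "SDW")


def test_subset_anova_missing_genotype_listed(tiny_table):
    with pytest.raises(DataValidationError, match="G9"):
        anova_gxp_subset(tiny_table, ["G1", "G9"], "SDW")


# -- estimator wrapper ---------------------------------------------------


def test_estimator_fit_attributes(tiny_table):
    est = BroadSenseHeritability(trait="SDW", scope="combined")
    assert est.get_params() == {"trait": "SDW", "scope": "combined"}
    est.fit(tiny_table)
    assert 0.0 <= est.h_ <= 1.0
    assert est.sigma2_g_ >= 0.0
    est2 = BroadSenseHeritability(trait="SDW", scope="SP").fit(tiny_table)
    vc = anova_single_condition(tiny_table, "SP", "SDW")
    assert est2.h_ == pytest.approx(heritability(vc))
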