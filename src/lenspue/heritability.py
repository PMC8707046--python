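"""Balanced-ANOVA variance components and broad-sense heritability.

Single-condition model (per P level): one-way random-effects genotype
ANOVA with expected mean squares ``E[MS_G] = sigma2_e + r sigma2_G``,
``E[MS_E] = sigma2_e``, giving the method-of-moments estimate
``sigma2_G = max(0, (MS_G - MS_E) / r)`` and

    H = sigma2_G / (sigma2_G + sigma2_e / r).

Combined model (both P levels, genotype random, P level fixed):
``E[MS_E] = sigma2_e``, ``E[MS_GE] = sigma2_e + r sigma2_GE``,
``E[MS_G] = sigma2_e + r sigma2_GE + r e sigma2_G`` with e = 2 levels;
genotypes are F-tested against the interaction mean square and the
interaction against the residual.  Combined heritability is

    H_com = sigma2_G / (sigma2_G + sigma2_GE / e + sigma2_e / (r e)).

Negative method-of-moments components are truncated at 0 (and the
truncation logged).  Mean squares come from an OLS fit via statsmodels;
these operations assume a balanced design and refuse unbalanced tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .exceptions import (DataValidationError, DomainError,
                         UnbalancedDesignError)
from .phenodata import PhenotypeTable

log = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    """Method-of-moments variance components for one trait and scope."""

    trait: str
    scope: str                   # "SP", "LP" or "combined"
    sigma2_G: float
    sigma2_GE: float | None      # None in single-condition scope
    sigma2_e: float
    r: int                       # replicates
    e: int                       # number of P levels in scope (1 or 2)
    ms_G: float
    ms_GE: float | None
    ms_E: float
    F_G: float
    F_GE: float | None
    p_G: float
    p_GE: float | None

    def significance(self, which: str = "G") -> str:
        """Printed annotation: '**' at p < 0.01, else 'ns'."""
        p = self.p_G if which == "G" else self.p_GE
        if p is None or np.isnan(p):
            return "ns"
        return "**" if p < 0.01 else "ns"


def _trait_frame(table: PhenotypeTable, trait: str,
                 treatment: str | None = None) -> pd.DataFrame:
    df = table.data
    sub = df[df["trait"] == trait]
    if treatment is not None:
        sub = sub[sub["treatment"] == treatment]
    if sub.empty:
        raise DataValidationError(
            f"no data for trait {trait!r}"
            + (f" under {treatment}" if treatment else ""))
    counts = sub.groupby(["genotype", "treatment"], observed=True)["value"].size()
    if counts.nunique() != 1:
        raise UnbalancedDesignError(
            f"unequal replicate counts for {trait}; balance or subsample "
            "the table before the ANOVA stage")
    r = int(counts.iloc[0])
    if r < 2:
        raise UnbalancedDesignError(
            f"ANOVA needs r >= 2 replicates, got r = {r}")
    if sub["genotype"].nunique() < 2:
        raise DataValidationError("ANOVA needs >= 2 genotypes")
    return sub.reset_index(drop=True)


def _snap(ms: float, scale: float) -> float:
    """Zero out mean squares that are numerically zero (OLS round-off)."""
    return 0.0 if abs(ms) < 1e-10 * max(scale, 1.0) else ms


def anova_single_condition(table: PhenotypeTable, treatment: str,
                           trait: str) -> VarianceComponents:
    """One-way random-effects genotype ANOVA within one P level."""
    sub = _trait_frame(table, trait, treatment)
    r = int(len(sub) / sub["genotype"].nunique())
    aov = anova_lm(ols("value ~ C(genotype)", data=sub).fit())
    vscale = float(sub["value"].abs().max()) ** 2
    ms_g = _snap(float(aov.loc["C(genotype)", "mean_sq"]), vscale)
    ms_e = _snap(float(aov.loc["Residual", "mean_sq"]), vscale)
    s2g = (ms_g - ms_e) / r
    if s2g < 0:
        log.info("sigma2_G truncated to 0 for %s under %s "
                 "(MS_G < MS_E)", trait, treatment)
        s2g = 0.0
    if ms_e > 0:
        f_g = ms_g / ms_e
        p_g = float(aov.loc["C(genotype)", "PR(>F)"])
    else:
        f_g, p_g = np.nan, np.nan  # degenerate: no within-genotype noise
    return VarianceComponents(
        trait=trait, scope=treatment, sigma2_G=s2g, sigma2_GE=None,
        sigma2_e=ms_e, r=r, e=1, ms_G=ms_g, ms_GE=None, ms_E=ms_e,
        F_G=f_g, p_G=p_g, F_GE=None, p_GE=None)


def anova_combined(table: PhenotypeTable, trait: str) -> VarianceComponents:
    """Two-way model across both P levels (genotype random, P fixed)."""
    sub = _trait_frame(table, trait)
    if sub["treatment"].nunique() != 2:
        raise DataValidationError(
            "combined analysis needs both SP and LP arms")
    g = sub["genotype"].nunique()
    e = 2
    r = int(len(sub) / (g * e))
    aov = anova_lm(
        ols("value ~ C(genotype) * C(treatment)", data=sub).fit())
    vscale = float(sub["value"].abs().max()) ** 2
    ms_g = _snap(float(aov.loc["C(genotype)", "mean_sq"]), vscale)
    ms_ge = _snap(float(aov.loc["C(genotype):C(treatment)", "mean_sq"]),
                  vscale)
    ms_e = _snap(float(aov.loc["Residual", "mean_sq"]), vscale)
    s2e = ms_e
    s2ge = (ms_ge - ms_e) / r
    s2g = (ms_g - ms_ge) / (r * e)
    for name, v in (("sigma2_GE", s2ge), ("sigma2_G", s2g)):
        if v < 0:
            log.info("%s truncated to 0 for %s (combined)", name, trait)
    s2ge, s2g = max(0.0, s2ge), max(0.0, s2g)
    df_g, df_ge = g - 1, (g - 1) * (e - 1)
    df_e = g * e * (r - 1)
    f_g = ms_g / ms_ge if ms_ge > 0 else np.nan
    p_g = float(sps.f.sf(f_g, df_g, df_ge)) if np.isfinite(f_g) else np.nan
    f_ge = ms_ge / ms_e if ms_e > 0 else np.nan
    p_ge = float(sps.f.sf(f_ge, df_ge, df_e)) if np.isfinite(f_ge) else np.nan
    return VarianceComponents(
        trait=trait, scope="combined", sigma2_G=s2g, sigma2_GE=s2ge,
        sigma2_e=s2e, r=r, e=e, ms_G=ms_g, ms_GE=ms_ge, ms_E=ms_e,
        F_G=f_g, p_G=p_g, F_GE=f_ge, p_GE=p_ge)


def heritability(vc: VarianceComponents) -> float:
    """Single-condition broad-sense heritability on a genotype-mean basis."""
    if vc.scope == "combined":
        raise ValueError("use heritability_combined for combined scope")
    denom = vc.sigma2_G + vc.sigma2_e / vc.r
    if denom == 0:
        raise DomainError(
            f"heritability undefined for {vc.trait}: all components zero")
    return vc.sigma2_G / denom


def heritability_combined(vc: VarianceComponents) -> float:
    """Combined broad-sense heritability across the two P levels."""
    if vc.scope != "combined":
        raise ValueError("heritability_combined needs combined scope")
    denom = vc.sigma2_G + (vc.sigma2_GE or 0.0) / vc.e \
        + vc.sigma2_e / (vc.r * vc.e)
    if denom == 0:
        raise DomainError(
            f"heritability undefined for {vc.trait}: all components zero")
    return vc.sigma2_G / denom


def anova_gxp_subset(table: PhenotypeTable, genotypes: list[str],
                     trait: str) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA for a genotype subset across P levels.

    Returns mean squares, F statistics against the residual, p-values and
    '**'/'ns' markers for Genotypes (G), Phosphorus (P) and G x P.
    """
    if len(genotypes) < 2:
        raise DataValidationError(
            "subset ANOVA needs >= 2 genotypes (G has 0 df otherwise)")
    sub = _trait_frame(table.subset(list(genotypes)), trait)
    if sub["treatment"].nunique() != 2:
        raise DataValidationError("subset ANOVA needs both SP and LP arms")
    aov = anova_lm(
        ols("value ~ C(genotype) * C(treatment)", data=sub).fit())
    rename = {"C(genotype)": "Genotypes (G)",
              "C(treatment)": "Phosphorus (P)",
              "C(genotype):C(treatment)": "G x P",
              "Residual": "Residual"}
    out = aov.rename(index=rename)[["df", "mean_sq", "F", "PR(>F)"]]
    out.columns = ["df", "mean_sq", "F", "p"]
    out["sig"] = ["**" if p < 0.01 else "ns" if np.isfinite(p) else ""
                  for p in out["p"].fillna(np.inf)]
    out.loc["Residual", ["F", "p", "sig"]] = [np.nan, np.nan, ""]
    return out


def heritability_table(table: PhenotypeTable,
                       traits: list[str] | None = None) -> pd.DataFrame:
    """Per-trait component/heritability report across SP, LP and combined."""
    traits = traits or [t for t in table.traits if t != "PCONC"]
    rows = []
    for t in traits:
        vc_sp = anova_single_condition(table, "SP", t)
        vc_lp = anova_single_condition(table, "LP", t)
        vc_c = anova_combined(table, t)
        rows.append({
            "trait": t,
            "sigma2_G_SP": vc_sp.sigma2_G, "sig_SP": vc_sp.significance(),
            "H_SP": heritability(vc_sp),
            "sigma2_G_LP": vc_lp.sigma2_G, "sig_LP": vc_lp.significance(),
            "H_LP": heritability(vc_lp),
            "sigma2_G_combined": vc_c.sigma2_G,
            "sig_G_combined": vc_c.significance("G"),
            "sigma2_GE": vc_c.sigma2_GE,
            "sig_GE": vc_c.significance("GE"),
            "H_combined": heritability_combined(vc_c),
        })
    return pd.DataFrame(rows).set_index("trait")


class BroadSenseHeritability(BaseEstimator):
    """Estimator wrapper around the balanced-ANOVA heritability analysis.

    Parameters
    ----------
    trait : str
        Trait code to analyse.
    scope : {"SP", "LP", "combined"}
        Single-condition arm or the combined two-level model.

    Attributes (after ``fit``)
    --------------------------
    components_ : VarianceComponents
    sigma2_g_, sigma2_ge_, sigma2_e_ : float
    h_ : float
        Broad-sense heritability for the requested scope.
    """

    def __init__(self, trait: str = "TDW", scope: str = "combined"):
        self.trait = trait
        self.scope = scope

    def fit(self, X: PhenotypeTable, y=None) -> "BroadSenseHeritability":
        if self.scope not in ("SP", "LP", "combined"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.scope == "combined":
            vc = anova_combined(X, self.trait)
            self.h_ = heritability_combined(vc)
        else:
            vc = anova_single_condition(X, self.scope, self.trait)
            self.h_ = heritability(vc)
        self.components_ = vc
        self.sigma2_g_ = vc.sigma2_G
        self.sigma2_ge_ = vc.sigma2_GE
        self.sigma2_e_ = vc.sigma2_e
        return self
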