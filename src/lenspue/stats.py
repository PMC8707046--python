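"""Descriptive trait statistics, correlation structure and PCA.

All population-level statistics operate on genotype means (replicates are
averaged first), mirroring how diversity-panel screens are summarized:
per-trait range/mean/CV tables per phosphorus arm, the percent change of
the low-P mean against the sufficient-P mean, pairwise-complete Pearson
correlations with t-test p-values, species-wise summaries, and a PCA of
the correlation matrix of per-genotype relative (LP/SP) trait values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DataValidationError, DomainError
from .phenodata import PhenotypeTable, genotype_means

log = logging.getLogger(__name__)


# -- Table-1-style summaries ---------------------------------------------


def summarize_traits(table: PhenotypeTable, treatment: str,
                     cv_mode: str = "genotype") -> pd.DataFrame:
    """Min / max / mean / CV% per trait over genotype means under one arm.

    CV% is 100 x sample SD / mean of the genotype means (``cv_mode=
    'genotype'``, the default, which needs no balance assumption) or the
    residual CV 100 x sqrt(MS_E) / grand mean (``cv_mode='residual'``).
    Traits whose mean is 0 get a missing CV.  Requires >= 2 genotypes.
    """
    if cv_mode not in ("genotype", "residual"):
        raise ValueError(f"cv_mode must be 'genotype' or 'residual', "
                         f"got {cv_mode!r}")
    means = genotype_means(table, treatment)
    rows = []
    for trait in means.columns:
        x = means[trait].dropna()
        if len(x) < 2:
            raise DataValidationError(
                f"need >= 2 genotypes with data for {trait} under "
                f"{treatment}, got {len(x)}")
        mean = float(x.mean())
        if cv_mode == "genotype":
            cv = 100.0 * float(x.std(ddof=1)) / mean if mean != 0 else np.nan
        else:
            cv = _residual_cv(table, treatment, trait)
        rows.append({"trait": trait, "treatment": treatment,
                     "min": float(x.min()), "max": float(x.max()),
                     "mean": mean, "cv_percent": cv, "n": int(len(x))})
    return pd.DataFrame(rows).set_index("trait")


def _residual_cv(table: PhenotypeTable, treatment: str, trait: str) -> float:
    df = table.data
    sub = df[(df["treatment"] == treatment) & (df["trait"] == trait)]
    grand = sub["value"].mean()
    if grand == 0:
        return np.nan
    within = sub.groupby("genotype", observed=True)["value"]
    sse = float(((sub["value"] - within.transform("mean")) ** 2).sum())
    dfe = len(sub) - sub["genotype"].nunique()
    if dfe <= 0:
        return np.nan
    return 100.0 * np.sqrt(sse / dfe) / grand


def percent_change(mean_sp: float, mean_lp: float) -> float:
    """Percent change of the LP mean relative to the SP mean.

    Returns ``100 * (mean_lp - mean_sp) / mean_sp``; negative values are
    reductions under low phosphorus.
    """
    if mean_sp <= 0:
        raise DomainError(f"mean_sp must be > 0, got {mean_sp}")
    if mean_lp < 0:
        raise DomainError(f"mean_lp must be >= 0, got {mean_lp}")
    return 100.0 * (mean_lp - mean_sp) / mean_sp


# -- correlations --------------------------------------------------------


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations with p-values and effective n."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        """Annotation frame: '**' at p < 0.01, '*' at p < 0.05, else 'ns'."""
        out = self.p.copy().astype(object)
        out[:] = "ns"
        out = out.mask(self.p < 0.05, "*").mask(self.p < 0.01, "**")
        np.fill_diagonal(out.values, "")
        return out


def correlation_matrix(means: pd.DataFrame) -> CorrelationMatrix:
    """Pearson correlation structure of a genotype x trait mean matrix.

    Pairs are deleted pairwise-complete; each pair needs >= 3 genotypes.
    Two-sided p-values come from the t transform
    ``t = r sqrt((n - 2) / (1 - r^2))``.  Zero-variance traits yield
    missing correlations for their pairs.
    """
    traits = list(means.columns)
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), int)
    for i in range(k):
        r[i, i], p[i, i] = 1.0, 0.0
        n[i, i] = int(means[traits[i]].notna().sum())
        for j in range(i + 1, k):
            pair = means[[traits[i], traits[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < 3:
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
                log.warning("zero variance in %s/%s pair; r undefined",
                            traits[i], traits[j])
                continue
            res = sps.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(traits, name="trait")
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=traits),
        p=pd.DataFrame(p, index=idx, columns=traits),
        n=pd.DataFrame(n, index=idx, columns=traits))


# -- relative values and PCA ---------------------------------------------


def relative_values(table: PhenotypeTable) -> pd.DataFrame:
    """Per-genotype relative trait values, 100 x LP mean / SP mean.

    Genotypes lacking either arm for a trait (or with SP mean 0) carry a
    missing entry; the count of dropped cells is logged.  The TDW column
    of this frame coincides with P utilization efficiency.
    """
    sp = genotype_means(table, "SP")
    lp = genotype_means(table, "LP")
    sp, lp = sp.align(lp, join="outer")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 100.0 * lp / sp
    rel = rel.mask(~(sp > 0))
    dropped = int(rel.isna().sum().sum())
    if dropped:
        log.info("relative_values: %d genotype x trait cells missing",
                 dropped)
    return rel


@dataclass
class PCAResult:
    """Eigenstructure of the trait correlation matrix."""

    eigenvalues: np.ndarray          # nonincreasing, >= 0
    pct_variance: np.ndarray         # sums to 100
    loadings: pd.DataFrame           # trait x component
    scores: pd.DataFrame             # genotype x component


def run_pca(matrix: pd.DataFrame) -> PCAResult:
    """PCA of a genotype x trait matrix on the correlation scale.

    Columns are standardized to zero mean and unit sample variance
    (ddof=1) and the correlation matrix is eigendecomposed; the percent
    variance of each component is 100 x eigenvalue / sum.  Component signs
    are fixed so each loading vector's largest-magnitude entry is
    positive.  Scores are the standardized data projected on the loadings,
    so their sample covariance is diagonal with the eigenvalues on the
    diagonal.
    """
    if matrix.isna().any().any():
        raise DataValidationError("PCA input must have no missing entries")
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise DataValidationError(
            f"PCA needs >= 2 rows and >= 2 columns, got {matrix.shape}")
    X = matrix.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    constant = [c for c, s in zip(matrix.columns, sd) if s == 0]
    if constant:
        raise DataValidationError(
            f"constant column(s) not admissible in PCA: {constant}")
    Z = (X - X.mean(axis=0)) / sd
    R = Z.T @ Z / (len(Z) - 1)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    for j in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    comps = [f"PC{i + 1}" for i in range(len(w))]
    return PCAResult(
        eigenvalues=w,
        pct_variance=100.0 * w / w.sum(),
        loadings=pd.DataFrame(V, index=matrix.columns, columns=comps),
        scores=pd.DataFrame(Z @ V, index=matrix.index, columns=comps))


# -- species summaries ---------------------------------------------------


def species_summary(table: PhenotypeTable) -> pd.DataFrame:
    """Trait means per species x treatment over genotype means.

    Returns a frame indexed by (species, treatment, trait) with the group
    mean and genotype count n; single-genotype groups are flagged.
    """
    df = table.data
    species_of = (df[["genotype", "species"]].drop_duplicates()
                  .set_index("genotype")["species"])
    rows = []
    for treatment in table.treatments:
        means = genotype_means(table, treatment)
        grouped = means.groupby(species_of.reindex(means.index))
        for species, block in grouped:
            for trait in block.columns:
                x = block[trait].dropna()
                if x.empty:
                    continue
                rows.append({"species": species, "treatment": treatment,
                             "trait": trait, "mean": float(x.mean()),
                             "n": int(len(x)), "single_genotype": len(x) == 1})
    return (pd.DataFrame(rows)
            .set_index(["species", "treatment", "trait"]).sort_index())
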