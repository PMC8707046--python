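"""Genotype categorization for phosphorus use efficiency.

Four complementary techniques, each fit on a genotype x trait mean matrix
and applied to (usually the same) genotypes:

1. ``TraitScorer`` - per-trait three-way scoring against population mean
   +/- SD thresholds, summed into a scorecard.
2. ``QuadrantClassifier`` - efficiency (dry mass) x responsiveness
   (utilization efficiency) quadrants at population-mean cuts:
   ER / ENR / IR / INR.
3. ``NineGroupClassifier`` - dry mass x P uptake, each axis binned low /
   medium / high at mean +/- SD: labels like ``HDM-HP``.
4. ``technique4_rank`` - ranking by the composite stress tolerance score.

Plus top-fraction selection with deterministic tie-breaking and the
presence matrix of overlapping selections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .exceptions import DataValidationError

#: Default trait list for the scorecard technique: biomass, allocation and
#: the P channel (concentration, uptake, utilization).
DEFAULT_SCORE_TRAITS = ("SDW", "RDW", "TDW", "RSR", "PCONC", "PUPE", "PUTIE")


def _check_means(X: pd.DataFrame, min_rows: int = 2) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError("expected a genotype x trait DataFrame of means")
    if len(X) < min_rows:
        raise DataValidationError(
            f"need >= {min_rows} genotypes, got {len(X)}")
    return X


class TraitScorer(BaseEstimator):
    """Population mean +/- SD scorecards (technique 1).

    Per trait a genotype is ``efficient`` (value > mu + SD), ``medium``
    (mu - SD <= value <= mu + SD, closed interval) or ``inefficient``
    (value < mu - SD); the categories map to points (default 3/2/1) which
    are summed into the genotype total.  Missing traits contribute 0
    points and are flagged.  Totals are invariant to affine rescaling of
    any trait because the thresholds move with the scale.

    Attributes: ``mu_``, ``sd_`` (per-trait Series), ``max_total_``.
    """

    def __init__(self, traits: tuple[str, ...] = DEFAULT_SCORE_TRAITS,
                 points: tuple[int, int, int] = (3, 2, 1)):
        self.traits = traits
        self.points = points

    def fit(self, X: pd.DataFrame, y=None) -> "TraitScorer":
        X = _check_means(X)
        use = [t for t in self.traits if t in X.columns]
        if not use:
            raise DataValidationError(
                f"none of the scoring traits {list(self.traits)} present")
        self.traits_ = list(use)
        self.mu_ = X[use].mean()
        self.sd_ = X[use].std(ddof=1)
        self.max_total_ = self.points[0] * len(use)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-trait category labels per genotype."""
        check_is_fitted(self, "mu_")
        out = pd.DataFrame(index=X.index, columns=self.traits_, dtype=object)
        for t in self.traits_:
            v = X[t] if t in X.columns else pd.Series(np.nan, index=X.index)
            hi, lo = self.mu_[t] + self.sd_[t], self.mu_[t] - self.sd_[t]
            out[t] = np.select(
                [v.isna(), v > hi, v < lo],
                ["missing", "efficient", "inefficient"], default="medium")
        return out

    def score_table(self, X: pd.DataFrame) -> pd.DataFrame:
        """Scorecard: per-trait points, total, max total, missing flags."""
        cats = self.transform(X)
        pts_map = {"efficient": self.points[0], "medium": self.points[1],
                   "inefficient": self.points[2], "missing": 0}
        pts = cats.apply(lambda col: col.map(pts_map)).astype(int)
        out = pts.add_suffix("_pts")
        out["total"] = pts.sum(axis=1)
        out["max_total"] = self.max_total_
        out["missing_traits"] = cats.apply(
            lambda row: ",".join(c for c in cats.columns
                                 if row[c] == "missing"), axis=1)
        return out


class QuadrantClassifier(BaseEstimator):
    """Efficiency x responsiveness quadrants (technique 2).

    ``x`` (efficiency axis, default total dry weight under the focal arm)
    and ``y`` (responsiveness axis, default utilization efficiency) are
    cut at their population means; boundary equality counts as above.

    (x >= cut, y >= cut) -> ER; (x >=, y <) -> ENR; (x <, y >=) -> IR;
    (x <, y <) -> INR.

    Attributes: ``x_cut_``, ``y_cut_``.
    """

    _LABELS = {(True, True): "ER", (True, False): "ENR",
               (False, True): "IR", (False, False): "INR"}

    def __init__(self, x: str = "TDW", y: str = "PUTIE"):
        self.x = x
        self.y = y

    def fit(self, X: pd.DataFrame, y=None) -> "QuadrantClassifier":
        X = _check_means(X)
        for axis in (self.x, self.y):
            if axis not in X.columns:
                raise DataValidationError(f"axis trait {axis!r} not in means")
        self.x_cut_ = float(X[self.x].mean())
        self.y_cut_ = float(X[self.y].mean())
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        check_is_fitted(self, "x_cut_")
        labels = [self._LABELS[(xv >= self.x_cut_, yv >= self.y_cut_)]
                  for xv, yv in zip(X[self.x], X[self.y])]
        return pd.Series(labels, index=X.index, name="quadrant")

    def classify_table(self, X: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame({
            "x_value": X[self.x], "y_value": X[self.y],
            "label": self.predict(X)})
        out["x_cut"], out["y_cut"] = self.x_cut_, self.y_cut_
        return out


class NineGroupClassifier(BaseEstimator):
    """Dry-mass x P-uptake nine-group classification (technique 3).

    Each axis (default x = TDW, y = PUPE) is binned low (< mu - SD),
    medium ([mu - SD, mu + SD]) or high (> mu + SD); the label combines
    the dry-mass level (LDM/MDM/HDM) with the P level (LP/MP/HP), e.g.
    ``HDM-HP``.  ``cut_mode='tercile'`` switches to tercile cuts.

    Attributes: ``x_cuts_``, ``y_cuts_`` ((low, high) tuples).
    """

    _DM = {0: "LDM", 1: "MDM", 2: "HDM"}
    _P = {0: "LP", 1: "MP", 2: "HP"}

    def __init__(self, x: str = "TDW", y: str = "PUPE",
                 cut_mode: str = "sd"):
        self.x = x
        self.y = y
        self.cut_mode = cut_mode

    def _cuts(self, v: pd.Series) -> tuple[float, float]:
        if self.cut_mode == "sd":
            return float(v.mean() - v.std(ddof=1)), \
                float(v.mean() + v.std(ddof=1))
        if self.cut_mode == "tercile":
            return float(v.quantile(1 / 3)), float(v.quantile(2 / 3))
        raise ValueError(f"cut_mode must be 'sd' or 'tercile', "
                         f"got {self.cut_mode!r}")

    def fit(self, X: pd.DataFrame, y=None) -> "NineGroupClassifier":
        X = _check_means(X)
        for axis in (self.x, self.y):
            if axis not in X.columns:
                raise DataValidationError(f"axis trait {axis!r} not in means")
        self.x_cuts_ = self._cuts(X[self.x])
        self.y_cuts_ = self._cuts(X[self.y])
        return self

    @staticmethod
    def _level(v: float, cuts: tuple[float, float]) -> int:
        lo, hi = cuts
        return 0 if v < lo else (2 if v > hi else 1)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        check_is_fitted(self, "x_cuts_")
        labels = [f"{self._DM[self._level(xv, self.x_cuts_)]}-"
                  f"{self._P[self._level(yv, self.y_cuts_)]}"
                  for xv, yv in zip(X[self.x], X[self.y])]
        return pd.Series(labels, index=X.index, name="nine_group")

    def classify_table(self, X: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame({
            "x_value": X[self.x], "y_value": X[self.y],
            "label": self.predict(X)})
        out["dm_level"] = out["label"].str.split("-").str[0]
        out["p_level"] = out["label"].str.split("-").str[1]
        return out


# -- technique 1-4 functional wrappers -----------------------------------


def technique1_scores(means: pd.DataFrame,
                      traits: tuple[str, ...] = DEFAULT_SCORE_TRAITS,
                      points: tuple[int, int, int] = (3, 2, 1)
                      ) -> pd.DataFrame:
    return TraitScorer(traits=traits, points=points).fit(means) \
        .score_table(means)


def technique2_classify(means: pd.DataFrame, x: str = "TDW",
                        y: str = "PUTIE") -> pd.DataFrame:
    return QuadrantClassifier(x=x, y=y).fit(means).classify_table(means)


def technique3_classify(means: pd.DataFrame, x: str = "TDW",
                        y: str = "PUPE",
                        cut_mode: str = "sd") -> pd.DataFrame:
    return NineGroupClassifier(x=x, y=y, cut_mode=cut_mode).fit(means) \
        .classify_table(means)


def technique4_rank(sts: pd.Series) -> pd.DataFrame:
    """Rank genotypes by descending composite stress tolerance score.

    Ties break lexicographically by genotype id; rank 1 is the most
    P-use-efficient genotype.  Genotypes with a missing score are excluded.
    """
    clean = sts.dropna()
    order = sorted(clean.items(), key=lambda kv: (-kv[1], str(kv[0])))
    out = pd.DataFrame(order, columns=["genotype", "sts"]) \
        .set_index("genotype")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# -- selection -----------------------------------------------------------


@dataclass(frozen=True)
class SelectionResult:
    """Top-fraction selection by one criterion."""

    criterion: str
    ranked: tuple[str, ...]
    k: int

    @property
    def selected(self) -> tuple[str, ...]:
        return self.ranked[:self.k]


def select_top_fraction(values: pd.Series, fraction: float = 0.10,
                        criterion: str = "TDW") -> SelectionResult:
    """Select the top ``floor(fraction x N)`` genotypes by a criterion.

    ``values`` maps genotype id to the criterion value (e.g. TDW means
    under low P).  Ranking is by descending value with lexicographic
    tie-break on the id.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    clean = values.dropna()
    if clean.empty:
        raise DataValidationError("no genotypes with criterion data")
    ranked = tuple(g for g, _ in
                   sorted(clean.items(), key=lambda kv: (-kv[1], str(kv[0]))))
    return SelectionResult(criterion=criterion, ranked=ranked,
                           k=math.floor(fraction * len(ranked)))


def membership_overlap(selections: dict[str, set[str] | tuple | list]
                       ) -> pd.DataFrame:
    """Genotype x criterion presence matrix of named selection sets."""
    if not selections:
        raise ValueError("at least one selection set required")
    genotypes = sorted(set().union(*[set(s) for s in selections.values()]))
    return pd.DataFrame(
        {name: [g in set(s) for g in genotypes]
         for name, s in selections.items()},
        index=pd.Index(genotypes, name="genotype"))
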