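"""Scorecards, quadrants, nine groups, STS ranking and top-fraction selection."""

import numpy as np
import pandas as pd
import pytest

from lenspue import (NineGroupClassifier, QuadrantClassifier,
                     StressIndexInput, TraitScorer, compute_stress_indices,
                     membership_overlap, select_top_fraction,
                     technique1_scores, technique2_classify,
                     technique3_classify, technique4_rank)
from lenspue.exceptions import DataValidationError


def _means_with_outlier():
    """20 genotypes: a mid pack, one high outlier, one low outlier."""
    rng = np.random.default_rng(0)
    traits = ["SDW", "RDW", "TDW", "RSR", "PCONC", "PUPE", "PUTIE"]
    X = pd.DataFrame(rng.normal(100, 5, size=(20, len(traits))),
                     columns=traits,
                     index=[f"G{i:02d}" for i in range(20)])
    X.loc["G00"] = 200.0   # > mu + SD on every trait
    X.loc["G01"] = 10.0    # < mu - SD on every trait
    return X


# -- technique 1 ---------------------------------------------------------


def test_scorecard_extremes_and_default_points():
    X = _means_with_outlier()
    scores = technique1_scores(X)
    assert scores["max_total"].iloc[0] == 21        # 7 traits x 3 points
    assert scores.loc["G00", "total"] == 21
    assert scores.loc["G01", "total"] == 7


def test_scorecard_all_medium_at_population_mean():
    X = _means_with_outlier()
    scorer = TraitScorer().fit(X)
    probe = pd.DataFrame([X.mean()], index=["probe"])
    card = scorer.score_table(probe)
    assert card.loc["probe", "total"] == 14         # 7 traits x 2 points


def test_scorecard_affine_rescaling_invariance():
    X = _means_with_outlier()
    rescaled = X.copy()
    rescaled["SDW"] = 7.3 * rescaled["SDW"] + 11.0
    a = technique1_scores(X)["total"]
    b = technique1_scores(rescaled)["total"]
    pd.testing.assert_series_equal(a, b)


def test_scorecard_missing_trait_scores_zero_and_flagged():
    X = _means_with_outlier()
    X.loc["G05", "PUPE"] = np.nan
    card = technique1_scores(X)
    assert card.loc["G05", "PUPE_pts"] == 0
    assert "PUPE" in card.loc["G05", "missing_traits"]


# -- technique 2 ---------------------------------------------------------


def test_quadrant_mapping_and_boundary():
    X = pd.DataFrame({"TDW": [200.0, 100.0, 200.0, 100.0],
                      "PUTIE": [80.0, 40.0, 40.0, 80.0]},
                     index=["hi-hi", "lo-lo", "hi-lo", "lo-hi"])
    out = technique2_classify(X)
    assert out.loc["hi-hi", "label"] == "ER"
    assert out.loc["lo-lo", "label"] == "INR"
    assert out.loc["hi-lo", "label"] == "ENR"
    assert out.loc["lo-hi", "label"] == "IR"
    # exactly at both cuts counts as >= (ER)
    clf = QuadrantClassifier().fit(X)
    probe = pd.DataFrame({"TDW": [clf.x_cut_], "PUTIE": [clf.y_cut_]},
                         index=["edge"])
    assert clf.predict(probe).loc["edge"] == "ER"


def test_quadrant_needs_two_genotypes():
    X = pd.DataFrame({"TDW": [100.0], "PUTIE": [50.0]}, index=["G1"])
    with pytest.raises(DataValidationError):
        technique2_classify(X)


# -- technique 3 ---------------------------------------------------------


def test_nine_group_cells():
    rng = np.random.default_rng(1)
    X = pd.DataFrame({"TDW": rng.normal(100, 10, 50),
                      "PUPE": rng.normal(50, 5, 50)},
                     index=[f"G{i}" for i in range(50)])
    clf = NineGroupClassifier().fit(X)
    mu_x, mu_y = X["TDW"].mean(), X["PUPE"].mean()
    sd_x, sd_y = X["TDW"].std(ddof=1), X["PUPE"].std(ddof=1)
    probes = pd.DataFrame(
        {"TDW": [mu_x, mu_x + 2 * sd_x, mu_x - 2 * sd_x],
         "PUPE": [mu_y, mu_y + 2 * sd_y, mu_y]},
        index=["centre", "both-high", "low-dm"])
    labels = clf.predict(probes)
    assert labels.loc["centre"] == "MDM-MP"
    assert labels.loc["both-high"] == "HDM-HP"
    assert labels.loc["low-dm"] == "LDM-MP"


def test_partitions_assign_exactly_one_label():
    rng = np.random.default_rng(2)
    X = pd.DataFrame({"TDW": rng.gamma(5, 20, 100),
                      "PUTIE": rng.uniform(30, 98, 100),
                      "PUPE": rng.gamma(4, 25, 100)},
                     index=[f"G{i:03d}" for i in range(100)])
    q = technique2_classify(X)
    n = technique3_classify(X)
    assert q["label"].isin(["ER", "ENR", "IR", "INR"]).all()
    assert len(q) == len(X)
    dm = {"LDM", "MDM", "HDM"}
    pl = {"LP", "MP", "HP"}
    assert n["dm_level"].isin(dm).all() and n["p_level"].isin(pl).all()
    assert len(n) == len(X)


def test_nine_group_monotonicity_in_dry_mass():
    """Raising one genotype's TDW (cuts refit) never lowers its DM level."""
    rng = np.random.default_rng(3)
    order = {"LDM": 0, "MDM": 1, "HDM": 2}
    X = pd.DataFrame({"TDW": rng.normal(100, 10, 30),
                      "PUPE": rng.normal(50, 5, 30)},
                     index=[f"G{i}" for i in range(30)])
    before = technique3_classify(X).loc["G0", "dm_level"]
    X2 = X.copy()
    X2.loc["G0", "TDW"] += 40.0
    after = technique3_classify(X2).loc["G0", "dm_level"]
    assert order[after] >= order[before]


# -- technique 4 ---------------------------------------------------------


def test_sts_ranking_matches_brute_force_reevaluation():
    rng = np.random.default_rng(4)
    C = rng.uniform(100, 400, 15)
    T = rng.uniform(50, 350, 15)
    xc, xt = C.mean(), T.mean()
    ids = [f"G{i:02d}" for i in range(15)]
    sts = pd.Series(
        [compute_stress_indices(StressIndexInput(c, t, xc, xt)).sts
         for c, t in zip(C, T)], index=ids)
    ranked = technique4_rank(sts)
    # brute-force: re-evaluate each printed formula independently
    brute = {}
    for gid, c, t in zip(ids, C, T):
        ssi = (1 - t / c) / (1 - xt / xc)
        mpi = (c + t) / 2
        gmpi = (c * t) ** 0.5
        hmi = 2 * c * t / (c + t)
        sti = c * t / xc ** 2
        brute[gid] = ssi + mpi + gmpi + hmi + sti + (c - t) + t / c
    expected = sorted(brute, key=lambda g: (-brute[g], g))
    assert list(ranked.index) == expected
    assert ranked["rank"].tolist() == list(range(1, 16))


def test_sts_rank_tie_break_lexicographic():
    sts = pd.Series({"B": 5.0, "A": 5.0, "C": 9.0})
    ranked = technique4_rank(sts)
    assert list(ranked.index) == ["C", "A", "B"]


def test_sts_rank_single_genotype():
    ranked = technique4_rank(pd.Series({"only": 3.0}))
    assert ranked.loc["only", "rank"] == 1


def test_dominant_dry_mass_orders_sts():
    xc, xt = 200.0, 150.0
    pairs = {"big": (300.0, 250.0), "mid": (200.0, 150.0),
             "small": (100.0, 50.0)}
    sts = pd.Series({g: compute_stress_indices(
        StressIndexInput(c, t, xc, xt)).sts for g, (c, t) in pairs.items()})
    assert sts["big"] > sts["mid"] > sts["small"]


# -- selection -----------------------------------------------------------


def test_top_fraction_counts():
    values = pd.Series(np.arange(85, dtype=float),
                       index=[f"G{i:02d}" for i in range(85)])
    sel = select_top_fraction(values, 0.10)
    assert sel.k == 8
    assert len(sel.selected) == 8
    assert select_top_fraction(values.iloc[:10], 0.10).k == 1


def test_top_fraction_tie_break():
    values = pd.Series({"B": 10.0, "A": 10.0, "C": 5.0})
    sel = select_top_fraction(values, 2 / 3)
    assert sel.selected == ("A", "B")


def test_top_fraction_invalid_fraction():
    values = pd.Series({"A": 1.0})
    with pytest.raises(ValueError):
        select_top_fraction(values, 0.0)


def test_membership_overlap_matrix():
    out = membership_overlap({"X": {"A", "B"}, "Y": {"B", "C"}})
    assert bool(out.loc["A", "X"]) and not bool(out.loc["A", "Y"])
    assert bool(out.loc["B", "X"]) and bool(out.loc["B", "Y"])
    disjoint = membership_overlap({"X": {"A"}, "Y": {"B"}})
    assert int(disjoint.sum(axis=1).max()) == 1
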