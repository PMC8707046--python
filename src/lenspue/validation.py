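"""Monte-Carlo parameter-recovery studies for the heritability pipeline.

Simulates repeated cohorts from the generative model and summarizes how
well the balanced-ANOVA method-of-moments estimators recover the known
variance components and the heritability they imply.  Used for estimator
calibration checks; cohort counts are configurable so desk-scale checks
stay fast.
"""

from __future__ import annotations

import numpy as np

from .heritability import (anova_combined, anova_single_condition,
                           heritability)
from .simulate import SyntheticConfig, expected_heritability, simulate_cohort


def heritability_recovery(n_cohorts: int = 200, n_genotypes: int = 85,
                          n_reps: int = 3, sigma2_g: float = 2000.0,
                          sigma2_ge: float = 500.0, sigma2_e: float = 2500.0,
                          mu_sp: float = 1000.0, mu_lp: float = 800.0,
                          seed: int = 0) -> dict:
    """Recover H and the combined-model components over repeated cohorts.

    Each cohort is a balanced ``n_genotypes x 2 treatments x n_reps``
    draw of a single trait.  Within a single P level the genotype effect
    is ``G_i + GT_it``, so the single-condition ANOVA estimates the
    confounded genotypic variance ``sigma2_G + sigma2_GE`` and its H
    targets ``(s2G + s2GE) / (s2G + s2GE + s2e/r)`` (0.75 under the
    defaults).  Returns that expected value, the mean and SD of the
    per-cohort H estimates (both arms pooled), the cohort-averaged
    combined-model component estimates and their relative errors against
    the generative truth (absolute error where the truth is 0).
    """
    h_hats, s2g_hats, s2ge_hats, s2e_hats = [], [], [], []
    root = np.random.SeedSequence(seed)
    cohort_seeds = root.generate_state(n_cohorts) % (2 ** 31)
    base = dict(n_genotypes=n_genotypes, n_reps=n_reps, traits=("SDW",),
                mu_sp={"SDW": mu_sp}, mu_lp={"SDW": mu_lp},
                sigma2_g={"SDW": sigma2_g}, sigma2_ge={"SDW": sigma2_ge},
                sigma2_e={"SDW": sigma2_e})
    cfg0 = SyntheticConfig(**base, seed=0)
    for s in cohort_seeds:
        cfg = SyntheticConfig(**base, seed=int(s))
        table = simulate_cohort(cfg)
        for arm in ("SP", "LP"):
            h_hats.append(
                heritability(anova_single_condition(table, arm, "SDW")))
        vc = anova_combined(table, "SDW")
        s2g_hats.append(vc.sigma2_G)
        s2ge_hats.append(vc.sigma2_GE)
        s2e_hats.append(vc.sigma2_e)
    mean = lambda x: float(np.mean(x))

    def rel_err(est: float, truth: float) -> float:
        return abs(est - truth) / truth if truth > 0 else abs(est - truth)

    g_arm = sigma2_g + sigma2_ge   # confounded single-arm genotypic variance
    return {
        "n_cohorts": n_cohorts,
        "expected_h_single": g_arm / (g_arm + sigma2_e / n_reps),
        "expected_h_config": expected_heritability(cfg0, "SDW", "single"),
        "mean_h_single": mean(h_hats),
        "sd_h_single": float(np.std(h_hats, ddof=1)),
        "mean_sigma2_g": mean(s2g_hats),
        "mean_sigma2_ge": mean(s2ge_hats),
        "mean_sigma2_e": mean(s2e_hats),
        "rel_err_sigma2_g": rel_err(mean(s2g_hats), sigma2_g),
        "rel_err_sigma2_ge": rel_err(mean(s2ge_hats), sigma2_ge),
        "rel_err_sigma2_e": rel_err(mean(s2e_hats), sigma2_e),
    }
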