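"""Synthetic genotype x phosphorus-treatment cohort generator.

Every downstream stage of the pipeline (descriptive statistics, variance
components, heritability, efficiency indices, classification) is exercised
against cohorts drawn from an additive random-effects model with known
variance components,

    value(i, t, k) = mu_t + G_i + GT_it + eps_itk,

where ``G_i ~ N(0, sigma2_G)`` (jointly across traits through a genotypic
correlation matrix), ``GT_it ~ N(0, sigma2_GE)`` is the genotype x P-level
interaction and ``eps_itk ~ N(0, sigma2_e)`` the plot residual.  Total dry
weight is emitted as SDW + RDW and the root-to-shoot ratio as RDW/SDW, so
the arithmetic consistency checks of :mod:`lenspue.phenodata` hold by
construction.  A tissue P-concentration channel (one draw per genotype x
treatment, in mg/g) makes P uptake efficiency derivable.

Default parameters emulate the published 85-genotype lentil screen: the
treatment means are the published panel means, genotypic spread is set to a
12% genotypic CV and error/interaction variances are backed out from the
published heritability magnitudes and interaction-to-genotype variance
ratios.  Phenotypes are nonnegative: draws below zero are clamped to zero
(rare under the defaults, < 0.1%) and counted in a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference
from .exceptions import ConfigError, DomainError
from .phenodata import PhenotypeTable
from .traits import LENS_SPECIES, MEASURED_TRAITS

#: Traits drawn directly from the generative model (TDW and RSR are derived).
SIMULATED_TRAITS = ("PRL", "TRL", "TSA", "ARD", "TRV", "TRT", "RF",
                    "SDW", "RDW")

_CANONICAL_ORDER = {t: i for i, t in enumerate(MEASURED_TRAITS)}


@dataclass
class SyntheticConfig:
    """Generative parameters for a balanced synthetic cohort.

    Per-trait parameters are mappings keyed by trait code; ``genetic_corr``
    (trait x trait, ordered as ``traits``) correlates genotypic effects and
    defaults to the identity.
    """

    n_genotypes: int = 85
    n_reps: int = 3
    traits: tuple[str, ...] = SIMULATED_TRAITS
    mu_sp: dict[str, float] = field(default_factory=dict)
    mu_lp: dict[str, float] = field(default_factory=dict)
    sigma2_g: dict[str, float] = field(default_factory=dict)
    sigma2_ge: dict[str, float] = field(default_factory=dict)
    sigma2_e: dict[str, float] = field(default_factory=dict)
    genetic_corr: np.ndarray | None = None
    pconc_mean_sp: float = 1.127
    pconc_mean_lp: float = 0.566
    pconc_sd: float = 0.12
    seed: int = 0

    def validate(self) -> None:
        if self.n_genotypes < 1 or self.n_reps < 1:
            raise ConfigError("n_genotypes and n_reps must be positive")
        for t in self.traits:
            if t not in MEASURED_TRAITS:
                raise ConfigError(f"unknown trait {t!r}")
            for name, m in (("mu_sp", self.mu_sp), ("mu_lp", self.mu_lp)):
                if m.get(t, 0.0) < 0:
                    raise ConfigError(f"{name}[{t}] must be >= 0")
            for name, m in (("sigma2_g", self.sigma2_g),
                            ("sigma2_ge", self.sigma2_ge),
                            ("sigma2_e", self.sigma2_e)):
                if m.get(t, 0.0) < 0:
                    raise ConfigError(f"{name}[{t}] must be >= 0")
        if self.pconc_sd < 0 or self.pconc_mean_sp < 0 or self.pconc_mean_lp < 0:
            raise ConfigError("P-concentration parameters must be >= 0")
        if self.genetic_corr is not None:
            R = np.asarray(self.genetic_corr, float)
            k = len(self.traits)
            if R.shape != (k, k):
                raise ConfigError(
                    f"genetic_corr must be {k}x{k}, got {R.shape}")
            if not np.allclose(R, R.T, atol=1e-10):
                raise ConfigError("genetic_corr must be symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-10):
                raise ConfigError("genetic_corr must have unit diagonal")
            if np.linalg.eigvalsh(R).min() < -1e-8:
                raise ConfigError(
                    "genetic_corr must be positive semi-definite")


def default_config(seed: int = 0, n_genotypes: int = 85,
                   n_reps: int = 3) -> SyntheticConfig:
    """Study-condition defaults calibrated to the published panel.

    Treatment means are the published per-trait panel means; the genotypic
    SD is 12% of the pooled mean; the residual variance is backed out of
    the published single-condition heritability (averaged over arms and
    clipped to [0.5, 0.9] so the normal model keeps phenotypes positive);
    the interaction variance uses the published interaction-to-genotype
    variance ratio clipped to [0.2, 1.0].
    """
    mu_sp, mu_lp, s2g, s2ge, s2e = {}, {}, {}, {}, {}
    summ = reference.PANEL_SUMMARY
    herit = reference.PUBLISHED_HERITABILITY
    for t in SIMULATED_TRAITS:
        m_sp = float(summ.loc[t, "mean_SP"])
        m_lp = float(summ.loc[t, "mean_LP"])
        mu_sp[t], mu_lp[t] = m_sp, m_lp
        sg = 0.12 * 0.5 * (m_sp + m_lp)
        h = float(np.clip(0.5 * (herit.loc[t, "H_SP"] + herit.loc[t, "H_LP"]),
                          0.5, 0.9))
        ratio = float(np.clip(reference.PUBLISHED_GE_RATIO[t], 0.2, 1.0))
        s2g[t] = sg ** 2
        s2ge[t] = ratio * sg ** 2
        s2e[t] = n_reps * sg ** 2 * (1.0 / h - 1.0)
    return SyntheticConfig(
        n_genotypes=n_genotypes, n_reps=n_reps, traits=SIMULATED_TRAITS,
        mu_sp=mu_sp, mu_lp=mu_lp, sigma2_g=s2g, sigma2_ge=s2ge,
        sigma2_e=s2e, seed=seed)


def config_from_yaml(path: str | Path,
                     seed: int | None = None) -> SyntheticConfig:
    """Load a SyntheticConfig from YAML, filling omitted fields from the
    calibrated defaults; an explicit *seed* argument overrides the file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = default_config(
        seed=raw.get("seed", 0),
        n_genotypes=raw.get("n_genotypes", 85),
        n_reps=raw.get("n_reps", 3))
    if "traits" in raw:
        cfg.traits = tuple(raw["traits"])
    for key in ("mu_sp", "mu_lp", "sigma2_g", "sigma2_ge", "sigma2_e"):
        if key in raw:
            getattr(cfg, key).update({k: float(v)
                                      for k, v in raw[key].items()})
    for key in ("pconc_mean_sp", "pconc_mean_lp", "pconc_sd"):
        if key in raw:
            setattr(cfg, key, float(raw[key]))
    if "genetic_corr" in raw:
        cfg.genetic_corr = np.asarray(raw["genetic_corr"], float)
    if seed is not None:
        cfg.seed = seed
    cfg.validate()
    return cfg


# -- random-number plumbing ----------------------------------------------


def _stream(seed: int, trait: str, channel: int) -> np.random.Generator:
    """Deterministic substream per (master seed, trait, channel).

    Substreams are keyed by the trait's position in the closed trait
    registry, so adding or removing a trait from a config never perturbs
    the draws of the remaining traits.
    """
    ss = np.random.SeedSequence(
        entropy=seed, spawn_key=(_CANONICAL_ORDER[trait], channel))
    return np.random.default_rng(ss)


def _corr_factor(R: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:  # PSD but singular
        w, V = np.linalg.eigh(R)
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _genotype_labels(n: int) -> pd.DataFrame:
    """Deterministic genotype ids with species / material-class labels
    mirroring the panel's 26 cultivated : 28 breeding-line : 31 wild split."""
    ids = [f"G{i + 1:03d}" for i in range(n)]
    n_cult = round(0.30 * n)
    n_breed = round(0.33 * n)
    wild_species = [s for s in LENS_SPECIES
                    if s not in ("L. culinaris", "unknown")]
    species, material = [], []
    for i in range(n):
        if i < n_cult:
            species.append("L. culinaris")
            material.append("cultivated")
        elif i < n_cult + n_breed:
            species.append("L. culinaris")
            material.append("breeding_line")
        else:
            species.append(wild_species[i % len(wild_species)])
            material.append("wild")
    return pd.DataFrame({"genotype": ids, "species": species,
                         "material_class": material})


def simulate_cohort(config: SyntheticConfig) -> PhenotypeTable:
    """Draw one balanced cohort from the generative model.

    Returns a :class:`PhenotypeTable` with ``n_genotypes x 2 treatments x
    n_reps`` records per trait: the configured traits plus derived TDW
    (= SDW + RDW) and RSR (= RDW/SDW) when both dry weights are simulated,
    plus the PCONC channel (constant across replicates within a genotype x
    treatment cell, as tissue P is measured on pooled samples).
    """
    config.validate()
    g, r = config.n_genotypes, config.n_reps
    labels = _genotype_labels(g)
    traits = list(config.traits)
    k = len(traits)

    # genotypic effects, correlated across traits via a factor of R
    Z = np.column_stack([_stream(config.seed, t, 0).standard_normal(g)
                         for t in traits])
    if config.genetic_corr is not None:
        Z = Z @ _corr_factor(np.asarray(config.genetic_corr, float)).T
    G = Z * np.sqrt([config.sigma2_g.get(t, 0.0) for t in traits])

    clamped = 0
    total = 0
    frames = {}
    for j, t in enumerate(traits):
        sge = np.sqrt(config.sigma2_ge.get(t, 0.0))
        se = np.sqrt(config.sigma2_e.get(t, 0.0))
        rng_ge = _stream(config.seed, t, 1)
        rng_e = _stream(config.seed, t, 2)
        arr = np.empty((g, 2, r))
        for ti, (treat, mu) in enumerate(
                (("SP", config.mu_sp), ("LP", config.mu_lp))):
            gt = sge * rng_ge.standard_normal(g)
            eps = se * rng_e.standard_normal((g, r))
            arr[:, ti, :] = (mu.get(t, 0.0) + G[:, j] + gt)[:, None] + eps
        clamped += int((arr < 0).sum())
        total += arr.size
        frames[t] = np.maximum(arr, 0.0)

    if clamped:
        warnings.warn(
            f"clamped {clamped} of {total} draws "
            f"({100 * clamped / total:.3f}%) at 0", stacklevel=2)

    if "SDW" in frames and "RDW" in frames:
        frames["TDW"] = frames["SDW"] + frames["RDW"]
        with np.errstate(divide="ignore", invalid="ignore"):
            frames["RSR"] = np.where(frames["SDW"] > 0,
                                     frames["RDW"] / np.maximum(frames["SDW"],
                                                                1e-300),
                                     0.0)

    # P-concentration channel: one draw per genotype x treatment
    rng_p = _stream(config.seed, "PCONC", 0)
    pc = np.empty((g, 2, r))
    for ti, mean in enumerate((config.pconc_mean_sp, config.pconc_mean_lp)):
        draw = np.maximum(mean + config.pconc_sd * rng_p.standard_normal(g),
                          0.0)
        pc[:, ti, :] = draw[:, None]
    frames["PCONC"] = pc

    records = []
    treatments = ("SP", "LP")
    for t, arr in frames.items():
        for gi in range(g):
            for ti in range(2):
                for rep in range(r):
                    records.append((labels.loc[gi, "genotype"],
                                    labels.loc[gi, "species"],
                                    labels.loc[gi, "material_class"],
                                    rep + 1, treatments[ti], t,
                                    arr[gi, ti, rep]))
    df = pd.DataFrame.from_records(
        records, columns=["genotype", "species", "material_class",
                          "replicate", "treatment", "trait", "value"])
    return PhenotypeTable(df)


def expected_heritability(config: SyntheticConfig, trait: str,
                          mode: str = "single") -> float:
    """Closed-form broad-sense heritability implied by the config.

    ``single``: sigma2_G / (sigma2_G + sigma2_e / r).
    ``combined`` (over e = 2 P levels):
    sigma2_G / (sigma2_G + sigma2_GE / e + sigma2_e / (r e)).
    """
    config.validate()
    if (trait == "TDW" and trait not in config.sigma2_g
            and {"SDW", "RDW"} <= set(config.traits)
            and config.genetic_corr is None):
        # TDW = SDW + RDW with independent effects: components add
        s2g = config.sigma2_g.get("SDW", 0.0) + config.sigma2_g.get("RDW", 0.0)
        s2ge = (config.sigma2_ge.get("SDW", 0.0)
                + config.sigma2_ge.get("RDW", 0.0))
        s2e = config.sigma2_e.get("SDW", 0.0) + config.sigma2_e.get("RDW", 0.0)
    else:
        s2g = config.sigma2_g.get(trait, 0.0)
        s2ge = config.sigma2_ge.get(trait, 0.0)
        s2e = config.sigma2_e.get(trait, 0.0)
    if s2g + s2ge + s2e == 0:
        raise DomainError(
            f"heritability undefined for {trait}: all variances zero")
    r = config.n_reps
    if mode == "single":
        return s2g / (s2g + s2e / r)
    if mode == "combined":
        e = 2
        return s2g / (s2g + s2ge / e + s2e / (r * e))
    raise ValueError(f"mode must be 'single' or 'combined', got {mode!r}")
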