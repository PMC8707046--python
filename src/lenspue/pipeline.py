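"""End-to-end orchestration: ingest/simulate -> report tables + manifest.

``run_pipeline`` sequences the analysis stages (descriptive summaries,
variance components / heritability, efficiency indices, classification)
over one phenotype table, writes every table as CSV (a full-precision
machine copy under ``tables/`` and a 2-decimal report copy under
``report/``) and records a manifest with checksums so a rerun with the
same configuration and seed is byte-identical.  Stages that cannot run on
the given data (no P-concentration channel, unbalanced design) are skipped
and listed in the manifest, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import (DEFAULT_SCORE_TRAITS, technique1_scores,
                       technique2_classify, technique3_classify,
                       technique4_rank, membership_overlap,
                       select_top_fraction)
from .exceptions import ConfigError, LenspueError, UnbalancedDesignError
from .heritability import anova_gxp_subset, heritability_table
from .indices import efficiency_table, stress_index_table
from .phenodata import (PhenotypeTable, check_tdw_consistency,
                        genotype_means, read_phenotype_table)
from .simulate import SyntheticConfig, default_config, simulate_cohort
from .stats import (correlation_matrix, percent_change, relative_values,
                    run_pca, species_summary, summarize_traits)

log = logging.getLogger(__name__)

ALL_STAGES = ("summaries", "heritability", "efficiency", "classification")
_ROOT_TRAITS = ("TRL", "TSA", "TRV", "TRT", "RF")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input`` (long CSV path) or ``synthetic`` (generator
    config) must be set.
    """

    outdir: Path
    input: Path | None = None
    synthetic: SyntheticConfig | None = None
    seed: int | None = None
    aliases: dict[str, str] = field(default_factory=dict)
    cv_mode: str = "genotype"
    score_traits: tuple[str, ...] = DEFAULT_SCORE_TRAITS
    score_points: tuple[int, int, int] = (3, 2, 1)
    nine_cut_mode: str = "sd"
    top_fraction: float = 0.10
    stages: tuple[str, ...] = ALL_STAGES

    def validate(self) -> None:
        if (self.input is None) == (self.synthetic is None):
            raise ConfigError(
                "exactly one of input path / synthetic config must be set")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")


@dataclass
class ReportBundle:
    """Tables produced by one run plus the manifest describing them."""

    tables: dict[str, pd.DataFrame]
    manifest: dict
    outdir: Path


def _analysis_means(table: PhenotypeTable, treatment: str) -> pd.DataFrame:
    """Genotype means for one arm, extended with derived PUPE / PUTIE."""
    means = genotype_means(table, treatment)
    eff = efficiency_table(table)
    col = f"PUPE_{treatment}"
    if col in eff.columns:
        means["PUPE"] = eff[col]
    means["PUTIE"] = eff["PUTIE"]
    return means


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the configured stages and write the report bundle."""
    config.validate()
    if config.synthetic is not None:
        if config.seed is not None:
            config.synthetic.seed = config.seed
        table = simulate_cohort(config.synthetic)
    else:
        table = read_phenotype_table(config.input, layout="long",
                                     aliases=config.aliases)
    if len(table) == 0:
        raise ConfigError("empty phenotype table")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    skipped: list[dict] = []
    has_pconc = "PCONC" in table.traits
    arms = [t for t in ("SP", "LP") if t in table.treatments]

    if config.synthetic is not None:
        table.to_csv(outdir / "cohort.csv")

    bad_tdw = check_tdw_consistency(table)
    if bad_tdw:
        log.warning("TDW != SDW + RDW in %d cell(s): %s",
                    len(bad_tdw), bad_tdw[:5])

    if "summaries" in config.stages:
        _stage_summaries(table, arms, config, tables, skipped, has_pconc)
    if "heritability" in config.stages:
        try:
            tables["table2_heritability"] = heritability_table(table)
        except (UnbalancedDesignError, LenspueError) as exc:
            log.warning("heritability stage skipped: %s", exc)
            skipped.append({"stage": "heritability", "reason": str(exc)})
    if "efficiency" in config.stages:
        tables["efficiency"] = efficiency_table(table)
        if not has_pconc:
            skipped.append({"stage": "efficiency",
                            "reason": "PCONC absent: PupE columns missing"})
        if "TDW" in table.traits and len(arms) == 2:
            tables["stress_indices"] = stress_index_table(table)
    if "classification" in config.stages:
        _stage_classification(table, arms, config, tables, skipped,
                              has_pconc)

    manifest = _write_bundle(tables, outdir, config, skipped)
    return ReportBundle(tables=tables, manifest=manifest, outdir=outdir)


def _stage_summaries(table, arms, config, tables, skipped, has_pconc):
    rows = []
    for arm in arms:
        rows.append(summarize_traits(table, arm, cv_mode=config.cv_mode)
                    .reset_index())
    summary = pd.concat(rows, ignore_index=True)
    if len(arms) == 2:
        wide = summary.pivot(index="trait", columns="treatment",
                             values="mean")
        pct = {t: percent_change(wide.loc[t, "SP"], wide.loc[t, "LP"])
               for t in wide.index
               if wide.loc[t].notna().all() and wide.loc[t, "SP"] > 0}
        tables["table1_percent_change"] = (
            pd.Series(pct, name="pct_change_mean").rename_axis("trait")
            .to_frame())
    tables["table1_summary"] = summary.set_index(["trait", "treatment"])

    eff = efficiency_table(table)
    putie = eff["PUTIE"].dropna()
    if len(putie) >= 2:
        tables["putie_summary"] = pd.DataFrame(
            {"min": [putie.min()], "max": [putie.max()],
             "mean": [putie.mean()],
             "cv_percent": [100 * putie.std(ddof=1) / putie.mean()],
             "n": [len(putie)]}, index=pd.Index(["PUTIE"], name="trait"))

    for arm in arms:
        means = _analysis_means(table, arm).dropna(axis=1, how="all")
        corr = correlation_matrix(means)
        tables[f"table3_correlations_{arm.lower()}"] = corr.r
        tables[f"table3_correlations_{arm.lower()}_p"] = corr.p
        tables[f"table3_correlations_{arm.lower()}_stars"] = corr.stars()

    if len(arms) == 2:
        rel = relative_values(table).dropna(axis=1, how="any")
        rel = rel.loc[:, rel.std(ddof=1) > 0]
        if rel.shape[0] >= 2 and rel.shape[1] >= 2:
            pca = run_pca(rel)
            tables["pca_eigenvalues"] = pd.DataFrame(
                {"eigenvalue": pca.eigenvalues,
                 "pct_variance": pca.pct_variance},
                index=pd.Index(pca.loadings.columns, name="component"))
            tables["pca_loadings"] = pca.loadings
            tables["pca_scores"] = pca.scores
        else:
            skipped.append({"stage": "pca",
                            "reason": "insufficient complete relative-value "
                                      "matrix"})
    tables["species_summary"] = species_summary(table)


def _stage_classification(table, arms, config, tables, skipped, has_pconc):
    for arm in arms:
        means = _analysis_means(table, arm)
        tables[f"technique1_scores_{arm.lower()}"] = technique1_scores(
            means, traits=config.score_traits, points=config.score_points)
        if {"TDW", "PUTIE"} <= set(means.columns):
            tables[f"technique2_quadrants_{arm.lower()}"] = \
                technique2_classify(means)
        if "PUPE" in means.columns:
            tables[f"technique3_ninegroups_{arm.lower()}"] = \
                technique3_classify(means, cut_mode=config.nine_cut_mode)
        elif not has_pconc:
            skipped.append({"stage": f"technique3_{arm}",
                            "reason": "PCONC absent: P uptake axis missing"})
    if "TDW" in table.traits and len(arms) == 2:
        sts = stress_index_table(table)
        tables["technique4_sts_rank"] = technique4_rank(sts["sts"])

        lp_means = _analysis_means(table, "LP")
        sels = {}
        for crit in ("TDW", "SDW", "RDW", "PUPE", "PUTIE"):
            if crit in lp_means.columns and lp_means[crit].notna().any():
                sel = select_top_fraction(lp_means[crit],
                                          fraction=config.top_fraction,
                                          criterion=crit)
                sels[crit] = set(sel.selected)
        if sels:
            primary = sels.get("TDW", set())
            overlap = membership_overlap(sels)
            tables["table4_overlap"] = overlap.loc[
                overlap.index.isin(primary) if primary else overlap.index]
            if primary and len(primary) >= 2:
                rows = []
                for trait in _ROOT_TRAITS:
                    if trait not in table.traits:
                        continue
                    try:
                        aov = anova_gxp_subset(table, sorted(primary), trait)
                    except LenspueError as exc:
                        skipped.append({"stage": f"table5_{trait}",
                                        "reason": str(exc)})
                        continue
                    aov = aov.reset_index(names="source")
                    aov.insert(0, "trait", trait)
                    rows.append(aov)
                if rows:
                    tables["table5_subset_anova"] = pd.concat(
                        rows, ignore_index=True).set_index(["trait", "source"])


def _write_bundle(tables, outdir, config, skipped) -> dict:
    (outdir / "tables").mkdir(exist_ok=True)
    (outdir / "report").mkdir(exist_ok=True)
    files = {}
    for name, df in sorted(tables.items()):
        full = outdir / "tables" / f"{name}.csv"
        df.to_csv(full, float_format="%.10g")
        rounded = outdir / "report" / f"{name}.csv"
        df.to_csv(rounded, float_format="%.2f")
        files[str(full.relative_to(outdir))] = _sha256(full)
        files[str(rounded.relative_to(outdir))] = _sha256(rounded)
    manifest = {
        "package": "lenspue",
        "version": __version__,
        "seed": config.seed if config.seed is not None else (
            config.synthetic.seed if config.synthetic else None),
        "config": _config_summary(config),
        "files": files,
        "skipped": skipped,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _config_summary(config: RunConfig) -> dict:
    return {
        "input": str(config.input) if config.input else None,
        "synthetic": (
            {"n_genotypes": config.synthetic.n_genotypes,
             "n_reps": config.synthetic.n_reps,
             "traits": list(config.synthetic.traits),
             "seed": config.synthetic.seed}
            if config.synthetic else None),
        "cv_mode": config.cv_mode,
        "score_traits": list(config.score_traits),
        "score_points": list(config.score_points),
        "nine_cut_mode": config.nine_cut_mode,
        "top_fraction": config.top_fraction,
        "stages": list(config.stages),
        "aliases": dict(config.aliases),
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()
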