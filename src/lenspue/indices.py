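"""Phosphorus uptake / utilization efficiency and stress-tolerance indices.

Uptake efficiency (PupE) is tissue P concentration times dry matter;
utilization efficiency (PutiE) is the percentage of sufficient-P total dry
weight achieved under low P.  The seven low-P tolerance/susceptibility
indices are computed from a genotype's total dry mass under control (C,
sufficient P) and stress (T, low P) and the population means xC and xT:

    SSI  = (1 - T/C) / (1 - xT/xC)      stress susceptibility index
    MPI  = (C + T) / 2                  mean productivity
    GMPI = sqrt(C T)                    geometric mean productivity
    HMI  = 2 C T / (C + T)              harmonic mean
    STI  = C T / xC^2                   stress tolerance index
    TI   = C - T                        tolerance (loss under stress)
    SI   = T / C                        stress (stability) index

and the composite stress tolerance score STS is their plain sum.  The
arithmetic-geometric-harmonic mean chain HMI <= GMPI <= MPI, the identity
STI = (GMPI/xC)^2 and SSI (1 - xT/xC) = 1 - SI hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .phenodata import PhenotypeTable, genotype_means

#: Index names in the order the composite score sums them.
INDEX_NAMES = ("ssi", "mpi", "gmpi", "hmi", "sti", "ti", "si")


def compute_pupe(p_conc: float, dry_matter: float) -> float:
    """P uptake efficiency: tissue P concentration x dry matter.

    ``p_conc`` is the measured tissue concentration in mg P per g dry
    matter and ``dry_matter`` the plant dry matter in mg.  The plain
    product is returned on the conventional reporting scale of this assay
    (numerically mg/g x mg, i.e. micrograms P per plant, customarily
    printed as an "mg per plant" index): a concentration of 1.269 mg/g at
    210 mg dry matter gives 266.49.
    """
    if p_conc < 0 or dry_matter < 0:
        raise DomainError("p_conc and dry_matter must be >= 0")
    return p_conc * dry_matter


def compute_putie(tdw_lp: float, tdw_sp: float) -> float:
    """P utilization efficiency: 100 x TDW(LP) / TDW(SP), in percent.

    One value per genotype; values above 100 (growth under low P
    exceeding sufficient P) are legitimate and not clipped.
    """
    if tdw_sp <= 0:
        raise DomainError(f"tdw_sp must be > 0, got {tdw_sp}")
    if tdw_lp < 0:
        raise DomainError(f"tdw_lp must be >= 0, got {tdw_lp}")
    return 100.0 * tdw_lp / tdw_sp


@dataclass(frozen=True)
class StressIndexInput:
    """Per-genotype dry-mass inputs for the tolerance indices."""

    C: float    # total dry mass under control (SP), > 0
    T: float    # total dry mass under stress (LP), >= 0
    xC: float   # population mean dry mass under SP, > 0
    xT: float   # population mean dry mass under LP, > 0

    def validate(self) -> None:
        if self.C <= 0:
            raise DomainError(f"C must be > 0, got {self.C}")
        if self.T < 0:
            raise DomainError(f"T must be >= 0, got {self.T}")
        if self.xC <= 0 or self.xT <= 0:
            raise DomainError("population means xC, xT must be > 0")
        if self.xT == self.xC:
            raise DomainError(
                "SSI undefined: population means equal (xT == xC)")


@dataclass(frozen=True)
class StressIndexSet:
    """The seven tolerance/susceptibility indices and their composite sum."""

    ssi: float
    mpi: float
    gmpi: float
    hmi: float
    sti: float
    ti: float
    si: float
    sts: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_stress_indices(inp: StressIndexInput,
                           si_mode: str = "T/C") -> StressIndexSet:
    """Evaluate the seven indices and their composite score for one genotype.

    ``si_mode`` selects the stress-index convention: the default ``"T/C"``
    (yield-stability ratio, which makes SSI (1 - xT/xC) = 1 - SI exact) or
    ``"T/xT"``.
    """
    inp.validate()
    C, T, xC, xT = inp.C, inp.T, inp.xC, inp.xT
    ssi = (1.0 - T / C) / (1.0 - xT / xC)
    mpi = (C + T) / 2.0
    gmpi = float(np.sqrt(C * T))
    hmi = 2.0 * C * T / (C + T)
    sti = C * T / xC ** 2
    ti = C - T
    if si_mode == "T/C":
        si = T / C
    elif si_mode == "T/xT":
        si = T / xT
    else:
        raise ValueError(f"si_mode must be 'T/C' or 'T/xT', got {si_mode!r}")
    values = (ssi, mpi, gmpi, hmi, sti, ti, si)
    return StressIndexSet(*values, sts=compute_sts(values))


def compute_sts(indices) -> float:
    """Composite stress tolerance score: the plain sum of the seven indices."""
    if isinstance(indices, StressIndexSet):
        values = [getattr(indices, n) for n in INDEX_NAMES]
    else:
        values = list(indices)
    if len(values) != 7 or any(v is None or not np.isfinite(v)
                               for v in values):
        raise DomainError("all seven indices are required for the score")
    return float(sum(values))


# -- cohort-level tables -------------------------------------------------


def efficiency_table(table: PhenotypeTable) -> pd.DataFrame:
    """Per-genotype PupE (per arm) and PutiE from a phenotype table.

    Needs TDW and PCONC; genotypes lacking an arm carry missing entries.
    Columns: TDW_SP, TDW_LP, PCONC_SP, PCONC_LP, PUPE_SP, PUPE_LP, PUTIE.
    """
    sp = genotype_means(table, "SP")
    lp = genotype_means(table, "LP")
    sp, lp = sp.align(lp, join="outer")
    out = pd.DataFrame(index=sp.index)
    out["TDW_SP"] = sp.get("TDW")
    out["TDW_LP"] = lp.get("TDW")
    if "PCONC" in sp.columns:
        out["PCONC_SP"] = sp["PCONC"]
        out["PCONC_LP"] = lp["PCONC"]
        out["PUPE_SP"] = sp["PCONC"] * sp["TDW"]
        out["PUPE_LP"] = lp["PCONC"] * lp["TDW"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["PUTIE"] = (100.0 * out["TDW_LP"] / out["TDW_SP"]).where(
            out["TDW_SP"] > 0)
    return out


def stress_index_table(table: PhenotypeTable,
                       si_mode: str = "T/C") -> pd.DataFrame:
    """Seven indices + composite score per genotype, from TDW means.

    ``C``/``T`` are genotype TDW means under SP/LP; ``xC``/``xT`` the
    population means over genotypes with both arms.  Genotypes missing an
    arm are excluded.
    """
    sp = genotype_means(table, "SP")["TDW"]
    lp = genotype_means(table, "LP")["TDW"]
    both = pd.concat({"C": sp, "T": lp}, axis=1).dropna()
    both = both[both["C"] > 0]
    xC, xT = float(both["C"].mean()), float(both["T"].mean())
    rows = {}
    for gid, row in both.iterrows():
        idx = compute_stress_indices(
            StressIndexInput(C=float(row["C"]), T=float(row["T"]),
                             xC=xC, xT=xT), si_mode=si_mode)
        rows[gid] = {"C": row["C"], "T": row["T"], **idx.as_dict()}
    out = pd.DataFrame.from_dict(rows, orient="index").rename_axis("genotype")
    out.attrs["xC"], out.attrs["xT"] = xC, xT
    # standardized composite alongside the plain sum (not a published
    # quantity; the plain sum is dominated by the mg-scale terms)
    z = out[list(INDEX_NAMES)].apply(
        lambda s: (s - s.mean()) / s.std(ddof=1) if s.std(ddof=1) > 0
        else s * 0.0)
    out["sts_standardized"] = z.sum(axis=1)
    return out
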