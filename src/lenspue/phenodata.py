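"""Phenotype data model and I/O.

The substrate of the whole pipeline is a long-format table with one row per
genotype x replicate x treatment x trait observation.  ``PhenotypeTable``
wraps a validated :class:`pandas.DataFrame` and exposes the design summary
(genotype count, replicate count, balance) that the ANOVA stages rely on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataValidationError
from .traits import DEFAULT_TREATMENT_ALIASES, MEASURED_TRAITS, TREATMENTS

log = logging.getLogger(__name__)

LONG_COLUMNS = [
    "genotype", "species", "material_class", "replicate", "treatment",
    "trait", "value",
]
_KEY = ["genotype", "replicate", "treatment", "trait"]
_WIDE_ID_COLUMNS = ["genotype", "species", "material_class", "replicate",
                    "treatment"]


@dataclass(frozen=True)
class DesignSummary:
    """Derived description of the experimental design."""

    n_genotypes: int
    n_replicates: int | None   # common replicate count, None if unbalanced
    balanced: bool
    treatments: tuple[str, ...]
    traits: tuple[str, ...]


class PhenotypeTable:
    """Validated replicate-level genotype x treatment x trait observations.

    Parameters
    ----------
    data : pandas.DataFrame
        Long-format frame with columns
        ``genotype, species, material_class, replicate, treatment, trait,
        value``.  Treatment labels are canonicalized through *aliases*
        (``HP`` maps to ``SP`` by default), values must be nonnegative
        numbers, and the key ``(genotype, replicate, treatment, trait)``
        must be unique.
    aliases : dict, optional
        Extra treatment label aliases merged over the built-in ``HP -> SP``.
    """

    def __init__(self, data: pd.DataFrame,
                 aliases: dict[str, str] | None = None) -> None:
        amap = dict(DEFAULT_TREATMENT_ALIASES)
        if aliases:
            amap.update(aliases)
        self._data = _validate(data, amap)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, records: list[dict],
                     aliases: dict[str, str] | None = None
                     ) -> "PhenotypeTable":
        return cls(pd.DataFrame.from_records(records), aliases=aliases)

    # -- accessors --------------------------------------------------------

    @property
    def data(self) -> pd.DataFrame:
        """The validated long-format frame (copy-on-write view)."""
        return self._data

    @property
    def genotypes(self) -> list[str]:
        return sorted(self._data["genotype"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self._data["trait"].unique())

    @property
    def treatments(self) -> list[str]:
        return sorted(self._data["treatment"].unique())

    @property
    def design(self) -> DesignSummary:
        counts = (self._data.groupby(["genotype", "treatment", "trait"],
                                     observed=True)["value"].size())
        uniq = counts.unique()
        balanced = len(uniq) == 1
        return DesignSummary(
            n_genotypes=self._data["genotype"].nunique(),
            n_replicates=int(uniq[0]) if balanced else None,
            balanced=balanced,
            treatments=tuple(self.treatments),
            traits=tuple(self.traits),
        )

    def is_balanced(self, treatment: str | None = None,
                    trait: str | None = None) -> bool:
        """True if every genotype cell in scope has the same replicate count."""
        df = self._data
        if treatment is not None:
            df = df[df["treatment"] == treatment]
        if trait is not None:
            df = df[df["trait"] == trait]
        if df.empty:
            return False
        counts = df.groupby(["genotype", "treatment", "trait"],
                            observed=True)["value"].size()
        return counts.nunique() == 1

    def subset(self, genotypes: list[str]) -> "PhenotypeTable":
        missing = sorted(set(genotypes) - set(self.genotypes))
        if missing:
            raise DataValidationError(
                f"genotypes absent from table: {missing}")
        return PhenotypeTable(
            self._data[self._data["genotype"].isin(genotypes)].copy())

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        a = self._data.sort_values(_KEY).reset_index(drop=True)
        b = other._data.sort_values(_KEY).reset_index(drop=True)
        return a.equals(b)

    # -- I/O --------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the canonical long CSV (UTF-8, header, '.' decimal)."""
        out = self._data.sort_values(_KEY).reset_index(drop=True)
        out.to_csv(path, index=False)


def read_phenotype_table(path: str | Path, layout: str = "long",
                         aliases: dict[str, str] | None = None
                         ) -> PhenotypeTable:
    """Read a phenotype CSV in ``long`` or ``wide`` layout.

    The long layout has exactly the columns
    ``genotype,species,material_class,replicate,treatment,trait,value``;
    the wide layout replaces ``trait,value`` by one column per trait code.
    Unknown trait columns in the wide layout are reported via a warning and
    skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout not in ("long", "wide"):
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    df = pd.read_csv(path, dtype={"genotype": str, "species": str,
                                  "material_class": str, "treatment": str})
    if layout == "long":
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise DataValidationError(
                f"missing mandatory column(s) {missing} in {path.name}")
        return PhenotypeTable(df[LONG_COLUMNS], aliases=aliases)

    missing = [c for c in _WIDE_ID_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(
            f"missing mandatory column(s) {missing} in {path.name}")
    trait_cols = [c for c in df.columns if c not in _WIDE_ID_COLUMNS]
    unknown = [c for c in trait_cols if c not in MEASURED_TRAITS]
    if unknown:
        warnings.warn(
            f"skipping unknown trait column(s): {unknown}", stacklevel=2)
        trait_cols = [c for c in trait_cols if c in MEASURED_TRAITS]
    if not trait_cols:
        raise DataValidationError("wide layout contains no known trait column")
    long = df.melt(id_vars=_WIDE_ID_COLUMNS, value_vars=trait_cols,
                   var_name="trait", value_name="value")
    long = long.dropna(subset=["value"])
    return PhenotypeTable(long[LONG_COLUMNS], aliases=aliases)


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    """Write the canonical long CSV; inverse of :func:`read_phenotype_table`."""
    table.to_csv(path)


def genotype_means(table: PhenotypeTable, treatment: str) -> pd.DataFrame:
    """Replicate means per genotype x trait under one treatment.

    Returns a genotype-indexed frame with one column per trait; cells where
    a genotype lacks the trait are NaN (explicit missing, never imputed).
    """
    df = table.data
    sub = df[df["treatment"] == treatment]
    if sub.empty:
        raise DataValidationError(
            f"treatment {treatment!r} absent from table "
            f"(present: {table.treatments})")
    wide = (sub.groupby(["genotype", "trait"], observed=True)["value"]
               .mean().unstack("trait"))
    wide.index.name = "genotype"
    return wide.sort_index()


def check_tdw_consistency(table: PhenotypeTable,
                          tol: float = 0.01) -> list[tuple[str, str]]:
    """Flag genotype x treatment cells where TDW deviates from SDW + RDW.

    The additive relation ``TDW = SDW + RDW`` is checked on replicate-mean
    values; cells with ``|TDW - (SDW + RDW)| / TDW > tol`` are returned.
    Cells missing any of the three traits are skipped.
    """
    df = table.data
    need = {"SDW", "RDW", "TDW"}
    if not need <= set(table.traits):
        return []
    cell = (df[df["trait"].isin(need)]
            .groupby(["genotype", "treatment", "trait"], observed=True)
            ["value"].mean().unstack("trait"))
    cell = cell.dropna(subset=list(need))
    cell = cell[cell["TDW"] > 0]
    bad = cell[(cell["TDW"] - (cell["SDW"] + cell["RDW"])).abs()
               / cell["TDW"] > tol]
    return sorted(map(tuple, bad.index))


# -- validation ----------------------------------------------------------


def _validate(df: pd.DataFrame, aliases: dict[str, str]) -> pd.DataFrame:
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"missing mandatory column(s): {missing}")
    if df.empty:
        raise DataValidationError("empty phenotype table")
    df = df[LONG_COLUMNS].copy()

    df["treatment"] = df["treatment"].replace(aliases)
    bad_t = sorted(set(df["treatment"]) - set(TREATMENTS))
    if bad_t:
        raise DataValidationError(
            f"unknown treatment label(s) {bad_t}; known: {list(TREATMENTS)} "
            f"plus aliases {aliases}")

    bad_trait = sorted(set(df["trait"]) - set(MEASURED_TRAITS))
    if bad_trait:
        raise DataValidationError(
            f"unknown trait code(s) {bad_trait}; "
            f"known: {sorted(MEASURED_TRAITS)}")

    vals = pd.to_numeric(df["value"], errors="coerce")
    nonnum = df.index[vals.isna() & df["value"].notna()]
    if len(nonnum):
        raise DataValidationError(
            f"non-numeric value at row index(es) {list(nonnum[:5])}")
    if vals.isna().any():
        raise DataValidationError(
            f"missing value at row index(es) "
            f"{list(df.index[vals.isna()][:5])}")
    if (vals < 0).any():
        raise DataValidationError(
            f"negative value at row index(es) "
            f"{list(df.index[vals < 0][:5])}")
    df["value"] = vals.astype(float)

    reps = pd.to_numeric(df["replicate"], errors="coerce")
    if reps.isna().any() or (reps < 1).any() or (reps != reps.astype(int)).any():
        raise DataValidationError("replicate must be a positive integer")
    df["replicate"] = reps.astype(int)

    dup = df.duplicated(subset=_KEY, keep=False)
    if dup.any():
        keys = (df.loc[dup, _KEY].drop_duplicates()
                  .itertuples(index=False, name=None))
        raise DataValidationError(
            f"duplicate (genotype, replicate, treatment, trait) key(s): "
            f"{sorted(keys)[:10]}")

    df["species"] = df["species"].fillna("unknown")
    df["material_class"] = df["material_class"].fillna("cultivated")
    return df.reset_index(drop=True)
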