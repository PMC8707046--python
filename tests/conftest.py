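import numpy as np
import pandas as pd
import pytest

from lenspue import PhenotypeTable, default_config, simulate_cohort


def make_long_frame(values: dict) -> pd.DataFrame:
    """Build a long frame from {(genotype, rep, treatment, trait): value}."""
    rows = [
        {"genotype": g, "species": "L. culinaris",
         "material_class": "cultivated", "replicate": r, "treatment": t,
         "trait": tr, "value": v}
        for (g, r, t, tr), v in values.items()
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_table() -> PhenotypeTable:
    """2 genotypes x 2 treatments x 3 reps x 1 trait (SDW)."""
    vals = {}
    base = {"G1": 100.0, "G2": 160.0}
    for g, mu in base.items():
        for t, shift in (("SP", 0.0), ("LP", -30.0)):
            for r, eps in enumerate((-10.0, 0.0, 10.0), start=1):
                vals[(g, r, t, "SDW")] = mu + shift + eps
    return PhenotypeTable(make_long_frame(vals))


@pytest.fixture(scope="session")
def default_cohort() -> PhenotypeTable:
    """One default 85-genotype synthetic cohort, shared across tests."""
    return simulate_cohort(default_config(seed=1234))


def balanced_table(values: np.ndarray, trait: str = "SDW",
                   treatments=("SP", "LP")) -> PhenotypeTable:
    """Build a balanced table from a (genotype, treatment, rep) array."""
    g, e, r = values.shape
    vals = {}
    for gi in range(g):
        for ti in range(e):
            for ri in range(r):
                vals[(f"G{gi + 1}", ri + 1, treatments[ti], trait)] = \
                    float(values[gi, ti, ri])
    return PhenotypeTable(make_long_frame(vals))
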