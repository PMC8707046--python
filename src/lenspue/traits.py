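"""Trait vocabulary for the root/shoot phosphorus phenotyping pipeline.

The measured trait set is closed: eleven root and shoot architecture /
biomass traits plus the tissue phosphorus concentration channel.  Two
efficiency quantities (P uptake efficiency and P utilization efficiency)
are derived downstream and may appear in genotype-mean tables but never in
replicate-level records.
"""

from __future__ import annotations

# Measured traits: code -> display unit. Units are metadata only; all
# computation treats values as unitless nonnegative reals.
MEASURED_TRAITS: dict[str, str] = {
    "PRL": "cm",        # primary root length
    "TRL": "cm",        # total root length
    "TSA": "cm2",       # total surface area
    "ARD": "mm",        # average root diameter
    "TRV": "cm3",       # total root volume
    "TRT": "count",     # total root tips
    "RF": "count",      # root forks
    "SDW": "mg/plant",  # shoot dry weight
    "RDW": "mg/plant",  # root dry weight
    "TDW": "mg/plant",  # total dry weight = SDW + RDW
    "RSR": "mg/mg",     # root-to-shoot dry weight ratio
    "PCONC": "mg/g",    # tissue P concentration
}

# Derived efficiency quantities (genotype-mean level only).
DERIVED_TRAITS: dict[str, str] = {
    "PUPE": "mg/plant",  # P uptake efficiency = PCONC x dry matter
    "PUTIE": "%",        # P utilization efficiency = 100 x TDW(LP)/TDW(SP)
}

ALL_TRAITS: dict[str, str] = {**MEASURED_TRAITS, **DERIVED_TRAITS}

TREATMENTS = ("SP", "LP")

#: Default alias map for treatment labels: the sufficient-phosphorus arm is
#: written both SP and HP in the field; SP is canonical here.
DEFAULT_TREATMENT_ALIASES: dict[str, str] = {"HP": "SP"}

MATERIAL_CLASSES = ("cultivated", "breeding_line", "wild")

#: The six Lens species of the diversity panel (plus a catch-all).
LENS_SPECIES = (
    "L. culinaris",
    "L. orientalis",
    "L. odemensis",
    "L. ervoides",
    "L. nigricans",
    "L. lamottei",
    "unknown",
)


def display_unit(trait: str) -> str:
    """Return the display unit for a trait code."""
    return ALL_TRAITS[trait]


def is_measured(trait: str) -> bool:
    return trait in MEASURED_TRAITS
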