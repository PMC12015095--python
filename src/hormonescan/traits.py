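"""Sexual size dimorphism and the species-level analysis table.

SSD is the natural log of the male/female body-mass ratio (positive means
males are larger); body size is the arithmetic mean of the two masses.
``build_species_table`` joins per-species traits to per-species HRE counts
and restricts to species present in the phylogeny, adding the
ln-transformed columns the models consume.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: unit conversion factors to kilograms
_MASS_UNITS = {"kg": 1.0, "g": 1e-3}

TRAIT_COLUMNS = ["species", "male_mass", "female_mass"]
COUNT_COLUMNS = ["species", "flank", "are_count", "ere_count", "interrogated_bp"]


def compute_ssd(male_mass: float, female_mass: float) -> float:
    """ln(male/female) body mass; antisymmetric under sex swap."""
    if male_mass <= 0 or female_mass <= 0:
        raise ValueError(
            f"masses must be positive, got male={male_mass}, female={female_mass}"
        )
    return math.log(male_mass) - math.log(female_mass)


def compute_body_size(male_mass: float, female_mass: float, geometric: bool = False) -> float:
    """Average of the two masses (arithmetic by default, geometric optional)."""
    if geometric:
        return math.sqrt(male_mass * female_mass)
    return (male_mass + female_mass) / 2.0


def read_traits(path: str | Path, mass_unit: str = "kg") -> pd.DataFrame:
    """Traits CSV: species, male_mass, female_mass [, order, contig_n50].

    Masses are converted to kilograms.  A ``units`` column, when present,
    overrides ``mass_unit`` per row.
    """
    df = pd.read_csv(path)
    missing = set(TRAIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trait columns {sorted(missing)}")
    if "units" in df.columns:
        factors = df["units"].map(_MASS_UNITS)
        if factors.isna().any():
            bad = sorted(set(df.loc[factors.isna(), "units"]))
            raise ValueError(f"{path}: unknown mass units {bad}")
    else:
        if mass_unit not in _MASS_UNITS:
            raise ValueError(f"unknown mass unit {mass_unit!r}")
        factors = pd.Series(_MASS_UNITS[mass_unit], index=df.index)
    df = df.copy()
    df["male_mass"] = df["male_mass"].astype(float) * factors
    df["female_mass"] = df["female_mass"].astype(float) * factors
    df.drop(columns=["units"], errors="ignore", inplace=True)
    return df


def add_ssd_columns(traits: pd.DataFrame, geometric_body: bool = False) -> pd.DataFrame:
    """Attach ``ssd`` and ``body_size`` computed from the mass columns."""
    out = traits.copy()
    out["ssd"] = [
        compute_ssd(m, f) for m, f in zip(out["male_mass"], out["female_mass"])
    ]
    out["body_size"] = [
        compute_body_size(m, f, geometric=geometric_body)
        for m, f in zip(out["male_mass"], out["female_mass"])
    ]
    return out


def build_species_table(
    traits: pd.DataFrame,
    counts: pd.DataFrame,
    tip_labels: Iterable[str],
) -> pd.DataFrame:
    """Join traits to HRE counts and restrict to species on the tree.

    Adds ``ssd``, ``body_size`` and the ln-transformed model columns
    (``ln_are``, ``ln_ere``, ``ln_body``; ``ln_n50`` when N50 is present).
    Species with a zero count in either class cannot be ln-transformed and
    are dropped with a warning.  Duplicate species or an empty intersection
    raise ``ValueError``.
    """
    for name, df in (("traits", traits), ("counts", counts)):
        if df["species"].duplicated().any():
            dups = sorted(df.loc[df["species"].duplicated(), "species"])
            raise ValueError(f"duplicated species in {name} input: {dups}")
    tips = set(tip_labels)
    table = traits.merge(counts, on="species", how="inner")
    n_joined = len(table)
    logger.info(
        "species join: %d trait rows x %d count rows -> %d shared",
        len(traits), len(counts), n_joined,
    )
    table = table[table["species"].isin(tips)].reset_index(drop=True)
    logger.info("restricted to tree tips: %d -> %d", n_joined, len(table))
    if table.empty:
        raise ValueError("no species shared between traits, counts and tree tips")
    table = add_ssd_columns(table)
    zero = (table["are_count"] <= 0) | (table["ere_count"] <= 0)
    if zero.any():
        logger.warning(
            "dropping %d species with zero HRE counts (ln-transform undefined): %s",
            int(zero.sum()), sorted(table.loc[zero, "species"]),
        )
        table = table[~zero].reset_index(drop=True)
    table["ln_are"] = np.log(table["are_count"].astype(float))
    table["ln_ere"] = np.log(table["ere_count"].astype(float))
    table["ln_body"] = np.log(table["body_size"].astype(float))
    if "contig_n50" in table.columns:
        table["ln_n50"] = np.log(table["contig_n50"].astype(float))
    return table
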