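"""Sexual size dimorphism index and selection-regime coding.

The size dimorphism index (SDI) quantifies sexual size dimorphism as a
signed percentage::

    SDI = +/- (S_L / S_S - 1) * 100

where ``S_L`` and ``S_S`` are the mean body masses of the larger and the
smaller sex.  The sign is positive when males are larger, negative when
females are larger, and SDI = 0 marks monomorphism.  SDI is stored and
modelled in percent throughout the package, so all OU optima are in percent
as well.

Species are coded on two categorical axes: social system (a proxy for the
strength of sexual selection) and diet (a proxy for niche divergence).  For
multi-optima OU modelling the 4 x 5 cross of categories is collapsed to six
combined regimes: {solitary, group} x {carnivory, omnivory, other}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SOCIAL_SYSTEMS",
    "DIETS",
    "COMBINED_REGIMES",
    "SpeciesRecord",
    "TraitTable",
    "compute_sdi",
    "assign_combined_regime",
    "load_trait_table",
    "TraitTableError",
]

SOCIAL_SYSTEMS = (
    "territorial_solitary",
    "pair_living",
    "group_living",
    "variable",
)

DIETS = (
    "carnivory",
    "omnivory",
    "insectivory",
    "herbivory",
    "aquatic_carnivory",
)

#: collapsed social classes
_SOCIAL_COLLAPSE = {
    "territorial_solitary": "solitary",
    "pair_living": "group",
    "group_living": "group",
    "variable": "group",
}

#: collapsed diet classes
_DIET_COLLAPSE = {
    "carnivory": "carnivory",
    "omnivory": "omnivory",
    "insectivory": "other",
    "herbivory": "other",
    "aquatic_carnivory": "other",
}

COMBINED_REGIMES = (
    "solitary_carnivory",
    "solitary_omnivory",
    "solitary_other",
    "group_carnivory",
    "group_omnivory",
    "group_other",
)

REQUIRED_COLUMNS = ("species", "male_mass_g", "female_mass_g", "social_system", "diet")


class TraitTableError(ValueError):
    """Raised when a trait table fails validation; carries per-row messages."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("trait table validation failed:\n  " + "\n  ".join(self.errors))


def compute_sdi(male_mass: float, female_mass: float) -> float:
    """Signed size dimorphism index in percent.

    Positive when males are larger, negative when females are larger, zero
    for monomorphic species.  Both masses must be strictly positive grams.
    """
    if not (male_mass > 0 and female_mass > 0):
        raise ValueError(
            f"masses must be strictly positive, got male={male_mass}, female={female_mass}"
        )
    if not (math.isfinite(male_mass) and math.isfinite(female_mass)):
        raise ValueError("masses must be finite")
    if male_mass == female_mass:
        return 0.0
    s_l, s_s = max(male_mass, female_mass), min(male_mass, female_mass)
    mag = (s_l / s_s - 1.0) * 100.0
    return mag if male_mass > female_mass else -mag


def assign_combined_regime(social: str, diet: str) -> str:
    """Collapse (social system, diet) to one of the six combined regimes.

    Social systems collapse to solitary vs. group (pair-living and variable
    groups are pooled with group-living); diets collapse to carnivory,
    omnivory, and a pooled "other" (insectivory, herbivory, aquatic
    carnivory).
    """
    if social not in _SOCIAL_COLLAPSE:
        raise ValueError(
            f"unknown social system {social!r}; allowed: {list(SOCIAL_SYSTEMS)}"
        )
    if diet not in _DIET_COLLAPSE:
        raise ValueError(f"unknown diet {diet!r}; allowed: {list(DIETS)}")
    return f"{_SOCIAL_COLLAPSE[social]}_{_DIET_COLLAPSE[diet]}"


@dataclass(frozen=True)
class SpeciesRecord:
    """One species' masses and ecological categories."""

    species: str
    male_mass_g: float
    female_mass_g: float
    social_system: str
    diet: str

    def __post_init__(self):
        if not (self.male_mass_g > 0 and math.isfinite(self.male_mass_g)):
            raise ValueError(f"{self.species}: male mass must be positive and finite")
        if not (self.female_mass_g > 0 and math.isfinite(self.female_mass_g)):
            raise ValueError(f"{self.species}: female mass must be positive and finite")
        if self.social_system not in SOCIAL_SYSTEMS:
            raise ValueError(
                f"{self.species}: unknown social system {self.social_system!r}"
            )
        if self.diet not in DIETS:
            raise ValueError(f"{self.species}: unknown diet {self.diet!r}")

    @property
    def sdi(self) -> float:
        return compute_sdi(self.male_mass_g, self.female_mass_g)

    @property
    def combined_regime(self) -> str:
        return assign_combined_regime(self.social_system, self.diet)


class TraitTable:
    """Validated per-species trait table with derived SDI and combined regime.

    Thin wrapper around a pandas DataFrame; access the frame via ``.df``.
    """

    def __init__(self, records):
        recs = list(records)
        seen = set()
        dupes = []
        for r in recs:
            if r.species in seen:
                dupes.append(r.species)
            seen.add(r.species)
        if dupes:
            raise TraitTableError([f"duplicate species: {s}" for s in sorted(set(dupes))])
        if not recs:
            raise TraitTableError(["trait table is empty"])
        self.records = recs
        self.df = pd.DataFrame(
            {
                "species": [r.species for r in recs],
                "male_mass_g": [r.male_mass_g for r in recs],
                "female_mass_g": [r.female_mass_g for r in recs],
                "social_system": [r.social_system for r in recs],
                "diet": [r.diet for r in recs],
                "sdi_percent": [r.sdi for r in recs],
                "combined_regime": [r.combined_regime for r in recs],
            }
        )

    def __len__(self):
        return len(self.records)

    @property
    def species(self):
        return list(self.df["species"])

    def sdi_vector(self, order=None) -> np.ndarray:
        """SDI values, optionally in a caller-supplied species order."""
        if order is None:
            return self.df["sdi_percent"].to_numpy()
        s = self.df.set_index("species")["sdi_percent"]
        return s.loc[list(order)].to_numpy()

    def states(self, column: str, order=None) -> dict:
        """Mapping species -> category for one of the categorical columns."""
        s = self.df.set_index("species")[column]
        if order is not None:
            s = s.loc[list(order)]
        return dict(s)

    def log_masses(self, order=None):
        """(ln female mass, ln male mass) arrays, optionally reordered."""
        df = self.df.set_index("species")
        if order is not None:
            df = df.loc[list(order)]
        return np.log(df["female_mass_g"].to_numpy()), np.log(df["male_mass_g"].to_numpy())

    def to_csv(self, path):
        """Write the analysis table (input columns + sdi_percent + combined_regime)."""
        self.df.to_csv(path, index=False)

    def __repr__(self):
        return f"<TraitTable {len(self)} species>"


def load_trait_table(path_or_df) -> TraitTable:
    """Load and validate a species trait table from CSV/TSV (or a DataFrame).

    The delimiter is sniffed from the extension (``.tsv`` -> tab, otherwise
    comma).  All row-level problems (non-positive or unparseable masses,
    unknown categories) are collected and reported together.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        sep = "\t" if str(path_or_df).endswith((".tsv", ".tab")) else ","
        df = pd.read_csv(path_or_df, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TraitTableError([f"missing required column: {c}" for c in missing])
    errors = []
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                SpeciesRecord(
                    species=str(row["species"]).strip(),
                    male_mass_g=float(row["male_mass_g"]),
                    female_mass_g=float(row["female_mass_g"]),
                    social_system=str(row["social_system"]).strip(),
                    diet=str(row["diet"]).strip(),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i} ({row.get('species', '?')}): {exc}")
    if errors:
        raise TraitTableError(errors)
    return TraitTable(records)
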