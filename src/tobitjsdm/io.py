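"""Survey-table reading/writing and the species inclusion filters.

The on-disk format is a plain CSV with one row per tow: identifier
columns (tow, lat, lon, year, season, stratum), environmental covariates
and one CPUE (kg/tow) column per species.  The synthetic generator emits
exactly this schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("tobitjsdm")

__all__ = ["FilterRule", "read_survey_csv", "write_survey_csv", "filter_species", "SurveyFormatError"]

ID_COLUMNS = ("tow", "lat", "lon", "year", "season", "stratum")


class SurveyFormatError(ValueError):
    """Raised for malformed survey CSV files."""


@dataclass(frozen=True)
class FilterRule:
    """Species inclusion rule for CPUE tables.

    Keep a species iff it is present (CPUE > 0) in at least
    ``min_presence_tows`` tows *and* has CPUE ≥ ``min_biomass`` kg/tow in
    strictly more than ``min_biomass_tows`` tows.  The production rule is
    (400, 0.5 kg/tow, 100).
    """

    min_presence_tows: int = 400
    min_biomass: float = 0.5
    min_biomass_tows: int = 100

    def __post_init__(self):
        if self.min_presence_tows < 0 or self.min_biomass < 0 or self.min_biomass_tows < 0:
            raise ValueError("filter thresholds must be nonnegative")


def read_survey_csv(path, covariates, species) -> pd.DataFrame:
    """Read and validate a survey table.

    Rows with missing covariate values are dropped (the count is
    logged).  Species columns must be numeric and nonnegative.
    """
    table = pd.read_csv(path)
    missing = [c for c in list(covariates) + list(species) if c not in table.columns]
    if missing:
        raise SurveyFormatError(f"missing required column(s): {missing}")
    for sp in species:
        col = pd.to_numeric(table[sp], errors="coerce")
        bad = np.where(col.isna() & table[sp].notna())[0]
        if bad.size:
            raise SurveyFormatError(
                f"non-numeric CPUE in column {sp!r} at row index {int(bad[0])}"
            )
        if (col.dropna() < 0).any():
            row = int(np.where(col < 0)[0][0])
            raise SurveyFormatError(f"negative CPUE in column {sp!r} at row index {row}")
        table[sp] = col
    before = len(table)
    mask = table[list(covariates)].notna().all(axis=1) & table[list(species)].notna().all(axis=1)
    table = table.loc[mask].reset_index(drop=True)
    dropped = before - len(table)
    if dropped:
        logger.info("dropped %d row(s) with missing covariate or CPUE values", dropped)
    return table


def write_survey_csv(table: pd.DataFrame, path):
    table.to_csv(path, index=False)


def filter_species(table: pd.DataFrame, species, rule: FilterRule = FilterRule()):
    """Apply the inclusion rule to a CPUE table.

    Returns (kept species names, per-species report DataFrame with the
    presence and biomass tow counts and the keep flag).
    """
    rows = []
    kept = []
    for sp in species:
        y = np.asarray(table[sp], dtype=float)
        presence = int(np.sum(y > 0))
        biomass = int(np.sum(y >= rule.min_biomass))
        keep = presence >= rule.min_presence_tows and biomass > rule.min_biomass_tows
        if keep:
            kept.append(sp)
        rows.append({"species": sp, "presence_tows": presence,
                     "biomass_tows": biomass, "kept": keep})
    return kept, pd.DataFrame(rows)
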