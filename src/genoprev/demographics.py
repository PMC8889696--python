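"""Country-level inputs: population, ancestry mixture, consanguinity rate."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .catalog import _open_rows
from .frequencies import ANALYSIS_GROUPS

__all__ = ["CountryDemographics", "load_country_table", "country_carrier_frequency"]

_WEIGHT_TOL = 1e-6


@dataclass(frozen=True)
class CountryDemographics:
    """Demographic inputs for one country.

    ``weights`` maps the four analysis ancestry groups (NFE, AFR, AMR, ASIAN)
    to population fractions summing to 1.  ``consanguinity_rate`` is the
    fraction of unions between first cousins or closer.  Life expectancies
    (years) drive the birth-to-population prevalence conversion: affected
    individuals live ``disease_life_expectancy`` years in a population whose
    turnover time is ``background_life_expectancy`` years.
    """

    country: str
    population: int
    weights: Mapping[str, float] = field(default_factory=dict)
    consanguinity_rate: float = 0.0
    disease_life_expectancy: float = 40.0
    background_life_expectancy: float = 80.0
    note: str = ""

    def __post_init__(self) -> None:
        if not self.country:
            raise ValueError("country name must be nonempty")
        if self.population < 0:
            raise ValueError(f"{self.country}: population must be >= 0")
        unknown = set(self.weights) - set(ANALYSIS_GROUPS)
        if unknown:
            raise ValueError(f"{self.country}: unknown weight groups {sorted(unknown)}")
        total = sum(self.weights.values())
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise ValueError(
                f"{self.country}: ancestry weights sum to {total}, expected 1 +/- {_WEIGHT_TOL}"
            )
        if any(w < 0 for w in self.weights.values()):
            raise ValueError(f"{self.country}: weights must be non-negative")
        if not (0 <= self.consanguinity_rate <= 1):
            raise ValueError(
                f"{self.country}: consanguinity rate {self.consanguinity_rate} not in [0, 1]"
            )
        if not (0 < self.disease_life_expectancy <= self.background_life_expectancy):
            raise ValueError(
                f"{self.country}: need 0 < disease life expectancy <= background"
            )


def load_country_table(path: str | Path) -> list[CountryDemographics]:
    """Read a country demographics CSV.

    Expected header: country, population, w_nfe, w_afr, w_amr, w_asian,
    consanguinity (an optional trailing ``note`` column is carried through).
    Populations are persons; a ``# population_units: thousands`` comment flag
    rescales them.  Duplicate countries and invalid weight vectors are
    rejected naming the country.
    """
    scale = 1
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") and "population_units:" in line:
                unit = line.split("population_units:")[1].strip()
                if unit == "thousands":
                    scale = 1000
                elif unit not in ("persons", "1"):
                    raise ValueError(f"{path}: unknown population_units {unit!r}")
    rows = list(_open_rows(path))
    if not rows:
        return []
    header = rows[0][1]
    expected = ["country", "population", "w_nfe", "w_afr", "w_amr", "w_asian", "consanguinity"]
    if header[: len(expected)] != expected:
        raise ValueError(f"{path}: expected header starting {expected}, got {header}")
    has_note = len(header) > len(expected) and header[len(expected)] == "note"
    out: list[CountryDemographics] = []
    seen: set[str] = set()
    for lineno, row in rows[1:]:
        country = row[0]
        if country in seen:
            raise ValueError(f"{path} row {lineno + 1}: duplicate country {country!r}")
        seen.add(country)
        try:
            weights = {
                "NFE": float(row[2]),
                "AFR": float(row[3]),
                "AMR": float(row[4]),
                "ASIAN": float(row[5]),
            }
            rec = CountryDemographics(
                country=country,
                population=round(float(row[1]) * scale),
                weights=weights,
                consanguinity_rate=float(row[6]),
                note=row[len(expected)] if has_note and len(row) > len(expected) else "",
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path} row {lineno + 1}: {exc}") from exc
        out.append(rec)
    return out


def country_carrier_frequency(
    weights: Mapping[str, float], group_frequencies: Mapping[str, float]
) -> float:
    """Mix per-group carrier frequencies by a country's ancestry weights.

    Returns the convex combination ``sum_g w_g * f_g``; every group with a
    nonzero weight must have a frequency.  The result necessarily lies
    between the smallest and largest group frequency.
    """
    f = 0.0
    # sorted iteration makes the floating-point sum independent of dict order
    for group, w in sorted(weights.items()):
        if w == 0:
            continue
        if group not in group_frequencies:
            raise ValueError(f"missing carrier frequency for weighted group {group!r}")
        f += w * group_frequencies[group]
    return f
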