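"""Packaged fixture loaders.

The package ships small plain-text fixtures for the worked ARG1-deficiency
instance: a synthetic case database whose marginal allele counts reproduce
the published tally, the ancestry-stratified allele-frequency table (with
synthetic denominators, since the source allele numbers are unpublished),
back-derived country demographics, and the published per-country reference
estimates used for cross-checks.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .catalog import CaseRecord, VariantRecord, load_case_table, load_variant_catalog
from .demographics import CountryDemographics, load_country_table
from .frequencies import GroupAlleleFrequency, load_frequency_table

__all__ = [
    "fixture_path",
    "load_case_fixture",
    "load_catalog_fixture",
    "load_frequency_fixture",
    "load_country_fixture",
    "load_reference_tables",
]

_FILES = {
    "cases": "cases_synthetic.csv",
    "catalog": "variant_catalog_synthetic.csv",
    "frequencies": "allele_frequencies_synthetic_denominators.tsv",
    "countries": "country_demographics_synthetic.csv",
    "reference": "country_reference_estimates.csv",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture (keys: cases, catalog,
    frequencies, countries, reference)."""
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FILES)}")
    return Path(str(resources.files("genoprev.data").joinpath(_FILES[name])))


def load_case_fixture() -> list[CaseRecord]:
    """114 synthetic biallelic cases reproducing the published allele tally."""
    return load_case_table(fixture_path("cases"))


def load_catalog_fixture() -> list[VariantRecord]:
    """62 catalogued variants, 28 of them frequency-annotated."""
    return load_variant_catalog(fixture_path("catalog"))


def load_frequency_fixture() -> list[GroupAlleleFrequency]:
    """Per-variant, per-group allele frequencies (synthetic denominators)."""
    return load_frequency_table(fixture_path("frequencies"))


def load_country_fixture() -> list[CountryDemographics]:
    """38 countries with back-derived ancestry weights and consanguinity rates."""
    return load_country_table(fixture_path("countries"))


def reference_estimates():
    """Published per-country values as estimate objects, for aggregation.

    Expected case counts are recomputed as population prevalence x population
    (ties away from zero); prevalences are converted from per-million back to
    raw probabilities.  Returns ``(estimates, populations)`` ready for
    :func:`genoprev.prevalence.aggregate_global`.
    """
    from .prevalence import PrevalenceEstimate, expected_cases

    df = load_reference_tables()
    estimates = []
    populations = {}
    for row in df.itertuples(index=False):
        pop = row.population_thousands * 1000.0
        pop_prev = row.population_prevalence_per_million / 1e6
        estimates.append(
            PrevalenceEstimate(
                country=row.country,
                carrier_frequency=row.carrier_frequency,
                baseline_birth_prevalence=row.baseline_per_million / 1e6,
                adjusted_birth_prevalence=row.adjusted_per_million / 1e6,
                ci_low=row.adjusted_ci_low / 1e6,
                ci_high=row.adjusted_ci_high / 1e6,
                population_prevalence=pop_prev,
                expected_cases=expected_cases(pop_prev, pop),
            )
        )
        populations[row.country] = pop
    return estimates, populations


def load_reference_tables() -> pd.DataFrame:
    """Published per-country estimates at printed precision.

    Columns: country, carrier_frequency, baseline_per_million,
    adjusted_per_million, adjusted_ci_low, adjusted_ci_high,
    population_thousands, cases, population_prevalence_per_million.
    """
    return pd.read_csv(fixture_path("reference"), comment="#")
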