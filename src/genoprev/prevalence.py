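"""Core prevalence arithmetic for an autosomal recessive disease.

Under Hardy-Weinberg equilibrium an affected birth requires two pathogenic
alleles, so the baseline birth prevalence is the squared carrier frequency,
``p = f**2``.  Consanguineous unions violate random mating: offspring of
first cousins are autozygous at a locus with probability F = 1/16, raising
their disease risk to ``q/16 + 15*q**2/16`` where ``q = sqrt(p)``.  Weighting
by the fraction ``c`` of first-cousin-or-closer unions gives the adjusted
birth prevalence

    p_adj = (1 - c) * p + c * (sqrt(p)/16 + 15*p/16)

Population prevalence follows from a stationary-population argument: cases
accumulate for the disease life expectancy (default 40 y) within a population
turning over every background life expectancy (default 80 y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

__all__ = [
    "PrevalenceEstimate",
    "GlobalSummary",
    "hwe_birth_prevalence",
    "consanguinity_adjust",
    "population_prevalence",
    "expected_cases",
    "propagate_ci",
    "aggregate_global",
    "round_half_away",
]

EquationMode = Literal["repaired", "as_printed"]


def round_half_away(x: float) -> int:
    """Round to the nearest integer with ties away from zero (not banker's)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def hwe_birth_prevalence(f: float) -> float:
    """Baseline birth prevalence under Hardy-Weinberg: f squared."""
    if not (0 <= f <= 1):
        raise ValueError(f"carrier frequency must be in [0, 1], got {f}")
    return f * f


def consanguinity_adjust(
    p: float, c: float, mode: EquationMode = "repaired"
) -> float:
    """Adjust a baseline birth prevalence for consanguineous unions.

    The ``repaired`` form is ``(1-c)p + c(sqrt(p)/16 + 15p/16)``, i.e. the
    standard inbreeding result ``F q + (1-F) q**2`` with F = 1/16 and
    q = sqrt(p), mixed over the consanguineous fraction ``c``.  It satisfies
    ``p_adj >= p`` for all p <= 1 and collapses to ``p`` at c = 0.

    ``mode="as_printed"`` evaluates ``(1-c)p + c(sqrt(c)/16 + 15c/16)``,
    reading the consanguineous-risk term with the mixing fraction under the
    radical.  It is provided for comparison only and is not recommended: it
    is discontinuous in its interpretation of the risk term and does not
    reduce to an inbreeding model.
    """
    if not (0 <= p <= 1):
        raise ValueError(f"birth prevalence must be in [0, 1], got {p}")
    if not (0 <= c <= 1):
        raise ValueError(f"consanguinity rate must be in [0, 1], got {c}")
    if mode == "repaired":
        risk = math.sqrt(p) / 16 + 15 * p / 16
    elif mode == "as_printed":
        risk = math.sqrt(c) / 16 + 15 * c / 16
    else:
        raise ValueError(f"unknown equation mode {mode!r}")
    return (1 - c) * p + c * risk


def population_prevalence(
    p_adj: float, disease_life_expectancy: float = 40.0, background_life_expectancy: float = 80.0
) -> float:
    """Convert adjusted birth prevalence to point population prevalence.

    Stationary-population conversion: multiply by the ratio of the disease
    life expectancy to the population turnover time (L_disease / L_background,
    default 40/80 = 0.5).
    """
    if disease_life_expectancy <= 0 or background_life_expectancy <= 0:
        raise ValueError("life expectancies must be positive")
    if disease_life_expectancy > background_life_expectancy:
        raise ValueError("disease life expectancy cannot exceed background")
    return p_adj * disease_life_expectancy / background_life_expectancy


def expected_cases(prev: float, population: float) -> int:
    """Expected living case count: prevalence x population, ties away from zero."""
    if population < 0:
        raise ValueError(f"population must be >= 0, got {population}")
    return round_half_away(prev * population)


def propagate_ci(
    f_lo: float,
    f_hi: float,
    c: float,
    disease_life_expectancy: float = 40.0,
    background_life_expectancy: float = 80.0,
    mode: EquationMode = "repaired",
) -> dict[str, tuple[float, float]]:
    """Push a carrier-frequency interval through the whole pipeline.

    Squaring, the consanguinity map and the life-expectancy scaling are all
    monotone increasing on [0, 1], so interval endpoints map to interval
    endpoints; no re-sampling is needed.  Returns intervals for the baseline
    birth prevalence, the adjusted birth prevalence and the population
    prevalence.
    """
    if not (0 <= f_lo <= f_hi <= 1):
        raise ValueError(f"need 0 <= f_lo <= f_hi <= 1, got ({f_lo}, {f_hi})")
    out: dict[str, tuple[float, float]] = {}
    p = (hwe_birth_prevalence(f_lo), hwe_birth_prevalence(f_hi))
    out["baseline"] = p
    p_adj = tuple(consanguinity_adjust(x, c, mode) for x in p)
    out["adjusted"] = p_adj  # type: ignore[assignment]
    out["population"] = tuple(
        population_prevalence(x, disease_life_expectancy, background_life_expectancy)
        for x in p_adj
    )  # type: ignore[assignment]
    return out


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Per-country estimates (all prevalences as raw probabilities)."""

    country: str
    carrier_frequency: float
    baseline_birth_prevalence: float
    adjusted_birth_prevalence: float
    ci_low: float
    ci_high: float
    population_prevalence: float
    expected_cases: int

    def __post_init__(self) -> None:
        if self.expected_cases < 0:
            raise ValueError("expected_cases must be >= 0")


@dataclass(frozen=True)
class GlobalSummary:
    """Aggregate over all analysed countries.

    ``global_birth_prevalence`` is the population-weighted mean of the
    per-country adjusted birth prevalences (raw probability);
    ``overall_population_prevalence`` is total cases over total population.
    The ``one_in_n`` reciprocals are rounded to the nearest thousand.
    """

    total_population: int
    total_cases: int
    global_birth_prevalence: float
    overall_population_prevalence: float
    one_in_n_population: int
    one_in_n_births: int


def aggregate_global(
    estimates: Sequence[PrevalenceEstimate],
    populations: Mapping[str, float],
) -> GlobalSummary:
    """Aggregate per-country estimates into headline global figures.

    ``populations`` maps country name to persons; its key set must match the
    estimates exactly (the mismatch error lists the difference).
    """
    est_countries = {e.country for e in estimates}
    if est_countries != set(populations):
        missing = sorted(est_countries ^ set(populations))
        raise ValueError(f"country sets differ between estimates and populations: {missing}")
    if not estimates:
        raise ValueError("no estimates to aggregate")
    total_pop = sum(populations.values())
    total_cases = sum(e.expected_cases for e in estimates)
    gbp = sum(e.adjusted_birth_prevalence * populations[e.country] for e in estimates) / total_pop
    opp = total_cases / total_pop if total_pop else 0.0
    return GlobalSummary(
        total_population=round(total_pop),
        total_cases=total_cases,
        global_birth_prevalence=gbp,
        overall_population_prevalence=opp,
        one_in_n_population=_round_thousand(1 / opp) if opp else 0,
        one_in_n_births=_round_thousand(1 / gbp) if gbp else 0,
    )


def _round_thousand(x: float) -> int:
    return round_half_away(x / 1000) * 1000
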