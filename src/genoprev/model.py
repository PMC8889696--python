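"""Model/Results interface tying the pipeline together.

``PrevalenceModel`` holds the three inputs (case database, ancestry-stratified
allele frequencies, country demographics) plus analysis options; ``fit()``
runs tally -> group carrier frequencies -> country mixing -> Hardy-Weinberg
-> consanguinity adjustment -> population prevalence -> global aggregation
and returns a ``PrevalenceResults`` carrying the estimate tables, confidence
intervals and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import catalog as cat
from . import frequencies as freq
from . import prevalence as prev
from .demographics import CountryDemographics, country_carrier_frequency

__all__ = ["PrevalenceModel", "PrevalenceResults"]

PER_MILLION = 1e6


class PrevalenceModel:
    """Genetic-database prevalence model for an autosomal recessive disease.

    Parameters
    ----------
    cases : sequence of CaseRecord
        Deduplicated diagnosed cases, two allele slots each.
    frequencies : sequence of GroupAlleleFrequency
        Per-variant, per-ancestry allele frequencies (EAS/SAS unpooled or
        pre-pooled; pooling is applied internally and is idempotent).
    demographics : sequence of CountryDemographics
        Countries to estimate, with ancestry weights and consanguinity rates.
    variant_catalog : sequence of VariantRecord, optional
        Needed only for annotation coverage (and hence ``coverage_adjust``).
    rare_threshold : int
        Variants with fewer case alleles are pooled into OTHER for reporting.
    alpha : float
        Two-sided miscoverage for the exact binomial intervals.
    coverage_adjust : bool
        Divide group carrier frequencies by the annotated-allele coverage to
        extrapolate over unannotated alleles.  Off by default: the group
        totals of the packaged fixture are treated as final.
    equation_mode : {"repaired", "as_printed"}
        Form of the consanguinity adjustment (see ``consanguinity_adjust``).
    """

    def __init__(
        self,
        cases: Sequence[cat.CaseRecord],
        frequencies: Sequence[freq.GroupAlleleFrequency],
        demographics: Sequence[CountryDemographics],
        *,
        variant_catalog: Sequence[cat.VariantRecord] | None = None,
        rare_threshold: int = 5,
        alpha: float = 0.05,
        coverage_adjust: bool = False,
        equation_mode: prev.EquationMode = "repaired",
    ) -> None:
        self.cases = list(cases)
        self.frequencies = list(frequencies)
        self.demographics = list(demographics)
        self.variant_catalog = list(variant_catalog) if variant_catalog else None
        self.rare_threshold = rare_threshold
        self.alpha = alpha
        self.coverage_adjust = coverage_adjust
        self.equation_mode: prev.EquationMode = equation_mode
        if coverage_adjust and not self.variant_catalog:
            raise ValueError("coverage_adjust requires a variant_catalog")

    @classmethod
    def from_csv(
        cls,
        cases_path: str | Path,
        frequencies_path: str | Path,
        countries_path: str | Path,
        catalog_path: str | Path | None = None,
        **kwargs,
    ) -> "PrevalenceModel":
        """Build a model from the three input files (plus optional catalog)."""
        from .catalog import load_case_table, load_variant_catalog
        from .demographics import load_country_table
        from .frequencies import load_frequency_table

        return cls(
            load_case_table(cases_path),
            load_frequency_table(frequencies_path),
            load_country_table(countries_path),
            variant_catalog=load_variant_catalog(catalog_path) if catalog_path else None,
            **kwargs,
        )

    def fit(self) -> "PrevalenceResults":
        """Run the full estimation pipeline."""
        tally = cat.tally_alleles(self.cases)
        collapsed = cat.collapse_rare(tally, self.rare_threshold)

        coverage = None
        if self.variant_catalog is not None and tally.total_alleles:
            annotated = {v.variant_id for v in self.variant_catalog if v.annotated}
            coverage = cat.annotation_coverage(tally, annotated)

        pooled = freq.pool_asian(self.frequencies)
        pathogenic_ids = {r.variant_id for r in pooled}
        group_cf: dict[str, freq.GroupCarrierFrequency] = {}
        for group in freq.ANALYSIS_GROUPS:
            gcf = freq.sum_carrier_frequency(pooled, group, pathogenic_ids, self.alpha)
            if self.coverage_adjust and coverage:
                gcf = freq.adjust_for_unknown(gcf, coverage)
            group_cf[group] = gcf

        f_by_group = {g: gcf.f for g, gcf in group_cf.items()}
        lo_by_group = {g: gcf.ci_low for g, gcf in group_cf.items()}
        hi_by_group = {g: gcf.ci_high for g, gcf in group_cf.items()}

        estimates: list[prev.PrevalenceEstimate] = []
        populations: dict[str, float] = {}
        for dem in self.demographics:
            f = country_carrier_frequency(dem.weights, f_by_group)
            f_lo = country_carrier_frequency(dem.weights, lo_by_group)
            f_hi = country_carrier_frequency(dem.weights, hi_by_group)
            p = prev.hwe_birth_prevalence(f)
            p_adj = prev.consanguinity_adjust(p, dem.consanguinity_rate, self.equation_mode)
            ci = prev.propagate_ci(
                f_lo,
                f_hi,
                dem.consanguinity_rate,
                dem.disease_life_expectancy,
                dem.background_life_expectancy,
                self.equation_mode,
            )
            pop_prev = prev.population_prevalence(
                p_adj, dem.disease_life_expectancy, dem.background_life_expectancy
            )
            estimates.append(
                prev.PrevalenceEstimate(
                    country=dem.country,
                    carrier_frequency=f,
                    baseline_birth_prevalence=p,
                    adjusted_birth_prevalence=p_adj,
                    ci_low=ci["adjusted"][0],
                    ci_high=ci["adjusted"][1],
                    population_prevalence=pop_prev,
                    expected_cases=prev.expected_cases(pop_prev, dem.population),
                )
            )
            populations[dem.country] = dem.population

        summary = (
            prev.aggregate_global(estimates, populations) if estimates else None
        )
        return PrevalenceResults(
            model=self,
            tally=tally,
            collapsed_tally=collapsed,
            coverage=coverage,
            group_carrier_frequencies=group_cf,
            estimates=estimates,
            global_summary=summary,
        )


@dataclass
class PrevalenceResults:
    """Fitted estimates, intervals and report tables."""

    model: PrevalenceModel
    tally: cat.AlleleTally
    collapsed_tally: cat.AlleleTally
    coverage: float | None
    group_carrier_frequencies: dict[str, freq.GroupCarrierFrequency]
    estimates: list[prev.PrevalenceEstimate]
    global_summary: prev.GlobalSummary | None

    def variant_table(self) -> pd.DataFrame:
        """Per-variant allele counts with per-group frequencies and a Total row."""
        pooled = freq.pool_asian(self.model.frequencies)
        by_vg = {(r.variant_id, r.group): r.frequency for r in pooled}
        rows = []
        counts = self.collapsed_tally.known_counts
        order = sorted(counts, key=lambda v: (v == cat.OTHER, -counts[v], v))
        for vid in order:
            row = {"variant_id": vid, "allele_count": counts[vid]}
            for g in freq.ANALYSIS_GROUPS:
                row[f"af_{g.lower()}"] = by_vg.get((vid, g), float("nan"))
            rows.append(row)
        total = {"variant_id": "Total", "allele_count": self.collapsed_tally.total_alleles}
        for g in freq.ANALYSIS_GROUPS:
            total[f"af_{g.lower()}"] = self.group_carrier_frequencies[g].f
        rows.append(total)
        return pd.DataFrame(rows)

    def country_table(self) -> pd.DataFrame:
        """Per-country carrier frequency and birth prevalence (per million)."""
        rows = []
        for e in self.estimates:
            rows.append(
                {
                    "country": e.country,
                    "carrier_frequency": e.carrier_frequency,
                    "baseline_per_million": e.baseline_birth_prevalence * PER_MILLION,
                    "adjusted_per_million": e.adjusted_birth_prevalence * PER_MILLION,
                    "adjusted_ci_low": e.ci_low * PER_MILLION,
                    "adjusted_ci_high": e.ci_high * PER_MILLION,
                }
            )
        return pd.DataFrame(rows)

    def population_table(self) -> pd.DataFrame:
        """Per-country case counts and population prevalence, with Total row."""
        pops = {d.country: d.population for d in self.model.demographics}
        rows = []
        for e in self.estimates:
            rows.append(
                {
                    "country": e.country,
                    "population_thousands": pops[e.country] / 1000,
                    "cases": e.expected_cases,
                    "population_prevalence_per_million": e.population_prevalence * PER_MILLION,
                }
            )
        if self.global_summary:
            gs = self.global_summary
            rows.append(
                {
                    "country": f"Total ({len(self.estimates)} countries)",
                    "population_thousands": gs.total_population / 1000,
                    "cases": gs.total_cases,
                    "population_prevalence_per_million": gs.overall_population_prevalence
                    * PER_MILLION,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report of group frequencies and global figures."""
        lines = ["Autosomal recessive prevalence estimates", "=" * 44]
        lines.append(
            f"Cases: {self.tally.n_cases}  alleles: {self.tally.total_alleles}"
            + (f"  annotation coverage: {self.coverage:.1%}" if self.coverage is not None else "")
        )
        lines.append("")
        lines.append("Group carrier frequencies (summed pathogenic allele frequencies):")
        for g, gcf in self.group_carrier_frequencies.items():
            flag = " [missing]" if gcf.missing else ""
            adj = " [coverage-adjusted]" if gcf.coverage_adjusted else ""
            lines.append(
                f"  {g:<6} f={gcf.f:.6f}  95% CI ({gcf.ci_low:.6f}, {gcf.ci_high:.6f})"
                f"  birth prevalence {gcf.f ** 2 * PER_MILLION:.2f}/million{flag}{adj}"
            )
        if self.global_summary:
            gs = self.global_summary
            lines.append("")
            lines.append(f"Countries analysed: {len(self.estimates)}")
            lines.append(f"Total population: {gs.total_population:,}")
            lines.append(f"Estimated cases: {gs.total_cases}")
            lines.append(
                f"Global birth prevalence: {gs.global_birth_prevalence * PER_MILLION:.1f}"
                f" per million live births (~1/{gs.one_in_n_births:,} births)"
            )
            lines.append(
                f"Overall population prevalence: "
                f"{gs.overall_population_prevalence * PER_MILLION:.2f} per million"
                f" (~1/{gs.one_in_n_population:,} people)"
            )
        return "\n".join(lines)

    def save_tables(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the three report CSVs; returns the written paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "variants": out / "variant_frequencies.csv",
            "countries": out / "country_birth_prevalence.csv",
            "population": out / "country_population_prevalence.csv",
        }
        self.variant_table().to_csv(paths["variants"], index=False)
        self.country_table().to_csv(paths["countries"], index=False)
        self.population_table().to_csv(paths["population"], index=False)
        return paths
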