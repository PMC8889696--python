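"""Synthetic-data generators and the pedigree Monte-Carlo oracle.

Three generators emulate the statistical structure the analysis assumes:

* group allele counts drawn ``k ~ Binomial(n_g, q_vg)`` per (variant, group),
  as a sequencing database would observe them;
* affected-conditional case genotypes, two pathogenic alleles per case drawn
  independently from the normalised pathogenic-frequency vector (compound
  heterozygotes arise naturally), with optional masking of slots to UNKNOWN;
* an explicit first-cousin pedigree simulation that drops grandparental
  alleles through the family — it never injects F = 1/16 directly, so it is
  an independent oracle for the closed-form consanguinity adjustment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .catalog import UNKNOWN, CaseRecord
from .frequencies import GroupAlleleFrequency

__all__ = [
    "SyntheticConfig",
    "generate_frequency_table",
    "generate_case_database",
    "simulate_consanguineous_cohort",
    "first_cousin_autozygosity",
    "write_frequency_table",
    "write_case_table",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters for synthetic pipeline inputs.

    ``true_frequencies`` maps (variant_id, group) to the true allele
    frequency; ``allele_numbers`` gives each group's sequenced chromosome
    count.  ``unknown_fraction`` of case allele slots are masked to UNKNOWN.
    """

    true_frequencies: Mapping[tuple[str, str], float] = field(default_factory=dict)
    allele_numbers: Mapping[str, int] = field(default_factory=dict)
    n_cases: int = 100
    unknown_fraction: float = 0.0
    consanguinity_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for (vid, grp), q in self.true_frequencies.items():
            if not (0 <= q <= 1):
                raise ValueError(f"frequency for ({vid}, {grp}) not in [0, 1]: {q}")
        for grp, n in self.allele_numbers.items():
            if n < 1:
                raise ValueError(f"allele number for {grp} must be >= 1")
        if not (0 <= self.unknown_fraction <= 1):
            raise ValueError("unknown_fraction must be in [0, 1]")
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")

    @property
    def variants(self) -> list[str]:
        return sorted({vid for vid, _ in self.true_frequencies})

    @property
    def groups(self) -> list[str]:
        return sorted({grp for _, grp in self.true_frequencies})


def generate_frequency_table(
    config: SyntheticConfig, rng: np.random.Generator
) -> list[GroupAlleleFrequency]:
    """Draw a binomially sampled allele-frequency table.

    Each (variant, group) cell gets ``k ~ Binomial(n_g, q_vg)`` independently
    and ``af = k / n_g``; deterministic under a fixed generator state.
    """
    out = []
    for vid in config.variants:
        for grp in config.groups:
            q = config.true_frequencies.get((vid, grp))
            if q is None:
                continue
            n = config.allele_numbers[grp]
            k = int(rng.binomial(n, q))
            out.append(GroupAlleleFrequency(vid, grp, k, n, k / n))
    return out


def generate_case_database(
    config: SyntheticConfig, rng: np.random.Generator
) -> list[CaseRecord]:
    """Draw affected-conditional case genotypes.

    Conditional on being affected, each of a case's two alleles is an
    independent draw from the pathogenic-frequency vector normalised over
    variants (frequencies summed over groups), so variant shares among case
    alleles recover the frequency proportions.  A fraction
    ``unknown_fraction`` of allele slots is masked to UNKNOWN.
    """
    totals: dict[str, float] = {}
    for (vid, _), q in config.true_frequencies.items():
        totals[vid] = totals.get(vid, 0.0) + q
    variants = sorted(totals)
    weights = np.array([totals[v] for v in variants], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("all-zero pathogenic frequencies: cannot sample case genotypes")
    weights /= weights.sum()
    draws = rng.choice(len(variants), size=(config.n_cases, 2), p=weights)
    masked = rng.random(size=(config.n_cases, 2)) < config.unknown_fraction
    cases = []
    for i in range(config.n_cases):
        a = UNKNOWN if masked[i, 0] else variants[draws[i, 0]]
        b = UNKNOWN if masked[i, 1] else variants[draws[i, 1]]
        cases.append(CaseRecord(f"SYN{i + 1:05d}", "synthetic", a, b))
    return cases


def simulate_consanguineous_cohort(
    q: float, c: float, n_births: int, rng: np.random.Generator
) -> float:
    """Forward-simulate births and return the affected fraction.

    With probability ``c`` a birth's parents are first cousins, simulated by
    explicit allele dropping: the two shared grandparents carry four i.i.d.
    Bernoulli(q) alleles; each linking parent inherits one grandparental
    allele at random plus an independent population allele; each cousin
    inherits one random allele from the linking parent plus a population
    allele; the child receives one random allele from each cousin.  Remaining
    births draw both parental transmissions i.i.d. Bernoulli(q).  A child is
    affected when both alleles are pathogenic.

    The pedigree is explicit — the kinship coefficient 1/16 is an emergent
    property, not an input — so this serves as an independent check of the
    closed-form adjustment ``(1-c)q**2 + c(q/16 + 15q**2/16)``.
    """
    if n_births < 1:
        raise ValueError("n_births must be >= 1")
    if not (0 <= q <= 1) or not (0 <= c <= 1):
        raise ValueError("q and c must be in [0, 1]")
    consang = rng.random(n_births) < c
    m = int(consang.sum())
    affected = np.zeros(n_births, dtype=bool)

    # random-mating births: two independent population alleles
    r = n_births - m
    if r:
        a1 = rng.random(r) < q
        a2 = rng.random(r) < q
        affected[~consang] = a1 & a2

    if m:
        labels = _first_cousin_child_labels(m, rng)
        gp_path = rng.random((m, 4)) < q  # grandparental alleles, iid Bernoulli(q)
        path = np.zeros((m, 2), dtype=bool)
        for side in range(2):
            lab = labels[:, side]
            from_gp = lab >= 0
            path[from_gp, side] = gp_path[np.arange(m)[from_gp], lab[from_gp]]
            # population-derived alleles are fresh independent draws
            path[~from_gp, side] = rng.random(int((~from_gp).sum())) < q
        affected[consang] = path[:, 0] & path[:, 1]

    return float(affected.mean())


def _first_cousin_child_labels(m: int, rng: np.random.Generator) -> np.ndarray:
    """Drop alleles through m independent first-cousin pedigrees.

    The child's parents are first cousins: their parents (the linking
    parents) are full siblings, children of one shared grandparental couple.
    Returns an (m, 2) array labelling each child allele by its origin:
    0..3 index the four grandparental alleles (grandparent A's pair then
    grandparent B's), -1 marks an allele from the unrelated population.
    """
    labels = np.empty((m, 2), dtype=np.int64)
    idx = np.arange(m)
    for side in range(2):
        # linking parent (a sibling): one random allele from each grandparent
        sib = np.stack(
            [rng.integers(0, 2, size=m), 2 + rng.integers(0, 2, size=m)], axis=1
        )
        # cousin: one random allele of the linking parent, one population allele
        cousin = np.stack(
            [sib[idx, rng.integers(0, 2, size=m)], np.full(m, -1)], axis=1
        )
        # child: one random allele from this cousin
        labels[:, side] = cousin[idx, rng.integers(0, 2, size=m)]
    return labels


def first_cousin_autozygosity(n_offspring: int, rng: np.random.Generator) -> float:
    """Fraction of first-cousin offspring whose two alleles are identical by
    descent (copies of the same grandparental allele).

    Converges to the kinship coefficient F = 1/16 regardless of allele
    frequency; emergent from the pedigree, not injected.
    """
    labels = _first_cousin_child_labels(n_offspring, rng)
    ibd = (labels[:, 0] >= 0) & (labels[:, 0] == labels[:, 1])
    return float(ibd.mean())


def write_frequency_table(records, path: str | Path) -> None:
    """Write records in the same TSV dialect the loader consumes."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rsid\tgroup\tac\tan\taf\n")
        for r in records:
            fh.write(f"{r.variant_id}\t{r.group}\t{r.allele_count}\t{r.allele_number}\t{r.frequency:.10g}\n")


def write_case_table(cases, path: str | Path) -> None:
    """Write cases in the same CSV dialect the loader consumes."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["case_id", "source_ref", "allele_a", "allele_b"])
        for case in cases:
            w.writerow([case.case_id, case.source_ref, case.allele_a, case.allele_b])
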