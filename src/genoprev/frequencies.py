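"""Ancestry-stratified allele frequencies and carrier-frequency summation.

Population allele frequencies come stratified by genetic-ancestry group
(non-Finnish European NFE, African/African-American AFR, Latino/Admixed
American AMR, East Asian EAS, South Asian SAS; Finnish rows are dropped).
EAS and SAS are pooled into a single ASIAN group by summing allele counts,
because census ancestry categories rarely separate Asian subgroups.  The
carrier frequency of a group is the sum of its pathogenic allele frequencies;
its exact binomial (Clopper-Pearson) confidence interval is built from the
pooled counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import beta

from .catalog import _check_variant_id, _open_rows

__all__ = [
    "INPUT_GROUPS",
    "ASIAN",
    "ANALYSIS_GROUPS",
    "GroupAlleleFrequency",
    "GroupCarrierFrequency",
    "load_frequency_table",
    "pool_asian",
    "sum_carrier_frequency",
    "adjust_for_unknown",
    "clopper_pearson",
]

logger = logging.getLogger(__name__)

#: Ancestry group codes accepted on input.
INPUT_GROUPS = ("NFE", "AFR", "AMR", "EAS", "SAS")

#: Pooled East+South Asian code, produced only by :func:`pool_asian`.
ASIAN = "ASIAN"

#: Groups used by the country-level analysis after pooling.
ANALYSIS_GROUPS = ("NFE", "AFR", "AMR", ASIAN)


@dataclass(frozen=True)
class GroupAlleleFrequency:
    """Allele count ``k`` out of ``n`` sequenced chromosomes for one group."""

    variant_id: str
    group: str
    allele_count: int
    allele_number: int
    frequency: float

    def __post_init__(self) -> None:
        _check_variant_id(self.variant_id)
        if self.group not in INPUT_GROUPS + (ASIAN,):
            raise ValueError(f"unknown ancestry group {self.group!r}")
        if not (0 <= self.allele_count <= self.allele_number):
            raise ValueError(
                f"{self.variant_id}/{self.group}: need 0 <= ac ({self.allele_count}) "
                f"<= an ({self.allele_number})"
            )
        if self.allele_number < 1:
            raise ValueError("allele_number must be >= 1")
        if abs(self.frequency - self.allele_count / self.allele_number) > 1e-12:
            raise ValueError(
                f"{self.variant_id}/{self.group}: frequency {self.frequency} "
                f"inconsistent with {self.allele_count}/{self.allele_number}"
            )


@dataclass(frozen=True)
class GroupCarrierFrequency:
    """Summed pathogenic allele frequency for one ancestry group.

    ``f`` is the carrier frequency in the Hardy-Weinberg sense used downstream
    (the probability that a random chromosome carries any pathogenic allele);
    ``pooled_k``/``pooled_n`` back the exact binomial confidence interval.
    ``missing`` flags a group that was absent from the frequency table.
    """

    group: str
    f: float
    pooled_k: int = 0
    pooled_n: int = 0
    ci_low: float = 0.0
    ci_high: float = 0.0
    coverage_adjusted: bool = False
    missing: bool = False

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("carrier frequency must be >= 0")
        if self.pooled_n and not self.coverage_adjusted:
            if not (self.ci_low <= self.f + 1e-12 and self.f <= self.ci_high + 1e-12):
                raise ValueError(
                    f"{self.group}: CI ({self.ci_low}, {self.ci_high}) does not bracket f={self.f}"
                )


def load_frequency_table(path: str | Path) -> list[GroupAlleleFrequency]:
    """Read a tab-delimited frequency table (columns rsid, group, ac, an, af).

    Finnish (FIN) rows are skipped with a warning: none of the pathogenic
    variants occur in that population and its sample is non-representative.
    Malformed rows raise with the offending line number.
    """
    rows = list(_open_rows(path, delimiter="\t"))
    if not rows:
        return []
    header = rows[0][1]
    expected = ["rsid", "group", "ac", "an", "af"]
    if header != expected:
        raise ValueError(f"{path}: expected header {expected}, got {header}")
    out = []
    for lineno, row in rows[1:]:
        if len(row) != 5:
            raise ValueError(f"{path} row {lineno + 1}: expected 5 fields, got {len(row)}")
        rsid, group, ac, an, af = row
        if group == "FIN":
            warnings.warn(
                f"{path} row {lineno + 1}: FIN row for {rsid} excluded", stacklevel=2
            )
            continue
        try:
            k, n, af_val = int(ac), int(an), float(af)
            # a file may print af at reduced precision; accept within half an
            # ulp of the printed decimals and store the exact ratio
            decimals = len(af.split(".")[1]) if "." in af else 0
            tol = max(1e-12, 0.5 * 10.0 ** -decimals)
            if n >= 1 and abs(af_val - k / n) > tol:
                raise ValueError(
                    f"af {af_val} inconsistent with ac/an = {k}/{n} = {k / n:.3g}"
                )
            rec = GroupAlleleFrequency(rsid, group, k, n, k / n if n >= 1 else af_val)
        except ValueError as exc:
            raise ValueError(f"{path} row {lineno + 1}: {exc}") from exc
        out.append(rec)
    return out


def pool_asian(records: Iterable[GroupAlleleFrequency]) -> list[GroupAlleleFrequency]:
    """Replace EAS and SAS records by a pooled ASIAN record per variant.

    Pooling sums allele counts and allele numbers (k, n), never averages
    frequencies; the pooled frequency is recomputed from the summed counts.
    A variant observed in only one of the two groups carries that group's
    counts through unchanged.
    """
    out = [r for r in records if r.group not in ("EAS", "SAS")]
    by_variant: dict[str, dict[str, GroupAlleleFrequency]] = {}
    for r in records:
        if r.group in ("EAS", "SAS"):
            slot = by_variant.setdefault(r.variant_id, {})
            if r.group in slot:
                raise ValueError(f"duplicate {r.group} record for {r.variant_id}")
            slot[r.group] = r
    for vid, slot in by_variant.items():
        k = sum(r.allele_count for r in slot.values())
        n = sum(r.allele_number for r in slot.values())
        out.append(GroupAlleleFrequency(vid, ASIAN, k, n, k / n))
    return out


def sum_carrier_frequency(
    records: Iterable[GroupAlleleFrequency],
    group: str,
    pathogenic_ids: Sequence[str] | set[str],
    alpha: float = 0.05,
) -> GroupCarrierFrequency:
    """Sum pathogenic allele frequencies for one ancestry group.

    ``f = sum over pathogenic variants of k_v / n_v`` for the requested group.
    The confidence interval is computed on the pooled counts: numerator
    ``sum k_v``, denominator the minimum allele number across the summed
    variants (a conservative shared-denominator rule, since variant-specific
    call rates differ).

    A group entirely absent from ``records`` yields a zero-frequency result
    flagged ``missing=True`` rather than silence.
    """
    ids = set(pathogenic_ids)
    if not ids:
        raise ValueError("pathogenic_ids must be nonempty")
    sub = [r for r in records if r.group == group and r.variant_id in ids]
    if not sub:
        logger.warning("group %s absent from frequency records", group)
        return GroupCarrierFrequency(group=group, f=0.0, missing=True)
    f = sum(r.frequency for r in sub)
    k = sum(r.allele_count for r in sub)
    n = min(r.allele_number for r in sub)
    lo, hi = clopper_pearson(min(k, n), n, alpha)
    # with unequal denominators f <= k/n_min; widen so the interval brackets f
    return GroupCarrierFrequency(
        group=group, f=f, pooled_k=k, pooled_n=n, ci_low=min(lo, f), ci_high=max(hi, f)
    )


def adjust_for_unknown(gcf: GroupCarrierFrequency, coverage: float) -> GroupCarrierFrequency:
    """Scale a carrier frequency up by the annotated-allele coverage.

    When only a fraction ``coverage`` of case alleles have population
    frequency data, dividing the summed frequency by that fraction
    extrapolates to the full pathogenic spectrum.  Linear in ``f`` and
    inverse-linear in ``coverage``; identity at coverage 1.
    """
    if not (0 < coverage <= 1):
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    return replace(
        gcf,
        f=gcf.f / coverage,
        ci_low=gcf.ci_low / coverage,
        ci_high=gcf.ci_high / coverage,
        coverage_adjusted=True,
    )


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval from beta-distribution quantiles.

    ``lo = BetaInv(alpha/2; k, n-k+1)`` (0 when k=0) and
    ``hi = BetaInv(1-alpha/2; k+1, n-k)`` (1 when k=n).  The interval always
    brackets k/n and its coverage is conservative (>= the nominal level).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi
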