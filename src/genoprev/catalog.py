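"""Case-level variant catalog: allele tallies, rare-variant collapsing, coverage.

A diagnosed case of an autosomal recessive disease carries two alleles at the
locus, each either a named pathogenic variant (keyed by rsID, or a stable
``local:`` label when no rsID exists) or the ``UNKNOWN`` sentinel for an
ungenotyped slot.  Tallying the two allele slots over all cases yields the
per-variant allele counts that anchor every downstream frequency estimate.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "UNKNOWN",
    "OTHER",
    "VariantRecord",
    "CaseRecord",
    "AlleleTally",
    "tally_alleles",
    "collapse_rare",
    "annotation_coverage",
    "load_case_table",
    "load_variant_catalog",
]

#: Sentinel for an allele slot with no identified variant.
UNKNOWN = "UNKNOWN"

#: Bucket label for rare variants pooled by :func:`collapse_rare`.
OTHER = "OTHER"

_VARIANT_ID_RE = re.compile(r"^(rs\d+|local:\S+|OTHER)$")


def _check_variant_id(vid: str) -> str:
    if not vid or not _VARIANT_ID_RE.match(vid):
        raise ValueError(
            f"invalid variant id {vid!r}: expected 'rs<digits>', 'local:<label>' or 'OTHER'"
        )
    return vid


@dataclass(frozen=True)
class VariantRecord:
    """A catalogued causative variant.

    Parameters
    ----------
    variant_id : str
        rsID (``rs`` + digits) or a stable ``local:`` label for variants with
        no rsID match.
    hgvs_label : str
        Free-text cDNA/protein name.
    annotated : bool
        True when population frequency data exist for this variant.
    """

    variant_id: str
    hgvs_label: str = ""
    annotated: bool = False

    def __post_init__(self) -> None:
        _check_variant_id(self.variant_id)


@dataclass(frozen=True)
class CaseRecord:
    """One diagnosed case with its two allele slots (biallelic locus)."""

    case_id: str
    source_ref: str = ""
    allele_a: str = UNKNOWN
    allele_b: str = UNKNOWN

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be nonempty")
        for slot in (self.allele_a, self.allele_b):
            if slot != UNKNOWN:
                _check_variant_id(slot)

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)


@dataclass(frozen=True)
class AlleleTally:
    """Per-variant allele counts over a case set.

    Invariants: ``total_alleles == 2 * n_cases`` and the variant counts plus
    the UNKNOWN count exhaust every allele slot.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    total_alleles: int = 0
    n_cases: int = 0

    def __post_init__(self) -> None:
        if self.total_alleles != 2 * self.n_cases:
            raise ValueError(
                f"total_alleles ({self.total_alleles}) != 2 x n_cases ({self.n_cases})"
            )
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("allele counts must be non-negative")
        if sum(self.counts.values()) != self.total_alleles:
            raise ValueError("counts (incl. UNKNOWN) must sum to total_alleles")

    @property
    def known_counts(self) -> dict[str, int]:
        """Counts excluding the UNKNOWN sentinel."""
        return {v: c for v, c in self.counts.items() if v != UNKNOWN}


def tally_alleles(cases: Iterable[CaseRecord]) -> AlleleTally:
    """Tally both allele slots of every case into per-variant counts.

    UNKNOWN slots count toward ``total_alleles`` (the 2-per-case identity is
    exact) but are kept under the sentinel key, never attributed to a variant.

    Raises
    ------
    ValueError
        If two cases share a ``case_id`` (the case database contract requires
        deduplicated cases).
    """
    counts: Counter[str] = Counter()
    seen: set[str] = set()
    n = 0
    for case in cases:
        if case.case_id in seen:
            raise ValueError(f"duplicate case_id: {case.case_id!r}")
        seen.add(case.case_id)
        counts[case.allele_a] += 1
        counts[case.allele_b] += 1
        n += 1
    return AlleleTally(counts=dict(counts), total_alleles=2 * n, n_cases=n)


def collapse_rare(tally: AlleleTally, threshold: int = 5) -> AlleleTally:
    """Pool variants observed fewer than ``threshold`` times into ``OTHER``.

    The comparison is strict ``count < threshold``; the grand total is
    preserved for every threshold.  UNKNOWN alleles are never pooled.
    """
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    out: dict[str, int] = {}
    other = tally.counts.get(OTHER, 0)
    for vid, c in tally.counts.items():
        if vid in (UNKNOWN,):
            out[vid] = c
        elif vid != OTHER and c >= threshold:
            out[vid] = c
        elif vid != OTHER:
            other += c
    if other:
        out[OTHER] = other
    return AlleleTally(counts=out, total_alleles=tally.total_alleles, n_cases=tally.n_cases)


def annotation_coverage(tally: AlleleTally, annotated_ids: set[str]) -> float:
    """Fraction of all alleles attributable to frequency-annotated variants.

    With 133 of 228 alleles annotated this is 0.583 (58.3%), the divisor used
    by the optional unknown-allele adjustment.
    """
    if tally.total_alleles == 0:
        raise ValueError("coverage undefined for an empty tally (0 alleles)")
    covered = sum(c for v, c in tally.counts.items() if v in annotated_ids and v != UNKNOWN)
    return covered / tally.total_alleles


def _open_rows(path: str | Path, delimiter: str = ","):
    """Yield (lineno, row) from a delimited file, skipping '#' comments."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(
            (line for line in fh if not line.startswith("#")), delimiter=delimiter
        )
        for i, row in enumerate(reader):
            if row:
                yield i, row


def load_case_table(path: str | Path) -> list[CaseRecord]:
    """Read a case database CSV (columns case_id, source_ref, allele_a, allele_b)."""
    rows = list(_open_rows(path))
    if not rows:
        return []
    header = rows[0][1]
    expected = ["case_id", "source_ref", "allele_a", "allele_b"]
    if header != expected:
        raise ValueError(f"{path}: expected header {expected}, got {header}")
    out = []
    for lineno, row in rows[1:]:
        if len(row) != 4:
            raise ValueError(f"{path} row {lineno + 1}: expected 4 fields, got {len(row)}")
        try:
            out.append(CaseRecord(*row))
        except ValueError as exc:
            raise ValueError(f"{path} row {lineno + 1}: {exc}") from exc
    return out


def load_variant_catalog(path: str | Path) -> list[VariantRecord]:
    """Read a variant catalog CSV (columns variant_id, hgvs_label, annotated)."""
    rows = list(_open_rows(path))
    if not rows:
        return []
    header = rows[0][1]
    expected = ["variant_id", "hgvs_label", "annotated"]
    if header != expected:
        raise ValueError(f"{path}: expected header {expected}, got {header}")
    out: list[VariantRecord] = []
    seen: set[str] = set()
    for lineno, row in rows[1:]:
        if len(row) != 3:
            raise ValueError(f"{path} row {lineno + 1}: expected 3 fields, got {len(row)}")
        vid, hgvs, annotated = row
        if annotated.lower() not in ("true", "false"):
            raise ValueError(f"{path} row {lineno + 1}: annotated must be true/false")
        if vid in seen:
            raise ValueError(f"{path} row {lineno + 1}: duplicate variant_id {vid!r}")
        seen.add(vid)
        out.append(VariantRecord(vid, hgvs, annotated.lower() == "true"))
    return out
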