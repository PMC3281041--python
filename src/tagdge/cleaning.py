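"""Raw tag library cleaning and library-level statistics.

A raw DGE library is a multiset of 21-nt reads plus adaptor-only artifacts.
Cleaning applies, in order: removal of adaptor-only records, removal of tags
containing N (the protocol's "low quality"), then removal of tags whose total
copy number is 1 — singletons are overwhelmingly sequencing-error variants of
abundant tags. Copy number is judged after the first two removals, on sequences
only. Reads that are not 21 nt or not CATG-anchored go to an explicit malformed
bucket; nothing is silently dropped, and the bucket totals reconcile exactly
with the raw total.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

from .virtual_tags import ANCHOR, TAG_LENGTH

_VALID = frozenset("ACGT")


@dataclass
class RawTagLibrary:
    """One stage's raw library: tag sequence -> copy count, plus artifacts.

    N-containing reads sit in ``tags`` (they have sequence identity); reads that
    are pure adaptor have none and are only counted.
    """

    library_id: str
    tags: Dict[str, int] = field(default_factory=dict)
    adaptor_only: int = 0

    @property
    def raw_total(self) -> int:
        return self.adaptor_only + sum(self.tags.values())

    @property
    def distinct_raw(self) -> int:
        """Distinct tag sequences; artifact records have no sequence identity."""
        return len(self.tags)


@dataclass
class CleanTagTable:
    library_id: str
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def clean_total(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct_clean(self) -> int:
        return len(self.counts)


@dataclass
class LibraryStats:
    """Copy-count bookkeeping of one library's cleaning pass.

    Invariant: clean + N-containing + adaptor-only + singleton + malformed
    copies = raw total.
    """

    library_id: str
    raw_total: int
    distinct_raw: int
    clean_total: int
    distinct_clean: int
    adaptor_only_copies: int
    n_copies: int
    singleton_copies: int
    malformed_copies: int

    @property
    def pct_clean_of_raw(self) -> Optional[float]:
        return pct(self.clean_total, self.raw_total)

    def component_percentages(self) -> Dict[str, Optional[float]]:
        """Fractions of the raw library per removal category (sum ~ 100%)."""
        return {
            "clean": pct(self.clean_total, self.raw_total),
            "n_containing": pct(self.n_copies, self.raw_total),
            "adaptor_only": pct(self.adaptor_only_copies, self.raw_total),
            "copy_lt2": pct(self.singleton_copies, self.raw_total),
            "malformed": pct(self.malformed_copies, self.raw_total),
        }


def pct(numerator, denominator) -> Optional[float]:
    """Percentage rounded half-up to 2 decimals; None when the denominator is 0.

    Half-up (not banker's) rounding so that printed ratios match conventional
    table formatting.
    """
    if denominator == 0:
        return None
    value = decimal.Decimal(numerator) / decimal.Decimal(denominator) * 100
    return float(value.quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))


def format_pct(value: Optional[float]) -> str:
    return "NA" if value is None else f"{value:.2f}%"


def is_wellformed_tag(tag: str) -> bool:
    return (
        len(tag) == TAG_LENGTH
        and tag.startswith(ANCHOR)
        and set(tag) <= _VALID
    )


def clean_raw_tags(raw: RawTagLibrary) -> Tuple[CleanTagTable, LibraryStats]:
    """Apply the three filter rules and tally every removal category.

    Filter order: adaptor-only, then N-containing, then copy-number-1 (judged on
    the surviving sequences). Malformed reads (wrong length, non-CATG anchor, or
    alphabet outside ACGTN) are counted separately and never silently dropped.
    """
    n_copies = 0
    malformed = 0
    survivors: Dict[str, int] = {}
    for tag, count in raw.tags.items():
        if count < 1:
            raise ValueError(f"copy count must be >= 1, got {count} for {tag!r}")
        if "N" in tag.upper():
            n_copies += count
        elif not is_wellformed_tag(tag):
            malformed += count
        else:
            survivors[tag] = survivors.get(tag, 0) + count
    singleton = sum(c for c in survivors.values() if c == 1)
    clean = {t: c for t, c in survivors.items() if c >= 2}
    table = CleanTagTable(raw.library_id, clean)
    stats = LibraryStats(
        library_id=raw.library_id,
        raw_total=raw.raw_total,
        distinct_raw=raw.distinct_raw,
        clean_total=table.clean_total,
        distinct_clean=table.distinct_clean,
        adaptor_only_copies=raw.adaptor_only,
        n_copies=n_copies,
        singleton_copies=singleton,
        malformed_copies=malformed,
    )
    assert (
        stats.clean_total
        + stats.n_copies
        + stats.adaptor_only_copies
        + stats.singleton_copies
        + stats.malformed_copies
        == stats.raw_total
    )
    return table, stats


def summarize_library(counts: Mapping[str, int]) -> Dict[str, Optional[float]]:
    """Percentage report over a mapping-statistics count table.

    Accepts the count fields of a library summary (raw/clean totals, mapping
    category counts on total-tag and distinct-tag bases, tag-mapped gene counts
    plus the reference gene total) and emits every ratio of the standard report:
    percent of clean tags for total-tag categories, percent of distinct clean
    tags for distinct categories, percent of reference genes for gene counts.
    Ratios with a zero denominator come back as None, never 0.
    """
    report: Dict[str, Optional[float]] = {}
    if "raw_total" in counts:
        report["pct_clean_of_raw"] = pct(counts.get("clean_total", 0), counts["raw_total"])
    clean = counts.get("clean_total", 0)
    distinct = counts.get("distinct_clean", 0)
    for key in ("gene_all", "gene_unambiguous", "genome", "unknown"):
        if key in counts:
            report[f"pct_{key}_of_clean"] = pct(counts[key], clean)
        dkey = f"distinct_{key}"
        if dkey in counts:
            report[f"pct_{dkey}_of_distinct_clean"] = pct(counts[dkey], distinct)
    n_ref = counts.get("n_ref_genes", 0)
    for key in ("genes_all", "genes_unambiguous"):
        if key in counts:
            report[f"pct_{key}_of_ref"] = pct(counts[key], n_ref)
    return report
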