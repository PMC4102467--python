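"""Functional classification of exome variants and the homozygous-deleterious catalog.

A variant is *amino-acid changing* when its consequence class is missense,
splicesense, frameshift, read-through, non-frameshift indel, or premature
stop.  Among these, four mutually exclusive *protein-function-affecting*
categories are recognised: splicesense, frameshift and premature-stop changes
affect function by construction; missense changes qualify through their
prediction scores (SIFT < 0.05 or PolyPhen-2 >= 0.85).  Priority when a
variant could fall into several buckets is
splicesense > frameshift > premature stop > score-based, so a census over the
categories never double-counts.

The catalog filter keeps variants that are homozygous in at least one line,
absent from both non-cancerous reference catalogs, amino-acid changing, and
function-affecting.  Homozygosity is inferred from percent conversion
(>= 95 by default; ~50 is heterozygous, ~100 homozygous).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Collection, Iterable

from scipy.stats import fisher_exact

from .io_formats import ChangeType, VariantRecord

__all__ = [
    "FunctionalCriteria",
    "FunctionalCategory",
    "CatalogReport",
    "is_amino_acid_changing",
    "assess_protein_function_effect",
    "filter_homozygous_deleterious",
    "driver_gene_enrichment_test",
]

AA_CHANGING_TYPES = frozenset(
    {
        ChangeType.MISSENSE,
        ChangeType.SPLICESENSE,
        ChangeType.FRAMESHIFT,
        ChangeType.READ_THROUGH,
        ChangeType.NONFRAMESHIFT_INDEL,
        ChangeType.PREMATURE_STOP,
    }
)

#: Mutually exclusive protein-function-affecting categories (plus "none").
FunctionalCategory = str
CATEGORY_SPLICESENSE = "splicesense"
CATEGORY_FRAMESHIFT = "frameshift"
CATEGORY_PREMATURE_STOP = "premature_stop"
CATEGORY_SIFT_POLYPHEN = "sift_polyphen"
CATEGORY_NONE = "none"
FUNCTIONAL_CATEGORIES = (
    CATEGORY_SPLICESENSE,
    CATEGORY_FRAMESHIFT,
    CATEGORY_PREMATURE_STOP,
    CATEGORY_SIFT_POLYPHEN,
)


@dataclass(frozen=True)
class FunctionalCriteria:
    """Thresholds defining "likely to affect protein function" and homozygosity.

    Parameters
    ----------
    sift_max:
        Missense variants with SIFT strictly below this are damaging (0.05).
    polyphen_min:
        Missense variants with PolyPhen-2 at or above this are damaging (0.85).
    homozygous_min_percent:
        Percent conversion at or above which a line is called homozygous (95).
    """

    sift_max: float = 0.05
    polyphen_min: float = 0.85
    homozygous_min_percent: float = 95.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sift_max <= 1.0):
            raise ValueError(f"sift_max must be in [0,1], got {self.sift_max}")
        if not (0.0 <= self.polyphen_min <= 1.0):
            raise ValueError(f"polyphen_min must be in [0,1], got {self.polyphen_min}")


def is_amino_acid_changing(record: VariantRecord) -> bool:
    """True iff the variant alters the amino-acid sequence (silent excluded)."""
    return record.change_type in AA_CHANGING_TYPES


def assess_protein_function_effect(
    record: VariantRecord, criteria: FunctionalCriteria = FunctionalCriteria()
) -> FunctionalCategory:
    """Assign the variant to exactly one protein-function-affecting category.

    Splicesense, frameshift and premature-stop changes map to their own
    categories regardless of prediction scores.  Missense changes map to
    ``sift_polyphen`` iff SIFT < ``sift_max`` OR PolyPhen-2 >= ``polyphen_min``
    (either score alone suffices); an unknown score never satisfies its
    criterion.  Everything else maps to ``none``.
    """
    ct = record.change_type
    if ct is ChangeType.SPLICESENSE:
        return CATEGORY_SPLICESENSE
    if ct is ChangeType.FRAMESHIFT:
        return CATEGORY_FRAMESHIFT
    if ct is ChangeType.PREMATURE_STOP:
        return CATEGORY_PREMATURE_STOP
    if ct is ChangeType.MISSENSE:
        sift_hit = record.sift is not None and record.sift < criteria.sift_max
        polyphen_hit = (
            record.polyphen2 is not None and record.polyphen2 >= criteria.polyphen_min
        )
        if sift_hit or polyphen_hit:
            return CATEGORY_SIFT_POLYPHEN
    return CATEGORY_NONE


def is_homozygous_anywhere(
    record: VariantRecord, criteria: FunctionalCriteria = FunctionalCriteria()
) -> bool:
    """True when at least one cell line carries the variant homozygously."""
    return any(
        pct >= criteria.homozygous_min_percent
        for pct in record.percent_conversion.values()
    )


@dataclass
class CatalogReport:
    """Filtered homozygous-deleterious subset plus its category census."""

    records: list[VariantRecord]
    categories: dict[str, FunctionalCategory]  # variant_id -> category
    category_counts: Counter = field(default_factory=Counter)
    unique_genes: int = 0

    def __len__(self) -> int:
        return len(self.records)


def filter_homozygous_deleterious(
    catalog: Iterable[VariantRecord],
    criteria: FunctionalCriteria = FunctionalCriteria(),
) -> CatalogReport:
    """Keep variants satisfying all four catalog conditions.

    i) homozygous in at least one cell line (percent conversion >=
    ``homozygous_min_percent``), ii) absent from both non-cancerous reference
    catalogs (frequency cells missing or exactly 0), iii) amino-acid changing,
    and iv) in a protein-function-affecting category.  Returns the subset
    together with per-category counts and the unique-gene count.
    """
    kept: list[VariantRecord] = []
    cats: dict[str, FunctionalCategory] = {}
    counts: Counter = Counter({c: 0 for c in FUNCTIONAL_CATEGORIES})
    for rec in catalog:
        if not is_homozygous_anywhere(rec, criteria):
            continue
        if not rec.absent_from_normals():
            continue
        if not is_amino_acid_changing(rec):
            continue
        category = assess_protein_function_effect(rec, criteria)
        if category == CATEGORY_NONE:
            continue
        kept.append(rec)
        cats[rec.variant_id] = category
        counts[category] += 1
    return CatalogReport(
        records=kept,
        categories=cats,
        category_counts=counts,
        unique_genes=len({r.gene for r in kept}),
    )


def driver_gene_enrichment_test(
    selected_genes: Collection[str],
    driver_genes: Collection[str],
    universe: Collection[str],
) -> float:
    """Two-tailed Fisher exact p for cancer-driver enrichment in a gene set.

    The 2x2 table crosses membership in ``selected_genes`` with membership in
    ``driver_genes`` over ``universe``.  Both sets are intersected with the
    universe first.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("gene universe is empty")
    selected = set(selected_genes) & universe
    drivers = set(driver_genes) & universe
    a = len(selected & drivers)
    b = len(selected - drivers)
    c = len(drivers - selected)
    d = len(universe) - a - b - c
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
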