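"""Per-gene combination of variant percent-conversions and multi-gene
variant-burden totals.

Within one gene, the per-cell-line percent conversions of its variants are
treated as independent event probabilities and combined as

    combined = 100 * (1 - prod_i (1 - P_i / 100))

so a single homozygous variant (P = 100) forces 100 and the combined value
never exceeds 100 — the cap is a property of the complement-product formula,
not a post-hoc clip.  Across genes, the per-gene combined values are simply
summed per cell line with no maximum; that column of totals is the
"variant burden" pattern used for pattern comparison.

Two parallel tables are produced per query: all amino-acid-changing
variants, and the subset that is both protein-function affecting and absent
from the non-cancerous reference catalogs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import VariantRecord
from .variant_catalog import (
    CATEGORY_NONE,
    FunctionalCriteria,
    assess_protein_function_effect,
    is_amino_acid_changing,
)

__all__ = [
    "GeneVariantProfile",
    "SummationTable",
    "SummationPair",
    "gene_variant_summary",
    "multi_gene_totals",
    "build_summation",
    "plot_variant_burden",
    "MAX_GENES",
]

#: Default cap on genes per query (a web-tool convention, not a hard limit).
MAX_GENES = 150


def gene_variant_summary(percents: Sequence[float]) -> float:
    """Combine one gene's variant percents for a single cell line.

    >>> round(gene_variant_summary([36, 42]), 2)
    62.88

    The empty list combines to 0; any P_i = 100 forces 100.
    """
    prod = 1.0
    for p in percents:
        if not (0.0 <= p <= 100.0):
            raise ValueError(f"percent {p} outside [0,100]")
        prod *= 1.0 - p / 100.0
    return 100.0 * (1.0 - prod)


@dataclass(frozen=True)
class GeneVariantProfile:
    """One gene's variants and combined percent per cell line.

    ``variants`` is a tuple of (variant id, aa impact, per-line percents
    aligned with ``cell_lines``).
    """

    gene: str
    cell_lines: tuple[str, ...]
    variants: tuple[tuple[str, str, tuple[float, ...]], ...]

    @property
    def summary(self) -> tuple[float, ...]:
        """Combined percent per cell line (complement-product formula)."""
        return tuple(
            gene_variant_summary([pcts[j] for _, _, pcts in self.variants])
            for j in range(len(self.cell_lines))
        )

    def variant_rows(self) -> Iterable[tuple[str, str, tuple[float, ...]]]:
        return iter(self.variants)


@dataclass(frozen=True)
class SummationTable:
    """Per-gene profiles plus the uncapped per-cell-line totals."""

    profiles: tuple[GeneVariantProfile, ...]
    cell_lines: tuple[str, ...]
    subset_flag: str  # "all_aa_changing" | "function_affecting_and_absent"

    @property
    def totals(self) -> tuple[float, ...]:
        """Column-wise sum of the gene summaries (may exceed 100)."""
        return multi_gene_totals(self.profiles, self.cell_lines)


@dataclass(frozen=True)
class SummationPair:
    """Both output tables of one summation query."""

    all_aa_changing: SummationTable
    function_affecting: SummationTable


def multi_gene_totals(
    profiles: Sequence[GeneVariantProfile],
    cell_lines: Sequence[str] | None = None,
) -> tuple[float, ...]:
    """Sum the per-gene combined percents per cell line (no maximum)."""
    if not profiles:
        return tuple(0.0 for _ in (cell_lines or ()))
    panels = {p.cell_lines for p in profiles}
    if len(panels) > 1:
        raise ValueError("profiles do not share one cell-line panel")
    panel = profiles[0].cell_lines
    if cell_lines is not None and tuple(cell_lines) != panel:
        raise ValueError("requested cell lines do not match the profiles' panel")
    totals = [0.0] * len(panel)
    for p in profiles:
        for j, v in enumerate(p.summary):
            totals[j] += v
    return tuple(totals)


def build_summation(
    genes: Sequence[str],
    catalog: Sequence[VariantRecord],
    cell_lines: Sequence[str],
    criteria: FunctionalCriteria = FunctionalCriteria(),
    max_genes: int = MAX_GENES,
    warn: bool = True,
) -> SummationPair:
    """Build both summation tables for a gene list over a cell-line panel.

    The first table holds every amino-acid-changing variant of each queried
    gene; the second the subset that is protein-function affecting and absent
    from the non-cancerous reference catalogs.  Unknown gene symbols yield an
    empty profile with a warning, not an error.
    """
    if len(genes) > max_genes:
        raise ValueError(
            f"{len(genes)} genes requested; at most {max_genes} per query"
        )
    panel = tuple(cell_lines)
    by_gene: dict[str, list[VariantRecord]] = {}
    for rec in catalog:
        by_gene.setdefault(rec.gene, []).append(rec)

    def profile(gene: str, records: Sequence[VariantRecord]) -> GeneVariantProfile:
        return GeneVariantProfile(
            gene=gene,
            cell_lines=panel,
            variants=tuple(
                (
                    r.variant_id,
                    r.aa_impact,
                    tuple(r.percent_in(line) for line in panel),
                )
                for r in sorted(records, key=lambda r: r.variant_id)
            ),
        )

    all_profiles, functional_profiles = [], []
    for gene in genes:
        records = by_gene.get(gene)
        if records is None:
            if warn:
                import warnings

                warnings.warn(f"unknown gene symbol {gene!r}; empty profile emitted")
            records = []
        aa = [r for r in records if is_amino_acid_changing(r)]
        func = [
            r
            for r in aa
            if assess_protein_function_effect(r, criteria) != CATEGORY_NONE
            and r.absent_from_normals()
        ]
        all_profiles.append(profile(gene, aa))
        functional_profiles.append(profile(gene, func))

    return SummationPair(
        all_aa_changing=SummationTable(
            profiles=tuple(all_profiles), cell_lines=panel, subset_flag="all_aa_changing"
        ),
        function_affecting=SummationTable(
            profiles=tuple(functional_profiles),
            cell_lines=panel,
            subset_flag="function_affecting_and_absent",
        ),
    )


def plot_variant_burden(table: SummationTable, ax=None):
    """Minimal horizontal bar plot of the per-cell-line burden totals."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, max(2, 0.18 * len(table.cell_lines))))
    totals = table.totals
    ax.barh(range(len(totals)), totals)
    ax.set_yticks(range(len(totals)), table.cell_lines, fontsize=6)
    ax.set_xlabel("summed variant percent (burden)")
    ax.invert_yaxis()
    return ax
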