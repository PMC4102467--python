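"""Panel-vs-reference variant frequency ratios, enrichment classes, and the
functional-fraction profile along the ratio ranking.

For a variant present in the non-cancerous reference, the comparison is the
ratio of its mean allelic fraction across the panel to its reference allelic
fraction.  Variants in the top ``tail_fraction`` of the ratio ranking whose
ratio is also >= ``enrich_ratio_min`` are *enriched*; symmetrically for
*depleted* at the bottom tail with ratio <= ``deplete_ratio_max``.  When the
tail cutoff lands inside a group of equal ratios, the whole tied group is
included — the cutoff never splits ties.

Reference frequencies come from the exome-sequenced reference column only
(ESP5400-style); the whole-genome 1000G column is carried by records but not
used here, because mixing sequencing modalities would distort the ratios.
Variants absent from the reference have no defined ratio and are excluded
(they belong to the cancer-associated class handled by the catalog filter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .io_formats import VariantRecord
from .variant_catalog import (
    CATEGORY_NONE,
    FunctionalCriteria,
    assess_protein_function_effect,
)

__all__ = [
    "EnrichmentConfig",
    "FrequencyComparison",
    "panel_variant_frequency",
    "build_comparisons",
    "classify_enrichment",
    "sliding_window_functional_fraction",
]

ENRICHED = "enriched"
DEPLETED = "depleted"
NEITHER = "neither"

_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class EnrichmentConfig:
    """Tail fractions, ratio gates and the sliding-window width.

    ``tail_fraction`` (default 0.025) selects the top/bottom 2.5% of the
    ratio ranking; ``enrich_ratio_min``/``deplete_ratio_max`` (10 and 0.1)
    additionally gate the classes; ``window_size`` (odd, default 2001) is the
    width of the functional-fraction sliding window.
    """

    tail_fraction: float = 0.025
    enrich_ratio_min: float = 10.0
    deplete_ratio_max: float = 0.1
    window_size: int = 2001

    def __post_init__(self) -> None:
        if not (0.0 < self.tail_fraction < 0.5):
            raise ValueError(f"tail_fraction must be in (0, 0.5), got {self.tail_fraction}")
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError(f"window_size must be odd and >= 3, got {self.window_size}")


@dataclass(frozen=True)
class FrequencyComparison:
    """One variant's panel-vs-reference frequency comparison."""

    variant_id: str
    panel_freq: float
    ref_freq: float
    functional: bool = False
    rank: int | None = None
    enrichment_class: str = NEITHER

    @property
    def ratio(self) -> float:
        return self.panel_freq / self.ref_freq


def panel_variant_frequency(record: VariantRecord, panel: Sequence[str]) -> float:
    """Mean allelic fraction of a variant across the panel.

    Each line contributes its percent conversion / 100; lines without the
    variant contribute 0.  The result is in [0, 1].
    """
    if not panel:
        raise ValueError("panel is empty")
    return sum(record.percent_in(line) for line in panel) / (100.0 * len(panel))


def build_comparisons(
    records: Sequence[VariantRecord],
    panel: Sequence[str],
    criteria: FunctionalCriteria = FunctionalCriteria(),
) -> list[FrequencyComparison]:
    """Comparisons for every record present in the reference (ref freq > 0)."""
    out = []
    for rec in records:
        if rec.freq_esp5400 is None or rec.freq_esp5400 <= 0.0:
            continue
        out.append(
            FrequencyComparison(
                variant_id=rec.variant_id,
                panel_freq=panel_variant_frequency(rec, panel),
                ref_freq=rec.freq_esp5400,
                functional=assess_protein_function_effect(rec, criteria) != CATEGORY_NONE,
            )
        )
    return out


def _ties(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=_TIE_RTOL, abs_tol=0.0)


def classify_enrichment(
    comparisons: Sequence[FrequencyComparison],
    config: EnrichmentConfig = EnrichmentConfig(),
) -> list[FrequencyComparison]:
    """Label each comparison enriched / depleted / neither.

    The list is ranked by ratio (descending).  The enriched class is the top
    ``tail_fraction`` of positions with ratio >= ``enrich_ratio_min``,
    extended to every variant whose ratio ties the one at the cutoff
    position; depleted is the mirror rule at the bottom tail with ratio <=
    ``deplete_ratio_max``.  Returns new comparisons carrying rank and class,
    in ranked order.
    """
    n = len(comparisons)
    if n == 0:
        return []
    ranked = sorted(comparisons, key=lambda c: (-c.ratio, c.variant_id))
    k = int(config.tail_fraction * n)

    enriched_ids: set[str] = set()
    depleted_ids: set[str] = set()
    if k > 0:
        top_cut = ranked[k - 1].ratio
        for c in ranked:
            if (c.ratio > top_cut or _ties(c.ratio, top_cut)) and c.ratio >= config.enrich_ratio_min:
                enriched_ids.add(c.variant_id)
            if c.ratio < top_cut and not _ties(c.ratio, top_cut):
                break
        bottom_cut = ranked[n - k].ratio
        for c in reversed(ranked):
            if (c.ratio < bottom_cut or _ties(c.ratio, bottom_cut)) and c.ratio <= config.deplete_ratio_max:
                depleted_ids.add(c.variant_id)
            if c.ratio > bottom_cut and not _ties(c.ratio, bottom_cut):
                break

    out = []
    for rank, c in enumerate(ranked, start=1):
        if c.variant_id in enriched_ids:
            cls = ENRICHED
        elif c.variant_id in depleted_ids:
            cls = DEPLETED
        else:
            cls = NEITHER
        out.append(replace(c, rank=rank, enrichment_class=cls))
    return out


def sliding_window_functional_fraction(
    comparisons: Sequence[FrequencyComparison], window_size: int = 2001
) -> list[tuple[float, float]]:
    """Percent of function-affecting variants in a ratio-ordered sliding window.

    ``comparisons`` must be ratio-sorted; for each full window the value is
    100 * (# functional) / window_size, reported against the window-centre
    ratio.  Series length is N - window_size + 1.
    """
    n = len(comparisons)
    if window_size < 1 or window_size % 2 == 0:
        raise ValueError(f"window_size must be odd and positive, got {window_size}")
    if n < window_size:
        raise ValueError(
            f"need at least window_size={window_size} comparisons, got {n}; "
            "use a smaller window"
        )
    flags = [1 if c.functional else 0 for c in comparisons]
    half = window_size // 2
    series: list[tuple[float, float]] = []
    running = sum(flags[:window_size])
    for start in range(n - window_size + 1):
        if start > 0:
            running += flags[start + window_size - 1] - flags[start - 1]
        series.append(
            (comparisons[start + half].ratio, 100.0 * running / window_size)
        )
    return series
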