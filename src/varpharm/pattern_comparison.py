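"""Correlate an arbitrary per-cell-line pattern against every drug's
activity profile, and test pathway-target enrichment among the significant
hits.

The pattern (typically a variant-burden Totals row) is compared with each
compound's z-score row by Pearson correlation over pairwise-complete
observations, with a two-tailed p from the t transform at n-2 df.  Positive
r means the drug works better in lines carrying the variants; negative r,
worse.  Enrichment of pathway-targeting drugs among the significant hits is
a two-tailed Fisher exact test (sum of all 2x2 tables with probability at
most that of the observed one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .drug_response import DrugActivityMatrix

__all__ = [
    "PatternCorrelation",
    "correlate_pattern",
    "pathway_target_enrichment",
]


@dataclass(frozen=True)
class PatternCorrelation:
    """Correlation of the input pattern with one drug's activity profile."""

    nsc: str
    r: float
    p: float
    n: int
    significant: bool
    targets_pathway: bool | None = None


def correlate_pattern(
    pattern: Mapping[str, float] | pd.Series,
    matrix: DrugActivityMatrix,
    alpha: float = 0.05,
    min_pairs: int = 3,
) -> list[PatternCorrelation]:
    """Rank every drug by |Pearson r| against the pattern.

    Observations are pairwise-complete per drug; drugs with fewer than
    ``min_pairs`` shared observed lines are skipped.  Ties in |r| break by
    NSC id so the ordering is stable.  A constant pattern has no defined
    correlation and raises.
    """
    pattern = pd.Series(pattern, dtype=float)
    shared = [c for c in matrix.cell_lines if c in pattern.index]
    vals = pattern[shared]
    obs = vals[~vals.isna()]
    if len(obs) >= 2 and float(np.std(obs)) == 0.0:
        raise ValueError("constant pattern: correlation undefined")
    targets_col = (
        matrix.drugs["targets_pathway"] if "targets_pathway" in matrix.drugs else None
    )

    out: list[PatternCorrelation] = []
    for nsc in matrix.nsc_ids:
        row = matrix.z_row(nsc)[shared]
        mask = ~(row.isna() | vals.isna())
        n = int(mask.sum())
        if n < min_pairs:
            continue
        x, y = vals[mask].to_numpy(), row[mask].to_numpy()
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            continue
        r, p = stats.pearsonr(x, y)
        out.append(
            PatternCorrelation(
                nsc=str(nsc),
                r=float(r),
                p=float(p),
                n=n,
                significant=bool(p < alpha),
                targets_pathway=None
                if targets_col is None
                else bool(targets_col.loc[nsc]),
            )
        )
    out.sort(key=lambda c: (-abs(c.r), c.nsc))
    return out


def pathway_target_enrichment(
    significant: Collection[str],
    pathway_targeting: Collection[str],
    universe: Collection[str],
) -> float:
    """Two-tailed Fisher exact p for pathway-targeting drugs among the hits.

    The 2x2 table crosses significance with pathway targeting over the
    universe of drugs with known mechanism of action.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("drug universe is empty")
    sig = set(significant) & universe
    targ = set(pathway_targeting) & universe
    a = len(sig & targ)
    b = len(sig - targ)
    c = len(targ - sig)
    d = len(universe) - a - b - c
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
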