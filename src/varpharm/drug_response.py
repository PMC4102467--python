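"""Drug-activity z-scores and per-cell-line resistance:sensitivity profiles.

Raw potencies (GI50, molar) are transformed per compound as
``z = (-log10(GI50) - mean) / SD`` over the observed cell lines (population
SD), so positive z means more sensitive than the panel average.  A line is
called *sensitive* to a compound at z >= 0.5, *resistant* at z <= -0.5, and
*no response* in between; missing assay cells are excluded from both the
standardisation and the response counts — they are never treated as "no
response".

Per cell line, the counts of resistant and sensitive calls over a drug set
give the resistance:sensitivity ratio (displayed as -log10).  Fold ranges
between extreme lines are ratios of raw ratios, not of the display values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DrugActivityMatrix",
    "ResponseProfile",
    "RESISTANT",
    "SENSITIVE",
    "NO_RESPONSE",
    "gi50_to_zscores",
    "gi50_matrix_to_zscores",
    "categorize_response",
    "resistance_sensitivity_profile",
    "ratio_fold_range",
    "compare_ratio_profiles",
]

RESISTANT = "resistant"
SENSITIVE = "sensitive"
NO_RESPONSE = "none"

STATUS_FDA = "fda_approved"
STATUS_CLINICAL = "clinical_trial"
STATUS_OTHER = "other"


@dataclass
class DrugActivityMatrix:
    """Compounds x cell lines z-score matrix with drug metadata.

    ``drugs`` is a DataFrame indexed by NSC id with at least the columns
    ``nsc, name, moa, status`` (optionally ``targets_pathway``); ``z`` is a
    float DataFrame with the same index and one column per cell line, NaN for
    missing assay cells.
    """

    drugs: pd.DataFrame
    z: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.drugs.index.equals(self.z.index):
            raise ValueError("drug metadata and z matrix must share their index")

    @property
    def cell_lines(self) -> list[str]:
        return list(self.z.columns)

    @property
    def nsc_ids(self) -> list[str]:
        return list(self.z.index)

    def __len__(self) -> int:
        return len(self.z)

    def z_row(self, nsc: str) -> pd.Series:
        return self.z.loc[nsc]

    def subset(self, predicate: Callable[[pd.Series], bool]) -> "DrugActivityMatrix":
        """Restrict to drugs whose metadata row satisfies ``predicate``."""
        keep = self.drugs.apply(predicate, axis=1)
        return DrugActivityMatrix(drugs=self.drugs[keep], z=self.z[keep.values])

    def with_status(self, status: str) -> "DrugActivityMatrix":
        return self.subset(lambda row: row["status"] == status)

    def exclude_tissues(self, prefixes: Iterable[str]) -> "DrugActivityMatrix":
        """Drop cell lines by tissue prefix (e.g. ``LE`` for leukemias)."""
        prefixes = set(prefixes)
        keep = [c for c in self.z.columns if c.split(":", 1)[0] not in prefixes]
        return DrugActivityMatrix(drugs=self.drugs, z=self.z[keep])


class ZeroVarianceError(ValueError):
    """Raised when a GI50 row cannot be standardised."""


def gi50_to_zscores(gi50_row: Sequence[float] | pd.Series) -> np.ndarray:
    """Standardise one compound's GI50 row to z-scores.

    z = (-log10(GI50) - mean) / SD over observed cells, population SD.
    Missing cells (NaN) stay missing; observed cells come out with mean 0 and
    SD 1.  Raises :class:`ZeroVarianceError` for all-missing or constant rows
    (callers exclude such rows rather than propagate NaN).
    """
    x = np.asarray(gi50_row, dtype=float)
    observed = ~np.isnan(x)
    if observed.sum() < 2:
        raise ZeroVarianceError("need at least 2 observed GI50 values")
    if np.any(x[observed] <= 0.0):
        raise ValueError("GI50 values must be positive molar concentrations")
    neglog = np.full_like(x, np.nan)
    neglog[observed] = -np.log10(x[observed])
    sd = float(np.std(neglog[observed]))
    if sd == 0.0:
        raise ZeroVarianceError("constant GI50 row has zero variance")
    out = (neglog - float(np.mean(neglog[observed]))) / sd
    return out


def gi50_matrix_to_zscores(
    gi50: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Standardise every row of a GI50 matrix; returns (z matrix, excluded ids).

    Rows that are all-missing or have zero variance are dropped and listed in
    the excluded ids instead of being NaN-propagated.
    """
    rows, excluded = {}, []
    for nsc, row in gi50.iterrows():
        try:
            rows[nsc] = gi50_to_zscores(row)
        except ZeroVarianceError:
            excluded.append(nsc)
    z = pd.DataFrame.from_dict(rows, orient="index", columns=gi50.columns)
    return z, excluded


def categorize_response(z: float) -> str:
    """Map one observed z to resistant (<= -0.5) / sensitive (>= 0.5) / none.

    The +-0.5 boundaries belong to the outer classes.  Missing values must be
    excluded by the caller (they are not "no response").
    """
    if math.isnan(z):
        raise ValueError("missing z has no response category; exclude it upstream")
    if z <= -0.5:
        return RESISTANT
    if z >= 0.5:
        return SENSITIVE
    return NO_RESPONSE


@dataclass(frozen=True)
class ResponseProfile:
    """Per-cell-line counts of sensitive/resistant calls over a drug set."""

    cell_line: str
    n_sensitive: int
    n_resistant: int
    n_none: int
    n_missing: int

    @property
    def ratio(self) -> float | None:
        """resistance:sensitivity ratio; undefined when nothing is sensitive."""
        if self.n_sensitive == 0:
            return None
        return self.n_resistant / self.n_sensitive

    @property
    def neg_log10_ratio(self) -> float | None:
        r = self.ratio
        if r is None or r == 0.0:
            return None if r is None else math.inf
        return -math.log10(r)


def resistance_sensitivity_profile(
    matrix: DrugActivityMatrix,
    drug_subset: Callable[[pd.Series], bool] | None = None,
    exclude_tissues: Iterable[str] = (),
) -> list[ResponseProfile]:
    """Count sensitive/resistant compounds per cell line.

    ``drug_subset`` optionally restricts the drugs (e.g. FDA-approved only);
    ``exclude_tissues`` drops lines by tissue prefix (e.g. leukemias).
    """
    if len(matrix) == 0:
        raise ValueError("empty drug matrix")
    m = matrix if drug_subset is None else matrix.subset(drug_subset)
    if exclude_tissues:
        m = m.exclude_tissues(exclude_tissues)
    z = m.z.to_numpy(dtype=float)
    profiles = []
    for j, line in enumerate(m.cell_lines):
        col = z[:, j]
        missing = np.isnan(col)
        obs = col[~missing]
        profiles.append(
            ResponseProfile(
                cell_line=line,
                n_sensitive=int(np.sum(obs >= 0.5)),
                n_resistant=int(np.sum(obs <= -0.5)),
                n_none=int(np.sum((obs > -0.5) & (obs < 0.5))),
                n_missing=int(np.sum(missing)),
            )
        )
    return profiles


def ratio_fold_range(profiles: Sequence[ResponseProfile]) -> float:
    """max/min of the defined raw resistance:sensitivity ratios.

    The fold range is a ratio of ratios; lines with an undefined or zero
    ratio are skipped.
    """
    ratios = [p.ratio for p in profiles if p.ratio]
    if len(ratios) < 2:
        raise ValueError("need at least two lines with defined non-zero ratios")
    return max(ratios) / min(ratios)


def compare_ratio_profiles(
    all_profile: Sequence[ResponseProfile],
    subset_profile: Sequence[ResponseProfile],
) -> tuple[float, float]:
    """Pearson r (and two-tailed p) between two -log10 ratio profiles.

    Profiles are matched by cell line; lines where either ratio is undefined
    or zero are dropped.  p comes from the t transform with n-2 df.
    """
    a = {p.cell_line: p.neg_log10_ratio for p in all_profile}
    b = {p.cell_line: p.neg_log10_ratio for p in subset_profile}
    shared = [
        line
        for line in a
        if line in b
        and a[line] is not None
        and b[line] is not None
        and math.isfinite(a[line])
        and math.isfinite(b[line])
    ]
    if len(shared) < 3:
        raise ValueError("need at least 3 paired observed ratios")
    x = np.array([a[l] for l in shared])
    y = np.array([b[l] for l in shared])
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
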