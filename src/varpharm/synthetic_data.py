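"""Synthetic 60-cell-line panels with planted variant-drug effects.

The generator emulates the shape of an NCI-60-style screen: cell lines named
``TISSUE:NAME`` across nine tissue prefixes, a sparse variant
percent-conversion catalog whose levels come from the het/hom mixture
{50, 100}, SIFT/PolyPhen scores and change types covering every functional
category, and per-compound activity z-score rows.  Planted gene-drug pairs
shift the carrier lines' z by ``effect_sd`` (on the noise scale, before the
row is restandardised); planted reference-frequency variants get
panel:reference ratios in the enriched (>= 10) or depleted (<= 0.1) range
against a log-normal background centred on parity.

All randomness flows from the single explicit seed in the config; the same
config yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drug_response import DrugActivityMatrix, STATUS_CLINICAL, STATUS_FDA, STATUS_OTHER
from .frequency_enrichment import FrequencyComparison
from .io_formats import ChangeType, VariantLocus, VariantRecord
from .variant_drug_association import RESISTANCE, SENSITIVITY

__all__ = [
    "PlantedPair",
    "SimulationConfig",
    "GroundTruth",
    "simulate_panel",
    "simulate_reference_frequencies",
    "TISSUE_PREFIXES",
]

TISSUE_PREFIXES = ("BR", "CNS", "CO", "LC", "LE", "ME", "OV", "PR", "RE")

_MOA_CODES = ("A7", "Ds", "YK", "DNMT", "Tu", "Ho", "PKC", "Db", "STK")

# one pass through this list guarantees every functional category (and the
# non-functional classes) is represented in any catalog of >= 8 variants
_TYPE_CYCLE = (
    ChangeType.MISSENSE,
    ChangeType.SILENT,
    ChangeType.SPLICESENSE,
    ChangeType.MISSENSE,
    ChangeType.FRAMESHIFT,
    ChangeType.PREMATURE_STOP,
    ChangeType.NONFRAMESHIFT_INDEL,
    ChangeType.READ_THROUGH,
)


@dataclass(frozen=True)
class PlantedPair:
    """One planted gene-drug association."""

    gene: str
    nsc: str
    direction: str  # sensitivity | resistance
    effect_sd: float

    def __post_init__(self) -> None:
        if self.direction not in (SENSITIVITY, RESISTANCE):
            raise ValueError(f"direction must be sensitivity/resistance, got {self.direction}")
        if self.effect_sd < 0:
            raise ValueError("effect_sd must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Panel shape, planted effects, and the seed for all randomness."""

    n_cell_lines: int = 60
    tissue_prefixes: tuple[str, ...] = TISSUE_PREFIXES
    n_genes: int = 20
    n_variants_per_gene: int = 3
    n_drugs: int = 10
    carrier_rate: float = 0.08
    het_fraction: float = 0.6  # carriers are het (50%) vs hom (100%)
    planted_pairs: tuple[PlantedPair, ...] = ()
    planted_carrier_n: int = 8
    enriched_variants: tuple[tuple[str, float, float], ...] = ()
    n_reference_background: int = 1000
    background_log_sigma: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.carrier_rate <= 1.0):
            raise ValueError("carrier_rate must be in [0,1]")
        if not (0.0 <= self.het_fraction <= 1.0):
            raise ValueError("het_fraction must be in [0,1]")


@dataclass
class GroundTruth:
    """What was planted, as realised in the emitted catalog and matrix."""

    planted: list[dict] = field(default_factory=list)  # gene, nsc, direction, carriers
    responders: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    enrichment_labels: dict[str, str] = field(default_factory=dict)

    def planted_carriers(self, gene: str) -> frozenset[str]:
        for entry in self.planted:
            if entry["gene"] == gene:
                return entry["carriers"]
        raise KeyError(gene)


def _cell_line_names(config: SimulationConfig) -> list[str]:
    names = []
    counters = {p: 0 for p in config.tissue_prefixes}
    for i in range(config.n_cell_lines):
        prefix = config.tissue_prefixes[i % len(config.tissue_prefixes)]
        counters[prefix] += 1
        names.append(f"{prefix}:CL{counters[prefix]:02d}")
    return names


def simulate_panel(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[list[VariantRecord], DrugActivityMatrix, GroundTruth]:
    """Generate (variant catalog, drug z-score matrix, ground truth).

    Deterministic for a given config.  Background z rows are standard normal
    then restandardised per row (population SD); planted pairs shift the
    planted gene's carrier lines before that restandardisation.  Planted
    genes carry exactly ``planted_carrier_n`` carrier lines, spread over the
    gene's variants, and their variants are kept screen-eligible (missense,
    unflagged).
    """
    rng = np.random.default_rng(config.seed)
    lines = _cell_line_names(config)
    genes = [f"GENE{i + 1:02d}" for i in range(config.n_genes)]
    nscs = [f"{700000 + i}" for i in range(config.n_drugs)]

    planted_genes = {p.gene for p in config.planted_pairs}
    for p in config.planted_pairs:
        if p.gene not in genes:
            raise ValueError(f"planted gene {p.gene!r} not in the simulated panel")
        if p.nsc not in nscs:
            raise ValueError(f"planted drug {p.nsc!r} not in the simulated panel")

    # --- variant catalog -------------------------------------------------
    catalog: list[VariantRecord] = []
    truth = GroundTruth()
    gene_carriers: dict[str, frozenset[str]] = {}
    type_i = 0
    used_positions: set[int] = set()
    for gene in genes:
        planted = gene in planted_genes
        if planted:
            chosen = rng.choice(config.n_cell_lines, size=config.planted_carrier_n, replace=False)
            assignment = rng.integers(0, config.n_variants_per_gene, size=len(chosen))
            gene_carriers[gene] = frozenset(lines[i] for i in chosen)
        for v in range(config.n_variants_per_gene):
            if planted:
                change_type = ChangeType.MISSENSE
                carrier_idx = [int(c) for c, a in zip(chosen, assignment) if a == v]
            else:
                change_type = _TYPE_CYCLE[type_i % len(_TYPE_CYCLE)]
                type_i += 1
                carrier_idx = [
                    i
                    for i in range(config.n_cell_lines)
                    if rng.random() < config.carrier_rate
                ]
            pos = int(rng.integers(10_000, 100_000_000))
            while pos in used_positions:
                pos = int(rng.integers(10_000, 100_000_000))
            used_positions.add(pos)
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            percents = {
                lines[i]: (50.0 if rng.random() < config.het_fraction else 100.0)
                for i in carrier_idx
            }
            sift = polyphen = None
            if change_type is ChangeType.MISSENSE:
                sift = round(float(rng.random()), 3)
                polyphen = round(float(rng.random()), 3)
            present = (not planted) and rng.random() < 0.5
            catalog.append(
                VariantRecord(
                    gene=gene,
                    locus=VariantLocus(
                        chromosome=str(int(rng.integers(1, 23))),
                        position=pos,
                        ref_allele=str(ref),
                        alt_allele=str(alt),
                    ),
                    change_type=change_type,
                    aa_impact=f"{ref}{v + 1}{alt}" if change_type is ChangeType.MISSENSE else "",
                    sift=sift,
                    polyphen2=polyphen,
                    dbsnp_id=None,
                    freq_1000g=round(float(rng.uniform(0.001, 0.1)), 4) if present and rng.random() < 0.6 else None,
                    freq_esp5400=round(float(rng.uniform(0.001, 0.1)), 4) if present else None,
                    percent_conversion=percents,
                    in_segdup=(not planted) and rng.random() < 0.02,
                    multimap=(not planted) and rng.random() < 0.02,
                )
            )

    # --- drug activity matrix -------------------------------------------
    planted_by_nsc: dict[str, list[PlantedPair]] = {}
    for p in config.planted_pairs:
        planted_by_nsc.setdefault(p.nsc, []).append(p)
    z_rows = {}
    for nsc in nscs:
        z = rng.normal(0.0, config.noise_sd, size=config.n_cell_lines)
        for p in planted_by_nsc.get(nsc, ()):
            sign = 1.0 if p.direction == SENSITIVITY else -1.0
            for i, line in enumerate(lines):
                if line in gene_carriers[p.gene]:
                    z[i] += sign * p.effect_sd
        z = (z - z.mean()) / z.std()
        z_rows[nsc] = z
    z_df = pd.DataFrame.from_dict(z_rows, orient="index", columns=lines)
    status_cycle = (STATUS_FDA, STATUS_CLINICAL, STATUS_OTHER)
    drugs = pd.DataFrame(
        {
            "nsc": nscs,
            "name": [f"compound-{i + 1:02d}" for i in range(config.n_drugs)],
            "moa": [_MOA_CODES[i % len(_MOA_CODES)] for i in range(config.n_drugs)],
            "status": [status_cycle[i % 3] for i in range(config.n_drugs)],
        },
        index=pd.Index(nscs, name=None),
    )
    matrix = DrugActivityMatrix(drugs=drugs, z=z_df)

    # --- ground truth ----------------------------------------------------
    for p in config.planted_pairs:
        truth.planted.append(
            {
                "gene": p.gene,
                "nsc": p.nsc,
                "direction": p.direction,
                "effect_sd": p.effect_sd,
                "carriers": gene_carriers[p.gene],
            }
        )
    for nsc in nscs:
        row = z_df.loc[nsc]
        truth.responders[(nsc, SENSITIVITY)] = frozenset(row.index[row >= 0.5])
        truth.responders[(nsc, RESISTANCE)] = frozenset(row.index[row <= -0.5])
    return catalog, matrix, truth


def simulate_reference_frequencies(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[list[FrequencyComparison], dict[str, str]]:
    """Generate reference-frequency comparisons with planted enrichment.

    Background variants draw a reference frequency uniformly and a
    panel:reference ratio log-normally around parity
    (sigma = ``background_log_sigma``), so background ratios rarely reach the
    enriched (>= 10) or depleted (<= 0.1) gates.  Each entry of
    ``config.enriched_variants`` — (variant id, panel freq, ref freq) — is
    appended as given and labelled enriched or depleted by its true ratio.
    Returns (comparisons, labels) where labels maps planted variant ids to
    ``"enriched"``/``"depleted"``.
    """
    rng = np.random.default_rng(config.seed + 1)
    comparisons: list[FrequencyComparison] = []
    for i in range(config.n_reference_background):
        ref = float(rng.uniform(0.005, 0.2))
        ratio = float(np.exp(rng.normal(0.0, config.background_log_sigma)))
        comparisons.append(
            FrequencyComparison(
                variant_id=f"chr1:{1000 + i}_A_G",
                panel_freq=min(ref * ratio, 1.0),
                ref_freq=ref,
                functional=bool(rng.random() < 0.3),
            )
        )
    labels: dict[str, str] = {}
    for vid, panel_freq, ref_freq in config.enriched_variants:
        comparisons.append(
            FrequencyComparison(
                variant_id=vid,
                panel_freq=panel_freq,
                ref_freq=ref_freq,
                functional=True,
            )
        )
        ratio = panel_freq / ref_freq
        labels[vid] = "enriched" if ratio >= 1.0 else "depleted"
    return comparisons, labels
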