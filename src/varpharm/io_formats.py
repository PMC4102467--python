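"""Readers and writers for the tabular dialects used across the toolkit.

The interchange key for a variant is its positional identifier in the
``chr<label>:<position>_<ref>_<alt>`` dialect (e.g. ``chr17:7577610_T_C``).
Coordinates are 1-based and fully closed throughout; no 0-based conversion
happens anywhere.  Insertions and deletions use ``*`` as the reference token
and a ``+SEQ`` / ``-SEQ`` payload as the alternate token
(e.g. ``chr13:48916816_*_-ACTT`` deletes ``ACTT``).

On disk the canonical dialect is TSV.  Spreadsheet workbooks (two-sheet
variant-summation exports) are an optional writer, never a required reader.
Missing numeric cells are typed as unknown (``None``) and excluded from
statistics rather than imputed: zero-imputation would silently alter
SIFT/PolyPhen classification downstream.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "VariantLocus",
    "ChangeType",
    "VariantRecord",
    "VariantTableError",
    "parse_variant_identifier",
    "format_variant_identifier",
    "read_variant_table",
    "write_variant_table",
    "read_drug_table",
    "write_drug_table",
    "write_summation_workbook",
    "read_summation_workbook",
    "VARIANT_TABLE_COLUMNS",
    "DRUG_TABLE_COLUMNS",
]

_NUC = re.compile(r"^[ACGTN]+$", re.IGNORECASE)
_ID = re.compile(r"^chr(?P<chrom>[0-9XYM]+|MT):(?P<pos>\d+)_(?P<ref>[^_]+)_(?P<alt>[^_]+)$")


class VariantTableError(ValueError):
    """Schema or value error raised while reading a variant/drug table."""


@dataclass(frozen=True)
class VariantLocus:
    """A genomic change: chromosome, 1-based start, and allele tokens.

    Exactly one of substitution (plain ref and alt nucleotides), insertion
    (ref ``*``, alt ``+SEQ``) or deletion (ref ``*``, alt ``-SEQ``) holds.
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        kinds = sum([self.is_substitution, self.is_insertion, self.is_deletion])
        if kinds != 1:
            raise ValueError(
                f"alleles {self.ref_allele!r}/{self.alt_allele!r} are neither a "
                "substitution, an insertion (+SEQ) nor a deletion (-SEQ)"
            )

    @property
    def is_substitution(self) -> bool:
        return bool(_NUC.match(self.ref_allele)) and bool(_NUC.match(self.alt_allele))

    @property
    def is_insertion(self) -> bool:
        return (
            self.ref_allele == "*"
            and self.alt_allele.startswith("+")
            and bool(_NUC.match(self.alt_allele[1:]))
        )

    @property
    def is_deletion(self) -> bool:
        return (
            self.ref_allele == "*"
            and self.alt_allele.startswith("-")
            and bool(_NUC.match(self.alt_allele[1:]))
        )

    @property
    def indel_sequence(self) -> str | None:
        """Inserted or deleted nucleotides, or None for substitutions."""
        if self.is_substitution:
            return None
        return self.alt_allele[1:]

    def identifier(self) -> str:
        return format_variant_identifier(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.identifier()


def parse_variant_identifier(id_string: str) -> VariantLocus:
    """Parse a positional variant identifier into a :class:`VariantLocus`.

    >>> parse_variant_identifier("chr17:7577610_T_C")
    VariantLocus(chromosome='17', position=7577610, ref_allele='T', alt_allele='C')

    Raises
    ------
    ValueError
        If the string is malformed; the message names the offending token.
    """
    if ":" not in id_string:
        raise ValueError(f"variant identifier {id_string!r}: missing ':' separator")
    m = _ID.match(id_string.strip())
    if m is None:
        head, _, tail = id_string.partition(":")
        if not head.startswith("chr"):
            raise ValueError(f"variant identifier {id_string!r}: must start with 'chr'")
        parts = tail.split("_")
        if len(parts) < 3:
            raise ValueError(
                f"variant identifier {id_string!r}: expected "
                "'chr<label>:<position>_<ref>_<alt>', missing allele fields"
            )
        if not parts[0].isdigit():
            raise ValueError(
                f"variant identifier {id_string!r}: position {parts[0]!r} is not an integer"
            )
        raise ValueError(f"variant identifier {id_string!r}: malformed allele tokens")
    locus = VariantLocus(
        chromosome=m.group("chrom"),
        position=int(m.group("pos")),
        ref_allele=m.group("ref").upper() if m.group("ref") != "*" else "*",
        alt_allele=_canon_alt(m.group("alt")),
    )
    return locus


def _canon_alt(token: str) -> str:
    if token and token[0] in "+-":
        return token[0] + token[1:].upper()
    return token.upper()


def format_variant_identifier(locus: VariantLocus) -> str:
    """Format a locus back into its identifier; inverse of the parser."""
    return f"chr{locus.chromosome}:{locus.position}_{locus.ref_allele}_{locus.alt_allele}"


class ChangeType(str, Enum):
    """Variant consequence classes used for amino-acid-changing triage."""

    MISSENSE = "missense"
    SPLICESENSE = "splicesense"
    FRAMESHIFT = "frameshift"
    PREMATURE_STOP = "premature_stop"
    READ_THROUGH = "read_through"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    SILENT = "silent"
    OTHER = "other"

    @classmethod
    def parse(cls, text: str) -> "ChangeType":
        key = re.sub(r"[\s\-]+", "_", text.strip().lower())
        aliases = {
            "splicesence": "splicesense",  # spelling seen in exports
            "splice_sense": "splicesense",
            "premature_stop": "premature_stop",
            "nonsense": "premature_stop",
            "stop_gain": "premature_stop",
            "readthrough": "read_through",
            "stop_loss": "read_through",
            "non_frameshift_indel": "nonframeshift_indel",
            "nonframeshift_insertion": "nonframeshift_indel",
            "nonframeshift_deletion": "nonframeshift_indel",
            "synonymous": "silent",
        }
        key = aliases.get(key, key)
        try:
            return cls(key)
        except ValueError:
            return cls.OTHER


@dataclass
class VariantRecord:
    """One annotated exome variant with per-cell-line percent conversion.

    ``percent_conversion`` maps cell-line ids (``TISSUE:NAME``) to the percent
    of reads supporting the variant allele, in [0, 100]; a line not present in
    the mapping carries the variant at 0%.  ``sift``/``polyphen2`` and the
    population frequencies are ``None`` when unknown.
    """

    gene: str
    locus: VariantLocus
    change_type: ChangeType
    aa_impact: str = ""
    sift: float | None = None
    polyphen2: float | None = None
    dbsnp_id: str | None = None
    freq_1000g: float | None = None
    freq_esp5400: float | None = None
    percent_conversion: dict[str, float] = field(default_factory=dict)
    in_segdup: bool = False
    multimap: bool = False

    def __post_init__(self) -> None:
        for name in ("sift", "polyphen2", "freq_1000g", "freq_esp5400"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1] or unknown, got {v}")
        for line, pct in self.percent_conversion.items():
            if not (0.0 <= pct <= 100.0):
                raise ValueError(
                    f"percent conversion for {line} must be in [0,100], got {pct}"
                )

    @property
    def variant_id(self) -> str:
        return self.locus.identifier()

    def percent_in(self, cell_line: str) -> float:
        """Percent conversion in one line; absent lines carry 0."""
        return self.percent_conversion.get(cell_line, 0.0)

    def carriers(self, panel: Iterable[str] | None = None) -> frozenset[str]:
        """Cell lines with any conversion (>0); heterozygotes count."""
        lines = self.percent_conversion if panel is None else panel
        return frozenset(l for l in lines if self.percent_in(l) > 0.0)

    def absent_from_normals(self) -> bool:
        """True when both reference-population frequency cells are missing or 0."""
        return (self.freq_1000g is None or self.freq_1000g == 0.0) and (
            self.freq_esp5400 is None or self.freq_esp5400 == 0.0
        )


VARIANT_TABLE_COLUMNS = [
    "gene",
    "variant_id",
    "change_type",
    "aa_impact",
    "dbsnp_id",
    "sift",
    "polyphen2",
    "freq_1000g",
    "freq_esp5400",
    "in_segdup",
    "multimap",
]

DRUG_TABLE_COLUMNS = ["nsc", "name", "moa", "status"]

_MISSING = {"", "na", "nan", "none", "null", "-", "."}


def _parse_float(cell: str, *, row: int, column: str) -> float | None:
    if cell.strip().lower() in _MISSING:
        return None
    try:
        return float(cell)
    except ValueError:
        raise VariantTableError(
            f"row {row}: column {column!r}: {cell!r} is not numeric"
        ) from None


def _parse_flag(cell: str) -> bool:
    return cell.strip().lower() in {"1", "true", "yes", "y", "t"}


def _is_cell_line_column(name: str) -> bool:
    # panel columns carry a tissue prefix, e.g. "BR:MCF7", "ME:LOXIMVI"
    return ":" in name


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a TSV variant table into :class:`VariantRecord` objects.

    The header must contain the mandatory columns
    (:data:`VARIANT_TABLE_COLUMNS`); every column containing ``:`` is taken as
    a cell-line percent-conversion column; other unknown columns are ignored.
    Missing SIFT/PolyPhen/frequency cells become ``None``, never 0.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in VARIANT_TABLE_COLUMNS if c not in header]
        if missing:
            raise VariantTableError(
                f"{path.name}: missing mandatory column(s): {', '.join(missing)}"
            )
        cell_lines = [c for c in header if _is_cell_line_column(c)]
        records: list[VariantRecord] = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            percents: dict[str, float] = {}
            for line in cell_lines:
                val = _parse_float(row[line] or "", row=i, column=line)
                if val is None:
                    val = 0.0
                if not (0.0 <= val <= 100.0):
                    raise VariantTableError(
                        f"row {i}: percent conversion {val} for {line!r} "
                        "outside [0,100]"
                    )
                if val > 0.0:
                    percents[line] = val
            records.append(
                VariantRecord(
                    gene=row["gene"].strip(),
                    locus=parse_variant_identifier(row["variant_id"]),
                    change_type=ChangeType.parse(row["change_type"]),
                    aa_impact=row["aa_impact"].strip(),
                    dbsnp_id=row["dbsnp_id"].strip() or None
                    if row["dbsnp_id"].strip().lower() not in _MISSING
                    else None,
                    sift=_parse_float(row["sift"], row=i, column="sift"),
                    polyphen2=_parse_float(row["polyphen2"], row=i, column="polyphen2"),
                    freq_1000g=_parse_float(row["freq_1000g"], row=i, column="freq_1000g"),
                    freq_esp5400=_parse_float(
                        row["freq_esp5400"], row=i, column="freq_esp5400"
                    ),
                    percent_conversion=percents,
                    in_segdup=_parse_flag(row["in_segdup"]),
                    multimap=_parse_flag(row["multimap"]),
                )
            )
    return records


def write_variant_table(
    records: Sequence[VariantRecord],
    path: str | Path,
    cell_lines: Sequence[str] | None = None,
) -> None:
    """Write records as TSV; inverse of :func:`read_variant_table`."""
    if cell_lines is None:
        seen: dict[str, None] = {}
        for rec in records:
            for line in rec.percent_conversion:
                seen.setdefault(line)
        cell_lines = list(seen)
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(VARIANT_TABLE_COLUMNS + list(cell_lines))
        for rec in records:
            writer.writerow(
                [
                    rec.gene,
                    rec.variant_id,
                    rec.change_type.value,
                    rec.aa_impact,
                    rec.dbsnp_id or "",
                    "" if rec.sift is None else repr(rec.sift),
                    "" if rec.polyphen2 is None else repr(rec.polyphen2),
                    "" if rec.freq_1000g is None else repr(rec.freq_1000g),
                    "" if rec.freq_esp5400 is None else repr(rec.freq_esp5400),
                    int(rec.in_segdup),
                    int(rec.multimap),
                ]
                + [repr(rec.percent_in(line)) for line in cell_lines]
            )


def read_drug_table(path: str | Path):
    """Read a TSV drug table into a :class:`~varpharm.drug_response.DrugActivityMatrix`.

    Columns: ``nsc, name, moa, status`` then per-cell-line z-score columns
    (tissue-prefixed).  Missing z cells stay missing (NaN).
    """
    import pandas as pd

    from .drug_response import DrugActivityMatrix

    df = pd.read_csv(path, sep="\t", dtype={"nsc": str})
    missing = [c for c in DRUG_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(
            f"{Path(path).name}: missing mandatory column(s): {', '.join(missing)}"
        )
    cell_lines = [c for c in df.columns if _is_cell_line_column(c)]
    meta_cols = [c for c in df.columns if c not in cell_lines]
    z = df[cell_lines].astype(float)
    z.index = df["nsc"]
    return DrugActivityMatrix(drugs=df[meta_cols].set_index("nsc", drop=False), z=z)


def write_drug_table(matrix, path: str | Path) -> None:
    """Write a :class:`~varpharm.drug_response.DrugActivityMatrix` as TSV."""
    out = matrix.drugs.reset_index(drop=True).copy()
    z = matrix.z.reset_index(drop=True)
    for col in z.columns:
        out[col] = z[col].values
    out.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Summation workbook: two sheets/sections named "AA Change" and
# "Prot. Func. Affecting AA Change", per-variant rows, a per-gene Summary row,
# and a closing Totals row for the multi-gene burden pattern.
# ---------------------------------------------------------------------------

SHEET_ALL = "AA Change"
SHEET_FUNCTIONAL = "Prot. Func. Affecting AA Change"
_SUMMATION_META = ["gene", "variant_id", "aa_impact"]


def _summation_rows(table) -> list[list]:
    rows: list[list] = []
    for profile in table.profiles:
        for vid, aa, percents in profile.variant_rows():
            rows.append([profile.gene, vid, aa] + list(percents))
        rows.append([profile.gene, "Summary", ""] + list(profile.summary))
    rows.append(["", "Totals", ""] + list(table.totals))
    return rows


def write_summation_workbook(result, path: str | Path) -> None:
    """Write a two-sheet variant-summation workbook.

    ``result`` is a :class:`~varpharm.variant_summation.SummationPair` holding
    both the all-amino-acid-changing table and the
    function-affecting-and-absent subset.  ``.xlsx`` paths get a real
    spreadsheet (percentages displayed with 1 decimal); any other suffix gets
    a sectioned TSV with ``# sheet:`` markers.  An empty gene set yields a
    headers-only workbook.
    """
    path = Path(path)
    sheets = [(SHEET_ALL, result.all_aa_changing), (SHEET_FUNCTIONAL, result.function_affecting)]
    if path.suffix.lower() == ".xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        wb.remove(wb.active)
        for name, table in sheets:
            ws = wb.create_sheet(title=name)
            ws.append(_SUMMATION_META + list(table.cell_lines))
            for row in _summation_rows(table):
                ws.append(row)
                for cell in ws[ws.max_row][len(_SUMMATION_META):]:
                    cell.number_format = "0.0"
        wb.save(path)
    else:
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            for name, table in sheets:
                writer.writerow([f"# sheet: {name}"])
                writer.writerow(_SUMMATION_META + list(table.cell_lines))
                for row in _summation_rows(table):
                    writer.writerow(row)


def read_summation_workbook(path: str | Path):
    """Read a workbook written by :func:`write_summation_workbook`.

    Returns a :class:`~varpharm.variant_summation.SummationPair`; numeric
    values round-trip up to cell formatting.
    """
    from .variant_summation import GeneVariantProfile, SummationPair, SummationTable

    path = Path(path)
    raw_sheets: dict[str, list[list[str]]] = {}
    if path.suffix.lower() == ".xlsx":
        from openpyxl import load_workbook

        wb = load_workbook(path, read_only=True)
        for name in wb.sheetnames:
            raw_sheets[name] = [
                ["" if c is None else str(c) for c in row]
                for row in wb[name].iter_rows(values_only=True)
            ]
    else:
        current: list[list[str]] | None = None
        with path.open(newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if row and row[0].startswith("# sheet: "):
                    current = raw_sheets.setdefault(row[0][len("# sheet: "):], [])
                elif current is not None:
                    current.append(row)

    def build(rows: list[list[str]], flag: str) -> SummationTable:
        header, body = rows[0], rows[1:]
        cell_lines = header[len(_SUMMATION_META):]
        profiles: list[GeneVariantProfile] = []
        pending: list[tuple[str, str, list[float]]] = []
        for row in body:
            gene, vid, aa = row[0], row[1], row[2]
            values = [float(v) for v in row[3:]]
            if vid == "Totals":
                continue
            if vid == "Summary":
                profiles.append(
                    GeneVariantProfile(
                        gene=gene,
                        cell_lines=tuple(cell_lines),
                        variants=tuple((v, a, tuple(p)) for v, a, p in pending),
                    )
                )
                pending = []
            else:
                pending.append((vid, aa, values))
        return SummationTable(
            profiles=tuple(profiles), cell_lines=tuple(cell_lines), subset_flag=flag
        )

    return SummationPair(
        all_aa_changing=build(raw_sheets[SHEET_ALL], "all_aa_changing"),
        function_affecting=build(raw_sheets[SHEET_FUNCTIONAL], "function_affecting_and_absent"),
    )
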