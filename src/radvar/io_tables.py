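"""Occurrence-chart, metadata, sequence and lineage I/O.

The canonical on-disk chart format is a TSV with columns
``asv_id, sequence, taxon, confidence`` followed by one column per
specimen holding absolute read counts.  A multi-sheet spreadsheet
importer handles the published supplementary layout (one sheet per
order, "full-length ASVs" / "V4-only" pairs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PR2_RANKS",
    "POLYCYSTINE_ORDERS",
    "Lineage",
    "OccurrenceChart",
    "SpecimenMeta",
    "ChartFormatError",
    "parse_lineage",
    "read_occurrence_chart",
    "write_occurrence_chart",
    "read_fasta",
    "write_fasta",
    "read_specimen_meta",
    "write_specimen_meta",
]

#: Default 8-rank PR2-style scheme (v4.x ordering).
PR2_RANKS: tuple[str, ...] = (
    "Domain",
    "Supergroup",
    "Division",
    "Class",
    "Order",
    "Family",
    "Genus",
    "Species",
)

POLYCYSTINE_ORDERS: frozenset[str] = frozenset({"Collodaria", "Nassellaria", "Spumellaria"})

UNASSIGNED = "unassigned"

_IUPAC = frozenset("ACGTRYSWKMBDHVN")

_META_COLUMNS = ("asv_id", "sequence", "taxon", "confidence")


class ChartFormatError(ValueError):
    """Raised when an on-disk chart violates the expected layout."""


@dataclass(frozen=True)
class Lineage:
    """An ordered ranked taxonomy path parsed from a lineage string."""

    ranks: tuple[tuple[str, str], ...]

    def get(self, rank_name: str) -> str:
        """Taxon at ``rank_name``; total lookup — missing ranks map to ``unassigned``."""
        for name, taxon in self.ranks:
            if name == rank_name:
                return taxon
        return UNASSIGNED

    @property
    def family(self) -> str:
        return self.get("Family")

    @property
    def order(self) -> str:
        return self.get("Order")

    def __str__(self) -> str:
        taxa = [t for _, t in self.ranks]
        while taxa and taxa[-1] == UNASSIGNED:
            taxa.pop()
        return ";".join(taxa)


def parse_lineage(taxon_string: str, scheme: Sequence[str] = PR2_RANKS) -> Lineage:
    """Positionally assign semicolon-delimited fields to ``scheme`` ranks.

    Total function: ragged or empty strings yield ``unassigned`` for the
    trailing ranks; surplus fields beyond the scheme are dropped.
    """
    fields = [f.strip() for f in taxon_string.split(";")] if taxon_string else []
    fields = [f for f in fields if f != ""] if fields == [""] else fields
    out = []
    for i, rank in enumerate(scheme):
        taxon = fields[i].strip() if i < len(fields) and fields[i].strip() else UNASSIGNED
        out.append((rank, taxon))
    return Lineage(ranks=tuple(out))


@dataclass(frozen=True)
class SpecimenMeta:
    """Per-specimen morphological metadata and filter exception flag."""

    specimen_id: str
    morphotaxon: str
    morph_rank: str  # species | genus | family | order | indeterminate
    order_name: str
    family_name: str = "unknown"
    relaxed_filter: bool = False

    def __post_init__(self) -> None:
        allowed = {"species", "genus", "family", "order", "indeterminate"}
        if self.morph_rank not in allowed:
            raise ValueError(f"morph_rank {self.morph_rank!r} not in {sorted(allowed)}")
        if self.relaxed_filter and not (
            self.family_name == "unknown" or self.morph_rank == "indeterminate"
        ):
            raise ValueError(
                f"specimen {self.specimen_id}: relaxed_filter requires family 'unknown' "
                "or indeterminate morph_rank"
            )


@dataclass
class OccurrenceChart:
    """ASV × specimen absolute read counts with per-ASV annotations.

    ``counts`` is indexed by ``asv_id`` with one integer column per
    specimen.  Relative abundances are always derived, never stored.
    """

    counts: pd.DataFrame
    sequences: dict[str, str]
    lineage: dict[str, Lineage]
    confidence: dict[str, float]
    merged_v4: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate asv_ids: {dupes}")
        if self.counts.columns.has_duplicates:
            dupes = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate specimen_ids: {dupes}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")
        for asv in self.counts.index:
            seq = self.sequences.get(asv, "")
            if len(seq) < 1:
                raise ValueError(f"ASV {asv} lacks a sequence")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def subset_asvs(self, asvs: Iterable[str]) -> "OccurrenceChart":
        keep = [a for a in self.counts.index if a in set(asvs)]
        return self._rebuild(self.counts.loc[keep])

    def subset_specimens(self, specimens: Iterable[str]) -> "OccurrenceChart":
        keep = [s for s in self.counts.columns if s in set(specimens)]
        return self._rebuild(self.counts[keep])

    def with_counts(self, counts: pd.DataFrame) -> "OccurrenceChart":
        return self._rebuild(counts)

    def _rebuild(self, counts: pd.DataFrame) -> "OccurrenceChart":
        asvs = set(counts.index)
        return OccurrenceChart(
            counts=counts.copy(),
            sequences={a: s for a, s in self.sequences.items() if a in asvs},
            lineage={a: l for a, l in self.lineage.items() if a in asvs},
            confidence={a: c for a, c in self.confidence.items() if a in asvs},
            merged_v4=frozenset(a for a in self.merged_v4 if a in asvs),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OccurrenceChart):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.sequences == other.sequences
            and {a: str(l) for a, l in self.lineage.items()}
            == {a: str(l) for a, l in other.lineage.items()}
            and self.confidence == other.confidence
            and self.merged_v4 == other.merged_v4
        )


def _validate_count(raw: object, row: str, col: str) -> int:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return 0
    if isinstance(raw, str):
        raw = raw.strip()
        if raw == "":
            return 0
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ChartFormatError(f"non-numeric count at row {row!r}, column {col!r}: {raw!r}")
    if value != int(value):
        raise ChartFormatError(f"non-integer count at row {row!r}, column {col!r}: {raw!r}")
    if value < 0:
        raise ChartFormatError(f"negative count at row {row!r}, column {col!r}: {raw!r}")
    return int(value)


def _clip_confidence(asv: str, value: float) -> float:
    if value < 0.0 or value > 1.0:
        warnings.warn(
            f"confidence {value} for ASV {asv} outside [0,1]; clipping", stacklevel=3
        )
        return min(max(value, 0.0), 1.0)
    return value


def _chart_from_records(
    records: list[tuple[str, str, str, float]],
    count_rows: list[list[int]],
    specimen_ids: list[str],
    merged: set[str],
    scheme: Sequence[str],
) -> OccurrenceChart:
    asv_ids = [r[0] for r in records]
    counts = pd.DataFrame(
        count_rows, index=pd.Index(asv_ids, name="asv_id"), columns=specimen_ids, dtype=np.int64
    )
    return OccurrenceChart(
        counts=counts,
        sequences={r[0]: r[1] for r in records},
        lineage={r[0]: parse_lineage(r[2], scheme) for r in records},
        confidence={r[0]: _clip_confidence(r[0], r[3]) for r in records},
        merged_v4=frozenset(merged),
    )


def read_occurrence_chart(
    path: str | Path,
    dialect: str = "tsv",
    scheme: Sequence[str] = PR2_RANKS,
) -> OccurrenceChart:
    """Read a chart from TSV (canonical) or the supplementary xlsx layout.

    All rows are retained, including ASVs below any presence threshold;
    empty cells become count 0.  Rows labelled ``merged`` in the ASV_ID
    column (the V4-only sheets) are kept and flagged via ``merged_v4``
    under a generated unique identifier.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_chart_tsv(path, scheme)
    if dialect == "s1data_xlsx":
        return _read_chart_xlsx(path, scheme)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_chart_tsv(path: Path, scheme: Sequence[str]) -> OccurrenceChart:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    header = [c.strip() for c in raw.columns]
    for i, expected in enumerate(_META_COLUMNS):
        if i >= len(header) or header[i].lower() != expected:
            found = header[i] if i < len(header) else "<missing>"
            raise ChartFormatError(
                f"expected column {i + 1} to be {expected!r}, found {found!r}"
            )
    specimen_ids = header[len(_META_COLUMNS):]
    records: list[tuple[str, str, str, float]] = []
    count_rows: list[list[int]] = []
    merged: set[str] = set()
    n_merged = 0
    for _, row in raw.iterrows():
        asv_id = row.iloc[0].strip()
        if asv_id.lower() == "merged":
            n_merged += 1
            asv_id = f"merged_{n_merged:04d}"
            merged.add(asv_id)
        seq = row.iloc[1].strip().upper()
        taxon = row.iloc[2].strip()
        conf_raw = row.iloc[3].strip()
        try:
            conf = float(conf_raw) if conf_raw else 0.0
        except ValueError:
            raise ChartFormatError(f"non-numeric confidence for ASV {asv_id!r}: {conf_raw!r}")
        counts = [
            _validate_count(row.iloc[len(_META_COLUMNS) + j], asv_id, s)
            for j, s in enumerate(specimen_ids)
        ]
        records.append((asv_id, seq, taxon, conf))
        count_rows.append(counts)
    return _chart_from_records(records, count_rows, specimen_ids, merged, scheme)


def _read_chart_xlsx(path: Path, scheme: Sequence[str]) -> OccurrenceChart:
    """Importer for the multi-sheet supplementary workbook layout.

    Sheets are concatenated; per-sheet specimen columns are merged into a
    single specimen axis (a specimen appears on one order's sheet only).
    By default only "full-length" sheets are read; V4-only sheets are
    available through :func:`read_s1_sheets`.
    """
    import openpyxl

    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    full_sheets = [n for n in wb.sheetnames if "v4" not in n.lower()]
    return _read_xlsx_sheets(wb, full_sheets or wb.sheetnames, scheme)


def read_s1_sheets(
    path: str | Path,
    sheet_names: Sequence[str],
    scheme: Sequence[str] = PR2_RANKS,
) -> OccurrenceChart:
    """Read a specific subset of sheets from a supplementary-layout workbook."""
    import openpyxl

    wb = openpyxl.load_workbook(Path(path), read_only=True, data_only=True)
    return _read_xlsx_sheets(wb, list(sheet_names), scheme)


def _read_xlsx_sheets(wb, sheet_names: list[str], scheme: Sequence[str]) -> OccurrenceChart:
    records: list[tuple[str, str, str, float]] = []
    rows_by_asv: dict[str, dict[str, int]] = {}
    specimen_ids: list[str] = []
    merged: set[str] = set()
    n_merged = 0
    for sheet_name in sheet_names:
        ws = wb[sheet_name]
        rows = ws.iter_rows(values_only=True)
        try:
            header = next(rows)
        except StopIteration:
            continue
        header = [str(h).strip() if h is not None else "" for h in header]
        if len(header) < 5:
            raise ChartFormatError(f"sheet {sheet_name!r}: fewer than 5 columns")
        sheet_specimens = [h for h in header[4:] if h]
        for s in sheet_specimens:
            if s not in specimen_ids:
                specimen_ids.append(s)
        for raw_row in rows:
            if raw_row is None or raw_row[0] is None or str(raw_row[0]).strip() == "":
                continue
            asv_id = str(raw_row[0]).strip()
            if asv_id.lower() == "merged":
                n_merged += 1
                asv_id = f"merged_{n_merged:04d}"
                merged.add(asv_id)
            seq = str(raw_row[1]).strip().upper() if raw_row[1] is not None else ""
            taxon = str(raw_row[2]).strip() if raw_row[2] is not None else ""
            conf = float(raw_row[3]) if raw_row[3] not in (None, "") else 0.0
            records.append((asv_id, seq, taxon, conf))
            cells = {}
            for j, s in enumerate(sheet_specimens):
                raw = raw_row[4 + j] if 4 + j < len(raw_row) else None
                cells[s] = _validate_count(raw, asv_id, s)
            rows_by_asv[asv_id] = cells
    count_rows = [
        [rows_by_asv[r[0]].get(s, 0) for s in specimen_ids] for r in records
    ]
    return _chart_from_records(records, count_rows, specimen_ids, merged, scheme)


def write_occurrence_chart(chart: OccurrenceChart, path: str | Path) -> None:
    """Write the canonical TSV; ``read(write(chart)) == chart``."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_META_COLUMNS + tuple(chart.specimen_ids)) + "\n")
        for asv in chart.asv_ids:
            label = "merged" if asv in chart.merged_v4 else asv
            row = [
                label,
                chart.sequences[asv],
                str(chart.lineage[asv]),
                repr(chart.confidence[asv]),
            ]
            row += [str(int(c)) for c in chart.counts.loc[asv]]
            fh.write("\t".join(row) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Order-preserving FASTA reader with uppercase normalization."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    dupes: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            dupes.append(rec.id)
            continue
        out[rec.id] = str(rec.seq).upper()
    if dupes:
        raise ValueError(f"duplicate FASTA ids: {dupes}")
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_META_TSV_COLUMNS = (
    "specimen_id",
    "morphotaxon",
    "morph_rank",
    "order",
    "family",
    "relaxed_filter",
)


def read_specimen_meta(path: str | Path) -> dict[str, SpecimenMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ChartFormatError(f"specimen metadata missing columns: {missing}")
    out: dict[str, SpecimenMeta] = {}
    for _, row in df.iterrows():
        m = SpecimenMeta(
            specimen_id=row["specimen_id"],
            morphotaxon=row["morphotaxon"],
            morph_rank=row["morph_rank"],
            order_name=row["order"],
            family_name=row["family"] or "unknown",
            relaxed_filter=row["relaxed_filter"].strip().lower() in {"1", "true", "yes"},
        )
        if m.specimen_id in out:
            raise ChartFormatError(f"duplicate specimen_id {m.specimen_id!r}")
        out[m.specimen_id] = m
    return out


def write_specimen_meta(meta: Mapping[str, SpecimenMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_META_TSV_COLUMNS) + "\n")
        for m in meta.values():
            fh.write(
                "\t".join(
                    [
                        m.specimen_id,
                        m.morphotaxon,
                        m.morph_rank,
                        m.order_name,
                        m.family_name,
                        "true" if m.relaxed_filter else "false",
                    ]
                )
                + "\n"
            )
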