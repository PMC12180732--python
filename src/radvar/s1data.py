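"""Loader for the published supplementary occurrence workbook.

The workbook itself is not redistributed here; place it (or a TSV export)
under ``data/s1/`` to enable the quantitative reproduction targets:

* ``data/s1/s1_data.xlsx`` — the original multi-sheet workbook, or
* ``data/s1/chart_full_length.tsv`` — canonical TSV of the full-length
  sheets (plus optional ``data/s1/meta.tsv``).

Specimen metadata is reconstructed from the specimen column names, which
follow a ``Genus-species-NN`` pattern (e.g. ``Collosphaera-huxleyi-01``),
unless an explicit ``meta.tsv`` is provided.  Because the deposited chart
only includes ASVs already matching each specimen's family assignment,
the per-specimen expected family is recovered as the modal lineage family
among that specimen's ASVs.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

from radvar.io_tables import (
    OccurrenceChart,
    SpecimenMeta,
    read_occurrence_chart,
    read_specimen_meta,
)

__all__ = ["find_s1_data", "load_s1_bundle", "meta_from_specimen_names"]

_GENUS_LEVEL_TOKENS = {"sp", "spp", "sp.", "spp."}


def find_s1_data(repo_root: str | Path) -> Path | None:
    """Locate a usable supplementary-data file under ``<root>/data/s1``."""
    base = Path(repo_root) / "data" / "s1"
    for name in ("chart_full_length.tsv", "s1_data.xlsx", "pone.0326053.s008.xlsx"):
        candidate = base / name
        if candidate.exists():
            return candidate
    return None


def _morphotaxon_from_column(column: str) -> tuple[str, str]:
    """(morphotaxon, morph_rank) from a ``Genus-species-NN`` column name."""
    parts = column.split("-")
    if parts and parts[-1].isdigit():
        parts = parts[:-1]
    name = " ".join(parts)
    lowered = [p.lower() for p in parts]
    if any(t in lowered for t in ("juvenile", "naked", "unknown")):
        return name, "indeterminate"
    if len(parts) >= 2 and lowered[1] not in _GENUS_LEVEL_TOKENS:
        return name, "species"
    if len(parts) == 1:
        return name, "genus"
    return name, "genus"


def meta_from_specimen_names(chart: OccurrenceChart) -> dict[str, SpecimenMeta]:
    """Reconstruct specimen metadata from column names and ASV lineages."""
    meta: dict[str, SpecimenMeta] = {}
    for s in chart.specimen_ids:
        morphotaxon, rank = _morphotaxon_from_column(s)
        col = chart.counts[s]
        fams = Counter()
        orders = Counter()
        for a in col.index[col > 0]:
            lin = chart.lineage[a]
            fams[lin.family] += 1
            orders[lin.order] += 1
        family = fams.most_common(1)[0][0] if fams else "unknown"
        order = orders.most_common(1)[0][0] if orders else "unknown"
        relaxed = rank == "indeterminate"
        meta[s] = SpecimenMeta(
            specimen_id=s,
            morphotaxon=morphotaxon,
            morph_rank=rank,
            order_name=order,
            family_name="unknown" if relaxed else family,
            relaxed_filter=relaxed,
        )
    return meta


def load_s1_bundle(path: str | Path) -> tuple[OccurrenceChart, dict[str, SpecimenMeta]]:
    """Load the full-length occurrence chart plus reconstructed metadata."""
    path = Path(path)
    if path.suffix == ".xlsx":
        chart = read_occurrence_chart(path, dialect="s1data_xlsx")
    else:
        chart = read_occurrence_chart(path, dialect="tsv")
    meta_path = path.parent / "meta.tsv"
    if meta_path.exists():
        meta = read_specimen_meta(meta_path)
    else:
        meta = meta_from_specimen_names(chart)
    return chart, meta
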