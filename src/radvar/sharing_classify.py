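"""Dominant-ASV sets, shared-ASV prevalence, and the three-way
intraspecies variation classification."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from radvar.io_tables import OccurrenceChart, SpecimenMeta

__all__ = [
    "Category",
    "DominantSet",
    "PrevalenceRecord",
    "VariationCategory",
    "dominant_set",
    "asv_prevalence",
    "classify_morphospecies",
    "classify_all",
]


class Category(str, Enum):
    SHARED_DOMINANT = "SHARED_DOMINANT"
    SHARED_ASV_DIFFERENT_DOMINANTS = "SHARED_ASV_DIFFERENT_DOMINANTS"
    NO_UNIVERSAL_ASV = "NO_UNIVERSAL_ASV"


@dataclass(frozen=True)
class DominantSet:
    specimen_id: str
    dominant_asvs: frozenset[str]  # singleton except under exact ties
    dominant_share: float

    @property
    def tied(self) -> bool:
        return len(self.dominant_asvs) > 1


@dataclass(frozen=True)
class PrevalenceRecord:
    asv_id: str
    n_specimens_present: int
    pct_specimens: float
    total_reads: int


@dataclass(frozen=True)
class VariationCategory:
    morphospecies: str
    n_specimens: int
    category: Category


def dominant_set(chart: OccurrenceChart, specimen_id: str) -> DominantSet:
    """ASVs attaining the specimen's maximum read count (ties preserved)."""
    if specimen_id not in chart.counts.columns:
        raise KeyError(f"unknown specimen {specimen_id!r}")
    col = chart.counts[specimen_id]
    total = int(col.sum())
    if total == 0:
        raise ValueError(f"specimen {specimen_id} has no reads")
    top = int(col.max())
    winners = frozenset(col.index[col == top])
    return DominantSet(
        specimen_id=specimen_id,
        dominant_asvs=winners,
        dominant_share=top / total,
    )


def asv_prevalence(
    chart: OccurrenceChart,
    specimens: Sequence[str],
    min_reads_presence: int = 3,
) -> list[PrevalenceRecord]:
    """Per-ASV presence prevalence over a specimen subset.

    Presence uses the same >= ``min_reads_presence`` rule as vetting;
    total reads are summed over the subset.  ASVs with zero reads in the
    whole subset are omitted.
    """
    if not specimens:
        raise ValueError("empty specimen subset")
    missing = [s for s in specimens if s not in chart.counts.columns]
    if missing:
        raise KeyError(f"unknown specimens: {missing}")
    sub = chart.counts[list(specimens)]
    records = []
    n = len(specimens)
    for asv in sub.index:
        row = sub.loc[asv]
        total = int(row.sum())
        if total == 0:
            continue
        present = int((row >= min_reads_presence).sum())
        records.append(
            PrevalenceRecord(
                asv_id=asv,
                n_specimens_present=present,
                pct_specimens=present / n,
                total_reads=total,
            )
        )
    return records


def _species_specimens(
    meta: Mapping[str, SpecimenMeta], morphospecies: str, chart: OccurrenceChart
) -> list[str]:
    return [
        s
        for s in chart.specimen_ids
        if s in meta
        and meta[s].morphotaxon == morphospecies
        and meta[s].morph_rank == "species"
    ]


def classify_morphospecies(
    chart: OccurrenceChart,
    meta: Mapping[str, SpecimenMeta],
    morphospecies: str,
    min_reads_presence: int = 3,
) -> VariationCategory:
    """Three-way classification of a morphospecies' ASV sharing structure.

    SHARED_DOMINANT: one ASV is in every specimen's dominant set.
    SHARED_ASV_DIFFERENT_DOMINANTS: otherwise, some ASV is present
    (>= ``min_reads_presence`` reads) in every specimen.
    NO_UNIVERSAL_ASV: otherwise.  Requires >= 2 species-level specimens.
    """
    specs = _species_specimens(meta, morphospecies, chart)
    if len(specs) < 2:
        raise ValueError(
            f"morphospecies {morphospecies!r} unclassifiable: "
            f"{len(specs)} species-level specimen(s) in chart"
        )
    dom_sets = [dominant_set(chart, s).dominant_asvs for s in specs]
    shared_dominant = frozenset.intersection(*dom_sets)
    if shared_dominant:
        cat = Category.SHARED_DOMINANT
    else:
        sub = chart.counts[specs]
        universal = (sub >= min_reads_presence).all(axis=1)
        cat = (
            Category.SHARED_ASV_DIFFERENT_DOMINANTS
            if bool(universal.any())
            else Category.NO_UNIVERSAL_ASV
        )
    return VariationCategory(
        morphospecies=morphospecies, n_specimens=len(specs), category=cat
    )


def classify_all(
    chart: OccurrenceChart,
    meta: Mapping[str, SpecimenMeta],
    min_reads_presence: int = 3,
) -> list[VariationCategory]:
    """Classify every morphospecies with >= 2 species-level specimens."""
    names: dict[str, int] = {}
    for s in chart.specimen_ids:
        m = meta.get(s)
        if m is not None and m.morph_rank == "species":
            names[m.morphotaxon] = names.get(m.morphotaxon, 0) + 1
    return [
        classify_morphospecies(chart, meta, name, min_reads_presence)
        for name in sorted(names)
        if names[name] >= 2
    ]
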