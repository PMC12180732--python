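"""ASV- and specimen-level inclusion rules with an auditable report.

Filter order: taxonomic consistency (with the naked/juvenile exception),
then per-cell presence zeroing, then the global keep-ASVs-seen-somewhere
rule, then removal of specimens with too few surviving reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from radvar.io_tables import POLYCYSTINE_ORDERS, OccurrenceChart, SpecimenMeta

__all__ = ["VettingConfig", "VettingReport", "filter_taxonomy_consistency", "apply_count_thresholds", "vet_dataset"]


@dataclass(frozen=True)
class VettingConfig:
    """Thresholds controlling chart vetting.

    ``strict_global_rule`` re-evaluates the keep-ASVs-seen-somewhere rule
    after specimen removal (the default evaluates it before).
    ``specimen_reads_before_zeroing`` counts a specimen's surviving reads
    before the per-cell presence zeroing instead of after.
    """

    min_reads_presence: int = 3
    min_specimen_reads: int = 5
    min_asv_reads_somewhere: int = 3
    min_confidence: float = 0.3
    strict_global_rule: bool = False
    specimen_reads_before_zeroing: bool = False

    def __post_init__(self) -> None:
        for name in ("min_reads_presence", "min_specimen_reads", "min_asv_reads_somewhere"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.min_confidence <= 1.0):
            raise ValueError("min_confidence must be in [0,1]")


@dataclass
class VettingReport:
    """What was removed at each stage and why; partitions the input."""

    removed_by_confidence: list[tuple[str, float]] = field(default_factory=list)
    removed_by_taxonomy: list[tuple[str, str, str, str]] = field(default_factory=list)
    removed_by_presence: list[tuple[str, str, int]] = field(default_factory=list)
    removed_asvs_global: list[str] = field(default_factory=list)
    removed_specimens: list[tuple[str, int]] = field(default_factory=list)
    retained_summary: dict[str, dict[str, int]] = field(default_factory=dict)
    input_total_reads: int = 0
    retained_total_reads: int = 0

    @property
    def removed_total_reads(self) -> int:
        return self.input_total_reads - self.retained_total_reads

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent)


def _family_key(name: str) -> str:
    return name.strip().casefold()


def filter_taxonomy_consistency(
    chart: OccurrenceChart,
    meta: Mapping[str, SpecimenMeta],
    cfg: VettingConfig = VettingConfig(),
) -> tuple[OccurrenceChart, VettingReport]:
    """Zero counts of ASVs whose assigned family conflicts with the specimen.

    Specimens flagged ``relaxed_filter`` (naked/juvenile) instead accept
    any ASV whose order is polycystine.  ASVs below ``min_confidence``
    are removed everywhere first.
    """
    report = VettingReport(input_total_reads=chart.total_reads)
    missing = [s for s in chart.specimen_ids if s not in meta]
    if missing:
        raise KeyError(f"specimens without metadata: {missing}")

    low_conf = [a for a in chart.asv_ids if chart.confidence[a] < cfg.min_confidence]
    report.removed_by_confidence = [(a, chart.confidence[a]) for a in low_conf]
    chart = chart.subset_asvs([a for a in chart.asv_ids if a not in set(low_conf)])

    counts = chart.counts.copy()
    for s in chart.specimen_ids:
        m = meta[s]
        for a in chart.asv_ids:
            if counts.at[a, s] == 0:
                continue
            lin = chart.lineage[a]
            if m.relaxed_filter:
                ok = lin.order in POLYCYSTINE_ORDERS
            else:
                ok = _family_key(lin.family) == _family_key(m.family_name)
            if not ok:
                report.removed_by_taxonomy.append((a, s, lin.family, m.family_name))
                counts.at[a, s] = 0
    return chart.with_counts(counts), report


def apply_count_thresholds(
    chart: OccurrenceChart, cfg: VettingConfig = VettingConfig()
) -> tuple[OccurrenceChart, VettingReport]:
    """Presence zeroing, global ASV rule, then the specimen read rule."""
    report = VettingReport(input_total_reads=chart.total_reads)
    counts = chart.counts.copy()
    arr = counts.to_numpy()
    pre_zero_totals = counts.sum(axis=0)

    below = (arr > 0) & (arr < cfg.min_reads_presence)
    for i, j in zip(*np.nonzero(below)):
        report.removed_by_presence.append(
            (counts.index[i], counts.columns[j], int(arr[i, j]))
        )
    arr = np.where(below, 0, arr)
    counts = pd.DataFrame(arr, index=counts.index, columns=counts.columns)

    def _drop_global(counts: pd.DataFrame) -> pd.DataFrame:
        keep = counts.max(axis=1) >= cfg.min_asv_reads_somewhere
        for a in counts.index[~keep]:
            if a not in report.removed_asvs_global:
                report.removed_asvs_global.append(a)
        return counts.loc[keep]

    counts = _drop_global(counts)

    totals = pre_zero_totals if cfg.specimen_reads_before_zeroing else counts.sum(axis=0)
    weak = [s for s in counts.columns if totals[s] < cfg.min_specimen_reads]
    surviving = counts.sum(axis=0)
    for s in weak:
        report.removed_specimens.append((s, int(surviving[s])))
    counts = counts[[s for s in counts.columns if s not in set(weak)]]

    if cfg.strict_global_rule:
        counts = _drop_global(counts)
    else:
        # Specimen removal can strand ASVs with no remaining reads; drop
        # them so vetting is idempotent (cells are 0 or >= presence here).
        empty = counts.max(axis=1) == 0 if len(counts.columns) else pd.Series(True, index=counts.index)
        for a in counts.index[empty]:
            if a not in report.removed_asvs_global:
                report.removed_asvs_global.append(a)
        counts = counts.loc[~empty]

    out = chart.with_counts(counts)
    report.retained_total_reads = out.total_reads
    return out, report


def vet_dataset(
    chart: OccurrenceChart,
    meta: Mapping[str, SpecimenMeta],
    cfg: VettingConfig = VettingConfig(),
) -> tuple[OccurrenceChart, VettingReport]:
    """Full vetting: taxonomy filter composed with count thresholds.

    Deterministic and idempotent; report totals reconcile with the
    input/retained read-mass partition.
    """
    taxed, rep1 = filter_taxonomy_consistency(chart, meta, cfg)
    vetted, rep2 = apply_count_thresholds(taxed, cfg)

    report = VettingReport(
        removed_by_confidence=rep1.removed_by_confidence,
        removed_by_taxonomy=rep1.removed_by_taxonomy,
        removed_by_presence=rep2.removed_by_presence,
        removed_asvs_global=rep2.removed_asvs_global,
        removed_specimens=rep2.removed_specimens,
        input_total_reads=chart.total_reads,
        retained_total_reads=vetted.total_reads,
    )
    summary: dict[str, dict[str, int]] = {}
    by_order_specimens: dict[str, set[str]] = {}
    by_order_asvs: dict[str, set[str]] = {}
    for s in vetted.specimen_ids:
        by_order_specimens.setdefault(meta[s].order_name, set()).add(s)
    for a in vetted.asv_ids:
        by_order_asvs.setdefault(vetted.lineage[a].order, set()).add(a)
    for order in sorted(set(by_order_specimens) | set(by_order_asvs)):
        summary[order] = {
            "n_specimens": len(by_order_specimens.get(order, ())),
            "n_asvs": len(by_order_asvs.get(order, ())),
        }
    report.retained_summary = summary
    return vetted, report
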