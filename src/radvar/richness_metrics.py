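"""Per-specimen richness at abundance thresholds and rank-abundance profiles."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

from radvar.io_tables import OccurrenceChart, SpecimenMeta

__all__ = [
    "DEFAULT_THRESHOLDS",
    "RichnessRecord",
    "RankProfile",
    "richness_per_specimen",
    "rank_abundance_profiles",
    "order_summary",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = (0.001, 0.01, 0.10)


@dataclass(frozen=True)
class RichnessRecord:
    specimen_id: str
    order_name: str
    n_asvs_total: int
    n_asvs_at: dict[float, int] = field(default_factory=dict)


@dataclass(frozen=True)
class RankProfile:
    specimen_id: str
    order_name: str
    rel_abundance_by_rank: tuple[float, ...]  # rank 1..top_n, truncated


def richness_per_specimen(
    chart: OccurrenceChart,
    meta: Mapping[str, SpecimenMeta] | None = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[RichnessRecord]:
    """Count ASVs whose relative abundance is >= each threshold (inclusive).

    Relative abundance is count / specimen total over the (vetted) chart;
    threshold 0 counts simple presence (count > 0).
    """
    records = []
    for s in chart.specimen_ids:
        col = chart.counts[s]
        total = int(col.sum())
        if total == 0:
            raise ValueError(f"specimen {s} has zero total reads (should have been vetted out)")
        rel = col / total
        n_at = {}
        for t in thresholds:
            if t <= 0:
                n_at[t] = int((col > 0).sum())
            else:
                n_at[t] = int((rel >= t).sum())
        order = meta[s].order_name if meta else "unknown"
        records.append(
            RichnessRecord(
                specimen_id=s,
                order_name=order,
                n_asvs_total=int((col > 0).sum()),
                n_asvs_at=n_at,
            )
        )
    return records


def rank_abundance_profiles(
    chart: OccurrenceChart,
    meta: Mapping[str, SpecimenMeta] | None = None,
    top_n: int = 10,
) -> list[RankProfile]:
    """Relative abundances of each specimen's top ``top_n`` ASVs.

    ASVs are ordered by descending count, ties broken by asv_id
    (lexicographic); ranks with no ASV are omitted, not zero-filled.
    """
    profiles = []
    for s in chart.specimen_ids:
        col = chart.counts[s]
        present = col[col > 0]
        total = int(col.sum())
        if total == 0:
            raise ValueError(f"specimen {s} has zero total reads")
        ordered = sorted(present.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        order = meta[s].order_name if meta else "unknown"
        profiles.append(
            RankProfile(
                specimen_id=s,
                order_name=order,
                rel_abundance_by_rank=tuple(c / total for _, c in ordered),
            )
        )
    return profiles


def _median(values: Sequence[float]) -> float:
    """Midpoint convention for even n (mean of the two central values)."""
    return float(np.median(np.asarray(values, dtype=float)))


def order_summary(
    records: Iterable[RichnessRecord | RankProfile],
    statistic: str = "median",
    value: str = "n_asvs_total",
) -> pd.DataFrame:
    """Per-order summaries of a richness field or the rank-1 share.

    ``value`` is a RichnessRecord attribute name, ``at:<threshold>`` for
    a thresholded richness, or ``rank1`` for the top-rank share of a
    RankProfile.  Empty orders are omitted with a warning.
    """
    by_order: dict[str, list[float]] = {}
    for r in records:
        if value == "rank1":
            if not isinstance(r, RankProfile):
                raise TypeError("value='rank1' requires RankProfile records")
            v = r.rel_abundance_by_rank[0]
        elif value.startswith("at:"):
            v = r.n_asvs_at[float(value[3:])]
        else:
            v = getattr(r, value)
        by_order.setdefault(r.order_name, []).append(float(v))

    rows = []
    for order, vals in sorted(by_order.items()):
        if not vals:
            warnings.warn(f"order {order} has no records; omitted")
            continue
        if statistic == "median":
            stat = _median(vals)
        elif statistic == "min":
            stat = min(vals)
        elif statistic == "max":
            stat = max(vals)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        rows.append({"order": order, "statistic": statistic, "value": stat, "n": len(vals)})
    return pd.DataFrame(rows, columns=["order", "statistic", "value", "n"])
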