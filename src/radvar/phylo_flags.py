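"""Dominant-ASV export for external tree building, and chimera-candidate
flagging on a supplied newick tree.

Flags are advisory: candidates are ASV tips (or ASV-only clades) with a
long stem branch, no reference tips in their clade, and few total reads.
Nothing is removed automatically.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import dendropy

from radvar.io_tables import OccurrenceChart, SpecimenMeta
from radvar.sharing_classify import dominant_set

__all__ = ["TreeView", "ChimeraFlag", "export_dominant_fasta", "flag_chimera_candidates", "write_split_fragments"]


@dataclass
class TreeView:
    """A parsed newick tree with tips classed as reference or asv."""

    tree: dendropy.Tree
    asv_tips: frozenset[str]
    reference_tips: frozenset[str]

    @classmethod
    def from_newick(
        cls, path: str | Path, chart: OccurrenceChart, reference_prefix: str = "ref"
    ) -> "TreeView":
        """Load a newick file; tips matching chart ASVs are ``asv`` tips,
        all others are treated as reference tips."""
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        labels = {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon}
        asv_ids = set(chart.asv_ids)
        asv_tips = frozenset(l for l in labels if l in asv_ids)
        return cls(tree=tree, asv_tips=asv_tips, reference_tips=frozenset(labels) - asv_tips)


@dataclass(frozen=True)
class ChimeraFlag:
    asv_id: str
    clade_tips: tuple[str, ...]
    reason: str
    branch_length: float
    total_reads: int


def export_dominant_fasta(
    chart: OccurrenceChart, meta: Mapping[str, SpecimenMeta]
) -> dict[str, str]:
    """One sequence per specimen: its dominant ASV, labelled
    ``specimen_id|morphotaxon`` (ties broken by lexicographically first)."""
    out: dict[str, str] = {}
    for s in chart.specimen_ids:
        dom = dominant_set(chart, s)
        rep = min(dom.dominant_asvs)
        morph = meta[s].morphotaxon if s in meta else "unknown"
        out[f"{s}|{morph.replace(' ', '_')}"] = chart.sequences[rep]
    return out


def _median_tip_branch_length(view: TreeView) -> float:
    lengths = [
        leaf.edge.length
        for leaf in view.tree.leaf_node_iter()
        if leaf.edge.length is not None
    ]
    if not lengths:
        raise ValueError("tree has no branch lengths")
    return statistics.median(lengths)


def flag_chimera_candidates(
    view: TreeView,
    chart: OccurrenceChart,
    long_branch_factor: float = 3.0,
    read_threshold: int = 50,
) -> list[ChimeraFlag]:
    """Flag long-branching, reference-free, low-read ASV tips/clades.

    A node is a candidate when its stem branch length exceeds
    ``long_branch_factor`` × the median tip branch length, its clade
    contains only ASV tips, and those ASVs' summed chart reads are
    below ``read_threshold``.
    """
    unresolved = sorted(
        t for t in view.asv_tips if t not in set(chart.asv_ids)
    )
    if unresolved:
        raise KeyError(f"tree ASV tips not in chart: {unresolved}")
    med = _median_tip_branch_length(view)
    cutoff = long_branch_factor * med
    totals = chart.counts.sum(axis=1)

    flags: list[ChimeraFlag] = []
    flagged_tips: set[str] = set()
    # postorder: prefer the largest qualifying asv-only clade
    for node in view.tree.preorder_node_iter():
        if node.edge.length is None or node.edge.length <= cutoff:
            continue
        tips = [leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon]
        if not tips or any(t in view.reference_tips for t in tips):
            continue
        if any(t in flagged_tips for t in tips):
            continue
        reads = int(sum(totals.get(t, 0) for t in tips))
        if reads >= read_threshold:
            continue
        rep = min(tips)
        flags.append(
            ChimeraFlag(
                asv_id=rep,
                clade_tips=tuple(sorted(tips)),
                reason="long_branch_no_reference_low_reads",
                branch_length=float(node.edge.length),
                total_reads=reads,
            )
        )
        flagged_tips.update(tips)
    flags.sort(key=lambda f: f.asv_id)
    return flags


def write_split_fragments(
    flags: list[ChimeraFlag],
    chart: OccurrenceChart,
    out_dir: str | Path,
    fragment_length: int = 300,
) -> list[Path]:
    """Emit head/tail fragments per flagged ASV for external database checks."""
    from radvar.io_tables import write_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for flag in flags:
        for asv in flag.clade_tips:
            seq = chart.sequences[asv]
            path = out_dir / f"{asv}_fragments.fasta"
            write_fasta(
                {
                    f"{asv}_head": seq[:fragment_length],
                    f"{asv}_tail": seq[-fragment_length:],
                },
                path,
            )
            written.append(path)
    return written
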