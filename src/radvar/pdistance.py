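"""Pairwise p-distance and within/between-group mean distances.

Groups of pre-aligned sequences (a supplied MSA, or equal-length
ungapped sequences) are compared directly; unequal-length sequences are
aligned pairwise with a built-in global aligner.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from itertools import combinations, product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from radvar.io_tables import read_fasta, write_fasta

__all__ = [
    "AlignedPair",
    "GroupDistanceSummary",
    "align_pair",
    "p_distance",
    "pair_p_distance",
    "group_mean_within",
    "group_mean_between",
    "align_with_mafft",
]

GAP = "-"


@dataclass(frozen=True)
class AlignedPair:
    seq_a: str
    seq_b: str
    source: str = "pairwise_nw"  # supplied_msa | pairwise_nw

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")


@dataclass(frozen=True)
class GroupDistanceSummary:
    level: str  # intragenomic | intraspecies | interspecies
    labels: tuple[str, ...]
    mean_p: float | None
    n_pairs: int


def align_pair(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> AlignedPair:
    """Optimal global (Needleman–Wunsch) alignment with linear gap cost.

    Traceback ties prefer a match/mismatch column, then a gap in ``a``,
    then a gap in ``b`` — fully deterministic.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = np.arange(n + 1) * gap
    score[0, :] = np.arange(m + 1) * gap
    sub = np.empty((n, m))
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    eq = arr_a[:, None] == arr_b[None, :]
    sub = np.where(eq, match, mismatch)
    for i in range(1, n + 1):
        prev = score[i - 1]
        row = score[i]
        diag = prev[:-1] + sub[i - 1]
        up = prev[1:] + gap
        best = np.maximum(diag, up)
        # left-dependency forces a scan
        acc = row[0]
        for j in range(1, m + 1):
            acc = max(best[j - 1], acc + gap)
            row[j] = acc
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif j > 0 and score[i, j] == score[i, j - 1] + gap:
            out_a.append(GAP)  # gap in a
            out_b.append(b[j - 1])
            j -= 1
        else:
            out_a.append(a[i - 1])
            out_b.append(GAP)  # gap in b
            i -= 1
    return AlignedPair("".join(reversed(out_a)), "".join(reversed(out_b)), "pairwise_nw")


def p_distance(pair: AlignedPair, deletion: str = "pairwise") -> float:
    """Proportion of differing bases over retained sites.

    ``pairwise`` deletion retains sites where neither member has a gap;
    ``complete`` here is equivalent for a single pair (complete-set
    context is applied by the group functions).
    """
    a = np.frombuffer(pair.seq_a.encode(), dtype="S1")
    b = np.frombuffer(pair.seq_b.encode(), dtype="S1")
    keep = (a != b"-") & (b != b"-")
    retained = int(keep.sum())
    if retained == 0:
        raise ValueError("no retained sites (all-gap overlap)")
    return float((a[keep] != b[keep]).sum() / retained)


def pair_p_distance(a: str, b: str, deletion: str = "pairwise") -> float:
    """p-distance for two sequences, aligning them first if lengths differ."""
    if len(a) == len(b):
        return p_distance(AlignedPair(a.upper(), b.upper(), "supplied_msa"), deletion)
    return p_distance(align_pair(a, b), deletion)


def _complete_deletion(seqs: Sequence[str]) -> list[str]:
    arr = np.array([np.frombuffer(s.encode(), dtype="S1") for s in seqs])
    keep = ~(arr == b"-").any(axis=0)
    return [bytes(row[keep]).decode() for row in arr]


def _prepare(seqs: Mapping[str, str], deletion: str) -> dict[str, str]:
    seqs = {k: v.upper() for k, v in seqs.items()}
    lengths = {len(v) for v in seqs.values()}
    if deletion == "complete" and len(lengths) == 1:
        names = list(seqs)
        trimmed = _complete_deletion([seqs[n] for n in names])
        return dict(zip(names, trimmed))
    return seqs


def group_mean_within(
    seqs: Mapping[str, str],
    level: str = "intragenomic",
    deletion: str = "pairwise",
) -> GroupDistanceSummary:
    """Arithmetic mean p-distance over all unordered pairs of a group.

    A singleton group yields an absent (None) mean — matching the N/A
    convention for groups where no pair exists.
    """
    names = sorted(seqs)
    if len(names) < 1:
        raise ValueError("empty group")
    if len(names) == 1:
        return GroupDistanceSummary(level, tuple(names), None, 0)
    prepped = _prepare(seqs, deletion)
    dists = [pair_p_distance(prepped[x], prepped[y]) for x, y in combinations(names, 2)]
    return GroupDistanceSummary(level, tuple(names), float(np.mean(dists)), len(dists))


def group_mean_between(
    group_a: Mapping[str, str],
    group_b: Mapping[str, str],
    level: str = "interspecies",
    deletion: str = "pairwise",
) -> GroupDistanceSummary:
    """Mean p-distance over all cross pairs (n_a × n_b); symmetric."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    names_a, names_b = sorted(group_a), sorted(group_b)
    merged = {f"a::{k}": v for k, v in group_a.items()}
    merged.update({f"b::{k}": v for k, v in group_b.items()})
    prepped = _prepare(merged, deletion)
    dists = [
        pair_p_distance(prepped[f"a::{x}"], prepped[f"b::{y}"])
        for x, y in product(names_a, names_b)
    ]
    return GroupDistanceSummary(
        level, tuple(names_a) + tuple(names_b), float(np.mean(dists)), len(dists)
    )


def align_with_mafft(seqs: Mapping[str, str], mafft_path: str | None = None) -> dict[str, str]:
    """Multiple-align a set of sequences with an external mafft binary."""
    exe = mafft_path or shutil.which("mafft")
    if exe is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fa_in = Path(tmp) / "in.fasta"
        write_fasta(seqs, fa_in)
        result = subprocess.run(
            [exe, "--auto", "--quiet", str(fa_in)],
            capture_output=True,
            text=True,
            check=True,
        )
        fa_out = Path(tmp) / "out.fasta"
        fa_out.write_text(result.stdout)
        return read_fasta(fa_out)
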