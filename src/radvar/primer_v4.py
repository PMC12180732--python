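"""IUPAC-aware primer matching, V4 extraction, and identical-V4 merging."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from radvar.io_tables import OccurrenceChart

__all__ = [
    "IUPAC_SETS",
    "TAR_EUK_F1",
    "TAR_EUK_R3",
    "PRIMER_SETS",
    "Primer",
    "PrimerHit",
    "V4Table",
    "find_primer_sites",
    "extract_v4",
    "merge_by_v4",
    "reverse_complement",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Primer:
    """A named IUPAC primer with its amplification orientation."""

    name: str
    sequence: str
    orientation: str  # forward | reverse

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"primer {self.name}: non-IUPAC symbols {sorted(bad)}")
        if self.orientation not in {"forward", "reverse"}:
            raise ValueError(f"primer {self.name}: bad orientation {self.orientation!r}")


#: General eukaryotic V4 primer pair used for sub-region extraction.
TAR_EUK_F1 = Primer("TAR-EukF1", "CCAGCASCYGCGGTAATTCC", "forward")
TAR_EUK_R3 = Primer("TAR-EukR3", "ACTTTCGTTCTTGATYRA", "reverse")

#: Shipped order-targeted amplification primer sets.
PRIMER_SETS: dict[str, tuple[Primer, Primer]] = {
    "polycystine-nas": (
        Primer("Nas-F", "GTCGGTAGTGTATTGGRCTAC", "forward"),
        Primer("Nas-R", "CYGCAGGTTCACCTACGG", "reverse"),
    ),
    "polycystine-spu": (
        Primer("Spu-F", "GACGTKTCATTCAAATTTCTGCC", "forward"),
        Primer("Spu-R", "GTTACGACTTCTCCTTCCTC", "reverse"),
    ),
    "polycystine-col": (
        Primer("Col-F", "GGTTGABCCTGCCAGTAG", "forward"),
        Primer("Col-R", "CYTATTGTAGCCCGTGCGC", "reverse"),
    ),
    "v4-eukaryote": (TAR_EUK_F1, TAR_EUK_R3),
}


@dataclass(frozen=True)
class PrimerHit:
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    mismatches: int
    strand_matched: str  # as-given | reverse-complement


def _iupac_mismatches(pattern: str, window: str) -> int:
    n = 0
    for p, s in zip(pattern, window):
        ps = IUPAC_SETS.get(p)
        ss = IUPAC_SETS.get(s)
        if ps is None or ss is None or ps.isdisjoint(ss):
            n += 1
    return n


def find_primer_sites(seq: str, primer: Primer, max_mismatch: int = 0) -> list[PrimerHit]:
    """All ungapped primer placements with ≤ ``max_mismatch`` incompatibilities.

    IUPAC codes on either side match when their base sets intersect.
    Reverse-orientation primers are searched as their reverse complement
    (the strand on which the site appears in a sense-oriented sequence);
    the as-given pattern is searched too and both strands are reported.
    Hits are sorted by (mismatches, start).
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    patterns = [(primer.sequence, "as-given")]
    if primer.orientation == "reverse":
        patterns.insert(0, (reverse_complement(primer.sequence), "reverse-complement"))
    hits: list[PrimerHit] = []
    for pattern, strand in patterns:
        k = len(pattern)
        if k > len(seq) or k == 0:
            continue
        for start in range(len(seq) - k + 1):
            mm = _iupac_mismatches(pattern, seq[start : start + k])
            if mm <= max_mismatch:
                hits.append(PrimerHit(start, start + k, mm, strand))
    hits.sort(key=lambda h: (h.mismatches, h.start))
    return hits


def extract_v4(
    seq: str,
    fwd: Primer = TAR_EUK_F1,
    rev: Primer = TAR_EUK_R3,
    max_mismatch: int = 0,
    include_primers: bool = False,
) -> str | None:
    """Sub-sequence between the forward and reverse primer sites, or None.

    Best forward hit = fewest mismatches then leftmost; best reverse hit
    = fewest mismatches then rightmost (maximizing the enclosed region).
    Primers are excluded by default.  Returns None when either site is
    missing or the geometry is degenerate.
    """
    if not seq:
        return None
    seq = seq.upper()
    fwd_hits = find_primer_sites(seq, fwd, max_mismatch)
    rev_hits = [
        h
        for h in find_primer_sites(seq, rev, max_mismatch)
        if h.strand_matched == ("reverse-complement" if rev.orientation == "reverse" else "as-given")
    ]
    if not fwd_hits or not rev_hits:
        return None
    best_fwd = min(fwd_hits, key=lambda h: (h.mismatches, h.start))
    best_rev = min(rev_hits, key=lambda h: (h.mismatches, -h.start))
    if include_primers:
        lo, hi = best_fwd.start, best_rev.end
    else:
        lo, hi = best_fwd.end, best_rev.start
    if hi <= lo:
        return None
    return seq[lo:hi]


@dataclass
class V4Table:
    """Occurrence chart keyed by extracted V4 sequence with provenance."""

    chart: OccurrenceChart
    provenance: dict[str, frozenset[str]]
    no_v4_asvs: list[str] = field(default_factory=list)

    @property
    def n_unique_v4(self) -> int:
        return len(self.chart.asv_ids)


def merge_by_v4(
    chart: OccurrenceChart,
    fwd: Primer = TAR_EUK_F1,
    rev: Primer = TAR_EUK_R3,
    max_mismatch: int = 0,
    include_primers: bool = False,
) -> V4Table:
    """Extract V4 per ASV and sum counts over ASVs with identical V4s.

    Merged rows take the lexicographically-first source ASV id; ASVs
    without an extractable V4 are excluded and listed in ``no_v4_asvs``.
    Per-specimen read mass is conserved over the merged subset.
    """
    groups: dict[str, list[str]] = {}
    no_v4: list[str] = []
    for asv in chart.asv_ids:
        v4 = extract_v4(chart.sequences[asv], fwd, rev, max_mismatch, include_primers)
        if v4 is None:
            no_v4.append(asv)
        else:
            groups.setdefault(v4, []).append(asv)

    rows = []
    seqs: dict[str, str] = {}
    lineage = {}
    confidence = {}
    provenance: dict[str, frozenset[str]] = {}
    for v4_seq, members in groups.items():
        members = sorted(members)
        rep = members[0]
        merged_counts = chart.counts.loc[members].sum(axis=0)
        rows.append((rep, merged_counts))
        seqs[rep] = v4_seq
        lineage[rep] = chart.lineage[rep]
        confidence[rep] = max(chart.confidence[m] for m in members)
        provenance[rep] = frozenset(members)

    rows.sort(key=lambda r: r[0])
    if rows:
        counts = pd.DataFrame(
            [r[1] for r in rows],
            index=pd.Index([r[0] for r in rows], name="asv_id"),
            dtype=np.int64,
        )
    else:
        counts = pd.DataFrame(
            np.empty((0, len(chart.specimen_ids)), dtype=np.int64),
            index=pd.Index([], name="asv_id"),
            columns=chart.specimen_ids,
        )
    merged_ids = frozenset(r for r, m in provenance.items() if len(m) > 1)
    v4_chart = OccurrenceChart(
        counts=counts,
        sequences=seqs,
        lineage=lineage,
        confidence=confidence,
        merged_v4=merged_ids,
    )
    return V4Table(chart=v4_chart, provenance=provenance, no_v4_asvs=no_v4)
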