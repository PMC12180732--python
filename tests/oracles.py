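"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive code paths: these must not share logic with the
package modules they verify.
"""

from __future__ import annotations

from itertools import combinations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
        "W": "W", "K": "M", "M": "K", "B": "V", "D": "H", "H": "D", "V": "B", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def naive_primer_hits(seq: str, pattern: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (start, mismatches) sliding-window placements of one pattern."""
    hits = []
    k = len(pattern)
    for start in range(len(seq) - k + 1):
        mm = 0
        for p, s in zip(pattern, seq[start : start + k]):
            if not (set(IUPAC.get(p, "")) & set(IUPAC.get(s, ""))):
                mm += 1
        if mm <= max_mismatch:
            hits.append((start, mm))
    return hits


def best_alignment_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Maximum global alignment score by exhaustive recursion (short seqs)."""

    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def score_alignment(sa: str, sb: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    total = 0.0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            total += gap
        elif x == y:
            total += match
        else:
            total += mismatch
    return total


def naive_p_distance(sa: str, sb: str) -> float:
    """Pairwise-deletion p-distance from an aligned pair, the long way."""
    retained = 0
    diff = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            continue
        retained += 1
        if x != y:
            diff += 1
    if retained == 0:
        raise ZeroDivisionError
    return diff / retained


def naive_classify(counts: dict[str, dict[str, int]], min_presence: int = 3) -> str:
    """Three-way category from {specimen: {asv: count}} by enumeration."""
    specimens = sorted(counts)
    assert len(specimens) >= 2
    dominant_sets = []
    for s in specimens:
        row = counts[s]
        top = max(row.values())
        dominant_sets.append({a for a, c in row.items() if c == top})
    common_dom = set.intersection(*dominant_sets)
    if common_dom:
        return "SHARED_DOMINANT"
    all_asvs = {a for row in counts.values() for a in row}
    for a in all_asvs:
        if all(counts[s].get(a, 0) >= min_presence for s in specimens):
            return "SHARED_ASV_DIFFERENT_DOMINANTS"
    return "NO_UNIVERSAL_ASV"


def naive_group_mean_within(seqs: list[str]) -> float:
    ds = [naive_p_distance(a, b) for a, b in combinations(seqs, 2)]
    return sum(ds) / len(ds)
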