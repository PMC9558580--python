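"""Independent brute-force reference implementations used only by tests.

Each function here recomputes a quantity by the most direct method possible
(exhaustive scans, plain dynamic programming, enumeration) so the package's
optimized code paths can be checked against something that shares none of
their machinery.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62_score(a: str, b: str) -> float:
    return float(_BLOSUM62[a, b])


def smith_waterman(a: str, b: str, gap_open: int = 11,
                   gap_extend: int = 1) -> int:
    """Plain Gotoh local alignment score (first gap position costs gap_open,
    each further position gap_extend)."""
    n, m = len(a), len(b)
    neg = -10 ** 9
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), neg, dtype=float)  # gap in b (consume a)
    Iy = np.full((n + 1, m + 1), neg, dtype=float)  # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend)
            s = blosum62_score(a[i - 1], b[j - 1])
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], Ix[i - 1][j - 1],
                                       Iy[i - 1][j - 1]))
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return int(best)


def gantc_count(sequence: str) -> int:
    """Position-by-position scan for GANTC (middle base may be N)."""
    count = 0
    for i in range(len(sequence) - 4):
        w = sequence[i:i + 5]
        if (w[0] == "G" and w[1] == "A" and w[3] == "T" and w[4] == "C"
                and w[2] in "ACGTN"):
            count += 1
    return count


def histogram_gaps(values: list[float], bin_width: float,
                   max_count: int) -> list[tuple[float, float]]:
    """Brute-force binning: assign each value to floor(v/w), then walk bins."""
    bins: dict[int, int] = {}
    for v in values:
        bins[int(np.floor(v / bin_width))] = bins.get(int(np.floor(v / bin_width)), 0) + 1
    occupied = sorted(k for k, c in bins.items() if c > max_count)
    if not occupied:
        return []
    gaps = []
    run_start = None
    for k in range(occupied[0], occupied[-1] + 1):
        if bins.get(k, 0) <= max_count:
            if run_start is None:
                run_start = k
        else:
            if run_start is not None:
                gaps.append((run_start * bin_width, k * bin_width))
                run_start = None
    return gaps


def all_clades(tree) -> set[frozenset[str]]:
    """Leaf-sets of every clade of a dendropy tree, by direct enumeration."""
    out = set()
    for node in tree.preorder_node_iter():
        out.add(frozenset(l.taxon.label for l in node.leaf_iter()))
    return out


def pairwise_identity(row_a: str, row_b: str,
                      excluded: str = "-X*") -> tuple[float, int]:
    """Site loop: (percent identity, compared sites) with pairwise deletion."""
    same = 0
    total = 0
    for x, y in zip(row_a, row_b):
        if x in excluded or y in excluded:
            continue
        total += 1
        if x == y:
            same += 1
    if total == 0:
        return float("nan"), 0
    return 100.0 * same / total, total
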