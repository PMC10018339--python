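"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and libraries) they validate:
pure-Python enumeration for overlap merging, a hand-rolled dynamic program
for infix alignment, dense pairwise distances for clash counting.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def best_overlap_bruteforce(
    s1: str, s2rc: str, min_overlap: int, max_diffs: int
) -> tuple[int, int, int] | None:
    """Exhaustively enumerate every placement of s2rc against s1.

    Returns (overlap, diffs, shift) of the acceptable placement maximizing
    overlap (ties: fewer diffs, then leftmost shift), or None.
    """
    best = None
    for shift in range(-(len(s2rc) - 1), len(s1)):
        a = max(0, shift)
        b = min(len(s1), shift + len(s2rc))
        ov = b - a
        if ov < min_overlap:
            continue
        diffs = sum(s1[i] != s2rc[i - shift] for i in range(a, b))
        if diffs > max_diffs:
            continue
        key = (ov, -diffs, -shift)
        if best is None or key > best:
            best = key
    if best is None:
        return None
    return best[0], -best[1], -best[2]


def min_edits_infix(query: str, target: str) -> int:
    """Minimum edit distance of query against any substring of target
    (free leading/trailing target bases), by straightforward DP."""
    prev = [0] * (len(target) + 1)
    for i in range(1, len(query) + 1):
        cur = [i] + [0] * len(target)
        qc = query[i - 1]
        for j in range(1, len(target) + 1):
            cur[j] = min(
                prev[j - 1] + (qc != target[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return min(prev)


def quality_trim_bruteforce(qual: tuple[int, ...], cutoff: int) -> int:
    """Cut index of the 3'-quality-trim rule, derived from explicit suffix
    sums: among the cut points reachable before the running sum from the 3'
    end first goes negative, pick the argmax of sum(cutoff - q) over the
    removed suffix (ties resolved toward trimming less)."""
    n = len(qual)
    stop = -1
    s = 0
    for i in range(n - 1, -1, -1):
        s += cutoff - qual[i]
        if s < 0:
            stop = i
            break
    candidates = range(stop + 1, n + 1)
    suffix_sum = {c: sum(cutoff - q for q in qual[c:]) for c in candidates}
    best = max(candidates, key=lambda c: (suffix_sum[c], c))
    return best if suffix_sum[best] > 0 else n


def count_clashes_bruteforce(set_a, set_b, overlap_cutoff: float = 0.6) -> int:
    """O(n^2) clash count over all cross pairs via a dense distance matrix."""
    ra = set_a.radii()
    rb = set_b.radii()
    d = np.linalg.norm(
        set_a.coords[:, None, :] - set_b.coords[None, :, :], axis=-1
    )
    return int(np.count_nonzero(ra[:, None] + rb[None, :] - d >= overlap_cutoff))
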