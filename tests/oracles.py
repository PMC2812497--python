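"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most literal method available
(full-matrix dynamic programming, full-rescan agglomeration) and share no
code with the implementation paths they check.
"""

from __future__ import annotations

from statistics import mean

NEG = float("-inf")


def sw_gotoh_score(a: str, b: str, matrix, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Naive O(mn) full-matrix Smith-Waterman score with affine gaps.

    A gap of length k costs ``gap_open + k * gap_extend``.
    """
    m, n = len(a), len(b)
    M = [[0.0] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(m + 1)]
    Iy = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = matrix[a[i - 1], b[j - 1]]
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0.0)
            M[i][j] = diag + s
            Ix[i][j] = max(M[i - 1][j] - (gap_open + gap_extend), Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - (gap_open + gap_extend), Iy[i][j - 1] - gap_extend)
            if M[i][j] > best:
                best = M[i][j]
    return max(0, int(best))


def upgma_rescan_merge_order(labels, D):
    """UPGMA merge sequence by full rescan.

    Inter-cluster distance is recomputed every step as the plain mean over
    all original leaf pairs (no recurrence).  Ties break on the
    lexicographically smallest sorted pair of minimum member labels.
    Returns [(sorted member tuple, merge height), ...].
    """
    idx = {lab: i for i, lab in enumerate(labels)}
    clusters = [(lab,) for lab in labels]
    order = []
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = mean(
                    D[idx[p]][idx[q]] for p in clusters[x] for q in clusters[y]
                )
                key = (d, tuple(sorted((min(clusters[x]), min(clusters[y])))))
                if best is None or key < best[0]:
                    best = (key, x, y)
        (d, _), x, y = best
        merged = tuple(sorted(clusters[x] + clusters[y]))
        order.append((merged, d / 2.0))
        clusters = [c for i, c in enumerate(clusters) if i not in (x, y)]
        clusters.append(merged)
    return order


def interval_reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Smaller of the two mutual overlap fractions of 1-based intervals."""
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    return min(ov / (a[1] - a[0] + 1), ov / (b[1] - b[0] + 1))
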