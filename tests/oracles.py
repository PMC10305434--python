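"""Independent reference implementations used only to check the package.

These are deliberately written as plain, slow, textbook algorithms with
no code shared with the implementation under test.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def sw_oracle(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Brute-force Gotoh local alignment: affine gap of length k costs
    gap_open + k * gap_extend."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            s = float(_B62[a[i - 1], b[j - 1]])
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def identity_oracle(a: str, b: str) -> float:
    """Unit-cost global alignment identity = matches / alignment columns,
    by full Needleman–Wunsch with traceback over (match=0/1, indel=1)."""
    n, m = len(a), len(b)
    D = np.zeros((n + 1, m + 1))
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = D[i - 1, j - 1] + (a[i - 1] != b[j - 1])
            D[i, j] = min(sub, D[i - 1, j] + 1, D[i, j - 1] + 1)
    # traceback counting columns and matches
    i, j = n, m
    columns = matches = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + (a[i - 1] != b[j - 1]):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            i -= 1
        else:
            j -= 1
        columns += 1
    return matches / columns if columns else 0.0


def mcl_reference(adjacency: np.ndarray, inflation: float = 2.0,
                  prune_below: float = 1e-5, tol: float = 1e-6,
                  max_iter: int = 200) -> list[set[int]]:
    """Dense textbook Markov clustering; returns node-index clusters as
    connected components of the converged flow matrix."""
    M = np.array(adjacency, dtype=float)
    M = M / M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        new = M @ M
        new = new**inflation
        new[new < prune_below] = 0.0
        new = new / new.sum(axis=0, keepdims=True)
        if np.abs(new - M).max() < tol:
            M = new
            break
        M = new
    pattern = (M + M.T) > 0
    n = M.shape[0]
    seen: set[int] = set()
    clusters: list[set[int]] = []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(int(u) for u in np.nonzero(pattern[v])[0] if u not in comp)
        seen |= comp
        clusters.append(comp)
    return clusters
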