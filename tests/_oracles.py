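"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately share no code with the package paths they check.
"""

from __future__ import annotations

import numpy as np

NEG_INF = float("-inf")


def gotoh_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Optimal global affine-gap alignment score by explicit 3-matrix DP.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``; end gaps
    are penalized (true global alignment).
    """
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (a residue vs -)
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = float(matrix[a[i - 1], b[j - 1]])
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] - gap_open,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - gap_open,
            )
    return max(M[n][m], X[n][m], Y[n][m])


def sliding_window_hits(sequence: str, name: str, pattern: str) -> list[tuple[str, int, str]]:
    """Every window of the sequence checked against the pattern directly."""
    hits = []
    k = len(pattern)
    for start in range(len(sequence) - k + 1):
        window = sequence[start : start + k]
        if all(p in "xX" or p == c for p, c in zip(pattern, window)):
            hits.append((name, start + 1, window))
    return hits


def mrca_depth_covariance(tree) -> tuple[np.ndarray, list[str]]:
    """Tip covariance via explicit per-pair MRCA search on ancestor paths."""
    parents: dict[int, object] = {}
    depth: dict[int, float] = {id(tree.root): tree.root.length or 0.0}
    stack = [tree.root]
    tips = []
    while stack:
        node = stack.pop()
        if node.is_leaf:
            tips.append(node)
        for child in node.children:
            parents[id(child)] = node
            depth[id(child)] = depth[id(node)] + (child.length or 0.0)
            stack.append(child)

    def ancestors(node):
        path = [node]
        while id(node) in parents:
            node = parents[id(node)]
            path.append(node)
        return path

    labels = [t.label for t in tips]
    n = len(tips)
    cov = np.zeros((n, n))
    for i in range(n):
        anc_i = ancestors(tips[i])
        ids_i = [id(x) for x in anc_i]
        for j in range(n):
            anc_j = ancestors(tips[j])
            mrca = next(x for x in anc_j if id(x) in ids_i)
            cov[i, j] = depth[id(mrca)]
    return cov, labels


def blomberg_k_oracle(cov: np.ndarray, y: np.ndarray) -> float:
    """Direct evaluation of the K formula with explicit matrix inverses."""
    n = len(y)
    cinv = np.linalg.inv(cov)
    one = np.ones(n)
    a = (one @ cinv @ y) / (one @ cinv @ one)
    resid = y - a
    mse0 = resid @ resid / (n - 1)
    mse = resid @ cinv @ resid / (n - 1)
    expected = (np.trace(cov) - n / (one @ cinv @ one)) / (n - 1)
    return float((mse0 / mse) / expected)


def patristic_distances(tree) -> dict[tuple[str, str], float]:
    """Tip-to-tip path lengths computed from scratch (for NJ checks)."""
    cov, labels = mrca_depth_covariance(tree)
    depths = np.diag(cov)
    out = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            out[(a, b)] = float(depths[i] + depths[j] - 2 * cov[i, j])
    return out
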