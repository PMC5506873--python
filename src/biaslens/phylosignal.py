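"""Per-trait phylogenetic signal (Blomberg's K) with permutation p-values.

K compares the observed partitioning of trait variance on a tree against
the partitioning expected if the trait had evolved by Brownian motion on
that tree. Writing C for the tips-by-tips shared-path-length matrix and
``a`` for the phylogenetic GLS mean of the trait ``y``:

    MSE0 = (y - a)'(y - a) / (n - 1)
    MSE  = (y - a)' C^-1 (y - a) / (n - 1)
    K    = (MSE0 / MSE) * (n - 1) / (tr(C) - n / sum(C^-1))

so K = 1 exactly when C is the identity (a star tree), and in expectation
under Brownian motion on any tree. The permutation null shuffles trait
values across tips and asks how often the shuffled MSE is at least as
small (small MSE = strong signal).

Also provides the distance-based fallback tree builder (p-distances +
neighbor joining) for when no externally inferred tree is supplied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .core_io import Alignment, GAP, Tree, TreeNode, parse_newick

__all__ = [
    "SignalResult",
    "phylo_covariance",
    "blomberg_k",
    "k_pvalue",
    "p_distance",
    "nj_tree",
    "profile_signal",
]

RIDGE = 1e-10  # added to the diagonal only when C is numerically singular


def phylo_covariance(tree: Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion tip covariance: C[i, j] = depth of MRCA(i, j).

    Requires a rooted tree; the diagonal holds root-to-tip distances.
    """
    if not tree.rooted:
        raise ValueError(
            "tree is unrooted; root it (e.g., with an outgroup) before "
            "computing phylogenetic covariance"
        )
    labels = tree.tip_labels
    index = {label: i for i, label in enumerate(labels)}
    n = len(labels)
    cov = np.zeros((n, n))

    def fill(node: TreeNode, depth: float) -> list[int]:
        depth += node.length or 0.0
        if node.is_leaf:
            i = index[node.label or ""]
            cov[i, i] = depth
            return [i]
        groups = [fill(child, depth) for child in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                block = np.ix_(groups[gi], groups[gj])
                cov[block] = depth
                cov[block[::-1]] = depth
        return [i for g in groups for i in g]

    fill(tree.root, 0.0)
    return cov, labels


def _trait_vector(trait: Mapping[str, float], labels: list[str]) -> np.ndarray:
    missing = [l for l in labels if l not in trait]
    if missing:
        raise ValueError(f"trait missing for tips: {missing[:5]}")
    extra = set(trait) - set(labels)
    if extra:
        raise ValueError(f"trait has labels not in tree: {sorted(extra)[:5]}")
    return np.array([float(trait[l]) for l in labels])


def _solve(cov: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    try:
        return cho_solve(cho_factor(cov), rhs)
    except np.linalg.LinAlgError:
        warnings.warn("covariance numerically singular; ridge regularized")
        return cho_solve(cho_factor(cov + RIDGE * np.eye(len(cov))), rhs)


def _k_from_cov(cov: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Returns (K, MSE); MSE is reused by the permutation test."""
    n = len(y)
    ones = np.ones(n)
    cinv_one = _solve(cov, ones)
    denom = ones @ cinv_one
    a_hat = (cinv_one @ y) / denom
    resid = y - a_hat
    mse0 = (resid @ resid) / (n - 1)
    mse = (resid @ _solve(cov, resid)) / (n - 1)
    expected_ratio = (np.trace(cov) - n / denom) / (n - 1)
    return float((mse0 / mse) / expected_ratio), float(mse)


def blomberg_k(tree: Tree, trait: Mapping[str, float]) -> float:
    """Blomberg's K for one trait; NaN (with a warning) if the trait is constant."""
    cov, labels = phylo_covariance(tree)
    if len(labels) < 4:
        raise ValueError("need at least 4 tips")
    y = _trait_vector(trait, labels)
    if np.ptp(y) == 0:
        warnings.warn("constant trait: K undefined")
        return math.nan
    k, _ = _k_from_cov(cov, y)
    return k


@dataclass(frozen=True)
class SignalResult:
    k: float
    p: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not math.isnan(self.k) and self.k < 0:
            raise ValueError("K must be nonnegative")
        if not math.isnan(self.p) and self.p < 1.0 / (self.n_permutations + 1):
            raise ValueError("p below permutation resolution")


def k_pvalue(
    tree: Tree,
    trait: Mapping[str, float],
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """K plus a tip-shuffle permutation p-value.

    p = (1 + #{permutations with MSE <= observed MSE}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    cov, labels = phylo_covariance(tree)
    if len(labels) < 4:
        raise ValueError("need at least 4 tips")
    y = _trait_vector(trait, labels)
    if np.ptp(y) == 0:
        warnings.warn("constant trait: K and p undefined")
        return SignalResult(math.nan, math.nan, n_perm)
    k, observed_mse = _k_from_cov(cov, y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, mse = _k_from_cov(cov, rng.permutation(y))
        if mse <= observed_mse:
            hits += 1
    return SignalResult(k, (1 + hits) / (n_perm + 1), n_perm)


# ---------------------------------------------------------------------------
# distance-based fallback tree
# ---------------------------------------------------------------------------


def p_distance(aln: Alignment) -> tuple[np.ndarray, list[str]]:
    """Pairwise p-distances; columns gapped in either sequence are ignored."""
    labels = aln.ids()
    rows = [np.frombuffer(r.residues.encode(), dtype="S1") for r in aln.records]
    gap = GAP.encode()
    n = len(rows)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = (rows[i] != gap) & (rows[j] != gap)
            total = int(usable.sum())
            if total == 0:
                warnings.warn(
                    f"no comparable columns between {labels[i]} and "
                    f"{labels[j]}; distance set to 0"
                )
                continue
            mism = int((rows[i][usable] != rows[j][usable]).sum())
            dist[i, j] = dist[j, i] = mism / total
    return dist, labels


def nj_tree(dist: np.ndarray, labels: list[str]) -> Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative branch lengths produced by the algorithm are clamped to zero.
    The result is unrooted (basal trifurcation).
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    nodes: dict[int, TreeNode] = {i: TreeNode(labels[i], None) for i in range(n)}
    active = list(range(n))
    d = {(i, j): dist[i, j] for i in range(n) for j in range(n)}
    next_id = n

    def get(i: int, j: int) -> float:
        return d[(i, j)] if i != j else 0.0

    while len(active) > 2:
        m = len(active)
        totals = {i: sum(get(i, k) for k in active) for i in active}
        best, bi, bj = None, None, None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - totals[i] - totals[j]
                if best is None or q < best:
                    best, bi, bj = q, i, j
        i, j = bi, bj  # type: ignore[assignment]
        dij = get(i, j)
        li = 0.5 * dij + (totals[i] - totals[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        node_i, node_j = nodes.pop(i), nodes.pop(j)
        node_i.length, node_j.length = li, lj
        parent = TreeNode(None, None, [node_i, node_j])
        nodes[next_id] = parent
        active.remove(i)
        active.remove(j)
        for k in active:
            dk = 0.5 * (get(i, k) + get(j, k) - dij)
            d[(next_id, k)] = d[(k, next_id)] = max(dk, 0.0)
        active.append(next_id)
        next_id += 1

    i, j = active
    node_i, node_j = nodes[i], nodes[j]
    residual = max(get(i, j), 0.0)
    node_j.length = residual
    if node_i.is_leaf:
        # keep leaves as leaves: hang both under a fresh root
        node_i.length = 0.0
        root = TreeNode(None, None, [node_i, node_j])
    else:
        node_i.children.append(node_j)
        root = TreeNode(node_i.label, None, node_i.children)
    return Tree(root, rooted=False)


def fallback_tree(aln: Alignment) -> Tree:
    """p-distance + neighbor-joining tree straight from an alignment."""
    dist, labels = p_distance(aln)
    return nj_tree(dist, labels)


# ---------------------------------------------------------------------------
# profile annotation
# ---------------------------------------------------------------------------


def _binary_trait(
    msa: Alignment, column: int, residue: str, exclude: set[str], tips: set[str]
) -> dict[str, float]:
    trait = {}
    for rec in msa.records:
        if rec.id in exclude or rec.id not in tips:
            continue
        trait[rec.id] = 1.0 if rec.residues[column - 1] == residue else 0.0
    return trait


def profile_signal(
    profile: pd.DataFrame,
    tree: Tree,
    msa: Alignment,
    focal_a: str,
    focal_b: str,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Append K and p columns (focal-A and focal-B indicator traits).

    For each profiled column, each homolog tip gets a binary trait: 1 if it
    carries the focal residue at that column, else 0. Tips in the tree but
    gapped at the column keep trait 0; tree tips absent from the alignment
    (and focal tips) are pruned, with a log record, before computing K.
    """
    exclude = {focal_a, focal_b}
    msa_ids = set(msa.ids())
    keep = [l for l in tree.tip_labels if l in msa_ids and l not in exclude]
    pruned = tree.prune_to(keep) if set(keep) != set(tree.tip_labels) else tree
    if not pruned.rooted:
        pruned = Tree(pruned.root, rooted=True)
    out = profile.copy()
    cols: dict[str, list[float]] = {"k_a": [], "p_a": [], "k_b": [], "p_b": []}
    rng = np.random.default_rng(seed)
    for row in profile.itertuples(index=False):
        for which, residue in (("a", row.res_a), ("b", row.res_b)):
            trait = _binary_trait(msa, int(row.column), residue, exclude, set(keep))
            sub_seed = int(rng.integers(2**31))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = k_pvalue(pruned, trait, n_perm=n_perm, seed=sub_seed)
            cols[f"k_{which}"].append(result.k)
            cols[f"p_{which}"].append(result.p)
    for name, values in cols.items():
        out[name] = values
    return out
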