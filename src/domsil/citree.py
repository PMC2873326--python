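"""Conditional-inference classification and regression trees.

Recursive partitioning in which the split variable at each node is
chosen by a multiplicity-adjusted permutation test of independence
between each candidate feature and the response, and growth stops when
the global null of independence cannot be rejected at level alpha.
The p-value stopping rule replaces pruning, and because variable
selection is done on test statistics standardised by their permutation
moments it is unbiased towards features with many split points.

For a numeric feature x and response y the linear test statistic is
T = sum_i x_i * g(y_i) with g the identity for a continuous response
and the class-1 indicator for a binary one.  Under the permutation null
(y shuffled against x over the node's non-missing cases)

    E[T]   = sum(x) * mean(g),
    Var[T] = (n / (n-1)) * var(x)*... (finite-population form below)

and the standardised statistic is referred to a two-sided normal
reference, or to the Monte-Carlo / exhaustive permutation distribution.

Split points are midpoints between consecutive distinct feature values,
scored by the standardised two-sample statistic of the response between
the two sides.  Cases with a missing feature value are routed to the
child with more cases.  Terminal nodes summarise the response by class
proportions (classification) or n/median/quartiles (regression).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TreeParams", "TreeNode", "TreeModel", "independence_p",
    "select_split_variable", "best_split_point", "grow_tree", "tree_rules",
]


@dataclass(frozen=True)
class TreeParams:
    """Growth parameters; defaults give asymptotic tests with Bonferroni control."""

    alpha: float = 0.05
    adjust: str = "bonferroni"
    n_perm: int = 0
    min_node: int = 20
    max_depth: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 0:
            raise ValueError("n_perm must be >= 0")
        if self.adjust not in ("bonferroni", "none"):
            raise ValueError("adjust must be 'bonferroni' or 'none'")


@dataclass
class TreeNode:
    node_id: int
    n: int
    depth: int
    # split node fields
    feature: str | None = None
    threshold: float | None = None
    p_adjusted: float | None = None
    missing_left: bool = True
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    # terminal summary
    summary: dict = field(default_factory=dict)

    @property
    def is_terminal(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {"node_id": self.node_id, "n": self.n, "depth": self.depth}
        if self.is_terminal:
            d["summary"] = self.summary
        else:
            d.update(
                feature=self.feature, threshold=self.threshold,
                p_adjusted=self.p_adjusted, missing_left=self.missing_left,
                left=self.left.to_dict(), right=self.right.to_dict(),
            )
        return d


@dataclass
class TreeModel:
    root: TreeNode
    kind: str  # 'binary' or 'continuous'
    params: TreeParams
    feature_names: list[str]

    def n_terminals(self) -> int:
        def count(node: TreeNode) -> int:
            if node.is_terminal:
                return 1
            return count(node.left) + count(node.right)
        return count(self.root)

    def depth(self) -> int:
        def d(node: TreeNode) -> int:
            if node.is_terminal:
                return 0
            return 1 + max(d(node.left), d(node.right))
        return d(self.root)

    def to_json(self, **kwargs) -> str:
        obj = {
            "kind": self.kind,
            "params": self.params.__dict__,
            "feature_names": self.feature_names,
            "root": self.root.to_dict(),
        }
        return json.dumps(obj, indent=2, **kwargs)


# ---------------------------------------------------------------------------
# independence test
# ---------------------------------------------------------------------------

def _encode_response(y: np.ndarray, kind: str) -> np.ndarray:
    if kind == "binary":
        return (np.asarray(y) == 1).astype(float)
    return np.asarray(y, dtype=float)


def _standardise(x: np.ndarray, g: np.ndarray) -> tuple[float, float, float]:
    """Observed T, its permutation mean and standard deviation."""
    n = len(x)
    t_obs = float(x @ g)
    mu = float(x.sum() * g.mean())
    ssx = float(((x - x.mean()) ** 2).sum())
    ssg = float(((g - g.mean()) ** 2).sum())
    var = ssx * ssg / (n - 1) if n > 1 else 0.0
    return t_obs, mu, math.sqrt(max(var, 0.0))


def _data_seed(base_seed: int, x: np.ndarray, g: np.ndarray) -> int:
    """Permutation RNG seed keyed to the data, not to row order."""
    h = hashlib.blake2b(digest_size=4)
    h.update(np.sort(x).tobytes())
    h.update(np.sort(g).tobytes())
    return (base_seed + int.from_bytes(h.digest(), "little")) % (2**31 - 1)


def independence_p(
    feature,
    response,
    kind: str = "continuous",
    n_perm: int = 0,
    seed: int = 0,
    exhaustive: bool = False,
) -> float:
    """Permutation p-value for independence of one feature and the response.

    ``n_perm == 0`` uses the two-sided normal approximation to the
    permutation distribution; otherwise a Monte-Carlo estimate
    (1 + #{|T*| >= |T|}) / (1 + n_perm).  ``exhaustive=True`` enumerates
    the full permutation distribution (all class-label assignments for a
    binary response, all orderings otherwise) — only feasible for tiny n.
    Cases with a missing feature value are excluded.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(response)
    if len(x) != len(y):
        raise ValueError("feature and response lengths differ")
    ok = ~np.isnan(x)
    x, y = x[ok], y[ok]
    g = _encode_response(y, kind)
    if len(np.unique(x)) < 2 or len(np.unique(g)) < 2:
        return 1.0
    t_obs, mu, sd = _standardise(x, g)
    if sd == 0:
        return 1.0
    z_obs = abs(t_obs - mu) / sd
    if exhaustive:
        return _exhaustive_p(x, g, kind, z_obs, mu, sd)
    if n_perm == 0:
        return float(2.0 * stats.norm.sf(z_obs))
    rng = np.random.default_rng(_data_seed(seed, x, g))
    # canonical (sorted) arrays keep the Monte-Carlo draw, and hence the
    # p-value, invariant under row reordering of the input
    xs, gs = np.sort(x), np.sort(g)
    hits = 0
    for _ in range(n_perm):
        t = float(xs @ rng.permutation(gs))
        if abs(t - mu) / sd >= z_obs - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def _exhaustive_p(x, g, kind, z_obs, mu, sd) -> float:
    n = len(x)
    if kind == "binary":
        ones = int(g.sum())
        total = 0
        hits = 0
        base = np.zeros(n)
        for idx in itertools.combinations(range(n), ones):
            base[:] = 0.0
            base[list(idx)] = 1.0
            t = float(x @ base)
            total += 1
            if abs(t - mu) / sd >= z_obs - 1e-12:
                hits += 1
        return hits / total
    if n > 9:
        raise ValueError("exhaustive enumeration over orderings is limited to n <= 9")
    total = 0
    hits = 0
    for perm in itertools.permutations(g):
        t = float(x @ np.asarray(perm))
        total += 1
        if abs(t - mu) / sd >= z_obs - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# variable selection and split search
# ---------------------------------------------------------------------------

def _node_pvalues(X: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Vectorised asymptotic independence p-values, one per feature column."""
    n, p = X.shape
    pvals = np.ones(p)
    ok = ~np.isnan(X)
    counts = ok.sum(axis=0)
    for j in range(p):
        if counts[j] < 2:
            continue
        xj = X[ok[:, j], j]
        gj = g[ok[:, j]]
        if np.unique(xj).size < 2 or np.unique(gj).size < 2:
            continue
        t_obs, mu, sd = _standardise(xj, gj)
        if sd == 0:
            continue
        pvals[j] = 2.0 * stats.norm.sf(abs(t_obs - mu) / sd)
    return pvals


def _testable(X: np.ndarray, g: np.ndarray) -> np.ndarray:
    ok = ~np.isnan(X)
    testable = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        xj = X[ok[:, j], j]
        testable[j] = xj.size >= 2 and np.unique(xj).size >= 2
    return testable


def select_split_variable(
    X: np.ndarray,
    response: np.ndarray,
    kind: str,
    params: TreeParams,
) -> tuple[int, float] | None:
    """Minimum-adjusted-p feature at a node, or None to stop.

    The Bonferroni factor is the number of features with at least two
    distinct values at the node; ties in adjusted p go to the smallest
    feature index.
    """
    g = _encode_response(response, kind)
    if np.unique(g).size < 2:
        return None
    testable = _testable(X, g)
    m = int(testable.sum())
    if m == 0:
        return None
    if params.n_perm == 0:
        pvals = _node_pvalues(X, g)
    else:
        pvals = np.ones(X.shape[1])
        for j in np.flatnonzero(testable):
            pvals[j] = independence_p(
                X[:, j], response, kind, n_perm=params.n_perm, seed=params.seed
            )
    if params.adjust == "bonferroni":
        adjusted = np.minimum(pvals * m, 1.0)
    else:
        adjusted = pvals
    adjusted[~testable] = 1.0
    j = int(np.argmin(adjusted))  # argmin takes the first (smallest index) on ties
    if adjusted[j] <= params.alpha:
        return j, float(adjusted[j])
    return None


def best_split_point(
    feature: np.ndarray,
    response: np.ndarray,
    kind: str,
    min_side: int = 1,
) -> float | None:
    """Threshold maximising the standardised two-sample response statistic.

    Candidate thresholds are midpoints between consecutive distinct
    sorted values of the feature (missing excluded) with at least
    ``min_side`` cases on each side; ties in the criterion go to the
    smaller threshold.  None when no admissible cut exists.
    """
    x = np.asarray(feature, dtype=float)
    g = _encode_response(np.asarray(response), kind)
    ok = ~np.isnan(x)
    x, g = x[ok], g[ok]
    n = len(x)
    if n < 2 * min_side:
        return None
    order = np.argsort(x, kind="mergesort")
    xs, gs = x[order], g[order]
    csum = np.cumsum(gs)
    total = csum[-1]
    g_mean = total / n
    ssg = float(((gs - g_mean) ** 2).sum())
    if ssg == 0:
        return None
    best_z, best_thr = -1.0, None
    # candidate cut after position i (left side = first i+1 cases)
    for i in range(n - 1):
        if xs[i + 1] <= xs[i]:
            continue
        n_l = i + 1
        if n_l < min_side or n - n_l < min_side:
            continue
        t = csum[i]
        mu = n_l * g_mean
        var = n_l * (n - n_l) / (n * (n - 1)) * ssg
        if var <= 0:
            continue
        z = abs(t - mu) / math.sqrt(var)
        thr = (xs[i] + xs[i + 1]) / 2.0
        if z > best_z + 1e-12:
            best_z, best_thr = z, thr
    return best_thr


def _terminal_summary(response: np.ndarray, kind: str) -> dict:
    y = np.asarray(response)
    if kind == "binary":
        n1 = int((y == 1).sum())
        return {"n": int(len(y)), "n_class1": n1, "prop_class1": n1 / len(y)}
    q1, med, q3 = (float(v) for v in np.percentile(y.astype(float), [25, 50, 75]))
    return {"n": int(len(y)), "median": med, "q1": q1, "q3": q3}


def grow_tree(
    table: pd.DataFrame,
    response,
    params: TreeParams | None = None,
    kind: str | None = None,
) -> TreeModel:
    """Fit a conditional-inference tree on a feature table.

    ``table`` holds numeric feature columns only (pass
    ``table.drop(columns=['gene_id'])`` if needed); ``kind`` defaults to
    'binary' when the response takes only values {0, 1}.
    """
    if params is None:
        params = TreeParams()
    y = np.asarray(response)
    if len(table) == 0:
        raise ValueError("empty feature table")
    if len(table) != len(y):
        raise ValueError("table rows and response length differ")
    if kind is None:
        kind = "binary" if set(np.unique(y)).issubset({0, 1, 0.0, 1.0}) else "continuous"
    X = table.to_numpy(dtype=float)
    # canonical row order keyed to the data itself: the fitted tree is then
    # bit-identical under any permutation of the input rows
    canon = np.lexsort(tuple(X[:, j] for j in reversed(range(X.shape[1]))) + (y,))
    X = X[canon]
    y = y[canon]
    names = list(table.columns)
    counter = itertools.count(1)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(node_id=next(counter), n=len(idx), depth=depth)
        sub_y = y[idx]
        if len(idx) < params.min_node or depth >= params.max_depth:
            node.summary = _terminal_summary(sub_y, kind)
            return node
        sel = select_split_variable(X[idx], sub_y, kind, params)
        if sel is None:
            node.summary = _terminal_summary(sub_y, kind)
            return node
        j, p_adj = sel
        min_side = max(1, params.min_node // 5)
        thr = best_split_point(X[idx, j], sub_y, kind, min_side=min_side)
        if thr is None:
            node.summary = _terminal_summary(sub_y, kind)
            return node
        xj = X[idx, j]
        missing = np.isnan(xj)
        go_left = xj <= thr
        n_left = int((go_left & ~missing).sum())
        n_right = int((~go_left & ~missing).sum())
        missing_left = n_left >= n_right  # ties -> left
        go_left = np.where(missing, missing_left, go_left).astype(bool)
        left_idx = idx[go_left]
        right_idx = idx[~go_left]
        if len(left_idx) == 0 or len(right_idx) == 0:
            node.summary = _terminal_summary(sub_y, kind)
            return node
        node.feature = names[j]
        node.threshold = float(thr)
        node.p_adjusted = p_adj
        node.missing_left = bool(missing_left)
        node.left = build(left_idx, depth + 1)
        node.right = build(right_idx, depth + 1)
        return node

    root = build(np.arange(len(y)), 0)
    return TreeModel(root=root, kind=kind, params=params, feature_names=names)


def tree_rules(tree: TreeModel) -> list[str]:
    """One human-readable rule per terminal node, root conditions first."""
    rules: list[str] = []

    def walk(node: TreeNode, conds: list[str]) -> None:
        if node.is_terminal:
            s = node.summary
            if tree.kind == "binary":
                desc = f"n={s['n']}, P(class 1)={s['prop_class1']:.3f}"
            else:
                desc = f"n={s['n']}, median={s['median']:.3f} [q1={s['q1']:.3f}, q3={s['q3']:.3f}]"
            cond = " AND ".join(conds) if conds else "(all cases)"
            rules.append(f"IF {cond} THEN {desc}")
            return
        walk(node.left, conds + [f"{node.feature} <= {node.threshold:.6g}"])
        walk(node.right, conds + [f"{node.feature} > {node.threshold:.6g}"])

    walk(tree.root, [])
    return rules


def root_feature(tree: TreeModel) -> str | None:
    """Name of the root split feature (None for a single-terminal tree)."""
    return tree.root.feature
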