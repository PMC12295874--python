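"""Monte Carlo Feature Selection with Interdependency Discovery (MCFS-ID).

The algorithm builds many decision (or regression) trees on random subsets of
samples and features.  Each feature g accumulates a relative importance

    RI(g) = sum over trees tau of q(tau)^u * sum over nodes n split on g of
            IG(n) * (n(n) / n(root))^v

where q is the tree's held-out predictive quality (weighted accuracy for
classification, a bounded Pearson quality for regression), IG is the node's
information gain in bits (variance reduction for regression) and n(.) counts
samples reaching a node.  Feature interdependencies accumulate on directed
edges: for every direct parent/child node pair, the edge from the parent's
feature to the child's feature gains IG(child) * n(child)/n(parent).

Significance comes from a permutation scheme: the full procedure is re-run on
uniformly permuted targets, the maximum RI of each permuted run is recorded,
and the cutoff is a percentile (default 95th) of those maxima, so features
above the cutoff beat the best that random labels achieve.

All randomness flows from a single seed; identical inputs and seed give
identical rankings, cutoffs and graphs.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("epireg")

Task = Literal["classification", "regression"]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MCFSParams:
    """Settings for one MCFS-ID run.

    ``m`` is the number of features per projection (the splitSetSize); the
    number of projections ``s`` defaults to enough sweeps for every feature to
    appear in at least ``projections_per_feature`` projections.  ``t`` is the
    number of train/test splits per projection.  ``u`` and ``v`` are the RI
    exponents.  ``mode`` 2 partitions the features into disjoint random blocks
    each sweep (every feature evaluated equally often); mode 1 draws each
    projection independently and uniformly.
    """

    m: int = 200
    s: int | None = None
    projections_per_feature: int = 30
    t: int = 5
    train_fraction: float = 0.66
    u: float = 1.0
    v: float = 1.0
    n_perm: int = 20
    mode: Literal[1, 2] = 2
    task: Task = "classification"
    stratified: bool = True     # class-stratified train/test splits
    min_samples_split: int = 2
    cutoff_percentile: float = 95.0
    cutoff_method: Literal["percentile", "mean_t"] = "percentile"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m (splitSetSize) must be >= 2")
        if self.t < 1 or (self.s is not None and self.s < 1):
            raise ValueError("s*t must be >= 1")
        if self.u < 0 or self.v < 0:
            raise ValueError("RI exponents u, v must be >= 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def entropy(class_counts: Sequence[float]) -> float:
    """Shannon entropy in bits of a count vector."""
    c = np.asarray(class_counts, dtype=float)
    if (c < 0).any() or c.sum() <= 0:
        raise ValueError("class counts must be >= 0 with a positive sum")
    p = c[c > 0] / c.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(parent_labels: Sequence, left: Sequence,
                     right: Sequence) -> float:
    """IG in bits of a binary split: H(parent) - weighted child entropies."""
    def counts(y):
        _, c = np.unique(np.asarray(y), return_counts=True)
        return c
    n = len(parent_labels)
    ig = entropy(counts(parent_labels))
    for child in (left, right):
        ig -= len(child) / n * entropy(counts(child))
    return max(0.0, float(ig))


def variance_reduction(parent_values: Sequence[float],
                       children: Sequence[Sequence[float]]) -> float:
    """Regression analog of IG: population variance of the parent minus the
    sample-weighted population variances of the children (units: value^2)."""
    p = np.asarray(parent_values, dtype=float)
    vr = float(np.var(p))
    for child in children:
        c = np.asarray(child, dtype=float)
        vr -= len(c) / len(p) * float(np.var(c))
    return max(0.0, vr)


def weighted_accuracy(y_true: Sequence, y_pred: Sequence) -> float:
    """Mean of per-class accuracies; classes absent from y_true are excluded."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    accs = [float((yp[yt == c] == c).mean()) for c in np.unique(yt)]
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# Decision / regression trees
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TreeNode:
    """A tree node; internal nodes carry the split and its information gain."""

    n: int
    prediction: float | int
    feature: str | None = None
    threshold: float | None = None
    ig: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclasses.dataclass
class FittedTree:
    root: TreeNode
    quality: float  # held-out q in [0, 1]


def _class_split_scores(Xs: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best IG and threshold per feature for a classification node.

    ``Xs`` is n x m, ``Y`` is the n x C one-hot label matrix.  Returns arrays
    (gain, threshold) of length m; features with no valid split get gain -inf.
    """
    n, m = Xs.shape
    order = np.argsort(Xs, axis=0, kind="stable")
    xs = np.take_along_axis(Xs, order, axis=0)
    # cumulative class counts below each candidate split
    ys = Y[order]                       # n x m x C
    cum = np.cumsum(ys, axis=0)         # counts in left part ending at row k
    total = cum[-1]                     # m x C
    left = cum[:-1]                     # (n-1) x m x C
    right = total[None] - left
    nl = left.sum(axis=2)
    nr = right.sum(axis=2)

    def ent(counts, sizes):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / sizes[..., None]
            t = np.where(counts > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        return t.sum(axis=2)

    h_parent = ent(total[None], total.sum(axis=1)[None])[0]
    ig = h_parent[None, :] - (nl / n) * ent(left, nl) - (nr / n) * ent(right, nr)
    valid = xs[:-1] < xs[1:]
    ig = np.where(valid, ig, -np.inf)
    best_k = np.argmax(ig, axis=0)
    gain = ig[best_k, np.arange(m)]
    thr = (xs[best_k, np.arange(m)] + xs[best_k + 1, np.arange(m)]) / 2.0
    return gain, thr


def _reg_split_scores(Xs: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best variance reduction and threshold per feature (regression node)."""
    n, m = Xs.shape
    order = np.argsort(Xs, axis=0, kind="stable")
    xs = np.take_along_axis(Xs, order, axis=0)
    ys = y[order]                       # n x m
    cs = np.cumsum(ys, axis=0)
    cs2 = np.cumsum(ys ** 2, axis=0)
    tot, tot2 = cs[-1], cs2[-1]
    k = np.arange(1, n)[:, None].astype(float)
    left_var = cs2[:-1] / k - (cs[:-1] / k) ** 2
    nr = n - k
    right_sum = tot[None] - cs[:-1]
    right_var = (tot2[None] - cs2[:-1]) / nr - (right_sum / nr) ** 2
    parent_var = tot2 / n - (tot / n) ** 2
    vr = parent_var[None] - (k / n) * left_var - (nr / n) * right_var
    valid = xs[:-1] < xs[1:]
    vr = np.where(valid, vr, -np.inf)
    best_k = np.argmax(vr, axis=0)
    gain = vr[best_k, np.arange(m)]
    thr = (xs[best_k, np.arange(m)] + xs[best_k + 1, np.arange(m)]) / 2.0
    return gain, thr


_GAIN_TOL = 1e-12


def build_tree(X: np.ndarray, y: np.ndarray, feature_ids: Sequence[str],
               task: Task = "classification",
               min_samples_split: int = 2,
               feature_rank: np.ndarray | None = None) -> TreeNode:
    """Greedy binary tree maximizing IG (or variance reduction).

    Ties between features are broken by lexicographic feature ID.  Stops when
    a node is pure, smaller than ``min_samples_split`` or has no positive-gain
    split; all-constant features give a single leaf.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError("need >= 1 sample and >= 1 feature")
    feature_ids = list(feature_ids)
    if feature_rank is None:
        feature_rank = np.argsort(np.argsort(feature_ids))
    if task == "classification":
        classes, y_enc = np.unique(y, return_inverse=True)
        Y = np.eye(len(classes))[y_enc]
    else:
        y_enc = np.asarray(y, dtype=float)
        Y = None

    def predict_leaf(idx: np.ndarray):
        if task == "classification":
            counts = Y[idx].sum(axis=0)
            return classes[int(np.argmax(counts))]  # ties -> first class
        return float(y_enc[idx].mean())

    def grow(idx: np.ndarray) -> TreeNode:
        node = TreeNode(n=len(idx), prediction=predict_leaf(idx))
        if len(idx) < max(2, min_samples_split):
            return node
        yi = y_enc[idx]
        if task == "classification":
            if (yi == yi[0]).all():
                return node
            gain, thr = _class_split_scores(X[idx], Y[idx])
        else:
            if np.ptp(yi) == 0:
                return node
            gain, thr = _reg_split_scores(X[idx], yi)
        best = gain.max()
        if not np.isfinite(best) or best <= _GAIN_TOL:
            return node
        cand = np.nonzero(gain >= best - _GAIN_TOL)[0]
        j = cand[np.argmin(feature_rank[cand])]
        node.feature = feature_ids[j]
        node.threshold = float(thr[j])
        node.ig = float(gain[j])
        mask = X[idx, j] <= node.threshold
        node.left = grow(idx[mask])
        node.right = grow(idx[~mask])
        return node

    return grow(np.arange(X.shape[0]))


def predict_tree(root: TreeNode, X: np.ndarray,
                 feature_index: dict[str, int]) -> np.ndarray:
    out = np.empty(X.shape[0], dtype=object)
    for i in range(X.shape[0]):
        node = root
        while not node.is_leaf:
            j = feature_index[node.feature]
            node = node.left if X[i, j] <= node.threshold else node.right
        out[i] = node.prediction
    return out


def tree_quality(root: TreeNode, X_test: np.ndarray, y_test: np.ndarray,
                 feature_index: dict[str, int], task: Task) -> float:
    """Held-out quality q in [0, 1]: wAcc for classification, clipped Pearson
    correlation between predictions and truth for regression."""
    pred = predict_tree(root, X_test, feature_index)
    if task == "classification":
        return weighted_accuracy(y_test, pred)
    pred = pred.astype(float)
    yt = np.asarray(y_test, dtype=float)
    if np.ptp(pred) == 0 or np.ptp(yt) == 0:
        return 0.0
    return float(max(0.0, np.corrcoef(pred, yt)[0, 1]))


# ---------------------------------------------------------------------------
# RI accumulation and the ID graph
# ---------------------------------------------------------------------------

def _walk(node: TreeNode):
    stack = [node]
    while stack:
        nd = stack.pop()
        yield nd
        if not nd.is_leaf:
            stack.extend((nd.left, nd.right))


def accumulate_ri(tree: FittedTree, u: float, v: float,
                  ri: dict[str, float]) -> None:
    root_n = tree.root.n
    qu = tree.quality ** u
    for node in _walk(tree.root):
        if node.is_leaf:
            continue
        ri[node.feature] = ri.get(node.feature, 0.0) + (
            qu * node.ig * (node.n / root_n) ** v)


def ri_from_trees(trees: Sequence[FittedTree], u: float = 1.0,
                  v: float = 1.0) -> dict[str, float]:
    """RI per feature from a set of fitted trees (the documented formula)."""
    ri: dict[str, float] = {}
    for t in trees:
        accumulate_ri(t, u, v, ri)
    return ri


class IDGraph:
    """Directed feature-interdependency graph with accumulated edge weights."""

    def __init__(self) -> None:
        self.edges: dict[tuple[str, str], float] = {}

    def add(self, parent: str, child: str, weight: float) -> None:
        if weight <= 0:
            return
        self.edges[(parent, child)] = self.edges.get((parent, child), 0.0) + weight

    def merge(self, other: "IDGraph") -> None:
        for (p, c), w in other.edges.items():
            self.add(p, c, w)

    @property
    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(((p, c, w) for (p, c), w in self.edges.items()),
                      key=lambda r: (-r[2], r[0], r[1]))
        return pd.DataFrame(rows, columns=["parent", "child", "weight"])

    def to_networkx(self):
        import networkx as nx
        g = nx.DiGraph()
        for (p, c), w in self.edges.items():
            g.add_edge(p, c, weight=w)
        return g


def compute_id_graph(trees: Sequence[FittedTree]) -> IDGraph:
    """Accumulate ID edges over direct parent/child node pairs of all trees:
    edge(parent feature -> child feature) += IG(child) * n(child)/n(parent)."""
    g = IDGraph()
    for t in trees:
        for node in _walk(t.root):
            if node.is_leaf:
                continue
            for child in (node.left, node.right):
                if child is not None and not child.is_leaf:
                    g.add(node.feature, child.feature,
                          child.ig * child.n / node.n)
    return g


def idgraph_view(graph: IDGraph, ranking: pd.DataFrame, top_nodes: int,
                 top_edges: int) -> IDGraph:
    """Restrict to the ``top_nodes`` features by RI, then keep the
    ``top_edges`` strongest edges among them (ties lexicographic)."""
    keep = set(ranking.sort_values(
        ["RI", "feature"], ascending=[False, True])["feature"].head(top_nodes))
    edges = [((p, c), w) for (p, c), w in graph.edges.items()
             if p in keep and c in keep]
    edges.sort(key=lambda e: (-e[1], e[0][0], e[0][1]))
    out = IDGraph()
    for (p, c), w in edges[:top_edges]:
        out.add(p, c, w)
    return out


# ---------------------------------------------------------------------------
# The full MCFS-ID procedure
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MCFSResult:
    ranking: pd.DataFrame        # feature, RI, rank[, significant]
    id_graph: IDGraph
    cutoff: float | None = None
    params: MCFSParams | None = None

    @property
    def significant(self) -> list[str]:
        if "significant" not in self.ranking.columns:
            raise ValueError("run with a permutation cutoff to get significance")
        return list(self.ranking.loc[self.ranking["significant"], "feature"])


def _projections(p: int, params: MCFSParams,
                 rng: np.random.Generator) -> list[np.ndarray]:
    m = min(params.m, p)
    if m < params.m:
        warnings.warn(f"splitSetSize {params.m} clamped to {m} available features")
    if params.mode == 2:
        blocks_per_sweep = int(np.ceil(p / m))
        if params.s is not None:
            sweeps = max(1, int(np.ceil(params.s / blocks_per_sweep)))
        else:
            sweeps = params.projections_per_feature
        out = []
        for _ in range(sweeps):
            perm = rng.permutation(p)
            out.extend(perm[i * m:(i + 1) * m]
                       for i in range(blocks_per_sweep))
        return out
    s = params.s
    if s is None:
        s = max(1, int(np.ceil(params.projections_per_feature * p / m)))
    return [rng.choice(p, size=m, replace=False) for _ in range(s)]


def run_mcfs(X: pd.DataFrame, y: pd.Series | np.ndarray,
             params: MCFSParams,
             collect_trees: bool = False,
             rng: np.random.Generator | None = None
             ) -> MCFSResult | tuple[MCFSResult, list[FittedTree]]:
    """One MCFS-ID run: projections, train/test splits, trees, RI, ID graph.

    ``X`` has samples in rows and features in columns (no missing values);
    ``y`` is the decision (classification) or numeric target (regression).
    """
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y)
    if Xv.shape[0] != len(yv):
        raise ValueError("target length must equal the sample count")
    if np.isnan(Xv).any():
        raise ValueError("missing values in the feature matrix")
    n, p = Xv.shape
    feature_ids = [str(c) for c in X.columns]
    lex_rank = np.argsort(np.argsort(feature_ids))
    if rng is None:
        rng = np.random.default_rng(params.seed)

    ri: dict[str, float] = {}
    graph = IDGraph()
    all_trees: list[FittedTree] = []
    n_train = max(2, int(round(params.train_fraction * n)))
    n_train = min(n_train, n - 1)
    stratify = params.stratified and params.task == "classification"
    if stratify:
        class_idx = [np.nonzero(yv == c)[0] for c in np.unique(yv)]

    def draw_split() -> tuple[np.ndarray, np.ndarray]:
        if stratify:
            tr_parts, te_parts = [], []
            for idx in class_idx:
                k = max(1, min(len(idx) - 1,
                               int(round(params.train_fraction * len(idx)))))
                perm = rng.permutation(idx)
                tr_parts.append(perm[:k])
                te_parts.append(perm[k:])
            return np.concatenate(tr_parts), np.concatenate(te_parts)
        perm = rng.permutation(n)
        return perm[:n_train], perm[n_train:]

    for proj in _projections(p, params, rng):
        ids = [feature_ids[j] for j in proj]
        ranks = lex_rank[proj]
        fidx = {f: k for k, f in enumerate(ids)}
        Xp = Xv[:, proj]
        for _ in range(params.t):
            for _attempt in range(20):
                tr, te = draw_split()
                if params.task != "classification":
                    break
                if len(np.unique(yv[tr])) >= 2:
                    break
            else:
                warnings.warn("could not draw a training split with >= 2 "
                              "classes; projection split skipped")
                continue
            root = build_tree(Xp[tr], yv[tr], ids, task=params.task,
                              min_samples_split=params.min_samples_split,
                              feature_rank=ranks)
            q = tree_quality(root, Xp[te], yv[te], fidx, params.task)
            tree = FittedTree(root=root, quality=q)
            accumulate_ri(tree, params.u, params.v, ri)
            graph.merge(compute_id_graph([tree]))
            if collect_trees:
                all_trees.append(tree)

    ranking = pd.DataFrame({
        "feature": feature_ids,
        "RI": [ri.get(f, 0.0) for f in feature_ids],
    })
    ranking = ranking.sort_values(["RI", "feature"],
                                  ascending=[False, True]).reset_index(drop=True)
    ranking["rank"] = np.arange(1, p + 1)
    result = MCFSResult(ranking=ranking, id_graph=graph, params=params)
    if collect_trees:
        return result, all_trees
    return result


def permutation_cutoff(X: pd.DataFrame, y: pd.Series | np.ndarray,
                       params: MCFSParams,
                       rng: np.random.Generator | None = None) -> float:
    """RI significance cutoff from ``n_perm`` runs on permuted targets.

    Each permuted run records its maximum RI; the cutoff is the
    ``cutoff_percentile`` of those maxima (or mean + t-interval upper bound
    with ``cutoff_method="mean_t"``).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    yv = np.asarray(y)
    maxima = []
    for _ in range(params.n_perm):
        y_perm = rng.permutation(yv)
        sub = run_mcfs(X, y_perm, params, rng=rng)
        maxima.append(float(sub.ranking["RI"].max()))
    maxima = np.asarray(maxima)
    if params.cutoff_method == "mean_t":
        from scipy import stats
        if len(maxima) == 1:
            return float(maxima[0])
        se = maxima.std(ddof=1) / np.sqrt(len(maxima))
        return float(maxima.mean() +
                     stats.t.ppf(0.95, len(maxima) - 1) * se)
    return float(np.percentile(maxima, params.cutoff_percentile))


def run_mcfs_with_cutoff(X: pd.DataFrame, y: pd.Series | np.ndarray,
                         params: MCFSParams) -> MCFSResult:
    """Full run plus permutation cutoff and per-feature significance flags."""
    rng = np.random.default_rng(params.seed)
    result = run_mcfs(X, y, params, rng=rng)
    cutoff = permutation_cutoff(X, y, params,
                                rng=np.random.default_rng(params.seed + 1))
    result.cutoff = cutoff
    result.ranking["significant"] = result.ranking["RI"] > cutoff
    log.info("MCFS cutoff %.4f: %d of %d features significant",
             cutoff, int(result.ranking["significant"].sum()),
             len(result.ranking))
    return result


# ---------------------------------------------------------------------------
# A bagged random forest built from this package's trees
# ---------------------------------------------------------------------------

def random_forest_predict(X_train: pd.DataFrame, y_train: Sequence,
                          X_test: pd.DataFrame, n_trees: int = 100,
                          seed: int = 0) -> np.ndarray:
    """Majority vote over bootstrap trees, each on a sqrt-sized feature draw."""
    rng = np.random.default_rng(seed)
    Xtr = X_train.to_numpy(dtype=float)
    Xte = X_test.to_numpy(dtype=float)
    yv = np.asarray(y_train)
    n, p = Xtr.shape
    k = max(1, int(np.ceil(np.sqrt(p))))
    ids = [str(c) for c in X_train.columns]
    votes: list[np.ndarray] = []
    for _ in range(n_trees):
        rows = rng.integers(0, n, size=n)
        cols = rng.choice(p, size=k, replace=False)
        sub_ids = [ids[j] for j in cols]
        if len(np.unique(yv[rows])) < 2:
            continue
        root = build_tree(Xtr[np.ix_(rows, cols)], yv[rows], sub_ids)
        fidx = {f: j for j, f in enumerate(sub_ids)}
        votes.append(predict_tree(root, Xte[:, cols], fidx))
    stacked = np.vstack(votes)
    out = np.empty(stacked.shape[1], dtype=object)
    for i in range(stacked.shape[1]):
        vals, counts = np.unique(stacked[:, i], return_counts=True)
        out[i] = vals[np.argmax(counts)]
    return out
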