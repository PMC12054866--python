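"""Ordinal classification trees and bagged ordinal forests.

Trees are grown on encoded design matrices with split quality measured on
the ordinal scale: the default CART criterion is the total misclassification
cost with absolute rank distance |i - j| (each child labelled with its
cost-minimizing category); a generalized Gini impurity with the same linear
costs is available and is the default for forest trees, whose near-pure
nodes it keeps splitting (plain cost reduction plateaus on noise, which
would starve deep growth). Cost-complexity pruning removes subtrees whose
per-split cost reduction falls below ``cp`` times the root cost. Terminal
prediction is the modal category of the training rows in the leaf; class
proportions are retained for probability output.

Forests are bagged ordinal trees: each tree is grown unpruned with a small
minimum node size on a bootstrap resample, sampling ``mtry`` candidate
variables (whole blocks) at every split. This is deliberately a plain
bagging scheme, not the published ordinal-forest score-set optimization,
whose extra hyperparameters the underlying study found immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ordval._fast_tree import HAVE_NUMBA, grow_forest_tree
from ordval.preprocess import DesignMatrix

K_CATEGORIES = 3
# cost[g, k]: cost of labelling a category-(k+1) row as category g+1
COST_ABS = np.abs(np.subtract.outer(np.arange(K_CATEGORIES), np.arange(K_CATEGORIES))).astype(float)
COST_QUAD = COST_ABS**2

_GAIN_TOL = 1e-12


def _cost_matrix(criterion: str) -> np.ndarray:
    if criterion in ("cost", "gini"):
        return COST_ABS
    if criterion in ("cost_quad", "gini_quad"):
        return COST_QUAD
    raise ValueError(f"unknown criterion {criterion!r}")


def _node_cost(counts: np.ndarray, C: np.ndarray) -> float:
    """Minimum total labelling cost of a node (cost-optimal single label)."""
    return float((C @ counts).min())


def _node_impurity(counts: np.ndarray, C: np.ndarray) -> float:
    """Size-weighted generalized Gini impurity n * sum C_kl p_k p_l."""
    n = counts.sum()
    if n == 0:
        return 0.0
    return float(counts @ C @ counts) / n


@dataclass
class _Node:
    counts: np.ndarray
    pred: int  # modal category, 1-based
    col: int = -1  # split column; -1 for a leaf
    thr: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    cost: float = 0.0  # this node's labelling cost if made a leaf

    @property
    def is_leaf(self) -> bool:
        return self.col < 0

    @property
    def probs(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass
class TreeFit:
    """A fitted ordinal tree."""

    root: _Node
    cp: float
    minsplit: int
    criterion: str
    n_train: int
    family: str = "CART"

    def _leaf_arrays(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized routing: (leaf probs, leaf modal category) per row."""
        n = X.shape[0]
        probs = np.empty((n, K_CATEGORIES))
        preds = np.empty(n, dtype=int)
        stack = [(self.root, np.arange(n))]
        while stack:
            node, rows = stack.pop()
            if rows.size == 0:
                continue
            if node.is_leaf:
                probs[rows] = node.probs
                preds[rows] = node.pred
            else:
                mask = X[rows, node.col] <= node.thr
                stack.append((node.left, rows[mask]))
                stack.append((node.right, rows[~mask]))
        return probs, preds

    def predict_proba(self, dm_or_X) -> np.ndarray:
        X = dm_or_X.X if isinstance(dm_or_X, DesignMatrix) else np.asarray(dm_or_X, dtype=float)
        return self._leaf_arrays(X)[0]

    def predict_category(self, dm_or_X) -> np.ndarray:
        X = dm_or_X.X if isinstance(dm_or_X, DesignMatrix) else np.asarray(dm_or_X, dtype=float)
        return self._leaf_arrays(X)[1]

    def n_leaves(self) -> int:
        def count(node: _Node) -> int:
            return 1 if node.is_leaf else count(node.left) + count(node.right)

        return count(self.root)

    def depth(self) -> int:
        def d(node: _Node) -> int:
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))

        return d(self.root)

    def _flatten(self):
        cols, thrs, lefts, rights, counts = [], [], [], [], []

        def walk(node: _Node) -> int:
            i = len(cols)
            cols.append(node.col)
            thrs.append(node.thr)
            lefts.append(-1)
            rights.append(-1)
            counts.append(node.counts.tolist())
            if not node.is_leaf:
                lefts[i] = walk(node.left)
                rights[i] = walk(node.right)
            return i

        walk(self.root)
        return cols, thrs, lefts, rights, counts

    def to_jsonable(self) -> dict:
        cols, thrs, lefts, rights, counts = self._flatten()
        return {
            "version": 1,
            "family": self.family,
            "cp": self.cp,
            "minsplit": self.minsplit,
            "criterion": self.criterion,
            "n_train": self.n_train,
            "nodes": {"col": cols, "thr": thrs, "left": lefts, "right": rights,
                      "counts": counts},
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "TreeFit":
        nd = d["nodes"]
        root = _root_from_arrays(
            np.asarray(nd["col"]), np.asarray(nd["thr"]),
            np.asarray(nd["left"]), np.asarray(nd["right"]),
            np.asarray(nd["counts"], dtype=float),
        )
        return cls(root=root, cp=d["cp"], minsplit=d["minsplit"],
                   criterion=d["criterion"], n_train=d["n_train"])


def _best_split(
    X: np.ndarray,
    onehot: np.ndarray,
    idx: np.ndarray,
    cols: np.ndarray,
    C: np.ndarray,
    criterion: str,
    parent_score: float,
):
    """Best (col, thr, gain, left_idx, right_idx) over candidate columns.

    ``parent_score`` is the node's score under the active criterion
    (labelling cost or size-weighted Gini impurity); only strictly
    score-reducing splits are returned. All candidate columns are scanned
    in one vectorized pass; ties go to the first (lowest column index,
    lowest cut) candidate.
    """
    use_gini = criterion.startswith("gini")
    sub = X[np.ix_(idx, cols)]  # (m, c)
    m, c = sub.shape
    order = np.argsort(sub, axis=0, kind="stable")
    xs = np.take_along_axis(sub, order, axis=0)
    valid = xs[:-1] < xs[1:]  # (m-1, c)
    if not valid.any():
        return None
    oh = onehot[idx]  # (m, K)
    cum = np.cumsum(oh[order], axis=0)[:-1]  # (m-1, c, K) left counts
    total = oh.sum(axis=0)  # (K,)
    right = total[None, None, :] - cum
    if use_gini:
        lsize = np.arange(1, m, dtype=float)[:, None]
        lscore = _pair_impurity(cum, C) / lsize
        rscore = _pair_impurity(right, C) / (m - lsize)
    else:
        lscore = (cum @ C.T).min(axis=2)
        rscore = (right @ C.T).min(axis=2)
    child = lscore + rscore
    child[~valid] = np.inf
    flat = int(np.argmin(child.T))  # column-major: lowest column, then lowest cut
    j, i = flat // (m - 1), flat % (m - 1)
    gain = parent_score - child[i, j]
    if gain <= _GAIN_TOL:
        return None
    col = int(cols[j])
    thr = float((xs[i, j] + xs[i + 1, j]) / 2.0)
    left_idx = idx[order[: i + 1, j]]
    right_idx = idx[order[i + 1 :, j]]
    return col, thr, float(gain), left_idx, right_idx


def _pair_impurity(counts: np.ndarray, C: np.ndarray) -> np.ndarray:
    """sum_{k,l} C[k,l] n_k n_l along the last axis of a counts array."""
    return ((counts @ C) * counts).sum(axis=-1)


def _grow(
    X: np.ndarray,
    onehot: np.ndarray,
    idx: np.ndarray,
    minsplit: int,
    C: np.ndarray,
    criterion: str,
    block_cols: list[np.ndarray] | None,
    mtry: int | None,
    rng: np.random.Generator | None,
) -> _Node:
    counts = onehot[idx].sum(axis=0)
    node = _Node(
        counts=counts,
        pred=int(np.argmax(counts)) + 1,
        cost=_node_cost(counts, C),  # labelling cost, used by pruning
    )
    parent_score = (
        _node_impurity(counts, C) if criterion.startswith("gini") else node.cost
    )
    if len(idx) < minsplit or parent_score <= 0:
        return node
    if mtry is not None:
        chosen = rng.choice(len(block_cols), size=min(mtry, len(block_cols)), replace=False)
        cols = np.concatenate([block_cols[i] for i in sorted(chosen)])
    else:
        cols = np.arange(X.shape[1])
    split = _best_split(X, onehot, idx, cols, C, criterion, parent_score)
    if split is None:
        return node
    col, thr, _, left_idx, right_idx = split
    node.col = col
    node.thr = thr
    node.left = _grow(X, onehot, left_idx, minsplit, C, criterion, block_cols, mtry, rng)
    node.right = _grow(X, onehot, right_idx, minsplit, C, criterion, block_cols, mtry, rng)
    return node


def _prune(node: _Node, cp: float, root_cost: float) -> tuple[float, int]:
    """Weakest-link pruning: collapse subtrees whose cost reduction per
    split is below cp * root_cost. Returns (subtree cost, leaf count)."""
    if node.is_leaf:
        return node.cost, 1
    lcost, lleaves = _prune(node.left, cp, root_cost)
    rcost, rleaves = _prune(node.right, cp, root_cost)
    sub_cost = lcost + rcost
    n_leaves = lleaves + rleaves
    if node.cost - sub_cost <= cp * root_cost * (n_leaves - 1) + _GAIN_TOL:
        node.col = -1
        node.left = node.right = None
        return node.cost, 1
    return sub_cost, n_leaves


def fit_tree(
    dm_or_X,
    y: np.ndarray,
    cp: float = 0.01,
    minsplit: int = 20,
    criterion: str = "cost",
) -> TreeFit:
    """Grow and cost-complexity-prune one ordinal tree.

    ``cp`` >= 0 scales the pruning penalty by the root's labelling cost (a
    split survives only if it reduces total cost by more than
    cp * root_cost per added leaf); ``minsplit`` >= 2 is the minimum node
    size eligible for splitting. ``minsplit`` larger than n yields a
    root-only tree.
    """
    X = dm_or_X.X if isinstance(dm_or_X, DesignMatrix) else np.asarray(dm_or_X, dtype=float)
    y = np.asarray(y, dtype=int)
    if cp < 0:
        raise ValueError("cp must be nonnegative")
    if minsplit < 2:
        raise ValueError("minsplit must be >= 2")
    C = _cost_matrix(criterion)
    cost_C = _cost_matrix("cost" if criterion in ("cost", "gini") else "cost_quad")
    if HAVE_NUMBA:
        p = X.shape[1]
        arrays = grow_forest_tree(
            X, y, np.arange(len(y)), minsplit, C, criterion.startswith("gini"),
            [np.array([j]) for j in range(p)], max(p, 1), 0,
        )
        root = _root_from_arrays(*arrays, cost_C=cost_C)
    else:  # pragma: no cover - exercised only without numba
        onehot = np.eye(K_CATEGORIES)[y - 1]
        root = _grow(X, onehot, np.arange(len(y)), minsplit, C, criterion, None, None, None)
    root_cost = _node_cost(np.bincount(y, minlength=K_CATEGORIES + 1)[1:].astype(float), cost_C)
    if root_cost > 0:
        _prune(root, cp, root_cost)
    return TreeFit(root=root, cp=cp, minsplit=minsplit, criterion=criterion, n_train=len(y))


def _root_from_arrays(node_col, node_thr, node_left, node_right, node_counts,
                      cost_C: np.ndarray = COST_ABS) -> _Node:
    """Rebuild the linked _Node tree from the fast grower's flat arrays."""
    nodes = []
    for i in range(len(node_col)):
        counts = node_counts[i]
        nodes.append(
            _Node(
                counts=counts,
                pred=int(np.argmax(counts)) + 1,
                col=int(node_col[i]),
                thr=float(node_thr[i]),
                cost=_node_cost(counts, cost_C),
            )
        )
    for i in range(len(node_col)):
        if node_col[i] >= 0:
            nodes[i].left = nodes[int(node_left[i])]
            nodes[i].right = nodes[int(node_right[i])]
    return nodes[0]


@dataclass
class ForestFit:
    """Bagged ordinal trees with per-split variable sampling."""

    trees: list[TreeFit]
    inbag: list[np.ndarray]  # bootstrap indices per tree
    mtry: int
    ntree: int
    n_train: int
    block_names: list[str] = field(default_factory=list)
    family: str = "RF"

    def predict_proba(self, dm_or_X) -> np.ndarray:
        X = dm_or_X.X if isinstance(dm_or_X, DesignMatrix) else np.asarray(dm_or_X, dtype=float)
        acc = np.zeros((X.shape[0], K_CATEGORIES))
        for tree in self.trees:
            acc += tree.predict_proba(X)
        return acc / len(self.trees)

    def oob_proba(self, dm_or_X) -> tuple[np.ndarray, np.ndarray]:
        """Out-of-bag probabilities on the training matrix.

        Returns (probs, covered): rows never out of bag get the marginal
        training distribution and covered=False.
        """
        X = dm_or_X.X if isinstance(dm_or_X, DesignMatrix) else np.asarray(dm_or_X, dtype=float)
        n = X.shape[0]
        acc = np.zeros((n, K_CATEGORIES))
        cnt = np.zeros(n)
        for tree, bag in zip(self.trees, self.inbag):
            mask = np.ones(n, dtype=bool)
            mask[bag] = False
            if mask.any():
                acc[mask] += tree.predict_proba(X[mask])
                cnt[mask] += 1
        covered = cnt > 0
        probs = np.full((n, K_CATEGORIES), 1.0 / K_CATEGORIES)
        probs[covered] = acc[covered] / cnt[covered, None]
        return probs, covered

    def to_jsonable(self) -> dict:
        return {
            "version": 1,
            "family": self.family,
            "mtry": self.mtry,
            "ntree": self.ntree,
            "n_train": self.n_train,
            "block_names": list(self.block_names),
            "inbag": [bag.tolist() for bag in self.inbag],
            "trees": [t.to_jsonable() for t in self.trees],
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "ForestFit":
        return cls(
            trees=[TreeFit.from_jsonable(t) for t in d["trees"]],
            inbag=[np.asarray(b, dtype=int) for b in d["inbag"]],
            mtry=d["mtry"],
            ntree=d["ntree"],
            n_train=d["n_train"],
            block_names=list(d["block_names"]),
        )


def fit_forest(
    dm: DesignMatrix,
    y: np.ndarray,
    mtry: int,
    ntree: int = 500,
    minsplit: int = 5,
    criterion: str = "gini",
    bootstrap: bool = True,
    seed: int | np.random.Generator = 0,
) -> ForestFit:
    """Bagged ordinal trees: unpruned, mtry variables sampled per split."""
    y = np.asarray(y, dtype=int)
    n_blocks = len(dm.main_blocks)
    if not (1 <= mtry <= n_blocks):
        raise ValueError(f"mtry must be in 1..{n_blocks}")
    if ntree < 1:
        raise ValueError("ntree must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    block_cols = [np.asarray(dm.blocks[b], dtype=int) for b in dm.main_blocks]
    C = _cost_matrix(criterion)
    n = dm.n
    trees: list[TreeFit] = []
    inbag: list[np.ndarray] = []
    onehot = None if HAVE_NUMBA else np.eye(K_CATEGORIES)[y - 1]
    Xc = np.ascontiguousarray(dm.X, dtype=np.float64)
    for _ in range(ntree):
        bag = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        if HAVE_NUMBA:
            tree_seed = int(rng.integers(0, 2**31 - 1))
            arrays = grow_forest_tree(
                Xc, y, np.sort(bag), minsplit, C, criterion.startswith("gini"),
                block_cols, mtry, tree_seed,
            )
            root = _root_from_arrays(*arrays)
        else:  # pragma: no cover - exercised only without numba
            root = _grow(
                Xc, onehot, np.sort(bag), minsplit, C, criterion, block_cols, mtry, rng
            )
        trees.append(
            TreeFit(root=root, cp=0.0, minsplit=minsplit, criterion=criterion, n_train=n)
        )
        inbag.append(bag)
    return ForestFit(
        trees=trees,
        inbag=inbag,
        mtry=mtry,
        ntree=ntree,
        n_train=n,
        block_names=list(dm.main_blocks),
    )
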