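"""Numba-accelerated grower for forest trees.

Grows one ordinal tree iteratively on flat arrays (no pruning; forests are
grown unpruned). The split criterion, tie-breaking (lowest column, then
lowest cut) and per-split mtry block sampling mirror the reference NumPy
grower in :mod:`ordval.tree`; with mtry equal to all variables and the
same growth settings the two produce identical trees. Falls back silently
when numba is unavailable (``HAVE_NUMBA`` is False).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco


_GAIN_TOL = 1e-12


@njit(cache=True)
def _leaf_score(c0, c1, c2, C, use_gini):
    if use_gini:
        m = c0 + c1 + c2
        if m <= 0.0:
            return 0.0
        s = 0.0
        s += C[0, 1] * c0 * c1 * 2.0
        s += C[0, 2] * c0 * c2 * 2.0
        s += C[1, 2] * c1 * c2 * 2.0
        s += C[0, 0] * c0 * c0 + C[1, 1] * c1 * c1 + C[2, 2] * c2 * c2
        return s / m
    best = 1e300
    for g in range(3):
        v = C[g, 0] * c0 + C[g, 1] * c1 + C[g, 2] * c2
        if v < best:
            best = v
    return best


@njit(cache=True)
def _grow_nb(X, y, bag, minsplit, C, use_gini, block_cols, block_ptr, mtry, seed):
    np.random.seed(seed)
    n_bag = bag.shape[0]
    max_nodes = 2 * n_bag + 1
    node_col = np.full(max_nodes, -1, np.int64)
    node_thr = np.zeros(max_nodes)
    node_left = np.full(max_nodes, -1, np.int64)
    node_right = np.full(max_nodes, -1, np.int64)
    node_counts = np.zeros((max_nodes, 3))
    idx = bag.copy()
    tmp = np.empty(n_bag, np.int64)
    n_blocks = block_ptr.shape[0] - 1
    perm = np.empty(n_blocks, np.int64)
    max_cols = X.shape[1]
    cand = np.empty(max_cols, np.int64)
    stack_s = np.empty(max_nodes, np.int64)
    stack_e = np.empty(max_nodes, np.int64)
    stack_n = np.empty(max_nodes, np.int64)
    stack_s[0] = 0
    stack_e[0] = n_bag
    stack_n[0] = 0
    top = 1
    n_nodes = 1
    while top > 0:
        top -= 1
        s = stack_s[top]
        e = stack_e[top]
        nid = stack_n[top]
        m = e - s
        c0 = 0.0
        c1 = 0.0
        c2 = 0.0
        for i in range(s, e):
            yy = y[idx[i]]
            if yy == 1:
                c0 += 1.0
            elif yy == 2:
                c1 += 1.0
            else:
                c2 += 1.0
        node_counts[nid, 0] = c0
        node_counts[nid, 1] = c1
        node_counts[nid, 2] = c2
        parent = _leaf_score(c0, c1, c2, C, use_gini)
        if m < minsplit or parent <= _GAIN_TOL:
            continue
        # sample mtry blocks (partial Fisher-Yates), candidate cols in
        # ascending block order for deterministic tie-breaking
        for i in range(n_blocks):
            perm[i] = i
        take = mtry if mtry < n_blocks else n_blocks
        for i in range(take):
            j = i + np.random.randint(0, n_blocks - i)
            t = perm[i]
            perm[i] = perm[j]
            perm[j] = t
        for i in range(1, take):  # insertion sort of the chosen block ids
            key = perm[i]
            j = i - 1
            while j >= 0 and perm[j] > key:
                perm[j + 1] = perm[j]
                j -= 1
            perm[j + 1] = key
        ccount = 0
        for i in range(take):
            b = perm[i]
            for q in range(block_ptr[b], block_ptr[b + 1]):
                cand[ccount] = block_cols[q]
                ccount += 1
        best_child = parent - _GAIN_TOL
        best_col = -1
        best_thr = 0.0
        xv = np.empty(m)
        for ci in range(ccount):
            col = cand[ci]
            for i in range(m):
                xv[i] = X[idx[s + i], col]
            order = np.argsort(xv)
            l0 = 0.0
            l1 = 0.0
            l2 = 0.0
            for i in range(m - 1):
                yy = y[idx[s + order[i]]]
                if yy == 1:
                    l0 += 1.0
                elif yy == 2:
                    l1 += 1.0
                else:
                    l2 += 1.0
                xa = xv[order[i]]
                xb = xv[order[i + 1]]
                if xa < xb:
                    score = _leaf_score(l0, l1, l2, C, use_gini) + _leaf_score(
                        c0 - l0, c1 - l1, c2 - l2, C, use_gini
                    )
                    if score < best_child:
                        best_child = score
                        best_col = col
                        best_thr = (xa + xb) / 2.0
        if best_col < 0:
            continue
        # stable partition by threshold
        nl = 0
        for i in range(s, e):
            if X[idx[i], best_col] <= best_thr:
                tmp[nl] = idx[i]
                nl += 1
        nr = nl
        for i in range(s, e):
            if X[idx[i], best_col] > best_thr:
                tmp[nr] = idx[i]
                nr += 1
        for i in range(m):
            idx[s + i] = tmp[i]
        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        node_col[nid] = best_col
        node_thr[nid] = best_thr
        node_left[nid] = lid
        node_right[nid] = rid
        stack_s[top] = s
        stack_e[top] = s + nl
        stack_n[top] = lid
        stack_s[top + 1] = s + nl
        stack_e[top + 1] = e
        stack_n[top + 1] = rid
        top += 2
    return node_col[:n_nodes], node_thr[:n_nodes], node_left[:n_nodes], node_right[:n_nodes], node_counts[:n_nodes]


def grow_forest_tree(
    X: np.ndarray,
    y: np.ndarray,
    bag: np.ndarray,
    minsplit: int,
    C: np.ndarray,
    use_gini: bool,
    block_cols_list: list[np.ndarray],
    mtry: int,
    seed: int,
):
    """Grow one tree and return flat node arrays (numba fast path)."""
    block_ptr = np.zeros(len(block_cols_list) + 1, dtype=np.int64)
    for i, bc in enumerate(block_cols_list):
        block_ptr[i + 1] = block_ptr[i] + len(bc)
    block_cols = (
        np.concatenate(block_cols_list).astype(np.int64)
        if block_cols_list
        else np.zeros(0, np.int64)
    )
    return _grow_nb(
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.int64),
        np.ascontiguousarray(bag, dtype=np.int64),
        int(minsplit),
        np.ascontiguousarray(C, dtype=np.float64),
        bool(use_gini),
        block_cols,
        block_ptr,
        int(mtry),
        int(seed),
    )
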