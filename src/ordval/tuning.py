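"""K-fold cross-validation over tuning grids, scored by held-out log-likelihood.

One template serves all four families: split the training rows into K
stratified folds, fit every grid candidate on each K-1-fold training set,
score the held-out fold by the sum of log predicted probabilities of the
observed categories, average across folds, pick the argmax, and refit on
all rows at the selected value. Ties on the averaged score go to the most
parsimonious candidate (smallest model, largest penalty, largest cp,
smallest mtry).

Tuned parameters: model size (and interaction count) for stepwise POLR;
lambda for RIDGE; (cp, minsplit) for CART; mtry for the forest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ordval.cumlogit import ConvergenceError
from ordval.models import (
    PolrFit,
    RidgeFit,
    fit_polr,
    fit_ridge,
    stepwise_interactions,
    stepwise_main,
)
from ordval.preprocess import DesignMatrix
from ordval.synthetic import substream
from ordval.tree import ForestFit, TreeFit, fit_forest, fit_tree

_EPS = 1e-12


def kfold_split(y: np.ndarray, K: int, seed: int) -> np.ndarray:
    """Stratified fold labels 0..K-1; overall fold sizes within 1 of each other.

    Within each outcome category, shuffled members are dealt cyclically,
    continuing a single global fold counter across categories, so each fold
    receives its share of every category (within 1) and the overall
    partition stays balanced. Categories with fewer members than K trigger
    a warning (best-effort stratification).
    """
    y = np.asarray(y)
    n = len(y)
    if n < K:
        raise ValueError("need n >= K")
    rng = substream(seed, "kfold")
    folds = np.empty(n, dtype=int)
    pos = int(rng.integers(K))
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        if len(members) < K:
            warnings.warn(
                f"outcome category {cls!r} has {len(members)} members < K={K}; "
                "best-effort stratification"
            )
        members = rng.permutation(members)
        for m in members:
            folds[m] = pos % K
            pos += 1
    return folds


@dataclass
class CVResult:
    """Grid, per-fold held-out scores, selection, and the full-data refit."""

    family: str
    grid: list[dict]
    folds: np.ndarray
    E: np.ndarray  # (K folds, J candidates) held-out log-likelihoods
    Ebar: np.ndarray
    selected: int
    params: dict
    fit: object
    seed: int
    extras: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "family": self.family,
            "grid": self.grid,
            "E": self.E.tolist(),
            "Ebar": self.Ebar.tolist(),
            "selected": self.selected,
            "params": self.params,
            "seed": self.seed,
        }


def heldout_score(fit, dm_test: DesignMatrix, y_test: np.ndarray) -> float:
    """Sum of log predicted probabilities of the observed categories."""
    probs = fit.predict_proba(dm_test)
    p_obs = probs[np.arange(len(y_test)), np.asarray(y_test, dtype=int) - 1]
    return float(np.sum(np.log(np.clip(p_obs, _EPS, None))))


def _select(Ebar: np.ndarray, parsimony_order: np.ndarray) -> int:
    """Argmax of Ebar; exact ties resolved toward earlier parsimony rank."""
    best = -np.inf
    best_j = int(parsimony_order[0])
    for j in parsimony_order:
        if Ebar[j] > best:
            best = Ebar[j]
            best_j = int(j)
    return best_j


def _fold_iter(folds: np.ndarray, K: int):
    for k in range(K):
        test = folds == k
        yield k, ~test, test


def tune_polr(
    dm: DesignMatrix,
    y: np.ndarray,
    max_main: int = 14,
    max_int: int = 5,
    K: int = 10,
    seed: int = 0,
) -> CVResult:
    """Tune stepwise-POLR model size, then interaction count, by K-fold CV.

    Stage 1 selects the number of main-effect blocks: each fold reruns the
    forward path on its training rows and scores every prefix on the held-
    out rows. Stage 2 (when the design carries interaction blocks) fixes
    the selected size, reruns main selection per fold, then scores forward
    interaction prefixes the same way. The final model refits the whole
    path on all rows.
    """
    y = np.asarray(y, dtype=int)
    folds = kfold_split(y, K, seed)
    max_main = min(max_main, len(dm.main_blocks))
    sizes = list(range(max_main + 1))
    E = np.full((K, len(sizes)), -np.inf)
    for k, train, test in _fold_iter(folds, K):
        path = stepwise_main(dm.take(train), y[train], max_main)
        dmt, yt = dm.take(test), y[test]
        for j, size in enumerate(sizes):
            if size <= path.max_size:
                E[k, j] = heldout_score(path.fit_at(size), dmt, yt)
    Ebar = E.mean(axis=0)
    j_main = _select(Ebar, np.arange(len(sizes)))  # parsimony: smaller first
    m_star = sizes[j_main]

    n_int_star = 0
    E2 = None
    has_ints = bool(dm.interaction_blocks) and max_int > 0 and m_star >= 2
    if has_ints:
        ints = list(range(max_int + 1))
        E2 = np.full((K, len(ints)), -np.inf)
        for k, train, test in _fold_iter(folds, K):
            dmk, yk = dm.take(train), y[train]
            mains_k = stepwise_main(dmk, yk, m_star).steps
            ipath = stepwise_interactions(dmk, yk, mains_k, max_int)
            dmt, yt = dm.take(test), y[test]
            for j, ni in enumerate(ints):
                if ni <= ipath.max_size:
                    E2[k, j] = heldout_score(ipath.fit_at(ni), dmt, yt)
        Ebar2 = E2.mean(axis=0)
        n_int_star = ints[_select(Ebar2, np.arange(len(ints)))]

    final_main = stepwise_main(dm, y, m_star)
    if n_int_star > 0:
        ipath = stepwise_interactions(dm, y, final_main.steps, n_int_star)
        final_fit = ipath.fit_at(min(n_int_star, ipath.max_size))
    else:
        final_fit = final_main.fit_at(final_main.max_size)
    grid = [{"size": s} for s in sizes]
    return CVResult(
        family="POLR",
        grid=grid,
        folds=folds,
        E=E,
        Ebar=Ebar,
        selected=j_main,
        params={
            "size": m_star,
            "n_interactions": n_int_star,
            "blocks": list(final_fit.block_names),
        },
        fit=final_fit,
        seed=seed,
        extras={"E_interactions": None if E2 is None else E2.tolist()},
    )


def tune_ridge(
    dm: DesignMatrix,
    y: np.ndarray,
    lambdas: np.ndarray | None = None,
    K: int = 10,
    seed: int = 0,
) -> CVResult:
    """Tune the ridge penalty over a lambda grid by K-fold CV."""
    y = np.asarray(y, dtype=int)
    if lambdas is None:
        lambdas = np.geomspace(1e-3, 1e3, 25)
    lambdas = np.asarray(lambdas, dtype=float)
    folds = kfold_split(y, K, seed)
    E = np.full((K, len(lambdas)), -np.inf)
    for k, train, test in _fold_iter(folds, K):
        dmk, yk = dm.take(train), y[train]
        dmt, yt = dm.take(test), y[test]
        for j, lam in enumerate(lambdas):
            try:
                fit = fit_ridge(dmk, yk, lam)
            except (ValueError, ConvergenceError):
                continue
            E[k, j] = heldout_score(fit, dmt, yt)
    Ebar = E.mean(axis=0)
    if not np.any(np.isfinite(Ebar)):
        raise RuntimeError("all ridge candidates failed")
    j = _select(Ebar, np.argsort(-lambdas, kind="stable"))  # ties -> larger lambda
    fit = fit_ridge(dm, y, float(lambdas[j]))
    return CVResult(
        family="RIDGE",
        grid=[{"lam": float(l)} for l in lambdas],
        folds=folds,
        E=E,
        Ebar=Ebar,
        selected=j,
        params={"lam": float(lambdas[j])},
        fit=fit,
        seed=seed,
    )


def tune_tree(
    dm: DesignMatrix,
    y: np.ndarray,
    cp_grid=(0.001, 0.005, 0.01, 0.02, 0.05),
    minsplit_grid=(10, 20, 50, 100),
    K: int = 10,
    seed: int = 0,
    criterion: str = "cost",
) -> CVResult:
    """Tune (cp, minsplit) for the ordinal tree by K-fold CV."""
    y = np.asarray(y, dtype=int)
    grid = [{"cp": float(cp), "minsplit": int(ms)} for cp in cp_grid for ms in minsplit_grid]
    folds = kfold_split(y, K, seed)
    E = np.full((K, len(grid)), -np.inf)
    for k, train, test in _fold_iter(folds, K):
        dmk, yk = dm.take(train), y[train]
        dmt, yt = dm.take(test), y[test]
        for j, g in enumerate(grid):
            fit = fit_tree(dmk, yk, cp=g["cp"], minsplit=g["minsplit"], criterion=criterion)
            E[k, j] = heldout_score(fit, dmt, yt)
    Ebar = E.mean(axis=0)
    # parsimony: largest cp, then largest minsplit
    order = sorted(
        range(len(grid)),
        key=lambda j: (-grid[j]["cp"], -grid[j]["minsplit"]),
    )
    j = _select(Ebar, np.asarray(order))
    g = grid[j]
    fit = fit_tree(dm, y, cp=g["cp"], minsplit=g["minsplit"], criterion=criterion)
    return CVResult(
        family="CART",
        grid=grid,
        folds=folds,
        E=E,
        Ebar=Ebar,
        selected=j,
        params=dict(g),
        fit=fit,
        seed=seed,
    )


def tune_forest(
    dm: DesignMatrix,
    y: np.ndarray,
    mtry_grid=(1, 2, 3, 4, 6, 8, 11, 14),
    ntree: int = 500,
    minsplit: int = 5,
    K: int = 10,
    seed: int = 0,
) -> CVResult:
    """Tune mtry for the bagged ordinal forest by K-fold CV."""
    y = np.asarray(y, dtype=int)
    mtry_grid = [m for m in mtry_grid if 1 <= m <= len(dm.main_blocks)]
    if not mtry_grid:
        raise ValueError("no valid mtry values for this design")
    folds = kfold_split(y, K, seed)
    E = np.full((K, len(mtry_grid)), -np.inf)
    for k, train, test in _fold_iter(folds, K):
        dmk, yk = dm.take(train), y[train]
        dmt, yt = dm.take(test), y[test]
        for j, mtry in enumerate(mtry_grid):
            fit = fit_forest(
                dmk, yk, mtry=mtry, ntree=ntree, minsplit=minsplit,
                seed=substream(seed, f"forest-fold{k}-mtry{mtry}"),
            )
            E[k, j] = heldout_score(fit, dmt, yt)
    Ebar = E.mean(axis=0)
    j = _select(Ebar, np.arange(len(mtry_grid)))  # ties -> smaller mtry
    fit = fit_forest(
        dm, y, mtry=mtry_grid[j], ntree=ntree, minsplit=minsplit,
        seed=substream(seed, "forest-final"),
    )
    return CVResult(
        family="RF",
        grid=[{"mtry": int(m)} for m in mtry_grid],
        folds=folds,
        E=E,
        Ebar=Ebar,
        selected=j,
        params={"mtry": int(mtry_grid[j]), "ntree": ntree},
        fit=fit,
        seed=seed,
    )
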