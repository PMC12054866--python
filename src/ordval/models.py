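"""Four ordinal model families behind one prediction contract.

Every fit exposes ``predict_proba(X) -> (n, 3)`` rows on the probability
simplex. POLR is the unpenalized proportional-odds fit with forward
stepwise selection of whole variable blocks (a categorical's indicators or
a continuous predictor's spline columns enter together) and, optionally,
pairwise interactions of the selected main effects. RIDGE is the same
parallel cumulative-logit likelihood with an L2 penalty on standardized
slopes. CART and the bagged ordinal forest live in :mod:`ordval.tree`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ordval.cumlogit import (
    ConvergenceError,
    CumLogitFit,
    fit_cumlogit,
    heldout_loglik,
)
from ordval.preprocess import DesignMatrix

K_CATEGORIES = 3


def _check_rank(X: np.ndarray) -> None:
    if X.shape[1] and np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")


@dataclass
class PolrFit:
    """Proportional-odds fit on a subset of variable blocks."""

    core: CumLogitFit
    block_names: list[str]  # blocks in the fit, selection order
    column_index: np.ndarray  # columns of the full DesignMatrix used
    family: str = "POLR"

    @property
    def loglik(self) -> float:
        return self.core.loglik

    def predict_proba(self, dm: DesignMatrix) -> np.ndarray:
        return self.core.predict_proba(dm.X[:, self.column_index])

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": 1,
                "family": self.family,
                "thetas": self.core.thetas.tolist(),
                "beta": self.core.beta.tolist(),
                "lam": self.core.lam,
                "blocks": self.block_names,
                "columns": self.column_index.tolist(),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PolrFit":
        d = json.loads(text)
        core = CumLogitFit(
            thetas=np.asarray(d["thetas"]),
            beta=np.asarray(d["beta"]),
            loglik=float("nan"),
            K=K_CATEGORIES,
            lam=d["lam"],
        )
        return cls(
            core=core,
            block_names=list(d["blocks"]),
            column_index=np.asarray(d["columns"], dtype=int),
        )


def fit_polr(dm: DesignMatrix, y: np.ndarray, block_names=None) -> PolrFit:
    """Unpenalized proportional-odds fit on the given blocks (default: all).

    Errors on rank-deficient designs, absent outcome categories, and
    non-convergence / separation (raised by the likelihood engine).
    """
    blocks = list(dm.main_blocks + dm.interaction_blocks if block_names is None else block_names)
    cols = dm.block_columns(blocks) if blocks else np.array([], dtype=int)
    X = dm.X[:, cols] if len(cols) else np.empty((dm.n, 0))
    _check_rank(X)
    core = fit_cumlogit(X, y, K=K_CATEGORIES, lam=0.0)
    return PolrFit(core=core, block_names=blocks, column_index=cols)


@dataclass
class RidgeFit:
    """Ridge-penalized parallel cumulative-logit fit on all blocks."""

    core: CumLogitFit
    lam: float
    block_names: list[str]
    column_index: np.ndarray
    family: str = "RIDGE"

    @property
    def loglik(self) -> float:
        return self.core.loglik

    def predict_proba(self, dm: DesignMatrix) -> np.ndarray:
        return self.core.predict_proba(dm.X[:, self.column_index])

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": 1,
                "family": self.family,
                "lam": self.lam,
                "thetas": self.core.thetas.tolist(),
                "beta": self.core.beta.tolist(),
                "blocks": self.block_names,
                "columns": self.column_index.tolist(),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RidgeFit":
        d = json.loads(text)
        core = CumLogitFit(
            thetas=np.asarray(d["thetas"]),
            beta=np.asarray(d["beta"]),
            loglik=float("nan"),
            K=K_CATEGORIES,
            lam=d["lam"],
        )
        return cls(
            core=core,
            lam=d["lam"],
            block_names=list(d["blocks"]),
            column_index=np.asarray(d["columns"], dtype=int),
        )


def fit_ridge(dm: DesignMatrix, y: np.ndarray, lam: float) -> RidgeFit:
    """Penalized fit: log-likelihood minus lam * ||standardized slopes||^2."""
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    blocks = list(dm.main_blocks + dm.interaction_blocks)
    cols = dm.block_columns(blocks)
    core = fit_cumlogit(dm.X[:, cols], y, K=K_CATEGORIES, lam=lam)
    return RidgeFit(core=core, lam=lam, block_names=blocks, column_index=cols)


# ---------------------------------------------------------------------------
# Forward stepwise selection over variable blocks


@dataclass
class StepwisePath:
    """Greedy forward path: cumulative prefix fits, best-first."""

    steps: list[str] = field(default_factory=list)  # block added at each step
    fits: list[PolrFit] = field(default_factory=list)  # fit after each step
    null_fit: PolrFit | None = None  # intercept-only fit (size 0)

    def fit_at(self, size: int) -> PolrFit:
        if size == 0:
            return self.null_fit
        return self.fits[size - 1]

    @property
    def max_size(self) -> int:
        return len(self.steps)


def _greedy_path(
    dm: DesignMatrix,
    y: np.ndarray,
    candidates: list[str],
    base_blocks: list[str],
    max_steps: int,
) -> StepwisePath:
    path = StepwisePath()
    path.null_fit = fit_polr(dm, y, block_names=base_blocks)
    selected = list(base_blocks)
    remaining = list(candidates)
    for _ in range(max_steps):
        if not remaining:
            break
        best_ll, best_block, best_fit = -np.inf, None, None
        for block in remaining:
            try:
                fit = fit_polr(dm, y, block_names=selected + [block])
            except (ValueError, ConvergenceError):
                continue  # singular or separated candidate: skip
            if fit.loglik > best_ll:
                best_ll, best_block, best_fit = fit.loglik, block, fit
        if best_block is None:
            break
        selected.append(best_block)
        remaining.remove(best_block)
        path.steps.append(best_block)
        path.fits.append(best_fit)
    return path


def stepwise_main(dm: DesignMatrix, y: np.ndarray, max_size: int) -> StepwisePath:
    """Forward selection of main-effect blocks by fitted log-likelihood."""
    max_size = min(max_size, len(dm.main_blocks))
    return _greedy_path(dm, y, list(dm.main_blocks), [], max_size)


def stepwise_interactions(
    dm: DesignMatrix, y: np.ndarray, main_blocks: list[str], max_ints: int
) -> StepwisePath:
    """Forward selection of interaction blocks among the chosen main effects.

    Hierarchy: only interactions whose two parent variables are both in
    ``main_blocks`` are candidates; the path starts from the main-effects
    fit (size 0 = mains only).
    """
    mains = set(main_blocks)
    candidates = [
        b
        for b in dm.interaction_blocks
        if set(dm.block_parents[b]) <= mains
    ]
    max_ints = min(max_ints, len(candidates))
    return _greedy_path(dm, y, candidates, list(main_blocks), max_ints)
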