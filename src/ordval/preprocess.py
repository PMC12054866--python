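"""Criterion-standard outcome derivation and design-matrix construction.

The criterion standard for dehydration severity is percent weight change
with rehydration: 100 * (stable - admission) / stable, where the stable
weight is the mean of the two highest consecutive four-hourly weights that
differ by less than 2% (relative to the larger of the pair). Severity cuts:
severe > 9%, some 3-9% (both endpoints included), none < 3%.

Four predictor encodings are supported for the regression families:
set 1: reference-coded indicators + linear continuous terms;
set 2: set 1 plus all two-way interactions of set-1 variables;
set 3: indicators + restricted-cubic-spline bases (3 knots) for continuous;
set 4: set 3 plus all two-way interactions of set-3 variables.
Tree-based families use set 1 only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ordval.schema import OUTCOME_COL, PredictorSchema, default_schema
from ordval.synthetic import WeightSeries

STABLE_TOL = 0.02  # consecutive weights must differ by < 2% of the larger

NOT_STABILIZED = None  # sentinel returned when no consecutive pair qualifies


# ---------------------------------------------------------------------------
# Criterion standard


def stable_weight(series: WeightSeries) -> float | None:
    """Mean of the two highest consecutive weights differing by < 2%.

    Among consecutive pairs whose relative difference (denominator: the
    larger weight of the pair) is below 2%, returns the mean of the pair
    with the largest mean; earliest such pair on ties. Returns ``None``
    (not stabilized) when no pair qualifies.
    """
    w = np.asarray(series.weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    pair_hi = np.maximum(w[:-1], w[1:])
    rel = np.abs(np.diff(w)) / pair_hi
    means = (w[:-1] + w[1:]) / 2.0
    ok = rel < STABLE_TOL
    if not np.any(ok):
        return NOT_STABILIZED
    qualifying = np.where(ok)[0]
    best = qualifying[np.argmax(means[qualifying])]  # argmax takes earliest tie
    return float(means[best])


def dehydration_category(admission: float, stable: float) -> tuple[float, str]:
    """Percent dehydration and its category from admission and stable weight."""
    if admission <= 0 or stable <= 0:
        raise ValueError("weights must be positive")
    percent = 100.0 * (stable - admission) / stable
    if percent > 9.0:
        category = "severe"
    elif percent >= 3.0:
        category = "some"
    else:
        category = "none"
    return percent, category


# ---------------------------------------------------------------------------
# Binning and complete cases


def bin_predictors(cohort: pd.DataFrame, schema: PredictorSchema | None = None) -> pd.DataFrame:
    """Convert raw count/duration columns to their categorical bin labels.

    Bins are closed on their printed integer endpoints ("1-5" means
    1 <= x <= 5). Columns not listed in the schema's bin map are untouched.
    """
    schema = schema if schema is not None else default_schema()
    out = cohort.copy()
    for name, edges in schema.bin_upper_edges.items():
        if name not in out:
            continue
        if isinstance(out[name].dtype, pd.CategoricalDtype) or out[name].dtype == object:
            continue  # already binned
        x = np.asarray(out[name], dtype=float)
        if np.any(x < 0):
            raise ValueError(f"negative values in {name!r}")
        levels = schema.categorical[name]
        # bin i holds edges[i-1] < x <= edges[i] (upper edges inclusive)
        codes = np.sum(x[:, None] > np.asarray(edges, dtype=float)[None, :], axis=1)
        out[name] = pd.Categorical.from_codes(codes, categories=list(levels))
    return out


def complete_cases(
    cohort: pd.DataFrame, schema: PredictorSchema | None = None
) -> tuple[pd.DataFrame, int]:
    """Drop rows with any missing predictor or outcome; return dropped count."""
    schema = schema if schema is not None else default_schema()
    cols = [c for c in schema.columns if c in cohort.columns]
    if OUTCOME_COL in cohort.columns and OUTCOME_COL not in cols:
        cols.append(OUTCOME_COL)
    mask = cohort[cols].notna().all(axis=1)
    dropped = int((~mask).sum())
    kept = cohort.loc[mask].reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError("all rows dropped as incomplete")
    return kept, dropped


# ---------------------------------------------------------------------------
# Restricted cubic splines


@dataclass(frozen=True)
class SplineBasis:
    """Three-knot restricted cubic spline basis (dimension 2) for one predictor."""

    knots: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.knots) != 3 or not np.all(np.diff(self.knots) > 0):
            raise ValueError("need 3 strictly increasing knots")

    @classmethod
    def from_training(cls, x: np.ndarray) -> "SplineBasis":
        """Knots at the 10th, 50th and 90th percentiles of the training values."""
        knots = np.percentile(np.asarray(x, dtype=float), [10, 50, 90])
        if not np.all(np.diff(knots) > 0):
            raise ValueError("degenerate knots: predictor nearly constant")
        return cls(knots=tuple(float(k) for k in knots))


def rcs_basis(x: np.ndarray, basis: SplineBasis) -> np.ndarray:
    """Two-column restricted cubic spline design: [x, nonlinear term].

    Standard truncated-power construction with tail restrictions, so the
    function is linear below the first and above the last knot; the
    nonlinear column is scaled by (t3 - t1)^2 to keep it on the scale of x.
    """
    x = np.asarray(x, dtype=float)
    t1, t2, t3 = basis.knots

    def cube(v: np.ndarray) -> np.ndarray:
        return np.maximum(v, 0.0) ** 3

    nl = (
        cube(x - t1)
        - cube(x - t2) * (t3 - t1) / (t3 - t2)
        + cube(x - t3) * (t2 - t1) / (t3 - t2)
    ) / (t3 - t1) ** 2
    return np.column_stack([x, nl])


# ---------------------------------------------------------------------------
# Design matrices


@dataclass
class DesignMatrix:
    """Encoded predictor matrix with column-to-variable lineage.

    ``blocks`` maps a block name (one variable, or "a:b" for an
    interaction) to the list of column indices belonging to it;
    ``block_parents`` records the two parent variables of each interaction
    block. ``main_blocks`` lists variable blocks, ``interaction_blocks``
    the interaction blocks, both in schema order.
    """

    X: np.ndarray
    columns: list[str]
    blocks: dict[str, list[int]]
    block_parents: dict[str, tuple[str, str]]
    main_blocks: list[str]
    interaction_blocks: list[str]
    set_id: int

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def block_columns(self, names) -> np.ndarray:
        idx: list[int] = []
        for b in names:
            idx.extend(self.blocks[b])
        return np.asarray(idx, dtype=int)

    def take(self, rows) -> "DesignMatrix":
        """Row-subset view sharing all column metadata (for CV folds)."""
        return DesignMatrix(
            X=self.X[np.asarray(rows)],
            columns=self.columns,
            blocks=self.blocks,
            block_parents=self.block_parents,
            main_blocks=self.main_blocks,
            interaction_blocks=self.interaction_blocks,
            set_id=self.set_id,
        )

    def subset(self, block_names) -> np.ndarray:
        """Column submatrix for the given blocks, in listed order."""
        if len(block_names) == 0:
            return np.empty((self.n, 0))
        return self.X[:, self.block_columns(block_names)]

    def lineage(self) -> dict:
        return {
            "set_id": self.set_id,
            "columns": list(self.columns),
            "blocks": {k: list(v) for k, v in self.blocks.items()},
            "block_parents": {k: list(v) for k, v in self.block_parents.items()},
        }


class DesignEncoder:
    """Fits encoding state on a training cohort; transforms any cohort.

    Encoding state — categorical level sets, reference levels, spline knots
    and the retained-column mask (all-constant interaction columns found in
    training are dropped) — is frozen at fit time and reapplied verbatim to
    new data, so external cohorts are encoded exactly as training was.
    """

    def __init__(self, set_id: int, schema: PredictorSchema | None = None):
        if set_id not in (1, 2, 3, 4):
            raise ValueError("set_id must be 1, 2, 3 or 4")
        self.set_id = set_id
        self.schema = schema if schema is not None else default_schema()
        self.knots_: dict[str, SplineBasis] = {}
        self.keep_: np.ndarray | None = None
        self._template: DesignMatrix | None = None

    # -- encoding of one variable ------------------------------------------
    def _encode_variable(
        self, cohort: pd.DataFrame, name: str
    ) -> tuple[np.ndarray, list[str]]:
        if name in self.schema.categorical:
            levels = self.schema.categorical[name]
            vals = np.asarray(cohort[name].astype(str))
            unseen = set(vals) - set(levels)
            if unseen:
                raise ValueError(f"unseen level(s) {sorted(unseen)} for {name!r}")
            cols = [
                (vals == lev).astype(float) for lev in levels[1:]
            ]  # reference level dropped
            names = [f"{name}[{lev}]" for lev in levels[1:]]
            return np.column_stack(cols), names
        x = np.asarray(cohort[name], dtype=float)
        if self.set_id in (3, 4):
            basis = self.knots_[name]
            return rcs_basis(x, basis), [name, f"{name}'"]
        return x[:, None], [name]

    def _build(self, cohort: pd.DataFrame) -> DesignMatrix:
        variables = list(self.schema.predictors)
        mats: list[np.ndarray] = []
        colnames: list[str] = []
        blocks: dict[str, list[int]] = {}
        parents: dict[str, tuple[str, str]] = {}
        main_blocks: list[str] = []
        interaction_blocks: list[str] = []
        for name in variables:
            M, names = self._encode_variable(cohort, name)
            blocks[name] = list(range(len(colnames), len(colnames) + M.shape[1]))
            main_blocks.append(name)
            mats.append(M)
            colnames.extend(names)
        if self.set_id in (2, 4):
            cache = {name: mats[i] for i, name in enumerate(variables)}
            for i, a in enumerate(variables):
                for b in variables[i + 1 :]:
                    Ma, Mb = cache[a], cache[b]
                    prod = Ma[:, :, None] * Mb[:, None, :]
                    prod = prod.reshape(len(cohort), -1)
                    bname = f"{a}:{b}"
                    blocks[bname] = list(
                        range(len(colnames), len(colnames) + prod.shape[1])
                    )
                    parents[bname] = (a, b)
                    interaction_blocks.append(bname)
                    mats.append(prod)
                    ai = blocks[a]
                    bi = blocks[b]
                    colnames.extend(
                        f"{colname_of(colnames, ai[j])}*{colname_of(colnames, bi[k])}"
                        for j in range(Ma.shape[1])
                        for k in range(Mb.shape[1])
                    )
        X = np.concatenate(mats, axis=1) if mats else np.empty((len(cohort), 0))
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite entries in design matrix")
        return DesignMatrix(
            X=X,
            columns=colnames,
            blocks=blocks,
            block_parents=parents,
            main_blocks=main_blocks,
            interaction_blocks=interaction_blocks,
            set_id=self.set_id,
        )

    def fit(self, cohort: pd.DataFrame) -> "DesignEncoder":
        if self.set_id in (3, 4):
            for name in self.schema.continuous:
                self.knots_[name] = SplineBasis.from_training(
                    np.asarray(cohort[name], dtype=float)
                )
        dm = self._build(cohort)
        # Drop columns constant in training (e.g., level combinations never
        # co-occurring); frozen into the encoder so test encoding matches.
        const = dm.X.std(axis=0) == 0.0
        self.keep_ = ~const
        self._template = self._apply_keep(dm)
        return self

    def _apply_keep(self, dm: DesignMatrix) -> DesignMatrix:
        keep = self.keep_
        old_to_new = np.full(dm.p, -1, dtype=int)
        old_to_new[keep] = np.arange(int(keep.sum()))
        blocks = {}
        parents = {}
        for bname, idx in dm.blocks.items():
            new_idx = [int(old_to_new[i]) for i in idx if keep[i]]
            if new_idx:
                blocks[bname] = new_idx
                if bname in dm.block_parents:
                    parents[bname] = dm.block_parents[bname]
        return DesignMatrix(
            X=dm.X[:, keep],
            columns=[c for c, k in zip(dm.columns, keep) if k],
            blocks=blocks,
            block_parents=parents,
            main_blocks=[b for b in dm.main_blocks if b in blocks],
            interaction_blocks=[b for b in dm.interaction_blocks if b in blocks],
            set_id=dm.set_id,
        )

    def transform(self, cohort: pd.DataFrame) -> DesignMatrix:
        if self.keep_ is None:
            raise RuntimeError("encoder not fitted")
        return self._apply_keep(self._build(cohort))

    def fit_transform(self, cohort: pd.DataFrame) -> DesignMatrix:
        return self.fit(cohort).transform(cohort)


def colname_of(colnames: list[str], idx: int) -> str:
    return colnames[idx]


def encode_design(
    cohort: pd.DataFrame,
    set_id: int,
    schema: PredictorSchema | None = None,
    encoder: DesignEncoder | None = None,
) -> DesignMatrix:
    """Encode a cohort for one of the four variable sets.

    Pass a fitted ``encoder`` to reuse frozen training state (knots, level
    maps, retained columns) on new data; otherwise a new encoder is fitted
    on this cohort.
    """
    if encoder is not None:
        return encoder.transform(cohort)
    return DesignEncoder(set_id, schema).fit_transform(cohort)


def export_design(dm: DesignMatrix, csv_path, lineage_path) -> None:
    """Design matrix to CSV plus a sidecar JSON column-lineage file."""
    pd.DataFrame(dm.X, columns=dm.columns).to_csv(csv_path, index=False)
    with open(lineage_path, "w") as fh:
        json.dump(dm.lineage(), fh, indent=1, sort_keys=True)
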