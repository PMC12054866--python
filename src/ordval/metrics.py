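"""Ordinal discrimination indices: ADC, ORC and GC.

All three generalize the binary c-statistic (AUC) to an ordered K-category
outcome, anchored at 0.5 for chance and 1 for perfect discrimination:

* ADC — mean of the K-1 binary AUCs from the cumulative dichotomizations
  Y <= k vs Y > k;
* ORC — unweighted mean of the K(K-1)/2 pairwise category AUCs (an
  adjacent-pairs variant is available);
* GC — concordance pooled over all cross-category pairs, identical to the
  n_i * n_j-weighted mean of the pairwise AUCs.

Ties always count 1/2 (Mann-Whitney convention). Models enter through a
scalar risk score; the default is the expected category rank sum_k k p_k,
applied uniformly to every model family so comparisons stay fair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import rankdata

INDEX_NAMES = ("ADC", "ORC", "GC")


@dataclass(frozen=True)
class IndexValue:
    """One discrimination index, optionally with a bootstrap percentile CI."""

    name: str
    value: float
    ci: tuple[float, float] | None = None
    B: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"{self.name} value {self.value} outside [0, 1]")
        if self.ci is not None and not (self.ci[0] <= self.value <= self.ci[1]):
            raise ValueError("CI must bracket the point value")


def risk_score(probs: np.ndarray, variant: str = "expected_rank") -> np.ndarray:
    """Scalar severity score from per-category probabilities.

    ``expected_rank`` (default): sum_k k * p_k, strictly monotone in the
    stochastic ordering of the category distribution. Alternatives:
    ``top_category`` = P(Y = K); ``cumulative`` = P(Y >= 2) + P(Y >= K).
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    K = probs.shape[1]
    if np.any(probs < -1e-10) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("probability rows must lie on the simplex")
    if variant == "expected_rank":
        return probs @ np.arange(1, K + 1)
    if variant == "top_category":
        return probs[:, -1]
    if variant == "cumulative":
        return probs[:, 1:].sum(axis=1) + probs[:, -1]
    raise ValueError(f"unknown score variant {variant!r}")


def pairwise_auc(scores_lower: np.ndarray, scores_higher: np.ndarray) -> float:
    """P(score of a higher-category patient > score of a lower-category one).

    Mann-Whitney U / (n_a * n_b) with ties counted 1/2. Raises on an empty
    group (the undefined case is distinct from 0 or 0.5).
    """
    a = np.asarray(scores_lower, dtype=float)
    b = np.asarray(scores_higher, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("pairwise AUC undefined for an empty group")
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[len(a):].sum() - len(b) * (len(b) + 1) / 2.0
    return float(u / (len(a) * len(b)))


def ordinal_indices(
    scores: np.ndarray,
    y: np.ndarray,
    orc_variant: str = "all_pairs",
    with_ci: bool = False,
    B: int = 1000,
    seed: int = 0,
) -> dict[str, IndexValue]:
    """ADC, ORC and GC for one set of scored outcomes.

    ``y`` holds category ranks 1..K. Category pairs with an empty side are
    dropped from ORC's mean (with a warning); GC pools the remaining pairs.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    values = _index_values(scores, y, orc_variant)
    out = {}
    for name, value in values.items():
        if with_ci:
            ci = bootstrap_ci(scores, y, name, orc_variant=orc_variant, B=B, seed=seed)
            out[name] = IndexValue(name=name, value=value, ci=ci, B=B)
        else:
            out[name] = IndexValue(name=name, value=value)
    return out


def _index_values(scores: np.ndarray, y: np.ndarray, orc_variant: str) -> dict[str, float]:
    cats = np.unique(y)
    if len(cats) < 2:
        raise ValueError("need >= 2 outcome categories")
    groups = {int(c): scores[y == c] for c in cats}
    K = int(cats.max())
    # pairwise category AUCs over categories actually present
    pair_auc: dict[tuple[int, int], float] = {}
    for i, j in combinations(sorted(groups), 2):
        pair_auc[(i, j)] = pairwise_auc(groups[i], groups[j])
    expected_pairs = list(combinations(range(1, K + 1), 2))
    if len(pair_auc) < len(expected_pairs):
        warnings.warn("empty category side: some pairwise AUCs dropped")
    # ADC over cumulative dichotomizations with both sides nonempty
    adcs = []
    for k in range(1, K):
        lo, hi = scores[y <= k], scores[y > k]
        if len(lo) and len(hi):
            adcs.append(pairwise_auc(lo, hi))
    if orc_variant == "all_pairs":
        orc_pairs = list(pair_auc)
    elif orc_variant == "adjacent":
        present = sorted(groups)  # adjacency among categories actually present
        orc_pairs = list(zip(present, present[1:]))
    else:
        raise ValueError(f"unknown ORC variant {orc_variant!r}")
    weights = {p: len(groups[p[0]]) * len(groups[p[1]]) for p in pair_auc}
    gc = sum(weights[p] * pair_auc[p] for p in pair_auc) / sum(weights.values())
    return {
        "ADC": float(np.mean(adcs)),
        "ORC": float(np.mean([pair_auc[p] for p in orc_pairs])),
        "GC": float(gc),
    }


def gc_pooled(scores: np.ndarray, y: np.ndarray) -> float:
    """GC computed directly over all pooled cross-category pairs.

    Independent route for the identity GC = weighted mean of pairwise
    AUCs; quadratic in n, meant for checks at small n.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    num = den = 0.0
    n = len(y)
    for i in range(n):
        for j in range(n):
            if y[i] < y[j]:
                den += 1.0
                if scores[j] > scores[i]:
                    num += 1.0
                elif scores[j] == scores[i]:
                    num += 0.5
    if den == 0:
        raise ValueError("no cross-category pairs")
    return num / den


def bootstrap_ci(
    scores: np.ndarray,
    y: np.ndarray,
    index_name: str,
    orc_variant: str = "all_pairs",
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """95% percentile bootstrap interval for one index; deterministic by seed."""
    reps = bootstrap_replicates(scores, y, index_name, orc_variant, B, seed)
    return (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))


def bootstrap_replicates(
    scores: np.ndarray,
    y: np.ndarray,
    index_name: str,
    orc_variant: str = "all_pairs",
    B: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """B bootstrap index values; degenerate (single-category) resamples are
    redrawn up to 10 times, then dropped with a warning."""
    if B < 2:
        raise ValueError("B must be >= 2")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    n = len(y)
    reps = []
    dropped = 0
    for _ in range(B):
        for _attempt in range(10):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) >= 2:
                reps.append(_index_values(scores[idx], y[idx], orc_variant)[index_name])
                break
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"{dropped} bootstrap replicates dropped (single category)")
    return np.asarray(reps)
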