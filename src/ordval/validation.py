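"""Bootstrap optimism correction and external validation.

Internal validation reruns the FULL modeling procedure (encoding, tuning,
selection, fitting) on every bootstrap resample and combines three
quantities per replicate b: the index on the resample itself (A_b), on the
original data (O_b), and on the out-of-bag rows (OOB_b), together with the
apparent index A on the original data:

* Harrell:     A - mean(A_b - O_b)
* Efron 0.632: 0.368 A + 0.632 mean(OOB_b)
* 0.632+:      relative overfitting rate R = (A - mean(OOB_b)) / (A - gamma),
               clipped to [0, 1]; weight w = 0.632 / (1 - 0.368 R);
               estimate (1 - w) A + w mean(OOB_b).

gamma is the no-information rate, 0.5 for every c-index (the chance
anchor); a permutation estimate is available for non-standard scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ordval.metrics import IndexValue, _index_values, bootstrap_ci
from ordval.synthetic import outcome_codes, substream

METHODS = ("harrell", "e632", "e632plus")


def no_info_rate(
    index_name: str,
    scores: np.ndarray | None = None,
    y: np.ndarray | None = None,
    mode: str = "chance",
    M: int = 200,
    seed: int = 0,
    orc_variant: str = "all_pairs",
) -> float:
    """No-information rate gamma for a c-index.

    ``chance`` mode returns 0.5 (a c-index on outcome-independent scores).
    ``permutation`` mode averages the index over M random permutations of
    the scores against the outcomes.
    """
    if mode == "chance":
        return 0.5
    if mode != "permutation":
        raise ValueError(f"unknown mode {mode!r}")
    if M < 1:
        raise ValueError("M must be >= 1 in permutation mode")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = substream(seed, "no-info")
    vals = [
        _index_values(rng.permutation(scores), y, orc_variant)[index_name]
        for _ in range(M)
    ]
    return float(np.mean(vals))


@dataclass
class OptimismResult:
    """Apparent index plus per-replicate components and corrected estimates."""

    index_name: str
    apparent: float
    A_b: np.ndarray
    O_b: np.ndarray
    OOB_b: np.ndarray
    oob_sizes: np.ndarray
    gamma: float
    B: int
    seed: int
    n_dropped: int = 0
    # percentile CIs over per-replicate corrected components, labelled as such
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def harrell(self) -> float:
        return _clip01(self.apparent - float(np.mean(self.A_b - self.O_b)))

    @property
    def e632(self) -> float:
        return _clip01(0.368 * self.apparent + 0.632 * float(np.mean(self.OOB_b)))

    @property
    def e632plus(self) -> float:
        return _e632plus(self.apparent, float(np.mean(self.OOB_b)), self.gamma)

    def corrected(self, method: str) -> float:
        if method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        return getattr(self, method)

    def to_jsonable(self) -> dict:
        return {
            "index": self.index_name,
            "apparent": self.apparent,
            "corrected": {m: self.corrected(m) for m in METHODS},
            "ci": {m: list(self.ci[m]) for m in self.ci},
            "A_b": self.A_b.tolist(),
            "O_b": self.O_b.tolist(),
            "OOB_b": self.OOB_b.tolist(),
            "oob_sizes": self.oob_sizes.tolist(),
            "gamma": self.gamma,
            "B": self.B,
            "seed": self.seed,
            "n_dropped": self.n_dropped,
        }

    def replicate_components(self, method: str) -> np.ndarray:
        """Per-replicate corrected values (used for percentile CIs)."""
        if method == "harrell":
            return np.clip(self.apparent - (self.A_b - self.O_b), 0.0, 1.0)
        if method == "e632":
            return np.clip(0.368 * self.apparent + 0.632 * self.OOB_b, 0.0, 1.0)
        if method == "e632plus":
            return np.asarray(
                [_e632plus(self.apparent, float(o), self.gamma) for o in self.OOB_b]
            )
        raise ValueError(f"method must be one of {METHODS}")


def _clip01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


def _e632plus(A: float, obar: float, gamma: float) -> float:
    """Efron 0.632+ with the standard guard rails (R clipped to [0, 1];
    R = 0 when the OOB mean is no worse than apparent)."""
    if obar >= A or A <= gamma:
        R = 0.0
    else:
        R = (A - obar) / (A - gamma)
        R = min(1.0, max(0.0, R))
    w = 0.632 / (1.0 - 0.368 * R)
    return _clip01((1.0 - w) * A + w * obar)


def optimism_correct(
    modeler,
    cohort,
    index_names=("ADC", "ORC", "GC"),
    B: int = 1000,
    seed: int = 0,
    gamma: float = 0.5,
    orc_variant: str = "all_pairs",
    score_variant: str = "expected_rank",
) -> dict[str, OptimismResult]:
    """Bootstrap the full modeling process and correct every index at once.

    ``modeler(cohort, seed)`` must return a scorer: a callable mapping a
    cohort to per-patient risk scores, with all preprocessing and tuning
    re-done inside. Each replicate refits on a size-n resample drawn with
    replacement and evaluates on the resample (A_b), the original cohort
    (O_b) and the out-of-bag rows (OOB_b). Replicates whose OOB index is
    undefined are dropped; more than 20% dropped is an error.
    """
    y_full = outcome_codes(cohort)
    n = len(cohort)
    scorer = modeler(cohort, _child_seed(seed, "apparent"))
    s_full = scorer(cohort)
    apparent = {
        name: _index_values(s_full, y_full, orc_variant)[name] for name in index_names
    }
    rng = substream(seed, "optimism-resample")
    A_b = {k: [] for k in index_names}
    O_b = {k: [] for k in index_names}
    OOB_b = {k: [] for k in index_names}
    oob_sizes = []
    dropped = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        boot = cohort.iloc[idx].reset_index(drop=True)
        try:
            scorer_b = modeler(boot, _child_seed(seed, f"replicate-{b}"))
            s_boot = scorer_b(boot)
            s_orig = scorer_b(cohort)
            vals_boot = _index_values(s_boot, y_full[idx], orc_variant)
            vals_orig = _index_values(s_orig, y_full, orc_variant)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals_oob = _index_values(s_orig[oob], y_full[oob], orc_variant)
        except ValueError:
            dropped += 1
            continue
        for name in index_names:
            A_b[name].append(vals_boot[name])
            O_b[name].append(vals_orig[name])
            OOB_b[name].append(vals_oob[name])
        oob_sizes.append(len(oob))
    if dropped > 0.2 * B:
        raise RuntimeError(f"{dropped}/{B} bootstrap replicates failed")
    out = {}
    for name in index_names:
        res = OptimismResult(
            index_name=name,
            apparent=apparent[name],
            A_b=np.asarray(A_b[name]),
            O_b=np.asarray(O_b[name]),
            OOB_b=np.asarray(OOB_b[name]),
            oob_sizes=np.asarray(oob_sizes),
            gamma=gamma,
            B=B,
            seed=seed,
            n_dropped=dropped,
        )
        for method in METHODS:
            comps = res.replicate_components(method)
            res.ci[method] = (
                float(np.percentile(comps, 2.5)),
                float(np.percentile(comps, 97.5)),
            )
        out[name] = res
    return out


def _child_seed(seed: int, name: str) -> int:
    return int(substream(seed, name).integers(0, 2**31 - 1))


def bootstrap_duplicate_stats(n: int, B: int = 1000, seed: int = 0) -> dict[str, float]:
    """Duplicate and out-of-bag structure of size-n bootstrap resamples.

    Returns the mean percentage of draws that duplicate an earlier draw in
    the same resample and the mean percentage of original rows left out of
    bag; both converge to 100 * (1 - (1 - 1/n)^n) ~ 36.8% for large n.
    """
    rng = substream(seed, "duplicate-stats")
    dup = np.empty(B)
    oob = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        n_unique = len(np.unique(idx))
        dup[b] = 100.0 * (n - n_unique) / n
        oob[b] = 100.0 * (n - n_unique) / n  # rows OOB = n - unique
    return {"mean_duplicate_pct": float(dup.mean()), "mean_oob_pct": float(oob.mean())}


def external_validate(
    scorer,
    test_cohort,
    index_names=("ADC", "ORC", "GC"),
    B: int = 1000,
    seed: int = 0,
    orc_variant: str = "all_pairs",
) -> dict[str, IndexValue]:
    """Evaluate a frozen scorer on an external cohort, with bootstrap CIs.

    The scorer must carry its training preprocessing (schema, reference
    levels, knots, retained columns) and is never refitted; unseen
    categorical levels in the test cohort raise from the encoder.
    """
    y = outcome_codes(test_cohort)
    scores = np.asarray(scorer(test_cohort), dtype=float)
    vals = _index_values(scores, y, orc_variant)
    out = {}
    for name in index_names:
        ci = bootstrap_ci(scores, y, name, orc_variant=orc_variant, B=B,
                          seed=_child_seed(seed, f"ext-{name}"))
        out[name] = IndexValue(name=name, value=vals[name], ci=ci, B=B)
    return out
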