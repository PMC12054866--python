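"""Synthetic cohort generator with a cumulative-logit outcome model.

Cohorts are drawn from configurable predictor marginals; the ordinal
dehydration outcome comes from a proportional-odds (cumulative-logit) model
on a latent linear predictor that may include nonlinear (quadratic) terms
and pairwise interactions. Intercepts are calibrated numerically on the
realized latent sample so that the expected marginal outcome distribution
hits the configured prevalences. A shifted "validation wave" spec emulates
a later cohort with different covariate distributions and a different
outcome mix. Per-patient rehydration weight courses are generated so the
criterion-standard outcome derivation (stable weight, percent dehydration)
can be tested end to end.

The predictor marginals are plausible clinical stand-ins, not estimates of
any real cohort; only the outcome model structure matters downstream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from ordval.schema import (
    OUTCOME_COL,
    OUTCOME_LEVELS,
    PredictorSchema,
    default_schema,
)

K_CATEGORIES = 3

# Derivation-cohort outcome mix: 431 none / 1431 some / 277 severe of 2139.
DERIVATION_N = 2139
DERIVATION_PREVALENCES = (431 / 2139, 1431 / 2139, 277 / 2139)
# Validation-cohort outcome mix: 301 / 1159 / 120 of 1580.
VALIDATION_N = 1580
VALIDATION_PREVALENCES = (301 / 1580, 1159 / 1580, 120 / 1580)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, decorrelated RNG substream derived from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), zlib.crc32(name.encode("utf-8"))))
    )


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class EffectMap:
    """Latent-scale effects of the predictors on dehydration severity.

    ``categorical`` maps predictor -> {non-reference level -> coefficient};
    the reference level always contributes 0. ``linear`` and ``quadratic``
    apply to continuous predictors standardized by the configured location
    and scale (so coefficients are per-SD). ``interactions`` maps a pair of
    categorical predictors to {(level_a, level_b) -> coefficient}.
    """

    categorical: dict[str, dict[str, float]] = field(default_factory=dict)
    linear: dict[str, float] = field(default_factory=dict)
    quadratic: dict[str, float] = field(default_factory=dict)
    interactions: dict[tuple[str, str], dict[tuple[str, str], float]] = field(
        default_factory=dict
    )


def default_effect_map() -> EffectMap:
    """Default effects: graded sign severity, a U-shaped age effect and a
    skin-pinch-by-eyes synergy, so that nonlinearity and interactions matter."""
    return EffectMap(
        categorical={
            "mental_status": {"confused_lethargic": 0.8, "unconscious": 1.6},
            "thirst": {"drinks_eagerly": 0.6, "refuses_unable": 1.2},
            "skin_pinch": {"slow": 0.9, "very_slow": 1.8},
            "eyes": {"sunken": 0.8},
            "respirations": {"deep": 0.5},
            "radial_pulse": {"decreased": 0.7, "absent": 1.5},
            "capillary_refill": {"prolonged": 0.6},
            "urine_output": {"decreased_dark": 0.5, "minimal_none": 1.0},
            "vomiting_episodes": {"1-5": 0.2, "6-10": 0.4, ">10": 0.7},
            "diarrheal_episodes": {"10-19": 0.3, ">19": 0.6},
            "diarrhea_duration_hr": {"13-23": 0.2, ">23": 0.4},
        },
        linear={"age": -0.2, "systolic_bp": -0.5, "muac": -0.3},
        quadratic={"age": 0.3},
        interactions={
            ("skin_pinch", "eyes"): {
                ("slow", "sunken"): 0.4,
                ("very_slow", "sunken"): 0.8,
            }
        },
    )


@dataclass(frozen=True)
class ContinuousDist:
    """Marginal for one continuous predictor.

    ``lognormal`` draws exp(Normal(log(location), shape)); otherwise a
    normal with mean ``location`` and SD ``shape`` truncated below at
    ``floor`` (redrawn by clipping). Effects standardize by
    (x - location) / scale.
    """

    location: float
    shape: float
    lognormal: bool = False
    floor: float = 0.0
    scale: float | None = None  # standardization scale; defaults to shape

    @property
    def std_scale(self) -> float:
        return self.shape if self.scale is None else self.scale


def default_covariate_model() -> dict[str, object]:
    """Marginal distributions: sign levels concentrated on "normal", age
    lognormal (median 35 y), systolic BP and MUAC truncated normals."""
    return {
        "mental_status": (0.75, 0.20, 0.05),
        "thirst": (0.55, 0.35, 0.10),
        "skin_pinch": (0.60, 0.30, 0.10),
        "eyes": (0.55, 0.45),
        "respirations": (0.80, 0.20),
        "radial_pulse": (0.80, 0.15, 0.05),
        "capillary_refill": (0.85, 0.15),
        "urine_output": (0.50, 0.35, 0.15),
        "vomiting_episodes": (0.30, 0.45, 0.15, 0.10),
        "diarrheal_episodes": (0.35, 0.45, 0.20),
        "diarrhea_duration_hr": (0.30, 0.40, 0.30),
        "age": ContinuousDist(location=35.0, shape=0.55, lognormal=True, floor=5.0,
                              scale=22.0),
        "systolic_bp": ContinuousDist(location=110.0, shape=18.0),
        "muac": ContinuousDist(location=25.0, shape=3.5),
    }


@dataclass(frozen=True)
class CohortShift:
    """Covariate-distribution and prevalence offsets for a validation wave."""

    prevalences: tuple[float, float, float] = VALIDATION_PREVALENCES
    # Additive offsets to ContinuousDist.location (multiplicative on the
    # median for lognormal marginals, expressed as a target median shift).
    continuous_location: dict[str, float] = field(
        default_factory=lambda: {"age": -7.0}
    )
    categorical_probs: dict[str, tuple[float, ...]] = field(default_factory=dict)


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to draw one cohort deterministically."""

    n: int = DERIVATION_N
    prevalences: tuple[float, float, float] = DERIVATION_PREVALENCES
    effect_map: EffectMap = field(default_factory=default_effect_map)
    covariates: dict[str, object] = field(default_factory=default_covariate_model)
    shift: CohortShift | None = field(default_factory=CohortShift)
    seed: int = 0
    mcar_rate: float = 0.0  # per-cell chance a predictor value is missing
    schema: PredictorSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        p = np.asarray(self.prevalences, dtype=float)
        if p.shape != (K_CATEGORIES,):
            raise ValueError("prevalences must have length 3")
        if np.any(p <= 0):
            raise ValueError("prevalences must be strictly positive")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"prevalences must sum to 1, got {p.sum()!r}")
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if not (0.0 <= self.mcar_rate < 1.0):
            raise ValueError("mcar_rate must be in [0, 1)")
        unknown = set(self.effect_map.categorical) - set(self.schema.categorical)
        unknown |= (set(self.effect_map.linear) | set(self.effect_map.quadratic)) - set(
            self.schema.continuous
        )
        for a, b in self.effect_map.interactions:
            unknown |= {a, b} - set(self.schema.categorical)
        if unknown:
            raise ValueError(
                f"effect_map references unknown predictors {sorted(unknown)}; "
                f"known: {sorted(self.schema.predictors)}"
            )


def null_effect_map() -> EffectMap:
    """All effects zero: outcome independent of every predictor."""
    return EffectMap()


# ---------------------------------------------------------------------------
# Intercept calibration


def calibrate_intercepts(
    prevalences: tuple[float, float, float] | np.ndarray, eta: np.ndarray
) -> np.ndarray:
    """Solve for K-1 ascending cumulative-logit thresholds on an eta sample.

    With P(Y <= k | eta) = expit(theta_k - eta), finds theta_k such that the
    mean over the empirical eta sample of P(Y <= k) equals the cumulative
    target prevalence, to within the root-finder tolerance (< 1e-6).
    """
    p = np.asarray(prevalences, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-10:
        raise ValueError("prevalences must be strictly positive and sum to 1")
    cums = np.cumsum(p)[:-1]
    thetas = []
    for ck in cums:
        lo = logit(ck) + eta.min() - 1.0
        hi = logit(ck) + eta.max() + 1.0
        f = lambda t: float(np.mean(expit(t - eta)) - ck)  # noqa: E731
        if f(lo) > 0 or f(hi) < 0:  # pragma: no cover - defensive
            raise ValueError(
                f"cannot calibrate threshold for cumulative prevalence {ck:.4g}"
            )
        thetas.append(brentq(f, lo, hi, xtol=1e-10))
    thetas = np.asarray(thetas)
    if not np.all(np.diff(thetas) > 0):
        raise ValueError(
            "calibrated thresholds not ascending; degenerate eta or prevalences"
        )
    return thetas


# ---------------------------------------------------------------------------
# Cohort generation


def _draw_covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for name, levels in spec.schema.categorical.items():
        probs = np.asarray(spec.covariates[name], dtype=float)
        if probs.shape != (len(levels),):
            raise ValueError(f"covariate probs for {name!r} must match level count")
        probs = probs / probs.sum()
        idx = rng.choice(len(levels), size=spec.n, p=probs)
        cols[name] = pd.Categorical.from_codes(idx, categories=list(levels))
    for name in spec.schema.continuous:
        dist: ContinuousDist = spec.covariates[name]
        if dist.lognormal:
            x = np.exp(rng.normal(np.log(dist.location), dist.shape, size=spec.n))
        else:
            x = rng.normal(dist.location, dist.shape, size=spec.n)
        cols[name] = np.maximum(x, dist.floor)
    return pd.DataFrame(cols)


def latent_predictor(spec: CohortSpec, covariates: pd.DataFrame) -> np.ndarray:
    """Latent linear predictor eta (higher = more severe) for each patient."""
    eta = np.zeros(len(covariates))
    em = spec.effect_map
    for name, level_effects in em.categorical.items():
        vals = np.asarray(covariates[name].astype(str))
        for level, coef in level_effects.items():
            if level not in spec.schema.categorical[name]:
                raise ValueError(f"unknown level {level!r} for {name!r}")
            eta += coef * (vals == level)
    for name, coef in em.linear.items():
        dist: ContinuousDist = spec.covariates[name]
        loc = dist.location if not dist.lognormal else dist.location
        z = (np.asarray(covariates[name], dtype=float) - loc) / dist.std_scale
        eta += coef * z
    for name, coef in em.quadratic.items():
        dist = spec.covariates[name]
        z = (np.asarray(covariates[name], dtype=float) - dist.location) / dist.std_scale
        eta += coef * z**2
    for (a, b), pair_effects in em.interactions.items():
        va = np.asarray(covariates[a].astype(str))
        vb = np.asarray(covariates[b].astype(str))
        for (la, lb), coef in pair_effects.items():
            eta += coef * ((va == la) & (vb == lb))
    return eta


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort: covariates, latent predictor, calibrated ordinal outcome."""
    if spec.n == 0:
        cols: dict[str, object] = {}
        for name, levels in spec.schema.categorical.items():
            cols[name] = pd.Categorical([], categories=list(levels))
        for name in spec.schema.continuous:
            cols[name] = np.array([], dtype=float)
        cols[OUTCOME_COL] = pd.Categorical([], categories=list(OUTCOME_LEVELS))
        return pd.DataFrame(cols)
    rng_cov = substream(spec.seed, "covariates")
    rng_out = substream(spec.seed, "outcome")
    cov = _draw_covariates(spec, rng_cov)
    eta = latent_predictor(spec, cov)
    thetas = calibrate_intercepts(spec.prevalences, eta)
    c1 = expit(thetas[0] - eta)
    c2 = expit(thetas[1] - eta)
    u = rng_out.uniform(size=spec.n)
    codes = (u > c1).astype(int) + (u > c2).astype(int)
    cov[OUTCOME_COL] = pd.Categorical.from_codes(codes, categories=list(OUTCOME_LEVELS))
    if spec.mcar_rate > 0:
        # missing completely at random, predictors only (outcome untouched)
        rng_miss = substream(spec.seed, "mcar")
        for name in spec.schema.predictors:
            mask = rng_miss.uniform(size=spec.n) < spec.mcar_rate
            if mask.any():
                cov.loc[mask, name] = np.nan
    return cov


def outcome_codes(cohort: pd.DataFrame) -> np.ndarray:
    """Ordinal outcome as integer ranks 1 (none) .. 3 (severe)."""
    cat = pd.Categorical(
        cohort[OUTCOME_COL].astype(str), categories=list(OUTCOME_LEVELS)
    )
    if np.any(cat.codes < 0):
        raise ValueError("outcome contains values outside none/some/severe")
    return cat.codes.astype(int) + 1


def shift_spec(spec: CohortSpec) -> CohortSpec:
    """Validation-wave spec: shifted covariates and prevalences, own substream."""
    if spec.shift is None:
        raise ValueError("spec.shift is not set")
    sh = spec.shift
    p = np.asarray(sh.prevalences, dtype=float)
    if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-12:
        raise ValueError("shifted prevalences must be positive and sum to 1")
    cov = dict(spec.covariates)
    for name, delta in sh.continuous_location.items():
        dist: ContinuousDist = cov[name]
        cov[name] = replace(dist, location=dist.location + delta)
    for name, probs in sh.categorical_probs.items():
        cov[name] = tuple(probs)
    return replace(
        spec,
        n=VALIDATION_N if spec.n == DERIVATION_N else spec.n,
        prevalences=tuple(sh.prevalences),
        covariates=cov,
        shift=None,
        seed=spec.seed + 1_000_003,  # disjoint substream family
    )


# ---------------------------------------------------------------------------
# Rehydration weight courses


@dataclass(frozen=True)
class WeightSeries:
    """Four-hourly weights for one patient, admission weight first."""

    patient_id: int
    weights: tuple[float, ...]
    admission_weight: float

    def __post_init__(self) -> None:
        if len(self.weights) < 2:
            raise ValueError("a weight series needs >= 2 measurements")
        if min(self.weights) <= 0 or self.admission_weight <= 0:
            raise ValueError("weights must be positive")


def generate_weight_course(
    true_percent_dehydration: float,
    stable_weight: float,
    noise_sd: float = 0.0,
    n_obs: int = 8,
    rng: np.random.Generator | None = None,
    patient_id: int = 0,
) -> WeightSeries:
    """Rehydration course: weight rises from admission to a stable plateau.

    Admission weight is exactly ``stable_weight * (1 - percent/100)``; the
    series rises linearly to the stable weight, holding the last three
    measurements at the plateau (plus measurement noise on post-admission
    weights), so the stable-weight rule can recover the plateau.
    """
    if not (0 <= true_percent_dehydration < 100):
        raise ValueError("true_percent_dehydration must be in [0, 100)")
    if stable_weight <= 0:
        raise ValueError("stable_weight must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if n_obs < 4:
        raise ValueError("need at least 4 measurements")
    rng = rng if rng is not None else np.random.default_rng(0)
    admission = stable_weight * (1.0 - true_percent_dehydration / 100.0)
    ramp_len = n_obs - 3  # plateau occupies the last 3 points
    frac = np.minimum(np.arange(n_obs) / ramp_len, 1.0)
    w = admission + (stable_weight - admission) * frac
    if noise_sd > 0:
        w[1:] = w[1:] + rng.normal(0.0, noise_sd, size=n_obs - 1)
    w = np.maximum(w, 1e-3)
    return WeightSeries(
        patient_id=patient_id, weights=tuple(float(v) for v in w), admission_weight=admission
    )


# ---------------------------------------------------------------------------
# Serialization


def _spec_to_dict(spec: CohortSpec) -> dict:
    em = spec.effect_map
    cov = {}
    for name, d in spec.covariates.items():
        if isinstance(d, ContinuousDist):
            cov[name] = {
                "location": d.location,
                "shape": d.shape,
                "lognormal": d.lognormal,
                "floor": d.floor,
                "scale": d.scale,
            }
        else:
            cov[name] = [float(x) for x in d]
    out = {
        "n": spec.n,
        "prevalences": [float(x) for x in spec.prevalences],
        "seed": spec.seed,
        "mcar_rate": spec.mcar_rate,
        "effect_map": {
            "categorical": {k: dict(v) for k, v in em.categorical.items()},
            "linear": dict(em.linear),
            "quadratic": dict(em.quadratic),
            "interactions": {
                f"{a}|{b}": {f"{la}|{lb}": c for (la, lb), c in v.items()}
                for (a, b), v in em.interactions.items()
            },
        },
        "covariates": cov,
    }
    if spec.shift is not None:
        out["shift"] = {
            "prevalences": [float(x) for x in spec.shift.prevalences],
            "continuous_location": dict(spec.shift.continuous_location),
            "categorical_probs": {
                k: [float(x) for x in v] for k, v in spec.shift.categorical_probs.items()
            },
        }
    return out


def _spec_from_dict(d: dict) -> CohortSpec:
    em = d["effect_map"]
    effect_map = EffectMap(
        categorical={k: dict(v) for k, v in em.get("categorical", {}).items()},
        linear=dict(em.get("linear", {})),
        quadratic=dict(em.get("quadratic", {})),
        interactions={
            tuple(k.split("|")): {tuple(lk.split("|")): c for lk, c in v.items()}
            for k, v in em.get("interactions", {}).items()
        },
    )
    cov: dict[str, object] = {}
    for name, v in d["covariates"].items():
        if isinstance(v, dict):
            cov[name] = ContinuousDist(
                location=v["location"],
                shape=v["shape"],
                lognormal=v.get("lognormal", False),
                floor=v.get("floor", 0.0),
                scale=v.get("scale"),
            )
        else:
            cov[name] = tuple(v)
    shift = None
    if "shift" in d:
        sh = d["shift"]
        shift = CohortShift(
            prevalences=tuple(sh["prevalences"]),
            continuous_location=dict(sh.get("continuous_location", {})),
            categorical_probs={
                k: tuple(v) for k, v in sh.get("categorical_probs", {}).items()
            },
        )
    return CohortSpec(
        n=d["n"],
        prevalences=tuple(d["prevalences"]),
        effect_map=effect_map,
        covariates=cov,
        shift=shift,
        seed=d["seed"],
        mcar_rate=d.get("mcar_rate", 0.0),
    )


def spec_to_yaml(spec: CohortSpec) -> str:
    return yaml.safe_dump(_spec_to_dict(spec), sort_keys=True)


def spec_from_yaml(text: str) -> CohortSpec:
    return _spec_from_dict(yaml.safe_load(text))


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path, schema: PredictorSchema | None = None) -> pd.DataFrame:
    schema = schema if schema is not None else default_schema()
    df = pd.read_csv(path)
    for name, levels in schema.categorical.items():
        if name in df:
            df[name] = pd.Categorical(df[name].astype(str), categories=list(levels))
    if OUTCOME_COL in df:
        df[OUTCOME_COL] = pd.Categorical(
            df[OUTCOME_COL].astype(str), categories=list(OUTCOME_LEVELS)
        )
    return df
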