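import numpy as np
import pytest

from ordval.preprocess import DesignEncoder
from ordval.schema import PredictorSchema, default_schema
from ordval.synthetic import (
    CohortSpec,
    ContinuousDist,
    EffectMap,
    generate_cohort,
    outcome_codes,
)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def cohort_small():
    """A 400-patient derivation-style cohort with the default effect map."""
    return generate_cohort(CohortSpec(n=400, seed=11))


@pytest.fixture(scope="session")
def encoded_small(cohort_small):
    enc = DesignEncoder(1).fit(cohort_small)
    return enc.transform(cohort_small), outcome_codes(cohort_small)


def mini_schema() -> PredictorSchema:
    """A 5-predictor schema for tests that need cheap model refits."""
    return PredictorSchema(
        categorical={
            "eyes": ("normal", "sunken"),
            "skin_pinch": ("rapid", "slow", "very_slow"),
            "thirst": ("normal", "drinks_eagerly", "refuses_unable"),
            "respirations": ("normal", "deep"),
        },
        continuous=("age",),
        bin_upper_edges={},
    )


def mini_covariates() -> dict:
    return {
        "eyes": (0.6, 0.4),
        "skin_pinch": (0.6, 0.3, 0.1),
        "thirst": (0.5, 0.35, 0.15),
        "respirations": (0.8, 0.2),
        "age": ContinuousDist(location=35.0, shape=0.55, lognormal=True, floor=5.0, scale=22.0),
    }


def mini_spec(n: int, seed: int, effect_map: EffectMap | None = None,
              prevalences=(0.2, 0.6, 0.2)) -> CohortSpec:
    return CohortSpec(
        n=n,
        prevalences=prevalences,
        effect_map=effect_map if effect_map is not None else EffectMap(),
        covariates=mini_covariates(),
        shift=None,
        seed=seed,
        schema=mini_schema(),
    )
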