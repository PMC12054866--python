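"""Predictor schema for the dehydration cohorts.

Fourteen candidate predictors: eight categorical clinical signs, three
count/duration variables reported on a binned categorical scale, and three
continuous measurements. Each categorical predictor has an ordered level set
whose first entry is the clinically "normal" reference level; indicator
coding is always relative to that reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Ordered level sets; the first level is the reference ("normal") level.
CLINICAL_SIGNS: dict[str, tuple[str, ...]] = {
    "mental_status": ("normal", "confused_lethargic", "unconscious"),
    "thirst": ("normal", "drinks_eagerly", "refuses_unable"),
    "skin_pinch": ("rapid", "slow", "very_slow"),
    "eyes": ("normal", "sunken"),
    "respirations": ("normal", "deep"),
    "radial_pulse": ("strong", "decreased", "absent"),
    "capillary_refill": ("normal", "prolonged"),
    "urine_output": ("normal", "decreased_dark", "minimal_none"),
}

# Binned count/duration predictors: label sets plus the raw-scale bin edges.
# A raw value x falls in bin i when edges[i-1] < x <= edges[i] (integer counts
# make the printed ranges inclusive on both endpoints).
BINNED_LEVELS: dict[str, tuple[str, ...]] = {
    "vomiting_episodes": ("<1", "1-5", "6-10", ">10"),
    "diarrheal_episodes": ("<10", "10-19", ">19"),
    "diarrhea_duration_hr": ("<13", "13-23", ">23"),
}

# Upper edges of all but the last bin, on the raw scale; inclusive.
BIN_UPPER_EDGES: dict[str, tuple[float, ...]] = {
    "vomiting_episodes": (0, 5, 10),
    "diarrheal_episodes": (9, 19),
    "diarrhea_duration_hr": (12, 23),
}

CONTINUOUS: tuple[str, ...] = ("age", "systolic_bp", "muac")

CONTINUOUS_UNITS: dict[str, str] = {
    "age": "years",
    "systolic_bp": "mmHg",
    "muac": "cm",
}

OUTCOME_COL = "dehydration_cat"
OUTCOME_LEVELS: tuple[str, ...] = ("none", "some", "severe")


@dataclass(frozen=True)
class PredictorSchema:
    """Ordered predictor list with level sets, reference levels and bin edges.

    Parameters
    ----------
    categorical
        Mapping of categorical predictor name to its ordered level tuple.
        Includes both clinical signs and the binned count/duration
        predictors; the first level is the reference.
    continuous
        Names of continuous predictors.
    bin_upper_edges
        For each binned predictor, the inclusive upper edges of all but the
        last bin on the raw scale.
    """

    categorical: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {**CLINICAL_SIGNS, **BINNED_LEVELS}
    )
    continuous: tuple[str, ...] = CONTINUOUS
    bin_upper_edges: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(BIN_UPPER_EDGES)
    )

    def __post_init__(self) -> None:
        for name, levels in self.categorical.items():
            if len(set(levels)) != len(levels):
                raise ValueError(f"duplicate levels for predictor {name!r}")
            if len(levels) < 2:
                raise ValueError(f"predictor {name!r} needs >= 2 levels")
        for name, edges in self.bin_upper_edges.items():
            if list(edges) != sorted(set(edges)):
                raise ValueError(f"bin edges for {name!r} not strictly increasing")

    @property
    def predictors(self) -> tuple[str, ...]:
        """All predictor names, categoricals first, in schema order."""
        return tuple(self.categorical) + tuple(self.continuous)

    @property
    def columns(self) -> tuple[str, ...]:
        """Cohort table columns: predictors plus the outcome."""
        return self.predictors + (OUTCOME_COL,)

    def reference_level(self, name: str) -> str:
        return self.categorical[name][0]

    def n_indicator_columns(self, name: str) -> int:
        return len(self.categorical[name]) - 1


def default_schema() -> PredictorSchema:
    """The 14-predictor schema used throughout the analysis."""
    return PredictorSchema()
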