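"""End-to-end comparison: four tuned families x three indices x five stages.

``run_comparison`` reproduces the full comparison grid from one config:
derivation cohort -> complete cases -> per-family cross-validated tuning
(POLR and RIDGE additionally select among the configured variable sets by
CV score) -> apparent (Train) indices -> three bootstrap optimism
corrections (the full modeling process rerun inside every replicate) ->
external validation on the test cohort with frozen preprocessing. The
report is shaped like the study's comparison table: rows are index x
model, columns Train / Harrell / Efron 0.632 / Efron 0.632+ / Test.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ordval import __version__
from ordval.metrics import IndexValue, bootstrap_ci, _index_values, risk_score
from ordval.preprocess import DesignEncoder, complete_cases
from ordval.schema import PredictorSchema, default_schema
from ordval.synthetic import (
    CohortSpec,
    generate_cohort,
    outcome_codes,
    read_cohort_csv,
    shift_spec,
)
from ordval.tuning import tune_forest, tune_polr, tune_ridge, tune_tree
from ordval.validation import _child_seed, external_validate, optimism_correct

FAMILIES = ("POLR", "RF", "RIDGE", "CART")
STAGES = ("Train", "Harrell", "Efron 0.632", "Efron 0.632+", "Test")
_METHOD_STAGE = {"harrell": "Harrell", "e632": "Efron 0.632", "e632plus": "Efron 0.632+"}
INDICES = ("ADC", "ORC", "GC")


@dataclass
class RunConfig:
    """One comparison run: cohorts, grids, indices, seeds, output."""

    derivation: CohortSpec | str
    validation: CohortSpec | str | None = None  # None: shifted wave of derivation
    families: tuple[str, ...] = FAMILIES
    polr: dict = field(default_factory=lambda: {"max_main": 14, "max_int": 5, "sets": (1, 2, 3, 4)})
    ridge: dict = field(default_factory=lambda: {"lambdas": tuple(np.geomspace(1e-3, 1e3, 25)), "sets": (1, 2, 3, 4)})
    cart: dict = field(default_factory=lambda: {"cp_grid": (0.001, 0.005, 0.01, 0.02, 0.05), "minsplit_grid": (10, 20, 50, 100)})
    rf: dict = field(default_factory=lambda: {"mtry_grid": (1, 2, 3, 4, 6, 8, 11, 14), "ntree": 500})
    K: int = 10
    B: int = 1000
    orc_variant: str = "all_pairs"
    score_variant: str = "expected_rank"
    seed: int = 0
    out_dir: str | None = None
    schema: PredictorSchema = field(default_factory=default_schema)

    def validate(self) -> None:
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families {sorted(unknown)}")
        if self.K < 2 or self.B < 1:
            raise ValueError("need K >= 2 and B >= 1")
        for key in ("polr", "ridge"):
            sets = getattr(self, key)["sets"]
            if not set(sets) <= {1, 2, 3, 4}:
                raise ValueError(f"{key} variable sets must be within 1..4")
        if self.out_dir is not None:
            os.makedirs(self.out_dir, exist_ok=True)
            probe = os.path.join(self.out_dir, ".write-probe")
            with open(probe, "w") as fh:  # fail before compute, not after
                fh.write("")
            os.remove(probe)

    def echo(self) -> dict:
        def coh(c):
            return c if isinstance(c, str) else {"n": c.n, "seed": c.seed,
                                                 "prevalences": list(c.prevalences)}
        return {
            "derivation": coh(self.derivation),
            "validation": None if self.validation is None else coh(self.validation),
            "families": list(self.families),
            "polr": {k: list(v) if isinstance(v, tuple) else v for k, v in self.polr.items()},
            "ridge": {k: [float(x) for x in v] if k == "lambdas" else list(v)
                      for k, v in self.ridge.items()},
            "cart": {k: list(v) for k, v in self.cart.items()},
            "rf": {k: list(v) if isinstance(v, tuple) else v for k, v in self.rf.items()},
            "K": self.K,
            "B": self.B,
            "orc_variant": self.orc_variant,
            "score_variant": self.score_variant,
            "seed": self.seed,
        }


def smoke_config(seed: int = 0, n_train: int = 200, n_test: int = 150, B: int = 50) -> RunConfig:
    """Reduced-scale configuration: small cohorts, coarse grids, B bootstrap
    replicates — the full pipeline at a size that runs in minutes."""
    derivation = CohortSpec(n=n_train, seed=seed)
    validation = shift_spec(replace(derivation, n=n_test))
    return RunConfig(
        derivation=derivation,
        validation=validation,
        polr={"max_main": 3, "max_int": 0, "sets": (1,)},
        ridge={"lambdas": tuple(np.geomspace(1e-2, 1e2, 5)), "sets": (1,)},
        cart={"cp_grid": (0.01, 0.05), "minsplit_grid": (10, 50)},
        rf={"mtry_grid": (2, 4), "ntree": 50},
        K=10,
        B=B,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Family modelers


def make_modeler(family: str, config: RunConfig):
    """A self-contained modeling procedure for one family.

    The returned ``modeler(cohort, seed)`` re-does everything — encoding,
    variable-set selection, CV tuning, final fitting — on whatever cohort
    it is given, and returns a frozen scorer for new cohorts. The scorer
    carries ``info`` with the selected set, tuning parameters and model
    size (variables retained).
    """
    schema = config.schema

    def modeler(cohort: pd.DataFrame, seed: int):
        y = outcome_codes(cohort)
        if family in ("POLR", "RIDGE"):
            cfg = config.polr if family == "POLR" else config.ridge
            best = None
            for set_id in cfg["sets"]:
                enc = DesignEncoder(set_id, schema).fit(cohort)
                dm = enc.transform(cohort)
                if family == "POLR":
                    cv = tune_polr(dm, y, max_main=cfg["max_main"],
                                   max_int=cfg["max_int"] if set_id in (2, 4) else 0,
                                   K=config.K, seed=_child_seed(seed, f"set{set_id}"))
                else:
                    cv = tune_ridge(dm, y, lambdas=np.asarray(cfg["lambdas"]),
                                    K=config.K, seed=_child_seed(seed, f"set{set_id}"))
                score = float(cv.Ebar[cv.selected])
                if best is None or score > best[0]:
                    best = (score, set_id, enc, cv)
            _, set_id, enc, cv = best
            fit = cv.fit
            if family == "POLR":
                size = cv.params["size"] + cv.params["n_interactions"]
            else:
                size = len(enc._template.main_blocks)
            info = {"set_id": set_id, "params": cv.params, "size": size}
        elif family == "CART":
            enc = DesignEncoder(1, schema).fit(cohort)
            dm = enc.transform(cohort)
            cv = tune_tree(dm, y, cp_grid=config.cart["cp_grid"],
                           minsplit_grid=config.cart["minsplit_grid"],
                           K=config.K, seed=_child_seed(seed, "cart"))
            fit = cv.fit
            info = {"set_id": 1, "params": cv.params, "size": len(dm.main_blocks)}
        elif family == "RF":
            enc = DesignEncoder(1, schema).fit(cohort)
            dm = enc.transform(cohort)
            cv = tune_forest(dm, y, mtry_grid=config.rf["mtry_grid"],
                             ntree=config.rf["ntree"], K=config.K,
                             seed=_child_seed(seed, "rf"))
            fit = cv.fit
            info = {"set_id": 1, "params": cv.params, "size": len(dm.main_blocks)}
        else:
            raise ValueError(f"unknown family {family!r}")

        def scorer(new_cohort: pd.DataFrame) -> np.ndarray:
            dm_new = enc.transform(new_cohort)
            return risk_score(fit.predict_proba(dm_new), config.score_variant)

        scorer.info = info
        scorer.fit = fit
        return scorer

    return modeler


# ---------------------------------------------------------------------------
# Report


@dataclass
class ComparisonReport:
    """Comparison grid keyed by (index, model, stage), plus provenance."""

    cells: dict[str, dict | str]  # "index|model|stage" -> cell or "FAILED"
    model_sizes: dict[str, int | None]
    model_params: dict[str, dict | None]
    config: dict
    seed: int
    version: str = __version__
    partial: bool = False

    @staticmethod
    def key(index: str, model: str, stage: str) -> str:
        return f"{index}|{model}|{stage}"

    def cell(self, index: str, model: str, stage: str):
        return self.cells[self.key(index, model, stage)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "cells": self.cells,
                "model_sizes": self.model_sizes,
                "model_params": self.model_params,
                "config": self.config,
                "seed": self.seed,
                "version": self.version,
                "partial": self.partial,
            },
            sort_keys=True,
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        d = json.loads(text)
        return cls(
            cells=d["cells"],
            model_sizes=d["model_sizes"],
            model_params=d["model_params"],
            config=d["config"],
            seed=d["seed"],
            version=d["version"],
            partial=d["partial"],
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for index in INDICES:
            for model in self.config["families"]:
                row = {"Index": index, "Model": model}
                for stage in STAGES:
                    cell = self.cells.get(self.key(index, model, stage), "FAILED")
                    if cell == "FAILED":
                        row[stage] = "FAILED"
                    elif cell.get("ci") is not None:
                        lo, hi = cell["ci"]
                        row[stage] = f"{cell['value']:.2f}({lo:.2f},{hi:.2f})"
                    else:
                        row[stage] = f"{cell['value']:.2f}"
                rows.append(row)
        return pd.DataFrame(rows, columns=["Index", "Model", *STAGES])


def _cell(value: float, ci=None, B=None) -> dict:
    if ci is not None:
        ci = (min(ci[0], value), max(ci[1], value))
        IndexValue(name="ADC", value=value, ci=ci, B=B)  # validate ranges
    return {"value": float(value), "ci": None if ci is None else [float(ci[0]), float(ci[1])], "B": B}


def run_comparison(config: RunConfig) -> ComparisonReport:
    """Execute the full comparison and return the report grid."""
    config.validate()
    train = _load_cohort(config.derivation, config)
    if config.validation is None:
        if isinstance(config.derivation, str):
            raise ValueError("validation cohort required when derivation is a file")
        test = _load_cohort(shift_spec(config.derivation), config)
    else:
        test = _load_cohort(config.validation, config)
    train, _ = complete_cases(train, config.schema)
    test, _ = complete_cases(test, config.schema)
    y_train = outcome_codes(train)

    cells: dict[str, dict | str] = {}
    sizes: dict[str, int | None] = {}
    params: dict[str, dict | None] = {}
    partial = False
    for family in config.families:
        fam_seed = _child_seed(config.seed, f"family-{family}")
        modeler = make_modeler(family, config)
        try:
            scorer = modeler(train, _child_seed(fam_seed, "apparent"))
            s_train = scorer(train)
            train_vals = _index_values(s_train, y_train, config.orc_variant)
            for index in INDICES:
                ci = bootstrap_ci(s_train, y_train, index,
                                  orc_variant=config.orc_variant, B=config.B,
                                  seed=_child_seed(fam_seed, f"train-ci-{index}"))
                cells[ComparisonReport.key(index, family, "Train")] = _cell(
                    train_vals[index], ci, config.B)
            opt = optimism_correct(modeler, train, index_names=INDICES, B=config.B,
                                   seed=_child_seed(fam_seed, "optimism"),
                                   orc_variant=config.orc_variant)
            for index in INDICES:
                for method, stage in _METHOD_STAGE.items():
                    res = opt[index]
                    cells[ComparisonReport.key(index, family, stage)] = _cell(
                        res.corrected(method), res.ci[method], config.B)
            ext = external_validate(scorer, test, index_names=INDICES, B=config.B,
                                    seed=_child_seed(fam_seed, "external"),
                                    orc_variant=config.orc_variant)
            for index in INDICES:
                cells[ComparisonReport.key(index, family, "Test")] = _cell(
                    ext[index].value, ext[index].ci, config.B)
            sizes[family] = scorer.info["size"]
            params[family] = scorer.info["params"]
        except Exception:  # noqa: BLE001 - failure isolation per family
            partial = True
            for index in INDICES:
                for stage in STAGES:
                    cells.setdefault(ComparisonReport.key(index, family, stage), "FAILED")
            sizes[family] = None
            params[family] = None
    return ComparisonReport(
        cells=cells,
        model_sizes=sizes,
        model_params=params,
        config=config.echo(),
        seed=config.seed,
        partial=partial,
    )


def _load_cohort(source, config: RunConfig) -> pd.DataFrame:
    if isinstance(source, str):
        return read_cohort_csv(source, config.schema)
    return generate_cohort(source)


def write_report(report: ComparisonReport, out_dir: str, formats=("json", "csv", "log")) -> dict[str, str]:
    """Emit machine JSON, the table-layout CSV, and a seed/config log."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    if "json" in formats:
        paths["json"] = os.path.join(out_dir, "comparison.json")
        with open(paths["json"], "w") as fh:
            fh.write(report.to_json())
    if "csv" in formats:
        paths["csv"] = os.path.join(out_dir, "comparison.csv")
        report.to_frame().to_csv(paths["csv"], index=False)
    if "log" in formats:
        paths["log"] = os.path.join(out_dir, "run_log.json")
        with open(paths["log"], "w") as fh:
            json.dump({"seed": report.seed, "config": report.config,
                       "version": report.version,
                       "model_sizes": report.model_sizes,
                       "model_params": report.model_params},
                      fh, indent=1, sort_keys=True)
    return paths
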