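"""Validated table IO, configuration hashing and pipeline orchestration."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly as asm
from . import checking, comparison, estimation, rt, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "read_table",
    "write_table",
    "PipelineConfig",
    "run_pipeline",
]


class SchemaError(ValueError):
    """A table failed schema validation; the message names the offender."""


@dataclass(frozen=True)
class _Schema:
    name: str
    dtypes: dict           # column -> numpy-compatible dtype string
    checks: tuple = ()     # (column, vectorized predicate, message)


SCHEMAS = {
    "item_bank": _Schema(
        "item_bank",
        {"clone_id": "int64", "template_id": "int64", "shape_set": "int64",
         "distractor_type": "str", "element_n": "int64", "rule_n": "int64",
         "dimensionality": "int64"},
        (("element_n", lambda s: s.between(1, 4), "element_n outside [1, 4]"),
         ("rule_n", lambda s: s.between(1, 6), "rule_n outside [1, 6]")),
    ),
    "responses": _Schema(
        "responses",
        {"person_id": "int64", "clone_id": "int64", "template_id": "int64",
         "accuracy": "int64", "rt": "float64", "timeout": "bool"},
        (("rt", lambda s: s > 0, "non-positive response time"),
         ("accuracy", lambda s: s.isin([0, 1]), "accuracy must be 0/1")),
    ),
    "persons": _Schema(
        "persons",
        {"person_id": "int64", "age_z": "float64", "gender_code": "float64",
         "mean_rt_z": "float64", "delta_rt_z": "float64"},
        (("gender_code", lambda s: s.isin([-0.5, 0.5]),
          "gender_code must be -0.5 or +0.5"),),
    ),
    "item_params": _Schema(
        "item_params",
        {"clone_id": "int64", "beta": "float64", "alpha": "float64",
         "gamma": "float64"},
        (("alpha", lambda s: s.between(0, 5), "alpha outside [0, 5]"),
         ("gamma", lambda s: (s >= 0) & (s < 1), "gamma outside [0, 1)")),
    ),
}


def _validate(df: pd.DataFrame, schema: _Schema) -> pd.DataFrame:
    missing = [c for c in schema.dtypes if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema.name}: missing required column(s) {missing}")
    out = df.copy()
    for col, dtype in schema.dtypes.items():
        try:
            if dtype == "bool" and out[col].dtype == object:
                mapped = out[col].map({"True": True, "False": False,
                                       True: True, False: False})
                if mapped.isna().any():
                    raise ValueError("non-boolean value")
                out[col] = mapped.astype(bool)
            else:
                out[col] = out[col].astype(dtype)
        except (TypeError, ValueError) as err:
            raise SchemaError(f"{schema.name}: column {col!r} is not {dtype}: {err}")
    for col, pred, message in schema.checks:
        ok = pred(out[col])
        if not ok.all():
            bad = out.index[~ok][0]
            raise SchemaError(f"{schema.name}: {message} (first offending row {bad})")
    return out


def read_table(path, schema: str) -> pd.DataFrame:
    """Schema-validated CSV load (floats parsed with correct rounding)."""
    return _validate(pd.read_csv(path, float_precision="round_trip"),
                     SCHEMAS[schema])


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    """Schema-validated CSV write (lossless round trip through read_table)."""
    _validate(df, SCHEMAS[schema])
    cols = [c for c in SCHEMAS[schema].dtypes] + [
        c for c in df.columns if c not in SCHEMAS[schema].dtypes
    ]
    df[cols].to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end run: simulate -> exclude -> fit -> compare -> check -> assemble."""

    simulation: simulate.SimulationConfig = field(default_factory=simulate.desk_config)
    models: tuple = (1, 3)
    sampler: estimation.SamplerConfig = field(default_factory=estimation.desk_sampler)
    cluster: str = "template"
    run_ppc: bool = True
    run_assembly: bool = True
    n_forms: int = 2
    form_length: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        bad = [m for m in self.models if m not in range(1, 7)]
        if bad:
            raise ValueError(f"invalid model id(s): {bad}; must be in 1..6")

    def hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the full analysis pipeline into a run directory.

    Every stage writes plain-text artifacts (CSV/JSON); the run metadata
    records the config hash and seed so reruns are reproducible.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger("cloneirt").addHandler(handler)
    try:
        return _run_pipeline(config, out)
    finally:
        logging.getLogger("cloneirt").removeHandler(handler)


def _run_pipeline(config: PipelineConfig, out: Path) -> Path:
    sim_cfg = replace(config.simulation, seed=config.seed)
    logger.info("simulating study (seed=%d, hash=%s)", config.seed, config.hash())
    study = simulate.simulate_study(sim_cfg)
    study.bank.clones.to_csv(out / "item_bank.csv", index=False)
    write_table(study.item_params, out / "true_item_params.csv", "item_params")
    study.persons.to_csv(out / "persons.csv", index=False)
    write_table(study.responses, out / "responses.csv", "responses")
    study.config.coefficients.to_json(out / "true_coefficients.json")

    filtered, report = estimation.apply_exclusions(study.responses)
    report.to_csv(out / "exclusion_report.csv", index=False)

    rt_table = rt.fit_rt_lmm(filtered)
    rt_table.to_csv(out / "rt_lmm.csv", index=False)
    covs = rt.person_rt_covariates(filtered)
    persons_analysis = (
        study.persons[["person_id", "age_z", "gender_code"]]
        .merge(covs[["person_id", "mean_rt_z", "delta_rt_z"]], on="person_id")
    )
    persons_analysis = persons_analysis[persons_analysis["person_id"]
                                        .isin(filtered["person_id"].unique())]
    write_table(persons_analysis, out / "persons_analysis.csv", "persons")

    fits = {}
    for m in config.models:
        logger.info("fitting model %d", m)
        sampler = replace(config.sampler, seed=config.seed + m)
        fits[m] = estimation.fit_amis(filtered, study.bank, m, sampler,
                                      persons=persons_analysis)
        summ = estimation.summarize_item_params(fits[m], study.bank,
                                                allow_unconverged=True)
        summ.clones.to_csv(out / f"model{m}_item_summary.csv", index=False)
        summ.structure.to_csv(out / f"model{m}_structure_summary.csv", index=False)

    if len(fits) > 1:
        clls = {m: estimation.pointwise_loglik(f, config.cluster,
                                               marginal_residuals=True,
                                               max_draws=400)
                for m, f in fits.items()}
        table = comparison.compare_models(clls)
        table.to_csv(out / "model_comparison.csv", index=False)
        best = int(table.iloc[0]["model"])
    else:
        best = list(fits)[0]

    if config.run_ppc:
        fit = fits[best]
        result = {}
        for stat in ("chi2_nc", "sgddm"):
            r = checking.ppp(fit, stat, seed=config.seed)
            result[stat] = {"ppp": r.ppp, "extreme": r.extreme,
                            "mean_realized": r.mean_realized,
                            "mean_replicated": r.mean_replicated}
        (out / "ppc.json").write_text(json.dumps(result, indent=1))

    if config.run_assembly:
        summ = estimation.summarize_item_params(fits[best], study.bank,
                                                allow_unconverged=True)
        items = summ.clones.rename(columns={"beta_mean": "beta", "alpha_mean": "alpha"})
        items = items.merge(
            study.bank.clones[["clone_id", "template_id", "distractor_type"]],
            on="clone_id",
        ).assign(gamma=sim_cfg.guessing)
        problem = asm.AssemblyProblem(items, config.n_forms, config.form_length)
        forms = asm.solve_assembly(problem)
        rows = [{"form": i + 1, "clone_ids": " ".join(map(str, f.clone_ids)),
                 "reliability": f.reliability} for i, f in enumerate(forms)]
        pd.DataFrame(rows).to_csv(out / "forms.csv", index=False)
        asm.evaluate_forms(forms, items).to_csv(out / "form_evaluation.csv", index=False)

    meta = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "models": list(config.models),
        "diagnostics": {m: _jsonable(f.diagnostics) for m, f in fits.items()},
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=1))
    return out
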