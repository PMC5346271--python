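"""Config-driven orchestration of the package's standard experiments.

A run config (YAML or a plain dict) names one experiment —
``timeseries``, ``relaxation``, ``sensitivity``, ``ivive_comparison``,
``ratio_grid`` or ``variant_analysis`` — plus the models, chemical (or
synthetic table spec), ensemble settings and output directory.
:func:`run_experiment` executes it deterministically for the recorded
seed and writes numeric CSV tables plus a JSON run log (seed,
parameters, package version).  Figures are deliberately not produced:
the tables are the result surface.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ivive import prediction_ratio_grid, ratio_statistics, reconstruct_exposures
from .model_core import ChemicalDescriptor, build_model
from .population import (
    DEFAULT_GSD,
    ensemble_timeseries,
    sample_physiology,
    sensitivity_scan,
)
from .relaxation import ensemble_half_lives, summarize_half_lives
from .rtk_inverse import steady_state_difference
from .synthetic import (
    SyntheticTableSpec,
    default_physiology,
    generate_chemical_table,
    preset_chemical,
)

__all__ = ["RunConfig", "validate_config", "run_experiment", "load_config"]

logger = logging.getLogger("fishrtk")

EXPERIMENTS = (
    "timeseries",
    "relaxation",
    "sensitivity",
    "ivive_comparison",
    "ratio_grid",
    "variant_analysis",
)


@dataclass
class RunConfig:
    """Validated run configuration (see :func:`validate_config`)."""

    experiment: str
    output_dir: str = "fishrtk_out"
    models: list[str] = field(default_factory=lambda: ["7C", "6C", "1C"])
    chemical: Union[str, dict[str, Any]] = "diazinon"
    c_env: float = 10.0  # uM, constant exposure level
    delta: float = 0.10  # relaxation perturbation fraction
    observable: str = "whole_body"
    n: int = 100  # ensemble size
    gsd: float = DEFAULT_GSD
    seed: int = 0
    t_grid: dict[str, float] = field(
        default_factory=lambda: {"t_min_s": 1.0, "t_max_s": 1e6, "points": 60}
    )
    sensitivity: dict[str, Any] = field(
        default_factory=lambda: {"parameter": "q_w",
                                 "folds": [0.25, 0.5, 1.0, 2.0, 4.0]}
    )
    grid: dict[str, Any] = field(
        default_factory=lambda: {
            "log10_kow": [0.0, 8.0, 50],
            "log10_kmet": [-7.0, -1.0, 50],
            "c_body_uM": 10.0,
            "pairs": [["6C", "1C"], ["7C", "1C"]],
        }
    )
    table: Optional[dict[str, Any]] = None  # SyntheticTableSpec overrides

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        issues = validate_config(raw)
        if issues:
            raise ValueError("invalid config:\n  " + "\n  ".join(issues))
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in raw.items() if k in known})


def load_config(path: Union[str, Path]) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(raw)


def validate_config(raw: dict[str, Any]) -> list[str]:
    """Schema check; returns all violations without executing anything."""
    issues = []
    if not isinstance(raw, dict):
        return ["config must be a mapping"]
    exp = raw.get("experiment")
    if exp is None:
        issues.append("missing required key 'experiment'")
    elif exp not in EXPERIMENTS:
        issues.append(f"unknown experiment {exp!r}; expected one of {EXPERIMENTS}")
    models = raw.get("models", ["7C", "6C", "1C"])
    if not isinstance(models, list) or not models:
        issues.append("'models' must be a non-empty list")
    else:
        from .model_core import MODEL_IDS

        for m in models:
            if m not in MODEL_IDS:
                issues.append(f"unknown model id {m!r}")
    for key in ("c_env", "delta", "gsd"):
        if key in raw and not (
            isinstance(raw[key], (int, float)) and raw[key] > 0
        ):
            issues.append(f"{key!r} must be a positive number")
    if "n" in raw and not (isinstance(raw["n"], int) and raw["n"] >= 1):
        issues.append("'n' must be a positive integer")
    if "seed" in raw and not isinstance(raw["seed"], int):
        issues.append("'seed' must be an integer")
    chem = raw.get("chemical", "diazinon")
    if isinstance(chem, str):
        from .synthetic import PRESET_CHEMICALS

        if chem not in PRESET_CHEMICALS:
            issues.append(f"unknown preset chemical {chem!r}")
    elif isinstance(chem, dict):
        if "name" not in chem or "log_kow" not in chem:
            issues.append("inline chemical needs at least 'name' and 'log_kow'")
    else:
        issues.append("'chemical' must be a preset name or a mapping")
    return issues


def _resolve_chemical(config: RunConfig) -> ChemicalDescriptor:
    if isinstance(config.chemical, str):
        return preset_chemical(config.chemical)
    return ChemicalDescriptor(**config.chemical)


def run_experiment(config: Union[RunConfig, dict[str, Any]]) -> Path:
    """Execute one experiment; returns the output directory."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    runner = {
        "timeseries": _run_timeseries,
        "relaxation": _run_relaxation,
        "sensitivity": _run_sensitivity,
        "ivive_comparison": _run_ivive,
        "ratio_grid": _run_ratio_grid,
        "variant_analysis": _run_variant_analysis,
    }[config.experiment]
    logger.info("running experiment %s -> %s", config.experiment, out)
    try:
        tables = runner(config, out)
    except Exception as exc:
        raise RuntimeError(
            f"experiment {config.experiment!r} failed: {exc}"
        ) from exc
    log = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "experiment": config.experiment,
        "seed": config.seed,
        "config": asdict(config),
        "tables": tables,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return out


def _float_fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _run_timeseries(config: RunConfig, out: Path) -> list[str]:
    chem = _resolve_chemical(config)
    tg = config.t_grid
    t_grid = np.logspace(
        np.log10(tg["t_min_s"]), np.log10(tg["t_max_s"]), int(tg["points"])
    )
    frames = []
    for model_id in config.models:
        base, comp = default_physiology(model_id)
        ensemble = sample_physiology(
            base, gsd=config.gsd, n=config.n, seed=config.seed
        )
        summary = ensemble_timeseries(
            model_id, chem, config.c_env, ensemble, t_grid, composition=comp
        )
        df = summary.to_frame()
        df.insert(0, "model", model_id)
        df["n_used"] = summary.n_used
        df["n_failed"] = summary.n_failed
        frames.append(df)
    _float_fmt(pd.concat(frames, ignore_index=True), out / "fig3_timeseries.csv")
    return ["fig3_timeseries.csv"]


def _run_relaxation(config: RunConfig, out: Path) -> list[str]:
    chem = _resolve_chemical(config)
    all_draws = []
    summaries = []
    for model_id in config.models:
        base, comp = default_physiology(model_id)
        ensemble = sample_physiology(
            base, gsd=config.gsd, n=config.n, seed=config.seed
        )
        df = ensemble_half_lives(
            model_id, chem, config.c_env, ensemble, config.delta, composition=comp
        )
        all_draws.append(df)
        s = summarize_half_lives(df)
        s.insert(0, "model", model_id)
        summaries.append(s)
    _float_fmt(pd.concat(all_draws, ignore_index=True), out / "fig5_halflives.csv")
    _float_fmt(pd.concat(summaries, ignore_index=True),
               out / "fig5_summary.csv")
    return ["fig5_halflives.csv", "fig5_summary.csv"]


def _run_sensitivity(config: RunConfig, out: Path) -> list[str]:
    chem = _resolve_chemical(config)
    frames = []
    for model_id in config.models:
        df = sensitivity_scan(
            model_id,
            chem,
            config.c_env,
            config.sensitivity["parameter"],
            config.sensitivity["folds"],
        )
        df.insert(0, "model", model_id)
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    _float_fmt(merged, out / "sensitivity.csv")
    return ["sensitivity.csv"]


def _run_ivive(config: RunConfig, out: Path) -> list[str]:
    table_kwargs = dict(config.table or {})
    table_kwargs.setdefault("seed", config.seed)
    records = generate_chemical_table(SyntheticTableSpec(**table_kwargs))
    loecs = [r.loec for r in records]
    names = [r.name for r in records]
    pecs_by_model = {}
    for model_id in config.models:
        preds = reconstruct_exposures(model_id, records, config.observable)
        pecs_by_model[model_id] = [p.pec for p in preds]
    result = ratio_statistics(pecs_by_model, loecs, chemicals=names)
    _float_fmt(result.ratios, out / "fig2_comparison.csv")
    tests = [
        {"test": "binomial", "model_a": m, "model_b": "",
         "k": b.k, "n": b.n, "p": b.p_two_sided}
        for m, b in result.binomial.items()
    ]
    for row in result.pairwise_tests.to_dict("records"):
        tests.append({"test": "t_welch", "model_a": row["model_a"],
                      "model_b": row["model_b"], "k": "", "n": "",
                      "p": row["p"]})
    _float_fmt(pd.DataFrame(tests), out / "fig2_tests.csv")
    return ["fig2_comparison.csv", "fig2_tests.csv"]


def _run_ratio_grid(config: RunConfig, out: Path) -> list[str]:
    g = config.grid
    kow = np.linspace(*g["log10_kow"][:2], int(g["log10_kow"][2]))
    kmet = np.linspace(*g["log10_kmet"][:2], int(g["log10_kmet"][2]))
    frames = []
    for model_a, model_b in g["pairs"]:
        grid = prediction_ratio_grid(
            model_a, model_b, kmet, kow, c_body=g.get("c_body_uM", 10.0)
        )
        df = grid.to_frame()
        df.insert(0, "pair", f"{model_a}_vs_{model_b}")
        frames.append(df)
    _float_fmt(pd.concat(frames, ignore_index=True), out / "fig6_grid.csv")
    return ["fig6_grid.csv"]


def _run_variant_analysis(config: RunConfig, out: Path) -> list[str]:
    chem = _resolve_chemical(config)
    physiology, comp = default_physiology("6C")
    m6 = build_model("6C", physiology, comp)
    mc = build_model("6C_collapsed", physiology, comp)
    mr = build_model("6C_rewired", physiology, comp)
    shared = ("arterial", "venous", "brain", "liver")
    d_collapse = steady_state_difference(mc, m6, chem, shared)
    d_rewire = steady_state_difference(mr, m6, chem, shared)
    from .rtk_inverse import response_coefficients

    s6 = response_coefficients(m6, chem)
    rows = [
        {
            "compartment": name,
            "s_6C": s6[name],
            "diff_collapsed_minus_6C": d_collapse[name],
            "diff_rewired_minus_6C": d_rewire[name],
        }
        for name in shared
    ]
    _float_fmt(pd.DataFrame(rows), out / "variant_differences.csv")
    return ["variant_differences.csv"]
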