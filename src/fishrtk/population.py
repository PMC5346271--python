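"""Population variability: log-normal body-parameter sampling and scans.

A population of fish is emulated by drawing every body parameter
(volumes, tissue flows, cardiac output, respiratory flow, body mass)
independently from a log-normal distribution whose arithmetic mean
equals the reference value: with geometric standard deviation ``gsd``
and ``sigma = ln(gsd)``, draws are
``base * exp(sigma * Z - sigma**2 / 2)``.  Tissue flows are re-scaled
after sampling so their sum matches the drawn cardiac output, keeping
every draw a valid physiology.  Chemical parameters are never varied.

The default dispersion is ``gsd = sqrt(2)`` (half a factor of two on
the log2 scale), so draws rarely stray beyond two-fold of the
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .forward_sim import integrate, steady_state
from .model_core import (
    ChemicalDescriptor,
    ModelStructure,
    PhysiologyParameterSet,
    TissueComposition,
    build_model,
)

__all__ = [
    "DEFAULT_GSD",
    "ParameterEnsemble",
    "EnsembleSummary",
    "sample_physiology",
    "ensemble_timeseries",
    "sensitivity_scan",
]

DEFAULT_GSD = float(np.sqrt(2.0))


@dataclass(frozen=True)
class ParameterEnsemble:
    """A seeded set of physiology draws around a reference parameter set."""

    draws: tuple[PhysiologyParameterSet, ...]
    n: int
    seed: int
    gsd: float
    base: PhysiologyParameterSet

    def __post_init__(self) -> None:
        if self.n != len(self.draws):
            raise ValueError("n must equal the number of draws")


def _lognormal(
    rng: np.random.Generator, base: float, sigma: float, mean_matching: str
) -> float:
    z = rng.standard_normal()
    if mean_matching == "arithmetic":
        return base * np.exp(sigma * z - 0.5 * sigma**2)
    if mean_matching == "geometric":
        return base * np.exp(sigma * z)
    raise ValueError(f"unknown mean_matching {mean_matching!r}")


def sample_physiology(
    base: PhysiologyParameterSet,
    gsd: float = DEFAULT_GSD,
    n: int = 1000,
    seed: int = 0,
    mean_matching: str = "arithmetic",
) -> ParameterEnsemble:
    """Draw ``n`` log-normal physiologies around ``base`` (seeded).

    ``gsd`` is the geometric standard deviation (>= 1); ``gsd = 1``
    reproduces ``base`` exactly.  The arithmetic mean of each varied
    parameter equals its base value under the default mean matching
    (``mu_log = ln(base) - sigma**2/2``); geometric mean matching is
    available via ``mean_matching="geometric"``.
    """
    if gsd < 1:
        raise ValueError(f"gsd must be >= 1, got {gsd}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    sigma = float(np.log(gsd))
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n):
        body_mass = _lognormal(rng, base.body_mass, sigma, mean_matching)
        volumes = {
            name: _lognormal(rng, v, sigma, mean_matching)
            for name, v in base.volumes.items()
        }
        q_w = _lognormal(rng, base.q_w, sigma, mean_matching)
        if base.flows:
            q_c = _lognormal(rng, base.q_c, sigma, mean_matching)
            raw = {
                name: _lognormal(rng, q, sigma, mean_matching)
                for name, q in base.flows.items()
            }
            scale = q_c / sum(raw.values())
            flows = {name: q * scale for name, q in raw.items()}
        else:
            q_c, flows = None, {}
        draws.append(
            PhysiologyParameterSet(
                body_mass=body_mass,
                volumes=volumes,
                flows=flows,
                q_c=q_c,
                q_w=q_w,
                assimilation_factor=base.assimilation_factor,
            )
        )
    return ParameterEnsemble(
        draws=tuple(draws), n=n, seed=seed, gsd=gsd, base=base
    )


@dataclass(frozen=True)
class EnsembleSummary:
    """Pointwise mean/sd of per-compartment and whole-body trajectories."""

    times: np.ndarray
    mean: np.ndarray  # (n_times, n_compartments)
    sd: np.ndarray
    whole_body_mean: np.ndarray
    whole_body_sd: np.ndarray
    compartments: tuple[str, ...]
    model_id: str
    n_used: int
    n_failed: int

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for j, name in enumerate(self.compartments):
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": self.times,
                        "observable": name,
                        "mean_uM": self.mean[:, j],
                        "sd_uM": self.sd[:, j],
                    }
                )
            )
        frames.append(
            pd.DataFrame(
                {
                    "time_s": self.times,
                    "observable": "whole_body",
                    "mean_uM": self.whole_body_mean,
                    "sd_uM": self.whole_body_sd,
                }
            )
        )
        return pd.concat(frames, ignore_index=True)


def ensemble_timeseries(
    model_id: str,
    chem: ChemicalDescriptor,
    c_env: float,
    ensemble: ParameterEnsemble,
    t_grid: np.ndarray,
    composition: Optional[TissueComposition] = None,
    kinetics: str = "first_order",
) -> EnsembleSummary:
    """Per-draw integration from zero state, then pointwise mean and sd.

    Draws whose integration fails are excluded and counted in
    ``n_failed``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if composition is None:
        from .synthetic import default_physiology

        composition = default_physiology(model_id)[1]
    trajectories = []
    wb = []
    n_failed = 0
    compartments: tuple[str, ...] = ()
    for draw in ensemble.draws:
        try:
            model = build_model(model_id, draw, composition)
            profile = integrate(
                model,
                chem,
                c_env,
                (0.0, float(t_grid[-1])),
                kinetics=kinetics,
                t_eval=t_grid,
            )
            conc = profile.concentrations
            if len(profile.times) == len(t_grid) + 1:
                conc = conc[1:]  # drop the prepended t=0 row
            compartments = model.compartments
            trajectories.append(conc)
            wb.append(conc @ model.volume_vector() / model.total_volume)
        except (ValueError, RuntimeError):
            n_failed += 1
    if not trajectories:
        raise RuntimeError("all ensemble draws failed to integrate")
    stack = np.stack(trajectories)
    wb_stack = np.stack(wb)
    return EnsembleSummary(
        times=t_grid,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0),
        whole_body_mean=wb_stack.mean(axis=0),
        whole_body_sd=wb_stack.std(axis=0),
        compartments=compartments,
        model_id=model_id,
        n_used=len(trajectories),
        n_failed=n_failed,
    )


def _perturbed(
    base: PhysiologyParameterSet, parameter: str, fold: float
) -> PhysiologyParameterSet:
    if fold <= 0:
        raise ValueError(f"fold must be > 0, got {fold}")
    if parameter == "q_w":
        return replace(base, q_w=base.q_w * fold)
    if parameter == "body_mass":
        return replace(base, body_mass=base.body_mass * fold)
    if parameter == "q_c":
        # scale every tissue flow with cardiac output to keep balance
        if not base.flows:
            raise ValueError("model has no cardiac output")
        flows = {k: v * fold for k, v in base.flows.items()}
        return replace(base, q_c=base.q_c * fold, flows=flows)
    if parameter == "assimilation_factor":
        if base.assimilation_factor is None:
            raise ValueError("model has no assimilation factor")
        return replace(base, assimilation_factor=base.assimilation_factor * fold)
    if parameter.startswith("V_"):
        name = parameter[2:]
        if name not in base.volumes:
            raise ValueError(f"unknown compartment volume {name!r}")
        volumes = dict(base.volumes)
        volumes[name] *= fold
        return replace(base, volumes=volumes)
    if parameter.startswith("Q_"):
        name = parameter[2:]
        if name not in base.flows:
            raise ValueError(f"unknown tissue flow {name!r}")
        flows = dict(base.flows)
        flows[name] *= fold
        # cardiac output follows the perturbed tissue flow sum
        return replace(base, flows=flows, q_c=sum(flows.values()))
    raise ValueError(f"unknown parameter {parameter!r}")


def sensitivity_scan(
    model_id: str,
    chem: ChemicalDescriptor,
    c_env: float,
    parameter_name: str,
    fold_grid: Sequence[float],
    base: Optional[PhysiologyParameterSet] = None,
    composition: Optional[TissueComposition] = None,
) -> pd.DataFrame:
    """One-at-a-time multiplicative scan of a named body parameter.

    Returns one row per fold change with the steady-state whole-body
    and per-compartment concentrations plus the exposure-independent
    response ratios (concentration / ``c_env``).
    """
    if base is None or composition is None:
        from .synthetic import default_physiology

        d_base, d_comp = default_physiology(model_id)
        base = base or d_base
        composition = composition or d_comp
    rows = []
    for fold in fold_grid:
        physiology = _perturbed(base, parameter_name, float(fold))
        model = build_model(model_id, physiology, composition)
        ss = steady_state(model, chem, c_env, method="linear_solve")
        row = {
            "parameter": parameter_name,
            "fold": float(fold),
            "whole_body_uM": ss.whole_body,
            "whole_body_ratio": ss.whole_body / c_env if c_env > 0 else np.nan,
        }
        for name in model.compartments:
            row[f"{name}_uM"] = ss.compartment(name)
        rows.append(row)
    return pd.DataFrame(rows)
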