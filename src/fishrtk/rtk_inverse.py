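"""Exact reverse-toxicokinetic (rTK) exposure reconstruction.

Under constant exposure and first-order kinetics each PBTK model is
linear, so every compartment's steady-state concentration is
proportional to the water concentration:

    C_i,ss = s_i * C_env,      s = -A^{-1} b,

with ``s_i`` a dimensionless, exposure-independent response
coefficient.  Inverting the relationship turns an observed internal
concentration into a predicted exposure concentration (PEC):

    PEC = C_obs / s_obs.

The inversion is computed from the linear system itself rather than
from hand-transcribed closed forms, so the forward and reverse models
can never disagree by construction; the forward simulator provides the
independent round-trip check in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_sim import system_matrices
from .model_core import ChemicalDescriptor, ModelStructure

__all__ = [
    "ExposurePrediction",
    "response_coefficients",
    "whole_body_coefficient",
    "predict_exposure",
    "steady_state_difference",
]

WHOLE_BODY = "whole_body"


@dataclass(frozen=True)
class ExposurePrediction:
    """A PEC together with the linear response coefficient behind it."""

    pec: float  # uM
    model_id: str
    observable: str  # "whole_body" or "tissue:<name>"
    response_coefficient: float  # dimensionless s_obs = C_obs,ss / C_env

    def __post_init__(self) -> None:
        if self.pec < 0:
            raise ValueError(f"pec must be >= 0, got {self.pec}")


def response_coefficients(
    model: ModelStructure, chem: ChemicalDescriptor
) -> dict[str, float]:
    """Per-compartment dimensionless steady-state response ``s_i``.

    With no metabolic or excretory sink every tissue equilibrates with
    the water thermodynamically and ``s_i`` reduces to the partition
    coefficient ``P_i``; sinks pull every coefficient below that limit.
    """
    A, b = system_matrices(model, chem)
    try:
        s = np.linalg.solve(A, -b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular rate matrix: {exc}") from exc
    return {name: float(s[i]) for i, name in enumerate(model.compartments)}


def whole_body_coefficient(model: ModelStructure, chem: ChemicalDescriptor) -> float:
    """Volume-weighted whole-body response coefficient (blood included)."""
    s = response_coefficients(model, chem)
    V = model.volumes
    total = sum(V[c] for c in model.compartments)
    return sum(V[c] * s[c] for c in model.compartments) / total


def _observable_coefficient(
    model: ModelStructure, chem: ChemicalDescriptor, observable: str
) -> float:
    if observable == WHOLE_BODY:
        return whole_body_coefficient(model, chem)
    if observable.startswith("tissue:"):
        name = observable.split(":", 1)[1]
        if name not in model.compartments:
            raise ValueError(
                f"model {model.model_id} has no compartment {name!r}"
            )
        return response_coefficients(model, chem)[name]
    raise ValueError(
        f"unknown observable {observable!r}; use 'whole_body' or 'tissue:<name>'"
    )


def predict_exposure(
    model: ModelStructure,
    chem: ChemicalDescriptor,
    observable: str,
    concentration: float,
) -> ExposurePrediction:
    """Exact exposure reconstruction for one observed concentration (uM)."""
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    s_obs = _observable_coefficient(model, chem, observable)
    if not np.isfinite(s_obs) or s_obs <= 0:
        raise ValueError(
            f"ill-posed observable {observable!r}: response coefficient {s_obs}"
        )
    return ExposurePrediction(
        pec=concentration / s_obs,
        model_id=model.model_id,
        observable=observable,
        response_coefficient=s_obs,
    )


def steady_state_difference(
    variant_a: ModelStructure,
    variant_b: ModelStructure,
    chem: ChemicalDescriptor,
    compartments: tuple[str, ...],
) -> dict[str, float]:
    """Signed differences ``s_a - s_b`` of the response coefficients.

    Because the response coefficients are exposure-independent, these
    differences characterise the structural variants for every exposure
    level at once.
    """
    s_a = response_coefficients(variant_a, chem)
    s_b = response_coefficients(variant_b, chem)
    out = {}
    for name in compartments:
        if name not in s_a or name not in s_b:
            raise ValueError(f"compartment {name!r} not shared by both variants")
        out[name] = s_a[name] - s_b[name]
    return out
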