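"""Self-contained inputs: physiology fixtures, preset chemicals, assay tables.

The package ships documented default physiologies for each model family
(CSV fixtures under ``fishrtk/data/``) so every analysis runs without
external downloads.  Values whose sources are not printed in the main
literature are flagged ``assumed`` in the fixtures' provenance column;
users can override any of them by loading their own CSVs with
:func:`physiology_from_frames`.

:func:`generate_chemical_table` emulates the structure of a
high-throughput estrogenicity screen joined to whole-organism effect
data: ~36 chemicals whose in vitro AC10s span orders of magnitude and
whose LOECs scatter around the AC10s by a log-normal offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .ivive import ChemicalAssayRecord
from .model_core import (
    ChemicalDescriptor,
    PhysiologyParameterSet,
    TissueComposition,
)

__all__ = [
    "SyntheticTableSpec",
    "default_physiology",
    "physiology_from_frames",
    "preset_chemical",
    "generate_chemical_table",
    "PRESET_CHEMICALS",
]

_FIXTURE_FILES = {"7C": "physiology_7C.csv", "6C": "physiology_6C.csv",
                  "1C": "physiology_1C.csv"}
_VARIANT_BASE = {"6C_collapsed": "6C", "6C_rewired": "6C"}

#: Preset chemical descriptors.  The octanol-water ratios are the
#: literature values for the two study chemicals; the clearance rate is
#: an assumed mid-range default (geometric midpoint of the 1e-7..1e-1
#: 1/s scan range used in the prediction-ratio grids).
PRESET_CHEMICALS = {
    "diazinon": ChemicalDescriptor(name="diazinon", log_kow=3.81, k_met=1e-4),
    "dichloroethane_12": ChemicalDescriptor(
        name="dichloroethane_12", log_kow=1.48, k_met=1e-4
    ),
}


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("fishrtk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def physiology_from_frames(
    compartments: pd.DataFrame, scalars: pd.Series
) -> tuple[PhysiologyParameterSet, TissueComposition]:
    """Build a physiology + composition pair from tabular inputs.

    ``compartments`` needs columns ``compartment, volume_mL,
    flow_mL_per_s, f_lipid, f_water`` (flow and fractions may be empty
    for blood); ``scalars`` needs ``body_mass_g, Qc_mL_per_s,
    Qw_mL_per_s`` and optionally ``assimilation_factor``.
    """
    volumes = {}
    flows = {}
    fractions = {}
    for row in compartments.itertuples(index=False):
        name = row.compartment
        volumes[name] = float(row.volume_mL)
        if pd.notna(row.flow_mL_per_s):
            flows[name] = float(row.flow_mL_per_s)
        if pd.notna(row.f_lipid) and pd.notna(row.f_water):
            fractions[name] = (float(row.f_lipid), float(row.f_water))
    q_c = scalars.get("Qc_mL_per_s")
    af = scalars.get("assimilation_factor")
    physiology = PhysiologyParameterSet(
        body_mass=float(scalars["body_mass_g"]),
        volumes=volumes,
        flows=flows,
        q_c=float(q_c) if pd.notna(q_c) else None,
        q_w=float(scalars["Qw_mL_per_s"]),
        assimilation_factor=float(af) if pd.notna(af) else None,
    )
    return physiology, TissueComposition(fractions)


def default_physiology(
    model_id: str,
) -> tuple[PhysiologyParameterSet, TissueComposition]:
    """Default fixture for ``model_id`` (variants share the 6C fixture)."""
    base = _VARIANT_BASE.get(model_id, model_id)
    if base not in _FIXTURE_FILES:
        raise ValueError(f"no default physiology for model_id {model_id!r}")
    compartments = _read_fixture(_FIXTURE_FILES[base])
    scalars_table = _read_fixture("physiology_scalars.csv")
    scalars = scalars_table.set_index("model_id").loc[base]
    return physiology_from_frames(compartments, scalars)


def preset_chemical(name: str) -> ChemicalDescriptor:
    """One of the documented preset chemicals (see ``PRESET_CHEMICALS``)."""
    try:
        return PRESET_CHEMICALS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset chemical {name!r}; "
            f"available: {sorted(PRESET_CHEMICALS)}"
        ) from None


@dataclass(frozen=True)
class SyntheticTableSpec:
    """Recipe for a synthetic chemical assay table.

    AC10s are drawn log-uniformly (they span orders of magnitude in
    real screens), log Kow uniformly, clearance rates log-uniformly,
    and each LOEC is tied to its AC10 through a log-normal offset:
    ``loec = ac10 * 10**eta`` with ``eta ~ N(mu_offset, sigma_offset)``.
    """

    n_chemicals: int = 36
    ac10_range: tuple[float, float] = (1e-3, 10.0)  # uM
    log_kow_range: tuple[float, float] = (0.5, 6.5)
    k_met_range: tuple[float, float] = (1e-6, 1e-3)  # 1/s
    mu_offset: float = 1.0
    sigma_offset: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chemicals < 1:
            raise ValueError("n_chemicals must be >= 1")
        for attr in ("ac10_range", "k_met_range"):
            lo, hi = getattr(self, attr)
            if not (0 < lo < hi):
                raise ValueError(f"{attr} must be positive and ordered")
        lo, hi = self.log_kow_range
        if not lo < hi:
            raise ValueError("log_kow_range must be ordered")
        if self.sigma_offset < 0:
            raise ValueError("sigma_offset must be >= 0")


def generate_chemical_table(
    spec: Optional[SyntheticTableSpec] = None,
) -> list[ChemicalAssayRecord]:
    """Draw a reproducible synthetic assay table from ``spec``."""
    spec = spec or SyntheticTableSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_chemicals
    ac10 = 10.0 ** rng.uniform(*np.log10(spec.ac10_range), size=n)
    log_kow = rng.uniform(*spec.log_kow_range, size=n)
    k_met = 10.0 ** rng.uniform(*np.log10(spec.k_met_range), size=n)
    eta = rng.normal(spec.mu_offset, spec.sigma_offset, size=n)
    loec = ac10 * 10.0 ** eta
    return [
        ChemicalAssayRecord(
            name=f"chem_{i:03d}",
            ac10=float(ac10[i]),
            log_kow=float(log_kow[i]),
            loec=float(loec[i]),
            k_met=float(k_met[i]),
        )
        for i in range(n)
    ]
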