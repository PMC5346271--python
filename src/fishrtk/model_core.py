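"""Compartment-graph definitions of the three fish PBTK architectures.

Three physiologically based toxicokinetic (PBTK) model structures of a
teleost fish are supported, in decreasing order of physiological fidelity:

``7C``
    Arterial and venous blood, brain, gonads, liver, poorly perfused
    tissue (``ppt``) and richly perfused tissue (``rpt``).  Gonad and
    richly-perfused effluent drains into the liver before reaching the
    venous blood; the liver is the sole metabolising organ.  Gill
    exchange carries an assimilation factor.
``6C``
    Arterial and venous blood, brain, gonads, liver and a lumped
    "other" tissue.  All four tissues drain directly into the venous
    blood; the liver metabolises and the "other" tissue may excrete.
``1C``
    A single well-mixed body compartment exchanging with the water
    across the gills, with whole-body first-order metabolism.

Two structural variants of the 6C model probe the effect of architecture
alone: :func:`collapse_gonads_other` merges the gonads into the "other"
tissue, and :func:`rewire_gonads_to_liver` reroutes the gonad effluent
through the liver as in the 7C model.

All tissues exchange with blood in the flow-limited regime: a tissue
with perfusion ``Q`` and tissue:water partition coefficient ``P``
receives ``Q * C_arterial`` and returns its effluent at the equilibrated
concentration ``C_tissue / P``.  Blood itself is assigned ``P = 1``
(no accumulation of chemical on blood components).

Units are seconds, millilitres and micromolar throughout; flows are
mL/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "ARTERIAL",
    "VENOUS",
    "BLOOD_COMPARTMENTS",
    "MODEL_IDS",
    "ChemicalDescriptor",
    "TissueComposition",
    "PhysiologyParameterSet",
    "FlowEdge",
    "GillExchange",
    "ModelStructure",
    "build_model",
    "partition_coefficient",
    "collapse_gonads_other",
    "rewire_gonads_to_liver",
]

ARTERIAL = "arterial"
VENOUS = "venous"
BRAIN = "brain"
GONADS = "gonads"
LIVER = "liver"
PPT = "ppt"
RPT = "rpt"
OTHER = "other"
BODY = "body"

BLOOD_COMPARTMENTS = frozenset({ARTERIAL, VENOUS})

#: Recognised model identifiers.
MODEL_IDS = ("7C", "6C", "1C", "6C_collapsed", "6C_rewired")

_REL_TOL_FLOW = 1e-9


@dataclass(frozen=True)
class ChemicalDescriptor:
    """Chemical-dependent inputs to the PBTK/rTK models.

    Parameters
    ----------
    name : str
        Chemical label.
    log_kow : float
        log10 octanol-water partition ratio, used as the lipid:water
        partitioning surrogate.
    k_met : float
        First-order hepatic metabolism rate, 1/s.
    k_exc : float
        First-order excretion rate acting in the 6C "other" tissue, 1/s.
    vmax, km : float, optional
        Michaelis-Menten maximal rate (uM/s) and half-saturation
        constant (uM) for saturable metabolism; both or neither.
    kd_plasma : float, optional
        Dissociation constant for plasma-protein binding (uM).  Carried
        for completeness but inert under the default assumption that
        blood does not accumulate chemical.
    ac10 : float, optional
        In vitro activity concentration at 10% of maximal response, uM.
    loec : float, optional
        Whole-organism lowest observed effect concentration, uM.
    """

    name: str
    log_kow: float
    k_met: float = 0.0
    k_exc: float = 0.0
    vmax: Optional[float] = None
    km: Optional[float] = None
    kd_plasma: Optional[float] = None
    ac10: Optional[float] = None
    loec: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_kow):
            raise ValueError(f"log_kow must be finite, got {self.log_kow}")
        if self.k_met < 0:
            raise ValueError(f"k_met must be >= 0, got {self.k_met}")
        if self.k_exc < 0:
            raise ValueError(f"k_exc must be >= 0, got {self.k_exc}")
        if (self.vmax is None) != (self.km is None):
            raise ValueError("vmax and km must be given together")
        if self.km is not None and self.km <= 0:
            raise ValueError(f"km must be > 0, got {self.km}")
        if self.vmax is not None and self.vmax < 0:
            raise ValueError(f"vmax must be >= 0, got {self.vmax}")
        for attr in ("kd_plasma", "ac10", "loec"):
            value = getattr(self, attr)
            if value is not None and value <= 0:
                raise ValueError(f"{attr} must be > 0 when set, got {value}")

    @property
    def kow(self) -> float:
        """Octanol-water partition ratio on the linear scale."""
        return 10.0 ** self.log_kow


@dataclass(frozen=True)
class TissueComposition:
    """Lipid and water volume fractions per compartment.

    ``fractions`` maps a compartment name to ``(f_lipid, f_water)``.
    Blood compartments need no entry; they are pinned to ``P = 1``.
    """

    fractions: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (f_lipid, f_water) in self.fractions.items():
            if f_lipid < 0 or f_water < 0:
                raise ValueError(
                    f"negative volume fraction for {name!r}: "
                    f"f_lipid={f_lipid}, f_water={f_water}"
                )
            if f_lipid > 1 or f_water > 1 or f_lipid + f_water > 1 + 1e-12:
                raise ValueError(
                    f"volume fractions for {name!r} exceed unity: "
                    f"f_lipid={f_lipid}, f_water={f_water}"
                )

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.fractions[name]

    def __contains__(self, name: str) -> bool:
        return name in self.fractions


@dataclass(frozen=True)
class PhysiologyParameterSet:
    """Body-dependent flows, volumes and scalars for one model family.

    Parameters
    ----------
    body_mass : float
        Wet mass of the fish, g.
    volumes : mapping
        Compartment volumes, mL (all compartments, blood included).
    flows : mapping
        Tissue blood flows, mL/s (perfused tissues only; empty for 1C).
    q_c : float, optional
        Cardiac output, mL/s; must equal the sum of tissue flows.
    q_w : float
        Respiratory (gill ventilation) water flow, mL/s.
    assimilation_factor : float, optional
        Gill chemical transfer efficiency in (0, 1]; 7C only.
    """

    body_mass: float
    volumes: Mapping[str, float]
    q_w: float
    flows: Mapping[str, float] = field(default_factory=dict)
    q_c: Optional[float] = None
    assimilation_factor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be > 0")
        if self.q_w <= 0:
            raise ValueError("q_w must be > 0")
        for name, v in self.volumes.items():
            if v <= 0:
                raise ValueError(f"volume of {name!r} must be > 0, got {v}")
        for name, q in self.flows.items():
            if q <= 0:
                raise ValueError(f"flow of {name!r} must be > 0, got {q}")
        if self.flows:
            if self.q_c is None or self.q_c <= 0:
                raise ValueError("q_c must be > 0 when tissue flows are given")
            total = sum(self.flows.values())
            if abs(total - self.q_c) > _REL_TOL_FLOW * self.q_c:
                raise ValueError(
                    f"tissue flows sum to {total} but cardiac output is {self.q_c}"
                )
        if self.assimilation_factor is not None and not (
            0 < self.assimilation_factor <= 1
        ):
            raise ValueError(
                f"assimilation_factor must lie in (0, 1], "
                f"got {self.assimilation_factor}"
            )

    @property
    def total_volume(self) -> float:
        return float(sum(self.volumes.values()))


@dataclass(frozen=True)
class FlowEdge:
    """Directed bulk-flow edge carrying effluent from ``source`` to ``sink``."""

    source: str
    sink: str
    flow: float


@dataclass(frozen=True)
class GillExchange:
    """Gill interface specification.

    The gills are treated as an instantaneous-equilibrium interface, not
    a state variable.  The net chemical flux into ``uptake_to`` is

        conductance * (C_env - C_reference / P_reference)

    i.e. uptake from the inspired water minus elimination of chemical
    carried by the blood (or body) passing the gills.  Exchange is
    limited by both carriers: the water can deliver at most ``q_w`` and
    the blood can carry away at most ``blood_flow``, so the conductance
    is the series (harmonic) combination of the two, scaled by the
    assimilation factor,

        conductance = factor / (1/q_w + 1/blood_flow),

    which is bounded by ``factor * q_w`` (cannot extract more chemical
    than the water delivers) and stays strictly below the blood flow
    (the post-gill blood can never overshoot equilibrium with the
    water).  The single-compartment fish has no explicit blood, so its
    conductance is ``factor * q_w`` alone.
    """

    uptake_to: str
    reference: str
    q_w: float
    factor: float = 1.0
    blood_flow: Optional[float] = None

    @property
    def conductance(self) -> float:
        """Effective gill exchange conductance, mL/s."""
        if self.blood_flow is None:
            return self.factor * self.q_w
        return self.factor / (1.0 / self.q_w + 1.0 / self.blood_flow)


@dataclass(frozen=True)
class ModelStructure:
    """A fully specified compartment graph plus its physiology."""

    model_id: str
    compartments: tuple[str, ...]
    volumes: Mapping[str, float]
    edges: tuple[FlowEdge, ...]
    gill: GillExchange
    metabolizing: frozenset[str]
    excreting: frozenset[str]
    composition: TissueComposition
    body_mass: float
    q_c: Optional[float] = None
    assimilation_factor: Optional[float] = None

    def __post_init__(self) -> None:
        self._check_flow_balance()

    # -- structural queries -------------------------------------------------
    def index(self, compartment: str) -> int:
        return self.compartments.index(compartment)

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def volume_vector(self) -> np.ndarray:
        return np.array([self.volumes[c] for c in self.compartments], dtype=float)

    @property
    def total_volume(self) -> float:
        return float(sum(self.volumes[c] for c in self.compartments))

    def partitions(self, chem: ChemicalDescriptor) -> np.ndarray:
        """Tissue:water partition coefficient per compartment (blood = 1)."""
        out = np.empty(self.n_compartments)
        for i, name in enumerate(self.compartments):
            if name in BLOOD_COMPARTMENTS:
                out[i] = 1.0
            else:
                out[i] = partition_coefficient(chem, self.composition[name])
        return out

    def inflows(self, compartment: str) -> list[FlowEdge]:
        return [e for e in self.edges if e.sink == compartment]

    def outflows(self, compartment: str) -> list[FlowEdge]:
        return [e for e in self.edges if e.source == compartment]

    # -- validation ---------------------------------------------------------
    def _check_flow_balance(self) -> None:
        if len(self.compartments) == 1:
            return
        for name in self.compartments:
            fin = sum(e.flow for e in self.inflows(name))
            fout = sum(e.flow for e in self.outflows(name))
            scale = max(fin, fout, 1e-300)
            if abs(fin - fout) > 1e-9 * scale:
                raise ValueError(
                    f"flow imbalance at {name!r} in model {self.model_id}: "
                    f"in={fin}, out={fout}"
                )


def partition_coefficient(
    chem: ChemicalDescriptor, comp: tuple[float, float]
) -> float:
    """Tissue:water partition coefficient from a lipid/water mixing rule.

    ``P = f_lipid * Kow + f_water``, with the octanol-water ratio as the
    lipid:water partitioning surrogate.  ``comp`` is a
    ``(f_lipid, f_water)`` pair.
    """
    f_lipid, f_water = comp
    if f_lipid < 0 or f_water < 0:
        raise ValueError(
            f"negative volume fraction: f_lipid={f_lipid}, f_water={f_water}"
        )
    return f_lipid * chem.kow + f_water


def _require(physiology: PhysiologyParameterSet, names: tuple[str, ...]) -> None:
    missing = [n for n in names if n not in physiology.volumes]
    if missing:
        raise ValueError(f"physiology is missing volumes for {missing}")
    missing_q = [
        n
        for n in names
        if n not in BLOOD_COMPARTMENTS and n not in physiology.flows
    ]
    if missing_q:
        raise ValueError(f"physiology is missing flows for {missing_q}")


def build_model(
    model_id: str,
    physiology: PhysiologyParameterSet,
    composition: TissueComposition,
) -> ModelStructure:
    """Assemble the compartment graph for ``model_id``.

    Raises
    ------
    ValueError
        For an unknown ``model_id``, a 7C physiology without an
        assimilation factor, or a flow-balance violation.
    """
    if model_id == "7C":
        return _build_7c(physiology, composition)
    if model_id == "6C":
        return _build_6c(physiology, composition)
    if model_id == "1C":
        return _build_1c(physiology, composition)
    if model_id == "6C_collapsed":
        return collapse_gonads_other(_build_6c(physiology, composition))
    if model_id == "6C_rewired":
        return rewire_gonads_to_liver(_build_6c(physiology, composition))
    raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")


def _build_7c(
    physiology: PhysiologyParameterSet, composition: TissueComposition
) -> ModelStructure:
    if physiology.assimilation_factor is None:
        raise ValueError("the 7C model requires an assimilation factor")
    tissues = (BRAIN, GONADS, LIVER, PPT, RPT)
    _require(physiology, (ARTERIAL, VENOUS) + tissues)
    q = physiology.flows
    edges = [FlowEdge(VENOUS, ARTERIAL, physiology.q_c)]
    edges += [FlowEdge(ARTERIAL, t, q[t]) for t in tissues]
    # gonad and richly-perfused effluent passes through the liver
    edges += [
        FlowEdge(GONADS, LIVER, q[GONADS]),
        FlowEdge(RPT, LIVER, q[RPT]),
        FlowEdge(BRAIN, VENOUS, q[BRAIN]),
        FlowEdge(LIVER, VENOUS, q[LIVER] + q[GONADS] + q[RPT]),
        FlowEdge(PPT, VENOUS, q[PPT]),
    ]
    return ModelStructure(
        model_id="7C",
        compartments=(ARTERIAL, VENOUS) + tissues,
        volumes=dict(physiology.volumes),
        edges=tuple(edges),
        gill=GillExchange(
            uptake_to=ARTERIAL,
            reference=VENOUS,
            q_w=physiology.q_w,
            factor=physiology.assimilation_factor,
            blood_flow=physiology.q_c,
        ),
        metabolizing=frozenset({LIVER}),
        excreting=frozenset(),
        composition=composition,
        body_mass=physiology.body_mass,
        q_c=physiology.q_c,
        assimilation_factor=physiology.assimilation_factor,
    )


def _build_6c(
    physiology: PhysiologyParameterSet, composition: TissueComposition
) -> ModelStructure:
    tissues = (BRAIN, GONADS, LIVER, OTHER)
    _require(physiology, (ARTERIAL, VENOUS) + tissues)
    q = physiology.flows
    edges = [FlowEdge(VENOUS, ARTERIAL, physiology.q_c)]
    edges += [FlowEdge(ARTERIAL, t, q[t]) for t in tissues]
    edges += [FlowEdge(t, VENOUS, q[t]) for t in tissues]
    return ModelStructure(
        model_id="6C",
        compartments=(ARTERIAL, VENOUS) + tissues,
        volumes=dict(physiology.volumes),
        edges=tuple(edges),
        gill=GillExchange(
            uptake_to=ARTERIAL,
            reference=VENOUS,
            q_w=physiology.q_w,
            blood_flow=physiology.q_c,
        ),
        metabolizing=frozenset({LIVER}),
        excreting=frozenset({OTHER}),
        composition=composition,
        body_mass=physiology.body_mass,
        q_c=physiology.q_c,
    )


def _build_1c(
    physiology: PhysiologyParameterSet, composition: TissueComposition
) -> ModelStructure:
    if BODY not in physiology.volumes:
        raise ValueError("1C physiology must provide a 'body' volume")
    if BODY not in composition:
        raise ValueError("1C composition must provide 'body' fractions")
    return ModelStructure(
        model_id="1C",
        compartments=(BODY,),
        volumes={BODY: physiology.volumes[BODY]},
        edges=(),
        gill=GillExchange(uptake_to=BODY, reference=BODY, q_w=physiology.q_w),
        metabolizing=frozenset({BODY}),
        excreting=frozenset(),
        composition=composition,
        body_mass=physiology.body_mass,
    )


def collapse_gonads_other(model: ModelStructure) -> ModelStructure:
    """Merge the 6C gonads into the "other" tissue (variant ``6C_collapsed``).

    The merged compartment takes the summed volume and inflow and the
    volume-weighted lipid/water composition; everything else is
    untouched.
    """
    if model.model_id != "6C":
        raise ValueError(
            f"collapse_gonads_other expects a 6C model, got {model.model_id!r}"
        )
    v_g = model.volumes[GONADS]
    v_o = model.volumes[OTHER]
    volumes = {
        c: v for c, v in model.volumes.items() if c != GONADS
    }
    volumes[OTHER] = v_g + v_o
    q_g = sum(e.flow for e in model.inflows(GONADS))
    edges = []
    for e in model.edges:
        if e.source == GONADS or e.sink == GONADS:
            continue
        if e.source == ARTERIAL and e.sink == OTHER:
            edges.append(replace(e, flow=e.flow + q_g))
        elif e.source == OTHER and e.sink == VENOUS:
            edges.append(replace(e, flow=e.flow + q_g))
        else:
            edges.append(e)
    fl_g, fw_g = model.composition[GONADS]
    fl_o, fw_o = model.composition[OTHER]
    merged = (
        (v_g * fl_g + v_o * fl_o) / (v_g + v_o),
        (v_g * fw_g + v_o * fw_o) / (v_g + v_o),
    )
    fractions = {
        name: fr
        for name, fr in model.composition.fractions.items()
        if name != GONADS
    }
    fractions[OTHER] = merged
    return replace(
        model,
        model_id="6C_collapsed",
        compartments=tuple(c for c in model.compartments if c != GONADS),
        volumes=volumes,
        edges=tuple(edges),
        composition=TissueComposition(fractions),
    )


def rewire_gonads_to_liver(model: ModelStructure) -> ModelStructure:
    """Route the 6C gonad effluent into the liver (variant ``6C_rewired``).

    Flow magnitudes are preserved; the liver outflow grows by the gonad
    flow so that flow balance at the liver node still holds.
    """
    if model.model_id != "6C":
        raise ValueError(
            f"rewire_gonads_to_liver expects a 6C model, got {model.model_id!r}"
        )
    q_g = sum(e.flow for e in model.inflows(GONADS))
    edges = []
    for e in model.edges:
        if e.source == GONADS and e.sink == VENOUS:
            edges.append(FlowEdge(GONADS, LIVER, e.flow))
        elif e.source == LIVER and e.sink == VENOUS:
            edges.append(replace(e, flow=e.flow + q_g))
        else:
            edges.append(e)
    return replace(model, model_id="6C_rewired", edges=tuple(edges))
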