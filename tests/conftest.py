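import numpy as np
import pytest

from fishrtk import build_model, default_physiology, preset_chemical
from fishrtk.model_core import ChemicalDescriptor

ALL_MODEL_IDS = ("7C", "6C", "1C", "6C_collapsed", "6C_rewired")


@pytest.fixture(scope="session")
def diazinon():
    return preset_chemical("diazinon")


@pytest.fixture(scope="session")
def dichloroethane():
    return preset_chemical("dichloroethane_12")


@pytest.fixture(scope="session")
def models():
    """Default-fixture model structures, one per supported architecture."""
    out = {}
    for model_id in ALL_MODEL_IDS:
        physiology, composition = default_physiology(model_id)
        out[model_id] = build_model(model_id, physiology, composition)
    return out


def random_chemical(rng: np.random.Generator, with_k_exc: bool = False):
    """A random but physically plausible chemical descriptor."""
    return ChemicalDescriptor(
        name="random",
        log_kow=float(rng.uniform(-1.0, 7.0)),
        k_met=float(10.0 ** rng.uniform(-7.0, -2.0)),
        k_exc=float(10.0 ** rng.uniform(-7.0, -2.0)) if with_k_exc else 0.0,
    )
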