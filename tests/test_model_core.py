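import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fishrtk import (
    build_model,
    collapse_gonads_other,
    default_physiology,
    partition_coefficient,
    rewire_gonads_to_liver,
)
from fishrtk.model_core import (
    ChemicalDescriptor,
    PhysiologyParameterSet,
    TissueComposition,
)


class TestChemicalDescriptor:
    def test_rejects_invalid_rates_and_concentrations(self):
        with pytest.raises(ValueError):
            ChemicalDescriptor(name="x", log_kow=2.0, k_met=-1e-4)
        with pytest.raises(ValueError):
            ChemicalDescriptor(name="x", log_kow=2.0, vmax=1.0)  # km missing
        with pytest.raises(ValueError):
            ChemicalDescriptor(name="x", log_kow=2.0, vmax=1.0, km=0.0)
        with pytest.raises(ValueError):
            ChemicalDescriptor(name="x", log_kow=2.0, ac10=-5.0)

    def test_kow_scale(self):
        assert ChemicalDescriptor(name="x", log_kow=2.0).kow == pytest.approx(100.0)


class TestPartitionCoefficient:
    def test_pure_water_phase_is_unity(self):
        chem = ChemicalDescriptor(name="x", log_kow=5.0)
        assert partition_coefficient(chem, (0.0, 1.0)) == pytest.approx(1.0)

    def test_lipid_water_mixing_value(self):
        # 0.05 * 10**3.81 + 0.8, checked against direct arithmetic
        chem = ChemicalDescriptor(name="diazinon-like", log_kow=3.81)
        assert partition_coefficient(chem, (0.05, 0.8)) == pytest.approx(
            323.63, abs=0.005
        )

    def test_negative_fraction_rejected(self):
        chem = ChemicalDescriptor(name="x", log_kow=1.0)
        with pytest.raises(ValueError):
            partition_coefficient(chem, (-0.1, 0.8))

    @settings(max_examples=100, derandomize=True)
    @given(
        lk1=st.floats(-1, 8),
        lk2=st.floats(-1, 8),
        fl=st.floats(0.001, 0.5),
        fw=st.floats(0.1, 0.5),
    )
    def test_monotone_in_log_kow_and_lipid(self, lk1, lk2, fl, fw):
        lo, hi = sorted((lk1, lk2))
        c_lo = ChemicalDescriptor(name="a", log_kow=lo)
        c_hi = ChemicalDescriptor(name="b", log_kow=hi)
        assert partition_coefficient(c_hi, (fl, fw)) >= partition_coefficient(
            c_lo, (fl, fw)
        )
        assert partition_coefficient(c_hi, (fl * 2, fw)) >= partition_coefficient(
            c_hi, (fl, fw)
        )


class TestPhysiologyValidation:
    def test_flow_balance_enforced(self):
        with pytest.raises(ValueError, match="cardiac output"):
            PhysiologyParameterSet(
                body_mass=1.0,
                volumes={"arterial": 0.1, "venous": 0.1, "brain": 0.1},
                flows={"brain": 1.0},
                q_c=2.0,
                q_w=1.0,
            )

    def test_assimilation_factor_bounds(self):
        phys, _ = default_physiology("7C")
        with pytest.raises(ValueError):
            PhysiologyParameterSet(
                body_mass=phys.body_mass,
                volumes=phys.volumes,
                flows=phys.flows,
                q_c=phys.q_c,
                q_w=phys.q_w,
                assimilation_factor=1.5,
            )


class TestBuildModel:
    def test_7c_compartments_and_routing(self, models):
        m = models["7C"]
        assert set(m.compartments) == {
            "arterial", "venous", "brain", "gonads", "liver", "ppt", "rpt",
        }
        sinks = {e.sink for e in m.outflows("gonads")}
        assert sinks == {"liver"}
        assert {e.sink for e in m.outflows("rpt")} == {"liver"}
        assert {e.sink for e in m.outflows("brain")} == {"venous"}
        assert m.metabolizing == {"liver"}
        assert m.assimilation_factor is not None

    def test_6c_tissues_drain_to_venous(self, models):
        m = models["6C"]
        for tissue in ("brain", "gonads", "liver", "other"):
            assert {e.sink for e in m.outflows(tissue)} == {"venous"}
        assert m.metabolizing == {"liver"}
        assert m.excreting == {"other"}

    def test_1c_single_compartment(self, models):
        m = models["1C"]
        assert m.compartments == ("body",)
        assert m.gill.reference == "body"

    def test_unknown_model_id_rejected(self):
        physiology, composition = default_physiology("7C")
        with pytest.raises(ValueError, match="unknown model_id"):
            build_model("9C", physiology, composition)

    def test_7c_requires_assimilation_factor(self):
        physiology, composition = default_physiology("6C")
        with pytest.raises(ValueError, match="assimilation"):
            build_model("7C", physiology, composition)

    @pytest.mark.parametrize(
        "model_id", ["7C", "6C", "1C", "6C_collapsed", "6C_rewired"]
    )
    def test_flow_conservation_at_every_node(self, models, model_id):
        m = models[model_id]
        for name in m.compartments:
            fin = sum(e.flow for e in m.inflows(name))
            fout = sum(e.flow for e in m.outflows(name))
            assert fin == pytest.approx(fout, rel=1e-12)


class TestStructuralVariants:
    def test_collapse_merges_volume_and_flow(self, models):
        m6, mc = models["6C"], models["6C_collapsed"]
        assert "gonads" not in mc.compartments
        assert mc.volumes["other"] == pytest.approx(
            m6.volumes["gonads"] + m6.volumes["other"]
        )
        q_in = sum(e.flow for e in mc.inflows("other"))
        q_in_6 = sum(
            e.flow for e in m6.inflows("gonads")
        ) + sum(e.flow for e in m6.inflows("other"))
        assert q_in == pytest.approx(q_in_6)

    def test_variants_preserve_totals(self, models):
        m6 = models["6C"]
        for variant in ("6C_collapsed", "6C_rewired"):
            mv = models[variant]
            assert mv.total_volume == pytest.approx(m6.total_volume)
            q_art = sum(e.flow for e in mv.outflows("arterial"))
            assert q_art == pytest.approx(m6.q_c)

    def test_rewire_moves_gonad_effluent_to_liver(self, models):
        mr = models["6C_rewired"]
        assert {e.sink for e in mr.outflows("gonads")} == {"liver"}
        assert not any(
            e.source == "gonads" and e.sink == "venous" for e in mr.edges
        )

    def test_variant_ops_reject_wrong_input(self, models):
        with pytest.raises(ValueError):
            collapse_gonads_other(models["7C"])
        with pytest.raises(ValueError):
            rewire_gonads_to_liver(models["1C"])
        with pytest.raises(ValueError):
            rewire_gonads_to_liver(models["6C_rewired"])


class TestComposition:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            TissueComposition({"brain": (0.7, 0.5)})
        with pytest.raises(ValueError):
            TissueComposition({"brain": (-0.1, 0.5)})
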