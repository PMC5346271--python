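import numpy as np
import pytest

from fishrtk import (
    derivatives,
    integrate,
    steady_state,
    system_matrices,
    whole_body,
)
from fishrtk.model_core import ChemicalDescriptor

from conftest import ALL_MODEL_IDS, random_chemical


class TestSystemMatrices:
    def test_1c_is_the_hand_derived_balance(self, models, diazinon):
        """dC/dt = Qw/V (Cenv - C/P) - k_met C for the one-compartment fish."""
        m = models["1C"]
        A, b = system_matrices(m, diazinon)
        V = m.volumes["body"]
        P = m.partitions(diazinon)[0]
        q_w = m.gill.q_w
        assert A.shape == (1, 1)
        assert A[0, 0] == pytest.approx(-(q_w / (V * P) + diazinon.k_met))
        assert b[0] == pytest.approx(q_w / V)

    @pytest.mark.parametrize("model_id", ALL_MODEL_IDS)
    def test_matches_derivatives_and_is_stable(self, models, model_id, diazinon):
        m = models[model_id]
        A, b = system_matrices(m, diazinon)
        rng = np.random.default_rng(7)
        for _ in range(5):
            state = rng.uniform(0, 50, m.n_compartments)
            c_env = rng.uniform(0, 20)
            expected = A @ state + b * c_env
            got = derivatives(m, diazinon, state, c_env)
            np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-15)
        assert np.linalg.eigvals(A).real.max() < 0
        assert np.all(b >= 0)
        # uptake feeds only the gill-facing compartment
        assert np.count_nonzero(b) == 1

    def test_no_sinks_conserves_internal_mass(self, models):
        """Without metabolism the only volume-weighted loss is at the gills."""
        m = models["6C"]
        inert = ChemicalDescriptor(name="inert", log_kow=3.0)
        A, b = system_matrices(m, inert)
        V = m.volume_vector()
        col_loss = V @ A  # volume-weighted column sums
        P = m.partitions(inert)
        iv = m.index("venous")
        expected = np.zeros(m.n_compartments)
        expected[iv] = -m.gill.conductance / P[iv]
        np.testing.assert_allclose(col_loss, expected, rtol=1e-12, atol=1e-16)

    def test_michaelis_not_expressible(self, models):
        chem = ChemicalDescriptor(name="m", log_kow=3.0, vmax=1.0, km=10.0)
        with pytest.raises(ValueError, match="first-order"):
            system_matrices(models["7C"], chem, kinetics="michaelis")


class TestDerivatives:
    def test_zero_state_zero_exposure_is_quiescent(self, models, diazinon):
        for m in models.values():
            rates = derivatives(m, diazinon, np.zeros(m.n_compartments), 0.0)
            np.testing.assert_array_equal(rates, 0.0)

    @pytest.mark.parametrize("model_id", ALL_MODEL_IDS)
    def test_steady_state_is_a_fixed_point(self, models, model_id, diazinon):
        m = models[model_id]
        ss = steady_state(m, diazinon, 10.0)
        rates = derivatives(m, diazinon, ss.c_ss, 10.0)
        scale = np.abs(ss.c_ss).max()
        assert np.abs(rates).max() * 1e9 < scale  # 1e-9 relative

    def test_negative_state_rejected(self, models, diazinon):
        m = models["6C"]
        state = np.zeros(m.n_compartments)
        state[0] = -1.0
        with pytest.raises(ValueError, match="negative state"):
            derivatives(m, diazinon, state, 1.0)

    def test_michaelis_requires_parameters(self, models, diazinon):
        m = models["7C"]
        with pytest.raises(ValueError, match="vmax/km"):
            derivatives(
                m, diazinon, np.ones(m.n_compartments), 1.0, kinetics="michaelis"
            )

    def test_mass_balance_over_random_states(self, models):
        """Volume-weighted rate sum equals gill net flux minus sink losses.

        Checked to 1e-12 relative over 500 random state/parameter draws
        spread across every architecture.
        """
        rng = np.random.default_rng(11)
        mids = list(models)
        for trial in range(500):
            m = models[mids[trial % len(mids)]]
            chem = random_chemical(rng, with_k_exc=True)
            state = rng.uniform(0, 100, m.n_compartments)
            c_env = rng.uniform(0, 50)
            V = m.volume_vector()
            P = m.partitions(chem)
            rates = derivatives(m, chem, state, c_env, kinetics="first_order")
            idx = {n: i for i, n in enumerate(m.compartments)}
            g = m.gill
            gill_net = g.conductance * (
                c_env - state[idx[g.reference]] / P[idx[g.reference]]
            )
            losses = sum(
                chem.k_met * state[idx[n]] * V[idx[n]] for n in m.metabolizing
            ) + sum(
                chem.k_exc * state[idx[n]] * V[idx[n]] for n in m.excreting
            )
            total = V @ rates
            expected = gill_net - losses
            scale = max(abs(gill_net), abs(losses), 1e-30)
            assert abs(total - expected) <= 1e-12 * scale

    def test_michaelis_limit_recovers_first_order(self, models, diazinon):
        """vmax/km = k_met with km >> C reproduces the linear rates."""
        m = models["7C"]
        km = 1e9
        chem = ChemicalDescriptor(
            name="mm",
            log_kow=diazinon.log_kow,
            k_met=diazinon.k_met,
            vmax=diazinon.k_met * km,
            km=km,
        )
        state = np.linspace(1.0, 50.0, m.n_compartments)
        first = derivatives(m, chem, state, 10.0, kinetics="first_order")
        mm = derivatives(m, chem, state, 10.0, kinetics="michaelis")
        np.testing.assert_allclose(mm, first, rtol=1e-6)


class TestIntegrate:
    def test_zero_exposure_zero_state_stays_zero(self, models, diazinon):
        profile = integrate(models["6C"], diazinon, 0.0, 1e4)
        assert profile.concentrations.max() == 0.0

    def test_long_horizon_reaches_linear_steady_state(self, models, diazinon):
        m = models["7C"]
        ss = steady_state(m, diazinon, 10.0)
        # horizon: many multiples of the slowest relaxation time
        A, _ = system_matrices(m, diazinon)
        t_end = 20 * 1.0 / np.abs(np.linalg.eigvals(A).real).min()
        profile = integrate(m, diazinon, 10.0, t_end)
        np.testing.assert_allclose(
            profile.concentrations[-1], ss.c_ss, rtol=1e-3 * 1e-3
        )  # 0.1 % criterion, met with margin

    def test_uptake_whole_body_monotone(self, models, diazinon):
        m = models["6C"]
        profile = integrate(m, diazinon, 10.0, 1e6)
        wb = whole_body(profile, m)
        assert np.all(np.diff(wb) >= -1e-9 * wb.max())

    def test_negative_exposure_rejected(self, models, diazinon):
        with pytest.raises(ValueError):
            integrate(models["1C"], diazinon, -1.0, 1e3)


class TestSteadyState:
    def test_zero_exposure_gives_zero(self, models, diazinon):
        ss = steady_state(models["7C"], diazinon, 0.0)
        np.testing.assert_array_equal(ss.c_ss, 0.0)

    @pytest.mark.parametrize("model_id", ALL_MODEL_IDS)
    def test_linear_in_exposure(self, models, model_id, diazinon):
        m = models[model_id]
        one = steady_state(m, diazinon, 3.0).c_ss
        two = steady_state(m, diazinon, 6.0).c_ss
        np.testing.assert_allclose(two, 2 * one, rtol=1e-12)

    @pytest.mark.parametrize("model_id", ALL_MODEL_IDS)
    def test_integration_agrees_with_linear_solve(self, models, model_id, diazinon):
        m = models[model_id]
        exact = steady_state(m, diazinon, 10.0)
        integ = steady_state(m, diazinon, 10.0, method="integration")
        assert integ.converged
        assert integ.time_to_ss is not None and integ.time_to_ss > 0
        np.testing.assert_allclose(integ.c_ss, exact.c_ss, rtol=1e-6)


class TestWholeBody:
    def test_single_compartment_identity(self, models, diazinon):
        m = models["1C"]
        ss = steady_state(m, diazinon, 5.0)
        assert ss.whole_body == pytest.approx(ss.c_ss[0])

    def test_volume_weighting(self, models):
        m = models["6C"]
        V = m.volume_vector()
        state = np.arange(1.0, m.n_compartments + 1)
        assert whole_body(state, m) == pytest.approx(state @ V / V.sum())

    def test_dimension_mismatch_rejected(self, models):
        with pytest.raises(ValueError):
            whole_body(np.ones(3), models["7C"])
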