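"""Right-hand-side flux terms and whole-model conservation properties."""

import numpy as np
import pytest

from vinpbpk import (
    DoseEvent,
    PBPKModel,
    simulate_iv_bolus,
    studies,
    tissue_free_concentration,
)
from vinpbpk.pbpk_core import (
    rhs_abcb1_tissue,
    rhs_brain,
    rhs_elimination,
    rhs_flow_limited,
    vinblastine_mouse,
)
from vinpbpk.physiology import ConfigurationError, ResolvedCompartment, mouse


@pytest.fixture()
def drug():
    return vinblastine_mouse()


@pytest.fixture()
def kidney():
    return ResolvedCompartment("kidney", volume=4.175e-4, flow=0.08)


class TestFlowLimited:
    def test_equilibrium_gives_zero_flux(self, drug, kidney):
        # pick CT such that the free concentration equals the arterial one
        ca = 50.0
        ct = ca * (drug.PC["kidney"] + drug.BC["kidney"] / (drug.KD_tubulin + ca))
        assert rhs_flow_limited(ct, kidney, ca, drug) == pytest.approx(0.0, abs=1e-9)

    def test_pure_uptake_from_empty_tissue(self, drug, kidney):
        assert rhs_flow_limited(0.0, kidney, 10.0, drug) == pytest.approx(
            kidney.flow * 10.0
        )

    def test_steady_state_matches_analytic_fixed_point(self, drug, kidney):
        # integrate dA/dt = Q (CA - CVT(A/V)) at constant CA; the steady
        # state must satisfy CVT = CA
        from scipy.integrate import solve_ivp

        ca = 25.0
        sol = solve_ivp(
            lambda t, y: [rhs_flow_limited(y[0] / kidney.volume, kidney, ca, drug)],
            (0, 50.0),
            [0.0],
            rtol=1e-10,
            atol=1e-14,
        )
        ct_ss = sol.y[0, -1] / kidney.volume
        cvt = tissue_free_concentration(
            ct_ss, drug.PC["kidney"], drug.BC["kidney"], drug.KD_tubulin
        )
        assert cvt == pytest.approx(ca, rel=1e-6)


class TestAbcb1Tissue:
    def test_zero_vmax_reduces_to_flow_limited(self, drug, kidney):
        off = drug.with_(Vmax_ABCB1=0.0)
        rate, efflux = rhs_abcb1_tissue(100.0, kidney, 5.0, off)
        assert efflux == 0.0
        assert rate == rhs_flow_limited(100.0, kidney, 5.0, off)

    def test_efflux_saturates(self, drug, kidney):
        ct = 1e7  # free concentration far above Km
        _, efflux = rhs_abcb1_tissue(ct, kidney, 0.0, drug)
        cap = drug.SF_ABCB1["kidney"] * kidney.volume * drug.Vmax_ABCB1
        assert efflux == pytest.approx(cap, rel=1e-2)

    def test_efflux_linear_in_scaling_factor(self, drug):
        gut = ResolvedCompartment("gut", volume=1.055e-3, flow=0.115)
        half = drug.with_(SF_ABCB1=dict(drug.SF_ABCB1, gut=0.07))
        _, e_full = rhs_abcb1_tissue(500.0, gut, 0.0, drug)
        _, e_half = rhs_abcb1_tissue(500.0, gut, 0.0, half)
        assert e_half == pytest.approx(0.5 * e_full, rel=1e-12)

    def test_missing_scaling_factor_is_config_error(self, drug):
        bm = ResolvedCompartment("bone_marrow", volume=1e-3, flow=0.01)
        with pytest.raises(ConfigurationError, match="bone_marrow"):
            rhs_abcb1_tissue(1.0, bm, 1.0, drug)


class TestBrain:
    def test_impermeable_barrier_keeps_brain_empty(self):
        st = studies.mouse_wild_type()
        drug = st.drug.with_(PSA_ml_per_h=0.0, Vmax_ABCB1=0.0)
        sim = simulate_iv_bolus(st.physiology, drug, st.dose, t_end=6.0)
        assert np.all(sim.concentrations["brain_tissue"] == 0.0)

    def test_knockout_brain_accumulates(self, mouse_ko_sim):
        c = mouse_ko_sim.concentrations["brain_tissue"]
        s = mouse_ko_sim.concentrations["blood"]
        t = mouse_ko_sim.times
        # brain keeps accumulating while serum collapses by orders of magnitude
        assert np.interp(2.0, t, c) > np.interp(0.25, t, c)
        assert c[-1] > 0.9 * c.max()  # no meaningful terminal decline by 6 h
        assert s[-1] < 0.05 * np.interp(0.25, t, s)

    def test_efflux_returns_drug_to_vascular_space(self, drug):
        bt = ResolvedCompartment("brain_tissue", volume=4.0e-4, flow=0.0)
        bv = ResolvedCompartment("brain_vascular", volume=1.24e-5, flow=0.029)
        d_t, d_v = rhs_brain(500.0, 0.0, bt, bv, 0.0, drug)
        # tissue loses what the vascular space gains (flow term is zero here)
        assert d_t == pytest.approx(-d_v, rel=1e-12)
        assert d_t < 0.0


class TestElimination:
    def test_all_zero_when_empty(self, drug):
        liver = ResolvedCompartment("liver", 1.37e-3, 0.018)
        kidney = ResolvedCompartment("kidney", 4.2e-4, 0.081)
        assert rhs_elimination(0.0, 0.0, liver, kidney, drug) == (0.0, 0.0, 0.0)

    def test_first_order_limit_below_km(self, drug):
        liver = ResolvedCompartment("liver", 1.37e-3, 0.018)
        kidney = ResolvedCompartment("kidney", 4.2e-4, 0.081)
        cv = 1.0  # nM, far below Km_met = 11.6 uM
        met, _, _ = rhs_elimination(cv, cv, liver, kidney, drug)
        expected = liver.volume * (drug.Vmax_met / drug.Km_met) * cv
        assert met == pytest.approx(expected, rel=1e-3)

    def test_filtration_is_gfr_fraction_of_renal_flow(self, drug):
        liver = ResolvedCompartment("liver", 1.37e-3, 0.018)
        kidney = ResolvedCompartment("kidney", 4.2e-4, 0.081)
        ca = 37.0
        _, _, filt = rhs_elimination(ca, 0.0, liver, kidney, drug)
        assert filt == pytest.approx(0.11 * kidney.flow * ca, rel=1e-12)


class TestWholeModelInvariants:
    def test_mass_conservation(self, mouse_wt_sim, mouse_ko_sim, dog_sim):
        for sim in (mouse_wt_sim, mouse_ko_sim, dog_sim):
            assert sim.mass_balance_error() < 1e-3

    def test_non_negative_states(self, mouse_wt_sim):
        for series in mouse_wt_sim.concentrations.values():
            assert np.all(series >= 0.0)

    def test_knockout_equivalence_bit_identical(self):
        phys = mouse()
        base = vinblastine_mouse()
        sf_zero = base.with_(SF_ABCB1={k: 0.0 for k in base.SF_ABCB1})
        vmax_zero = base.with_(Vmax_ABCB1=0.0)
        m1 = PBPKModel(phys, sf_zero)
        m2 = PBPKModel(phys, vmax_zero)
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = rng.uniform(0.0, 10.0, m1.n_state)
            assert np.array_equal(m1.rhs(0.0, y), m2.rhs(0.0, y))

    def test_brain_auc_monotone_in_efflux_and_psa(self):
        from vinpbpk.nca import ConcentrationSeries, auc_linlog

        st = studies.mouse_wild_type()

        def brain_auc(drug):
            sim = simulate_iv_bolus(st.physiology, drug, st.dose, t_end=6.0,
                                    n_out=200)
            return auc_linlog(
                ConcentrationSeries(sim.times,
                                    sim.concentrations["brain_tissue"]),
                0.0, 6.0,
            )

        base = st.drug
        aucs_vmax = [brain_auc(base.with_(Vmax_ABCB1=v))
                     for v in (0.0, 928.8, 5000.0)]
        assert aucs_vmax[0] > aucs_vmax[1] > aucs_vmax[2]
        aucs_psa = [brain_auc(base.with_(PSA_ml_per_h=p))
                    for p in (0.379, 0.1, 0.0)]
        assert aucs_psa[0] > aucs_psa[1] > aucs_psa[2]
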