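import numpy as np
import pytest

from mlpbpk import (
    DoseEvent,
    build_partition_set,
    build_system,
    clearance_invitro,
    peripheral_profile,
    psa_from_papp,
    simulate,
    simulate_linear,
    venous_profile,
)


class TestPsa:
    def test_unit_conversion(self):
        # 1e-6 cm/s across 1e6 cm2 = 1 cm3/s = 3.6 L/h
        assert psa_from_papp(1.0, 1e6) == pytest.approx(3.6)

    def test_linear_in_surface_area(self):
        assert psa_from_papp(5.0, 2e5) == pytest.approx(2 * psa_from_papp(5.0, 1e5))

    @pytest.mark.parametrize("papp,sa", [(0.0, 1e5), (10.0, 0.0), (-1.0, 1e5)])
    def test_nonpositive_inputs_rejected(self, papp, sa):
        with pytest.raises(ValueError):
            psa_from_papp(papp, sa)


class TestClearanceInvitro:
    def test_zero_clint_leaves_only_renal(self, body, drug_by_name):
        import dataclasses
        drug = dataclasses.replace(drug_by_name["Caffeine"], clint=0.0)
        hepatic, renal = clearance_invitro(drug, body)
        assert hepatic == 0.0
        assert renal == pytest.approx(drug.fup * body.gfr)

    def test_flow_limited_asymptote(self, body, drug_by_name):
        import dataclasses
        drug = dataclasses.replace(drug_by_name["Caffeine"], clint=1e9,
                                   fup=1.0, bp=1.0)
        hepatic, _ = clearance_invitro(drug, body)
        q_h = body.tissues["liver"].blood_flow
        assert hepatic == pytest.approx(q_h, rel=1e-4)

    def test_acetaminophen_well_stirred_value(self, invitro_records, body):
        drug = {r.name: r for r in invitro_records}["Acetaminophen"]
        # hand arithmetic: CLint 12 mL/min/kg * 70 kg * 0.06 = 50.4 L/h;
        # fub = 0.52/1.04 = 0.5; Qh = 99.45 L/h (blood);
        # CLb = 99.45*25.2/124.65 = 20.1054; plasma CL = *1.04 = 20.9096
        hepatic, renal = clearance_invitro(drug, body)
        assert hepatic == pytest.approx(20.9096, rel=1e-4)
        assert renal == pytest.approx(0.52 * 6.7, rel=1e-9)

    def test_missing_clint_is_configuration_error(self, drug_by_name, body):
        with pytest.raises(ValueError, match="clint"):
            clearance_invitro(drug_by_name["Caffeine"], body)


class TestSystemStructure:
    def test_mass_conserved_without_clearance(self, body, drug_by_name):
        system = build_system(drug_by_name["Propranolol"], body, mode="ml",
                              include_clearance=False)
        rng = np.random.default_rng(0)
        for _ in range(5):
            state = rng.uniform(0, 10, system.n_states)
            assert abs(system.rate(0.0, state).sum()) < 1e-9 * state.sum()

    def test_clearance_only_removes_from_venous_plasma_in_ml_mode(
            self, body, drug_by_name):
        drug = drug_by_name["Caffeine"]
        with_cl = build_system(drug, body, mode="ml")
        without = build_system(drug, body, mode="ml", include_clearance=False)
        diff = with_cl.matrix - without.matrix
        i = with_cl.index("venous_pls")
        e = with_cl.index("eliminated")
        expected_cl = drug.clt * body.body_weight
        v = with_cl.volumes[i]
        assert diff[i, i] == pytest.approx(-expected_cl / v)
        assert diff[e, i] == pytest.approx(expected_cl / v)
        diff[i, i] = diff[e, i] = 0.0
        assert np.abs(diff).max() == 0.0

    def test_invitro_mode_clears_at_liver_and_kidney(self, body, invitro_records):
        drug = {r.name: r for r in invitro_records}["Acetaminophen"]
        system = build_system(drug, body, mode="invitro")
        assert set(system.clearances) == {"hepatic_plasma", "renal_plasma"}

    def test_mode_requires_matching_clearance_input(self, body, drug_by_name,
                                                    invitro_records):
        with pytest.raises(ValueError, match="clint"):
            build_system(drug_by_name["Caffeine"], body, mode="invitro")
        iv = {r.name: r for r in invitro_records}["Caffeine"]
        with pytest.raises(ValueError, match="clt"):
            build_system(iv, body, mode="ml")

    def test_zero_psa_confines_drug_to_vasculature(self, body, drug_by_name):
        import dataclasses
        drug = dataclasses.replace(drug_by_name["Caffeine"], papp_caco2=1e-12)
        system = build_system(drug, body, mode="ml", include_clearance=False)
        result = simulate(system, DoseEvent(amount=70.0), t_end=24.0)
        for label in system.labels:
            if label.endswith(("interstitial", "intracellular")):
                assert np.abs(result.amounts[system.index(label)]).max() < 1e-6


class TestSimulate:
    def test_zero_dose_gives_zero_profiles(self, body, drug_by_name):
        system = build_system(drug_by_name["Caffeine"], body, mode="ml")
        result = simulate(system, DoseEvent(amount=0.0), t_end=24.0)
        assert np.all(result.amounts == 0.0)

    def test_mass_conserved_with_no_clearance(self, body, drug_by_name):
        system = build_system(drug_by_name["Morphine"], body, mode="ml",
                              include_clearance=False)
        result = simulate(system, DoseEvent(amount=70.0), t_end=100.0)
        assert np.abs(result.total_in_body() - 70.0).max() < 1e-6 * 70.0

    def test_mass_balance_with_elimination(self, body, drug_by_name):
        system = build_system(drug_by_name["Morphine"], body, mode="ml")
        result = simulate(system, DoseEvent(amount=70.0))
        assert np.abs(result.mass_balance_residual()).max() < 1e-6 * 70.0

    def test_clt_auc_identity(self, body, drug_by_name):
        # total elimination = integral of CLt * C_venous must equal the dose
        drug = drug_by_name["Metoprolol"]
        system = build_system(drug, body, mode="ml")
        result = simulate(system, DoseEvent(amount=70.0))
        venous = venous_profile(result)
        auc = np.trapezoid(venous, result.times)
        auc += venous[-1] / (system.total_clearance() / system.vss_plasma())
        cl_implied = 70.0 / auc
        assert cl_implied == pytest.approx(system.total_clearance(), rel=0.005)

    def test_infusion_reaches_same_total_as_bolus(self, body, drug_by_name):
        system = build_system(drug_by_name["Caffeine"], body, mode="ml",
                              include_clearance=False)
        inf = simulate(system, DoseEvent(amount=70.0, route="iv_infusion",
                                         duration=2.0), t_end=48.0)
        assert inf.total_in_body()[-1] == pytest.approx(70.0, rel=1e-6)
        assert np.abs(inf.mass_balance_residual()).max() < 1e-6 * 70.0

    def test_equilibrium_recovers_partition_coefficients(self, body, drug_by_name):
        # with clearances off, every tissue:venous-plasma concentration ratio
        # converges to the volume-weighted partition coefficient
        for name in ("Caffeine", "Ketoprofen", "Propranolol", "Naloxone"):
            drug = drug_by_name[name]
            parts = build_partition_set(drug, body)
            system = build_system(drug, body, parts, mode="ml",
                                  include_clearance=False)
            result = simulate(system, DoseEvent(amount=70.0), t_end=2000.0)
            c_ven = venous_profile(result)[-1]
            for tname, t in body.tissues.items():
                amount = sum(
                    result.amounts[system.index(f"{tname}_{sub}")][-1]
                    for sub in ("vasc_pls", "vasc_bc", "interstitial",
                                "intracellular"))
                ratio = amount / t.volume_total / c_ven
                assert ratio == pytest.approx(parts.kp_total[tname], rel=0.01), \
                    (name, tname)


class TestTwoCompartmentOracle:
    def test_matches_biexponential_closed_form(self):
        # central V1 with clearance CL, peripheral V2, inter-compartment flow Q
        v1, v2, q, cl, dose = 5.0, 20.0, 10.0, 2.0, 100.0
        k10, k12, k21 = cl / v1, q / v1, q / v2
        m = np.array([[-(k10 + k12), k21], [k12, -k21]])
        t = np.linspace(0.01, 48.0, 500)
        y = simulate_linear(m, np.array([dose, 0.0]), np.concatenate([[0], t]))
        c1 = y[0, 1:] / v1
        # closed form: alpha/beta from the standard quadratic
        s = k10 + k12 + k21
        alpha = (s + np.sqrt(s * s - 4 * k10 * k21)) / 2
        beta = (s - np.sqrt(s * s - 4 * k10 * k21)) / 2
        a = dose / v1 * (alpha - k21) / (alpha - beta)
        b = dose / v1 * (k21 - beta) / (alpha - beta)
        expected = a * np.exp(-alpha * t) + b * np.exp(-beta * t)
        assert np.max(np.abs(c1 - expected) / expected) < 1e-3


class TestPeripheralProfile:
    def test_uniform_concentration_passthrough(self, body, drug_by_name):
        system = build_system(drug_by_name["Caffeine"], body, mode="ml",
                              include_clearance=False)
        result = simulate(system, DoseEvent(amount=70.0), t_end=500.0)
        periph = peripheral_profile(result)
        venous = venous_profile(result)
        # at distribution equilibrium all plasma spaces share one concentration
        assert periph[-1] == pytest.approx(venous[-1], rel=1e-3)

    def test_peripheral_cmax_below_venous_cmax(self, body, drug_by_name):
        system = build_system(drug_by_name["Caffeine"], body, mode="ml")
        result = simulate(system, DoseEvent(amount=70.0))
        assert peripheral_profile(result).max() < venous_profile(result).max()

    def test_peripheral_auc_matches_venous_auc(self, body, drug_by_name):
        # tissues without elimination transmit the full exposure: the
        # flow-weighted effluent AUC equals the venous AUC
        drug = drug_by_name["Cimetidine"]
        system = build_system(drug, body, mode="ml")
        result = simulate(system, DoseEvent(amount=70.0))
        kel = system.total_clearance() / system.vss_plasma()
        p = peripheral_profile(result)
        v = venous_profile(result)
        auc_p = np.trapezoid(p, result.times) + p[-1] / kel
        auc_v = np.trapezoid(v, result.times) + v[-1] / kel
        assert auc_p == pytest.approx(auc_v, rel=0.01)
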