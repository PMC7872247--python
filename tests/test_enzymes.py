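"""Enzyme-module construction, rate-constant fitting, merging, analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from massdyn import (
    Model,
    ModelError,
    Reaction,
    Species,
    build_mwc_uni_uni,
    build_ordered_bi_bi,
    build_uni_uni,
    compile_kernel,
    conserved_pools,
    fit_rate_constants,
    fractional_abundance,
    gibbs_energy,
    integrate,
    make_linear_chain,
    mass_action_rate,
    merge_module,
    remove_module,
    split_flux,
    steady_state_net_flux,
)
from massdyn.core import stoichiometric_matrix
from massdyn.enzymes import form_distribution


@pytest.fixture
def fitted_uni_uni():
    mod = build_uni_uni("E1", "S", "P", keq_net=4.0, e_total=1e-6)
    fit_rate_constants(mod, {"S": 2e-3, "P": 1e-3}, 0.5)
    return mod


class TestTemplates:
    def test_two_step_structure(self):
        mod = build_uni_uni("E1", "S", "P", 2.0, n_steps=2)
        assert mod.form_ids == ["E1", "E1_S"]
        assert len(mod.steps) == 2

    def test_three_step_structure(self):
        mod = build_uni_uni("E1", "S", "P", 2.0, n_steps=3)
        assert mod.form_ids == ["E1", "E1_S", "E1_P"]
        assert len(mod.steps) == 3

    def test_substrate_equals_product_rejected(self):
        with pytest.raises(ModelError):
            build_uni_uni("E1", "S", "S", 1.0)

    def test_enzyme_pool_in_left_nullspace(self):
        """The all-ones vector over forms annihilates the step stoichiometry."""
        mod = build_uni_uni("E1", "S", "P", 2.0, n_steps=3)
        species = [Species(f, x0=1.0) for f in mod.form_ids] + [
            Species("S", x0=1.0, fixed=True), Species("P", x0=1.0, fixed=True)
        ]
        m = Model("module_only", species, mod.steps)
        pools = conserved_pools(m)
        assert {f: 1 for f in mod.form_ids} in pools

    def test_ordered_bi_bi_structure(self):
        mod = build_ordered_bi_bi("E2", "A", "B", "P", "Q", 3.0)
        assert len(mod.forms) == 4
        assert len(mod.steps) == 4
        assert mod.net_reactants == {"A": 1, "B": 1}

    def test_mwc_template_categories(self):
        mod = build_mwc_uni_uni("E3", "S", "P", 2.0, inhibitor="I")
        cats = {f.id: f.categories for f in mod.forms}
        assert "R-state" in cats["E3_R"] and "active" in cats["E3_R"]
        assert "T-state" in cats["E3_T"] and "inactive" in cats["E3_T"]
        assert "E3_T_I" in cats


class TestFitting:
    def test_achievable_target_hit(self, fitted_uni_uni):
        v = steady_state_net_flux(fitted_uni_uni, {"S": 2e-3, "P": 1e-3})
        assert abs(v - 0.5) / 0.5 < 1e-8

    def test_haldane_constraint_exact(self, fitted_uni_uni):
        assert abs(fitted_uni_uni.haldane_product() - 4.0) / 4.0 < 1e-10

    def test_target_against_driving_force_rejected(self):
        mod = build_uni_uni("E1", "S", "P", keq_net=1.0)
        # Gamma = P/S = 2 > Keq = 1, so positive flux is impossible
        with pytest.raises(ModelError, match="driving force|equilibrium"):
            fit_rate_constants(mod, {"S": 1e-3, "P": 2e-3}, 0.1)

    def test_three_step_fit(self):
        mod = build_uni_uni("E1", "S", "P", keq_net=10.0, n_steps=3)
        fit_rate_constants(mod, {"S": 1e-3, "P": 5e-4}, 0.02)
        v = steady_state_net_flux(mod, {"S": 1e-3, "P": 5e-4})
        assert abs(v - 0.02) / 0.02 < 1e-8
        assert abs(mod.haldane_product() - 10.0) / 10.0 < 1e-10

    def test_km_kcat_constraints_honored(self):
        mod = build_uni_uni("E1", "S", "P", keq_net=50.0, e_total=1e-6)
        kin = {"Km": 2e-3, "kcat": 2e6}
        fit_rate_constants(mod, {"S": 1e-3, "P": 1e-5}, 0.5,
                           kinetic_constraints=kin)
        k1, k2 = mod.steps[0].kf, mod.steps[1].kf
        km = (k1 / mod.steps[0].Keq + k2) / k1
        assert km == pytest.approx(kin["Km"], rel=0.05)
        assert k2 == pytest.approx(kin["kcat"], rel=0.05)


class TestNetFlux:
    def test_equilibrium_gives_zero(self):
        mod = build_uni_uni("E1", "S", "P", keq_net=1.0)
        for st_ in mod.steps:
            st_.kf = 1e5
            st_.Keq = 1.0 if st_.id.endswith("cat") else 1.0
        # S = P and all step Keq = 1: no driving force
        mod.steps[0].Keq = 1e3  # binding constant (1/M scale)
        mod.steps[1].Keq = 1e-3
        v = steady_state_net_flux(mod, {"S": 1e-3, "P": 1e-3})
        assert abs(v) < 1e-18

    def test_matches_reversible_michaelis_menten_grid(self, fitted_uni_uni):
        """2-step module equals the King-Altman closed form on a 10x10 grid."""
        mod = fitted_uni_uni
        k1, k2 = mod.steps[0].kf, mod.steps[1].kf
        k1r, k2r = k1 / mod.steps[0].Keq, k2 / mod.steps[1].Keq
        for S in np.geomspace(1e-5, 1e-2, 10):
            for P in np.geomspace(1e-5, 1e-2, 10):
                v = steady_state_net_flux(mod, {"S": S, "P": P})
                vmm = mod.e_total * (k1 * k2 * S - k1r * k2r * P) / (
                    k1r + k2 + k1 * S + k2r * P
                )
                assert v == pytest.approx(vmm, rel=1e-8)

    def test_flux_linear_in_e_total(self, fitted_uni_uni):
        lig = {"S": 2e-3, "P": 1e-3}
        v1 = steady_state_net_flux(fitted_uni_uni, lig)
        fitted_uni_uni.e_total *= 2.0
        v2 = steady_state_net_flux(fitted_uni_uni, lig)
        assert v2 == pytest.approx(2.0 * v1, rel=1e-12)

    def test_step_gibbs_energies_sum_to_net(self, fitted_uni_uni):
        """dG additivity along the catalytic path (log-sum identity)."""
        mod = fitted_uni_uni
        lig = {"S": 2e-3, "P": 1e-3}
        e = form_distribution(mod, lig)
        x = dict(lig)
        x.update(e)
        total = sum(gibbs_energy(st_, x) for st_ in mod.steps)
        net = Reaction("net", {"S": 1}, {"P": 1}, Keq=mod.keq_net)
        assert total == pytest.approx(gibbs_energy(net, lig), rel=1e-6)


class TestMerge:
    @pytest.fixture
    def merged_chain(self):
        model, ss = make_linear_chain(3, seed=11)
        host = model.get_reaction("r1")
        x_ref = model.x0_dict()
        target = mass_action_rate(host, x_ref)
        mod = build_uni_uni("r1_enz", "x1", "x2", keq_net=host.Keq,
                            replaces="r1")
        fit_rate_constants(mod, x_ref, target)
        return model, mod, merge_module(model, mod)

    def test_species_and_reaction_counts(self, merged_chain):
        model, mod, merged = merged_chain
        assert len(merged.species) == len(model.species) + len(mod.forms)
        assert len(merged.reactions) == len(model.reactions) + len(mod.steps) - 1

    def test_reference_steady_state_preserved(self, merged_chain):
        model, mod, merged = merged_chain
        kern = compile_kernel(merged)
        resid = np.max(np.abs(kern.rhs(merged.x0_vector())))
        vmax = np.max(np.abs(kern.rates(merged.x0_vector())))
        assert resid < max(1e-9, 1e-6 * vmax)

    def test_enzyme_pool_appears(self, merged_chain):
        _, mod, merged = merged_chain
        pools = conserved_pools(merged)
        assert {f: 1 for f in mod.form_ids} in pools

    def test_double_merge_collides(self, merged_chain):
        _, mod, merged = merged_chain
        with pytest.raises(ModelError, match="collision|not in model"):
            merge_module(merged, mod)

    def test_unfitted_module_rejected(self):
        model, _ = make_linear_chain(3, seed=11)
        mod = build_uni_uni("r1_enz", "x1", "x2", keq_net=2.0, replaces="r1")
        with pytest.raises(ModelError, match="not fitted"):
            merge_module(model, mod)

    def test_remove_restores_steady_state_fluxes(self, merged_chain):
        model, mod, merged = merged_chain
        restored = remove_module(merged, mod)
        k0 = compile_kernel(model)
        k1 = compile_kernel(restored)
        x = model.x0_vector()
        idx = [restored.reaction_ids.index(r) for r in model.reaction_ids]
        np.testing.assert_allclose(
            k1.rates(restored.x0_vector())[idx], k0.rates(x), rtol=1e-6
        )

    def test_enzyme_total_conserved_along_trajectory(self, merged_chain):
        _, mod, merged = merged_chain
        x0 = {mod.form_ids[0]: mod.e_total * 0.9,
              mod.form_ids[1]: mod.e_total * 0.1}
        rtol = 1e-9
        traj = integrate(merged, x0, (0.0, 0.1), rtol=rtol, n_points=51)
        total = sum(traj.series(f) for f in mod.form_ids)
        assert np.max(np.abs(total - mod.e_total)) <= 10 * rtol * mod.e_total


class TestFractionalAbundance:
    def test_single_form(self):
        mod = build_uni_uni("E1", "S", "P", 2.0)
        fr = fractional_abundance(mod, {"E1": 1e-6, "E1_S": 0.0})
        assert fr == {"E1": 1.0, "E1_S": 0.0}

    def test_two_equal_forms(self):
        mod = build_uni_uni("E1", "S", "P", 2.0)
        fr = fractional_abundance(mod, {"E1": 1e-7, "E1_S": 1e-7})
        assert fr["E1"] == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        mod = build_uni_uni("E1", "S", "P", 2.0)
        with pytest.raises(ModelError):
            fractional_abundance(mod, {"E1": 0.0, "E1_S": 0.0})

    @settings(max_examples=30, derandomize=True)
    @given(a=st.floats(1e-12, 1.0), b=st.floats(1e-12, 1.0))
    def test_fractions_sum_to_one(self, a, b):
        mod = build_uni_uni("E1", "S", "P", 2.0)
        fr = fractional_abundance(mod, {"E1": a, "E1_S": b})
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)


class TestSplitFlux:
    def test_major_minor_isozyme_split(self):
        # 75% / 25% major/minor isozyme assignment
        assert split_flux(1.0, [0.75, 0.25]) == [0.75, 0.25]

    def test_zero_flux_gives_zeros(self):
        assert split_flux(0.0, [0.6, 0.4]) == [0.0, 0.0]

    def test_bad_fractions_rejected(self):
        with pytest.raises(ModelError):
            split_flux(1.0, [0.7, 0.7])
        with pytest.raises(ModelError):
            split_flux(1.0, [-0.5, 1.5])

    @settings(max_examples=30, derandomize=True)
    @given(v=st.floats(-5, 5), f=st.floats(0.0, 1.0))
    def test_sum_preserved(self, v, f):
        parts = split_flux(v, [f, 1.0 - f])
        assert sum(parts) == pytest.approx(v, abs=1e-12)
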