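"""Polytope construction, hit-and-run correctness, flux sampling, QP fits."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from massdyn import (
    Model,
    Polytope,
    Reaction,
    Species,
    SteadyStateData,
    adjust_concentrations_min,
    build_concentration_polytope,
    check_direction_consistency,
    find_interior_point,
    fit_fluxes,
    futile_cycle_inflate,
    hit_and_run,
    sample_fluxes,
)
from massdyn.sampling import EmptyPolytopeError


def box(lb, ub, ids=None):
    k = len(lb)
    ids = ids or [f"y{i}" for i in range(k)]
    return Polytope(np.zeros((0, k)), np.zeros(0), lb, ub, ids, space="flux")


def ab_model(keq=2.0):
    return Model(
        "ab",
        [Species("A", x0=1.0), Species("B", x0=1.0)],
        [Reaction("r", {"A": 1}, {"B": 1}, Keq=keq)],
    )


class TestConcentrationPolytope:
    def test_single_reaction_constraint(self):
        p = build_concentration_polytope(ab_model(), {"r": 1},
                                         {"A": 1.0, "B": 1.0}, d=0.8)
        # y_B - y_A <= ln 2 - eps
        assert p.A.tolist() == [[-1.0, 1.0]]
        assert p.b[0] == pytest.approx(math.log(2.0) - 1e-6)

    def test_degenerate_box_feasible_iff_reference_feasible(self):
        p = build_concentration_polytope(ab_model(), {"r": 1},
                                         {"A": 1.0, "B": 1.0}, d=0.0)
        np.testing.assert_allclose(p.lb, p.ub)
        assert p.contains(p.lb)
        # reference on the wrong side of Keq is infeasible at d=0
        with pytest.raises(EmptyPolytopeError):
            build_concentration_polytope(ab_model(keq=0.5), {"r": 1},
                                         {"A": 1.0, "B": 1.0}, d=0.0)

    def test_toy_glycolysis_wide_bound_nonempty(self, toy_gly):
        model, ss = toy_gly
        dirs = {rid: int(np.sign(v)) for rid, v in ss.fluxes.items()}
        p = build_concentration_polytope(model, dirs, ss.concentrations, d=0.8)
        r = find_interior_point(p)
        assert p.contains(r)

    def test_backward_irreversible_rejected(self):
        m = Model(
            "m",
            [Species("A", x0=1.0), Species("B", x0=1.0)],
            [Reaction("r", {"A": 1}, {"B": 1}, reversible=False)],
        )
        with pytest.raises(Exception, match="irreversible"):
            build_concentration_polytope(m, {"r": -1}, {"A": 1.0, "B": 1.0})

    def test_magnitude_mode_bounds(self):
        p = build_concentration_polytope(ab_model(), {}, {"A": 1.0, "B": 1.0},
                                         bound_mode="magnitude", d=1.0)
        np.testing.assert_allclose(p.lb, -math.log(10.0))
        np.testing.assert_allclose(p.ub, math.log(10.0))


class TestInteriorPoint:
    def test_unit_box_center(self):
        np.testing.assert_allclose(
            find_interior_point(box([0, 0, 0], [1, 1, 1])), 0.5, atol=1e-9
        )

    def test_half_box_slab_center(self):
        p = Polytope([[1.0, 0.0]], [0.5], [0, 0], [1, 1], ["a", "b"],
                     space="flux")
        c = find_interior_point(p)
        # Chebyshev center of the 0.5 x 1 slab: x = 0.25, ball radius 0.25
        assert c[0] == pytest.approx(0.25, abs=1e-8)

    def test_infeasible_raises(self):
        p = Polytope([[1.0]], [0.0], [1.0], [2.0], ["a"], space="flux")
        with pytest.raises(EmptyPolytopeError):
            find_interior_point(p)


class TestHitAndRun:
    def test_interval_mean(self):
        s = hit_and_run(box([0.0], [1.0]), n=10_000, thin=10, seed=0)
        se = 1.0 / math.sqrt(12 * 10_000)
        assert abs(s.samples.mean() - 0.5) < 3 * se * 3  # autocorrelation slack

    def test_every_sample_feasible(self):
        p = Polytope([[1.0, 1.0]], [1.0], [0, 0], [1, 1], ["a", "b"],
                     space="flux")
        s = hit_and_run(p, n=500, thin=5, seed=1)
        for row in s.samples:
            assert p.slack(row) >= -1e-9

    def test_triangle_means_match_rejection_oracle(self):
        p = Polytope([[1.0, 1.0]], [1.0], [0, 0], [1, 1], ["a", "b"],
                     space="flux")
        s = hit_and_run(p, n=4000, thin=10, seed=2)
        rng = np.random.default_rng(99)
        pts = rng.uniform(0, 1, (200_000, 2))
        oracle = pts[pts.sum(axis=1) <= 1.0]
        se = oracle[:, 0].std() / math.sqrt(4000)
        for k in range(2):
            assert abs(s.samples[:, k].mean() - oracle[:, k].mean()) < 4 * se

    def test_seed_determinism(self):
        p = box([0.0, 0.0], [1.0, 2.0])
        a = hit_and_run(p, n=50, thin=3, seed=42)
        b = hit_and_run(p, n=50, thin=3, seed=42)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_uniformity_ks_on_box(self):
        """Per-coordinate KS vs uniform at alpha = 0.01 (n=1e4, thin=10)."""
        p = box([0.0, -1.0], [2.0, 1.0])
        s = hit_and_run(p, n=10_000, thin=10, seed=3)
        for k, (lo, hi) in enumerate([(0.0, 2.0), (-1.0, 1.0)]):
            u = (s.samples[:, k] - lo) / (hi - lo)
            assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_log_space_polytope_returns_natural_scale(self):
        p = Polytope(np.zeros((0, 1)), np.zeros(0), [0.0], [1.0], ["x"],
                     space="log-concentration")
        s = hit_and_run(p, n=100, thin=2, seed=4)
        assert np.all(s.samples >= 1.0) and np.all(s.samples <= math.e)


class TestSampleFluxes:
    def test_zero_dimensional_cone_is_a_point(self, two_step_chain):
        bounds = {"r1": (1.0, 1.0), "r2": (-10.0, 10.0)}
        s = sample_fluxes(two_step_chain, bounds, n=7, thin=2, seed=0)
        np.testing.assert_allclose(s.samples, 1.0, atol=1e-9)

    def test_parallel_routes_uniform_split(self):
        # src -> a by two routes; total pinned to 1: v1 ~ U[0, 1]
        m = Model(
            "par",
            [Species("src", x0=1.0, fixed=True), Species("a", x0=1.0),
             Species("snk", x0=1.0, fixed=True)],
            [Reaction("r1", {"src": 1}, {"a": 1}, reversible=False),
             Reaction("r2", {"src": 1}, {"a": 1}, reversible=False),
             Reaction("out", {"a": 1}, {"snk": 1}, reversible=False)],
        )
        bounds = {"r1": (0.0, 1.0), "r2": (0.0, 1.0), "out": (1.0, 1.0)}
        s = sample_fluxes(m, bounds, n=5000, thin=10, seed=1)
        v1 = s.samples[:, 0]
        se = 1.0 / math.sqrt(12 * 5000)
        assert abs(v1.mean() - 0.5) < 4 * se
        assert stats.kstest(v1, "uniform").pvalue > 0.01

    def test_balance_residual_invariant(self, toy_gly):
        model, ss = toy_gly
        from massdyn.sampling import default_flux_bounds
        from massdyn.core import stoichiometric_matrix

        s = sample_fluxes(model, n=50, thin=5, seed=2)
        S = stoichiometric_matrix(model)[~model.fixed_mask, :]
        assert np.max(np.abs(S @ s.samples.T)) <= 1e-9


class TestAdjustConcentrations:
    def test_feasible_input_unchanged(self):
        x = {"A": 2.0, "B": 1.0}
        out = adjust_concentrations_min(ab_model(), x, {"r": 1})
        assert out == pytest.approx(x)

    def test_symmetric_projection(self):
        # A<=>B, Keq=1, v>0, x=(1,2): project onto y_B - y_A = -eps
        out = adjust_concentrations_min(ab_model(keq=1.0),
                                        {"A": 1.0, "B": 2.0}, {"r": 1})
        ya, yb = math.log(out["A"]), math.log(out["B"])
        assert yb - ya == pytest.approx(-1e-6, abs=1e-7)
        # symmetric move in log space
        assert ya == pytest.approx(math.log(2.0) / 2, rel=1e-3)

    def test_beats_grid_search(self):
        x0 = {"A": 1.0, "B": 2.0}
        out = adjust_concentrations_min(ab_model(keq=1.0), x0, {"r": 1})
        y0 = np.log([x0["A"], x0["B"]])
        d_opt = np.sum((np.log([out["A"], out["B"]]) - y0) ** 2)
        grid = np.linspace(-1.0, 1.5, 81)
        for ya in grid:
            for yb in grid:
                if yb - ya <= -1e-6:  # feasible grid point
                    d = (ya - y0[0]) ** 2 + (yb - y0[1]) ** 2
                    assert d_opt <= d + 1e-8


class TestFitFluxes:
    def test_consistent_measurements_recovered(self, two_step_chain):
        out = fit_fluxes(two_step_chain, {"r1": 1.3, "r2": 1.3})
        assert out["r1"] == pytest.approx(1.3, abs=1e-10)
        assert out["r2"] == pytest.approx(1.3, abs=1e-10)

    def test_conflicting_measurements_averaged(self, two_step_chain):
        # chain forces v1 = v2; measured (1, 2) -> least squares (1.5, 1.5)
        out = fit_fluxes(two_step_chain, {"r1": 1.0, "r2": 2.0})
        assert out["r1"] == pytest.approx(1.5, abs=1e-8)
        assert out["r2"] == pytest.approx(1.5, abs=1e-8)

    def test_active_bound_clips(self, two_step_chain):
        bounds = {"r1": (-1e3, 1.2), "r2": (-1e3, 1.2)}
        out = fit_fluxes(two_step_chain, {"r1": 1.0, "r2": 2.0}, bounds)
        assert out["r1"] == pytest.approx(1.2, abs=1e-6)
        assert out["r2"] == pytest.approx(1.2, abs=1e-6)


class TestFutileCycleInflate:
    def test_ten_percent_inflation(self):
        assert futile_cycle_inflate(1.0, 0.0, 0.1) == (1.1, 0.1)

    def test_exact_net_preservation_with_rationals(self):
        v_fwd, v_rev = Fraction(11, 10), Fraction(1, 10)
        f2, r2 = futile_cycle_inflate(v_fwd, v_rev, Fraction(1, 10))
        assert f2 - r2 == v_fwd - v_rev  # exact rational identity
        assert f2 == Fraction(12, 10) and r2 == Fraction(2, 10)

    def test_zero_fraction_is_identity(self):
        assert futile_cycle_inflate(2.0, 0.5, 0.0) == (2.0, 0.5)

    @settings(max_examples=50, derandomize=True)
    @given(
        vf=st.floats(-10, 10), vr=st.floats(-10, 10), frac=st.floats(0, 1),
    )
    def test_net_invariance_property(self, vf, vr, frac):
        f2, r2 = futile_cycle_inflate(vf, vr, frac)
        assert f2 - r2 == pytest.approx(vf - vr, abs=1e-12)
        assert f2 >= vf and r2 >= vr


class TestDirectionConsistencyOfSamples:
    def test_conc_samples_respect_reference_directions(self, toy_gly):
        model, ss = toy_gly
        dirs = {rid: int(np.sign(v)) for rid, v in ss.fluxes.items()}
        p = build_concentration_polytope(model, dirs, ss.concentrations, d=0.8)
        s = hit_and_run(p, n=40, thin=10, seed=5)
        fixed = {sp.id: sp.x0 for sp in model.species if sp.fixed}
        for i in range(s.n):
            conc = dict(fixed)
            conc.update(s.row_dict(i))
            ssd = SteadyStateData(fluxes=ss.fluxes, concentrations=conc)
            assert check_direction_consistency(model, ssd) == []
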