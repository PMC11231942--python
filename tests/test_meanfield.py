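"""Unit tests of the random-distribution (mean-field) model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bvocgame import (ModelParams, binomial_gross_inter_oracle, classify_ess,
                      coexistence_condition, emission_viability_threshold,
                      emitter_fixation_bound, fitness_pair,
                      gross_inter_effect_meanfield, integrate_dynamics,
                      interior_equilibrium, mean_fitness,
                      phase_diagram_meanfield, replicator_rhs,
                      replicator_slope)

FOCAL = dict(p=0.4, c=0.1, n=8)


def params(alpha1, alpha2, **kw):
    return ModelParams(alpha1=alpha1, alpha2=alpha2, **{**FOCAL, **kw})


class TestGrossInterEffect:
    @pytest.mark.parametrize("x_e, alpha2, n, expected", [
        (0.0, 0.6, 8, 1.0),          # no emitters anywhere
        (1.0, 0.6, 8, 0.6 ** 8),     # every neighbor emits
        (1.0, 0.5, 3, 0.125),
        (0.5, 0.5, 2, 0.5625),       # 0.25*1 + 0.5*0.5 + 0.25*0.25
    ])
    def test_examples(self, x_e, alpha2, n, expected):
        assert gross_inter_effect_meanfield(x_e, alpha2, n) == pytest.approx(
            expected, abs=1e-12)
        assert binomial_gross_inter_oracle(x_e, alpha2, n) == pytest.approx(
            expected, abs=1e-12)

    def test_rejects_out_of_range_frequency(self):
        with pytest.raises(ValueError, match="x_e"):
            gross_inter_effect_meanfield(1.5, 0.5, 8)

    @settings(derandomize=True, max_examples=300)
    @given(x_e=st.floats(min_value=0, max_value=1, allow_subnormal=False),
           alpha2=st.floats(min_value=0.01, max_value=0.99),
           n=st.integers(min_value=0, max_value=20))
    def test_closed_form_matches_binomial_sum(self, x_e, alpha2, n):
        """The closed form (1+(alpha2-1)x)^n is exactly the binomial
        expectation of alpha2^k."""
        assert gross_inter_effect_meanfield(x_e, alpha2, n) == pytest.approx(
            binomial_gross_inter_oracle(x_e, alpha2, n), abs=1e-12)


class TestReplicatorDynamics:
    def test_mean_fitness_is_frequency_weighted_average(self, focal_params):
        f_e, f_n = fitness_pair(0.3, focal_params)
        assert mean_fitness(0.3, focal_params) == pytest.approx(
            0.3 * f_e + 0.7 * f_n)
        # boundary: all non-emitters see no signal at all
        assert mean_fitness(0.0, focal_params) == pytest.approx(
            (1 - focal_params.p) * focal_params.fhat)

    def test_boundaries_are_fixed_points(self, focal_params):
        assert replicator_rhs(0.0, focal_params) == 0.0
        assert replicator_rhs(1.0, focal_params) == 0.0

    def test_rhs_vanishes_at_interior_equilibrium(self, focal_params):
        x_star = interior_equilibrium(focal_params)
        assert abs(replicator_rhs(x_star, focal_params)) < 1e-10

    def test_rhs_is_selection_gradient_times_frequencies(self, focal_params):
        x = 0.37
        f_e, f_n = fitness_pair(x, focal_params)
        assert replicator_rhs(x, focal_params) == pytest.approx(
            x * (1 - x) * (f_e - f_n))


class TestEquilibria:
    def test_focal_interior_equilibrium_value(self):
        # target gross effect 0.1/(0.4*0.55) = 0.4545..., eighth root
        # 0.906139..., so x* = (0.906139 - 1)/(0.9 - 1) = 0.938561...
        x = interior_equilibrium(params(0.5, 0.9))
        assert x == pytest.approx(0.9385611315385536, abs=1e-12)
        f_e, f_n = fitness_pair(x, params(0.5, 0.9))
        assert abs(f_e - f_n) < 1e-12

    def test_absent_above_viability_threshold(self):
        assert interior_equilibrium(params(0.9, 0.5)) is None

    def test_absent_below_fixation_bound(self):
        # alpha1=0.05 < (0.9^8*0.4-0.1)/(0.9^8*0.4*0.9) ~= 0.466
        assert interior_equilibrium(params(0.05, 0.9)) is None

    @settings(derandomize=True, max_examples=300)
    @given(alpha1=st.floats(min_value=0.01, max_value=0.99),
           alpha2=st.floats(min_value=0.01, max_value=0.99),
           p=st.floats(min_value=0.05, max_value=0.95),
           c=st.floats(min_value=0.01, max_value=0.9),
           n=st.integers(min_value=1, max_value=20))
    def test_presence_agrees_with_coexistence_band(self, alpha1, alpha2,
                                                   p, c, n):
        pp = ModelParams(alpha1=alpha1, alpha2=alpha2, p=p, c=c, n=n)
        lo = emitter_fixation_bound(p, c, alpha2, n)
        hi = emission_viability_threshold(p, c)
        if min(abs(alpha1 - lo), abs(alpha1 - hi)) < 1e-9:
            return  # marginal: presence is numerically ambiguous
        assert (interior_equilibrium(pp) is not None) == \
            coexistence_condition(pp)

    def test_interior_equilibrium_decreases_with_alpha1(self):
        xs = [interior_equilibrium(params(a1, 0.9))
              for a1 in (0.5, 0.6, 0.7, 0.8)]
        assert all(x is not None for x in xs)
        assert all(a > b for a, b in zip(xs, xs[1:]))


class TestViabilityThreshold:
    def test_focal_value(self):
        assert emission_viability_threshold(0.4, 0.1) == pytest.approx(5 / 6)

    def test_cost_equals_damage_never_pays(self):
        assert emission_viability_threshold(0.3, 0.3) == 0.0

    def test_free_emission_always_viable(self):
        assert emission_viability_threshold(0.4, 0.0) == 1.0

    def test_coexistence_window_collapses_as_alpha2_to_one(self):
        hi = emission_viability_threshold(0.4, 0.1)
        for alpha2, tol in ((0.99, 0.15), (0.9999, 2e-3)):
            lo = emitter_fixation_bound(0.4, 0.1, alpha2, 8)
            assert hi - lo < tol


class TestEssClassification:
    def test_nonemitter_ess_above_threshold(self):
        rep = classify_ess(params(0.9, 0.5))
        stable = [eq for eq in rep.equilibria if eq.stable]
        assert [eq.x_e for eq in stable] == [0.0]
        assert rep.regime == "nonemitter-dominant"

    def test_coexistent_ess_in_band(self):
        rep = classify_ess(params(0.5, 0.9))
        by_kind = {eq.kind: eq for eq in rep.equilibria}
        assert by_kind["coexistent"].stable
        assert not by_kind["monomorphic_nonemitter"].stable
        assert not by_kind["monomorphic_emitter"].stable
        assert rep.stable_density == pytest.approx(0.93856, abs=1e-4)

    def test_emitter_ess_below_fixation_bound(self):
        rep = classify_ess(params(0.05, 0.9))
        stable = [eq for eq in rep.equilibria if eq.stable]
        assert [eq.x_e for eq in stable] == [1.0]
        assert rep.regime == "emitter-dominant"

    def test_marginal_point_carries_no_stability_claim(self):
        rep = classify_ess(params(5 / 6, 0.9).with_(p=0.4, c=0.1))
        assert rep.marginal
        assert all(eq.stable is None for eq in rep.equilibria)
        assert np.isnan(rep.stable_density)

    def test_boundary_equilibria_always_reported(self):
        for a1 in (0.05, 0.5, 0.9):
            xs = [eq.x_e for eq in classify_ess(params(a1, 0.9)).equilibria]
            assert 0.0 in xs and 1.0 in xs


class TestIntegration:
    def test_converges_to_interior_equilibrium(self, focal_params):
        x_star = interior_equilibrium(focal_params)
        for x0 in (0.01, 0.99):
            _, x = integrate_dynamics(x0, focal_params, t_max=4000)
            assert x[-1] == pytest.approx(x_star, abs=1e-6)

    def test_monotone_decay_to_zero_above_threshold(self):
        pp = params(0.9, 0.5)
        _, x = integrate_dynamics(0.5, pp, t_max=4000)
        assert np.all(np.diff(x) <= 1e-12)
        assert x[-1] < 1e-4

    def test_fixed_point_stays_fixed(self, focal_params):
        x_star = interior_equilibrium(focal_params)
        _, x = integrate_dynamics(x_star, focal_params, t_max=100)
        assert np.allclose(x, x_star, atol=1e-8)

    def test_rejects_out_of_range_start(self, focal_params):
        with pytest.raises(ValueError):
            integrate_dynamics(1.5, focal_params)

    def test_meanfield_neutrality_at_no_cost_no_intra_benefit(self):
        """With alpha1=1 and c=0 the selection gradient vanishes
        identically, so any frequency is a fixed point of the mean-field
        dynamics."""
        pp = ModelParams(alpha1=1.0, alpha2=0.7, p=0.4, c=0.0, n=8)
        for x in (0.1, 0.5, 0.9):
            assert abs(replicator_rhs(x, pp)) < 1e-15
        _, traj = integrate_dynamics(0.3, pp, t_max=500)
        assert np.allclose(traj, 0.3, atol=1e-9)


class TestMeanFieldPhaseDiagram:
    def test_regions_match_closed_form_curves(self):
        base = ModelParams(alpha1=0.5, alpha2=0.5, **FOCAL)
        grid = np.round(np.arange(0.05, 1.0, 0.05), 10)
        diagram = phase_diagram_meanfield(grid, grid, base)
        hi = emission_viability_threshold(0.4, 0.1)
        for i, a2 in enumerate(grid):
            lo = emitter_fixation_bound(0.4, 0.1, a2, 8)
            for j, a1 in enumerate(grid):
                regime = diagram.regime[i, j]
                if a1 < lo:
                    assert regime == "emitter-dominant"
                    assert diagram.stable_density[i, j] == 1.0
                elif a1 > hi:
                    assert regime == "nonemitter-dominant"
                    assert diagram.stable_density[i, j] == 0.0
                else:
                    assert regime == "coexistent"
                    assert 0.0 < diagram.stable_density[i, j] < 1.0

    def test_dataframe_roundtrip(self, tmp_path):
        base = ModelParams(alpha1=0.5, alpha2=0.5, **FOCAL)
        diagram = phase_diagram_meanfield([0.3, 0.6], [0.5, 0.9], base)
        path = tmp_path / "mf.csv"
        diagram.to_csv(path)
        df = __import__("pandas").read_csv(path)
        assert list(df.columns) == ["alpha1", "alpha2", "stable_density",
                                    "regime"]
        assert len(df) == 4

    def test_rejects_grid_outside_unit_interval(self, focal_params):
        with pytest.raises(ValueError):
            phase_diagram_meanfield([0.0, 0.5], [0.5], focal_params)


@settings(derandomize=True, max_examples=100)
@given(alpha1=st.floats(min_value=0.05, max_value=0.95),
       alpha2=st.floats(min_value=0.05, max_value=0.95),
       x=st.floats(min_value=0.01, max_value=0.99))
def test_slope_matches_analytic_derivative_of_rhs(alpha1, alpha2, x):
    """Central finite difference of g agrees with a fine-step numerical
    derivative at interior points (sanity of the stability criterion)."""
    pp = ModelParams(alpha1=alpha1, alpha2=alpha2, **FOCAL)
    coarse = replicator_slope(x, pp, h=1e-4)
    fine = replicator_slope(x, pp, h=1e-7)
    assert coarse == pytest.approx(fine, rel=1e-3, abs=1e-8)
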