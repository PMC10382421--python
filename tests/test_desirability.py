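"""Derringer–Suich desirability, multi-response optimization, %bias."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pharmrsm as pr
from pharmrsm.desirability import _evaluate


def goal(direction="minimize", lower=0.0, upper=1.0, **kw):
    return pr.DesirabilityGoal(
        response_name="Y", direction=direction, lower=lower, upper=upper, **kw
    )


class TestIndividualDesirability:
    def test_minimize_ramp_endpoints(self):
        g = goal("minimize", 168.5, 416.3)
        assert pr.individual_desirability(416.3, g) == 0.0
        assert pr.individual_desirability(168.5, g) == 1.0
        assert pr.individual_desirability(500.0, g) == 0.0
        assert pr.individual_desirability(100.0, g) == 1.0

    def test_maximize_ramp_on_zeta_range(self):
        # |ZP| observed extremes 19.0..39.2; the reported optimum predicts 25
        g = goal("maximize", 19.0, 39.2)
        assert pr.individual_desirability(25.0, g) == pytest.approx(6 / 20.2, abs=1e-9)

    def test_minimize_ramp_on_ps_range(self):
        g = goal("minimize", 168.5, 416.3)
        assert pr.individual_desirability(278.928, g) == pytest.approx(0.554, abs=5e-4)

    def test_target_ramp(self):
        g = goal("target", 0.0, 10.0, target=4.0)
        assert pr.individual_desirability(4.0, g) == 1.0
        assert pr.individual_desirability(2.0, g) == 0.5
        assert pr.individual_desirability(7.0, g) == 0.5
        assert pr.individual_desirability(-1.0, g) == 0.0
        assert pr.individual_desirability(11.0, g) == 0.0

    def test_weight_bends_ramp(self):
        g = goal("minimize", 0.0, 1.0, weight=2.0)
        assert pr.individual_desirability(0.5, g) == pytest.approx(0.25)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(-50, 50, allow_nan=False),
        st.floats(0.1, 10),
        st.floats(-20, 20),
    )
    def test_affine_rescaling_invariance(self, y, a, b):
        g = goal("maximize", 19.0, 39.2)
        g2 = goal("maximize", a * 19.0 + b, a * 39.2 + b)
        assert pr.individual_desirability(y, g) == pytest.approx(
            pr.individual_desirability(a * y + b, g2), abs=1e-9
        )

    def test_invalid_goals_rejected(self):
        with pytest.raises(ValueError):
            goal("minimize", 5.0, 5.0)
        with pytest.raises(ValueError):
            goal("shrink")
        with pytest.raises(ValueError):
            goal("target", 0, 1, target=2.0)
        with pytest.raises(ValueError):
            goal("minimize", 0, 1, weight=0.0)


class TestOverallDesirability:
    def test_reported_optimum_combination(self):
        # the three ramp values at the study's reported optimum combine to
        # the printed overall desirability ~0.52
        D = pr.overall_desirability({"PS": 0.554, "PDI": 0.849, "ZP": 0.297})
        assert D == pytest.approx(0.52, abs=0.01)

    def test_zero_and_one_cases(self):
        assert pr.overall_desirability({"a": 0.0, "b": 0.9}) == 0.0
        assert pr.overall_desirability({"a": 1.0, "b": 1.0, "c": 1.0}) == 1.0

    def test_importance_weighting(self):
        D = pr.overall_desirability({"a": 0.25, "b": 1.0}, {"a": 3.0, "b": 1.0})
        assert D == pytest.approx(0.25 ** (3 / 4))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.dictionaries(
            st.sampled_from(["a", "b", "c"]),
            st.floats(0.01, 1.0),
            min_size=2,
            max_size=3,
        ),
        st.floats(0.001, 0.2),
    )
    def test_monotone_and_bracketed(self, ds, bump):
        D = pr.overall_desirability(ds)
        assert min(ds.values()) - 1e-12 <= D <= max(ds.values()) + 1e-12
        name = sorted(ds)[0]
        higher = dict(ds, **{name: min(1.0, ds[name] + bump)})
        assert pr.overall_desirability(higher) >= D - 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pr.overall_desirability({"a": 1.2})


class TestOptimize:
    def test_paper_models_best_solution(self, models, paper_goals):
        res = pr.optimize(list(models.values()), paper_goals, grid_step=0.01)
        assert res.feasible
        # the global box optimum sits on the +1 PC:VA face
        assert res.coded_point[0] == pytest.approx(1.0, abs=1e-6)
        assert res.overall_D == pytest.approx(0.757, abs=0.005)
        assert min(res.individual_d.values()) - 1e-12 <= res.overall_D
        assert res.overall_D <= max(res.individual_d.values()) + 1e-12

    def test_paper_reported_optimum_recovered_as_local_solution(
        self, models, paper_goals
    ):
        res = pr.optimize(list(models.values()), paper_goals, grid_step=0.01)
        local = [
            s
            for s in res.solutions
            if abs(s.actual_point[0] - 1.3) < 0.15
            and abs(s.actual_point[1] - 53.164) < 1.0
        ]
        assert local, "reported optimum basin not found among solutions"
        assert local[0].overall_D == pytest.approx(0.522, abs=0.01)

    def test_two_stage_search_matches_fine_grid_oracle(self, models, paper_goals):
        res = pr.optimize(list(models.values()), paper_goals, grid_step=0.01)
        # brute-force oracle: exhaustive 0.001-step scan of the box
        axis = np.linspace(-1, 1, 2001)
        mesh = np.meshgrid(axis, axis, indexing="ij")
        pts = np.column_stack([m.ravel() for m in mesh])
        goal_map = {g.response_name: g for g in paper_goals}
        D = _evaluate(list(models.values()), goal_map, pts)
        assert res.overall_D == pytest.approx(float(D.max()), abs=1e-3)

    def test_single_response_bowl_minimized_at_argmin(self):
        factors = [pr.FactorSpec(name=f"f{i}", center=0, half_range=1) for i in range(2)]
        design = pr.build_ccd(factors, n_center=5)
        # convex bowl with argmin (0.5, -0.25), inside the box
        truth = (10.0, -2.0, 1.0, 0.0, 2.0, 2.0)
        table = pr.simulate_ccd_responses(
            design, [pr.TrueResponseModel("Y", truth)], seed=0
        )
        m = pr.fit_quadratic(table, "Y")
        g = pr.DesirabilityGoal(
            response_name="Y", direction="minimize", lower=0.0, upper=20.0
        )
        res = pr.optimize([m], [g], grid_step=0.01)
        assert res.coded_point == pytest.approx((0.5, -0.25), abs=1e-3)

    def test_region_constraints_respected(self, models, paper_goals):
        box = pr.optimize(list(models.values()), paper_goals, grid_step=0.02)
        assert max(abs(v) for v in box.coded_point) <= 1 + 1e-9
        disc = pr.optimize(
            list(models.values()), paper_goals, region="axial_disc", grid_step=0.02
        )
        alpha = list(models.values())[0].design.alpha
        assert np.linalg.norm(disc.coded_point) <= alpha + 1e-9
        # a larger region can only improve the optimum
        assert disc.overall_D >= box.overall_D - 1e-9

    def test_invariant_to_response_order_and_rescaling(self, models, paper_goals):
        base = pr.optimize(list(models.values()), paper_goals, grid_step=0.02)
        rev = pr.optimize(
            list(models.values())[::-1], paper_goals[::-1], grid_step=0.02
        )
        assert base.coded_point == pytest.approx(rev.coded_point, abs=1e-6)
        assert base.overall_D == pytest.approx(rev.overall_D, abs=1e-9)
        # rescale PS (and its bounds) by 10: same optimum
        m = models["PS"]
        scaled = pr.QuadraticModel(
            response_name="PS",
            terms=m.terms,
            coef=m.coef * 10,
            design=m.design,
            y=m.y * 10,
            fitted=m.fitted * 10,
            residuals=m.residuals * 10,
            leverages=m.leverages,
            xtx_inv=m.xtx_inv,
        )
        goals2 = [
            pr.DesirabilityGoal("PS", "minimize", g.lower * 10, g.upper * 10)
            if g.response_name == "PS"
            else g
            for g in paper_goals
        ]
        scaled_res = pr.optimize(
            [scaled, models["PDI"], models["ZP"]], goals2, grid_step=0.02
        )
        assert scaled_res.coded_point == pytest.approx(base.coded_point, abs=1e-5)
        assert scaled_res.overall_D == pytest.approx(base.overall_D, abs=1e-7)

    def test_infeasible_everywhere_flagged(self, models):
        goals = [
            pr.DesirabilityGoal("PS", "minimize", lower=-100.0, upper=-50.0),
            pr.DesirabilityGoal("PDI", "minimize", lower=-2.0, upper=-1.0),
            pr.DesirabilityGoal("ZP", "maximize", lower=100.0, upper=200.0),
        ]
        res = pr.optimize(list(models.values()), goals, grid_step=0.05)
        assert not res.feasible
        assert res.overall_D == 0.0

    def test_mismatched_goals_rejected(self, models, paper_goals):
        with pytest.raises(ValueError, match="do not match"):
            pr.optimize(list(models.values()), paper_goals[:2])


class TestPercentBias:
    @pytest.mark.parametrize(
        "expected,observed,value",
        [(0.312, 0.29, 7.05), (25.0, 30.8, 23.20), (3.0, 3.0, 0.0)],
    )
    def test_values(self, expected, observed, value):
        assert pr.percent_bias(expected, observed) == pytest.approx(value, abs=0.005)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            pr.percent_bias(0.0, 1.0)

    def test_validation_records(self):
        recs = pr.validate_predictions(
            {"PDI": 0.312, "ZP": 25.0}, {"PDI": 0.29, "ZP": 30.8}
        )
        by_name = {r.response_name: r for r in recs}
        assert by_name["PDI"].percent_bias == pytest.approx(7.05, abs=0.005)
        assert by_name["ZP"].percent_bias == pytest.approx(23.20, abs=0.005)
        with pytest.raises(KeyError):
            pr.validate_predictions({"PS": 1.0}, {})
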