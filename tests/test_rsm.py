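"""Quadratic response-surface fitting, prediction and partial sums of squares."""

import numpy as np
import pytest

import pharmrsm as pr
from pharmrsm.rsm import SingularDesignError, model_matrix


class TestFitQuadratic:
    def test_particle_size_coefficients_match_refit(self, models):
        # the PS equation's printed "+3.34*X12" is really the linear X2 term;
        # the design-table refit is ground truth
        c = models["PS"].coef_dict
        assert c["b0"] == pytest.approx(316.60, abs=0.01)
        assert c["b1"] == pytest.approx(-21.43, abs=0.01)
        assert c["b2"] == pytest.approx(3.34, abs=0.01)
        assert c["b12"] == pytest.approx(-0.35, abs=0.01)
        assert c["b11"] == pytest.approx(-60.26, abs=0.01)
        assert c["b22"] == pytest.approx(42.97, abs=0.01)

    def test_pdi_coefficients_match_printed_equation(self, models):
        c = models["PDI"].coef_dict
        assert c["b0"] == pytest.approx(0.42, abs=0.005)
        assert c["b1"] == pytest.approx(0.049, abs=0.001)
        assert c["b2"] == pytest.approx(0.023, abs=0.001)
        assert c["b12"] == pytest.approx(0.000, abs=1e-9)
        assert c["b11"] == pytest.approx(-0.060, abs=0.001)
        assert c["b22"] == pytest.approx(0.082, abs=0.001)

    def test_zeta_magnitude_model_matches_printed_equation(self, models):
        # fitted on |ZP|: the printed intercept +32.20 equals the
        # center-point |ZP| mean, confirming the magnitude convention
        c = models["ZP"].coef_dict
        assert models["ZP"].sign == -1
        assert c["b0"] == pytest.approx(32.20, abs=0.01)
        assert c["b1"] == pytest.approx(6.78, abs=0.01)
        assert c["b2"] == pytest.approx(2.46, abs=0.01)

    def test_residual_identities_and_leverages(self, models):
        m = models["PS"]
        X = model_matrix(m.design.coded_matrix)
        assert abs(m.residuals.sum()) < 1e-8
        assert np.allclose(X.T @ m.residuals, 0.0, atol=1e-7)
        assert np.all(m.leverages > 0) and np.all(m.leverages < 1)
        assert m.leverages.sum() == pytest.approx(m.p)

    def test_ss_decomposition(self, models):
        for m in models.values():
            assert m.ss_model + m.ss_residual == pytest.approx(
                m.ss_total, rel=1e-8
            )

    def test_fit_invariant_to_run_order(self, table1, models, rng):
        perm = rng.permutation(table1.design.n_runs)
        design = table1.design
        pts = tuple(design.points[i] for i in perm)
        shuffled = pr.ResponseTable(
            design=pr.CCDDesign(design.factors, design.alpha, pts),
            means={k: v[perm] for k, v in table1.means.items()},
            sds={k: v[perm] for k, v in table1.sds.items()},
            magnitude_responses=table1.magnitude_responses,
        )
        m = pr.fit_quadratic(shuffled, "PS")
        assert np.allclose(m.coef, models["PS"].coef, atol=1e-9)

    def test_oracle_agreement_on_fixture(self, table1, models, oracle):
        X = model_matrix(table1.design.coded_matrix)
        for name, m in models.items():
            y, _ = table1.analysis_values(name)
            ref = oracle(X, y)
            assert np.allclose(m.coef, ref, rtol=1e-8, atol=1e-10)

    def test_statsmodels_cross_check(self, table1, models):
        sm = pytest.importorskip("statsmodels.api")
        X = model_matrix(table1.design.coded_matrix)
        y, _ = table1.analysis_values("PS")
        fit = sm.OLS(y, X).fit()
        assert np.allclose(models["PS"].coef, fit.params, rtol=1e-10)
        assert models["PS"].leverages == pytest.approx(
            fit.get_influence().hat_matrix_diag, rel=1e-8
        )

    def test_noise_free_table_recovered_exactly(self):
        factors = [pr.FactorSpec(name=f"f{i}", center=0, half_range=1) for i in range(2)]
        design = pr.build_ccd(factors, n_center=5)
        truth = (5.0, -2.0, 3.0, 1.5, -0.7, 0.9)
        table = pr.simulate_ccd_responses(
            design, [pr.TrueResponseModel("Y", truth, noise_sd=0.0)], seed=0
        )
        m = pr.fit_quadratic(table, "Y")
        assert np.allclose(m.coef, truth, atol=1e-10)
        assert m.ss_residual == pytest.approx(0.0, abs=1e-18)

    def test_rank_deficiency_names_collinear_columns(self):
        # two perfectly confounded factors -> x1 and x2 columns collinear
        factors = [pr.FactorSpec(name=f"f{i}", center=0, half_range=1) for i in range(2)]
        design = pr.build_ccd(factors, n_center=5)
        pts = []
        for p in design.points:
            c = (p.coded[0], p.coded[0])
            pts.append(
                pr.DesignPoint(p.run_id, c, c, "center" if c[0] == 0 else p.point_class)
            )
        bad = pr.CCDDesign(design.factors, design.alpha, tuple(pts))
        table = pr.ResponseTable(design=bad, means={"Y": np.arange(13.0)})
        with pytest.raises(SingularDesignError, match="collinear"):
            pr.fit_quadratic(table, "Y")

    def test_too_few_runs_rejected(self):
        factors = [pr.FactorSpec(name=f"f{i}", center=0, half_range=1) for i in range(2)]
        d = pr.build_ccd(factors, n_center=1)
        pts = d.points[:5]
        small = pr.CCDDesign(d.factors, d.alpha, pts)
        table = pr.ResponseTable(design=small, means={"Y": np.ones(5)})
        with pytest.raises(ValueError, match="at least"):
            pr.fit_quadratic(table, "Y")


class TestPredict:
    def test_center_prediction_is_intercept(self, models):
        for m in models.values():
            assert pr.predict(m, [0.0, 0.0]) == pytest.approx(m.b0)

    def test_ps_prediction_at_reported_optimum(self, models):
        # coded (-1, +0.12656) == actual (1.3, 53.164 mg/mL)
        assert pr.predict(models["PS"], [-1.0, 0.12656]) == pytest.approx(
            278.928, abs=0.05
        )

    def test_pdi_prediction_at_corner_tracks_observation(self, models):
        # direct evaluation of the PDI equation at (-1,-1); the measured
        # PDI there was 0.37
        val = pr.predict(models["PDI"], [-1.0, -1.0])
        assert val == pytest.approx(0.42 - 0.049 - 0.023 - 0.060 + 0.082, abs=0.005)
        assert val == pytest.approx(0.37, abs=0.01)

    def test_wrong_length_rejected(self, models):
        with pytest.raises(ValueError):
            pr.predict(models["PS"], [0.0])


class TestPartialSS:
    def test_table_values_reproduced(self, models):
        ss = pr.partial_ss(models["PS"])
        assert ss["b1"] == pytest.approx(3672.8, abs=0.1)
        assert ss["b2"] == pytest.approx(89.39, abs=0.01)
        assert ss["b12"] == pytest.approx(0.49, abs=0.01)
        assert ss["b11"] == pytest.approx(25257.9, abs=0.1)
        assert ss["b22"] == pytest.approx(12843.9, abs=0.1)

    def test_orthogonal_closed_forms(self, models):
        # on this CCD: SS(linear i) = b_i^2 * 8, SS(interaction) = b_12^2 * 4
        for m in models.values():
            ss = pr.partial_ss(m)
            c = m.coef_dict
            assert ss["b1"] == pytest.approx(8 * c["b1"] ** 2, rel=1e-10)
            assert ss["b2"] == pytest.approx(8 * c["b2"] ** 2, rel=1e-10)
            assert ss["b12"] == pytest.approx(4 * c["b12"] ** 2, rel=1e-10, abs=1e-12)

    def test_quadratic_terms_equal_drop_one_extra_ss(self, table1, models):
        # oracle: refit without the term, compare residual-SS increase
        X = model_matrix(table1.design.coded_matrix)
        y, _ = table1.analysis_values("PS")
        full_res = models["PS"].ss_residual
        ss = pr.partial_ss(models["PS"])
        for j, term in enumerate(models["PS"].terms):
            if term == "b0":
                continue
            Xr = np.delete(X, j, axis=1)
            beta, *_ = np.linalg.lstsq(Xr, y, rcond=None)
            red_res = float(np.sum((y - Xr @ beta) ** 2))
            assert ss[term] == pytest.approx(red_res - full_res, rel=1e-8, abs=1e-10)

    def test_zero_coefficient_gives_zero_ss(self):
        factors = [pr.FactorSpec(name=f"f{i}", center=0, half_range=1) for i in range(2)]
        design = pr.build_ccd(factors, n_center=5)
        table = pr.simulate_ccd_responses(
            design, [pr.TrueResponseModel("Y", (1.0, 0.0, 2.0, 0.0, 0.0, 1.0))], seed=0
        )
        ss = pr.partial_ss(pr.fit_quadratic(table, "Y"))
        assert ss["b1"] == pytest.approx(0.0, abs=1e-18)
        assert ss["b12"] == pytest.approx(0.0, abs=1e-18)


def test_oracle_agreement_on_random_tables(oracle, rng):
    """Main solver equals the brute-force normal-equations oracle on 100
    seeded random response tables."""
    factors = [pr.FactorSpec(name=f"f{i}", center=0, half_range=1) for i in range(2)]
    design = pr.build_ccd(factors, n_center=5)
    X = model_matrix(design.coded_matrix)
    for _ in range(100):
        y = rng.normal(0, 10, size=13) + rng.uniform(-100, 100)
        table = pr.ResponseTable(design=design, means={"Y": y})
        m = pr.fit_quadratic(table, "Y")
        assert np.allclose(m.coef, oracle(X, y), rtol=1e-8, atol=1e-8)


def test_model_json_export_round_trip(models, tmp_path):
    import json

    path = tmp_path / "m.json"
    models["ZP"].to_json(path)
    payload = json.loads(path.read_text())
    assert payload["response"] == "ZP"
    assert payload["n"] == 13 and payload["p"] == 6
    assert payload["sign"] == -1
    assert payload["coefficients"]["b1"] == pytest.approx(6.786, abs=0.001)
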