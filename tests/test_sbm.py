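import numpy as np
import pytest

from healtheff.malmquist import radial_distance
from healtheff.sbm import (DEAOptions, decompose_scale, efficiency_score,
                           solve_sbm_standard, solve_sbm_super)

from conftest import brute_force_sbm, make_panel, random_instance

TOL = 1e-6


@pytest.fixture
def ab_panel():
    # A dominates B on the input/output ratio
    return make_panel([[2], [4]], [[4], [4]])


class TestStandard:
    def test_frontier_unit_scores_one_with_zero_slacks(self, ab_panel):
        res = solve_sbm_standard(ab_panel, "A", 2015)
        assert res.score == 1.0
        assert res.slacks_zero

    def test_dominated_unit_analytic_score(self, ab_panel):
        # any feasible lambda gives (lam/2)/lam = 1/2
        res = solve_sbm_standard(ab_panel, "B", 2015)
        assert res.score == pytest.approx(0.5, abs=TOL)

    def test_undesirable_output_penalized(self):
        # P(1,1,1) vs Q(1,1,2): lam_P=1 leaves bad slack 1,
        # rho = 1 / (1 + (1/2)(1/2)) = 0.8
        d = make_panel([[1], [1]], [[1], [1]], [[1], [2]], units=["P", "Q"])
        res = solve_sbm_standard(d, "Q", 2015)
        assert res.score == pytest.approx(0.8, abs=TOL)

    def test_score_one_iff_zero_slacks(self, rng):
        for i in range(8):
            data = random_instance(rng)
            for unit in data.units:
                res = solve_sbm_standard(data, unit, 2015)
                assert (res.score == 1.0) == res.slacks_zero
                assert 0 < res.score <= 1.0

    def test_monotone_in_dominating_peer(self, rng):
        for _ in range(5):
            data = random_instance(rng, with_bads=False)
            unit = data.units[0]
            before = solve_sbm_standard(data, unit, 2015).score
            x_o, y_o, _ = data.xyb(unit, 2015)
            x = data.frame[list(data.inputs)].to_numpy()
            y = data.frame[list(data.outputs)].to_numpy()
            dom = make_panel(np.vstack([x, 0.8 * x_o]),
                             np.vstack([y, 1.2 * y_o]),
                             units=data.units + ["DOM"])
            after = solve_sbm_standard(dom, unit, 2015).score
            assert after <= before + TOL


class TestSuper:
    def test_super_score_of_frontier_unit(self, ab_panel):
        # objective equals 2 along the whole feasible lambda segment
        res = solve_sbm_super(ab_panel, "A", 2015)
        assert res.score == pytest.approx(2.0, abs=TOL)
        assert res.stage == "super"

    def test_identical_units_score_one(self):
        d = make_panel([[1], [1]], [[2], [2]])
        for unit in ("A", "B"):
            assert solve_sbm_super(d, unit, 2015).score == 1.0

    def test_single_unit_is_infeasible(self):
        d = make_panel([[1], [1]], [[1], [1]], units=["A", "A"],
                       periods=[2015, 2016])
        res = solve_sbm_super(d, "A", 2015)
        assert res.status == "infeasible"
        assert np.isnan(res.score)


class TestTwoStage:
    def test_composition(self, ab_panel):
        scores = {u: efficiency_score(ab_panel, u, 2015).score
                  for u in ("A", "B")}
        assert scores["A"] == pytest.approx(2.0, abs=TOL)
        assert scores["B"] == pytest.approx(0.5, abs=TOL)

    def test_all_identical_units_all_one(self):
        d = make_panel([[1], [1], [1]], [[1], [1], [1]])
        for u in d.units:
            assert efficiency_score(d, u, 2015).score == 1.0

    def test_super_disabled_caps_at_one(self, ab_panel):
        res = efficiency_score(ab_panel, "A", 2015, DEAOptions(super=False))
        assert res.score == 1.0 and res.stage == "standard"


class TestDecomposition:
    def test_crste_vrste_scale_analytic(self):
        # A(1,1), B(2,4): VRS convexity forces lam_A=1 -> vrste 1;
        # CRS frontier ray through B -> crste 0.5
        d = make_panel([[1], [2]], [[1], [4]])
        dec = decompose_scale(d, DEAOptions(super=False)).set_index("unit")
        assert dec.loc["A", "crste"] == pytest.approx(0.5, abs=TOL)
        assert dec.loc["A", "vrste"] == pytest.approx(1.0, abs=TOL)
        assert dec.loc["A", "scale"] == pytest.approx(0.5, abs=TOL)

    def test_proportional_units_fully_efficient(self):
        d = make_panel([[2], [4]], [[4], [8]])
        dec = decompose_scale(d, DEAOptions(super=False))
        assert np.allclose(dec[["crste", "vrste", "scale"]], 1.0, atol=TOL)

    def test_crs_never_exceeds_vrs_standard_stage(self, rng):
        for _ in range(5):
            data = random_instance(rng)
            dec = decompose_scale(data, DEAOptions(super=False))
            assert (dec["crste"] <= dec["vrste"] + TOL).all()
            assert ((dec["scale"] > 0) & (dec["scale"] <= 1 + TOL)).all()


class TestInvariance:
    def test_units_invariance(self, rng):
        # multiplying any single column by c > 0 leaves SBM scores unchanged
        data = random_instance(rng, with_bads=True)
        x = data.frame[list(data.inputs)].to_numpy().copy()
        y = data.frame[list(data.outputs)].to_numpy().copy()
        b = data.frame[list(data.bads)].to_numpy().copy()
        base = {u: efficiency_score(data, u, 2015).score for u in data.units}
        for arrs, col, c in [((x, y, b), 0, 7.3), ]:
            x2, y2, b2 = x.copy(), y.copy(), b.copy()
            x2[:, 0] *= c
            y2[:, 0] *= 0.013
            b2[:, 0] *= 410.0
            scaled = make_panel(x2, y2, b2, units=data.units)
            for u in data.units:
                assert efficiency_score(scaled, u, 2015).score == \
                    pytest.approx(base[u], abs=1e-6)

    def test_sbm_bounded_by_radial_efficiency(self, rng):
        # non-radial SBM is the more exacting measure: score <= the radial
        # CRS efficiency (1/phi* equals the input-oriented score under CRS)
        for _ in range(5):
            data = random_instance(rng, with_bads=False)
            for unit in data.units:
                sbm_score = solve_sbm_standard(data, unit, 2015).score
                radial = radial_distance(data, unit, 2015, 2015, "CRS").value
                assert sbm_score <= radial + 1e-6


class TestOracleAgreement:
    def test_lp_matches_fractional_minimizer(self, rng):
        # spot check; the full 50-instance sweep runs in the acceptance suite
        for i in range(6):
            data = random_instance(rng)
            for unit in data.units:
                lp = solve_sbm_standard(data, unit, 2015)
                bf = brute_force_sbm(data, unit, 2015, seed=i)
                assert lp.score == pytest.approx(bf, abs=1e-4)
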