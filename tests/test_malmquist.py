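import numpy as np
import pandas as pd
import pytest

from healtheff.malmquist import (malmquist_pair, malmquist_summary,
                                 malmquist_table, radial_distance)

from conftest import brute_force_output_distance, make_panel, random_instance


def two_period_panel(rng, n=4, m=2, q=1, drift=1.0):
    """Random units observed in two periods, outputs drifting by `drift`."""
    x = rng.uniform(0.5, 4.0, size=(n, m))
    y = rng.uniform(0.5, 4.0, size=(n, q))
    x2 = x * rng.uniform(0.9, 1.1, size=(n, m))
    y2 = y * drift * rng.uniform(0.9, 1.1, size=(n, q))
    return make_panel(np.vstack([x, x2]), np.vstack([y, y2]),
                      units=[chr(65 + i) for i in range(n)] * 2,
                      periods=[1] * n + [2] * n)


class TestRadialDistance:
    def test_self_reference_single_unit(self):
        d = make_panel([[1], [1]], [[1], [2]], units=["A", "A"],
                       periods=[1, 2])
        assert radial_distance(d, "A", 1, 1).value == pytest.approx(1.0)

    def test_point_above_frontier(self):
        # frontier {(1,1)}, evaluated (1,2): phi* = 1/2, D = 2
        d = make_panel([[1], [1]], [[1], [2]], units=["A", "A"],
                       periods=[1, 2])
        assert radial_distance(d, "A", 2, 1).value == pytest.approx(2.0)

    def test_cross_period_vrs_infeasible(self):
        # VRS convexity pins reference inputs above x_o while outputs
        # cannot reach the evaluated point: no feasible (phi, lam)
        d = make_panel([[5], [1]], [[1], [10]], units=["A", "A"],
                       periods=[1, 2])
        res = radial_distance(d, "A", 2, 1, rts="VRS")
        assert res.status == "infeasible" and np.isnan(res.value)

    def test_contemporaneous_crs_distance_bounded(self, rng):
        data = two_period_panel(rng)
        for period in (1, 2):
            vals = [radial_distance(data, u, period, period).value
                    for u in data.units]
            assert all(v <= 1 + 1e-7 for v in vals)
            assert max(vals) == pytest.approx(1.0, abs=1e-7)

    def test_matches_brute_force_phi_search(self, rng):
        for i in range(4):
            data = two_period_panel(rng, n=3)
            for unit in data.units:
                for fp in (1, 2):
                    lp = radial_distance(data, unit, 2, fp).value
                    bf = brute_force_output_distance(data, unit, 2, fp,
                                                     seed=i)
                    assert lp == pytest.approx(bf, abs=1e-4)


class TestMalmquistPair:
    def test_no_change_gives_unit_indices(self):
        d = make_panel([[1], [2], [1], [2]], [[1], [3], [1], [3]],
                       units=["A", "B", "A", "B"], periods=[1, 1, 2, 2])
        for unit in ("A", "B"):
            r = malmquist_pair(d, unit, 1, 2)
            for val in (r.mi, r.effch, r.techch, r.pech, r.sech):
                assert val == pytest.approx(1.0, abs=1e-7)

    def test_single_unit_output_doubling(self):
        d = make_panel([[1], [1]], [[1], [2]], units=["A", "A"],
                       periods=[1, 2])
        r = malmquist_pair(d, "A", 1, 2)
        assert r.mi == pytest.approx(2.0, abs=1e-6)
        assert r.effch == pytest.approx(1.0, abs=1e-6)
        assert r.techch == pytest.approx(2.0, abs=1e-6)

    def test_decomposition_identities_exact(self, rng):
        for _ in range(5):
            data = two_period_panel(rng, drift=float(rng.uniform(0.7, 1.4)))
            for unit in data.units:
                r = malmquist_pair(data, unit, 1, 2)
                if np.isfinite(r.mi):
                    assert r.mi == pytest.approx(r.effch * r.techch,
                                                 rel=1e-12)
                if np.isfinite(r.pech) and np.isfinite(r.sech):
                    assert r.effch == pytest.approx(r.pech * r.sech,
                                                    rel=1e-12)

    def test_period_swap_inverts_index(self, rng):
        data = two_period_panel(rng, drift=1.2)
        for unit in data.units:
            fwd = malmquist_pair(data, unit, 1, 2)
            bwd = malmquist_pair(data, unit, 2, 1)
            if np.isfinite(fwd.mi) and np.isfinite(bwd.mi):
                assert fwd.mi == pytest.approx(1.0 / bwd.mi, rel=1e-9)

    def test_proportional_frontier_shift_is_techch(self):
        # single unit, inputs fixed, outputs scaled by c: pure frontier shift
        c = 1.37
        d = make_panel([[1, 2], [1, 2]], [[2], [2 * c]], units=["A", "A"],
                       periods=[1, 2])
        r = malmquist_pair(d, "A", 1, 2)
        assert r.effch == pytest.approx(1.0, abs=1e-9)
        assert r.techch == pytest.approx(c, rel=1e-9)


class TestSummary:
    def test_geometric_mean_of_pairs(self):
        res = pd.DataFrame({
            "unit": ["A", "A"], "from_period": [1, 2], "to_period": [2, 3],
            "mi": [2.0, 0.5], "effch": [1.0, 1.0], "techch": [2.0, 0.5],
            "pech": [1.0, 1.0], "sech": [1.0, 1.0], "n_infeasible": [0, 0],
        })
        s = malmquist_summary(res, by="unit")
        assert s.loc[0, "mi"] == pytest.approx(1.0)

    def test_ranks_order_by_mean_mi_descending(self):
        res = pd.DataFrame({
            "unit": ["A", "B"], "from_period": [1, 1], "to_period": [2, 2],
            "mi": [1.2, 0.9], "effch": [1.0, 1.0], "techch": [1.2, 0.9],
            "pech": [1.0, 1.0], "sech": [1.0, 1.0], "n_infeasible": [0, 0],
        })
        s = malmquist_summary(res, by="unit").set_index("unit")
        assert s.loc["A", "rank"] == 1 and s.loc["B", "rank"] == 2

    def test_group_period_summary_with_total_row(self, rng):
        data = two_period_panel(rng)
        tab = malmquist_table(data)
        grouping = {u: ("G1" if i % 2 else "G2")
                    for i, u in enumerate(data.units)}
        s = malmquist_summary(tab, grouping=grouping, by="period")
        assert set(s["group"]) == {"G1", "G2", "All"}

    def test_identical_panels_all_unit_summaries(self):
        d = make_panel([[1], [2], [1], [2]], [[1], [3], [1], [3]],
                       units=["A", "B", "A", "B"], periods=[1, 1, 2, 2])
        s = malmquist_summary(malmquist_table(d), by="unit")
        for col in ("mi", "effch", "techch", "pech", "sech"):
            assert np.allclose(s[col], 1.0, atol=1e-7)
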