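import numpy as np
import pytest

from esnet.bands import ALPHA
from esnet.config import AnalysisConfig
from esnet.connectivity import WPLIMatrix, threshold_proportional
from esnet.suppression import (LocalOrderParameters, concentration_to_coupling,
                               dominant_region, edge_suppression,
                               local_order_parameters, suppression_strength,
                               suppression_timecourse)

from conftest import make_recording


def wmat(values):
    n = values.shape[0]
    return WPLIMatrix(values, [f"E{i+1}" for i in range(n)], 2, ALPHA)


def full_net(n):
    values = np.ones((n, n)) - np.eye(n)
    return threshold_proportional(wmat(values), 1.0)


class TestCoupling:
    def test_baseline(self):
        assert concentration_to_coupling(0.0) == 1.0

    def test_max_dose(self):
        assert concentration_to_coupling(1.0) == 0.0

    def test_half(self):
        assert concentration_to_coupling(0.5) == 0.5

    @pytest.mark.parametrize("c", [-0.1, 1.2])
    def test_out_of_range(self, c):
        with pytest.raises(ValueError):
            concentration_to_coupling(c)


class TestLocalOrderParameters:
    def test_mean_over_neighbors(self):
        values = np.zeros((4, 4))
        for j, v in ((1, 0.2), (2, 0.4), (3, 0.6)):
            values[0, j] = values[j, 0] = v
        values[1, 2] = values[2, 1] = 0.5
        values[1, 3] = values[3, 1] = 0.5
        values[2, 3] = values[3, 2] = 0.5
        r = local_order_parameters(wmat(values), full_net(4))
        assert r.r[0] == pytest.approx(0.4)

    def test_all_ones(self):
        values = np.ones((3, 3)) - np.eye(3)
        r = local_order_parameters(wmat(values), full_net(3))
        assert np.allclose(r.r, 1.0)

    def test_isolated_node_missing(self):
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = 0.8
        net = threshold_proportional(wmat(values), 1.0)
        net.adjacency[:, 2] = 0
        net.adjacency[2, :] = 0
        r = local_order_parameters(wmat(values), net)
        assert np.isnan(r.r[2])


class TestEdgeSuppression:
    def test_hand_check_suppressed(self):
        net = full_net(2)
        y = np.array([[0.0, 0.3], [0.3, 0.0]])
        r = LocalOrderParameters(np.array([0.2, 0.2]))
        res = edge_suppression(y, r, lam=0.5, net=net)
        assert res.s_edge[0] == pytest.approx(0.1)
        assert res.e_edge[0] == 1

    def test_hand_check_synchronizable(self):
        net = full_net(2)
        y = np.array([[0.0, 0.1], [0.1, 0.0]])
        r = LocalOrderParameters(np.array([0.3, 0.3]))
        res = edge_suppression(y, r, lam=1.0, net=net)
        assert res.s_edge[0] == pytest.approx(-0.5)
        assert res.e_edge[0] == 0

    def test_boundary_zero_is_non_suppressive(self):
        net = full_net(2)
        y = np.array([[0.0, 0.4], [0.4, 0.0]])
        r = LocalOrderParameters(np.array([0.2, 0.2]))
        res = edge_suppression(y, r, lam=1.0, net=net)
        assert res.s_edge[0] == pytest.approx(0.0)
        assert res.e_edge[0] == 0

    def test_missing_endpoint_rejected(self):
        net = full_net(2)
        y = np.array([[0.0, np.nan], [np.nan, 0.0]])
        r = LocalOrderParameters(np.array([0.2, 0.2]))
        with pytest.raises(ValueError):
            edge_suppression(y, r, lam=0.5, net=net)


class TestSuppressionStrength:
    def _star_result(self, statuses):
        # star: center 0 with 4 leaves
        values = np.zeros((5, 5))
        values[0, 1:] = values[1:, 0] = 0.5
        net = threshold_proportional(wmat(values), 4 / 10)
        res = edge_suppression(np.ones((5, 5)) * 0.5, LocalOrderParameters(np.full(5, 0.1)),
                               lam=1.0, net=net)
        res.e_edge = np.array(statuses)
        return res, net

    def test_three_of_four_suppressed(self):
        res, net = self._star_result([1, 1, 1, 0])
        out = suppression_strength(res, net, ["frontal"] * 5)
        assert out.s_node[0] == pytest.approx(0.75)

    def test_all_suppressed(self):
        res, net = self._star_result([1, 1, 1, 1])
        out = suppression_strength(res, net, ["frontal"] * 5)
        assert out.s_global == 1.0
        assert out.s_region["frontal"] == 1.0
        assert np.nanmax(out.s_node) == 1.0

    def test_none_suppressed(self):
        res, net = self._star_result([0, 0, 0, 0])
        out = suppression_strength(res, net, ["frontal"] * 5)
        assert out.s_global == 0.0

    def test_isolated_node_excluded(self):
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = 0.9
        net = threshold_proportional(wmat(values), 1 / 3)
        y = np.full((3, 3), 0.5)
        r = LocalOrderParameters(np.array([0.1, 0.1, np.nan]))
        res = edge_suppression(y, r, lam=0.1, net=net)
        out = suppression_strength(res, net, ["frontal"] * 3)
        assert np.isnan(out.s_node[2])
        assert out.s_global == 1.0  # mean over the two connected nodes only

    def test_conservation_edge_ends(self, rng):
        # sum_i L_i * S_i = 2 * (number of suppressed edges)
        values = rng.random((10, 10))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 0)
        net = threshold_proportional(wmat(values), 0.4)
        y = rng.random((10, 10))
        y = (y + y.T) / 2
        r = LocalOrderParameters(rng.random(10) * 0.3)
        res = edge_suppression(y, r, lam=0.5, net=net)
        out = suppression_strength(res, net, ["frontal"] * 10)
        deg = net.adjacency.sum(axis=1)
        lhs = np.nansum(deg * out.s_node)
        assert lhs == pytest.approx(2 * res.e_edge.sum())

    def test_relabeling_equivariance(self, rng):
        values = rng.random((8, 8))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 0)
        y = rng.random((8, 8))
        y = (y + y.T) / 2
        np.fill_diagonal(y, 0)
        rvals = rng.random(8) * 0.4

        def s_nodes(order):
            v = values[np.ix_(order, order)]
            net = threshold_proportional(wmat(v), 0.5)
            res = edge_suppression(y[np.ix_(order, order)],
                                   LocalOrderParameters(rvals[order]), 0.5, net)
            return suppression_strength(res, net, ["frontal"] * 8).s_node

        ident = s_nodes(np.arange(8))
        perm = rng.permutation(8)
        assert np.allclose(s_nodes(perm), ident[perm], equal_nan=True)

    def test_region_rule_both_vs_either(self):
        values = np.zeros((4, 4))
        values[0, 1] = values[1, 0] = 0.9   # frontal-frontal
        values[2, 3] = values[3, 2] = 0.9   # frontal-occipital
        net = threshold_proportional(wmat(values), 2 / 6)
        y = np.zeros((4, 4))
        y[0, 1] = y[1, 0] = 0.9
        r = LocalOrderParameters(np.full(4, 0.1))
        res = edge_suppression(y, r, lam=1.0, net=net)
        regions = ["frontal", "frontal", "frontal", "occipital"]
        either = suppression_strength(res, net, regions, "either")
        both = suppression_strength(res, net, regions, "both")
        # frontal: either-rule sees both edges (one suppressed), both-rule
        # sees only the frontal-frontal (suppressed) edge
        assert either.s_region["frontal"] == pytest.approx(0.5)
        assert both.s_region["frontal"] == pytest.approx(1.0)

    def test_monotone_in_c_and_single_switch(self, rng):
        values = rng.random((12, 12))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 0)
        net = threshold_proportional(wmat(values), 0.4)
        y = rng.random((12, 12)) * 0.6
        y = (y + y.T) / 2
        r = LocalOrderParameters(rng.random(12) * 0.5)
        prev_s, prev_e = -1.0, None
        for c in np.linspace(0, 1, 101):
            res = edge_suppression(y, r, concentration_to_coupling(c), net)
            out = suppression_strength(res, net, ["frontal"] * 12)
            assert out.s_global >= prev_s - 1e-12
            if prev_e is not None:
                assert np.all(res.e_edge >= prev_e)  # 0 -> 1 only
            prev_s, prev_e = out.s_global, res.e_edge


class TestDominantRegion:
    def test_argmax(self):
        assert dominant_region({"frontal": 0.2, "occipital": 0.8}) == "occipital"

    def test_tie_breaks_in_fixed_order(self):
        assert dominant_region({"occipital": 0.5, "frontal": 0.5}) == "frontal"

    def test_empty(self):
        assert dominant_region({}) is None


class TestTimecourse:
    def _session(self, c_mid):
        from esnet.session.annotation import SessionAnnotation
        from esnet.synth.protocol import SessionProtocol, simulate_session

        protocol = SessionProtocol(
            schedule=[(0.0, 0.0), (30.0, c_mid)], duration=60.0,
            n_channels=16, rate=250.0, seed=3)
        rec, ann, _ = simulate_session(protocol)
        return rec, ann

    def test_step_in_c_raises_s(self):
        rec, ann = self._session(1.0)
        cfg = AnalysisConfig()
        rows = suppression_timecourse(rec, ann, cfg)
        assert len(rows) == 6
        before = np.nanmean([r.s_global for r in rows[:3]])
        after = np.nanmean([r.s_global for r in rows[3:]])
        assert after > before

    def test_constant_zero_c_low_s(self):
        rec, ann = self._session(0.0)
        rows = suppression_timecourse(rec, ann, AnalysisConfig())
        s = np.array([r.s_global for r in rows])
        assert np.nanmax(s) < 0.15

    def test_artifact_window_flagged_missing(self):
        rec, ann = self._session(0.0)
        rec.samples[:, 250 * 35: 250 * 40] *= 200.0  # huge artifact in window 3
        rows = suppression_timecourse(rec, ann, AnalysisConfig())
        assert rows[3].flagged
        assert np.isnan(rows[3].s_global)

    def test_too_short_recording_rejected(self, rng):
        rec = make_recording(rng.standard_normal((4, 1000)), rate=250.0)
        from esnet.session.annotation import SessionAnnotation

        ann = SessionAnnotation(concentration=[(0.0, 0.0)],
                                responsiveness=[(0.0, 1.0)], duration=4.0)
        with pytest.raises(ValueError):
            suppression_timecourse(rec, ann, AnalysisConfig())
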