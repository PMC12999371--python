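"""ICER point estimation, quadrant bookkeeping, and the bootstrap wedge
arc, cross-checked against a literal slope-sort-and-conjoin oracle."""

import math

import numpy as np
import pytest

import cemeta as cm
from cemeta.wedge import BootstrapCloud, _quadrant_of_angle

from conftest import make_dataset

# counterclockwise quadrant cycle starting at angle -pi
CCW = ("SW", "SE", "NE", "NW")


def make_cloud(de, dc, seed=0, method="ratio"):
    de = np.asarray(de, float)
    dc = np.asarray(dc, float)
    counts = {q: 0 for q in CCW}
    for e, c in zip(de, dc):
        counts[_quadrant_of_angle(float(np.arctan2(c, e)) if np.arctan2(c, e) != np.pi else -np.pi)] += 1
    return BootstrapCloud(de, dc, B=de.size, seed=seed, method=method,
                          quadrant_counts=counts)


def conjoin_oracle(de, dc, level):
    """The literal wedge recipe: sort replicate slopes within each quadrant,
    conjoin adjacent occupied quadrants counterclockwise starting after the
    empty run, then count alpha/2*B in from each end."""
    de = np.asarray(de, float)
    dc = np.asarray(dc, float)
    B = de.size
    quads = []
    for e, c in zip(de, dc):
        th = np.arctan2(c, e)
        quads.append(_quadrant_of_angle(float(th) if th != np.pi else -np.pi))
    occupied = [q for q in CCW if q in quads]
    assert len(occupied) <= 3
    # rotate the cycle so it starts on the first occupied quadrant after an empty one
    start = next(i for i in range(4) if CCW[i] in occupied and CCW[i - 1] not in occupied)
    cycle = [CCW[(start + i) % 4] for i in range(4)]
    ordered = []
    for q in cycle:
        members = [i for i in range(B) if quads[i] == q]
        # within a quadrant, ascending slope == counterclockwise
        members.sort(key=lambda i: (dc[i] / de[i], i))
        ordered.extend(members)
    k = math.ceil(B * (1 - level) / 2 - 1e-9)
    cb_i, ccb_i = ordered[k - 1], ordered[B - k]
    return dc[cb_i] / de[cb_i], dc[ccb_i] / de[ccb_i]


class TestQuadrantClassification:
    @pytest.mark.parametrize(
        "de, dc, expected",
        [(0.025, -3362.0, "SE"), (-0.009, 371.0, "NW"), (2.0, 10.0, "NE"),
         (-1.0, -1.0, "SW"), (0.0, 0.0, "on_axis"), (0.0, 5.0, "on_axis")],
    )
    def test_sign_based(self, de, dc, expected):
        assert cm.classify_quadrant(de, dc) == expected

    def test_tricco_summary(self, tricco):
        assert cm.quadrant_summary(tricco) == {
            "NE": 5, "NW": 1, "SE": 10, "SW": 0, "on_axis": 0}

    def test_cost_negation_swaps_hemispheres(self, tricco):
        flipped = make_dataset(-tricco.delta_c, tricco.delta_e, tricco.n)
        c0, c1 = cm.quadrant_summary(tricco), cm.quadrant_summary(flipped)
        assert (c1["NE"], c1["SE"], c1["NW"], c1["SW"]) == (
            c0["SE"], c0["NE"], c0["SW"], c0["NW"])

    def test_permutation_invariance(self, tricco):
        rng = np.random.default_rng(5)
        perm = rng.permutation(tricco.M)
        shuffled = cm.MetaDataset(tuple(tricco.studies[i] for i in perm))
        assert cm.quadrant_summary(shuffled) == cm.quadrant_summary(tricco)


class TestICERPoint:
    def test_tricco_point(self, tricco):
        point = cm.icer_point(cm.pool_ratio(tricco, "cost"),
                              cm.pool_ratio(tricco, "effect"), wtp=50_000)
        assert round(point.slope) == -9332
        assert point.quadrant == "SE"
        assert point.decision == "dominant"

    def _pd(self, est, outcome):
        return cm.PooledDifference("ratio", outcome, est, 1.0, 10, est - 2, est + 2)

    def test_simple_ne_slope(self):
        p = cm.icer_point(self._pd(10.0, "cost"), self._pd(2.0, "effect"))
        assert p.slope == pytest.approx(5.0)
        assert p.quadrant == "NE"
        assert p.decision == "indeterminate"  # no WTP given

    def test_zero_denominator_warns_not_raises(self):
        with pytest.warns(UserWarning, match="unbounded"):
            p = cm.icer_point(self._pd(10.0, "cost"), self._pd(0.0, "effect"))
        assert p.slope == math.inf
        assert p.quadrant == "on_axis"

    @pytest.mark.parametrize(
        "dc, de, wtp, expected",
        [(10.0, 2.0, 50.0, "cost_effective_under_wtp"),
         (10.0, 2.0, 4.0, "not_cost_effective_under_wtp"),
         (-10.0, -2.0, 4.0, "cost_effective_under_wtp"),   # SW: saves 5 per unit forgone
         (-10.0, -2.0, 50.0, "not_cost_effective_under_wtp")],
    )
    def test_wtp_decisions(self, dc, de, wtp, expected):
        p = cm.icer_point(self._pd(dc, "cost"), self._pd(de, "effect"), wtp=wtp)
        assert p.decision == expected


class TestBootstrapCloud:
    def test_deterministic_given_seed(self, tricco):
        a = cm.bootstrap_cloud(tricco, "ratio", B=200, seed=42)
        b = cm.bootstrap_cloud(tricco, "ratio", B=200, seed=42)
        assert np.array_equal(a.delta_e, b.delta_e)
        assert np.array_equal(a.delta_c, b.delta_c)

    def test_mostly_southeast_on_tricco(self, tricco):
        cloud = cm.bootstrap_cloud(tricco, "ratio", B=500, seed=7)
        assert cloud.quadrant_counts["SE"] / 500 >= 0.95

    def test_identical_studies_collapse_to_point(self):
        ds = make_dataset([100.0] * 6, [0.2] * 6, [40] * 6)
        cloud = cm.bootstrap_cloud(ds, "ratio", B=100, seed=0)
        assert np.allclose(cloud.delta_c, 100.0)
        assert np.allclose(cloud.delta_e, 0.2)

    def test_ivw_method_requires_ses(self, tricco):
        with pytest.raises(ValueError, match="SE"):
            cm.bootstrap_cloud(tricco, "ivw_re", B=100, seed=0)

    def test_counts_sum_to_B(self, tricco):
        cloud = cm.bootstrap_cloud(tricco, "ratio_constant", B=150, seed=3)
        assert sum(cloud.quadrant_counts.values()) == 150


class TestWedgeArc:
    def test_single_quadrant_reduces_to_percentiles(self):
        rng = np.random.default_rng(0)
        de = rng.uniform(0.5, 2.0, 200)
        dc = rng.uniform(100.0, 5000.0, 200)  # all NE
        cloud = make_cloud(de, dc)
        point = cm.icer_point(
            cm.PooledDifference("ratio", "cost", float(np.median(dc)), 1.0, 10, 0, 1e5),
            cm.PooledDifference("ratio", "effect", float(np.median(de)), 1.0, 10, 0, 10),
        )
        arc = cm.wedge_ci(cloud, point, level=0.95)
        slopes = np.sort(dc / de)
        k = math.ceil(200 * 0.025)
        assert arc.cb_slope == pytest.approx(slopes[k - 1])
        assert arc.ccb_slope == pytest.approx(slopes[200 - k])
        assert arc.mode == "percentile_1to3_quadrants"
        assert arc.occupied_quadrants == ("NE",)

    def test_three_quadrant_hand_built_ordering(self):
        """A 12-point NW/NE/SE cloud: counterclockwise order runs SE steep
        -> SE flat -> NE -> NW, so at the 80% level (k=2) the bounds are the
        2nd replicate in from each end."""
        nw = [(-1.0, 1.0), (-1.0, 5.0), (-1.0, 97.0), (-1.0, 1000.0)]
        ne = [(1.0, 9999.0), (1.0, 864.0), (1.0, 2.0), (1.0, 1.0)]
        se = [(1.0, -1.0), (1.0, -50.0), (1.0, -400.0), (1.0, -10000.0)]
        de, dc = zip(*(se + ne + nw))
        cloud = make_cloud(de, dc)
        point = cm.icer_point(
            cm.PooledDifference("ratio", "cost", 5.0, 1.0, 10, 0, 10),
            cm.PooledDifference("ratio", "effect", 1.0, 1.0, 10, 0, 10),
        )
        arc = cm.wedge_ci(cloud, point, level=0.8)
        assert (arc.cb_slope, arc.cb_quadrant) == (-400.0, "SE")
        assert (arc.ccb_slope, arc.ccb_quadrant) == (-5.0, "NW")
        cb, ccb = conjoin_oracle(de, dc, 0.8)
        assert arc.cb_slope == pytest.approx(cb)
        assert arc.ccb_slope == pytest.approx(ccb)

    @pytest.mark.parametrize("seed", range(12))
    def test_gap_cut_equals_conjoin_oracle(self, seed):
        """Angular-gap algorithm vs the literal slope-sort-with-conjoining
        description on random arcs spanning up to three quadrants."""
        rng = np.random.default_rng(seed)
        center = rng.uniform(-np.pi, np.pi)
        span = rng.uniform(0.4, 2.2)
        th = center + (rng.beta(2, 2, 150) - 0.5) * span
        r = rng.lognormal(0, 0.6, 150)
        de, dc = r * np.cos(th), r * np.sin(th)
        cloud = make_cloud(de, dc)
        mean_th = center
        point = cm.icer_point(
            cm.PooledDifference("r", "cost", float(np.sin(mean_th)), 1.0, 10, -2, 2),
            cm.PooledDifference("r", "effect", float(np.cos(mean_th)), 1.0, 10, -2, 2),
        )
        arc = cm.wedge_ci(cloud, point, level=0.9)
        cb, ccb = conjoin_oracle(de, dc, 0.9)
        assert arc.cb_slope == pytest.approx(cb)
        assert arc.ccb_slope == pytest.approx(ccb)

    @pytest.mark.parametrize("seed", range(6))
    def test_cyclic_order_invariant_to_axis_rescaling(self, seed):
        """Separate positive rescaling of the cost and effect axes is a
        monotone circular map: the counterclockwise replicate order is
        unchanged, so the wedge bounds pick the same replicates."""
        rng = np.random.default_rng(seed + 100)
        th = rng.uniform(-0.3, 1.8, 120)  # SE through NE into NW
        de, dc = np.cos(th), np.sin(th)
        a, b = rng.uniform(0.2, 40.0, 2)
        cloud = make_cloud(de, dc)
        scaled = make_cloud(b * de, a * dc)
        point = cm.icer_point(
            cm.PooledDifference("r", "cost", float(np.mean(dc)), 1.0, 10, -2, 2),
            cm.PooledDifference("r", "effect", float(np.mean(de)), 1.0, 10, -2, 2),
        )
        point_s = cm.icer_point(
            cm.PooledDifference("r", "cost", a * float(np.mean(dc)), 1.0, 10, -2 * a, 2 * a),
            cm.PooledDifference("r", "effect", b * float(np.mean(de)), 1.0, 10, -2 * b, 2 * b),
        )
        arc = cm.wedge_ci(cloud, point, level=0.9)
        arc_s = cm.wedge_ci(scaled, point_s, level=0.9)
        # same replicates selected => slopes transform by a/b exactly
        assert arc_s.cb_slope == pytest.approx(arc.cb_slope * a / b)
        assert arc_s.ccb_slope == pytest.approx(arc.ccb_slope * a / b)

    def test_icer_scale_equivariance(self, tricco):
        k = 3.5
        scaled = make_dataset(k * tricco.delta_c, tricco.delta_e, tricco.n)
        pt = cm.icer_point(cm.pool_ratio(tricco, "cost"), cm.pool_ratio(tricco, "effect"))
        pt_s = cm.icer_point(cm.pool_ratio(scaled, "cost"), cm.pool_ratio(scaled, "effect"))
        assert pt_s.slope == pytest.approx(k * pt.slope)
        arc = cm.wedge_ci(cm.bootstrap_cloud(tricco, "ratio", 300, seed=5), pt)
        arc_s = cm.wedge_ci(cm.bootstrap_cloud(scaled, "ratio", 300, seed=5), pt_s)
        assert arc_s.cb_slope == pytest.approx(k * arc.cb_slope)
        assert arc_s.ccb_slope == pytest.approx(k * arc.ccb_slope)

    def test_arc_contains_point_and_nominal_mass(self, tricco):
        pt = cm.icer_point(cm.pool_ratio(tricco, "cost"), cm.pool_ratio(tricco, "effect"))
        cloud = cm.bootstrap_cloud(tricco, "ratio", 500, seed=2)
        arc = cm.wedge_ci(cloud, pt, level=0.95)
        assert arc.contained_fraction >= 0.95 - 1 / 500
        th_hat = np.arctan2(pt.delta_c_pooled, pt.delta_e_pooled)
        rel_hat = (th_hat - arc.cb_angle) % (2 * np.pi)
        rel_ccb = (arc.ccb_angle - arc.cb_angle) % (2 * np.pi)
        assert rel_hat <= rel_ccb

    def test_four_quadrant_mode_counts_inward(self):
        rng = np.random.default_rng(8)
        th = rng.uniform(-np.pi, np.pi, 400)
        de, dc = np.cos(th), np.sin(th)
        cloud = make_cloud(de, dc)
        point = cm.icer_point(
            cm.PooledDifference("r", "cost", 0.05, 1.0, 10, -2, 2),
            cm.PooledDifference("r", "effect", 0.05, 1.0, 10, -2, 2),
        )
        with pytest.warns(UserWarning, match="four quadrants"):
            arc = cm.wedge_ci(cloud, point, level=0.95)
        assert arc.mode == "inward_4_quadrants"
        assert not arc.informative
        assert len(arc.occupied_quadrants) == 4
        # excluded tail is antipodal to the point estimate
        th_hat = np.arctan2(0.05, 0.05)
        for bound in (arc.cb_angle, arc.ccb_angle):
            dev = abs((bound - th_hat + np.pi) % (2 * np.pi) - np.pi)
            assert dev > np.pi / 2

    def test_too_few_replicates_rejected(self):
        cloud = make_cloud([1.0] * 10, [2.0] * 10)
        point = cm.icer_point(
            cm.PooledDifference("r", "cost", 2.0, 1.0, 10, 0, 4),
            cm.PooledDifference("r", "effect", 1.0, 1.0, 10, 0, 2),
        )
        with pytest.raises(ValueError, match="replicates"):
            cm.wedge_ci(cloud, point, level=0.95)

    def test_origin_replicates_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        de = np.concatenate([rng.uniform(0.5, 1.5, 120), [0.0]])
        dc = np.concatenate([rng.uniform(10.0, 50.0, 120), [0.0]])
        cloud = make_cloud(de, dc)
        point = cm.icer_point(
            cm.PooledDifference("r", "cost", 25.0, 1.0, 10, 0, 60),
            cm.PooledDifference("r", "effect", 1.0, 1.0, 10, 0, 2),
        )
        with pytest.warns(UserWarning, match="origin"):
            arc = cm.wedge_ci(cloud, point, level=0.9)
        assert arc.B == 120


class TestTaylorICER:
    def test_finite_interval_around_tricco_icer(self, tricco):
        with pytest.warns(UserWarning, match="unreliable"):
            t = cm.taylor_icer_ci(tricco)
        assert t.ci_lower < -9332 < t.ci_upper
        assert np.isfinite(t.ci_lower) and np.isfinite(t.ci_upper)
        assert t.estimate == pytest.approx(-9331.71, abs=0.01)

    def test_identical_studies_zero_width(self):
        ds = make_dataset([-100.0] * 6, [0.5] * 6, [30] * 6)
        t = cm.taylor_icer_ci(ds)
        assert t.estimate == pytest.approx(-200.0)
        assert t.ci_upper - t.ci_lower == pytest.approx(0.0, abs=1e-9)

    def test_cost_sign_flip_negates_interval(self, tricco):
        flipped = make_dataset(-tricco.delta_c, tricco.delta_e, tricco.n)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t0 = cm.taylor_icer_ci(tricco)
            t1 = cm.taylor_icer_ci(flipped)
        assert t1.estimate == pytest.approx(-t0.estimate)
        assert t1.ci_lower == pytest.approx(-t0.ci_upper)
        assert t1.ci_upper == pytest.approx(-t0.ci_lower)
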