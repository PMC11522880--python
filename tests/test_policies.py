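import math

import pytest

from herdsim.geometry import GeometryError
from herdsim.policies import (
    POLICY_CATALOGUE,
    PolicySpec,
    angular_distance_ha_ta,
    collinear_clusters,
    policy_from_name,
    predict_order_from_initial,
    sca_select,
    select_next,
)


def at_bearing(bearing_deg, r):
    b = math.radians(bearing_deg)
    return (r * math.sin(b), r * math.cos(b))


def test_catalogue_has_twenty_policies():
    assert len(POLICY_CATALOGUE) == 20
    assert "successive_collinear_angle" in POLICY_CATALOGUE
    assert "furthest_from_containment_zone" in POLICY_CATALOGUE
    # names round-trip through the lookup
    for name, spec in POLICY_CATALOGUE.items():
        assert spec.name == name
        assert policy_from_name(name) == spec


def test_policy_spec_validation():
    with pytest.raises(ValueError):
        PolicySpec(timing="successive", criterion="distance_from_zone")
    with pytest.raises(ValueError):
        PolicySpec(timing="sometimes")
    with pytest.raises(ValueError):
        policy_from_name("nope")


@pytest.mark.parametrize("ha, ta, expected", [
    ((10.0, 0.0), (0.0, 10.0), 90.0),
    ((10.0, 0.0), (20.0, 0.0), 0.0),
    ((1.0, 1.0), (-1.0, 1.0), 90.0),
])
def test_angular_distance(ha, ta, expected):
    assert angular_distance_ha_ta(ha, ta) == pytest.approx(expected)


def test_angular_distance_degenerate():
    with pytest.raises(GeometryError):
        angular_distance_ha_ta((0.0, 0.0), (1.0, 1.0))


class TestCollinearClusters:
    def test_chain_partition(self):
        tas = [at_bearing(100, 20), at_bearing(110, 25), at_bearing(170, 30)]
        assert collinear_clusters(tas, 18.9) == [[0, 1], [2]]

    def test_all_singletons_above_threshold(self):
        tas = [at_bearing(0, 20), at_bearing(45, 20), at_bearing(120, 20)]
        assert collinear_clusters(tas, 18.9) == [[0], [1], [2]]

    def test_single_linkage_closure(self):
        tas = [at_bearing(0, 20), at_bearing(15, 25), at_bearing(30, 30)]
        # 0-15 and 15-30 both below 18.9, 0-30 above: one chain cluster
        assert collinear_clusters(tas, 18.9) == [[0, 1, 2]]

    def test_monotone_coarsening(self, rng):
        tas = [at_bearing(float(b), float(r))
               for b, r in zip(rng.uniform(-180, 180, 6),
                               rng.uniform(10, 40, 6))]
        for lo, hi in [(5.0, 15.0), (15.0, 40.0), (40.0, 120.0)]:
            fine = collinear_clusters(tas, lo)
            coarse = collinear_clusters(tas, hi)
            # every fine cluster is contained in some coarse cluster
            for c in fine:
                assert any(set(c) <= set(g) for g in coarse)

    def test_zero_threshold_never_clusters(self):
        tas = [at_bearing(10, 20), at_bearing(10.0001, 25)]
        assert collinear_clusters(tas, 0.0) == [[0], [1]]


class TestSelectNext:
    def test_single_target_trivial(self):
        for spec in POLICY_CATALOGUE.values():
            if spec.timing == "initial" and spec.criterion == "distance_from_zone":
                continue
            assert select_next(spec, (10.0, 10.0), [(0.0, 20.0)], [0]) == 0

    def test_closest_vs_furthest_angle(self):
        ha = at_bearing(0, 30)
        tas = [at_bearing(20, 25), at_bearing(160, 25)]
        near = PolicySpec("initial", "angle_from_herder", "closest")
        far = PolicySpec("initial", "angle_from_herder", "furthest")
        assert select_next(near, ha, tas, [0, 1]) == 0
        assert select_next(far, ha, tas, [0, 1]) == 1

    def test_cluster_prefers_farther_from_zone(self):
        # pair 10 degrees apart with radii 30 and 45: one cluster; the 45 m
        # member precedes even though angularly farther from the herder
        ha = at_bearing(-20, 30)
        tas = [at_bearing(0, 30.0), at_bearing(10, 45.0), at_bearing(120, 30.0)]
        assert sca_select(ha, tas, [0, 1, 2]) == 1

    def test_sca_reduces_to_closest_angle_without_clusters(self):
        ha = at_bearing(0, 30)
        tas = [at_bearing(40, 20), at_bearing(90, 25), at_bearing(-120, 30)]
        base = PolicySpec("successive", "angle_from_herder", "closest")
        assert sca_select(ha, tas, [0, 1, 2]) == \
            select_next(base, ha, tas, [0, 1, 2])

    def test_tie_broken_by_lower_id(self):
        ha = at_bearing(0, 30)
        tas = [at_bearing(30, 20), at_bearing(-30, 20)]
        spec = PolicySpec("initial", "angle_from_herder", "closest")
        assert select_next(spec, ha, tas, [0, 1]) == 0
        assert select_next(spec, ha, tas, [1]) == 1

    def test_no_remaining_errors(self):
        with pytest.raises(ValueError):
            sca_select((10.0, 0.0), [(0.0, 20.0)], [])


class TestPredictOrderInitial:
    def test_rank_by_zone_distance(self):
        tas = [at_bearing(0, 30), at_bearing(90, 10), at_bearing(180, 20)]
        far = policy_from_name("furthest_from_containment_zone")
        close = policy_from_name("closest_from_containment_zone")
        assert predict_order_from_initial(far, (5.0, 5.0), tas) == [0, 2, 1]
        assert predict_order_from_initial(close, (5.0, 5.0), tas) == [1, 2, 0]

    def test_collinear_zero_threshold_degenerates_to_base(self, rng):
        coll = POLICY_CATALOGUE["initial_collinear_angle"].with_threshold(0.0)
        base = policy_from_name("closest_angle_from_herder")
        for _ in range(20):
            tas = [at_bearing(float(b), float(r))
                   for b, r in zip(rng.uniform(-180, 180, 3),
                                   rng.uniform(8, 40, 3))]
            ha = at_bearing(float(rng.uniform(-180, 180)),
                            float(rng.uniform(10, 40)))
            assert predict_order_from_initial(coll, ha, tas) == \
                predict_order_from_initial(base, ha, tas)

    def test_cluster_concatenation_order(self):
        # cluster {near-pair} ranked first by its best member, ordered
        # far-from-zone first inside the cluster
        ha = at_bearing(-5, 30)
        tas = [at_bearing(5, 20), at_bearing(15, 35), at_bearing(100, 25)]
        sca_like = POLICY_CATALOGUE["initial_collinear_angle"]
        assert predict_order_from_initial(sca_like, ha, tas) == [1, 0, 2]

    def test_rotational_invariance(self, rng):
        spec = policy_from_name("closest_angle_from_herder")
        for _ in range(20):
            bearings = rng.uniform(-180, 180, 3)
            radii = rng.uniform(8, 40, 3)
            ha_b = float(rng.uniform(-180, 180))
            rot = float(rng.uniform(-180, 180))
            tas = [at_bearing(float(b), float(r))
                   for b, r in zip(bearings, radii)]
            tas_rot = [at_bearing(float(b + rot), float(r))
                       for b, r in zip(bearings, radii)]
            assert predict_order_from_initial(spec, at_bearing(ha_b, 25), tas) == \
                predict_order_from_initial(spec, at_bearing(ha_b + rot, 25), tas_rot)

    def test_permutation_invariant_output(self, rng):
        spec = policy_from_name("closest_distance_from_herder")
        tas = [at_bearing(float(b), float(r))
               for b, r in zip(rng.uniform(-180, 180, 4), rng.uniform(8, 40, 4))]
        order = predict_order_from_initial(spec, (10.0, 10.0), tas)
        assert sorted(order) == [0, 1, 2, 3]

    def test_non_initial_requires_log(self):
        with pytest.raises(ValueError):
            predict_order_from_initial(
                POLICY_CATALOGUE["successive_closest_angle_from_herder"],
                (10.0, 10.0), [(0.0, 20.0)])
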