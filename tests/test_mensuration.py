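import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cervimetrics import (
    CERVICAL_LEVELS,
    LEVEL_PAIRS,
    DegenerateGeometryError,
    GeneratorConfig,
    LandmarkSet,
    Point2D,
    VertebraQuad,
    apply_rigid_transform,
    compute_ara,
    compute_c1h,
    compute_ka,
    compute_rra,
    compute_st,
    compute_tr,
    endplate_line,
    generate_spine,
    measure_all,
    posterior_tangent,
    signed_angle,
)
from conftest import random_landmark_set

# ---------------------------------------------------------------------------
# Independent oracles: polar-angle differences for every rotational measure,
# a cross-product point-line distance for the translational one. These touch
# only raw corner coordinates, not the package's line constructions.
# ---------------------------------------------------------------------------


def wrap_deg(a):
    """Wrap an angle into (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def polar_angle(p_from, p_to):
    return math.degrees(math.atan2(p_to.y - p_from.y, p_to.x - p_from.x))


def oracle_rra(upper, lower):
    return wrap_deg(polar_angle(upper.pi, upper.ps) - polar_angle(lower.pi, lower.ps))


def oracle_ka(upper, lower):
    return wrap_deg(polar_angle(upper.pi, upper.ai) - polar_angle(lower.ps, lower.as_))


def oracle_st(upper, lower):
    """Signed point-line distance via the 2-D cross product."""
    d = np.array([lower.ps.x - lower.pi.x, lower.ps.y - lower.pi.y])
    v = np.array([upper.pi.x - lower.pi.x, upper.pi.y - lower.pi.y])
    cross = v[0] * d[1] - v[1] * d[0]
    return float(cross) / float(np.linalg.norm(d))


def oracle_c1h(atlas):
    return wrap_deg(polar_angle(atlas.post_laminar_mid, atlas.ant_tubercle))


class TestSignedAngle:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0.0, 1.0), (0.0, 1.0), 0.0),
            ((1.0, 0.0), (0.0, 1.0), 90.0),
            ((0.0, 1.0), (1.0, 0.0), -90.0),
            # quarter-precision hand oracle: atan2(cross, dot) for a 10 deg turn
            ((0.0, 1.0), (-math.sin(math.radians(10)), math.cos(math.radians(10))), 10.0),
            ((0.0, 1.0), (0.0, -1.0), 180.0),  # branch point folds to +180
        ],
    )
    def test_known_rotations(self, a, b, expected):
        assert signed_angle(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            signed_angle((0.0, 0.0), (1.0, 0.0))

    @settings(max_examples=200, derandomize=True)
    @given(
        t1=st.floats(-math.pi, math.pi, allow_nan=False),
        t2=st.floats(-math.pi, math.pi, allow_nan=False),
    )
    def test_antisymmetric_and_in_range(self, t1, t2):
        a = (math.cos(t1), math.sin(t1))
        b = (math.cos(t2), math.sin(t2))
        ang = signed_angle(a, b)
        assert -180.0 < ang <= 180.0
        if abs(ang) < 179.999:  # antisymmetry away from the branch point
            assert signed_angle(b, a) == pytest.approx(-ang, abs=1e-9)


class TestConstructionLines:
    def test_vertical_posterior_tangent(self):
        quad = VertebraQuad(
            label="C4", as_=Point2D(16, 10), ps=Point2D(0, 10), ai=Point2D(16, 0), pi=Point2D(0, 0)
        )
        line = posterior_tangent(quad)
        assert line.anchor == quad.pi
        assert line.direction == pytest.approx((0.0, 1.0))

    def test_oblique_tangent_is_normalized(self):
        quad = VertebraQuad(
            label="C4", as_=Point2D(15, 11), ps=Point2D(-1, 10), ai=Point2D(16, 0), pi=Point2D(0, 0)
        )
        d = posterior_tangent(quad).direction
        expected = np.array([-1.0, 10.0]) / np.linalg.norm([-1.0, 10.0])
        assert d == pytest.approx(tuple(expected), abs=1e-12)

    def test_endplate_lines_point_anteriorly(self):
        quad = VertebraQuad(
            label="C4", as_=Point2D(15, 12), ps=Point2D(0, 10), ai=Point2D(15, 0), pi=Point2D(0, 0)
        )
        inf = endplate_line(quad, "inferior")
        assert inf.direction == pytest.approx((1.0, 0.0))
        sup = endplate_line(quad, "superior")
        expected = np.array([15.0, 2.0]) / np.linalg.norm([15.0, 2.0])
        assert sup.direction == pytest.approx(tuple(expected), abs=1e-12)

    def test_unknown_endplate_name_rejected(self):
        quad = VertebraQuad(
            label="C4", as_=Point2D(16, 10), ps=Point2D(0, 10), ai=Point2D(16, 0), pi=Point2D(0, 0)
        )
        with pytest.raises(ValueError):
            endplate_line(quad, "middle")


class TestOracleEquivalence:
    """Every rotational measure must agree with an independent polar-angle
    oracle and the translational measure with a cross-product point-line
    oracle, on a large sample of random non-degenerate landmark sets."""

    N_SETS = 1000

    def test_all_measures_match_oracles(self, rng):
        for i in range(self.N_SETS):
            lset = random_landmark_set(rng, image_id=f"o{i}")
            quads = lset.vertebrae
            assert compute_ara(lset) == pytest.approx(
                wrap_deg(
                    polar_angle(quads["C2"].pi, quads["C2"].ps)
                    - polar_angle(quads["C7"].pi, quads["C7"].ps)
                ),
                abs=1e-9,
            )
            assert compute_c1h(lset.atlas) == pytest.approx(oracle_c1h(lset.atlas), abs=1e-9)
            for upper_lvl, lower_lvl in zip(CERVICAL_LEVELS, CERVICAL_LEVELS[1:]):
                u, l = quads[upper_lvl], quads[lower_lvl]
                assert compute_rra(u, l) == pytest.approx(oracle_rra(u, l), abs=1e-9)
                assert compute_ka(u, l) == pytest.approx(oracle_ka(u, l), abs=1e-9)
                assert compute_st(u, l) == pytest.approx(oracle_st(u, l), abs=1e-9)

    def test_c1h_hand_value(self):
        from cervimetrics import AtlasLandmarks

        atlas = AtlasLandmarks(
            ant_tubercle=Point2D(40.0, 1.0),
            dens_post_mid=Point2D(20.0, 0.5),
            post_laminar_mid=Point2D(0.0, 0.0),
        )
        assert compute_c1h(atlas) == pytest.approx(math.degrees(math.atan(1 / 40)), abs=1e-9)
        assert compute_c1h(atlas) == pytest.approx(1.4321, abs=5e-5)


class TestInvariants:
    def test_telescoping_ara_equals_sum_of_rras(self, rng):
        for i in range(1000):
            lset = random_landmark_set(rng, image_id=f"t{i}", with_atlas=False)
            m = measure_all(lset)
            rra_sum = sum(m[f"RRA{p}"] for p in LEVEL_PAIRS)
            assert abs(m["ARA"] - rra_sum) <= 1e-9

    def test_rigid_motion_invariance(self, rng):
        for i in range(200):
            lset = random_landmark_set(rng, image_id=f"r{i}")
            rot = float(rng.uniform(-45, 45))
            trans = (float(rng.uniform(-100, 100)), float(rng.uniform(-100, 100)))
            moved = apply_rigid_transform(lset, rotation_deg=rot, translation=trans)
            m0, m1 = measure_all(lset), measure_all(moved)
            for p in LEVEL_PAIRS:
                for var in (f"RRA{p}", f"KA{p}", f"ST{p}"):
                    assert abs(m1[var] - m0[var]) <= 1e-9, var
            assert abs(m1["ARA"] - m0["ARA"]) <= 1e-9
            # the horizontal-reference measures are equivariant, not invariant
            assert m1["C1H"] - m0["C1H"] == pytest.approx(rot, abs=1e-9)

    def test_translation_leaves_horizontal_measures_unchanged(self, rng):
        lset = random_landmark_set(rng)
        moved = apply_rigid_transform(lset, translation=(31.0, -17.0))
        m0, m1 = measure_all(lset), measure_all(moved)
        assert m1["TR"] == pytest.approx(m0["TR"], abs=1e-9)
        assert m1["C1H"] == pytest.approx(m0["C1H"], abs=1e-9)

    def test_uniform_scaling_scales_distances_not_angles(self, rng):
        lset = random_landmark_set(rng)
        scaled = apply_rigid_transform(lset, scale=2.5)
        m0, m1 = measure_all(lset), measure_all(scaled)
        for name, v in m1.to_dict().items():
            if name.startswith("ST") or name == "TR":
                assert v == pytest.approx(2.5 * m0[name], abs=1e-9)
            else:
                assert v == pytest.approx(m0[name], abs=1e-9)

    def test_measure_all_is_deterministic(self, rng):
        lset = random_landmark_set(rng)
        a, b = measure_all(lset), measure_all(lset)
        assert a.to_dict() == b.to_dict()  # bit-identical, no tolerance


class TestMeasureAll:
    def test_complete_set_yields_18_finite_values(self, rng):
        m = measure_all(random_landmark_set(rng))
        values = m.to_dict()
        assert len(values) == 18
        assert all(v is not None and math.isfinite(v) for v in values.values())

    def test_missing_atlas_reports_c1h_missing(self, rng):
        m = measure_all(random_landmark_set(rng, with_atlas=False))
        values = m.to_dict()
        assert values["C1H"] is None
        finite = [v for v in values.values() if v is not None]
        assert len(finite) == 17

    def test_missing_vertebra_propagates_to_its_measures(self, rng):
        full = random_landmark_set(rng)
        partial = LandmarkSet(
            image_id=full.image_id,
            vertebrae={k: v for k, v in full.vertebrae.items() if k != "C4"},
            atlas=full.atlas,
        )
        m = measure_all(partial)
        assert m["RRA34"] is None and m["RRA45"] is None
        assert m["KA34"] is None and m["ST45"] is None
        assert m["ARA"] is not None  # C2 and C7 still present

    def test_parallelogram_bodies_make_ka_equal_rra(self, rng):
        # zero endplate wedge => each body is a parallelogram => the facing
        # endplates reproduce the posterior-tangent geometry exactly
        cfg = GeneratorConfig(n_images=1, seed=0)
        for i in range(50):
            lset, _ = generate_spine(
                cfg,
                image_id=f"p{i}",
                ara=float(rng.normal(20, 10)),
                base_tilt=float(rng.normal(0, 5)),
                weights=rng.dirichlet(np.full(5, 30.0)),
                translations={p: float(rng.normal(0, 1)) for p in LEVEL_PAIRS},
            )
            m = measure_all(lset)
            for p in LEVEL_PAIRS:
                assert m[f"KA{p}"] == pytest.approx(m[f"RRA{p}"], abs=1e-9)

    def test_straight_stacked_translation_example(self):
        """Two square bodies stacked vertically, upper shifted 2 mm anterior:
        ST is exactly +2 and the segmental angles are zero."""
        lower = VertebraQuad(
            label="C5", as_=Point2D(16, 11), ps=Point2D(0, 11), ai=Point2D(16, 0), pi=Point2D(0, 0)
        )
        upper = VertebraQuad(
            label="C4",
            as_=Point2D(18, 27),
            ps=Point2D(2, 27),
            ai=Point2D(18, 16),
            pi=Point2D(2, 16),
        )
        assert compute_st(upper, lower) == pytest.approx(2.0, abs=1e-12)
        assert compute_rra(upper, lower) == pytest.approx(0.0, abs=1e-12)
        assert compute_ka(upper, lower) == pytest.approx(0.0, abs=1e-12)

    def test_tr_is_x_offset(self):
        quads = {}
        for level, y0 in zip(CERVICAL_LEVELS, range(80, -1, -16)):
            x0 = 15.0 if level == "C2" else 0.0
            quads[level] = VertebraQuad(
                label=level,
                as_=Point2D(x0 + 16, y0 + 11),
                ps=Point2D(x0, y0 + 11),
                ai=Point2D(x0 + 16, y0),
                pi=Point2D(x0, y0),
            )
        lset = LandmarkSet(image_id="tr", vertebrae=quads)
        assert compute_tr(lset) == pytest.approx(15.0, abs=1e-12)
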