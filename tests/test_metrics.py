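import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from osteoreduce.errors import RegistrationError
from osteoreduce.landmarks import Axis, LandmarkSet, OrientedCube
from osteoreduce.metrics import (
    METRIC_INFO,
    MetricVector,
    RhoConfig,
    angle_between_axes,
    compute_metric_vector,
    compute_rho,
    cube_overlap,
    register_template,
    rotation_triangle_area,
)
from osteoreduce.transforms import RigidTransform


def synthetic_landmarks(**overrides) -> LandmarkSet:
    """Hand-coordinate landmark set resembling a right humerus."""
    base = dict(
        head_center=np.array([-4.0, -4.0, 280.0]),
        bicipital_groove=np.array([1.5, 7.0, 234.0]),
        trochlea_center=np.array([-11.0, 0.0, 0.0]),
        capitulum_center=np.array([11.0, 0.0, 0.0]),
        medial_epicondyle=np.array([-31.0, 0.0, 5.0]),
        lateral_epicondyle=np.array([31.0, 0.0, 5.0]),
        head_radius=24.0,
        hsa=Axis([0.0, 0.0, 0.0], [0.0, 0.0, 1.0]),
    )
    base.update(overrides)
    return LandmarkSet.from_primary(**base)


def random_rigid(rng) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    rot = Rotation.from_rotvec(rng.uniform(0, np.pi) * axis)
    return RigidTransform.from_rotation(rot, rng.normal(scale=30, size=3))


class TestAngles:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 0, 0], [1, 0, 0], 0.0),
            ([1, 0, 0], [0, 1, 0], 90.0),
            ([1, 0, 0], [-1 / np.sqrt(2), 1 / np.sqrt(2), 0], 45.0),
        ],
    )
    def test_analytic_cases(self, a, b, expected):
        assert angle_between_axes(np.array(a, float), np.array(b, float)) == (
            pytest.approx(expected, abs=1e-9)
        )

    def test_zero_direction_raises(self):
        with pytest.raises(ValueError):
            angle_between_axes(np.zeros(3), np.array([1.0, 0, 0]))


class TestRegistration:
    def test_aligned_template_gives_identity(self):
        lm = synthetic_landmarks()
        rt = register_template(lm, lm)
        assert rt.is_identity(tol=1e-9)

    def test_known_transform_is_recovered(self):
        lm = synthetic_landmarks()
        rng = np.random.default_rng(4)
        moved = lm.transformed(random_rigid(rng))
        rt = register_template(lm, moved)
        back = moved.transformed(rt)
        for name in ("head_center", "bicipital_groove", "trochlea_center"):
            assert np.linalg.norm(getattr(back, name) - getattr(lm, name)) < 1e-6

    def test_rotation_is_always_proper(self):
        rng = np.random.default_rng(5)
        lm = synthetic_landmarks()
        for _ in range(10):
            rt = register_template(lm, lm.transformed(random_rigid(rng)))
            assert np.linalg.det(rt.rotation.as_matrix()) == pytest.approx(
                1.0, abs=1e-9
            )

    def test_collinear_anchor_raises(self):
        # groove placed on the HSA through the head -> collinear triplet
        lm = synthetic_landmarks(
            head_center=np.array([0.0, 0.0, 280.0]),
            bicipital_groove=np.array([0.0, 0.0, 234.0]),
        )
        with pytest.raises(RegistrationError):
            register_template(lm, lm)


class TestCubeOverlap:
    def test_identical_cubes(self):
        c = OrientedCube(np.zeros(3), np.eye(3), 2.0)
        assert cube_overlap(c, c, 0.05) == 1.0

    def test_disjoint_cubes(self):
        a = OrientedCube(np.zeros(3), np.eye(3), 1.0)
        b = OrientedCube(np.array([3.0, 0, 0]), np.eye(3), 1.0)
        assert cube_overlap(a, b, 0.02) == 0.0

    def test_half_shifted_unit_cubes(self):
        a = OrientedCube(np.zeros(3), np.eye(3), 1.0)
        b = OrientedCube(np.array([0.5, 0.0, 0.0]), np.eye(3), 1.0)
        assert cube_overlap(a, b, 1.0 / 50) == pytest.approx(1 / 3, abs=0.02)

    def test_pitch_validation(self):
        c = OrientedCube(np.zeros(3), np.eye(3), 1.0)
        with pytest.raises(ValueError):
            cube_overlap(c, c, 0.5)


class TestRotationTriangle:
    def test_identical_sides_give_zero(self):
        lm = synthetic_landmarks()
        assert rotation_triangle_area(lm, lm) == 0.0

    def test_analytic_area_difference(self):
        # apex is shifted off the FEA line so triangles have analytic areas
        a = synthetic_landmarks(hsa=Axis([0.0, 5.0, 0.0], [0.0, 0.0, 1.0]))
        b = synthetic_landmarks(
            hsa=Axis([0.0, 5.0, 0.0], [0.0, 0.0, 1.0]),
            trochlea_center=np.array([-22.0, 0.0, 0.0]),
            capitulum_center=np.array([22.0, 0.0, 0.0]),
        )
        # base 22, height 5 -> 55; base 44, height 5 -> 110
        assert rotation_triangle_area(a, b) == pytest.approx(55.0, abs=1e-9)

    def test_rigidly_moved_identical_sets_give_zero(self):
        lm = synthetic_landmarks(hsa=Axis([0.0, 5.0, 0.0], [0.0, 0.0, 1.0]))
        moved = lm.transformed(random_rigid(np.random.default_rng(6)))
        assert rotation_triangle_area(lm, moved) < 1e-6


class TestMetricVector:
    def test_identical_bones_are_perfect(self):
        lm = synthetic_landmarks()
        mv = compute_metric_vector(lm, lm)
        for name, value in mv.as_dict().items():
            if name.endswith("overlap"):
                assert value == 1.0
            else:
                assert value == pytest.approx(0.0, abs=1e-9)

    def test_five_degree_distal_rotation_reads_on_eca(self):
        lm = synthetic_landmarks()
        rot = RigidTransform.from_rotvec_deg([0, 0, 1], 5.0)
        mv = compute_metric_vector(_rotate_distal(lm, rot), lm)
        assert mv.angle_eca_deg == pytest.approx(5.0, abs=0.5)
        assert mv.head_mm < 1e-9

    def test_three_mm_distal_translation_reads_on_distances(self):
        lm = synthetic_landmarks()
        shift = RigidTransform(translation=np.array([3.0, 0.0, 0.0]))
        mv = compute_metric_vector(_shift_distal(lm, shift), lm)
        for name in ("trochlea_mm", "capitulum_mm", "medial_epicondyle_mm",
                     "lateral_epicondyle_mm"):
            assert getattr(mv, name) == pytest.approx(3.0, abs=0.3)
        for name in ("angle_hsa_deg", "angle_eca_deg", "angle_fea_deg"):
            assert getattr(mv, name) < 0.5

    def test_rigid_invariance(self):
        """Moving both bones together leaves every metric unchanged."""
        reduced = synthetic_landmarks()
        template = _rotate_distal(
            synthetic_landmarks(), RigidTransform.from_rotvec_deg([0, 1, 0], 3.0)
        )
        mv0 = compute_metric_vector(reduced, template)
        rt = random_rigid(np.random.default_rng(8))
        mv1 = compute_metric_vector(reduced.transformed(rt), template.transformed(rt))
        for name, v0 in mv0.as_dict().items():
            assert abs(mv1.as_dict()[name] - v0) < 1e-6, name


def _rotate_distal(lm: LandmarkSet, rt: RigidTransform) -> LandmarkSet:
    """Apply a transform to the distal landmarks only (simulated malreduction)."""
    return LandmarkSet.from_primary(
        head_center=lm.head_center,
        bicipital_groove=lm.bicipital_groove,
        trochlea_center=rt.apply(lm.trochlea_center),
        capitulum_center=rt.apply(lm.capitulum_center),
        medial_epicondyle=rt.apply(lm.medial_epicondyle),
        lateral_epicondyle=rt.apply(lm.lateral_epicondyle),
        head_radius=lm.head_radius,
        hsa=lm.hsa,
    )


_shift_distal = _rotate_distal


class TestRho:
    def test_perfect_vector_scores_one(self):
        lm = synthetic_landmarks()
        assert compute_rho(compute_metric_vector(lm, lm)) == pytest.approx(1.0)

    def test_all_deviations_at_tolerance_score_zero(self):
        values = {}
        cfg = RhoConfig()
        for name in METRIC_INFO:
            if name.endswith("overlap"):
                values[name] = 0.0
            else:
                values[name] = cfg.tolerances[name]
        assert compute_rho(MetricVector(**values), cfg) == 0.0

    def test_hand_arithmetic_example(self):
        """13 perfect metrics, trochlea at half tolerance, distal overlap 0.9."""
        values = {name: 0.0 for name in METRIC_INFO}
        values["distal_overlap"] = 0.9
        values["proximal_overlap"] = 1.0
        values["trochlea_mm"] = 5.0
        rho = compute_rho(MetricVector(**values))
        assert rho == pytest.approx((13 + 0.5 + 0.9) / 15)

    def test_bounds_and_perfection_condition(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            values = {
                name: (rng.uniform(0, 1) if name.endswith("overlap")
                       else rng.uniform(0, 30))
                for name in METRIC_INFO
            }
            mv = MetricVector(**values)
            rho = compute_rho(mv)
            assert 0.0 <= rho <= 1.0
            deviations_zero = all(
                v == 0 for k, v in values.items() if not k.endswith("overlap")
            )
            overlaps_one = all(
                v == 1 for k, v in values.items() if k.endswith("overlap")
            )
            assert (rho == 1.0) == (deviations_zero and overlaps_one)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.sampled_from(sorted(METRIC_INFO)),
    )
    def test_monotonicity_in_every_metric(self, seed, name):
        """rho never improves when a deviation grows or an overlap shrinks."""
        rng = np.random.default_rng(seed)
        values = {
            k: (rng.uniform(0, 1) if k.endswith("overlap") else rng.uniform(0, 15))
            for k in METRIC_INFO
        }
        rho0 = compute_rho(MetricVector(**values))
        worse = dict(values)
        if name.endswith("overlap"):
            worse[name] = values[name] * rng.uniform(0, 1)
        else:
            worse[name] = values[name] + rng.uniform(0.1, 10)
        rho1 = compute_rho(MetricVector(**worse))
        assert rho1 <= rho0 + 1e-12


class TestMirrorConsistency:
    def test_exact_mirror_pair_perfectly_reduced(
        self, displaced_state, template_landmarks
    ):
        """Mirror pair + perfect reduction -> rho = 1 within 1e-3."""
        from osteoreduce.fracture import apply_move
        from osteoreduce.landmarks import detect_landmarks

        st = apply_move(
            displaced_state, "distal", displaced_state.truth_displacement.inverse()
        )
        reduced = detect_landmarks(st.reassembled_mesh())
        mv = compute_metric_vector(reduced, template_landmarks)
        assert compute_rho(mv) == pytest.approx(1.0, abs=1e-3)
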