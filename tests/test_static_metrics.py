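"""The six static measurement procedures."""
import numpy as np
import pytest

from conftest import random_rigid
from stiflemetrics import measure_limb
from stiflemetrics.anatomy import AnatomicalFrame, LandmarkSet, build_frame
from stiflemetrics.errors import (
    DegenerateGeometryError,
    DegenerateTuberosityError,
    IncompleteProfileError,
)
from stiflemetrics.geometry import Line3, angle_between_directions
from stiflemetrics.static_metrics import (
    METRIC_FIELDS,
    assemble_limb_metrics,
    extensor_line_of_action,
    femoral_length,
    flexion_angle,
    moment_arm,
    moment_arm_torque_effective,
    pennation_angle,
    tibial_length,
    tp_tt_metrics,
    transepicondylar_axis,
)
from stiflemetrics.synthetic import SyntheticLimbSpec, generate_limb

CANONICAL_FRAME = AnatomicalFrame((0, 0, 0), (0, 1, 0), (0, 0, 1), (1, 0, 0))


class TestSegmentLengths:
    def test_femoral_length_in_sagittal_plane(self):
        lms = LandmarkSet({
            "greater_trochanter": [0, 0, 196.1],
            "intercondylar_notch": [0, 0, 0],
        })
        assert femoral_length(lms, CANONICAL_FRAME) == pytest.approx(196.1)
        # a lateral offset is invisible on the sagittal plane
        lms.points["greater_trochanter"] = np.array([[30.0, 0.0, 196.1]])
        assert femoral_length(lms, CANONICAL_FRAME) == pytest.approx(196.1)

    def test_femoral_length_zero_when_along_normal(self):
        lms = LandmarkSet({
            "greater_trochanter": [25, 0, 0],
            "intercondylar_notch": [0, 0, 0],
        })
        assert femoral_length(lms, CANONICAL_FRAME) == pytest.approx(0.0)

    def test_tibial_length_in_coronal_plane(self):
        lms = LandmarkSet({
            "tibial_plateau_ref": [0, 0, 0],
            "lateral_malleolus": [0, 0, -395.5],
        })
        assert tibial_length(lms, CANONICAL_FRAME) == pytest.approx(395.5)
        lms.points["lateral_malleolus"] = np.array([[0.0, 0.0, 0.0]])
        assert tibial_length(lms, CANONICAL_FRAME) == pytest.approx(0.0)

    def test_synthetic_lengths_exact(self, default_limb, default_measurement):
        metrics, _ = default_measurement
        assert metrics.fl == pytest.approx(default_limb.truth.fl, abs=1e-6)
        assert metrics.tl == pytest.approx(default_limb.truth.tl, abs=1e-6)


class TestFlexionAngle:
    def _lms(self, f, t):
        return LandmarkSet({
            "femur_midshaft_proximal": f,
            "knee_center": [0, 0, 0],
            "tibia_midshaft_distal": t,
        })

    def test_right_angle(self):
        lms = self._lms([0, 0, 200], [0, 300, 0])
        assert flexion_angle(lms, CANONICAL_FRAME) == pytest.approx(90.0)

    def test_full_extension_is_180(self):
        lms = self._lms([0, 0, 200], [0, 0, -300])
        assert flexion_angle(lms, CANONICAL_FRAME) == pytest.approx(180.0)

    def test_matches_projected_dot_product_oracle(self, rng):
        for _ in range(100):
            f, t = rng.uniform(-100, 100, size=(2, 3))
            if min(np.linalg.norm(f[1:]), np.linalg.norm(t[1:])) < 1e-2:
                continue
            lms = self._lms(f, t)
            fp = f * np.array([0.0, 1.0, 1.0])  # drop the sagittal-normal (x) part
            tp = t * np.array([0.0, 1.0, 1.0])
            assert flexion_angle(lms, CANONICAL_FRAME) == pytest.approx(
                angle_between_directions(fp, tp), abs=1e-9
            )

    def test_degenerate_projection_rejected(self):
        lms = self._lms([50, 0, 0], [0, 300, 0])  # femur point projects onto knee
        with pytest.raises(DegenerateGeometryError):
            flexion_angle(lms, CANONICAL_FRAME)


class TestMomentArm:
    def test_transepicondylar_axis_through_sulci(self):
        lms = LandmarkSet({"medial_sulcus": [-20, 0, 0], "lateral_sulcus": [20, 0, 0]})
        axis = transepicondylar_axis(lms)
        np.testing.assert_allclose(axis.point, (-20, 0, 0))
        np.testing.assert_allclose(axis.direction, (1, 0, 0))

    def test_axis_rigid_equivariance(self, rng):
        lms = LandmarkSet({"medial_sulcus": [-20, 1, 2], "lateral_sulcus": [20, 3, 4]})
        axis = transepicondylar_axis(lms)
        r, t = random_rigid(rng)
        moved = transepicondylar_axis(lms.transformed(r, t))
        np.testing.assert_allclose(moved.point, r @ axis.point + t, atol=1e-9)
        np.testing.assert_allclose(moved.direction, r @ axis.direction, atol=1e-9)

    def test_constructed_value_and_symmetry(self):
        axis = Line3((0, 0, 0), (1, 0, 0))
        loa = Line3((0, 0, 28.9), (0, 1, 0))
        assert moment_arm(axis, loa) == pytest.approx(28.9)
        assert moment_arm(loa, axis) == pytest.approx(28.9)
        crossing = Line3((0, 0, 0), (0, 1, 1))
        assert moment_arm(axis, crossing) == pytest.approx(0.0, abs=1e-12)

    def test_torque_effective_arm_orthogonal_case(self):
        axis = Line3((0, 0, 0), (1, 0, 0))
        loa = Line3((0, 0, 28.9), (0, 1, 0))
        assert moment_arm_torque_effective(axis, loa) == pytest.approx(28.9)

    def test_line_of_action_straight_strap(self):
        z = np.linspace(0, 100, 8)
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        pts = np.vstack([pts + [1, 0, 0], pts - [1, 0, 0]])  # strap with width
        lms = LandmarkSet({"extensor_path_points": pts})
        loa = extensor_line_of_action(lms)
        assert abs(abs(loa.direction[2]) - 1.0) < 1e-9

    def test_line_of_action_within_fitted_plane(self, rng):
        # curved but coplanar path: the direction stays in the fitted plane
        u = np.linspace(-1, 1, 12)
        pts = np.column_stack([u * 40, np.zeros_like(u), 50 * u**2])
        lms = LandmarkSet({"extensor_path_points": pts})
        loa = extensor_line_of_action(lms)
        assert abs(loa.direction @ np.array([0.0, 1.0, 0.0])) < 1e-9

    def test_synthetic_moment_arm_exact(self, default_limb, default_measurement):
        metrics, _ = default_measurement
        assert metrics.moment_arm == pytest.approx(
            default_limb.truth.moment_arm, rel=1e-9
        )


class TestTpTtMetrics:
    def test_constructed_example(self):
        # cortex-to-apex 30 mm, cortex-to-plateau 54 mm, TL 400 mm
        spec = SyntheticLimbSpec(tl_true=400.0, tt_projection=30.0, plateau_depth=54.0)
        limb = generate_limb(spec, with_mask=False)
        frame = build_frame(limb.landmarks)
        res = tp_tt_metrics(limb.tibia, limb.landmarks, frame, 400.0)
        assert res.d1 == pytest.approx(30.0, abs=1e-9)
        assert res.d2 == pytest.approx(54.0, abs=1e-9)
        assert res.tp_tt_ratio == pytest.approx(1.8, abs=1e-9)
        assert res.tt_projection_index == pytest.approx(7.5, abs=1e-9)

    def test_apex_on_cortex_plane_rejected(self, default_limb):
        lms = default_limb.landmarks
        frame = build_frame(lms)
        apex = lms.get("tt_anterior_region")[0]
        bad = LandmarkSet(dict(lms.points), side=lms.side)
        bad.points["anterior_cortex_ref"] = np.array([[0.0, apex[1], -10.0]])
        with pytest.raises(DegenerateTuberosityError):
            tp_tt_metrics(default_limb.tibia, bad, frame, 400.0)

    def test_translation_along_anterior_axis_preserves_d1_d2(self, default_limb):
        lms = default_limb.landmarks
        frame = build_frame(lms)
        res = tp_tt_metrics(default_limb.tibia, lms, frame, 400.0)
        shift = np.array([0.0, 25.0, 0.0])  # anterior translation of the tibia
        moved_tibia = type(default_limb.tibia)(
            default_limb.tibia.vertices + shift, default_limb.tibia.faces
        )
        moved_lms = lms.transformed(np.eye(3), shift)
        moved = tp_tt_metrics(moved_tibia, moved_lms, frame, 400.0)
        assert moved.d1 == pytest.approx(res.d1, abs=1e-9)
        assert moved.d2 == pytest.approx(res.d2, abs=1e-9)


class TestPennation:
    def test_perpendicular_and_parallel(self):
        apo = Line3((0, 0, 0), (1, 0, 0))
        assert pennation_angle(apo, Line3((5, 5, 0), (0, 1, 0))) == pytest.approx(90.0)
        assert pennation_angle(apo, Line3((5, 5, 0), (1, 0, 0))) == pytest.approx(0.0)
        assert pennation_angle(apo, Line3((5, 5, 0), (-1, 0, 0))) == pytest.approx(0.0)

    def test_always_acute_and_matches_dot_oracle(self, rng):
        for _ in range(200):
            d1, d2 = rng.normal(size=(2, 3))
            if min(np.linalg.norm(d1), np.linalg.norm(d2)) < 1e-3:
                continue
            got = pennation_angle(Line3((0, 0, 0), d1), Line3((1, 1, 1), d2))
            full = angle_between_directions(d1, d2)
            expected = 180.0 - full if full > 90.0 else full
            assert got == pytest.approx(expected, abs=1e-6)
            assert 0.0 <= got <= 90.0


class TestAssembly:
    def test_missing_components_named(self, default_measurement):
        metrics, _ = default_measurement
        partial = {f: getattr(metrics, f) for f in METRIC_FIELDS}
        partial["pennation_vl"] = None
        del partial["pennation_rf"]
        with pytest.raises(IncompleteProfileError) as err:
            assemble_limb_metrics(**partial)
        assert err.value.missing == ["pennation_rf", "pennation_vl"]

    def test_round_trip(self, default_measurement):
        metrics, _ = default_measurement
        rebuilt = assemble_limb_metrics(**metrics.as_dict())
        assert rebuilt == metrics


class TestEndToEndInvariance:
    def test_rigid_motion_leaves_all_metrics_unchanged(self, rng, default_limb):
        base, _ = measure_limb(
            default_limb.landmarks, default_limb.tibia, default_limb.mask
        )
        r, t = random_rigid(rng)
        tibia = type(default_limb.tibia)(
            default_limb.tibia.vertices @ r.T + t, default_limb.tibia.faces
        )
        lms = default_limb.landmarks.transformed(r, t)
        moved, _ = measure_limb(lms, tibia, default_limb.mask)
        for f in METRIC_FIELDS:
            assert getattr(moved, f) == pytest.approx(getattr(base, f), rel=1e-6)

    @pytest.mark.parametrize("s", [0.5, 2.0, 10.0])
    def test_uniform_scaling_equivariance(self, default_limb, s):
        base, _ = measure_limb(
            default_limb.landmarks, default_limb.tibia, default_limb.mask
        )
        tibia = type(default_limb.tibia)(
            default_limb.tibia.vertices * s, default_limb.tibia.faces
        )
        scaled, _ = measure_limb(
            default_limb.landmarks.scaled(s), tibia, default_limb.mask.scaled(s)
        )
        factors = {"tl": s, "fl": s, "moment_arm": s, "qca": s**2, "qca_fl": s**3}
        for f in METRIC_FIELDS:
            assert getattr(scaled, f) == pytest.approx(
                factors.get(f, 1.0) * getattr(base, f), rel=1e-9
            )

    def test_noiseless_parameter_recovery_sample(self):
        from stiflemetrics.synthetic import random_spec

        for seed in (11, 222, 3333):
            limb = generate_limb(random_spec(seed))
            metrics, _ = measure_limb(limb.landmarks, limb.tibia, limb.mask)
            for f in METRIC_FIELDS:
                true = getattr(limb.truth, f)
                assert getattr(metrics, f) == pytest.approx(true, rel=0.02), f
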