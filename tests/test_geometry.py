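"""Signed-angle statistics and two-point registration."""

import math

import pytest

from copasym.datatypes import LandmarkObservation, ValidationError
from copasym.geometry import (
    bookstein_register,
    signed_angle_frontal,
    signed_angle_top,
)


def _pose(points, phi, scale, tx, ty):
    a = scale * complex(math.cos(phi), math.sin(phi))
    b = complex(tx, ty)
    return [((a * complex(x, y) + b).real, (a * complex(x, y) + b).imag) for x, y in points]


def _mirror_x(points):
    return [(-x, y) for x, y in points]


class TestTopAngle:
    def test_collinear_male_behind_female_scores_zero(self):
        assert signed_angle_top((0, 0), (0, 1), (0, 2)) == pytest.approx(0.0, abs=1e-12)

    def test_male_on_female_right_scores_positive(self):
        # oracle: atan(0.1 / 1) with +x on the female's right when she faces up-screen
        expected = math.degrees(math.atan(0.1 / 1.0))
        assert signed_angle_top((0, 0), (0, 1), (0.1, 2)) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(5.7106, abs=5e-5)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValidationError):
            signed_angle_top((0, 0), (0, 0), (1, 1))
        with pytest.raises(ValidationError):
            signed_angle_top((0, 0), (1, 1), (1, 1))


class TestFrontalAngle:
    def test_male_on_dorsoventral_axis_scores_zero(self):
        assert signed_angle_frontal((0, -1), (0, 0), (0, -2)) == pytest.approx(0.0, abs=1e-12)

    def test_tilt_toward_viewer_left_is_females_right_positive(self):
        expected = math.degrees(math.atan(0.1 / 2.0))
        assert signed_angle_frontal((0, -1), (0, 0), (-0.1, -2)) == pytest.approx(
            expected, abs=1e-9
        )
        assert expected == pytest.approx(2.8624, abs=5e-5)


def test_similarity_invariance_and_mirror_antisymmetry(rng):
    """1000 random poses: angles invariant to 1e-9 deg; reflections flip the sign."""
    for _ in range(1000):
        pts = [tuple(p) for p in rng.uniform(-50, 50, size=(3, 2))]
        try:
            base_top = signed_angle_top(*pts)
            base_fr = signed_angle_frontal(*pts)
        except ValidationError:
            continue
        phi = rng.uniform(0, 2 * math.pi)
        scale = rng.uniform(0.1, 10.0)
        tx, ty = rng.uniform(-500, 500, size=2)
        moved = _pose(pts, phi, scale, tx, ty)
        assert signed_angle_top(*moved) == pytest.approx(base_top, abs=1e-9)
        assert signed_angle_frontal(*moved) == pytest.approx(base_fr, abs=1e-9)
        mirrored = _mirror_x(pts)
        assert signed_angle_top(*mirrored) == pytest.approx(-base_top, abs=1e-9)
        assert signed_angle_frontal(*mirrored) == pytest.approx(-base_fr, abs=1e-9)
        assert -180.0 < base_top <= 180.0


def _obs(p1, p2, p3, exp="e", tp="settling", rep=1):
    return LandmarkObservation(exp, "top", tp, rep, {"P1": p1, "P2": p2, "P3": p3})


class TestBooksteinRegistration:
    def test_similarity_transform_example(self):
        (reg,) = bookstein_register([_obs((3, 4), (3, 6), (3.2, 8))])
        assert reg.points["P1"] == pytest.approx((0, 0), abs=1e-12)
        assert reg.points["P2"] == pytest.approx((0, 1), abs=1e-12)
        assert reg.points["P3"] == pytest.approx((0.1, 2), abs=1e-12)

    def test_idempotent_on_registered_frames(self):
        (reg,) = bookstein_register([_obs((0, 0), (0, 1), (0.1, 2))])
        assert reg.points["P3"] == pytest.approx((0.1, 2), abs=1e-12)

    def test_closure_on_124_random_poses_and_angle_preservation(self, rng):
        obs = []
        for i in range(124):
            base = [(0.0, 0.0), (0.0, 100.0), tuple(rng.uniform(-80, 80, 2) + (0, 180))]
            moved = _pose(base, rng.uniform(0, 2 * math.pi), rng.uniform(0.5, 2.0),
                          rng.uniform(100, 700), rng.uniform(100, 500))
            obs.append(_obs(*moved, exp=f"e{i}"))
        registered = bookstein_register(obs)
        for before, after in zip(obs, registered):
            assert after.points["P1"] == pytest.approx((0, 0), abs=1e-9)
            assert after.points["P2"] == pytest.approx((0, 1), abs=1e-9)
            assert signed_angle_top(*[after.points[k] for k in ("P1", "P2", "P3")]) == (
                pytest.approx(
                    signed_angle_top(*[before.points[k] for k in ("P1", "P2", "P3")]),
                    abs=1e-9,
                )
            )

    def test_degenerate_baseline_rejected_with_observation_named(self):
        with pytest.raises(ValidationError, match="e_bad"):
            bookstein_register([_obs((0, 0), (0.4, 0), (5, 5), exp="e_bad")])

    def test_frontal_frames_not_registrable(self):
        obs = LandmarkObservation("e", "frontal", "clock(0)", 1,
                                  {"P4": (0, -1), "P5": (0, 0), "P6": (0, -2)})
        with pytest.raises(ValidationError):
            bookstein_register([obs])
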