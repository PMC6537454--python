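"""Signed mating angles and two-point (Bookstein) registration.

Coordinates are image pixels with the y axis pointing down.  Both angle
statistics are deviations of the male head from a female body axis, signed so
that positive means the male lies or tilts toward the *female's* right side.
They are invariant under translation, rotation and positive uniform scaling of
the landmark set, and flip sign under reflection — so arbitrary camera pose
cannot change the sign of a measured angle.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

from .datatypes import (
    AngleMeasurement,
    LandmarkObservation,
    ValidationError,
)

Point = Sequence[float]

#: Baselines shorter than this (pixels) are rejected as degenerate.
MIN_BASELINE_PX = 1.0


def _signed_deviation_deg(u: tuple[float, float], v: tuple[float, float]) -> float:
    """Signed angle (degrees) from direction u to direction v, y-down convention.

    Returns -deg(atan2(u x v, u . v)); with y pointing down this makes a
    clockwise-on-screen deviation positive, which is what puts "toward the
    female's right" on the positive side in both camera views.
    """
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    return -math.degrees(math.atan2(cross, dot))


def _vec(a: Point, b: Point) -> tuple[float, float]:
    return (b[0] - a[0], b[1] - a[1])


def _check_distinct(label_a: str, a: Point, label_b: str, b: Point) -> None:
    if a[0] == b[0] and a[1] == b[1]:
        raise ValidationError(f"landmarks {label_a} and {label_b} coincide at {tuple(a)}")


def signed_angle_top(P1: Point, P2: Point, P3: Point) -> float:
    """Dorsal-view mating angle: deviation of the male head from the female midline.

    P1 = anterior tip of the female head (midline), P2 = distal tip of the
    female scutellum, P3 = most posterior medial point of the male head.  A
    male directly behind the female on her midline extension scores 0; a male
    displaced toward the female's right scores positive.  Range (-180, 180].
    """
    _check_distinct("P1", P1, "P2", P2)
    _check_distinct("P2", P2, "P3", P3)
    u = _vec(P1, P2)  # female head -> scutellum (posterior direction)
    v = _vec(P2, P3)  # scutellum -> male head
    return _signed_deviation_deg(u, v)


def signed_angle_frontal(P4: Point, P5: Point, P6: Point) -> float:
    """Frontal-view tilt of the male body off the female dorso-ventral axis.

    P4 = medial most dorsal edge of the female head, P5 = most ventral medial
    point of the female head (proboscis), P6 = medial most dorsal edge of the
    male head.  The frontal camera mirrors left and right: the female's right
    is the viewer's left, so a tilt toward -x is scored positive.
    """
    _check_distinct("P4", P4, "P5", P5)
    _check_distinct("P5", P5, "P6", P6)
    u = _vec(P5, P4)  # female ventral -> dorsal axis
    v = _vec(P5, P6)  # proboscis -> male head
    return _signed_deviation_deg(u, v)


def angle_of_observation(obs: LandmarkObservation) -> AngleMeasurement:
    """Compute the signed mating angle of one landmark observation."""
    if obs.view == "top":
        angle = signed_angle_top(obs.points["P1"], obs.points["P2"], obs.points["P3"])
    else:
        angle = signed_angle_frontal(obs.points["P4"], obs.points["P5"], obs.points["P6"])
    return AngleMeasurement(
        experiment_id=obs.experiment_id,
        view=obs.view,
        timepoint_label=obs.timepoint_label,
        replicate_id=obs.replicate_id,
        angle_deg=angle,
        time_s=obs.time_s,
    )


def bookstein_register(
    observations: Iterable[LandmarkObservation],
    min_baseline_px: float = MIN_BASELINE_PX,
) -> list[LandmarkObservation]:
    """Two-point registration of dorsal-view frames onto a common baseline.

    Each frame is mapped by a translation + rotation + positive uniform
    scaling (no reflection) that sends P1 to (0, 0) and P2 to (0, 1), so that
    all female bodies are superimposed and the registered P3 positions can be
    overlaid directly.  Signed angles are unchanged by this transform.
    """
    registered = []
    for obs in observations:
        if obs.view != "top":
            raise ValidationError(
                f"registration is defined for top-view frames, got {obs.view!r} "
                f"({obs.experiment_id})"
            )
        p1 = complex(*obs.points["P1"])
        p2 = complex(*obs.points["P2"])
        baseline = p2 - p1
        if abs(baseline) < min_baseline_px:
            raise ValidationError(
                f"degenerate baseline |P1P2|={abs(baseline):.3g} px < {min_baseline_px} "
                f"in {obs.experiment_id}/{obs.timepoint_label}/rep{obs.replicate_id}"
            )
        # z -> i * (z - p1) / (p2 - p1): orientation-preserving similarity.
        new_points = {}
        for label, (x, y) in obs.points.items():
            w = 1j * (complex(x, y) - p1) / baseline
            new_points[label] = (w.real, w.imag)
        registered.append(
            LandmarkObservation(
                experiment_id=obs.experiment_id,
                view=obs.view,
                timepoint_label=obs.timepoint_label,
                replicate_id=obs.replicate_id,
                points=new_points,
                time_s=obs.time_s,
            )
        )
    return registered
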