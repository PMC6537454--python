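"""Copulation validity rules, durations and the posture sampling schedule.

A mount only counts as a copulation start when the male stays mounted at
least 15 s.  Posture is scored at the settling time point (when the mounted
male first adopts an invariant position) and at 10% of the elapsed time
between settling and copulation end; long-copulating species additionally get
a periodic grid anchored at the settling time point, with a step chosen from
the species' mean copulation duration (> 2.5 min -> 2.5 min step, > 15 min ->
5 min, > 60 min -> 10 min).
"""

from __future__ import annotations

from typing import Sequence

from .datatypes import EventTimes, SamplingSchedule, ValidationError

#: Minimum mount duration (seconds) for a mount to count as a copulation.
MIN_COPULATION_S = 15.0

#: (mean-duration threshold in minutes, grid step in seconds); strict ">".
GRID_RULES = ((60.0, 600.0), (15.0, 300.0), (2.5, 150.0))

#: Two schedule points closer than this are one measurement (seconds).
DEDUP_TOL_S = 1.0


def is_valid_copulation(mount_duration_s: float) -> bool:
    """True iff a mount of this duration counts as a copulation (>= 15 s)."""
    if mount_duration_s < 0:
        raise ValidationError(f"mount duration must be non-negative, got {mount_duration_s}")
    return mount_duration_s >= MIN_COPULATION_S


def durations(events: EventTimes) -> tuple[float | None, float | None]:
    """(courtship, copulation) durations in minutes; ``None`` when an event is missing.

    Courtship ends at copulation start; copulation ends when the male has
    completely descended from the female.
    """
    courtship = None
    copulation = None
    if events.courtship_start_s is not None and events.copulation_start_s is not None:
        courtship = (events.copulation_start_s - events.courtship_start_s) / 60.0
    if events.copulation_start_s is not None and events.copulation_end_s is not None:
        copulation = (events.copulation_end_s - events.copulation_start_s) / 60.0
    return courtship, copulation


def grid_step_s(species_mean_copulation_min: float) -> float | None:
    """Periodic-measurement step for a species, or None below the 2.5-min mean."""
    for threshold_min, step_s in GRID_RULES:
        if species_mean_copulation_min > threshold_min:
            return step_s
    return None


def sampling_schedule(
    events: EventTimes,
    species_mean_copulation_min: float,
    experiment_id: str = "",
) -> SamplingSchedule:
    """Build the ordered posture-measurement schedule for one trial.

    Points: the settling time point, the 10% stable-copulation time point, and
    (for long-copulating species) a periodic grid anchored at settling with
    points strictly after settling and at most at copulation end.  A grid
    point within 1 s of the 10% point is dropped as a duplicate.
    """
    if events.settling_s is None or events.copulation_end_s is None:
        raise ValidationError("sampling schedule requires settling and copulation end times")
    settling = events.settling_s
    end = events.copulation_end_s
    if settling >= end:
        raise ValidationError(
            f"settling ({settling} s) must precede copulation end ({end} s)"
        )
    pct10 = settling + 0.10 * (end - settling)
    points: list[tuple[str, float]] = [("settling", settling), ("pct10", pct10)]
    step = grid_step_s(species_mean_copulation_min)
    if step is not None:
        k = 1
        while settling + k * step <= end + 1e-9:
            t = settling + k * step
            if abs(t - pct10) >= DEDUP_TOL_S:
                points.append((f"grid({k})", t))
            k += 1
    points.sort(key=lambda lt: lt[1])
    return SamplingSchedule(experiment_id=experiment_id, timepoints=tuple(points))


def snap_to_frames(times_s: Sequence[float], frame_times_s: Sequence[float]) -> list[float]:
    """Map each schedule time to the nearest available frame time.

    Ties between two equally near frames are broken toward the earlier frame.
    """
    if not frame_times_s:
        raise ValidationError("no frames available to snap to")
    frames = sorted(frame_times_s)
    out = []
    for t in times_s:
        best = min(frames, key=lambda f: (abs(f - t), f))
        out.append(best)
    return out
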