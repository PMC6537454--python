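"""Synthetic mating-experiment generator.

Stands in for the original video recordings: for each species it draws
courtship and copulation durations from truncated normal distributions (the
study conditions report mean, SD and observed range only), places the
settling time point uniformly within the first 20% of copulation, builds the
posture sampling schedule, and for every scheduled frame emits landmark
coordinates of an ideal couple — whose true mating angle follows the species'
time-binned angle trajectory plus a per-experiment random intercept — under
an arbitrary camera pose (rotation, translation, uniform scale), with
Gaussian pixel noise added independently per replicate acquisition.  Ground
truth (true angle per frame) accompanies every emitted observation, so
parameter-recovery tests can compare pipeline estimates against the
generating values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import timeline
from .datatypes import (
    BilateralRecord,
    EventTimes,
    ExclusionReason,
    ExperimentRecord,
    LandmarkObservation,
    SPECIES_CODES,
    ValidationError,
)

#: Landmark placement noise on an 800 x 600 px frame (per coordinate, SD).
DEFAULT_LANDMARK_NOISE_PX = 2.0

#: SD of the per-experiment random intercept of the true angle (deg); models
#: within-couple consistency of posture across time points.
DEFAULT_EXPERIMENT_INTERCEPT_SD = 5.0

#: Female head-to-scutellum baseline length in the ideal couple (px).
BODY_AXIS_PX = 100.0

#: Frontal-view image sampling step (s): frames were scored every 15-30 s.
FRONTAL_STEP_S = 20.0


@dataclass(frozen=True)
class SpeciesSimSpec:
    """Generating parameters for one species' simulated experiments.

    ``angle_trajectory`` is an ordered tuple of (bin start in minutes after
    copulation start, true mean angle in degrees, true between-experiment SD
    in degrees); a measurement at time t uses the last bin starting at or
    before t.  ``exclusion_probs`` optionally marks whole experiments as
    discarded with the given per-reason probabilities (summing to < 1).
    """

    species_code: str
    n_experiments: int
    copulation_mean_min: float
    copulation_sd_min: float
    copulation_range_min: tuple[float, float] | None = None
    courtship_mean_min: float | None = None
    courtship_sd_min: float | None = None
    courtship_range_min: tuple[float, float] | None = None
    angle_trajectory: tuple[tuple[float, float, float], ...] = ((0.0, 0.0, 12.0),)
    landmark_noise_px: float = DEFAULT_LANDMARK_NOISE_PX
    experiment_intercept_sd: float = DEFAULT_EXPERIMENT_INTERCEPT_SD
    exclusion_probs: Mapping[ExclusionReason, float] = field(default_factory=dict)
    view: str = "top"
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if self.species_code not in SPECIES_CODES:
            raise ValidationError(f"unknown species code {self.species_code!r}")
        if self.n_experiments < 0:
            raise ValidationError("n_experiments must be non-negative")
        if self.copulation_sd_min < 0:
            raise ValidationError("copulation SD must be non-negative")
        if self.courtship_sd_min is not None and self.courtship_sd_min < 0:
            raise ValidationError("courtship SD must be non-negative")
        if self.landmark_noise_px < 0:
            raise ValidationError("landmark noise must be non-negative")
        starts = [b[0] for b in self.angle_trajectory]
        if starts != sorted(starts) or len(set(starts)) != len(starts):
            raise ValidationError("angle trajectory bins must be strictly increasing")
        if any(b[2] < 0 for b in self.angle_trajectory):
            raise ValidationError("trajectory SDs must be non-negative")
        total_p = sum(self.exclusion_probs.values())
        if total_p > 1.0 or any(p < 0 for p in self.exclusion_probs.values()):
            raise ValidationError("exclusion probabilities must be >= 0 and sum to <= 1")
        if self.view not in ("top", "frontal"):
            raise ValidationError("view must be 'top' or 'frontal'")


@dataclass
class SimOutput:
    """Everything one simulation run emits, with per-frame ground truth."""

    experiments: list[ExperimentRecord]
    observations: list[LandmarkObservation]
    truth: pd.DataFrame  # experiment_id, timepoint_label, time_s, true_angle_deg
    species_specs: dict[str, SpeciesSimSpec]


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lower: float,
    upper: float,
) -> float:
    """One draw from Normal(mean, sd) truncated to [lower, upper]."""
    if sd == 0.0:
        return min(max(mean, lower), upper)
    a, b = (lower - mean) / sd, (upper - mean) / sd
    u = rng.uniform(sps.norm.cdf(a), sps.norm.cdf(b))
    return mean + sd * sps.norm.ppf(u)


def _trajectory_value(
    trajectory: Sequence[tuple[float, float, float]], t_min: float
) -> tuple[float, float]:
    """(true mean, SD) of the bin covering *t_min* minutes after copulation start."""
    mean, sd = trajectory[0][1], trajectory[0][2]
    for start, m, s in trajectory:
        if t_min >= start:
            mean, sd = m, s
        else:
            break
    return mean, sd


def _ideal_landmarks(view: str, angle_deg: float) -> dict[str, tuple[float, float]]:
    """Canonical noise-free landmark triplet realizing *angle_deg* exactly."""
    theta = math.radians(angle_deg)
    L = BODY_AXIS_PX
    if view == "top":
        # female midline along +y (head up-screen at origin), male behind her
        p1 = (0.0, 0.0)
        p2 = (0.0, L)
        p3 = (p2[0] + L * math.sin(theta), p2[1] + L * math.cos(theta))
        return {"P1": p1, "P2": p2, "P3": p3}
    # frontal view: female dorso-ventral axis along -y, mirror-imaged left/right
    p5 = (0.0, 0.0)
    p4 = (0.0, -L)
    p6 = (-2 * L * math.sin(theta), -2 * L * math.cos(theta))
    return {"P4": p4, "P5": p5, "P6": p6}


def _apply_pose(
    points: Mapping[str, tuple[float, float]], rng: np.random.Generator
) -> dict[str, tuple[float, float]]:
    """Random orientation-preserving similarity: rotation, scale, translation."""
    phi = rng.uniform(0.0, 2.0 * math.pi)
    scale = rng.uniform(0.5, 2.0)
    a = scale * complex(math.cos(phi), math.sin(phi))
    b = complex(rng.uniform(100.0, 700.0), rng.uniform(100.0, 500.0))
    return {lbl: ((a * complex(x, y) + b).real, (a * complex(x, y) + b).imag)
            for lbl, (x, y) in points.items()}


def simulate(specs: Sequence[SpeciesSimSpec], seed: int) -> SimOutput:
    """Generate a full multi-species data set of experiments and landmark frames.

    Deterministic given *seed*.  Excluded experiments (when a spec carries
    exclusion probabilities) are emitted with their reason set but without
    event times or landmark frames.
    """
    codes = [s.species_code for s in specs]
    if len(set(codes)) != len(codes):
        raise ValidationError("duplicate species in simulation specs")
    rng = np.random.default_rng(seed)
    experiments: list[ExperimentRecord] = []
    observations: list[LandmarkObservation] = []
    truth_rows: list[dict] = []

    for spec in specs:
        reasons = list(spec.exclusion_probs.keys())
        probs = np.array([spec.exclusion_probs[r] for r in reasons], dtype=float)
        for i in range(spec.n_experiments):
            exp_id = f"{spec.species_code}01_{i + 1:02d}"
            drawn: frozenset[ExclusionReason] = frozenset()
            if len(reasons) > 0:
                u = rng.uniform()
                cum = np.cumsum(probs)
                hit = np.searchsorted(cum, u)
                if hit < len(reasons):
                    drawn = frozenset({reasons[hit]})
            if drawn:
                experiments.append(
                    ExperimentRecord(
                        experiment_id=exp_id,
                        species_code=spec.species_code,
                        events=EventTimes(),
                        exclusion_reasons=drawn,
                    )
                )
                continue

            cop_lo, cop_hi = spec.copulation_range_min or (0.25, math.inf)
            cop_lo = max(cop_lo, timeline.MIN_COPULATION_S / 60.0)
            cop_min = _truncated_normal(
                rng, spec.copulation_mean_min, spec.copulation_sd_min, cop_lo, cop_hi
            )
            if spec.courtship_mean_min is not None:
                crt_lo, crt_hi = spec.courtship_range_min or (0.0, math.inf)
                court_min = _truncated_normal(
                    rng, spec.courtship_mean_min, spec.courtship_sd_min or 0.0,
                    crt_lo, crt_hi,
                )
                courtship_start = rng.uniform(0.0, 60.0)
                cop_start = courtship_start + court_min * 60.0
            else:
                courtship_start = None
                cop_start = rng.uniform(0.0, 60.0)
            cop_end = cop_start + cop_min * 60.0
            settling = cop_start + rng.uniform(0.0, 0.2) * (cop_end - cop_start)
            events = EventTimes(
                courtship_start_s=courtship_start,
                copulation_start_s=cop_start,
                settling_s=settling,
                copulation_end_s=cop_end,
            )
            experiments.append(
                ExperimentRecord(
                    experiment_id=exp_id,
                    species_code=spec.species_code,
                    events=events,
                    exclusion_reasons=frozenset(),
                )
            )

            if spec.view == "top":
                schedule = timeline.sampling_schedule(
                    events, spec.copulation_mean_min, experiment_id=exp_id
                )
                points_list = list(schedule.timepoints)
            else:
                ts = np.arange(cop_start, cop_end + 1e-9, FRONTAL_STEP_S)
                points_list = [(f"clock({j})", float(t)) for j, t in enumerate(ts)]

            intercept = rng.normal(0.0, spec.experiment_intercept_sd)
            for label, t in points_list:
                t_rel_min = (t - cop_start) / 60.0
                bin_mean, bin_sd = _trajectory_value(spec.angle_trajectory, t_rel_min)
                resid_sd = math.sqrt(
                    max(bin_sd**2 - spec.experiment_intercept_sd**2, 1.0)
                )
                true_angle = bin_mean + intercept + rng.normal(0.0, resid_sd)
                ideal = _ideal_landmarks(spec.view, true_angle)
                posed = _apply_pose(ideal, rng)
                truth_rows.append(
                    {
                        "experiment_id": exp_id,
                        "species_code": spec.species_code,
                        "view": spec.view,
                        "timepoint_label": label,
                        "time_s": t,
                        "true_angle_deg": true_angle,
                    }
                )
                for rep in range(1, spec.n_replicates + 1):
                    noisy = {
                        lbl: (
                            x + rng.normal(0.0, spec.landmark_noise_px),
                            y + rng.normal(0.0, spec.landmark_noise_px),
                        )
                        for lbl, (x, y) in posed.items()
                    }
                    observations.append(
                        LandmarkObservation(
                            experiment_id=exp_id,
                            view=spec.view,
                            timepoint_label=label,
                            replicate_id=rep,
                            points=noisy if spec.landmark_noise_px > 0 else dict(posed),
                            time_s=t,
                        )
                    )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "experiment_id", "species_code", "view",
            "timepoint_label", "time_s", "true_angle_deg",
        ],
    )
    return SimOutput(
        experiments=experiments,
        observations=observations,
        truth=truth,
        species_specs={s.species_code: s for s in specs},
    )


def simulate_bilateral(
    species_code: str,
    structure: str,
    true_index: float,
    sd: float,
    n: int,
    seed: int,
    base_um: float = 100.0,
) -> tuple[list[BilateralRecord], pd.DataFrame]:
    """Paired left/right lengths with a controlled normalized asymmetry index.

    Draws d_i ~ Normal(true_index, sd) and sets L = base (1 + d/2),
    R = base (1 - d/2), so the per-specimen index 2(L-R)/(L+R) equals d_i
    exactly.  Returns the records plus a ground-truth table.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if sd < 0:
        raise ValidationError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    d = rng.normal(true_index, sd, size=n)
    d = np.clip(d, -1.9, 1.9)  # keep both lengths positive
    records = [
        BilateralRecord(
            specimen_id=f"{species_code}_{structure}_{i + 1:02d}",
            species_code=species_code,
            structure=structure,
            left_um=base_um * (1.0 + d[i] / 2.0),
            right_um=base_um * (1.0 - d[i] / 2.0),
        )
        for i in range(n)
    ]
    truth = pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "true_index": d,
            "generating_mean_index": true_index,
        }
    )
    return records, truth
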