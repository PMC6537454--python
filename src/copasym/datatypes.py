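"""Core domain types for the mating-posture and asymmetry pipeline.

All times are stored in seconds from the start of the recording; durations are
converted to minutes only at the presentation layer.  Landmark coordinates are
pixels in the standard image convention (origin top-left, y axis pointing
down).  Signed angles are degrees, positive when the male is displaced or
tilted toward the female's right side.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence


class ValidationError(ValueError):
    """Raised when an input record violates a documented invariant."""


SPECIES_CODES = ("aca", "pac", "nan", "mac", "bro", "moj", "buz", "tri", "wil", "mel")

#: Full species names keyed by the three-letter codes used in experiment ids.
SPECIES_NAMES = {
    "aca": "Drosophila acanthoptera",
    "pac": "Drosophila pachea",
    "nan": "Drosophila nannoptera",
    "mac": "Drosophila machalilla",
    "bro": "Drosophila bromeliae",
    "moj": "Drosophila mojavensis",
    "buz": "Drosophila buzzatii",
    "tri": "Drosophila tripunctata",
    "wil": "Drosophila willistoni",
    "mel": "Drosophila melanogaster",
}


class ExclusionReason(str, enum.Enum):
    """Why a recorded trial was discarded from one or more measurements.

    ``MULTIPLE`` is a bookkeeping marker attached to trials annotated with
    more than one reason; accounting files such a trial once, under its own
    "multiple reasons" category, so that per-reason counts still sum to the
    number of discarded trials.
    """

    CAMERA_OR_FILE_DAMAGED = "camera_or_file_damaged"
    INCOMPLETE_COURTSHIP_RECORDING = "incomplete_courtship_recording"
    INCOMPLETE_COPULATION_RECORDING = "incomplete_copulation_recording"
    LEG_OR_WING_DAMAGED = "leg_or_wing_damaged"
    NO_COPULATION_45MIN = "no_copulation_45min"
    LANDMARKS_NOT_VISIBLE = "landmarks_not_visible"
    FEMALE_HEAD_OUT_OF_VIEW = "female_head_out_of_view"
    MULTIPLE = "multiple"


#: Reasons that invalidate the courtship-duration measurement of a trial.
COURTSHIP_DISCARD = frozenset(
    {
        ExclusionReason.CAMERA_OR_FILE_DAMAGED,
        ExclusionReason.INCOMPLETE_COURTSHIP_RECORDING,
        ExclusionReason.LEG_OR_WING_DAMAGED,
        ExclusionReason.NO_COPULATION_45MIN,
    }
)

#: Reasons that invalidate the copulation-duration measurement of a trial.
COPULATION_DISCARD = frozenset(
    {
        ExclusionReason.CAMERA_OR_FILE_DAMAGED,
        ExclusionReason.INCOMPLETE_COPULATION_RECORDING,
        ExclusionReason.LEG_OR_WING_DAMAGED,
        ExclusionReason.NO_COPULATION_45MIN,
    }
)

#: Additional reasons that invalidate only the posture measurement.
POSTURE_ONLY_DISCARD = frozenset({ExclusionReason.LANDMARKS_NOT_VISIBLE})


@dataclass(frozen=True)
class EventTimes:
    """Manually annotated event times of one trial, seconds from recording start."""

    courtship_start_s: float | None = None
    copulation_start_s: float | None = None
    settling_s: float | None = None
    copulation_end_s: float | None = None

    _ORDER = ("courtship_start_s", "copulation_start_s", "settling_s", "copulation_end_s")

    def __post_init__(self) -> None:
        present = [(n, getattr(self, n)) for n in self._ORDER if getattr(self, n) is not None]
        for name, value in present:
            if not math.isfinite(value) or value < 0:
                raise ValidationError(f"event {name} must be a finite non-negative time, got {value}")
        for (n1, t1), (n2, t2) in zip(present, present[1:]):
            if t1 > t2:
                raise ValidationError(f"event ordering violated: {n1}={t1} > {n2}={t2}")


@dataclass
class ExperimentRecord:
    """One mating trial: identity, annotated events and exclusion bookkeeping."""

    experiment_id: str
    species_code: str
    temperature_C: float | None = None
    events: EventTimes = field(default_factory=EventTimes)
    exclusion_reasons: frozenset[ExclusionReason] = frozenset()

    def __post_init__(self) -> None:
        if self.species_code not in SPECIES_CODES:
            raise ValidationError(
                f"unknown species code {self.species_code!r}; expected one of {SPECIES_CODES}"
            )
        self.exclusion_reasons = frozenset(self.exclusion_reasons)

    # Usability flags are derived, never stored, so the filter-accounting
    # identity (usable + discarded = total) holds by construction.
    @property
    def usable_for_courtship(self) -> bool:
        return not (self.exclusion_reasons & COURTSHIP_DISCARD)

    @property
    def usable_for_copulation_duration(self) -> bool:
        return not (self.exclusion_reasons & COPULATION_DISCARD)

    @property
    def usable_for_posture(self) -> bool:
        return self.usable_for_copulation_duration and not (
            self.exclusion_reasons & POSTURE_ONLY_DISCARD
        )


TOP_LABELS = ("P1", "P2", "P3")
FRONTAL_LABELS = ("P4", "P5", "P6")


@dataclass
class LandmarkObservation:
    """One frame's labelled landmark coordinates (pixels, y-down).

    Dorsal ("top") view frames carry P1 (anterior tip of the female head on
    its midline), P2 (distal tip of the female scutellum) and P3 (most
    posterior medial point of the male head).  Frontal view frames carry P4
    (medial most dorsal edge of the female head), P5 (most ventral medial
    point of the female head) and P6 (medial most dorsal edge of the male
    head).
    """

    experiment_id: str
    view: str  # "top" | "frontal"
    timepoint_label: str  # "settling", "pct10", "grid(k)", "clock(t)"
    replicate_id: int
    points: dict[str, tuple[float, float]]
    time_s: float | None = None

    def __post_init__(self) -> None:
        if self.view not in ("top", "frontal"):
            raise ValidationError(f"view must be 'top' or 'frontal', got {self.view!r}")
        required = TOP_LABELS if self.view == "top" else FRONTAL_LABELS
        if set(self.points) != set(required):
            raise ValidationError(
                f"{self.view} view requires exactly landmarks {required}, got {sorted(self.points)}"
            )
        pts = list(self.points.items())
        for (la, pa), (lb, pb) in zip(pts, pts[1:]):
            if pa == pb:
                raise ValidationError(
                    f"landmarks {la} and {lb} coincide at {pa} in {self.experiment_id}"
                )


@dataclass(frozen=True)
class BlindingMap:
    """Bijection from original movie names to seven-digit blind codes."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [p[0] for p in self.pairs]
        codes = [p[1] for p in self.pairs]
        if len(set(names)) != len(names):
            raise ValidationError("blinding input names must be distinct")
        if len(set(codes)) != len(codes):
            raise ValidationError("blinding codes collide")
        for c in codes:
            if not (len(c) == 7 and c.isdigit() and c[0] != "0"):
                raise ValidationError(f"blinding code {c!r} is not a 7-digit number")

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)

    def inverse(self) -> dict[str, str]:
        return {c: n for n, c in self.pairs}


@dataclass(frozen=True)
class BilateralRecord:
    """Paired left/right length of one structure on one specimen (micrometers)."""

    specimen_id: str
    species_code: str
    structure: str
    left_um: float
    right_um: float

    def __post_init__(self) -> None:
        if not (self.left_um > 0 and self.right_um > 0):
            raise ValidationError(
                f"lengths must be positive, got L={self.left_um}, R={self.right_um} "
                f"for {self.specimen_id}"
            )


@dataclass(frozen=True)
class SamplingSchedule:
    """Ordered posture-measurement time points of one trial."""

    experiment_id: str
    timepoints: tuple[tuple[str, float], ...]  # (label, time_s), strictly increasing

    def labels(self) -> list[str]:
        return [lbl for lbl, _ in self.timepoints]

    def times(self) -> list[float]:
        return [t for _, t in self.timepoints]


@dataclass(frozen=True)
class AngleMeasurement:
    """One signed mating-angle measurement (degrees, positive = female's right)."""

    experiment_id: str
    view: str
    timepoint_label: str
    replicate_id: int
    angle_deg: float
    time_s: float | None = None


@dataclass(frozen=True)
class SpeciesAngleTest:
    """Per-species contrast of the mean mating angle against zero."""

    species_code: str
    timepoint_label: str
    n: int
    estimate_deg: float
    se_deg: float
    z: float
    p_raw: float
    p_bonf: float


@dataclass(frozen=True)
class AnovaRow:
    term: str
    df: int
    ss: float
    ms: float
    F: float | None
    p: float | None


@dataclass(frozen=True)
class AnovaTable:
    """Classical ANOVA table: one row per model term plus the residual row."""

    rows: tuple[AnovaRow, ...]

    def __getitem__(self, term: str) -> AnovaRow:
        for row in self.rows:
            if row.term == term:
                return row
        raise KeyError(term)

    @property
    def residual(self) -> AnovaRow:
        return self["residual"]


@dataclass(frozen=True)
class IntervalSummary:
    """Across-experiment summary of angles in one minute-bin after copulation start."""

    interval_min: tuple[int, int]
    mean_deg: float
    sd_deg: float | None  # None when only one experiment contributes
    n: int


@dataclass(frozen=True)
class AsymmetryResult:
    """Directional vs fluctuating asymmetry verdict for one structure/species."""

    species_code: str
    structure: str
    n: int
    mean_signed_diff_um: float
    asymmetry_index_mean: float
    sign_counts: tuple[int, int, int]  # (#L>R, #R>L, ties)
    p_sign: float
    p_t: float
    verdict: str  # directional_left | directional_right | fluctuating_only | insufficient


@dataclass(frozen=True)
class CharacterOnTree:
    """A rooted cladogram plus a leaf→state map for one discrete character.

    ``states`` values equal to ``None`` or the string ``"nd"`` mark leaves
    with undetermined states; such leaves impose no constraint on the
    reconstruction.
    """

    tree: "dendropy.Tree"  # noqa: F821 - typed loosely to avoid a hard import here
    states: Mapping[str, str | None]
    name: str = "character"

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def __post_init__(self) -> None:
        leaves = self.leaf_labels()
        missing = [lf for lf in leaves if lf not in self.states]
        if missing:
            raise ValidationError(f"leaves without a state for {self.name!r}: {missing}")
        extra = [k for k in self.states if k not in leaves]
        if extra:
            raise ValidationError(f"state keys that are not tree leaves: {extra}")


@dataclass(frozen=True)
class ParsimonyResult:
    """Minimum-change reconstruction of one character on the cladogram."""

    character: str
    min_changes: int
    labeling: dict[str, str]  # one optimal assignment, internal nodes by id
    root_states: frozenset[str]


def parse_reasons(cell: str | None) -> frozenset[ExclusionReason]:
    """Parse a semicolon-separated exclusion-reason cell; empty/NA means none."""
    if cell is None or cell == "" or cell == "NA":
        return frozenset()
    out = set()
    for token in str(cell).split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            out.add(ExclusionReason(token))
        except ValueError as exc:
            raise ValidationError(f"unknown exclusion reason {token!r}") from exc
    return frozenset(out)


def format_reasons(reasons: Sequence[ExclusionReason] | frozenset[ExclusionReason]) -> str:
    return ";".join(sorted(r.value for r in reasons))
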