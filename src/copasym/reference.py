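"""Built-in study conditions: species parameters, census and cladogram.

This module freezes the quantitative conditions of the ten-species mating
study that the synthetic generator emulates: per-species courtship and
copulation duration distributions (mean, SD, observed range, sample size),
per-species true mean mating angles at the settling time point, the
minute-binned frontal tilt trajectory of *D. nannoptera*, the exclusion
census of the 315 recorded trials, the group cladogram and the discrete
sexual-character states mapped on it.
"""

from __future__ import annotations

from .datatypes import (
    CharacterOnTree,
    EventTimes,
    ExclusionReason,
    ExperimentRecord,
    SPECIES_CODES,
)
from .synthetic import SpeciesSimSpec

# ---------------------------------------------------------------------------
# Duration and angle parameters per species.
#
# Columns: courtship mean/SD/range/n [min], copulation mean/SD/range/n [min],
# settling-point true mean angle [deg].  Courtship was not measurable for
# D. acanthoptera (pairs were transferred only after copulation had begun).
# ---------------------------------------------------------------------------

DURATION_TABLE = {
    # code: (court_mean, court_sd, court_range, court_n,
    #        cop_mean,   cop_sd,   cop_range,   cop_n)
    "aca": (None, None, None, 0, 88.49, 35.18, (38.85, 144.3), 12),
    "pac": (4.67, 3.91, (0.17, 12.37), 18, 29.58, 7.86, (7.33, 42.63), 21),
    "nan": (1.89, 3.25, (0.05, 12.67), 15, 11.9, 4.2, (4.03, 20.1), 21),
    "mac": (1.97, 3.44, (0.08, 11.85), 13, 2.28, 0.53, (1.07, 3.55), 18),
    "bro": (2.07, 2.4, (0.23, 8.37), 10, 0.92, 0.28, (0.65, 1.73), 12),
    "moj": (1.56, 2.71, (0.13, 5.63), 4, 2.3, 0.35, (1.83, 2.57), 4),
    "buz": (2.87, 5.26, (0.08, 18.87), 15, 1.79, 0.65, (1.13, 3.42), 17),
    "tri": (5.17, 5.98, (0.68, 13.82), 4, 33.34, 9.54, (20.47, 42.15), 4),
    "wil": (5.72, 5.39, (0.53, 14.65), 5, 16.88, 2.58, (13.9, 21.55), 6),
    "mel": (13.48, 8.9, (2.55, 40.23), 27, 13.83, 4.33, (7.57, 24.55), 31),
}

#: True settling-point mean mating angles (deg, positive = female's right).
#: Only D. pachea and D. nannoptera mate one-sided; the rest scatter near 0.
SETTLING_ANGLE_MEAN = {
    "aca": -1.91,
    "pac": 21.40,
    "nan": 32.53,
    "mac": 5.76,
    "bro": -3.99,
    "moj": 3.00,
    "buz": 2.49,
    "tri": 3.62,
    "wil": 0.73,
    "mel": 6.62,
}

#: Between-experiment SD of the mating angle (deg), common default.
ANGLE_SD_DEG = 12.0

#: D. nannoptera frontal tilt trajectory: (bin start [min after copulation
#: start], true mean [deg], true SD [deg]); the male settles right-sided and
#: tilts further onto the female's right flank over the first minutes.
NAN_FRONTAL_TRAJECTORY = (
    (0, 10.36, 6.88),
    (1, 15.46, 8.82),
    (2, 23.44, 12.15),
    (3, 27.16, 10.81),
    (4, 29.10, 11.62),
    (5, 28.97, 11.92),
    (6, 32.48, 8.29),
    (7, 26.44, 10.20),
    (8, 23.21, 11.80),
    (9, 24.70, 13.66),
    (10, 18.65, 14.03),
    (11, 8.07, 10.0),  # single-trial bin; SD is a generator default, not an estimate
)


def default_specs() -> list[SpeciesSimSpec]:
    """Dorsal-view generator specs at the study's sample sizes and parameters."""
    specs = []
    for code in SPECIES_CODES:
        (cm, cs, cr, _cn, pm, ps, pr, pn) = DURATION_TABLE[code]
        specs.append(
            SpeciesSimSpec(
                species_code=code,
                n_experiments=pn,
                copulation_mean_min=pm,
                copulation_sd_min=ps,
                copulation_range_min=pr,
                courtship_mean_min=cm,
                courtship_sd_min=cs,
                courtship_range_min=cr,
                angle_trajectory=((0, SETTLING_ANGLE_MEAN[code], ANGLE_SD_DEG),),
                view="top",
            )
        )
    return specs


def nannoptera_frontal_spec(n_experiments: int = 29) -> SpeciesSimSpec:
    """Frontal-view generator spec for the *D. nannoptera* tilt analysis."""
    (cm, cs, cr, _cn, pm, ps, pr, _pn) = DURATION_TABLE["nan"]
    return SpeciesSimSpec(
        species_code="nan",
        n_experiments=n_experiments,
        copulation_mean_min=pm,
        copulation_sd_min=ps,
        copulation_range_min=pr,
        courtship_mean_min=cm,
        courtship_sd_min=cs,
        courtship_range_min=cr,
        angle_trajectory=NAN_FRONTAL_TRAJECTORY,
        view="frontal",
    )


# ---------------------------------------------------------------------------
# Exclusion census of the 315 recorded trials.
#
# Of 315 recordings, 111 were usable for courtship duration, 146 for
# copulation duration and 124 for posture.  Courtship discards (204):
# camera/file damaged 4, incomplete courtship recording 43, leg or wing
# damaged 27, no copulation within 45 min 129, multiple reasons 1.
# Copulation discards (169): camera/file damaged 4, incomplete copulation
# recording 7, leg or wing damaged 27, no copulation 129, multiple reasons 2.
# Of the 146 copulation-usable trials, 22 lacked visible landmarks (posture
# discard) and one further trial lost the female head from view at the 10%
# stable copulation time point only, leaving 123 images for the duplicate-
# measurement repeatability analysis.
# ---------------------------------------------------------------------------

R = ExclusionReason

#: copulation-usable trials per species (sums to 146)
_CENSUS_COP_N = {c: DURATION_TABLE[c][7] for c in SPECIES_CODES}
#: of those, trials whose courtship recording was incomplete (sums to 43);
#: all D. acanthoptera pairs were filmed only from copulation onward.
_CENSUS_COP_ONLY = {
    "aca": 12, "pac": 3, "nan": 6, "mac": 5, "bro": 2,
    "moj": 0, "buz": 2, "tri": 0, "wil": 1, "mel": 12,
}
#: courtship-usable trials whose copulation recording was incomplete (7),
#: plus one multi-reason trial; both groups assigned to D. melanogaster.
_CENSUS_COURT_ONLY_MEL = 7
#: posture exclusions (landmarks not visible) among the copulation-usable 146
_CENSUS_POSTURE_EXCL = {
    "aca": 2, "pac": 0, "nan": 0, "mac": 4, "bro": 2,
    "moj": 0, "buz": 4, "tri": 1, "wil": 1, "mel": 8,
}  # sums to 22


def make_census() -> list[ExperimentRecord]:
    """The full 315-trial census with exclusion reasons, no measurements.

    Deterministic; reproduces the study's retained counts exactly:
    111 courtship-usable, 146 copulation-usable, 124 posture-usable trials,
    and 123 images at the 10% stable copulation time point.
    """
    records: list[ExperimentRecord] = []
    counter = {c: 0 for c in SPECIES_CODES}

    def new_id(code: str) -> str:
        counter[code] += 1
        return f"{code}01_{counter[code]:02d}"

    def add(code: str, reasons: frozenset[ExclusionReason]) -> None:
        records.append(
            ExperimentRecord(
                experiment_id=new_id(code),
                species_code=code,
                temperature_C=25.0,
                events=EventTimes(),
                exclusion_reasons=reasons,
            )
        )

    # Copulation-usable trials, per species.
    posture_excluded = {c: 0 for c in SPECIES_CODES}
    head_out_assigned = False
    for code in SPECIES_CODES:
        for i in range(_CENSUS_COP_N[code]):
            reasons: set[ExclusionReason] = set()
            if i < _CENSUS_COP_ONLY[code]:
                reasons.add(R.INCOMPLETE_COURTSHIP_RECORDING)
            if posture_excluded[code] < _CENSUS_POSTURE_EXCL[code]:
                reasons.add(R.LANDMARKS_NOT_VISIBLE)
                posture_excluded[code] += 1
            elif not head_out_assigned and code == "mel":
                # posture-usable, but unusable at the 10% time point only
                reasons.add(R.FEMALE_HEAD_OUT_OF_VIEW)
                head_out_assigned = True
            add(code, frozenset(reasons))

    # Courtship-usable trials whose copulation recording was incomplete.
    for _ in range(_CENSUS_COURT_ONLY_MEL):
        add("mel", frozenset({R.INCOMPLETE_COPULATION_RECORDING}))
    # Multi-reason trial, discarded for copulation only (incomplete copulation
    # recording plus landmarks never visible).
    add("mel", frozenset({R.MULTIPLE, R.INCOMPLETE_COPULATION_RECORDING,
                          R.LANDMARKS_NOT_VISIBLE}))
    # Multi-reason trial discarded for both (wing damaged + incomplete courtship).
    add("mel", frozenset({R.MULTIPLE, R.LEG_OR_WING_DAMAGED,
                          R.INCOMPLETE_COURTSHIP_RECORDING}))

    # Trials unusable for both measurements, spread across species round-robin.
    unusable = (
        [frozenset({R.CAMERA_OR_FILE_DAMAGED})] * 4
        + [frozenset({R.LEG_OR_WING_DAMAGED})] * 27
        + [frozenset({R.NO_COPULATION_45MIN})] * 129
    )
    for j, reasons in enumerate(unusable):
        add(SPECIES_CODES[j % len(SPECIES_CODES)], reasons)

    assert len(records) == 315
    return records


# ---------------------------------------------------------------------------
# Cladogram and discrete sexual characters.
# ---------------------------------------------------------------------------

#: Rooted cladogram of the ten filmed species plus D. wassermani ("was"),
#: with the nannoptera group (nan,(was,(aca,pac))) nested inside successive
#: outgroups.  An alternative topology with the nannoptera-group species as
#: an unresolved polytomy (weak internal support) is provided alongside.
CLADOGRAM_NEWICK = "(mel,(wil,(tri,((buz,moj),(bro,(mac,(nan,(was,(aca,pac)))))))));"
CLADOGRAM_POLYTOMY_NEWICK = "(mel,(wil,(tri,((buz,moj),(bro,(mac,(nan,was,aca,pac)))))));"

#: Discrete character states per species; "nd" = not determined.
#: mating_position distinguishes the two right-sided postures: the upright
#: right-shifted posture of D. pachea and the right-tilted posture of
#: D. nannoptera; all other filmed species mate symmetrically.
CHARACTER_STATES: dict[str, dict[str, str]] = {
    "mating_position": {
        "nan": "tilted_right", "was": "nd", "aca": "symmetric", "pac": "upright_right",
        "mac": "symmetric", "bro": "symmetric", "moj": "symmetric", "buz": "symmetric",
        "tri": "symmetric", "wil": "symmetric", "mel": "symmetric",
    },
    "phallus": {
        "nan": "symmetric", "was": "nd", "aca": "asymmetric_bent",
        "pac": "asymmetric_gonopore",
        "mac": "symmetric", "bro": "symmetric", "moj": "symmetric", "buz": "symmetric",
        "tri": "nd", "wil": "nd", "mel": "symmetric",
    },
    "epandrial_lobes": {
        "nan": "symmetric", "was": "nd", "aca": "symmetric", "pac": "asymmetric",
        "mac": "symmetric", "bro": "nd", "moj": "symmetric", "buz": "symmetric",
        "tri": "nd", "wil": "nd", "mel": "symmetric",
    },
    "cerci": {
        "nan": "symmetric", "was": "asymmetric", "aca": "symmetric", "pac": "symmetric",
        "mac": "symmetric", "bro": "nd", "moj": "symmetric", "buz": "symmetric",
        "tri": "nd", "wil": "nd", "mel": "symmetric",
    },
    "sperm_length_class": {
        "nan": "giant", "was": "nd", "aca": "short", "pac": "giant",
        "mac": "nd", "bro": "nd", "moj": "short", "buz": "short",
        "tri": "nd", "wil": "nd", "mel": "short",
    },
    "sperm_storage_organ": {
        "nan": "receptacle", "was": "spermathecae", "aca": "spermathecae",
        "pac": "spermathecae",
        "mac": "nd", "bro": "nd", "moj": "receptacle", "buz": "receptacle",
        "tri": "nd", "wil": "nd", "mel": "receptacle",
    },
}


def characters_on_cladogram(polytomy: bool = False) -> list[CharacterOnTree]:
    """Bind the built-in character states to the group cladogram."""
    from .io import read_newick  # local import to avoid a cycle

    tree = read_newick(CLADOGRAM_POLYTOMY_NEWICK if polytomy else CLADOGRAM_NEWICK)
    out = []
    for name, states in CHARACTER_STATES.items():
        clean = {leaf: (None if s == "nd" else s) for leaf, s in states.items()}
        out.append(CharacterOnTree(tree=tree, states=clean, name=name))
    return out
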