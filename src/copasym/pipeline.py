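"""End-to-end orchestration: from event tables and landmark frames to reports.

Every numeric output is computed by exactly one upstream module function; this
layer only selects records, wires stages together and formats files.  All
output files are stamped with the seed and package version so a rerun with
the same configuration reproduces them byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import geometry, stats, timeline, traitmap
from .bilateral import directional_asymmetry_test
from .datatypes import (
    BilateralRecord,
    CharacterOnTree,
    COURTSHIP_DISCARD,
    COPULATION_DISCARD,
    ExclusionReason,
    ExperimentRecord,
    LandmarkObservation,
    POSTURE_ONLY_DISCARD,
    ValidationError,
)

log = logging.getLogger("copasym")


def _version() -> str:
    from . import __version__

    return __version__


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    seed: int = 1
    alpha: float = 0.05
    bonferroni_m: int = 10
    experiments_csv: Path | None = None
    landmarks_csv: Path | None = None
    frontal_landmarks_csv: Path | None = None
    bilateral_csv: Path | None = None
    tree_newick: Path | None = None
    characters_csv: Path | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        self.out_dir = Path(self.out_dir)


def _categorize(reasons: frozenset[ExclusionReason], relevant: frozenset) -> str:
    """Accounting category of one discarded trial for one measurement."""
    hits = reasons & relevant
    if ExclusionReason.MULTIPLE in reasons or len(hits) > 1:
        return ExclusionReason.MULTIPLE.value
    return next(iter(hits)).value


def accounting(records: Sequence[ExperimentRecord]) -> dict:
    """Retained/discarded bookkeeping for each measurement.

    For every measurement the per-reason discard counts sum to the number of
    discarded trials, and retained + discarded = total.  Trials annotated
    with several reasons are counted once, under the "multiple" category.
    """
    total = len(records)
    out: dict = {"total": total, "measurements": {}}
    for name, relevant, extra in (
        ("courtship_duration", COURTSHIP_DISCARD, frozenset()),
        ("copulation_duration", COPULATION_DISCARD, frozenset()),
        ("posture", COPULATION_DISCARD, POSTURE_ONLY_DISCARD),
    ):
        relevant_all = relevant | extra
        discarded = [r for r in records if r.exclusion_reasons & relevant_all]
        reasons_count: dict[str, int] = {}
        for r in discarded:
            cat = _categorize(r.exclusion_reasons, relevant_all)
            reasons_count[cat] = reasons_count.get(cat, 0) + 1
        out["measurements"][name] = {
            "retained": total - len(discarded),
            "discarded": len(discarded),
            "by_reason": dict(sorted(reasons_count.items())),
        }
    # the 10% stable-copulation time point additionally loses trials whose
    # female head left the camera field of view
    pct10_excl = POSTURE_ONLY_DISCARD | {ExclusionReason.FEMALE_HEAD_OUT_OF_VIEW}
    pct10_usable = [
        r
        for r in records
        if not (r.exclusion_reasons & (COPULATION_DISCARD | pct10_excl))
    ]
    out["pct10_images"] = len(pct10_usable)
    return out


def _format_accounting(acct: dict) -> str:
    lines = [f"total recorded experiments: {acct['total']}"]
    for name, m in acct["measurements"].items():
        lines.append(f"[{name}] retained {m['retained']}, discarded {m['discarded']}")
        for reason, k in m["by_reason"].items():
            lines.append(f"    {reason}: {k}")
    lines.append(f"images at 10% stable copulation time point: {acct['pct10_images']}")
    return "\n".join(lines) + "\n"


def durations_table(records: Sequence[ExperimentRecord]) -> pd.DataFrame:
    """Per-trial durations (minutes), restricted to usable trials per measurement."""
    rows = []
    for r in records:
        court, cop = timeline.durations(r.events)
        if not r.usable_for_courtship:
            court = None
        if not r.usable_for_copulation_duration:
            cop = None
        elif cop is not None and not timeline.is_valid_copulation(cop * 60.0):
            cop = None
        rows.append(
            {
                "experiment_id": r.experiment_id,
                "species_code": r.species_code,
                "courtship_min": court,
                "copulation_min": cop,
            }
        )
    return pd.DataFrame(rows)


def angles_table(observations: Iterable[LandmarkObservation]) -> pd.DataFrame:
    """Signed angles of all landmark observations, one row per measurement."""
    meas = [geometry.angle_of_observation(o) for o in observations]
    return pd.DataFrame(
        [
            {
                "experiment_id": m.experiment_id,
                "view": m.view,
                "timepoint_label": m.timepoint_label,
                "replicate_id": m.replicate_id,
                "angle_deg": m.angle_deg,
                "time_s": m.time_s,
            }
            for m in meas
        ]
    )


def _write(path: Path, header: str, body: str) -> None:
    path.write_text(header + body)


def run_pipeline(
    config: RunConfig,
    experiments: Sequence[ExperimentRecord] | None = None,
    observations: Sequence[LandmarkObservation] | None = None,
    frontal_observations: Sequence[LandmarkObservation] | None = None,
    frontal_experiments: Sequence[ExperimentRecord] | None = None,
    bilateral_records: Sequence[BilateralRecord] | None = None,
    characters: Sequence[CharacterOnTree] | None = None,
) -> dict:
    """Run every analysis stage for which inputs are available.

    Inputs may be passed in memory or read from the paths in *config*; the
    in-memory arguments win.  Returns a dict of in-memory results and writes
    the standard report files into ``config.out_dir``.
    """
    from . import io as cio

    cfg = config
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    header = f"# copasym {_version()} seed={cfg.seed} alpha={cfg.alpha} m={cfg.bonferroni_m}\n"
    results: dict = {}

    if experiments is None and cfg.experiments_csv is not None:
        experiments = cio.read_experiments(cfg.experiments_csv)
    if observations is None and cfg.landmarks_csv is not None:
        observations = cio.read_landmarks(cfg.landmarks_csv)
    if frontal_observations is None and cfg.frontal_landmarks_csv is not None:
        frontal_observations = cio.read_landmarks(cfg.frontal_landmarks_csv)
    if bilateral_records is None and cfg.bilateral_csv is not None:
        bilateral_records = cio.read_bilateral(cfg.bilateral_csv)
    if characters is None and cfg.characters_csv is not None:
        if cfg.tree_newick is None:
            raise ValidationError("characters.csv given without a newick tree")
        tree = cio.read_newick_file(cfg.tree_newick)
        characters = cio.read_characters(cfg.characters_csv, tree)

    if experiments is not None:
        log.info("accounting over %d experiments", len(experiments))
        acct = accounting(experiments)
        results["accounting"] = acct
        _write(cfg.out_dir / "accounting.txt", header, _format_accounting(acct))

        dur = durations_table(experiments)
        results["durations"] = dur
        summaries = []
        for col, label in (("courtship_min", "courtship"), ("copulation_min", "copulation")):
            if dur[col].notna().any():
                s = stats.species_summary(dur, value_col=col)
                s.insert(0, "measurement", label)
                summaries.append(s)
        if summaries:
            table1 = pd.concat(summaries, ignore_index=True)
            results["table1"] = table1
            with open(cfg.out_dir / "table1.csv", "w") as fh:
                fh.write(header)
                table1.to_csv(fh, index=False, na_rep="NA")
        cop = dur.dropna(subset=["copulation_min"])
        anova_text = ""
        if cop["species_code"].nunique() >= 2:
            aov = stats.one_way_anova(cop["copulation_min"], cop["species_code"])
            results["duration_anova"] = aov
            g, r = aov["group"], aov.residual
            anova_text += (
                "copulation duration ~ species: "
                f"df1={g.df}, df2={r.df}, F={g.F:.2f}, p={g.p:.3g}\n"
            )

    if observations is not None:
        log.info("computing angles for %d observations", len(observations))
        ang = angles_table(observations)
        results["angles"] = ang
        with open(cfg.out_dir / "angles.csv", "w") as fh:
            fh.write(header)
            ang.to_csv(fh, index=False, na_rep="NA")

        if experiments is not None:
            species_of = {e.experiment_id: e.species_code for e in experiments}
            ang = ang.assign(species_code=ang["experiment_id"].map(species_of))
            tests = []
            for tp in ("settling", "pct10"):
                for rep in sorted(ang["replicate_id"].unique()):
                    sub = ang[(ang["timepoint_label"] == tp) & (ang["replicate_id"] == rep)]
                    if sub.empty or sub["species_code"].nunique() < 2:
                        continue
                    tests.extend(
                        stats.species_angle_test(
                            sub, m=cfg.bonferroni_m,
                            timepoint_label=f"{tp}/rep{rep}",
                        )
                    )
            tests_df = pd.DataFrame([t.__dict__ for t in tests])
            results["tests"] = tests_df
            with open(cfg.out_dir / "tests.csv", "w") as fh:
                fh.write(header)
                tests_df.to_csv(fh, index=False, na_rep="NA")

            pct10 = ang[ang["timepoint_label"] == "pct10"].rename(
                columns={"experiment_id": "image_id"}
            )
            if not pct10.empty and pct10["replicate_id"].nunique() >= 2:
                rep_table, verdict = stats.repeatability_anova(pct10)
                results["repeatability"] = rep_table
                results["repeatability_verdict"] = verdict
                img, rep_row, res = rep_table["image"], rep_table["replicate"], rep_table.residual
                anova_text += (
                    "angle ~ image + replicate: "
                    f"image df1={img.df} F={img.F:.3f} p={img.p:.3g}; "
                    f"replicate df1={rep_row.df} F={rep_row.F:.3f} p={rep_row.p:.3g}; "
                    f"residual df2={res.df}\n    -> {verdict}\n"
                )

    if experiments is not None and anova_text:
        _write(cfg.out_dir / "anova.txt", header, anova_text)

    if frontal_observations is not None and (
        frontal_experiments is not None or experiments is not None
    ):
        fr = angles_table(frontal_observations)
        start_of = {
            e.experiment_id: e.events.copulation_start_s
            for e in (frontal_experiments if frontal_experiments is not None else experiments)
            if e.events.copulation_start_s is not None
        }
        fr = fr.assign(copulation_start_s=fr["experiment_id"].map(start_of)).dropna(
            subset=["copulation_start_s"]
        )
        summary = stats.interval_summary(fr)
        results["table3"] = summary
        rows = pd.DataFrame(
            [
                {
                    "interval_min": f"{s.interval_min[0]}-{s.interval_min[1]}",
                    "mean_deg": s.mean_deg,
                    "sd_deg": s.sd_deg,
                    "n": s.n,
                }
                for s in summary
            ]
        )
        with open(cfg.out_dir / "table3.csv", "w") as fh:
            fh.write(header)
            rows.to_csv(fh, index=False, na_rep="NA")

    if bilateral_records is not None:
        groups: dict[tuple[str, str], list[BilateralRecord]] = {}
        for rec in bilateral_records:
            groups.setdefault((rec.species_code, rec.structure), []).append(rec)
        reports = [
            directional_asymmetry_test(recs, alpha=cfg.alpha)
            for _, recs in sorted(groups.items())
        ]
        results["asymmetry"] = reports
        rep_df = pd.DataFrame(
            [
                {
                    "species_code": r.species_code,
                    "structure": r.structure,
                    "n": r.n,
                    "mean_signed_diff_um": r.mean_signed_diff_um,
                    "asymmetry_index_mean": r.asymmetry_index_mean,
                    "n_left_longer": r.sign_counts[0],
                    "n_right_longer": r.sign_counts[1],
                    "ties": r.sign_counts[2],
                    "p_sign": r.p_sign,
                    "p_t": r.p_t,
                    "verdict": r.verdict,
                }
                for r in reports
            ]
        )
        with open(cfg.out_dir / "asymmetry_report.csv", "w") as fh:
            fh.write(header)
            rep_df.to_csv(fh, index=False, na_rep="NA")

    if characters is not None:
        parsimony = [traitmap.fitch_min_changes(c) for c in characters]
        results["parsimony"] = parsimony
        lines = []
        for p in parsimony:
            roots = ",".join(sorted(p.root_states))
            lines.append(
                f"{p.character}: minimum changes = {p.min_changes} "
                f"(equally parsimonious root states: {roots})"
            )
        _write(cfg.out_dir / "parsimony.txt", header, "\n".join(lines) + "\n")

    return results


def run_synthetic(config: RunConfig) -> dict:
    """One-command synthetic end-to-end run at the built-in study conditions."""
    from . import reference
    from .synthetic import simulate, simulate_bilateral

    sim = simulate(reference.default_specs(), seed=config.seed)
    frontal = simulate([reference.nannoptera_frontal_spec()], seed=config.seed + 1)
    census = reference.make_census()
    bilateral_records: list[BilateralRecord] = []
    # paired spur/elongation lengths: a right-longer directional pattern in
    # D. acanthoptera, fluctuating-only variation elsewhere
    for i, (code, structure, true_index, sd, n) in enumerate(
        (
            ("aca", "apical_spur", -0.10, 0.05, 10),
            ("nan", "ventral_elongation", 0.0, 0.03, 15),
            ("mac", "lateral_hook", 0.0, 0.02, 10),
            ("bro", "lateral_ridge", 0.0, 0.02, 10),
        )
    ):
        recs, _ = simulate_bilateral(code, structure, true_index, sd, n, config.seed + 10 + i)
        bilateral_records.extend(recs)
    characters = reference.characters_on_cladogram()
    results = run_pipeline(
        config,
        experiments=sim.experiments,
        observations=sim.observations,
        frontal_observations=frontal.observations,
        frontal_experiments=frontal.experiments,
        bilateral_records=bilateral_records,
        characters=characters,
    )
    # accounting over the full census (the simulated experiments are all usable)
    acct = accounting(census)
    results["census_accounting"] = acct
    header = (
        f"# copasym {_version()} seed={config.seed} alpha={config.alpha} "
        f"m={config.bonferroni_m}\n"
    )
    _write(config.out_dir / "accounting.txt", header, _format_accounting(acct))
    results["sim"] = sim
    return results
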