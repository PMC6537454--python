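"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are comma-separated UTF-8 with a mandatory header row, ``.`` as the
decimal separator and ``NA`` for missing values.  Trees are newick.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .datatypes import (
    BilateralRecord,
    BlindingMap,
    CharacterOnTree,
    EventTimes,
    ExperimentRecord,
    LandmarkObservation,
    ValidationError,
    format_reasons,
    parse_reasons,
)

_EVENT_COLS = ("courtship_start_s", "copulation_start_s", "settling_s", "copulation_end_s")


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA"], keep_default_na=False, comment="#")


def _cell(row: pd.Series, col: str) -> float | None:
    if col not in row or pd.isna(row[col]):
        return None
    return float(row[col])


def read_experiments(path: str | Path) -> list[ExperimentRecord]:
    """Read an experiment-event table into validated :class:`ExperimentRecord` s.

    Required columns: ``experiment_id``, ``species_code``.  Optional:
    ``temperature_C``, the four event-time columns (seconds) and
    ``exclusion_reasons`` (semicolon-separated).  Missing cells stay missing;
    they are never coerced to zero.  Rows violating the event ordering or
    naming an unknown species are rejected with their row number.
    """
    df = _read_csv(path)
    for col in ("experiment_id", "species_code"):
        if col not in df.columns:
            raise ValidationError(f"experiments table must contain a {col!r} column")
    records: list[ExperimentRecord] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based, counting the header line
        try:
            events = EventTimes(**{c: _cell(row, c) for c in _EVENT_COLS})
            rec = ExperimentRecord(
                experiment_id=str(row["experiment_id"]),
                species_code=str(row["species_code"]),
                temperature_C=_cell(row, "temperature_C"),
                events=events,
                exclusion_reasons=parse_reasons(
                    None if "exclusion_reasons" not in row or pd.isna(row["exclusion_reasons"])
                    else str(row["exclusion_reasons"])
                ),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {rowno}: {exc}") from exc
        records.append(rec)
    return records


def write_experiments(records: Iterable[ExperimentRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "experiment_id": r.experiment_id,
                "species_code": r.species_code,
                "temperature_C": r.temperature_C,
                **{c: getattr(r.events, c) for c in _EVENT_COLS},
                "exclusion_reasons": format_reasons(r.exclusion_reasons) or "NA",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, na_rep="NA")


def blind_names(names: Sequence[str], seed: int) -> BlindingMap:
    """Replace movie names by seven-digit random codes, reproducibly.

    Codes are drawn without replacement from [1000000, 9999999], so every code
    has exactly seven digits and the map is a bijection.  The same seed always
    yields the same map.
    """
    names = list(names)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate names cannot be blinded: {dupes}")
    if len(names) > 9_000_000:
        raise ValidationError("more names than available 7-digit codes")
    rng = np.random.default_rng(seed)
    codes: list[str] = []
    seen: set[int] = set()
    while len(codes) < len(names):
        draw = int(rng.integers(1_000_000, 10_000_000))
        if draw not in seen:
            seen.add(draw)
            codes.append(str(draw))
    return BlindingMap(tuple(zip(names, codes)))


def write_blinding_map(bmap: BlindingMap, path: str | Path) -> None:
    pd.DataFrame(list(bmap.pairs), columns=["original", "code"]).to_csv(path, index=False)


def read_blinding_map(path: str | Path) -> BlindingMap:
    df = _read_csv(path)
    return BlindingMap(tuple(zip(df["original"].astype(str), df["code"].astype(str))))


def read_newick(text: str) -> dendropy.Tree:
    """Parse a rooted newick string, preserving child order; polytomies allowed."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise ValidationError(f"invalid newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None]
    if any(lf.taxon is None for lf in tree.leaf_node_iter()):
        raise ValidationError("invalid newick: unlabeled leaf")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"duplicate leaf labels: {dupes}")
    tree.is_rooted = True
    return tree


def read_newick_file(path: str | Path) -> dendropy.Tree:
    return read_newick(Path(path).read_text())


def read_landmarks(path: str | Path) -> list[LandmarkObservation]:
    """Read a long-format landmark table into per-frame observations.

    Columns: ``experiment_id, view, timepoint_label, replicate_id, label, x, y``
    and optionally ``time_s``; one row per landmark, three rows per frame.
    """
    df = _read_csv(path)
    required = {"experiment_id", "view", "timepoint_label", "replicate_id", "label", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"landmarks table missing columns: {sorted(missing)}")
    obs: list[LandmarkObservation] = []
    keys = ["experiment_id", "view", "timepoint_label", "replicate_id"]
    for (exp, view, tp, rep), grp in df.groupby(keys, sort=False):
        points = {str(r["label"]): (float(r["x"]), float(r["y"])) for _, r in grp.iterrows()}
        time_s = None
        if "time_s" in grp.columns and not grp["time_s"].isna().all():
            time_s = float(grp["time_s"].iloc[0])
        obs.append(
            LandmarkObservation(
                experiment_id=str(exp),
                view=str(view),
                timepoint_label=str(tp),
                replicate_id=int(rep),
                points=points,
                time_s=time_s,
            )
        )
    return obs


def write_landmarks(observations: Iterable[LandmarkObservation], path: str | Path) -> None:
    rows = []
    for o in observations:
        for label, (x, y) in sorted(o.points.items()):
            rows.append(
                {
                    "experiment_id": o.experiment_id,
                    "view": o.view,
                    "timepoint_label": o.timepoint_label,
                    "replicate_id": o.replicate_id,
                    "label": label,
                    "x": x,
                    "y": y,
                    "time_s": o.time_s,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, na_rep="NA")


def read_bilateral(path: str | Path) -> list[BilateralRecord]:
    """Read paired left/right structure lengths (micrometers)."""
    df = _read_csv(path)
    required = {"specimen_id", "species_code", "structure", "left_um", "right_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"bilateral table missing columns: {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                BilateralRecord(
                    specimen_id=str(row["specimen_id"]),
                    species_code=str(row["species_code"]),
                    structure=str(row["structure"]),
                    left_um=float(row["left_um"]),
                    right_um=float(row["right_um"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {int(idx) + 2}: {exc}") from exc
    return records


def write_bilateral(records: Iterable[BilateralRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "specimen_id": r.specimen_id,
                "species_code": r.species_code,
                "structure": r.structure,
                "left_um": r.left_um,
                "right_um": r.right_um,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_characters(path: str | Path, tree: dendropy.Tree) -> list[CharacterOnTree]:
    """Read a leaf/character/state table and bind each character to *tree*.

    The state value ``nd`` (not determined) is mapped to missing.
    """
    df = _read_csv(path)
    required = {"leaf", "character", "state"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"characters table missing columns: {sorted(missing)}")
    out = []
    for char, grp in df.groupby("character", sort=False):
        states = {}
        for _, row in grp.iterrows():
            state = row["state"]
            states[str(row["leaf"])] = None if (pd.isna(state) or state == "nd") else str(state)
        out.append(CharacterOnTree(tree=tree, states=states, name=str(char)))
    return out
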