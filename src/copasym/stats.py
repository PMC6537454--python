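"""Per-species directional tests, ANOVA tables and summary statistics.

The sidedness test fits a one-way gaussian linear model without intercept
(angle ~ species), so each species' coefficient is its sample mean angle and
its standard error uses the residual variance pooled across species.  The
null hypothesis angle = 0 is tested per species with an asymptotic-normal
(z) Wald statistic and Bonferroni correction over the family of species
tested at one time point.

ANOVA tables are computed in closed form for the two layouts the pipeline
needs — a one-way between-species fit and a balanced additive two-way
(image + replicate) repeatability fit — so that degenerate inputs (zero
residual variance) can be flagged explicitly; both are cross-checked against
scipy/statsmodels in the test suite.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    AnovaRow,
    AnovaTable,
    IntervalSummary,
    SpeciesAngleTest,
    ValidationError,
)


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m * p_raw)."""
    if not (0.0 <= p_raw <= 1.0):
        raise ValidationError(f"p-value must lie in [0, 1], got {p_raw}")
    if m < 1:
        raise ValidationError(f"family size must be a positive integer, got {m}")
    return min(1.0, m * p_raw)


def species_angle_test(
    angles: pd.DataFrame,
    m: int,
    timepoint_label: str = "",
    angle_col: str = "angle_deg",
    group_col: str = "species_code",
) -> list[SpeciesAngleTest]:
    """Test each species' mean mating angle against zero.

    *angles* holds one row per measurement with a species column and an angle
    column.  The per-species estimate is the sample mean; its standard error
    is pooled_residual_sd / sqrt(n_species); z = estimate / se; p_raw is the
    two-sided normal tail probability and p_bonf = min(1, m * p_raw) with the
    family size *m* given explicitly.
    """
    df = angles[[group_col, angle_col]].dropna()
    groups = df.groupby(group_col, sort=True)
    k = groups.ngroups
    if k < 2:
        raise ValidationError("sidedness testing requires at least two species")
    n_total = len(df)
    if n_total <= k:
        raise ValidationError("pooled residual variance needs more observations than species")
    means = groups[angle_col].mean()
    counts = groups[angle_col].count()
    sse = float(((df[angle_col] - df[group_col].map(means)) ** 2).sum())
    resid_df = n_total - k
    sigma2 = sse / resid_df
    if sigma2 <= 0:
        raise ValidationError("zero residual variance: sidedness test undefined")
    sigma = math.sqrt(sigma2)
    out = []
    for species in means.index:
        n_s = int(counts[species])
        est = float(means[species])
        se = sigma / math.sqrt(n_s)
        z = est / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        out.append(
            SpeciesAngleTest(
                species_code=str(species),
                timepoint_label=timepoint_label,
                n=n_s,
                estimate_deg=est,
                se_deg=se,
                z=z,
                p_raw=float(p_raw),
                p_bonf=bonferroni(float(p_raw), m),
            )
        )
    return out


def one_way_anova(values: Sequence[float], groups: Sequence[str]) -> AnovaTable:
    """One-way fixed-effects ANOVA, F = MS_between / MS_within.

    With k groups and N observations: df_between = k - 1, df_within = N - k.
    When every within-group residual is zero the F statistic is reported as
    +inf (between-group signal over zero noise) or flagged undefined (nan)
    when the between-group sum of squares is zero as well.
    """
    y = np.asarray(values, dtype=float)
    g = pd.Series(groups)
    if len(y) != len(g):
        raise ValidationError("values and groups must have equal length")
    labels = g.unique()
    k = len(labels)
    n = len(y)
    if k < 2:
        raise ValidationError("ANOVA requires at least two groups")
    if n <= k:
        raise ValidationError("ANOVA requires more observations than groups")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    group_means = pd.Series(y).groupby(g.values).transform("mean").to_numpy()
    ss_within = float(((y - group_means) ** 2).sum())
    ss_between = ss_total - ss_within
    df1, df2 = k - 1, n - k
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0.0:
        F = math.inf if ms_between > 0 else math.nan
        p = 0.0 if ms_between > 0 else math.nan
    else:
        F = ms_between / ms_within
        p = float(sps.f.sf(F, df1, df2))
    return AnovaTable(
        rows=(
            AnovaRow("group", df1, ss_between, ms_between, F, p),
            AnovaRow("residual", df2, ss_within, ms_within, None, None),
        )
    )


def repeatability_anova(angles: pd.DataFrame) -> tuple[AnovaTable, str]:
    """Additive two-way ANOVA (angle ~ image + replicate) for repeatability.

    Requires a complete layout: every image measured exactly once under every
    replicate round.  Both factors are tested against the additive-model
    residual.  Returns the table plus a verdict string: the measurement is
    called repeatable when the replicate effect is negligible (p > 0.05).

    Columns: ``image_id``, ``replicate_id``, ``angle_deg``.
    """
    required = {"image_id", "replicate_id", "angle_deg"}
    missing = required - set(angles.columns)
    if missing:
        raise ValidationError(f"repeatability table missing columns: {sorted(missing)}")
    wide = angles.pivot_table(
        index="image_id", columns="replicate_id", values="angle_deg", aggfunc="count"
    )
    bad = wide.index[wide.isna().any(axis=1) | (wide != 1).any(axis=1)].tolist()
    if bad:
        raise ValidationError(f"incomplete image x replicate layout for images: {bad}")
    y = angles.pivot(index="image_id", columns="replicate_id", values="angle_deg").to_numpy()
    a, b = y.shape  # images x replicates
    if a < 2 or b < 2:
        raise ValidationError("repeatability needs >= 2 images and >= 2 replicate rounds")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    row_means = y.mean(axis=1, keepdims=True)
    col_means = y.mean(axis=0, keepdims=True)
    ss_image = float(b * ((row_means - grand) ** 2).sum())
    ss_rep = float(a * ((col_means - grand) ** 2).sum())
    ss_resid = ss_total - ss_image - ss_rep
    df_image, df_rep = a - 1, b - 1
    df_resid = (a - 1) * (b - 1)
    ms_image, ms_rep = ss_image / df_image, ss_rep / df_rep
    ms_resid = ss_resid / df_resid
    if ms_resid <= 0:
        f_image = math.inf if ms_image > 0 else 0.0
        f_rep = math.inf if ms_rep > 0 else 0.0
        p_image = 0.0 if ms_image > 0 else 1.0
        p_rep = 0.0 if ms_rep > 0 else 1.0
    else:
        f_image = ms_image / ms_resid
        f_rep = ms_rep / ms_resid
        p_image = float(sps.f.sf(f_image, df_image, df_resid))
        p_rep = float(sps.f.sf(f_rep, df_rep, df_resid))
    table = AnovaTable(
        rows=(
            AnovaRow("image", df_image, ss_image, ms_image, f_image, p_image),
            AnovaRow("replicate", df_rep, ss_rep, ms_rep, f_rep, p_rep),
            AnovaRow("residual", df_resid, ss_resid, ms_resid, None, None),
        )
    )
    verdict = (
        "replicate effect negligible (measurement repeatable)"
        if p_rep > 0.05
        else "replicate effect significant (measurement not repeatable)"
    )
    return table, verdict


def interval_summary(
    frontal_angles: pd.DataFrame,
    bin_width_min: float = 1.0,
) -> list[IntervalSummary]:
    """Minute-binned summary of frontal tilt angles after copulation start.

    Rows need ``experiment_id``, ``angle_deg``, ``time_s`` and
    ``copulation_start_s``.  Within each experiment all measurements falling
    in a bin are first averaged; the reported mean and SD (n-1 denominator)
    are then taken across experiments, with n the number of experiments
    contributing to the bin.  SD is missing when n = 1.
    """
    required = {"experiment_id", "angle_deg", "time_s", "copulation_start_s"}
    missing = required - set(frontal_angles.columns)
    if missing:
        raise ValidationError(f"interval summary missing columns: {sorted(missing)}")
    df = frontal_angles.copy()
    rel_min = (df["time_s"] - df["copulation_start_s"]) / 60.0
    if (rel_min < -1e-9).any():
        bad = df.loc[rel_min < -1e-9, "experiment_id"].unique().tolist()
        raise ValidationError(f"measurements before copulation start in: {bad}")
    df["bin"] = np.floor(rel_min.clip(lower=0.0) / bin_width_min).astype(int)
    per_exp = df.groupby(["bin", "experiment_id"])["angle_deg"].mean().reset_index()
    out = []
    for b, grp in per_exp.groupby("bin", sort=True):
        vals = grp["angle_deg"].to_numpy()
        n = len(vals)
        out.append(
            IntervalSummary(
                interval_min=(int(b * bin_width_min), int((b + 1) * bin_width_min)),
                mean_deg=float(vals.mean()),
                sd_deg=float(vals.std(ddof=1)) if n > 1 else None,
                n=n,
            )
        )
    return out


def species_summary(
    durations: pd.DataFrame,
    value_col: str,
    group_col: str = "species_code",
) -> pd.DataFrame:
    """Per-species mean, SD (n-1), range and n of a duration column (minutes)."""
    df = durations[[group_col, value_col]].dropna()
    if df.empty:
        raise ValidationError("no values to summarize")
    agg = df.groupby(group_col)[value_col].agg(
        mean="mean", sd=lambda v: v.std(ddof=1), min="min", max="max", n="count"
    )
    agg["n"] = agg["n"].astype(int)
    return agg.reset_index()
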