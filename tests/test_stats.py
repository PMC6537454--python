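"""Directional tests, ANOVA layouts and summary tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from copasym.datatypes import ValidationError
from copasym.stats import (
    bonferroni,
    interval_summary,
    one_way_anova,
    repeatability_anova,
    species_angle_test,
    species_summary,
)


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [(0.2, 10, 1.0), (0.004, 10, 0.04), (0.0, 5, 0.0)])
    def test_values(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_monotone_and_never_decreases(self, rng):
        ps = np.sort(rng.uniform(0, 1, 50))
        corrected = [bonferroni(p, 10) for p in ps]
        assert corrected == sorted(corrected)
        assert all(c >= p for p, c in zip(ps, corrected))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bonferroni(1.5, 10)


def _angles_frame(means, sds, ns, rng):
    rows = []
    for code, mu, sd, n in zip([f"sp{i}" for i in range(len(means))], means, sds, ns):
        for a in rng.normal(mu, sd, n):
            rows.append({"species_code": code, "angle_deg": a})
    return pd.DataFrame(rows)


class TestSpeciesAngleTest:
    def test_estimate_is_species_mean(self, rng):
        df = _angles_frame([5.0, 0.0], [0.0, 3.0], [4, 30], rng)
        tests = {t.species_code: t for t in species_angle_test(df, m=2)}
        assert tests["sp0"].estimate_deg == pytest.approx(5.0)

    def test_matches_statsmodels_no_intercept_fit(self, rng):
        import statsmodels.formula.api as smf

        df = _angles_frame([10.0, -3.0, 0.5], [4, 4, 4], [8, 12, 5], rng)
        fit = smf.ols("angle_deg ~ C(species_code) - 1", data=df).fit()
        tests = species_angle_test(df, m=3)
        for t in tests:
            coef = f"C(species_code)[{t.species_code}]"
            assert t.estimate_deg == pytest.approx(fit.params[coef], rel=1e-10)
            assert t.se_deg == pytest.approx(fit.bse[coef], rel=1e-10)
            z = fit.params[coef] / fit.bse[coef]
            assert t.p_raw == pytest.approx(2 * sps.norm.sf(abs(z)), rel=1e-10)

    def test_negation_antisymmetry(self, rng):
        df = _angles_frame([12.0, 1.0, -4.0], [3, 3, 3], [10, 10, 10], rng)
        neg = df.assign(angle_deg=-df["angle_deg"])
        t1 = species_angle_test(df, m=3)
        t2 = species_angle_test(neg, m=3)
        for a, b in zip(t1, t2):
            assert a.estimate_deg == pytest.approx(-b.estimate_deg)
            assert abs(a.z) == pytest.approx(abs(b.z))
            assert a.p_bonf == pytest.approx(b.p_bonf)

    def test_true_one_sided_species_detected_among_nulls(self, rng):
        # one species at +32.5 deg (sd 12, n 21) among nine null species
        means = [32.5] + [0.0] * 9
        df = _angles_frame(means, [12.0] * 10, [21] + [12] * 9, rng)
        tests = {t.species_code: t for t in species_angle_test(df, m=10)}
        target = tests["sp0"]
        assert target.p_bonf < 0.001
        assert abs(target.estimate_deg - 32.5) < 2 * target.se_deg

    def test_zero_residual_variance_rejected(self):
        df = pd.DataFrame({"species_code": ["a", "a", "b", "b"], "angle_deg": [1, 1, 2, 2]})
        with pytest.raises(ValidationError, match="residual variance"):
            species_angle_test(df, m=2)


class TestOneWayAnova:
    def test_dfs_and_F_against_scipy(self, rng):
        groups = ["g1"] * 12 + ["g2"] * 21 + ["g3"] * 7
        values = rng.normal([0] * 12 + [3] * 21 + [1] * 7, 1.0)
        table = one_way_anova(values, groups)
        assert table["group"].df == 2
        assert table.residual.df == 37
        F, p = sps.f_oneway(values[:12], values[12:33], values[33:])
        assert table["group"].F == pytest.approx(F, rel=1e-10)
        assert table["group"].p == pytest.approx(p, rel=1e-10)

    def test_ss_decomposition_and_shift_invariance(self, rng):
        values = rng.normal(0, 2, 30)
        groups = [f"g{i % 3}" for i in range(30)]
        t1 = one_way_anova(values, groups)
        total = ((values - values.mean()) ** 2).sum()
        assert t1["group"].ss + t1.residual.ss == pytest.approx(total, rel=1e-8)
        t2 = one_way_anova(values + 100.0, groups)
        assert t2["group"].F == pytest.approx(t1["group"].F, rel=1e-9)

    def test_zero_within_variance_flagged_infinite(self):
        table = one_way_anova([0.0, 0.0, 1.0, 1.0], ["a", "a", "b", "b"])
        assert table["group"].F == np.inf

    def test_p_value_matches_permutation_oracle(self, rng):
        values = list(rng.normal(0, 1, 8)) + list(rng.normal(1.2, 1, 8))
        groups = ["a"] * 8 + ["b"] * 8
        table = one_way_anova(values, groups)
        obs_F = table["group"].F
        values = np.array(values)
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(values)
            if one_way_anova(perm, groups)["group"].F >= obs_F:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(table["group"].p - p_perm) < mc_err + 0.01


class TestRepeatability:
    @staticmethod
    def _layout(n_images, image_sd, replicate_shift, noise_sd, rng):
        image_effect = rng.normal(0, image_sd, n_images)
        rows = []
        for i in range(n_images):
            for rep in (1, 2):
                rows.append(
                    {
                        "image_id": f"img{i:03d}",
                        "replicate_id": rep,
                        "angle_deg": image_effect[i]
                        + (replicate_shift if rep == 2 else 0.0)
                        + rng.normal(0, noise_sd),
                    }
                )
        return pd.DataFrame(rows)

    def test_dfs_for_123_images_twice(self, rng):
        df = self._layout(123, 10.0, 0.0, 1.0, rng)
        table, verdict = repeatability_anova(df)
        assert table["image"].df == 122
        assert table["replicate"].df == 1
        assert table.residual.df == 122
        assert "repeatable" in verdict

    def test_matches_statsmodels_additive_fit(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = self._layout(20, 5.0, 0.5, 1.0, rng)
        table, _ = repeatability_anova(df)
        fit = smf.ols("angle_deg ~ C(image_id) + C(replicate_id)", data=df).fit()
        aov = sm.stats.anova_lm(fit, typ=2)
        assert table["image"].F == pytest.approx(aov.loc["C(image_id)", "F"], rel=1e-8)
        assert table["replicate"].F == pytest.approx(
            aov.loc["C(replicate_id)", "F"], rel=1e-8
        )

    def test_identical_replicates_give_zero_replicate_ss(self, rng):
        df = self._layout(10, 5.0, 0.0, 0.0, rng)
        table, verdict = repeatability_anova(df)
        assert table["replicate"].ss == pytest.approx(0.0, abs=1e-18)
        assert "repeatable" in verdict

    def test_image_variation_dominates_replicate(self, rng):
        """Variance from images (sd 10) dwarfs a null replicate effect: in 100
        simulated layouts the image F always exceeds the replicate F."""
        wins = 0
        for _ in range(100):
            df = self._layout(40, 10.0, 0.0, 1.0, rng)
            table, _ = repeatability_anova(df)
            if table["image"].F > table["replicate"].F:
                wins += 1
        assert wins >= 99

    def test_incomplete_layout_rejected_with_image_ids(self, rng):
        df = self._layout(5, 1.0, 0.0, 1.0, rng).iloc[:-1]
        with pytest.raises(ValidationError, match="img004"):
            repeatability_anova(df)


class TestIntervalSummary:
    def test_within_experiment_averaging_before_pooling(self):
        df = pd.DataFrame(
            {
                "experiment_id": ["e1", "e1", "e2"],
                "angle_deg": [10.0, 14.0, 12.0],
                "time_s": [110.0, 150.0, 130.0],
                "copulation_start_s": [100.0, 100.0, 100.0],
            }
        )
        (s,) = interval_summary(df)
        assert s.interval_min == (0, 1)
        assert s.mean_deg == pytest.approx(12.0)
        assert s.n == 2

    def test_single_experiment_bin_has_missing_sd(self):
        df = pd.DataFrame(
            {
                "experiment_id": ["e1"],
                "angle_deg": [8.07],
                "time_s": [700.0],
                "copulation_start_s": [0.0],
            }
        )
        (s,) = interval_summary(df)
        assert s.interval_min == (11, 12)
        assert s.sd_deg is None and s.n == 1

    def test_measurement_before_copulation_start_rejected(self):
        df = pd.DataFrame(
            {
                "experiment_id": ["e1"],
                "angle_deg": [0.0],
                "time_s": [50.0],
                "copulation_start_s": [100.0],
            }
        )
        with pytest.raises(ValidationError):
            interval_summary(df)


def test_species_summary_basics():
    df = pd.DataFrame({"species_code": ["a"] * 3, "courtship_min": [1.0, 2.0, 3.0]})
    out = species_summary(df, "courtship_min")
    row = out.iloc[0]
    assert row["mean"] == 2.0 and row["sd"] == 1.0
    assert (row["min"], row["max"], row["n"]) == (1.0, 3.0, 3)
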