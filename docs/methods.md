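# Methods

## Scope and data model

The pipeline starts downstream of video capture: its inputs are manually
annotated event times (courtship start, copulation start, settling,
copulation end; seconds from recording start), manually placed landmark
coordinates per extracted frame (pixels, y axis pointing down), paired
left/right structure lengths (µm), and a rooted cladogram with leaf
character states.  Ten species are modeled, identified by three-letter codes
(aca, pac, nan, mac, bro, moj, buz, tri, wil, mel), with *D. wassermani*
("was") appearing only as a cladogram leaf with mostly undetermined states.
Event times are stored in seconds and converted to minutes only for
reporting.  Trials carry exclusion-reason sets; usability flags (courtship /
copulation duration / posture) are derived from the reasons rather than
stored, so the accounting identity retained + discarded = total holds by
construction.  A trial annotated with several reasons carries a `multiple`
marker and is counted once, under a "multiple reasons" category, keeping
per-reason counts summing exactly to the discard total.

Blinding replaces movie names by seven-digit codes drawn without replacement
from [1000000, 9999999] with a seeded generator: bijective, reproducible,
and guaranteed seven digits.

## Timeline rules

A mount counts as a copulation start only if the male remains mounted at
least 15 s (inclusive threshold).  The posture schedule measures at the
settling point and the 10% stable-copulation point
t_s + 0.1 (t_e − t_s); species whose mean copulation exceeds 2.5, 15 or
60 min (strict comparisons) add a grid every 2.5, 5 or 10 min.  Choices the
source protocol leaves open, fixed here: the grid is anchored at the
settling point (the trajectory plots' time axis starts there); grid points
lie strictly after settling and at most at copulation end; a grid point
within 1 s of the 10% point is dropped as a duplicate; schedule times snap
to the nearest available frame with ties broken toward the earlier frame;
the species mean used for the step is computed from the trials retained for
copulation duration.

## Angle statistics

Both angles are *deviation* angles of the male head from a female body axis,
signed positive toward the female's right, ranging over (−180°, 180°].  With
u the female axis direction and v the axis-to-male-head direction, the
statistic is −deg(atan2(u×v, u·v)) in y-down coordinates.  In the dorsal
view u runs from female head tip (P1) to scutellum tip (P2) and v from P2 to
the male head (P3); a perfectly aligned couple scores 0, which matches the
near-zero values reported for symmetric maters (the raw interior angle
P1-P2-P3 would score ~180° there; the deviation form, 180° minus the
interior angle with a sign, is adopted as the canonical statistic).  The
frontal view mirrors left/right, so the sign convention absorbs the
reflection: a male tilted toward −x (viewer's left = female's right) scores
positive.  Both statistics are exactly invariant under similarity transforms
without reflection, which is why arbitrary, unknown camera pose affects at
most the magnitude, never the sign — the analysis therefore treats the sign
(and the species mean) as the reliable quantity, and no attempt is made to
model the magnitude bias of oblique views.

Bookstein two-point registration maps each dorsal frame by the unique
orientation-preserving similarity z ↦ i(z − P1)/(P2 − P1) sending
P1 → (0,0), P2 → (0,1); it is idempotent and preserves the signed angle to
machine precision.  Baselines shorter than 1 px are rejected as degenerate
rather than warned about.

## Statistical tests

*Sidedness.*  One-way gaussian linear model without intercept
(angle ~ species): estimates are species means, standard errors use the
residual variance pooled across species, and the null angle = 0 is tested
per species by a z (asymptotic normal) Wald statistic — matching
GLM-contrast machinery rather than t intervals.  Bonferroni correction uses
an explicit family size, m = 10 by default (the species tested at one time
point); the family is never inferred silently.  The closed-form fit is
cross-checked in the test suite against a statsmodels OLS no-intercept fit.

*Duration ANOVA.*  Classical one-way fixed-effects table (df1 = k−1,
df2 = N−k).  Zero within-group variance is flagged (F = ∞, or undefined when
the between-group signal is also zero) instead of propagating NaNs.
Cross-checked against `scipy.stats.f_oneway` and a permutation oracle.

*Repeatability.*  The duplicate landmark acquisitions are partitioned by a
balanced additive two-way ANOVA (angle ~ image + replicate), both factors
tested against the additive residual with df = (a−1)(b−1); the measurement
is called repeatable when the replicate effect's p > 0.05.  Published
df values for this layout are mutually inconsistent with a single additive
fit (they suggest two sequential one-factor fits); this package deliberately
exposes both factor tests from one additive model and documents the
difference rather than guessing.  Note that with a truly null replicate
effect the verdict is itself a 5%-level test: about one seed in twenty will
read "not repeatable" by chance.

*Frontal trajectory.*  Tilt angles are binned per minute after copulation
start; within each experiment all measurements in a bin are averaged first,
then the mean ± SD (n−1) is taken across experiments, with n the number of
experiments contributing; SD is reported missing when n = 1.

*Bilateral DA/FA.*  The source comparison of left/right spur lengths is
qualitative ("consistently longer"); this package formalizes it as an exact
two-sided binomial sign test on non-tied signs of L − R plus a one-sample
two-sided t test on the signed differences, declaring directional asymmetry
(toward the side with the larger mean) only when min(p_sign, p_t) < α = 0.05
*and* the sign majority agrees — a deliberately conservative conjunction.
Differences below 0.5 µm (measurement resolution) count as ties and leave
the sign test.  Samples with n < 5 are labelled insufficient, because a
two-sided sign test cannot reach p < 0.05 below n = 6.

*Parsimony.*  Unit-cost minimum-change reconstruction via the Sankoff
dynamic program, which generalizes Fitch's method exactly to polytomies and
missing leaf states ("nd" leaves contribute no constraint).  The witness
labeling uses a deterministic alphabetical tie-break.  Scenario enumeration
is exhaustive over internal labelings and restricted to ≤ 12 leaves.  The
built-in cladogram nests (nan,(was,(aca,pac))) inside successive outgroups;
because the internode supporting the (was,(aca,pac)) resolution is weak, an
alternative topology with the four group species as a polytomy ships
alongside, and the mating-position minimum of two changes holds on both.
Gains and losses are weighted equally; no asymmetric-cost variant is
offered.

## Synthetic generator

The generator emulates, per species: copulation and courtship durations from
normal distributions truncated to the observed ranges (and to ≥ 15 s) —
means, SDs, ranges and sample sizes follow the study conditions (e.g.
copulation 88.49 ± 35.18 min at n = 12 for *D. acanthoptera*, 11.9 ± 4.2 at
n = 21 for *D. nannoptera*, 0.92 ± 0.28 at n = 12 for *D. bromeliae*; the
ten copulation ns sum to 146, the courtship ns to 111); the settling point
uniform within the first 20% of copulation; true mean angles per species
(+21.4° for pac, +32.5° for nan, near 0 elsewhere) with a common 12°
between-experiment SD, decomposed into a 5° per-experiment random intercept
(posture consistency within a couple) plus residual; the *D. nannoptera*
frontal trajectory as a rise-then-plateau of per-minute bin means (10.36° in
minute 0–1 up to ~29° around minutes 4–7); frames every 20 s in the frontal
view.  Landmarks are placed on an ideal couple with a 100-px female axis,
transformed by a random camera pose (rotation U[0,2π), scale U[0.5,2],
translation within an 800×600 frame), with independent 2-px Gaussian noise
per coordinate and per replicate.  With zero noise the measured angle equals
the generating angle to 1e-9°, closing the loop between generator and
geometry.  Paired bilateral lengths are generated as L = base(1 + d/2),
R = base(1 − d/2) with d ~ Normal(true index, sd), so the per-specimen
normalized index equals d exactly.

What the generator does *not* emulate: pixel rendering and landmark-
placement behaviour of human scorers (noise is isotropic Gaussian, real
placement error is not), occlusion and visibility loss over time, behavioral
autocorrelation beyond the random intercept, oblique-view magnitude bias
(poses are in-plane similarities), and any courtship behavioral structure.
Passing recovery tests therefore show the estimators are correct and well
calibrated under the stated noise model — not that the noise model captures
every property of real video scoring.

A deterministic census fixture reproduces the exclusion bookkeeping of the
315 recorded trials exactly (111/146/124 usable; discard categories
4+43+27+129+1 and 4+7+27+129+2; 22 posture exclusions; one trial usable
except at the 10% time point, leaving 123 repeatability images).  The
record-level assignment of reason combinations is constructed, not recorded
in the source tables: reason combinations were chosen as the simplest set
consistent with every published count, with the courtship-incomplete trials
distributed so each species' courtship/copulation sample-size pair is met
(all *D. acanthoptera* trials lack courtship recordings, as that species was
filmed only from copulation onward).

## Numerical and reproducibility choices

All simulations and the blinding scheme consume a single integer seed
through `numpy.random.default_rng`; identical seeds give byte-identical
outputs, and every report file is stamped with seed and package version.
Truncating durations at the observed ranges shrinks the realized
within-species SD below the nominal one (most visibly for *D. acanthoptera*,
whose range spans only ±1.5 SD), which inflates the simulated duration-ANOVA
F statistic relative to an untruncated model; degrees of freedom are
unaffected.  Angle computations reject exactly coincident landmarks;
registration rejects sub-pixel baselines.  Statistical-property tests run at
fixed problem sizes chosen to keep the whole suite around half a minute on
one core (200 recovery seeds, 1000 type-I replicates, 2000 null DA/FA
samples, 200 random parsimony trees), with Monte-Carlo slack terms included
in the acceptance bounds.

## Known limitations

Magnitudes of measured angles in oblique real views are biased in ways the
in-plane pose model cannot show; only signs and species contrasts should be
interpreted.  The additive repeatability model assumes no image × replicate
interaction.  The DA/FA classifier conditions on a fixed 0.5 µm tie
resolution.  The cladogram is consumed as given — no uncertainty in topology
is propagated beyond the alternative polytomy topology.  Duration
distributions are an assumption (truncated normal); only their first two
moments and ranges are constrained by the study conditions.
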