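"""Directional versus fluctuating asymmetry of paired left/right lengths.

Directional asymmetry (DA) is a consistent left-right bias shared across
specimens (e.g. a right apical spur consistently longer than the left);
fluctuating asymmetry (FA) is random, zero-mean deviation between sides.  The
classifier combines an exact two-sided binomial sign test on the non-tied
signs of L - R with a one-sample two-sided t test on the signed differences,
and only declares directionality when the test evidence and the sign majority
agree.  Neither test alone is treated as sufficient; the paired-length data
sets in this domain are small and the combined rule is deliberately
conservative.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps

from .datatypes import AsymmetryResult, BilateralRecord, ValidationError

#: Differences below the measurement resolution count as ties (micrometers).
TIE_RESOLUTION_UM = 0.5

#: Below this sample size no verdict is attempted: a two-sided sign test
#: cannot reach p < 0.05 with fewer than six informative specimens.
MIN_N_FOR_VERDICT = 5


def asymmetry_scores(
    records: Sequence[BilateralRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-specimen signed difference L - R (um) and normalized index 2(L-R)/(L+R).

    The index is dimensionless and lies in (-2, 2); swapping left and right
    negates both scores.
    """
    if not records:
        raise ValidationError("no bilateral records")
    left = np.array([r.left_um for r in records], dtype=float)
    right = np.array([r.right_um for r in records], dtype=float)
    diff = left - right
    index = 2.0 * diff / (left + right)
    return diff, index


def directional_asymmetry_test(
    records: Sequence[BilateralRecord],
    alpha: float = 0.05,
    tie_resolution_um: float = TIE_RESOLUTION_UM,
) -> AsymmetryResult:
    """Classify one species/structure sample as directional or fluctuating.

    Verdicts:

    - ``insufficient`` when n < 5;
    - ``directional_left`` / ``directional_right`` (toward the side with the
      larger mean length) when min(p_sign, p_t) < alpha and the non-tied sign
      majority points the same way;
    - ``fluctuating_only`` otherwise.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    species = {r.species_code for r in records}
    structures = {r.structure for r in records}
    if len(species) != 1 or len(structures) != 1:
        raise ValidationError(
            "directional_asymmetry_test expects one species and one structure per call"
        )
    diff, index = asymmetry_scores(records)
    n = len(diff)
    n_left = int((diff > tie_resolution_um).sum())
    n_right = int((diff < -tie_resolution_um).sum())
    ties = n - n_left - n_right
    n_informative = n_left + n_right

    if n_informative > 0:
        p_sign = float(sps.binomtest(n_left, n_informative, 0.5).pvalue)
    else:
        p_sign = 1.0
    if n >= 2 and float(np.std(diff, ddof=1)) > 0:
        p_t = float(sps.ttest_1samp(diff, 0.0).pvalue)
    elif n >= 2:
        # zero variance: all differences identical
        p_t = 0.0 if abs(float(diff[0])) > 0 else 1.0
    else:
        p_t = 1.0

    mean_diff = float(diff.mean())
    if n < MIN_N_FOR_VERDICT:
        verdict = "insufficient"
    else:
        direction = "directional_left" if mean_diff > 0 else "directional_right"
        majority_agrees = (n_left > n_right) if mean_diff > 0 else (n_right > n_left)
        if min(p_sign, p_t) < alpha and majority_agrees:
            verdict = direction
        else:
            verdict = "fluctuating_only"
    return AsymmetryResult(
        species_code=next(iter(species)),
        structure=next(iter(structures)),
        n=n,
        mean_signed_diff_um=mean_diff,
        asymmetry_index_mean=float(index.mean()),
        sign_counts=(n_left, n_right, ties),
        p_sign=p_sign,
        p_t=p_t,
        verdict=verdict,
    )
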