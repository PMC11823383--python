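"""Welch-based classification of the drug-drug interaction.

The experimentally fitted mixture IC50 is compared against the additive
prediction with the unpaired Welch t-test (Satterthwaite degrees of
freedom, fractional allowed).  A non-significant difference is read as
additivity; a mixture significantly more potent than the additive
reference is synergy, significantly less potent is antagonism.  For
non-parallel predictions the comparison runs against the bound nearer to
the observed mixture IC50 (ties resolved toward the lower bound).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy import stats

from .isobolography import AdditivePrediction
from .probit_core import PotencyEstimate

__all__ = [
    "WelchComparison",
    "InteractionCall",
    "welch_compare",
    "choose_reference",
    "classify",
    "p_two_sided",
]

ReferenceBound = Literal["single", "lower", "upper"]
Classification = Literal["synergistic", "additive", "antagonistic"]


@dataclass(frozen=True)
class WelchComparison:
    """Result of one unpaired Welch comparison.

    ``t_stat`` is stored non-negative; ``difference`` keeps the signed
    mixture-minus-reference difference in µM.
    """

    t_stat: float
    df: float
    p_value: float
    reference_bound: ReferenceBound
    difference: float
    degenerate: bool = False


@dataclass(frozen=True)
class InteractionCall:
    classification: Classification
    alpha: float
    comparison: WelchComparison


def p_two_sided(t: float, df: float) -> float:
    """Two-sided tail probability of Student's t at (possibly fractional) df."""
    if df <= 0:
        raise ValueError(f"df must be positive, got {df!r}")
    return float(2.0 * stats.t.sf(abs(t), df))


def welch_compare(
    mix: PotencyEstimate,
    reference_ic50: float,
    reference_sem: float,
    reference_n: int,
    reference_bound: ReferenceBound = "single",
) -> WelchComparison:
    """Unpaired Welch t-test between the mixture IC50 and a reference IC50.

    t  = |IC50_mix − IC50_ref| / sqrt(sem_mix² + sem_ref²)
    df = (sem_mix² + sem_ref²)² /
         (sem_mix⁴/(n_mix − 1) + sem_ref⁴/(n_ref − 1))
    """
    if mix.n_items < 2 or reference_n < 2:
        raise ValueError("both item counts must be >= 2")
    if mix.sem < 0 or reference_sem < 0:
        raise ValueError("SEMs must be non-negative")
    diff = mix.ic50 - reference_ic50
    v_mix, v_ref = mix.sem**2, reference_sem**2
    pooled = v_mix + v_ref
    if pooled == 0.0:
        if diff == 0.0:
            return WelchComparison(0.0, math.inf, 1.0, reference_bound, 0.0)
        return WelchComparison(
            math.inf, math.inf, 0.0, reference_bound, diff, degenerate=True
        )
    t = abs(diff) / math.sqrt(pooled)
    df = pooled**2 / (
        v_mix**2 / (mix.n_items - 1) + v_ref**2 / (reference_n - 1)
    )
    return WelchComparison(t, df, p_two_sided(t, df), reference_bound, diff)


def choose_reference(
    mix: PotencyEstimate, prediction: AdditivePrediction
) -> tuple[ReferenceBound, float, float, int]:
    """Pick the additive reference for the Welch comparison.

    Parallel predictions expose a single additive value.  Non-parallel
    predictions are tested against the bound nearer to the observed
    mixture IC50; an exact tie goes to the lower bound.

    Returns ``(bound_label, ic50, sem, n)``.
    """
    if prediction.parallel_case:
        return (
            "single",
            prediction.lower_ic50_add,
            prediction.sem_lower,
            prediction.n_add,
        )
    d_lower = abs(mix.ic50 - prediction.lower_ic50_add)
    d_upper = abs(mix.ic50 - prediction.upper_ic50_add)
    if d_lower <= d_upper:
        return ("lower", prediction.lower_ic50_add, prediction.sem_lower, prediction.n_add)
    return ("upper", prediction.upper_ic50_add, prediction.sem_upper, prediction.n_add)


def classify(
    mix: PotencyEstimate, prediction: AdditivePrediction, alpha: float = 0.05
) -> InteractionCall:
    """Classify the interaction as synergistic, additive or antagonistic.

    p > alpha → additive.  Otherwise the direction decides: a mixture
    IC50 significantly below the reference (below the lower bound for
    non-parallel predictions) is synergistic; above, antagonistic.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    bound, ref_ic50, ref_sem, ref_n = choose_reference(mix, prediction)
    comparison = welch_compare(mix, ref_ic50, ref_sem, ref_n, bound)
    if comparison.p_value > alpha:
        label: Classification = "additive"
    elif comparison.difference < 0:
        label = "synergistic"
    else:
        label = "antagonistic"
    return InteractionCall(label, alpha, comparison)
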