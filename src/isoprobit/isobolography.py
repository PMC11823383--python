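"""Fixed-ratio (type I) isobolographic analysis at the 50 % effect level.

Two drugs A and B are combined along the fixed-ratio ray through
(f·IC50_A, (1−f)·IC50_B).  If their log-probit lines are parallel the
Loewe-additive expectation for the mixture's total IC50 is the straight
isobole value

    IC50_add = f·IC50_A + (1−f)·IC50_B.

If the lines are not parallel the relative potency of the two drugs varies
with effect level and the straight line is replaced by two curved
dose-equivalence isoboles, whose intersections with the ray give a lower
and an upper additive IC50 that bracket the straight-line value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize, stats

from .probit_core import PotencyEstimate, ProbitLineFit

__all__ = [
    "FixedRatioDesign",
    "ParallelismResult",
    "AdditivePrediction",
    "IsobologramPoint",
    "IsoboleConstructionError",
    "test_parallelism",
    "additive_parallel",
    "dose_equivalent_b_of_a",
    "dose_equivalent_a_of_b",
    "additive_nonparallel",
    "isobologram_coordinates",
]


class IsoboleConstructionError(RuntimeError):
    """Raised when an additive isobole cannot be intersected with the ray."""


@dataclass(frozen=True)
class FixedRatioDesign:
    """A fixed-ratio combination design.

    ``fraction_f`` is the proportion of drug A's IC50 contributed at the
    additive reference point; 0.5 encodes the 1:1 design in which each
    drug enters at half its own IC50.
    """

    fraction_f: float = 0.5
    drug_a_label: str = "A"
    drug_b_label: str = "B"

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_f < 1.0:
            raise ValueError("fraction_f must lie strictly between 0 and 1")

    def ray_components(
        self, total: float, a50: float, b50: float
    ) -> tuple[float, float]:
        """Decompose a total mixture dose into (dose_a, dose_b) on the ray."""
        s = self.fraction_f * a50 + (1.0 - self.fraction_f) * b50
        return (
            total * self.fraction_f * a50 / s,
            total * (1.0 - self.fraction_f) * b50 / s,
        )


@dataclass(frozen=True)
class ParallelismResult:
    t_stat: float
    df: float
    p_value: float
    is_parallel: bool
    alpha: float
    degenerate_variance: bool = False


@dataclass(frozen=True)
class AdditivePrediction:
    """Theoretical additive IC50 of the mixture (total concentration, µM).

    In the parallel case lower == upper; in the non-parallel case they are
    the two curved-isobole bounds.  ``n_add`` is the summed well count of
    the two single-drug series.
    """

    lower_ic50_add: float
    upper_ic50_add: float
    sem_lower: float
    sem_upper: float
    n_add: int
    parallel_case: bool

    def __post_init__(self) -> None:
        if not 0.0 < self.lower_ic50_add <= self.upper_ic50_add:
            raise ValueError("require 0 < lower <= upper additive IC50")
        if self.sem_lower < 0 or self.sem_upper < 0:
            raise ValueError("SEMs must be non-negative")
        if self.parallel_case and self.lower_ic50_add != self.upper_ic50_add:
            raise ValueError("parallel case requires lower == upper")


CurveId = Literal["additive_lower", "additive_upper", "fixed_ratio_ray", "experimental_mix"]


@dataclass(frozen=True)
class IsobologramPoint:
    dose_a: float
    dose_b: float
    curve_id: CurveId


def test_parallelism(
    fit_a: ProbitLineFit, fit_b: ProbitLineFit, alpha: float = 0.05
) -> ParallelismResult:
    """Welch-style test of slope equality between two log-probit lines.

    t = (b_A − b_B) / sqrt(se_A² + se_B²) with Welch–Satterthwaite degrees
    of freedom using each fit's residual degrees of freedom (n_items − 2).
    A non-significant difference (p > alpha) is read as parallel.
    """
    for fit in (fit_a, fit_b):
        if fit.inverted:
            raise ValueError(f"fit {fit.label!r} flagged as inverted")
    va, vb = fit_a.slope_var, fit_b.slope_var
    diff = fit_a.slope_b - fit_b.slope_b
    pooled = va + vb
    if pooled == 0.0:
        if diff == 0.0:
            return ParallelismResult(0.0, math.inf, 1.0, True, alpha)
        return ParallelismResult(
            math.inf, math.inf, 0.0, False, alpha, degenerate_variance=True
        )
    t = diff / math.sqrt(pooled)
    df = pooled**2 / (
        va**2 / (fit_a.n_items - 2) + vb**2 / (fit_b.n_items - 2)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return ParallelismResult(t, df, float(p), bool(p > alpha), alpha)


def additive_parallel(
    est_a: PotencyEstimate, est_b: PotencyEstimate, design: FixedRatioDesign
) -> AdditivePrediction:
    """Straight-isobole additive IC50 for parallel concentration-response
    lines: f·A50 + (1−f)·B50, with SEMs combined in quadrature."""
    f = design.fraction_f
    value = f * est_a.ic50 + (1.0 - f) * est_b.ic50
    sem = math.sqrt((f * est_a.sem) ** 2 + ((1.0 - f) * est_b.sem) ** 2)
    return AdditivePrediction(
        lower_ic50_add=value,
        upper_ic50_add=value,
        sem_lower=sem,
        sem_upper=sem,
        n_add=est_a.n_items + est_b.n_items,
        parallel_case=True,
    )


def dose_equivalent_b_of_a(
    fit_a: ProbitLineFit, fit_b: ProbitLineFit, dose_a: float
) -> float:
    """Dose of B producing the same probit effect as ``dose_a`` of A.

    Equates the two fitted lines:
    10^((b_A·log10(dose_a) + a_A − a_B) / b_B).
    """
    if dose_a <= 0:
        raise ValueError("dose_a must be positive")
    if fit_a.slope_b <= 0 or fit_b.slope_b <= 0:
        raise ValueError("dose equivalence requires positive slopes")
    log_dose_b = (
        fit_a.slope_b * math.log10(dose_a) + fit_a.intercept_a - fit_b.intercept_a
    ) / fit_b.slope_b
    return 10.0**log_dose_b


def dose_equivalent_a_of_b(
    fit_a: ProbitLineFit, fit_b: ProbitLineFit, dose_b: float
) -> float:
    """Dose of A producing the same probit effect as ``dose_b`` of B."""
    return dose_equivalent_b_of_a(fit_b, fit_a, dose_b)


def _isobole_residuals(fit_a, fit_b, a50, b50, design):
    """Residual functions of total dose T for the two curved isoboles.

    Isobole 1 ("B frame"): dose_b + B-equivalent(dose_a) = B50.
    Isobole 2 ("A frame"): dose_a + A-equivalent(dose_b) = A50.
    Each residual is continuous and increasing in T along the ray.
    """

    def r1(log_t: float) -> float:
        a, b = design.ray_components(10.0**log_t, a50, b50)
        return b + dose_equivalent_b_of_a(fit_a, fit_b, a) - b50

    def r2(log_t: float) -> float:
        a, b = design.ray_components(10.0**log_t, a50, b50)
        return a + dose_equivalent_a_of_b(fit_a, fit_b, b) - a50

    return r1, r2


def _bracketed_root(residual, lo: float, hi: float) -> float:
    """Bisection root of ``residual`` on log10(total dose) in [lo, hi],
    expanding the bracket up to 4 decades each way if needed."""
    log_lo, log_hi = math.log10(lo), math.log10(hi)
    f_lo, f_hi = residual(log_lo), residual(log_hi)
    for _ in range(4):
        if f_lo < 0.0:
            break
        log_lo -= 1.0
        f_lo = residual(log_lo)
    for _ in range(4):
        if f_hi > 0.0:
            break
        log_hi += 1.0
        f_hi = residual(log_hi)
    if not (f_lo < 0.0 <= f_hi or f_lo <= 0.0 < f_hi):
        raise IsoboleConstructionError(
            f"no sign change on [{10**log_lo:.4g}, {10**log_hi:.4g}] µM "
            f"(residuals {f_lo:.4g}, {f_hi:.4g})"
        )
    root = optimize.bisect(residual, log_lo, log_hi, xtol=1e-12)
    return 10.0**root


def _nonparallel_bounds(fit_a, fit_b, design) -> tuple[float, float]:
    """Both ray-intersection totals from the raw fit coefficients."""
    a50 = 10.0 ** ((5.0 - fit_a.intercept_a) / fit_a.slope_b)
    b50 = 10.0 ** ((5.0 - fit_b.intercept_a) / fit_b.slope_b)
    r1, r2 = _isobole_residuals(fit_a, fit_b, a50, b50, design)
    lo = min(a50, b50) * 1e-4
    hi = a50 + b50
    t1 = _bracketed_root(r1, lo, hi)
    t2 = _bracketed_root(r2, lo, hi)
    return t1, t2


def _delta_sem(fit_a, fit_b, design, which: int) -> float:
    """Delta-method SEM of one ray-intersection total.

    Numerical central-difference gradient with respect to the four line
    coefficients (a_A, b_A, a_B, b_B), combined with the block-diagonal
    coefficient covariance of the two independent fits.
    """
    theta = np.array(
        [fit_a.intercept_a, fit_a.slope_b, fit_b.intercept_a, fit_b.slope_b]
    )

    def value(t: np.ndarray) -> float:
        fa = ProbitLineFit(
            slope_b=t[1], intercept_a=t[0], r_squared=1.0, se_slope=0.0,
            se_intercept=0.0, cov_ab=0.0, n_items=fit_a.n_items,
            n_doses=fit_a.n_doses,
        )
        fb = ProbitLineFit(
            slope_b=t[3], intercept_a=t[2], r_squared=1.0, se_slope=0.0,
            se_intercept=0.0, cov_ab=0.0, n_items=fit_b.n_items,
            n_doses=fit_b.n_doses,
        )
        return _nonparallel_bounds(fa, fb, design)[which]

    grad = np.zeros(4)
    for i in range(4):
        h = 1e-5 * max(abs(theta[i]), 1e-3)
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        grad[i] = (value(up) - value(dn)) / (2.0 * h)

    cov = np.zeros((4, 4))
    cov[0, 0] = fit_a.intercept_var
    cov[1, 1] = fit_a.slope_var
    cov[0, 1] = cov[1, 0] = fit_a.cov_ab
    cov[2, 2] = fit_b.intercept_var
    cov[3, 3] = fit_b.slope_var
    cov[2, 3] = cov[3, 2] = fit_b.cov_ab
    var = float(grad @ cov @ grad)
    return math.sqrt(max(var, 0.0))


def additive_nonparallel(
    fit_a: ProbitLineFit,
    fit_b: ProbitLineFit,
    est_a: PotencyEstimate,
    est_b: PotencyEstimate,
    design: FixedRatioDesign,
) -> AdditivePrediction:
    """Lower/upper additive IC50 for non-parallel lines.

    The two 50 %-effect dose-equivalence isoboles — dose_b + b_eq(dose_a) =
    B50 and dose_a + a_eq(dose_b) = A50 — are intersected with the
    fixed-ratio ray by bisection on log10(total dose).  When the slopes
    coincide both isoboles collapse onto the straight additive line and the
    bounds coincide with :func:`additive_parallel`.
    """
    if fit_a.inverted or fit_b.inverted:
        raise ValueError("inverted fits cannot enter isobolographic analysis")
    t1, t2 = _nonparallel_bounds(fit_a, fit_b, design)
    order = (0, 1) if t1 <= t2 else (1, 0)
    totals = (t1, t2)
    sems = (
        _delta_sem(fit_a, fit_b, design, 0),
        _delta_sem(fit_a, fit_b, design, 1),
    )
    return AdditivePrediction(
        lower_ic50_add=totals[order[0]],
        upper_ic50_add=totals[order[1]],
        sem_lower=sems[order[0]],
        sem_upper=sems[order[1]],
        n_add=est_a.n_items + est_b.n_items,
        parallel_case=False,
    )


def isobologram_coordinates(
    est_a: PotencyEstimate,
    est_b: PotencyEstimate,
    prediction: AdditivePrediction,
    mix: PotencyEstimate,
    design: FixedRatioDesign,
    fit_a: ProbitLineFit | None = None,
    fit_b: ProbitLineFit | None = None,
    resolution: int = 100,
) -> list[IsobologramPoint]:
    """Coordinates for a 50 %-isobole plot.

    Emits the additive isobole(s) from (A50, 0) to (0, B50) — the straight
    line when parallel, the two dose-equivalence curves otherwise (raw fits
    required) — the fixed-ratio ray from the origin, and the experimental
    mixture point M decomposed into component doses along the ray.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    a50, b50 = est_a.ic50, est_b.ic50
    pts: list[IsobologramPoint] = []

    a_grid = np.linspace(a50, 0.0, resolution)
    if prediction.parallel_case or fit_a is None or fit_b is None:
        if not prediction.parallel_case:
            raise ValueError("non-parallel curves require the raw line fits")
        for a in a_grid:
            b = b50 * (1.0 - a / a50)
            pts.append(IsobologramPoint(float(a), float(b), "additive_lower"))
            pts.append(IsobologramPoint(float(a), float(b), "additive_upper"))
    else:
        # curve 1 lives in the B frame, curve 2 in the A frame; tag each by
        # which ray intersection (lower/upper bound) it produced
        t1, t2 = _nonparallel_bounds(fit_a, fit_b, design)
        tag1: CurveId = "additive_lower" if t1 <= t2 else "additive_upper"
        tag2: CurveId = "additive_upper" if t1 <= t2 else "additive_lower"
        for a in a_grid:
            b1 = b50 - dose_equivalent_b_of_a(fit_a, fit_b, a) if a > 0 else b50
            pts.append(IsobologramPoint(float(a), float(max(b1, 0.0)), tag1))
        for b in np.linspace(b50, 0.0, resolution):
            a2 = a50 - dose_equivalent_a_of_b(fit_a, fit_b, b) if b > 0 else a50
            pts.append(IsobologramPoint(float(max(a2, 0.0)), float(b), tag2))

    ray_top = 1.25 * max(prediction.upper_ic50_add, mix.ic50)
    for t in np.linspace(0.0, ray_top, resolution):
        if t == 0.0:
            pts.append(IsobologramPoint(0.0, 0.0, "fixed_ratio_ray"))
        else:
            a, b = design.ray_components(float(t), a50, b50)
            pts.append(IsobologramPoint(a, b, "fixed_ratio_ray"))

    ma, mb = design.ray_components(mix.ic50, a50, b50)
    pts.append(IsobologramPoint(ma, mb, "experimental_mix"))
    return pts
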