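"""Log-probit dose-response modelling.

Viability readouts (percent of untreated control) are converted to effect
fractions, transformed to probits (normal equivalent deviate + 5, so the
median effect sits at probit 5), and regressed on log10(dose).  The fitted
line ``y = b·x + a`` yields the median inhibitory concentration

    IC50 = 10 ** ((5 − a) / b)

and its standard error by the delta method on log10(IC50).

This is the classical log-probit treatment of graded concentration-response
data: a single straight line per treatment arm, unweighted least squares on
per-well points by default, with wells at effect exactly 0 or 1 excluded
(they carry no probit information).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PROBIT_OFFSET",
    "DoseResponseRecord",
    "DoseResponseDataset",
    "ProbitLineFit",
    "PotencyEstimate",
    "UnfittableDatasetError",
    "DegenerateFitError",
    "effect_from_viability",
    "probit",
    "inverse_probit",
    "fit_probit_line",
    "ic50_from_fit",
    "ic50_sem",
]

#: Offset added to the normal equivalent deviate; probit(0.5) == 5 exactly.
PROBIT_OFFSET = 5.0

AggregationPolicy = Literal["per_well", "per_dose_mean"]
SaturationPolicy = Literal["drop", "clamp"]


class UnfittableDatasetError(ValueError):
    """Raised when a dataset cannot support a log-probit line fit."""


class DegenerateFitError(ValueError):
    """Raised when a fitted line cannot be inverted for an IC50."""


@dataclass(frozen=True)
class DoseResponseRecord:
    """One well: a dose (µM; total concentration for mixtures) and the
    fraction of cells affected, in [0, 1]."""

    treatment_label: str
    dose: float
    replicate_id: int
    effect: float

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"negative dose {self.dose!r}")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError(f"effect {self.effect!r} outside [0, 1]")


@dataclass(frozen=True)
class DoseResponseDataset:
    """One treatment arm's concentration series.

    Records are kept sorted by (dose, replicate).  ``control_mean`` records
    the viability value used for normalisation, for provenance only.
    """

    treatment_label: str
    records: tuple[DoseResponseRecord, ...]
    control_mean: float | None = None

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.records, key=lambda r: (r.dose, r.replicate_id))
        )
        object.__setattr__(self, "records", ordered)
        seen: set[tuple[float, int]] = set()
        for rec in ordered:
            key = (rec.dose, rec.replicate_id)
            if key in seen:
                raise ValueError(
                    f"duplicate replicate {rec.replicate_id} at dose "
                    f"{rec.dose} in arm {self.treatment_label!r}"
                )
            seen.add(key)

    @classmethod
    def from_arrays(
        cls,
        treatment_label: str,
        doses: Sequence[float],
        effects: Sequence[float],
        replicate_ids: Sequence[int] | None = None,
        control_mean: float | None = None,
    ) -> "DoseResponseDataset":
        doses = np.asarray(doses, dtype=float)
        effects = np.asarray(effects, dtype=float)
        if doses.shape != effects.shape:
            raise ValueError("doses and effects must have equal length")
        if replicate_ids is None:
            # number replicates within each dose level
            counter: dict[float, int] = {}
            replicate_ids = []
            for d in doses:
                counter[d] = counter.get(d, 0) + 1
                replicate_ids.append(counter[d])
        records = tuple(
            DoseResponseRecord(treatment_label, float(d), int(r), float(e))
            for d, r, e in zip(doses, replicate_ids, effects)
        )
        return cls(treatment_label, records, control_mean)

    @property
    def doses(self) -> np.ndarray:
        return np.array([r.dose for r in self.records], dtype=float)

    @property
    def effects(self) -> np.ndarray:
        return np.array([r.effect for r in self.records], dtype=float)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ProbitLineFit:
    """OLS fit of probit(effect) on log10(dose in µM).

    ``inverted`` flags a non-positive slope: the line is returned for
    inspection but downstream isobolography refuses it.
    """

    slope_b: float
    intercept_a: float
    r_squared: float
    se_slope: float
    se_intercept: float
    cov_ab: float
    n_items: int
    n_doses: int
    label: str = ""
    inverted: bool = False

    def predict_probit(self, dose: float | np.ndarray) -> np.ndarray:
        return self.slope_b * np.log10(np.asarray(dose, dtype=float)) + self.intercept_a

    @property
    def slope_var(self) -> float:
        return self.se_slope**2

    @property
    def intercept_var(self) -> float:
        return self.se_intercept**2


@dataclass(frozen=True)
class PotencyEstimate:
    """An IC50 (µM) with its standard error and the well count behind it."""

    ic50: float
    sem: float
    n_items: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if self.sem < 0:
            raise ValueError("sem must be non-negative")
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")


def effect_from_viability(viability_pct, control_mean=100.0):
    """Fraction affected from a viability reading, ``1 − v/control``.

    Clamped to [0, 1]; vectorised over ``viability_pct``.
    """
    if control_mean <= 0:
        raise ValueError(f"control_mean must be positive, got {control_mean!r}")
    v = np.asarray(viability_pct, dtype=float)
    if np.any(v < 0):
        raise ValueError("viability_pct must be non-negative")
    out = np.clip(1.0 - v / control_mean, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def probit(p):
    """Probit of an effect fraction: Φ⁻¹(p) + 5, defined on (0, 1)."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError("probit is defined only on the open interval (0, 1)")
    out = stats.norm.ppf(arr) + PROBIT_OFFSET
    return float(out) if out.ndim == 0 else out


def inverse_probit(y):
    """Effect fraction from a probit value: Φ(y − 5)."""
    out = stats.norm.cdf(np.asarray(y, dtype=float) - PROBIT_OFFSET)
    return float(out) if out.ndim == 0 else out


def _clamped_effects(dataset: DoseResponseDataset) -> np.ndarray:
    """Winsorise saturated wells to (1/(2m), 1 − 1/(2m)), m = replicates
    at that dose level."""
    doses = dataset.doses
    effects = dataset.effects.copy()
    for d in np.unique(doses):
        mask = doses == d
        m = int(mask.sum())
        lo, hi = 1.0 / (2 * m), 1.0 - 1.0 / (2 * m)
        effects[mask] = np.clip(effects[mask], lo, hi)
    return effects


def fit_probit_line(
    dataset: DoseResponseDataset,
    aggregation: AggregationPolicy = "per_well",
    saturation: SaturationPolicy = "drop",
) -> ProbitLineFit:
    """Fit the log-probit line for one treatment arm.

    Parameters
    ----------
    dataset
        The concentration series.  Dose-zero (control) wells never enter
        the fit.
    aggregation
        ``"per_well"`` (default) fits one point per well, so ``n_items``
        equals the number of contributing wells; ``"per_dose_mean"``
        averages effects within each dose first.
    saturation
        ``"drop"`` (default) excludes wells with effect exactly 0 or 1;
        ``"clamp"`` winsorises them to (1/(2m), 1 − 1/(2m)) where m is the
        replicate count at that dose.

    Raises
    ------
    UnfittableDatasetError
        If fewer than two distinct dose levels carry usable effects.
    """
    doses = dataset.doses
    treated = doses > 0
    doses = doses[treated]
    if saturation == "clamp":
        effects = _clamped_effects(dataset)[treated]
    elif saturation == "drop":
        effects = dataset.effects[treated]
    else:
        raise ValueError(f"unknown saturation policy {saturation!r}")

    if aggregation == "per_dose_mean":
        unique = np.unique(doses)
        effects = np.array([effects[doses == d].mean() for d in unique])
        doses = unique
    elif aggregation != "per_well":
        raise ValueError(f"unknown aggregation policy {aggregation!r}")

    usable = (effects > 0.0) & (effects < 1.0)
    doses, effects = doses[usable], effects[usable]
    if len(doses) == 0:
        raise UnfittableDatasetError(
            f"arm {dataset.treatment_label!r}: all effects saturated at 0 or 1"
        )
    n_doses = len(np.unique(doses))
    if n_doses < 2:
        raise UnfittableDatasetError(
            f"arm {dataset.treatment_label!r}: need >= 2 distinct doses with "
            f"effects inside (0, 1), found {n_doses}"
        )

    x = np.log10(doses)
    y = probit(effects)
    res = stats.linregress(x, y)
    se_slope = float(res.stderr)
    se_intercept = float(res.intercept_stderr)
    n = len(x)
    if n <= 2 or not math.isfinite(se_slope):
        # no residual degrees of freedom: line is exact, no sampling error
        se_slope = se_intercept = 0.0
    r2 = float(res.rvalue) ** 2
    # OLS covariance of (intercept, slope): Cov(a, b) = −x̄ · Var(b)
    cov_ab = -float(np.mean(x)) * se_slope**2
    slope = float(res.slope)
    return ProbitLineFit(
        slope_b=slope,
        intercept_a=float(res.intercept),
        r_squared=r2,
        se_slope=se_slope,
        se_intercept=se_intercept,
        cov_ab=cov_ab,
        n_items=n,
        n_doses=n_doses,
        label=dataset.treatment_label,
        inverted=slope <= 0,
    )


def ic50_from_fit(fit: ProbitLineFit) -> PotencyEstimate:
    """Median inhibitory concentration from a fitted line.

    IC50 = 10^((5 − a)/b), i.e. the dose whose predicted probit is 5.
    The SEM is delta-method propagated from the line's coefficient
    covariance (see :func:`ic50_sem`).
    """
    if fit.slope_b == 0:
        raise DegenerateFitError("zero slope: no dose yields the median effect")
    log_ic50 = (PROBIT_OFFSET - fit.intercept_a) / fit.slope_b
    ic50 = 10.0**log_ic50
    return PotencyEstimate(
        ic50=ic50, sem=ic50_sem(fit), n_items=fit.n_items, label=fit.label
    )


def ic50_sem(fit: ProbitLineFit) -> float:
    """Delta-method SEM of the IC50 in µM.

    With g = (5 − a)/b,
    Var(log10 IC50) = (Var(a) + 2·g·Cov(a,b) + g²·Var(b)) / b² and
    SEM(IC50) = ln(10) · IC50 · sqrt(Var(log10 IC50)).
    """
    if fit.slope_b == 0:
        raise DegenerateFitError("zero slope: IC50 undefined")
    g = (PROBIT_OFFSET - fit.intercept_a) / fit.slope_b
    var_log = (
        fit.intercept_var + 2.0 * g * fit.cov_ab + g**2 * fit.slope_var
    ) / fit.slope_b**2
    if var_log < -1e-12:
        raise ArithmeticError(
            f"negative propagated variance {var_log:.3e} "
            f"(a={fit.intercept_a}, b={fit.slope_b}, cov={fit.cov_ab})"
        )
    var_log = max(var_log, 0.0)
    return math.log(10.0) * 10.0**g * math.sqrt(var_log)
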