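"""Synthetic 96-well viability plates with known ground truth.

The generator emulates an MTT-style screen: each drug's mean viability
follows a probit-linear concentration-response curve,

    viability% = 100 · (1 − Φ(slope · (log10 d − log10 IC50))),

with additive Gaussian plate-reader noise on the viability scale,
truncated to [0, 100].  Fixed-ratio mixtures are generated under Loewe
dose equivalence with a tunable interaction index λ: the effect E at
component doses (a, b) solves a/A(E) + b/B(E) = λ, so λ = 1 encodes exact
additivity, λ < 1 synergy and λ > 1 antagonism.

Determinism contract: identical (seed, stream_label) pairs reproduce
byte-identical datasets; distinct stream labels give independent streams.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .isobolography import FixedRatioDesign
from .probit_core import (
    PROBIT_OFFSET,
    DoseResponseDataset,
    DoseResponseRecord,
    effect_from_viability,
)

__all__ = [
    "DrugTruth",
    "MixtureTruth",
    "RngSpec",
    "default_dose_grid",
    "simulate_drug",
    "simulate_fixed_ratio_mixture",
]

#: Two-fold dilution multipliers spanning 0.25×–8× the reference dose,
#: loosely emulating a 6-point single-drug MTT series.
DEFAULT_DILUTIONS = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


def default_dose_grid(ic50: float) -> tuple[float, ...]:
    """Six two-fold dilutions centred on the IC50 (0.25×–8×)."""
    return tuple(ic50 * m for m in DEFAULT_DILUTIONS)


@dataclass(frozen=True)
class RngSpec:
    """Seedable, labelled random stream.

    The stream label is hashed (SHA-256) into the seed sequence so that
    streams with different labels are statistically independent while the
    whole simulation remains reproducible from one integer seed.
    """

    seed: int
    stream_label: str = ""

    def generator(self) -> np.random.Generator:
        label_key = int.from_bytes(
            hashlib.sha256(self.stream_label.encode("utf-8")).digest()[:4],
            "little",
        )
        seq = np.random.SeedSequence(entropy=self.seed, spawn_key=(label_key,))
        return np.random.default_rng(seq)


@dataclass(frozen=True)
class DrugTruth:
    """Ground-truth single-drug response.

    ``true_slope`` is in probit units per log10(µM); ``noise_sd`` is the
    Gaussian viability noise in percent-of-control units.  ``doses`` of
    ``None`` selects the default 0.25×–8× IC50 two-fold grid.
    """

    label: str
    true_ic50: float
    true_slope: float
    doses: tuple[float, ...] | None = None
    replicates: int = 8
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.true_ic50 <= 0:
            raise ValueError("true_ic50 must be positive")
        if self.true_slope <= 0:
            raise ValueError("true_slope must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.doses is not None and any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")

    @property
    def dose_grid(self) -> tuple[float, ...]:
        return self.doses if self.doses is not None else default_dose_grid(self.true_ic50)

    @property
    def intercept(self) -> float:
        """Implied probit-line intercept: 5 − slope·log10(IC50)."""
        return PROBIT_OFFSET - self.true_slope * math.log10(self.true_ic50)

    def mean_effect(self, dose) -> np.ndarray:
        """Noise-free effect fraction at a dose (vectorised)."""
        d = np.asarray(dose, dtype=float)
        return stats.norm.cdf(
            self.true_slope * (np.log10(d) - math.log10(self.true_ic50))
        )

    def dose_at_effect(self, effect) -> np.ndarray:
        """Inverse of :meth:`mean_effect` on (0, 1)."""
        e = np.asarray(effect, dtype=float)
        return 10.0 ** (
            stats.norm.ppf(e) / self.true_slope + math.log10(self.true_ic50)
        )


@dataclass(frozen=True)
class MixtureTruth:
    """Ground truth for a fixed-ratio mixture series.

    ``interaction_index_lambda`` is the Loewe index λ (1 additive, < 1
    synergistic, > 1 antagonistic).  ``dilution_steps`` are fractions of
    the additive reference total dose f·A50 + (1−f)·B50.  Replicate count
    and noise level are inherited from drug A's truth.
    """

    design: FixedRatioDesign = field(default_factory=FixedRatioDesign)
    interaction_index_lambda: float = 1.0
    dilution_steps: tuple[float, ...] = DEFAULT_DILUTIONS

    def __post_init__(self) -> None:
        if self.interaction_index_lambda <= 0:
            raise ValueError("interaction_index_lambda must be positive")
        if any(s <= 0 for s in self.dilution_steps):
            raise ValueError("dilution_steps must be positive")


def _noisy_viability(
    mean_effect: np.ndarray, replicates: int, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-well viability%: truncated Gaussian noise around the mean curve.

    Shape (n_doses, replicates)."""
    mean_v = 100.0 * (1.0 - mean_effect)
    noise = rng.normal(0.0, noise_sd, size=(len(mean_v), replicates)) if noise_sd > 0 \
        else np.zeros((len(mean_v), replicates))
    return np.clip(mean_v[:, None] + noise, 0.0, 100.0)


def _dataset_from_viability(
    label: str, doses: np.ndarray, viability: np.ndarray
) -> DoseResponseDataset:
    records = []
    for i, dose in enumerate(doses):
        for rep in range(viability.shape[1]):
            records.append(
                DoseResponseRecord(
                    treatment_label=label,
                    dose=float(dose),
                    replicate_id=rep + 1,
                    effect=float(effect_from_viability(viability[i, rep], 100.0)),
                )
            )
    return DoseResponseDataset(label, tuple(records), control_mean=100.0)


def simulate_drug(truth: DrugTruth, rng: RngSpec) -> DoseResponseDataset:
    """Simulate one single-drug concentration series.

    Effects are derived against a noiseless 100 % control, so the effect
    column is exactly ``1 − viability/100`` clipped to [0, 1].
    """
    gen = rng.generator()
    doses = np.asarray(truth.dose_grid, dtype=float)
    viability = _noisy_viability(
        truth.mean_effect(doses), truth.replicates, truth.noise_sd, gen
    )
    return _dataset_from_viability(truth.label, doses, viability)


def _loewe_effect(
    a: float, b: float, truth_a: DrugTruth, truth_b: DrugTruth, lam: float
) -> float | None:
    """Solve a/A(E) + b/B(E) = λ for the effect E at component doses (a, b).

    The left side is strictly decreasing in E (both equivalent doses grow
    with E), so the root is unique when bracketed; returns None when the
    dose pair falls outside the solvable effect range.
    """
    eps = 1e-9

    def residual(e: float) -> float:
        return (
            a / float(truth_a.dose_at_effect(e))
            + b / float(truth_b.dose_at_effect(e))
            - lam
        )

    lo, hi = residual(eps), residual(1.0 - eps)
    if not (hi < 0.0 < lo):
        return None
    return float(optimize.brentq(residual, eps, 1.0 - eps, xtol=1e-12))


def simulate_fixed_ratio_mixture(
    truth_a: DrugTruth,
    truth_b: DrugTruth,
    mix: MixtureTruth,
    rng: RngSpec,
    label: str | None = None,
) -> DoseResponseDataset:
    """Simulate the fixed-ratio mixture series under Loewe index λ.

    Total doses are ``dilution_steps`` × the additive reference total
    f·A50 + (1−f)·B50, split into components along the ray.  At each total
    dose the generated mean effect solves the Loewe equation; viability
    noise is then added exactly as for single drugs.
    """
    f = mix.design.fraction_f
    reference_total = f * truth_a.true_ic50 + (1.0 - f) * truth_b.true_ic50
    lam = mix.interaction_index_lambda
    totals, effects = [], []
    for step in mix.dilution_steps:
        total = step * reference_total
        a, b = mix.design.ray_components(total, truth_a.true_ic50, truth_b.true_ic50)
        e = _loewe_effect(a, b, truth_a, truth_b, lam)
        if e is None:
            warnings.warn(
                f"total dose {total:.4g} µM outside the solvable effect "
                "range; dose level skipped",
                stacklevel=2,
            )
            continue
        totals.append(total)
        effects.append(e)
    gen = rng.generator()
    viability = _noisy_viability(
        np.asarray(effects), truth_a.replicates, truth_a.noise_sd, gen
    )
    name = label or f"{truth_a.label}:{truth_b.label}"
    return _dataset_from_viability(name, np.asarray(totals), viability)
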