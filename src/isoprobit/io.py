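"""Plate-file I/O, published-summary re-analysis and the end-to-end pipeline.

Two input modes are supported:

* **Raw plates** — a long-format CSV with one row per well
  (``treatment,dose_um,replicate,viability_pct`` or an ``effect`` column
  instead of viability; ``dose_um = 0`` rows are untreated controls used
  only for normalisation).  The full pipeline fits the two single-drug
  lines and the mixture line, tests parallelism, computes the additive
  prediction and classifies the interaction.

* **Published summaries** — a JSON file of already-fitted line
  coefficients and IC50 ± SEM (n) tables, for re-analysing reported
  numbers when raw plates are unavailable.  A summary for the EX527 +
  paclitaxel combination in five breast-cancer cell lines is packaged
  with the module (:func:`load_published_summary`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .interaction_stats import InteractionCall, classify
from .isobolography import (
    AdditivePrediction,
    FixedRatioDesign,
    IsobologramPoint,
    ParallelismResult,
    additive_nonparallel,
    additive_parallel,
    isobologram_coordinates,
    test_parallelism,
)
from .probit_core import (
    DoseResponseDataset,
    PotencyEstimate,
    ProbitLineFit,
    effect_from_viability,
    fit_probit_line,
    ic50_from_fit,
)

__all__ = [
    "AnalysisConfig",
    "RunReport",
    "PlateSchemaError",
    "read_plate_csv",
    "write_plate_csv",
    "fit_summary_frame",
    "load_published_summary",
    "summary_line_fit",
    "summary_mixture_estimate",
    "summary_additive_prediction",
    "run_interaction_analysis",
    "isobologram_frame",
]

PLATE_COLUMNS = ("treatment", "dose_um", "replicate")


class PlateSchemaError(ValueError):
    """Raised when a plate CSV violates the long-format schema."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the end-to-end interaction analysis."""

    alpha: float = 0.05
    fraction_f: float = 0.5
    saturation_policy: str = "drop"
    aggregation: str = "per_well"
    seed: int = 0
    isobole_resolution: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.fraction_f < 1.0:
            raise ValueError("fraction_f must lie in (0, 1)")
        if self.isobole_resolution < 2:
            raise ValueError("isobole_resolution must be >= 2")


@dataclass(frozen=True)
class RunReport:
    """Everything one combination analysis produced."""

    config: AnalysisConfig
    fits: dict[str, ProbitLineFit]
    estimates: dict[str, PotencyEstimate]
    parallelism: ParallelismResult
    prediction: AdditivePrediction
    call: InteractionCall
    isobologram: list[IsobologramPoint]
    labels: dict[str, str]

    def report_row(self, name: str = "") -> dict[str, Any]:
        """One Table-style summary row (4 s.f. on concentrations,
        3 decimals on t/df/p)."""
        mix = self.estimates[self.labels["mixture"]]
        cmp_ = self.call.comparison
        pred = self.prediction
        return {
            "cell_line": name,
            "ic50_mix": float(f"{mix.ic50:.4g}"),
            "sem_mix": float(f"{mix.sem:.4g}"),
            "n_mix": mix.n_items,
            "l_ic50_add": float(f"{pred.lower_ic50_add:.4g}"),
            "sem_l": float(f"{pred.sem_lower:.4g}"),
            "u_ic50_add": float(f"{pred.upper_ic50_add:.4g}"),
            "sem_u": float(f"{pred.sem_upper:.4g}"),
            "n_add": pred.n_add,
            "t": round(cmp_.t_stat, 3),
            "df": round(cmp_.df, 3),
            "p": round(cmp_.p_value, 3),
            "interaction": self.call.classification,
        }


def read_plate_csv(path) -> dict[str, DoseResponseDataset]:
    """Read a long-format plate CSV into one dataset per treatment arm.

    Exactly one of ``viability_pct`` and ``effect`` must be present.
    Controls (``dose_um == 0``) set each arm's normalisation mean; arms
    without controls are normalised against 100 %.
    """
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateSchemaError(f"missing required column(s): {missing}")
    has_viab = "viability_pct" in df.columns
    has_eff = "effect" in df.columns
    if has_viab == has_eff:
        raise PlateSchemaError(
            "exactly one of 'viability_pct' and 'effect' must be present"
        )
    if (df["dose_um"] < 0).any():
        bad = int(df.index[df["dose_um"] < 0][0]) + 2  # 1-based incl. header
        raise PlateSchemaError(f"negative dose at line {bad}")

    datasets: dict[str, DoseResponseDataset] = {}
    for label, sub in df.groupby("treatment", sort=True):
        controls = sub[sub["dose_um"] == 0]
        treated = sub[sub["dose_um"] > 0]
        if has_viab:
            control_mean = (
                float(controls["viability_pct"].mean()) if len(controls) else 100.0
            )
            effects = effect_from_viability(
                treated["viability_pct"].to_numpy(), control_mean
            )
        else:
            control_mean = None
            effects = treated["effect"].to_numpy(dtype=float)
            if ((effects < 0) | (effects > 1)).any():
                raise PlateSchemaError(
                    f"arm {label!r}: effect values outside [0, 1]"
                )
        datasets[str(label)] = DoseResponseDataset.from_arrays(
            str(label),
            treated["dose_um"].to_numpy(dtype=float),
            np.atleast_1d(effects),
            treated["replicate"].to_numpy(dtype=int),
            control_mean=control_mean,
        )
    return datasets


def write_plate_csv(path, datasets: Mapping[str, DoseResponseDataset]) -> None:
    """Write datasets back to the long-format schema (effect column)."""
    rows = []
    for label in sorted(datasets):
        for rec in datasets[label].records:
            rows.append(
                {
                    "treatment": label,
                    "dose_um": rec.dose,
                    "replicate": rec.replicate_id,
                    "effect": rec.effect,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def fit_summary_frame(fits: Mapping[str, ProbitLineFit]) -> pd.DataFrame:
    """Fit summary table: one row per treatment with line coefficients,
    their uncertainties and the derived IC50 ± SEM."""
    rows = []
    for label in sorted(fits):
        fit = fits[label]
        est = ic50_from_fit(fit)
        rows.append(
            {
                "treatment": label,
                "slope": fit.slope_b,
                "intercept": fit.intercept_a,
                "r_squared": fit.r_squared,
                "se_slope": fit.se_slope,
                "se_intercept": fit.se_intercept,
                "cov_ab": fit.cov_ab,
                "n_items": fit.n_items,
                "ic50_um": est.ic50,
                "sem_um": est.sem,
            }
        )
    return pd.DataFrame(rows)


def load_published_summary(path=None) -> dict[str, Any]:
    """Load a published-summary JSON (the packaged EX527+paclitaxel
    breast-cancer summary when ``path`` is None)."""
    if path is None:
        ref = resources.files("isoprobit").joinpath("data/ex527_pax_summary.json")
        return json.loads(ref.read_text(encoding="utf-8"))
    return json.loads(Path(path).read_text(encoding="utf-8"))


def summary_line_fit(entry: Mapping[str, Any], label: str = "") -> ProbitLineFit:
    """A :class:`ProbitLineFit` from published coefficients.

    Coefficient uncertainties are rarely printed; absent ones default to
    zero, which restricts downstream use to IC50 extraction.
    """
    slope = float(entry["slope"])
    return ProbitLineFit(
        slope_b=slope,
        intercept_a=float(entry["intercept"]),
        r_squared=float(entry.get("r_squared", float("nan"))),
        se_slope=float(entry.get("se_slope", 0.0)),
        se_intercept=float(entry.get("se_intercept", 0.0)),
        cov_ab=float(entry.get("cov_ab", 0.0)),
        n_items=int(entry.get("n", 2)),
        n_doses=int(entry.get("n_doses", 2)),
        label=label,
        inverted=slope <= 0,
    )


def summary_mixture_estimate(cell_entry: Mapping[str, Any], label: str = "") -> PotencyEstimate:
    m = cell_entry["mixture"]
    return PotencyEstimate(
        ic50=float(m["ic50_um"]), sem=float(m["sem_um"]), n_items=int(m["n"]), label=label
    )


def summary_additive_prediction(cell_entry: Mapping[str, Any]) -> AdditivePrediction:
    a = cell_entry["additive"]
    return AdditivePrediction(
        lower_ic50_add=float(a["lower_um"]),
        upper_ic50_add=float(a["upper_um"]),
        sem_lower=float(a["sem_lower_um"]),
        sem_upper=float(a["sem_upper_um"]),
        n_add=int(a["n"]),
        parallel_case=bool(cell_entry["parallel"]),
    )


def run_interaction_analysis(
    plates: Mapping[str, DoseResponseDataset],
    config: AnalysisConfig = AnalysisConfig(),
    drug_a: str | None = None,
    drug_b: str | None = None,
    mixture: str | None = None,
) -> RunReport:
    """Full fixed-ratio interaction analysis from raw plates.

    Fits the three log-probit lines, tests parallelism of the two
    single-drug lines, computes the additive prediction (straight isobole
    when parallel, curved dose-equivalence bounds otherwise) and runs the
    Welch classification of the mixture against it.

    When the arm labels are not given, a three-arm plate set is consumed
    in sorted label order as (drug A, drug B, mixture) with any label
    containing ``":"`` preferred as the mixture arm.
    """
    labels = sorted(plates)
    if mixture is None:
        mixture = next((l for l in labels if ":" in l), labels[-1])
    remaining = [l for l in labels if l != mixture]
    if drug_a is None or drug_b is None:
        if len(remaining) != 2:
            raise ValueError(
                f"cannot infer single-drug arms from labels {labels!r}; "
                "pass drug_a/drug_b explicitly"
            )
        drug_a, drug_b = remaining
    for name, lab in (("drug_a", drug_a), ("drug_b", drug_b), ("mixture", mixture)):
        if lab not in plates:
            raise KeyError(f"{name} arm {lab!r} not found in plates")

    fits: dict[str, ProbitLineFit] = {}
    estimates: dict[str, PotencyEstimate] = {}
    for lab in (drug_a, drug_b, mixture):
        try:
            fit = fit_probit_line(
                plates[lab],
                aggregation=config.aggregation,
                saturation=config.saturation_policy,
            )
        except ValueError as exc:
            raise type(exc)(f"[fit:{lab}] {exc}") from exc
        if fit.inverted:
            raise ValueError(f"[fit:{lab}] inverted concentration-response line")
        fits[lab] = fit
        estimates[lab] = ic50_from_fit(fit)

    design = FixedRatioDesign(config.fraction_f, drug_a, drug_b)
    parallelism = test_parallelism(fits[drug_a], fits[drug_b], alpha=config.alpha)
    if parallelism.is_parallel:
        prediction = additive_parallel(estimates[drug_a], estimates[drug_b], design)
    else:
        prediction = additive_nonparallel(
            fits[drug_a], fits[drug_b], estimates[drug_a], estimates[drug_b], design
        )
    call = classify(estimates[mixture], prediction, alpha=config.alpha)
    coords = isobologram_coordinates(
        estimates[drug_a],
        estimates[drug_b],
        prediction,
        estimates[mixture],
        design,
        fit_a=fits[drug_a],
        fit_b=fits[drug_b],
        resolution=config.isobole_resolution,
    )
    return RunReport(
        config=config,
        fits=fits,
        estimates=estimates,
        parallelism=parallelism,
        prediction=prediction,
        call=call,
        isobologram=coords,
        labels={"drug_a": drug_a, "drug_b": drug_b, "mixture": mixture},
    )


def isobologram_frame(points: list[IsobologramPoint]) -> pd.DataFrame:
    """Isobologram export table: ``curve_id,dose_a_um,dose_b_um``."""
    return pd.DataFrame(
        [
            {"curve_id": p.curve_id, "dose_a_um": p.dose_a, "dose_b_um": p.dose_b}
            for p in points
        ]
    )
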