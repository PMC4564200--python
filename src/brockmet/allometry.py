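"""Allometric BMR predictions and measured-vs-predicted comparisons.

Historical allometric equations predict basal metabolic rate as a power law
``M = a·W^b`` of body mass, each in its own units.  This module evaluates them
on a common kJ·d⁻¹ scale, fits the same power-law form to measured data by
ordinary least squares on log10–log10 axes, and runs the comparison procedure:
per-animal percentage errors against each prediction, a Welch-corrected
one-way ANOVA across the measured and predicted groups, and Dunnett
many-to-one contrasts with the measured group as control.

The four literature equations ship as presets:

========================  =========================  ==========  ============
name                      equation                   mass unit   output unit
========================  =========================  ==========  ============
``iversen1972``           84.6·W^0.78 (mustelids)    kg          kcal·d⁻¹
``kleiber1961``           70·W^0.75 (mammals)        kg          kcal·d⁻¹
``white_seymour2003``     4.17·W^0.68 (mammals)      g           ml O2·h⁻¹
``mcnab2008``             3·W^0.752 (carnivores)     g           ml O2·h⁻¹
========================  =========================  ==========  ============
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import gas_exchange as gx
from .errors import ConfigError, InvalidInputError
from .inference import dunnett_many_to_one, welch_anova

#: RQ used to convert ml O2·h⁻¹ predictions to energy when no measured RQ
#: applies (the study-average value).
DEFAULT_CONVERSION_RQ = 0.76

MASS_UNITS = ("kg", "g")
OUTPUT_UNITS = ("kcal_per_day", "mlO2_per_hour", "kj_per_day")


@dataclass(frozen=True)
class AllometricModel:
    """One power-law BMR prediction ``M = coefficient · W^exponent``."""

    name: str
    coefficient: float
    exponent: float
    mass_unit: str = "kg"
    output_unit: str = "kj_per_day"

    def __post_init__(self):
        if self.coefficient <= 0:
            raise ConfigError(f"coefficient must be positive, got {self.coefficient!r}")
        if self.mass_unit not in MASS_UNITS:
            raise ConfigError(
                f"unknown mass_unit {self.mass_unit!r}; allowed: {', '.join(MASS_UNITS)}"
            )
        if self.output_unit not in OUTPUT_UNITS:
            raise ConfigError(
                f"unknown output_unit {self.output_unit!r}; allowed: {', '.join(OUTPUT_UNITS)}"
            )


MODEL_REGISTRY: dict[str, AllometricModel] = {
    "iversen1972": AllometricModel("iversen1972", 84.6, 0.78, "kg", "kcal_per_day"),
    "kleiber1961": AllometricModel("kleiber1961", 70.0, 0.75, "kg", "kcal_per_day"),
    "white_seymour2003": AllometricModel("white_seymour2003", 4.17, 0.68, "g", "mlO2_per_hour"),
    "mcnab2008": AllometricModel("mcnab2008", 3.0, 0.752, "g", "mlO2_per_hour"),
}


def get_model(name: str) -> AllometricModel:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise ConfigError(
            f"unknown allometric model {name!r}; registered: "
            f"{', '.join(sorted(MODEL_REGISTRY))}"
        ) from None


def predict_bmr(model: AllometricModel, mass_kg,
                rq_for_conversion: float = DEFAULT_CONVERSION_RQ):
    """Evaluate a power-law prediction at body mass, returning kJ·d⁻¹.

    Mass is converted to the model's unit before the power law; the output is
    converted to energy with 4.184 kJ·kcal⁻¹ or the oxyjoule factor at
    ``rq_for_conversion`` as required.  Vectorised over mass.
    """
    mass_kg = np.asarray(mass_kg, dtype=float)
    if np.any(mass_kg <= 0):
        raise InvalidInputError("mass_kg must be positive")
    w = mass_kg if model.mass_unit == "kg" else mass_kg * 1000.0
    m = model.coefficient * w ** model.exponent
    if model.output_unit == "kcal_per_day":
        out = m * gx.KCAL_TO_KJ
    elif model.output_unit == "mlO2_per_hour":
        out = m * gx.oxyjoule_factor(rq_for_conversion) * 24.0 / 1e3
    else:
        out = m
    return float(out) if out.ndim == 0 else out


def percentage_error(measured, predicted):
    """Signed error of a measurement relative to a prediction, percent.

    ``100·(measured − predicted)/predicted``; positive when the animal exceeds
    the prediction.
    """
    predicted = np.asarray(predicted, dtype=float)
    if np.any(predicted <= 0):
        raise InvalidInputError("predicted values must be positive")
    out = 100.0 * (np.asarray(measured, dtype=float) - predicted) / predicted
    return float(out) if out.ndim == 0 else out


def percentage_difference(a: float, b: float) -> float:
    """Symmetric percentage difference: absolute difference over the mean.

    ``100·|a − b| / ((a + b)/2)``; used for comparing two adjusted means on an
    equal footing.  Bounded in [0, 200) for positive inputs.
    """
    if a <= 0 or b <= 0:
        raise InvalidInputError("percentage_difference requires positive inputs")
    return 100.0 * abs(a - b) / ((a + b) / 2.0)


@dataclass(frozen=True)
class ScalingFit:
    """Power-law fit ``RMR = a·W^b`` from log10–log10 least squares."""

    a: float  # mass scaling coefficient (base-10 antilog of the intercept)
    b: float  # mass scaling exponent (slope)
    n: int
    r2: float

    def predict(self, mass_kg):
        return self.a * np.asarray(mass_kg, dtype=float) ** self.b


def fit_scaling(masses_kg, rmr_kj_d) -> ScalingFit:
    """OLS of log10(RMR) on log10(mass); returns antilogged intercept + slope."""
    w = np.asarray(masses_kg, dtype=float)
    y = np.asarray(rmr_kj_d, dtype=float)
    if w.size != y.size:
        raise InvalidInputError("masses and RMR values must have equal length")
    if w.size < 2:
        raise InvalidInputError("need at least 2 points for a scaling fit")
    if np.any(w <= 0) or np.any(y <= 0):
        raise InvalidInputError("scaling fit requires positive masses and RMR values")
    lw, ly = np.log10(w), np.log10(y)
    slope, intercept = np.polyfit(lw, ly, 1)
    resid = ly - (intercept + slope * lw)
    tss = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
    return ScalingFit(a=float(10.0**intercept), b=float(slope), n=int(w.size), r2=r2)


@dataclass(frozen=True)
class PredictionErrorSummary:
    """Per-model summary of percentage errors plus the Dunnett-adjusted p."""

    model: str
    season: str
    mean_error_pct: float
    sd_error_pct: float
    min_error_pct: float
    max_error_pct: float
    p_adjusted: float
    n: int


def compare_measured_vs_predictions(masses_kg, measured_kj_d, models,
                                    season: str = "combined",
                                    rq_for_conversion: float = DEFAULT_CONVERSION_RQ,
                                    mc_draws: int = 100_000,
                                    seed: int = 20150909):
    """Compare measured RMR with allometric predictions at the same masses.

    Builds one group of measured values plus one group of predicted values per
    model (evaluated at the identical masses), runs a Welch-corrected one-way
    ANOVA across all groups, then Dunnett many-to-one contrasts with the
    measured group as control.  Adults only — callers exclude juveniles, whose
    growth elevates metabolic rate relative to any basal prediction.

    Returns
    -------
    (summaries, welch) : list[PredictionErrorSummary], WelchAnovaResult
    """
    masses = np.asarray(masses_kg, dtype=float)
    measured = np.asarray(measured_kj_d, dtype=float)
    if masses.size != measured.size:
        raise InvalidInputError("masses and measured values must have equal length")
    if masses.size < 2:
        raise InvalidInputError("need at least 2 animals for the comparison")
    if not models:
        raise InvalidInputError("need at least one allometric model to compare against")
    models = [get_model(m) if isinstance(m, str) else m for m in models]

    groups = {"measured": measured}
    for m in models:
        groups[m.name] = np.asarray(predict_bmr(m, masses, rq_for_conversion))
    welch = welch_anova(list(groups.values()))
    contrasts = dunnett_many_to_one(groups, control="measured",
                                    mc_draws=mc_draws, seed=seed)
    p_by_model = {c.label.split(" - ")[0]: c.p_adjusted for c in contrasts}

    summaries = []
    for m in models:
        err = percentage_error(measured, groups[m.name])
        summaries.append(
            PredictionErrorSummary(
                model=m.name,
                season=season,
                mean_error_pct=float(np.mean(err)),
                sd_error_pct=float(np.std(err, ddof=1)) if err.size > 1 else 0.0,
                min_error_pct=float(np.min(err)),
                max_error_pct=float(np.max(err)),
                p_adjusted=float(p_by_model[m.name]),
                n=int(masses.size),
            )
        )
    return summaries, welch


def prey_equivalent(energy_kj_d: float, kj_per_item: float) -> tuple[float, int]:
    """Daily energy budget as prey items (e.g. earthworms) per day.

    Returns the raw quotient and, for presentation, the value rounded to the
    nearest 5 items.
    """
    if kj_per_item <= 0:
        raise InvalidInputError("kj_per_item must be positive")
    if energy_kj_d < 0:
        raise InvalidInputError("energy_kj_d must be non-negative")
    raw = energy_kj_d / kj_per_item
    return raw, int(5 * round(raw / 5))
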