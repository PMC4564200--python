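"""Open-circuit respirometry arithmetic.

Converts incurrent/excurrent gas fractions and flow into oxygen-consumption
and carbon-dioxide-production rates, accounting for the dilution and
concentration effects that arise because the animal removes O2 from, and adds
CO2 to, the air stream (so excurrent flow differs from incurrent flow).  Also
provides the respiratory-quotient-dependent oxyjoule energy conversion and the
unit bridging (whole-animal vs mass-specific, O2 vs CO2 vs energy) used in
summary tables.

All gas fractions are handled internally as proportions in (0, 1); percent is
a file-format concern and is converted at the I/O boundary.  Flow rates are
ml·min⁻¹ at standard temperature and pressure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import InvalidInputError

#: kcal → kJ conversion used everywhere a historical equation reports kcal.
KCAL_TO_KJ = 4.184

#: Ambient (outside-air) defaults used when no incurrent baseline is supplied.
#: O2 matches the analyser calibration value for outside air; CO2 is the
#: nominal ambient fraction (the study does not report its incurrent CO2, so
#: this is a documented, overridable default).
DEFAULT_FI_O2 = 0.2095
DEFAULT_FI_CO2 = 0.0004

#: Tolerance below which excurrent-above-incurrent O2 is treated as noise.
_RESPIRING_TOL = 1e-6


@dataclass(frozen=True)
class GasFractions:
    """Incurrent and excurrent O2/CO2 fractions for one reading.

    Parameters
    ----------
    fi_o2, fe_o2 : float
        Incurrent and excurrent O2 fractions (proportions).
    fi_co2, fe_co2 : float
        Incurrent and excurrent CO2 fractions (proportions).
    """

    fi_o2: float = DEFAULT_FI_O2
    fe_o2: float = DEFAULT_FI_O2
    fi_co2: float = DEFAULT_FI_CO2
    fe_co2: float = DEFAULT_FI_CO2

    def __post_init__(self):
        for name in ("fi_o2", "fe_o2", "fi_co2", "fe_co2"):
            v = getattr(self, name)
            if not (0.0 < v < 0.25):
                raise InvalidInputError(
                    f"{name}={v!r} outside the physical range (0, 0.25); "
                    "fractions are proportions, not percent"
                )

    @property
    def o2_depletion_pct(self) -> float:
        """Incurrent minus excurrent O2, in percentage points."""
        return (self.fi_o2 - self.fe_o2) * 100.0


@dataclass(frozen=True)
class GasExchangeRates:
    """Dilution-corrected gas-exchange rates for one stable reading.

    ``rq`` is NaN (with the ``rq_undefined`` flag) when V̇O2 is zero.  A
    negative V̇O2 — excurrent O2 above incurrent beyond measurement tolerance —
    is never produced silently: it is returned as-is with the ``negative_vo2``
    flag so the caller can discard or investigate the reading.
    """

    vo2_ml_min: float
    vco2_ml_min: float
    rq: float
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.vo2_ml_min < 0 and "negative_vo2" not in self.flags:
            raise InvalidInputError(
                "negative vo2_ml_min requires the 'negative_vo2' flag"
            )


@dataclass(frozen=True)
class EnergyEquivalent:
    """Whole-animal energy expenditure derived from V̇O2 and RQ."""

    kj_per_day: float
    oxyjoule_j_per_ml: float
    mass_specific_kj_kg_h: float | None = None


def compute_gas_exchange(fractions: GasFractions, flow_ml_min: float) -> GasExchangeRates:
    """Compute V̇O2 and V̇CO2 from gas fractions and incurrent flow.

    Uses the flow-through equations for a system in which excurrent flow is
    not measured, correcting each gas for the dilution/concentration caused by
    the exchange of the other:

        V̇O2  = FR·[(FiO2 − FeO2) − FeO2·(FeCO2 − FiCO2)] / (1 − FeO2)
        V̇CO2 = FR·[(FeCO2 − FiCO2) − FeCO2·(FiO2 − FeO2)] / (1 − FeCO2)

    Parameters
    ----------
    fractions : GasFractions
    flow_ml_min : float
        Incurrent flow rate, ml·min⁻¹ STP.  Must be positive.

    Returns
    -------
    GasExchangeRates
        RQ is V̇CO2/V̇O2; NaN with a flag when V̇O2 is zero or negative.
    """
    if not (flow_ml_min > 0):
        raise InvalidInputError(f"flow_ml_min must be positive, got {flow_ml_min!r}")
    f = fractions
    vo2 = flow_ml_min * ((f.fi_o2 - f.fe_o2) - f.fe_o2 * (f.fe_co2 - f.fi_co2)) / (1.0 - f.fe_o2)
    vco2 = flow_ml_min * ((f.fe_co2 - f.fi_co2) - f.fe_co2 * (f.fi_o2 - f.fe_o2)) / (1.0 - f.fe_co2)

    flags = set()
    if vo2 < 0:
        if vo2 > -flow_ml_min * _RESPIRING_TOL:
            vo2 = 0.0  # within measurement tolerance of zero
        else:
            flags.add("negative_vo2")
    if vco2 < 0:
        flags.add("negative_vco2")
    if vo2 > 0:
        rq = vco2 / vo2
    else:
        rq = math.nan
        flags.add("rq_undefined")
    return GasExchangeRates(vo2_ml_min=vo2, vco2_ml_min=vco2, rq=rq, flags=frozenset(flags))


def oxyjoule_factor(rq: float) -> float:
    """Energy released per ml O2 consumed, J·ml⁻¹, as a linear function of RQ.

    ``15.97 + 5.164·RQ``: 15.97 J·ml⁻¹ for pure fat oxidation (RQ → 0 limit of
    the fit), 21.134 J·ml⁻¹ for pure carbohydrate (RQ = 1).  Numerically equal
    to kJ per litre of O2.  Values of RQ outside the physiological band
    [0.7, 1.0] are accepted with a warning.
    """
    if not math.isfinite(rq):
        raise InvalidInputError(f"rq must be finite, got {rq!r}")
    if not (0.7 <= rq <= 1.0):
        warnings.warn(
            f"RQ={rq:.3f} outside the physiological band [0.7, 1.0]; "
            "oxyjoule factor extrapolated, not clamped",
            stacklevel=2,
        )
    return 15.97 + 5.164 * rq


def energy_rate(rates: GasExchangeRates, default_rq: float | None = None) -> EnergyEquivalent:
    """Convert V̇O2 (+RQ) into whole-animal energy expenditure, kJ·d⁻¹.

    ``kJ·d⁻¹ = V̇O2(ml·min⁻¹) · oxyjoule(RQ)(J·ml⁻¹) · 1440(min·d⁻¹) / 1000``.

    If the RQ of ``rates`` is undefined while V̇O2 is positive, the caller must
    pass ``default_rq`` explicitly; silently assuming one would bias the
    energy value.
    """
    if rates.vo2_ml_min < 0:
        raise InvalidInputError("cannot convert a negative V̇O2 to an energy rate")
    rq = rates.rq
    if not math.isfinite(rq):
        if rates.vo2_ml_min == 0:
            return EnergyEquivalent(kj_per_day=0.0, oxyjoule_j_per_ml=math.nan)
        if default_rq is None:
            raise InvalidInputError(
                "RQ is undefined for this reading; pass default_rq explicitly "
                "to convert V̇O2 to energy"
            )
        rq = default_rq
    oj = oxyjoule_factor(rq)
    kj_d = rates.vo2_ml_min * oj * 1440.0 / 1000.0
    return EnergyEquivalent(kj_per_day=kj_d, oxyjoule_j_per_ml=oj)


@dataclass(frozen=True)
class UnitSet:
    """One measurement expressed in every reporting unit of a summary table."""

    kj_per_day: float
    kj_per_kg_h: float
    ml_o2_per_h: float
    ml_o2_per_kg_h: float
    ml_co2_per_h: float
    ml_co2_per_kg_h: float
    rq: float
    mass_kg: float

    def to_dict(self) -> dict:
        return {
            "rmr_kj_d": self.kj_per_day,
            "rmr_kj_kg_h": self.kj_per_kg_h,
            "rmr_ml_o2_h": self.ml_o2_per_h,
            "rmr_ml_o2_kg_h": self.ml_o2_per_kg_h,
            "rmr_ml_co2_h": self.ml_co2_per_h,
            "rmr_ml_co2_kg_h": self.ml_co2_per_kg_h,
            "rq": self.rq,
            "mass_kg": self.mass_kg,
        }


def derive_unit_set(kj_per_day: float, rq: float, mass_kg: float) -> UnitSet:
    """Express one whole-animal energy rate in the full set of reporting units.

    The transformations are exact inverses of the oxyjoule conversion, so
    ``kJ·d⁻¹ → ml O2·h⁻¹ → kJ·d⁻¹`` round-trips to floating-point precision:

    - ml O2·h⁻¹    = kJ·d⁻¹ · 10³ / (oxyjoule(RQ) · 24)
    - ml CO2·h⁻¹   = RQ · ml O2·h⁻¹
    - kJ·kg⁻¹·h⁻¹  = kJ·d⁻¹ / (24 · mass)
    - per-kg rates divide the whole-animal rate by body mass
    """
    if not (mass_kg > 0):
        raise InvalidInputError(f"mass_kg must be positive, got {mass_kg!r}")
    oj = oxyjoule_factor(rq)
    ml_o2_h = kj_per_day * 1e3 / (oj * 24.0)
    ml_co2_h = rq * ml_o2_h
    return UnitSet(
        kj_per_day=kj_per_day,
        kj_per_kg_h=kj_per_day / (24.0 * mass_kg),
        ml_o2_per_h=ml_o2_h,
        ml_o2_per_kg_h=ml_o2_h / mass_kg,
        ml_co2_per_h=ml_co2_h,
        ml_co2_per_kg_h=ml_co2_h / mass_kg,
        rq=rq,
        mass_kg=mass_kg,
    )


def ml_o2_per_h_to_kj_per_day(ml_o2_h: float, rq: float) -> float:
    """Inverse of the O2 column of :func:`derive_unit_set`."""
    return ml_o2_h * oxyjoule_factor(rq) * 24.0 / 1e3
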