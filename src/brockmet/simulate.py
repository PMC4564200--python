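"""Synthetic study inputs: chamber gas traces and animal cohorts.

The trace simulator integrates the well-mixed chamber balance

    V·dC/dt = FR_in·C_in − FR_out·C − uptake(t)

for O2 (with release ``rq·uptake`` for CO2), using the exact exponential
update of the linear mixing dynamics on each sub-step, so there is no ODE
tolerance to tune.  Excurrent flow is tracked as
``FR_out = FR_in − V̇O2 + V̇CO2`` — the animal removes O2 volume and adds CO2
volume — which is exactly the dilution/concentration effect the flow-through
equations correct for.  A deliberately naive equal-flow variant
(``FR_out = FR_in``) is provided to quantify the bias that correction
removes.  Linear analyser drift and Gaussian reading noise are applied on
top; everything is bit-reproducible given the seed.

The cohort generator draws body masses per (season, age class, sex) cell and
assigns RMR from a linear mass + season model with Gaussian residual noise,
mirroring the structure of a field respirometry campaign on a medium-sized
carnivore: a chamber of 235 L, flows of 35–70 L·min⁻¹ chosen to hold O2
depletion in the 0.2–0.8 percentage-point band, adults near 8–10 kg and
summer cubs near 3.6 kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import gas_exchange as gx
from .errors import InvalidInputError
from .inference import AnimalRecord
from .traces import BaselinePair, GasTrace


@dataclass(frozen=True)
class Phase:
    """One metabolic phase: constant baseline V̇O2 and RQ from ``start_min``."""

    label: str
    start_min: float
    vo2_ml_min: float
    rq: float = 0.76


@dataclass(frozen=True)
class TraceSimConfig:
    """Chamber, sampling, metabolic profile and error model for one trace.

    The default profile is a resting animal whose initial activity decays
    exponentially (time constant ``settling_tau_min``) on top of the phase
    baseline — the settling shape seen in real chamber traces.  The default
    baseline V̇O2 of 110 ml·min⁻¹ at the default 46.12 L·min⁻¹ flow puts O2
    depletion mid-band at ≈0.23 percentage points.
    """

    chamber_volume_l: float = 235.0
    flow_ml_min: float = 46120.0
    fi_o2: float = gx.DEFAULT_FI_O2
    fi_co2: float = gx.DEFAULT_FI_CO2
    sample_interval_min: float = 2.0
    duration_min: float = 100.0
    phases: tuple = (Phase("rest", 0.0, 110.0, 0.76),)
    settling_excess_vo2_ml_min: float = 60.0
    settling_tau_min: float = 25.0
    noise_sd_pct: float = 0.002
    drift_pct_per_hour: float = -0.02
    co2_drift_pct_per_hour: float = 0.0
    seed: int = 0
    animal_id: str = "sim"
    chamber_temp_c: float = 20.0
    dilution_bookkeeping: bool = True  # False → naive equal-flow chamber
    start_at_steady_state: bool = False  # chamber pre-equilibrated to phase 1

    def __post_init__(self):
        if self.chamber_volume_l <= 0:
            raise InvalidInputError("chamber volume must be positive")
        if not self.phases:
            raise InvalidInputError("at least one phase is required")
        starts = [p.start_min for p in self.phases]
        if starts[0] != 0.0:
            raise InvalidInputError("the first phase must start at 0 min")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise InvalidInputError("phase starts must be strictly increasing")
        for p in self.phases:
            if not (0.6 < p.rq < 1.1):
                raise InvalidInputError(
                    f"phase {p.label!r} rq={p.rq} outside (0.6, 1.1)"
                )
            if p.vo2_ml_min < 0:
                raise InvalidInputError(f"phase {p.label!r} has negative V̇O2")


@dataclass(frozen=True)
class BurstSpec:
    """Square-wave V̇O2 bursts (movement/grooming) within one phase."""

    phase_label: str
    amplitude_ml_min: float
    period_min: float = 15.0
    duration_min: float = 5.0


def _phase_at(phases, t):
    cur = phases[0]
    for p in phases:
        if t >= p.start_min:
            cur = p
        else:
            break
    return cur


def steady_state_fractions(config: TraceSimConfig, vo2_ml_min: float, rq: float):
    """Analytic steady-state excurrent fractions for a constant V̇O2."""
    vco2 = rq * vo2_ml_min
    fr_in = config.flow_ml_min
    fr_out = fr_in - vo2_ml_min + vco2 if config.dilution_bookkeeping else fr_in
    fe_o2 = (fr_in * config.fi_o2 - vo2_ml_min) / fr_out
    fe_co2 = (fr_in * config.fi_co2 + vco2) / fr_out
    if fe_o2 <= 0:
        raise InvalidInputError(
            f"V̇O2={vo2_ml_min} ml/min exhausts chamber O2 at flow "
            f"{fr_in} ml/min"
        )
    return fe_o2, fe_co2


def simulate_trace(config: TraceSimConfig,
                   bursts: tuple = ()) -> tuple[GasTrace, dict]:
    """Integrate the chamber model and return the measured trace plus truth.

    Returns
    -------
    (trace, truth) : GasTrace, dict
        ``truth`` carries the per-phase table (true V̇O2/RQ and analytic
        steady-state fractions), the noise-free trace arrays, the baseline
        pair implied by the drift model, and the chamber time constant.
    """
    rng = np.random.default_rng(config.seed)
    v_ml = config.chamber_volume_l * 1000.0
    fr_in = config.flow_ml_min

    def vo2_at(t):
        p = _phase_at(config.phases, t)
        vo2 = p.vo2_ml_min
        if config.settling_excess_vo2_ml_min > 0:
            vo2 += config.settling_excess_vo2_ml_min * math.exp(
                -t / config.settling_tau_min
            )
        for b in bursts:
            if b.phase_label == p.label:
                rel = t - p.start_min
                if rel % b.period_min < b.duration_min:
                    vo2 += b.amplitude_ml_min
        return vo2, p.rq

    n_samples = int(math.floor(config.duration_min / config.sample_interval_min)) + 1
    times = np.arange(n_samples) * config.sample_interval_min
    if config.start_at_steady_state:
        p0 = config.phases[0]
        c_o2, c_co2 = steady_state_fractions(config, p0.vo2_ml_min, p0.rq)
    else:
        c_o2, c_co2 = config.fi_o2, config.fi_co2  # chamber starts flushed
    true_o2 = np.empty(n_samples)
    true_co2 = np.empty(n_samples)
    true_o2[0], true_co2[0] = c_o2, c_co2

    sub = min(0.25, config.sample_interval_min)
    for i in range(1, n_samples):
        t0, t1 = times[i - 1], times[i]
        nsub = max(1, int(round((t1 - t0) / sub)))
        dt = (t1 - t0) / nsub
        for k in range(nsub):
            tm = t0 + (k + 0.5) * dt
            vo2, rq = vo2_at(tm)
            vco2 = rq * vo2
            fr_out = fr_in - vo2 + vco2 if config.dilution_bookkeeping else fr_in
            ss_o2 = (fr_in * config.fi_o2 - vo2) / fr_out
            ss_co2 = (fr_in * config.fi_co2 + vco2) / fr_out
            if ss_o2 <= 0:
                raise InvalidInputError(
                    f"V̇O2={vo2:.1f} ml/min exhausts chamber O2 at t={tm:.1f} min"
                )
            decay = math.exp(-fr_out * dt / v_ml)
            c_o2 = ss_o2 + (c_o2 - ss_o2) * decay
            c_co2 = ss_co2 + (c_co2 - ss_co2) * decay
        true_o2[i], true_co2[i] = c_o2, c_co2

    drift_o2 = config.drift_pct_per_hour / 100.0 / 60.0  # fraction per minute
    drift_co2 = config.co2_drift_pct_per_hour / 100.0 / 60.0
    noise_sd = config.noise_sd_pct / 100.0
    meas_o2 = true_o2 + drift_o2 * times + rng.normal(0.0, noise_sd, n_samples)
    meas_co2 = true_co2 + drift_co2 * times + rng.normal(0.0, noise_sd, n_samples)

    labels = {p.label for p in config.phases}
    marks = (
        tuple((p.start_min, p.label) for p in config.phases)
        if labels <= {"before", "during", "waking", "after"}
        else ()
    )
    trace = GasTrace(
        time_min=times,
        fe_o2=meas_o2,
        fe_co2=meas_co2,
        flow_ml_min=fr_in,
        fi_o2=config.fi_o2,
        fi_co2=config.fi_co2,
        chamber_temp_c=config.chamber_temp_c,
        animal_id=config.animal_id,
        phase_marks=marks,
    )

    t_pre, t_post = -10.0, config.duration_min + 10.0
    baselines = BaselinePair(
        pre=(t_pre, config.fi_o2 + drift_o2 * t_pre, config.fi_co2 + drift_co2 * t_pre),
        post=(t_post, config.fi_o2 + drift_o2 * t_post, config.fi_co2 + drift_co2 * t_post),
    )
    phase_table = []
    for p in config.phases:
        ss_o2, ss_co2 = steady_state_fractions(config, p.vo2_ml_min, p.rq)
        phase_table.append(
            {
                "label": p.label,
                "start_min": p.start_min,
                "true_vo2_ml_min": p.vo2_ml_min,
                "true_rq": p.rq,
                "ss_fe_o2": ss_o2,
                "ss_fe_co2": ss_co2,
            }
        )
    truth = {
        "phase_table": phase_table,
        "true_fe_o2": true_o2,
        "true_fe_co2": true_co2,
        "baselines": baselines,
        "time_constant_min": v_ml / fr_in,
        "seed": config.seed,
    }
    return trace, truth


def default_anaesthesia_config(after_vo2_ml_min: float = 70.0,
                               during_ratio: float = 0.745,
                               rq: float = 0.76,
                               flow_ml_min: float = 46120.0,
                               seed: int = 0,
                               noise_sd_pct: float = 0.002,
                               drift_pct_per_hour: float = -0.02) -> TraceSimConfig:
    """Anaesthesia session profile: during → waking (bursty) → after.

    Anaesthetised metabolism is ``during_ratio`` of the recovered rate; the
    "after" phase begins 125 min after waking, beyond the 120-min recovery
    lag.  The animal enters the chamber already anaesthetised, so there is no
    settling excess.
    """
    if not during_ratio < 1.0:
        raise InvalidInputError("during-anaesthesia V̇O2 must be below the recovered rate")
    return TraceSimConfig(
        flow_ml_min=flow_ml_min,
        duration_min=365.0,
        sample_interval_min=1.0,
        phases=(
            Phase("during", 0.0, during_ratio * after_vo2_ml_min, rq),
            Phase("waking", 120.0, after_vo2_ml_min, rq),
            Phase("after", 245.0, after_vo2_ml_min, rq),
        ),
        settling_excess_vo2_ml_min=0.0,
        noise_sd_pct=noise_sd_pct,
        drift_pct_per_hour=drift_pct_per_hour,
        seed=seed,
        animal_id="sim-anaesthesia",
    )


def simulate_anaesthesia_session(config: TraceSimConfig | None = None,
                                 burst_amplitude_ml_min: float = 40.0,
                                 **kw) -> tuple[GasTrace, dict]:
    """Simulate a during/waking/after session with movement bursts while waking."""
    if config is None:
        config = default_anaesthesia_config(**kw)
    labels = [p.label for p in config.phases]
    if labels != ["during", "waking", "after"]:
        raise InvalidInputError(
            f"anaesthesia session needs phases during/waking/after, got {labels}"
        )
    during, _, after = config.phases
    if not during.vo2_ml_min < after.vo2_ml_min:
        raise InvalidInputError("during-anaesthesia V̇O2 must be below the after value")
    bursts = ()
    if burst_amplitude_ml_min > 0:
        bursts = (BurstSpec("waking", burst_amplitude_ml_min),)
    return simulate_trace(config, bursts=bursts)


# -- cohort generator --------------------------------------------------------

#: Default cell sizes (season, age_class, sex) → n, totalling 37 animals with
#: the study's season/age composition: 18 summer (17 adults + 1 cub),
#: 11 autumn (10 adults + 1 cub), 8 winter adults.
DEFAULT_CELLS = {
    ("summer", "adult", "M"): 9,
    ("summer", "adult", "F"): 8,
    ("summer", "cub", "F"): 1,
    ("autumn", "adult", "M"): 5,
    ("autumn", "adult", "F"): 5,
    ("autumn", "cub", "M"): 1,
    ("winter", "adult", "M"): 4,
    ("winter", "adult", "F"): 4,
}

#: (mean, sd, lower truncation) of body mass per (season, age_class), kg.
DEFAULT_MASS_PARAMS = {
    ("summer", "adult"): (8.80, 2.15, 3.0),
    ("autumn", "adult"): (8.24, 0.92, 3.0),
    ("winter", "adult"): (9.61, 1.15, 3.0),
    ("summer", "cub"): (3.58, 0.38, 1.0),
    ("autumn", "cub"): (5.70, 0.50, 1.0),
    ("winter", "cub"): (9.85, 0.35, 1.0),
}

#: Residual SD (kJ·d⁻¹) calibrated so the mass-only regression on a default
#: cohort explains ≈46% of the variance on average.
DEFAULT_RESIDUAL_SD = 230.0

#: Season offsets (kJ·d⁻¹) relative to summer, sized to the observed
#: summer/autumn/winter adjusted-mean spacing.
DEFAULT_SEASON_OFFSETS = {"summer": 0.0, "autumn": -237.0, "winter": -521.0}


@dataclass(frozen=True)
class CohortSimConfig:
    """Design and generating model for a synthetic cohort."""

    cells: dict = field(default_factory=lambda: dict(DEFAULT_CELLS))
    mass_params: dict = field(default_factory=lambda: dict(DEFAULT_MASS_PARAMS))
    intercept: float = 766.0
    mass_slope: float = 164.93
    season_offsets: dict = field(default_factory=lambda: dict(DEFAULT_SEASON_OFFSETS))
    residual_sd: float = DEFAULT_RESIDUAL_SD
    seed: int = 0

    def __post_init__(self):
        if not self.cells or all(n == 0 for n in self.cells.values()):
            raise InvalidInputError("cohort design is empty")
        if any(n < 0 for n in self.cells.values()):
            raise InvalidInputError("cell sizes must be non-negative")
        if self.residual_sd < 0:
            raise InvalidInputError("residual_sd must be non-negative")


def simulate_cohort(config: CohortSimConfig | None = None,
                    ) -> tuple[list[AnimalRecord], dict]:
    """Draw a cohort and its RMR values; deterministic given the seed.

    Masses are truncated normals per cell; RMR is
    ``intercept + slope·mass + season offset + N(0, residual_sd)``.
    """
    if config is None:
        config = CohortSimConfig()
    rng = np.random.default_rng(config.seed)
    records = []
    idx = 0
    for (season, age, sex), n in sorted(config.cells.items()):
        mean, sd, lo = config.mass_params[(season, age)]
        for _ in range(n):
            mass = rng.normal(mean, sd)
            while mass <= lo:
                mass = rng.normal(mean, sd)
            rmr = (
                config.intercept
                + config.mass_slope * mass
                + config.season_offsets[season]
                + rng.normal(0.0, config.residual_sd)
            )
            idx += 1
            records.append(
                AnimalRecord(
                    id=f"B{idx:03d}", sex=sex, age_class=age, season=season,
                    mass_kg=float(mass), rmr_kj_d=float(rmr),
                )
            )
    truth = {
        "intercept": config.intercept,
        "mass_slope": config.mass_slope,
        "season_offsets": dict(config.season_offsets),
        "residual_sd": config.residual_sd,
        "seed": config.seed,
        "n": len(records),
    }
    return records, truth


def simulate_anaesthesia_cohort(n_badgers: int = 8,
                                before_n: int = 6,
                                state_effects: dict | None = None,
                                mass_mean: float = 8.84,
                                mass_sd: float = 1.90,
                                intercept: float = 766.0,
                                mass_slope: float = 164.93,
                                id_sd: float = 150.0,
                                residual_sd: float = 120.0,
                                seed: int = 0) -> tuple[list[AnimalRecord], dict]:
    """Repeated-measures cohort for the anaesthesia mixed model.

    Each adult contributes during/after measurements and the first
    ``before_n`` also a before measurement, reproducing the unbalanced
    before/during/after design of a same-day session series.  State effects
    default to a ≈25% depression during anaesthesia relative to the awake
    states at the cohort's expected RMR.
    """
    if state_effects is None:
        state_effects = {"before": 0.0, "during": -630.0, "after": -45.0}
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_badgers):
        mass = rng.normal(mass_mean, mass_sd)
        while mass <= 3.0:
            mass = rng.normal(mass_mean, mass_sd)
        b_i = rng.normal(0.0, id_sd)
        base = intercept + mass_slope * mass + b_i
        states = ["during", "after"] + (["before"] if i < before_n else [])
        for state in states:
            rmr = base + state_effects[state] + rng.normal(0.0, residual_sd)
            records.append(
                AnimalRecord(
                    id=f"A{i + 1:02d}", sex="F" if i % 2 else "M",
                    age_class="adult", season="summer",
                    mass_kg=float(mass), state=state, rmr_kj_d=float(rmr),
                )
            )
    truth = {
        "state_effects": dict(state_effects),
        "id_sd": id_sd,
        "residual_sd": residual_sd,
        "intercept": intercept,
        "mass_slope": mass_slope,
        "seed": seed,
    }
    return records, truth
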