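"""Chamber-trace processing: from raw analyser readings to an RMR value.

A respirometry session yields a time series of excurrent %O2/%CO2.  Four steps
turn it into a resting-metabolic-rate measurement:

1. linear baseline (drift) correction against ambient-air readings taken
   before and after the session;
2. detection of the stable segment at *minimum* O2 consumption — the window of
   maximum mean excurrent O2 among all sufficiently flat windows, reflecting
   the settled, resting animal rather than the initial activity dip;
3. dilution-corrected gas exchange + energy conversion on the segment means
   (:mod:`brockmet.gas_exchange`), with a QC flag when O2 depletion falls
   outside the 0.2–0.8 percentage-point band the flow rate is tuned for;
4. for anaesthesia sessions, segmentation into before/during/waking/after
   phases at the recorded marks, each phase processed independently.

Also provides the lower-critical-temperature estimate from a series of
(ambient temperature, RMR) points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import gas_exchange as gx
from .errors import InvalidInputError, NoStableSegmentError

#: Default stability criteria (percent-O2 units at the interface for
#: readability; converted to fractions internally).
DEFAULT_WINDOW_MIN = 15.0
DEFAULT_SLOPE_TOL_PCT_PER_MIN = 0.0005
DEFAULT_RANGE_TOL_PCT = 0.01

#: O2-depletion QC band, percentage points.
DEPLETION_BAND_PCT = (0.2, 0.8)

#: Minimum time between waking and an acceptable "after anaesthesia"
#: measurement, minutes.
DEFAULT_RECOVERY_LAG_MIN = 120.0

ANAESTHESIA_STATES = ("before", "during", "after")
PHASE_LABELS = ("before", "during", "waking", "after")


@dataclass(frozen=True)
class StabilityCriteria:
    """Operational definition of a 'stable value' on the O2 trace."""

    window_min: float = DEFAULT_WINDOW_MIN
    slope_tol_pct_per_min: float = DEFAULT_SLOPE_TOL_PCT_PER_MIN
    range_tol_pct: float = DEFAULT_RANGE_TOL_PCT


@dataclass(frozen=True)
class GasTrace:
    """One chamber session: times (min), excurrent fractions, and metadata."""

    time_min: np.ndarray
    fe_o2: np.ndarray
    fe_co2: np.ndarray
    flow_ml_min: float
    fi_o2: float = gx.DEFAULT_FI_O2
    fi_co2: float = gx.DEFAULT_FI_CO2
    chamber_temp_c: float = 20.0
    animal_id: str = ""
    phase_marks: tuple = ()  # ordered (time_min, label) pairs

    def __post_init__(self):
        t = np.asarray(self.time_min, dtype=float)
        o2 = np.asarray(self.fe_o2, dtype=float)
        co2 = np.asarray(self.fe_co2, dtype=float)
        if not (t.shape == o2.shape == co2.shape):
            raise InvalidInputError("time/O2/CO2 arrays must have equal length")
        if t.size < 3:
            raise InvalidInputError("a trace needs at least 3 readings")
        if np.any(np.diff(t) <= 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise InvalidInputError(f"times must be strictly increasing (row {bad})")
        if not (1000.0 <= self.flow_ml_min <= 200000.0):
            raise InvalidInputError(
                f"flow_ml_min={self.flow_ml_min!r} outside the supported range "
                "[1000, 200000] ml/min"
            )
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "fe_o2", o2)
        object.__setattr__(self, "fe_co2", co2)

    @property
    def duration_min(self) -> float:
        return float(self.time_min[-1] - self.time_min[0])

    def slice(self, t_start: float, t_end: float) -> "GasTrace":
        m = (self.time_min >= t_start) & (self.time_min < t_end)
        return replace(
            self,
            time_min=self.time_min[m],
            fe_o2=self.fe_o2[m],
            fe_co2=self.fe_co2[m],
            phase_marks=(),
        )


@dataclass(frozen=True)
class BaselinePair:
    """Ambient-air analyser readings bracketing a session in time.

    ``pre`` and ``post`` are (time_min, o2_fraction, co2_fraction).  A single
    (constant) baseline can be expressed by giving both the same gas values at
    different times.
    """

    pre: tuple
    post: tuple

    def __post_init__(self):
        if not (self.pre[0] < self.post[0]):
            raise InvalidInputError(
                "baseline times must satisfy pre.time < post.time "
                f"(got {self.pre[0]} and {self.post[0]})"
            )


@dataclass(frozen=True)
class StableSegment:
    """The selected stable window and its summary statistics (fractions)."""

    t_start: float
    t_end: float
    mean_fe_o2: float
    mean_fe_co2: float
    slope_o2: float  # fraction per minute
    range_o2: float  # fraction
    n_points: int


@dataclass(frozen=True)
class MetabolicMeasurement:
    """An animal-linked RMR with provenance, QC flags and all unit variants."""

    animal_id: str
    state: str  # before | during | after | none
    rates: gx.GasExchangeRates
    energy: gx.EnergyEquivalent
    depletion_pct: float
    time_to_stable_min: float
    segment: StableSegment
    qc_flags: frozenset = field(default_factory=frozenset)
    mass_kg: float | None = None

    def unit_set(self) -> gx.UnitSet | None:
        if self.mass_kg is None:
            return None
        return gx.derive_unit_set(self.energy.kj_per_day, self.rates.rq, self.mass_kg)


def correct_drift(trace: GasTrace, baselines: BaselinePair,
                  true_ambient: gx.GasFractions | None = None) -> GasTrace:
    """Remove linear analyser drift using bracketing ambient-air baselines.

    Drift is assumed linear in time.  The measured-minus-true ambient offset
    at the pre and post baselines is interpolated to each reading time and
    subtracted.  When both baselines equal true ambient the trace is returned
    unchanged (the correction is idempotent in that state).
    """
    if true_ambient is None:
        true_ambient = gx.GasFractions(
            fi_o2=trace.fi_o2, fe_o2=trace.fi_o2,
            fi_co2=trace.fi_co2, fe_co2=trace.fi_co2,
        )
    t0, pre_o2, pre_co2 = baselines.pre
    t1, post_o2, post_co2 = baselines.post
    if t0 == t1:
        raise InvalidInputError("baseline times are identical; drift slope undefined")
    if not (t0 <= trace.time_min[0] and t1 >= trace.time_min[-1]):
        raise InvalidInputError(
            f"baselines at t={t0} and t={t1} min do not bracket the trace "
            f"[{trace.time_min[0]}, {trace.time_min[-1]}] min"
        )
    off_o2_pre = pre_o2 - true_ambient.fi_o2
    off_o2_post = post_o2 - true_ambient.fi_o2
    off_co2_pre = pre_co2 - true_ambient.fi_co2
    off_co2_post = post_co2 - true_ambient.fi_co2
    frac = (trace.time_min - t0) / (t1 - t0)
    return replace(
        trace,
        fe_o2=trace.fe_o2 - (off_o2_pre + frac * (off_o2_post - off_o2_pre)),
        fe_co2=trace.fe_co2 - (off_co2_pre + frac * (off_co2_post - off_co2_pre)),
    )


def _window_stats(t, o2):
    """Least-squares slope, range and mean of one candidate window."""
    slope = float(np.polyfit(t, o2, 1)[0]) if t.size > 1 else 0.0
    return slope, float(o2.max() - o2.min()), float(o2.mean())


def detect_stable_segment(trace: GasTrace,
                          criteria: StabilityCriteria | None = None) -> StableSegment:
    """Find the stable window at minimum O2 consumption.

    Candidate windows anchor at each reading and extend to the shortest span
    ≥ ``window_min``.  A window qualifies when the absolute least-squares O2
    slope and the O2 range both fall within tolerance.  Among qualifying
    windows the one with **maximum mean excurrent O2** is returned (ties by
    latest start), i.e. the reading at minimum O2 consumption — the settled
    animal, not its initial activity dip.

    Raises
    ------
    NoStableSegmentError
        When no window qualifies; carries the flattest window found.
    """
    if criteria is None:
        criteria = StabilityCriteria()
    t, o2, co2 = trace.time_min, trace.fe_o2, trace.fe_co2
    if trace.duration_min < criteria.window_min:
        raise InvalidInputError(
            f"trace duration {trace.duration_min:g} min shorter than the "
            f"stability window {criteria.window_min:g} min"
        )
    slope_tol = criteria.slope_tol_pct_per_min / 100.0
    range_tol = criteria.range_tol_pct / 100.0

    best = None  # (mean_o2, t_start) ordering key
    flattest = None
    n = t.size
    # First reading at/after t[i] + window completes the window anchored at i.
    ends = np.searchsorted(t, t + criteria.window_min - 1e-9, side="left")
    for i in range(n):
        j = min(int(ends[i]) + 1, n)
        sl = slice(i, j)
        tw, ow = t[sl], o2[sl]
        if tw.size < 2 or tw[-1] - tw[0] < criteria.window_min - 1e-9:
            break  # remaining starts have even less span
        slope, rng, mean_o2 = _window_stats(tw, ow)
        seg = StableSegment(
            t_start=float(tw[0]), t_end=float(tw[-1]),
            mean_fe_o2=mean_o2, mean_fe_co2=float(co2[sl].mean()),
            slope_o2=slope, range_o2=rng, n_points=int(tw.size),
        )
        if flattest is None or abs(slope) < abs(flattest.slope_o2):
            flattest = seg
        if abs(slope) <= slope_tol and rng <= range_tol:
            key = (mean_o2, seg.t_start)
            if best is None or key >= best[0]:
                best = (key, seg)
    if best is None:
        raise NoStableSegmentError(
            "no window satisfied the stability criteria "
            f"(window ≥ {criteria.window_min:g} min, |slope| ≤ "
            f"{criteria.slope_tol_pct_per_min:g} %O2/min, range ≤ "
            f"{criteria.range_tol_pct:g} %O2); flattest window had slope "
            f"{(flattest.slope_o2 * 100 if flattest else math.nan):.3g} %O2/min",
            best_window=flattest,
        )
    return best[1]


def extract_rmr(trace: GasTrace,
                criteria: StabilityCriteria | None = None,
                state: str = "none",
                mass_kg: float | None = None,
                extra_flags: frozenset = frozenset()) -> MetabolicMeasurement:
    """Stable segment → gas exchange → energy, with depletion QC.

    The trace is assumed drift-corrected.  Gas exchange is computed on the
    segment means; the ``depletion_out_of_band`` flag is set exactly when the
    O2 depletion leaves the 0.2–0.8 percentage-point band.
    """
    seg = detect_stable_segment(trace, criteria)
    fractions = gx.GasFractions(
        fi_o2=trace.fi_o2, fe_o2=seg.mean_fe_o2,
        fi_co2=trace.fi_co2, fe_co2=seg.mean_fe_co2,
    )
    rates = gx.compute_gas_exchange(fractions, trace.flow_ml_min)
    energy = gx.energy_rate(rates)
    depletion = fractions.o2_depletion_pct
    flags = set(extra_flags) | set(rates.flags)
    lo, hi = DEPLETION_BAND_PCT
    if not (lo <= depletion <= hi):
        flags.add("depletion_out_of_band")
    if mass_kg is None:
        flags.add("missing_mass")
    return MetabolicMeasurement(
        animal_id=trace.animal_id,
        state=state,
        rates=rates,
        energy=energy,
        depletion_pct=depletion,
        time_to_stable_min=seg.t_end - float(trace.time_min[0]),
        segment=seg,
        qc_flags=frozenset(flags),
        mass_kg=mass_kg,
    )


def segment_phases(trace: GasTrace) -> list[tuple[str, GasTrace]]:
    """Partition an anaesthesia-session trace at its phase marks.

    Marks are (time, label) with labels from before/during/waking/after; each
    mark opens the phase that runs to the next mark (the last runs to the end
    of the trace).  A trace without marks is returned whole with state
    ``"none"``.
    """
    marks = list(trace.phase_marks)
    if not marks:
        return [("none", trace)]
    times = [m[0] for m in marks]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise InvalidInputError(f"phase marks must be strictly increasing in time: {times}")
    for _, label in marks:
        if label not in PHASE_LABELS:
            raise InvalidInputError(
                f"unknown phase label {label!r}; allowed: {', '.join(PHASE_LABELS)}"
            )
    out = []
    bounds = times + [float(trace.time_min[-1]) + 1e-9]
    for (t_lo, label), t_hi in zip(marks, bounds[1:]):
        sub = trace.slice(t_lo, t_hi)
        if sub.time_min.size >= 3:
            out.append((label, sub))
    return out


def process_session(trace: GasTrace,
                    criteria: StabilityCriteria | None = None,
                    mass_kg: float | None = None,
                    recovery_lag_min: float = DEFAULT_RECOVERY_LAG_MIN,
                    ) -> list[MetabolicMeasurement]:
    """Run :func:`extract_rmr` on every RMR-bearing phase of a session.

    The waking phase (animal intermittently moving) is transitional and is not
    converted to an RMR.  The "after anaesthesia" phase is flagged
    ``recovery_lag_short`` unless it starts at least ``recovery_lag_min``
    minutes after the waking mark, so measurements taken too soon after
    recovery are never accepted silently.
    """
    waking_time = None
    for t, label in trace.phase_marks:
        if label == "waking":
            waking_time = t
    out = []
    for label, sub in segment_phases(trace):
        if label == "waking":
            continue
        flags = set()
        if label == "after" and waking_time is not None:
            if float(sub.time_min[0]) - waking_time < recovery_lag_min:
                flags.add("recovery_lag_short")
        out.append(
            extract_rmr(sub, criteria=criteria, state=label, mass_kg=mass_kg,
                        extra_flags=frozenset(flags))
        )
    return out


def estimate_lct(temps_c, rmr_kj_d) -> float:
    """Lower critical temperature from a (temperature, RMR) series.

    RMR falls with rising ambient temperature below the thermoneutral zone and
    stops decreasing at its lower boundary; the estimate is the lowest
    temperature attaining the minimum RMR of the series.
    """
    temps = np.asarray(temps_c, dtype=float)
    rmr = np.asarray(rmr_kj_d, dtype=float)
    if temps.size != rmr.size:
        raise InvalidInputError("temperature and RMR series must have equal length")
    if np.unique(temps).size < 2:
        raise InvalidInputError("need at least 2 distinct temperatures to estimate LCT")
    order = np.argsort(temps, kind="stable")
    temps, rmr = temps[order], rmr[order]
    return float(temps[int(np.argmin(rmr))])
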