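"""Plain-CSV readers/writers and label validation.

File formats use percent for gas columns (matching analyser output); the
in-memory representation is fractions, converted here at the boundary.

Trace CSV:   ``time_min,o2_pct,co2_pct`` (+ optional ``flow_ml_min``), with
             session metadata (flow, incurrent percentages, chamber
             temperature, animal id, phase marks) supplied alongside.
Cohort CSV:  ``animal_id,sex,age_class,season,mass_kg[,state][,rmr_kj_d]``.
Measurement CSV: one row per (animal, state) with every reporting unit and
             the QC flags.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

from . import gas_exchange as gx
from .errors import InvalidInputError, VocabularyError
from .inference import AGE_CLASSES, SEASONS, SEXES, STATES, AnimalRecord
from .traces import GasTrace, MetabolicMeasurement

TRACE_COLUMNS = ("time_min", "o2_pct", "co2_pct")
COHORT_COLUMNS = ("animal_id", "sex", "age_class", "season", "mass_kg")


def parse_phase_marks(specs) -> tuple:
    """``["during@0", "waking@90"]`` → ((0.0, "during"), (90.0, "waking"))."""
    marks = []
    for spec in specs:
        if "@" not in spec:
            raise InvalidInputError(
                f"phase mark {spec!r} is not of the form label@minute"
            )
        label, _, t = spec.partition("@")
        marks.append((float(t), label.strip()))
    return tuple(marks)


def read_trace_csv(path, flow_ml_min: float | None = None,
                   fi_o2_pct: float = gx.DEFAULT_FI_O2 * 100.0,
                   fi_co2_pct: float = gx.DEFAULT_FI_CO2 * 100.0,
                   chamber_temp_c: float = 20.0,
                   animal_id: str = "",
                   phase_marks: tuple = ()) -> GasTrace:
    """Load a chamber trace; percent columns are converted to fractions."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(
            f"{path}: missing columns {', '.join(missing)}; expected header "
            f"{','.join(TRACE_COLUMNS)}"
        )
    t = df["time_min"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise InvalidInputError(
            f"{path}: time_min not strictly increasing at row {int(bad[0]) + 3} "
            "(1-based, counting the header)"
        )
    if flow_ml_min is None:
        if "flow_ml_min" not in df.columns:
            raise InvalidInputError(
                f"{path}: no flow_ml_min column and no flow supplied"
            )
        flow_ml_min = float(df["flow_ml_min"].iloc[0])
    return GasTrace(
        time_min=t,
        fe_o2=df["o2_pct"].to_numpy(dtype=float) / 100.0,
        fe_co2=df["co2_pct"].to_numpy(dtype=float) / 100.0,
        flow_ml_min=flow_ml_min,
        fi_o2=fi_o2_pct / 100.0,
        fi_co2=fi_co2_pct / 100.0,
        chamber_temp_c=chamber_temp_c,
        animal_id=animal_id,
        phase_marks=tuple(phase_marks),
    )


def write_trace_csv(trace: GasTrace, path) -> None:
    pd.DataFrame(
        {
            "time_min": trace.time_min,
            "o2_pct": trace.fe_o2 * 100.0,
            "co2_pct": trace.fe_co2 * 100.0,
            "flow_ml_min": trace.flow_ml_min,
        }
    ).to_csv(path, index=False)


def _check_vocab(value, allowed, column, row):
    if value not in allowed:
        raise VocabularyError(
            f"row {row}: {column}={value!r}; allowed values: {', '.join(allowed)}"
        )


def read_cohort_csv(path) -> list[AnimalRecord]:
    """Load an animal table, validating labels row by row."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(
            f"{path}: missing columns {', '.join(missing)}"
        )
    records = []
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based with header
        _check_vocab(row["sex"], SEXES, "sex", rownum)
        _check_vocab(row["age_class"], AGE_CLASSES, "age_class", rownum)
        _check_vocab(row["season"], SEASONS, "season", rownum)
        state = row.get("state", "none")
        if pd.isna(state):
            state = "none"
        _check_vocab(state, STATES, "state", rownum)
        rmr = row.get("rmr_kj_d", None)
        if rmr is not None and pd.isna(rmr):
            rmr = None
        try:
            records.append(
                AnimalRecord(
                    id=str(row["animal_id"]), sex=row["sex"],
                    age_class=row["age_class"], season=row["season"],
                    mass_kg=float(row["mass_kg"]), state=state,
                    rmr_kj_d=None if rmr is None else float(rmr),
                )
            )
        except InvalidInputError as e:
            raise InvalidInputError(f"row {rownum}: {e}") from e
    return records


def write_cohort_csv(records, path) -> None:
    from .inference import records_to_frame

    # %.17g guarantees float round-trip to full precision
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def measurements_to_frame(measurements: list[MetabolicMeasurement]) -> pd.DataFrame:
    """Measurement list → one tidy row per (animal, state) in all units."""
    rows = []
    for m in measurements:
        row = {
            "animal_id": m.animal_id,
            "state": m.state,
            "vo2_ml_min": m.rates.vo2_ml_min,
            "vco2_ml_min": m.rates.vco2_ml_min,
            "rq": m.rates.rq,
            "rmr_kj_d": m.energy.kj_per_day,
            "depletion_pct": m.depletion_pct,
            "time_to_stable_min": m.time_to_stable_min,
            "mass_kg": m.mass_kg,
            "qc_flags": ";".join(sorted(m.qc_flags)),
        }
        us = m.unit_set()
        if us is not None:
            d = us.to_dict()
            for key in ("rmr_kj_kg_h", "rmr_ml_o2_h", "rmr_ml_o2_kg_h",
                        "rmr_ml_co2_h", "rmr_ml_co2_kg_h"):
                row[key] = d[key]
        rows.append(row)
    return pd.DataFrame(rows)


def season_from_date(date) -> str:
    """Map a capture date to the trapping-calendar season.

    Cutoffs at month-half granularity: mid-June to mid-September is summer,
    late September to mid-December is autumn, late December through January is
    winter.  February–May (and early June) fall outside the trapping calendar
    and raise a :class:`VocabularyError`.
    """
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    month, second_half = date.month, date.day > 15
    if (month == 6 and second_half) or month in (7, 8) or (month == 9 and not second_half):
        return "summer"
    if (month == 9 and second_half) or month in (10, 11) or (month == 12 and not second_half):
        return "autumn"
    if (month == 12 and second_half) or month == 1:
        return "winter"
    raise VocabularyError(
        f"date {date.isoformat()} falls outside the trapping calendar "
        "(no season defined for February–early June)"
    )
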