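"""CSV interchange formats.

Two tidy tables drive the pipeline:

* patients: one row per subject, ``injury_time`` as 24-h ``HH:MM``,
  comorbidities semicolon-delimited;
* measurements: long format, one row per (patient, mediator, time,
  concentration).

Mediator names may contain ``/`` (NO2-/NO3-) and other punctuation;
standard CSV quoting preserves them.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cohort import AIS_REGIONS, PatientRecord

MEASUREMENT_COLUMNS = ("patient_id", "mediator", "time_h", "value_pg_ml")
PATIENT_COLUMNS = (
    "patient_id", "age", "sex", "iss",
    "ais_head_neck", "ais_face", "ais_chest", "ais_abdomen",
    "ais_extremities", "ais_external",
    "injury_time", "mechanism", "comorbidities",
    "icu_los", "hospital_los", "vent_days", "ni",
)


def read_measurements(path) -> pd.DataFrame:
    """Read a long-format measurements CSV with row-level validation.

    Unknown mediator names are preserved (the panel is open).  Malformed
    or negative rows are rejected with the 1-based file line number.
    """
    df = pd.read_csv(path, dtype=str)
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: empty measurements file")
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no measurement rows")
    out = df[list(MEASUREMENT_COLUMNS)].copy()
    for col in ("time_h", "value_pg_ml"):
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & out[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: malformed {col} at line {line}")
        nan = out[col].isna()
        if nan.any():
            line = int(nan.idxmax()) + 2
            raise ValueError(f"{path}: missing {col} at line {line}")
        out[col] = converted
    neg = out["value_pg_ml"] < 0
    if neg.any():
        line = int(neg.idxmax()) + 2
        raise ValueError(f"{path}: negative concentration at line {line}")
    return out


def write_measurements(samples: pd.DataFrame, path) -> None:
    samples[list(MEASUREMENT_COLUMNS)].to_csv(path, index=False)


def _minutes_from_hhmm(text: str) -> int:
    parts = text.strip().split(":")
    if len(parts) != 2:
        raise ValueError(f"injury_time {text!r} is not HH:MM")
    h, m = int(parts[0]), int(parts[1])
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ValueError(f"injury_time {text!r} out of range")
    return 60 * h + m


def _hhmm_from_minutes(t: int) -> str:
    return f"{t // 60:02d}:{t % 60:02d}"


def read_patients(path) -> list[PatientRecord]:
    """Read the patients CSV into typed records (group derived from time)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(PATIENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no patient rows")
    records = []
    for i, row in df.iterrows():
        try:
            comorbs = {c for c in row["comorbidities"].split(";") if c}
            records.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    age=float(row["age"]),
                    sex=row["sex"],
                    iss=int(row["iss"]),
                    ais={r: int(row[f"ais_{r}"]) for r in AIS_REGIONS},
                    injury_clock_time=_minutes_from_hhmm(row["injury_time"]),
                    mechanism=row["mechanism"],
                    comorbidities=comorbs,
                    icu_los_days=float(row["icu_los"]),
                    hospital_los_days=float(row["hospital_los"]),
                    vent_days=float(row["vent_days"]),
                    nosocomial_infection=row["ni"].strip().lower()
                    in ("1", "true", "yes"),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: bad patient row at line {int(i) + 2}: {exc}")
    return records


def write_patients(records, path) -> None:
    rows = []
    for p in records:
        row = {
            "patient_id": p.patient_id,
            "age": p.age,
            "sex": p.sex,
            "iss": p.iss,
        }
        row.update({f"ais_{r}": p.ais.get(r, 0) for r in AIS_REGIONS})
        row.update(
            {
                "injury_time": _hhmm_from_minutes(p.injury_clock_time),
                "mechanism": p.mechanism,
                "comorbidities": ";".join(sorted(p.comorbidities)),
                "icu_los": p.icu_los_days,
                "hospital_los": p.hospital_los_days,
                "vent_days": p.vent_days,
                "ni": int(p.nosocomial_infection),
            }
        )
        rows.append(row)
    pd.DataFrame(rows, columns=list(PATIENT_COLUMNS)).to_csv(path, index=False)


def write_graphml(net, path) -> None:
    """Attributed GraphML export of a correlation network."""
    import networkx as nx

    nx.write_graphml(net.to_graph(), Path(path))


def write_sif(net, path) -> None:
    Path(path).write_text(net.to_sif())
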