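"""Patient-level registry data model, CSV I/O, complete-case filtering,
observability logic and per-hospital aggregation."""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

#: canonical registry columns in write order
REGISTRY_COLUMNS = [
    "patient_id",
    "hospital_id",
    "age",
    "kps",
    "year",
    "gender",
    "surgery_type",
    "surgery_date",
    "time_days",
    "status",
    "potential_followup_days",
]

GENDERS = {"male", "female"}
SURGERY_TYPES = {"biopsy", "resection"}
STATUSES = {"dead", "censored"}
KPS_LEVELS = set(range(10, 110, 10))
YEARS = set(range(2011, 2015))


@dataclass(frozen=True)
class PatientRecord:
    """One surgical case.

    ``time_days`` counts whole days from surgery (day 0) to death or last
    contact; ``potential_followup_days`` counts days from surgery to the
    administrative lookup date, i.e. the longest follow-up this patient could
    have had.
    """

    patient_id: str
    hospital_id: str
    age: float | None
    kps: int | None
    year: int | None
    gender: str | None
    surgery_type: str | None
    time_days: int
    status: str
    potential_followup_days: int

    def validate(self) -> None:
        if self.time_days < 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: negative time_days {self.time_days}")
        if self.status not in STATUSES:
            raise ValidationError(
                f"patient {self.patient_id!r}: bad status {self.status!r}")
        if self.status == "censored" and self.time_days > self.potential_followup_days:
            raise ValidationError(
                f"patient {self.patient_id!r}: censored beyond potential follow-up "
                f"({self.time_days} > {self.potential_followup_days})")
        if self.kps is not None and self.kps not in KPS_LEVELS:
            raise ValidationError(
                f"patient {self.patient_id!r}: KPS {self.kps} not on the 10..100 ladder")
        if self.gender is not None and self.gender not in GENDERS:
            raise ValidationError(
                f"patient {self.patient_id!r}: bad gender {self.gender!r}")
        if self.surgery_type is not None and self.surgery_type not in SURGERY_TYPES:
            raise ValidationError(
                f"patient {self.patient_id!r}: bad surgery_type {self.surgery_type!r}")


@dataclass
class RegistrySchema:
    """Column mapping and date handling for registry CSV files.

    When ``time_days``/``status`` columns are absent the reader derives them
    from ``death_date`` / ``last_contact_date`` and the lookup date.
    """

    columns: Mapping[str, str] = field(default_factory=dict)  # canonical -> file
    lookup_date: str = "2016-03-01"

    def file_column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


def _parse_optional(value, kind, row_number, column):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        return kind(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(
            f"row {row_number}: cannot parse column {column!r} value {value!r}") from exc


def read_registry(path: str | Path, schema: RegistrySchema | None = None) -> pd.DataFrame:
    """Read a patient registry CSV into the canonical frame.

    Missing age/KPS/year/gender/surgery_type are permitted (and later removed
    by :func:`complete_case_filter` where they matter); malformed values raise
    :class:`ValidationError` naming the row and field.
    """
    schema = schema or RegistrySchema()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)

    col = schema.file_column
    required = ["patient_id", "hospital_id"]
    for canonical in required:
        if col(canonical) not in raw.columns:
            raise ValidationError(f"missing required column {col(canonical)!r}")

    has_times = col("time_days") in raw.columns and col("status") in raw.columns
    has_dates = col("surgery_date") in raw.columns
    if not has_times and not has_dates:
        raise ValidationError(
            "registry must carry either time_days/status or surgery/death/contact dates")

    lookup = dt.date.fromisoformat(schema.lookup_date)
    records = []
    for i, row in enumerate(raw.itertuples(index=False), start=2):  # header = line 1
        row = dict(zip(raw.columns, row))

        def get(canonical):
            return row.get(col(canonical), "")

        age = _parse_optional(get("age"), float, i, "age")
        kps = _parse_optional(get("kps"), int, i, "kps")
        year = _parse_optional(get("year"), int, i, "year")
        gender = get("gender") or None
        surgery_type = get("surgery_type") or None
        surgery_date = get("surgery_date") or None

        if has_times:
            time_days = _parse_optional(get("time_days"), int, i, "time_days")
            status = get("status") or None
            pfu = _parse_optional(get("potential_followup_days"), int,
                                  i, "potential_followup_days")
            if pfu is None:
                if surgery_date is None:
                    raise ValidationError(
                        f"row {i}: potential_followup_days missing and no surgery_date")
                pfu = (lookup - dt.date.fromisoformat(surgery_date)).days
        else:
            if not surgery_date:
                raise ValidationError(f"row {i}: missing surgery_date")
            surgery = dt.date.fromisoformat(surgery_date)
            pfu = (lookup - surgery).days
            death = get("death_date") or None
            contact = get("last_contact_date") or None
            if death:
                d = (dt.date.fromisoformat(death) - surgery).days
                time_days, status = min(d, pfu), "dead"
            else:
                last = dt.date.fromisoformat(contact) if contact else lookup
                time_days = min((last - surgery).days, pfu)
                status = "censored"
        if time_days is None or status is None:
            raise ValidationError(f"row {i}: missing time_days or status")
        if year is None and surgery_date:
            year = dt.date.fromisoformat(surgery_date).year

        rec = PatientRecord(
            patient_id=str(get("patient_id")),
            hospital_id=str(get("hospital_id")),
            age=age, kps=kps, year=year, gender=gender,
            surgery_type=surgery_type, time_days=time_days,
            status=status, potential_followup_days=pfu,
        )
        try:
            rec.validate()
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        d = dataclasses.asdict(rec)
        d["surgery_date"] = surgery_date
        records.append(d)

    frame = pd.DataFrame(records, columns=REGISTRY_COLUMNS)
    if frame.empty:
        frame = pd.DataFrame(columns=REGISTRY_COLUMNS)
    return frame


def write_registry(records: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical registry frame to CSV (UTF-8, ISO dates)."""
    out = records.reindex(columns=REGISTRY_COLUMNS)
    out.to_csv(path, index=False)


def validate_registry(records: pd.DataFrame) -> None:
    """Run the PatientRecord invariants over a frame; raise on first failure."""
    for _, row in records.iterrows():
        PatientRecord(
            patient_id=str(row["patient_id"]),
            hospital_id=str(row["hospital_id"]),
            age=None if pd.isna(row["age"]) else float(row["age"]),
            kps=None if pd.isna(row["kps"]) else int(row["kps"]),
            year=None if pd.isna(row["year"]) else int(row["year"]),
            gender=None if pd.isna(row.get("gender")) else row.get("gender"),
            surgery_type=None if pd.isna(row.get("surgery_type")) else row.get("surgery_type"),
            time_days=int(row["time_days"]),
            status=str(row["status"]),
            potential_followup_days=int(row["potential_followup_days"]),
        ).validate()


# model covariates that must be nonmissing for inclusion; gender and surgery
# type are not model covariates and do not trigger exclusion
COMPLETE_CASE_FIELDS = ("age", "kps", "year")


def complete_case_filter(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records missing any model covariate (age, KPS, year).

    Returns ``(kept, exclusion_log)`` where the log counts exclusions per
    missing field per hospital (a record missing two fields appears under
    both).
    """
    missing = {f: records[f].isna() for f in COMPLETE_CASE_FIELDS}
    any_missing = np.logical_or.reduce(list(missing.values())) if len(records) else \
        np.zeros(0, dtype=bool)
    kept = records.loc[~any_missing].reset_index(drop=True)

    log_rows = []
    for fld, mask in missing.items():
        if mask.any():
            counts = records.loc[mask, "hospital_id"].value_counts()
            for hosp, n in counts.items():
                log_rows.append({"hospital_id": hosp, "field": fld, "n_excluded": int(n)})
    log = pd.DataFrame(log_rows, columns=["hospital_id", "field", "n_excluded"])
    return kept, log


def observable_at(records: pd.DataFrame, horizon_days: int) -> pd.DataFrame:
    """Restrict to patients whose status at the horizon is determined.

    A patient is observable at horizon ``h`` iff they died within ``h`` days
    or their potential follow-up reaches ``h``.  The returned frame carries a
    boolean ``dead_by_horizon`` column ("within h" uses the closed boundary
    ``time_days <= h``).
    """
    if horizon_days <= 0:
        raise ValidationError(f"horizon must be positive, got {horizon_days}")
    dead_by = (records["status"] == "dead") & (records["time_days"] <= horizon_days)
    observable = dead_by | (records["potential_followup_days"] >= horizon_days)
    out = records.loc[observable].copy()
    out["dead_by_horizon"] = dead_by[observable].to_numpy()
    return out.reset_index(drop=True)


def summarize_hospitals(records: pd.DataFrame,
                        academic: Mapping[str, bool] | None = None,
                        all_records: pd.DataFrame | None = None) -> pd.DataFrame:
    """Build a per-hospital summary table plus an ``overall`` pseudo-row.

    ``records`` should already be complete-case filtered; ``all_records``
    (pre-filter) supplies the total registration counts when given.
    Percentages are ratios in [0, 1]; round for display only.
    """
    academic = dict(academic or {})
    if all_records is None:
        all_records = records
    hospitals = sorted(set(all_records["hospital_id"]) | set(records["hospital_id"]))
    unknown = [h for h in academic if h not in hospitals]
    if unknown:
        raise ValidationError(f"academic map names unknown hospitals: {unknown}")

    obs30 = observable_at(records, 30)
    obs730 = observable_at(records, 730)

    rows = []
    for hosp in hospitals + ["overall"]:
        if hosp == "overall":
            sel = records
            sel_all = all_records
            sel30, sel730 = obs30, obs730
        else:
            sel = records[records["hospital_id"] == hosp]
            sel_all = all_records[all_records["hospital_id"] == hosp]
            sel30 = obs30[obs30["hospital_id"] == hosp]
            sel730 = obs730[obs730["hospital_id"] == hosp]
        n_res = int((sel_all["surgery_type"] == "resection").sum())
        n_bio = int((sel_all["surgery_type"] == "biopsy").sum())
        deaths30 = int(sel30["dead_by_horizon"].sum())
        surv2y = int((~sel730["dead_by_horizon"]).sum())
        row = {
            "hospital_id": hosp,
            "n_total": len(sel_all),
            "n_complete": len(sel),
            "n_resection": n_res,
            "n_biopsy": n_bio,
            "biopsy_fraction": n_bio / (n_bio + n_res) if (n_bio + n_res) else np.nan,
            "deaths_30d": deaths30,
            "observable_30d": len(sel30),
            "mortality_30d": deaths30 / len(sel30) if len(sel30) else np.nan,
            "survivors_2y": surv2y,
            "observable_2y": len(sel730),
            "survival_2y": surv2y / len(sel730) if len(sel730) else np.nan,
            "age_mean": float(sel["age"].mean()) if len(sel) else np.nan,
            "age_sd": float(sel["age"].std(ddof=1)) if len(sel) > 1 else np.nan,
            "academic": academic.get(hosp) if hosp != "overall" else None,
        }
        for level in sorted(KPS_LEVELS):
            row[f"kps_{level}"] = int((sel["kps"] == level).sum())
        for year in sorted(YEARS):
            row[f"year_{year}"] = int((sel["year"] == year).sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("hospital_id")


def export_summary(summary: pd.DataFrame, csv_path=None, json_path=None) -> None:
    if csv_path is not None:
        summary.to_csv(csv_path)
    if json_path is not None:
        payload = json.loads(summary.reset_index().to_json(orient="records"))
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
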