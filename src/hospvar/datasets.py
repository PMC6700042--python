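"""Built-in reference dataset: aggregate counts for a 14-hospital glioblastoma
surgery cohort (2,409 adults, 2011-2014, administrative follow-up lookup on
2016-03-01).

The table carries per-hospital registration counts, complete-case counts,
covariate distributions, surgery-type counts and the observed 30-day / 2-year
outcome counts.  It is used in examples, validation tests and the acceptance
report; all downstream percentages (mortality, survival, biopsy share) are
recomputed from the raw counts, never stored.
"""

from __future__ import annotations

import pandas as pd

HOSPITALS = list("abcdefghijklmn")

#: per-hospital aggregate counts, one row per hospital in HOSPITALS order
_COLUMNS = {
    "hospital_id": HOSPITALS,
    "n_total": [81, 229, 293, 97, 161, 269, 197, 91, 103, 233, 103, 121, 73, 358],
    "n_complete": [77, 228, 277, 95, 116, 268, 196, 82, 102, 232, 103, 111, 73, 348],
    "n_male": [49, 152, 178, 61, 97, 172, 127, 58, 55, 145, 64, 55, 44, 219],
    "n_female": [32, 77, 114, 36, 63, 94, 70, 33, 48, 88, 39, 47, 29, 136],
    "age_mean": [64.6, 60.5, 63.6, 54.6, 60.3, 60.6, 60.8, 62.9, 61.2, 61.7, 64.8, 59.7, 59.0, 62.0],
    "age_sd": [10.8, 13.3, 11.9, 14.7, 11.9, 12.6, 12.2, 10.2, 12.5, 11.8, 10.8, 12.7, 13.0, 10.9],
    "n_missing_age": [1, 0, 0, 1, 0, 0, 1, 0, 0, 1, 0, 0, 0, 6],
    "kps_100": [1, 23, 9, 35, 3, 25, 15, 8, 1, 12, 10, 3, 16, 55],
    "kps_90": [30, 57, 91, 25, 44, 82, 56, 26, 50, 84, 26, 28, 24, 167],
    "kps_80": [21, 48, 65, 19, 30, 62, 47, 26, 27, 87, 38, 33, 11, 67],
    "kps_70": [8, 59, 54, 13, 21, 54, 25, 10, 9, 26, 16, 21, 10, 31],
    "kps_60": [13, 29, 33, 1, 11, 23, 24, 3, 10, 15, 8, 4, 6, 19],
    "kps_50": [4, 11, 19, 1, 3, 12, 20, 11, 6, 5, 5, 11, 4, 15],
    "kps_40": [0, 1, 4, 2, 0, 2, 3, 2, 0, 2, 0, 4, 1, 0],
    "kps_30": [0, 0, 1, 0, 1, 2, 6, 1, 0, 0, 0, 1, 1, 0],
    "kps_20": [1, 0, 1, 0, 3, 5, 0, 3, 0, 2, 0, 7, 0, 0],
    "kps_10": [0, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0],
    "kps_missing": [3, 1, 16, 1, 45, 1, 0, 1, 0, 0, 0, 9, 0, 4],
    "year_2011": [9, 53, 3, 23, 42, 66, 58, 31, 20, 63, 21, 26, 13, 95],
    "year_2012": [23, 49, 99, 16, 46, 68, 45, 20, 30, 63, 35, 2, 14, 91],
    "year_2013": [21, 53, 102, 25, 26, 58, 47, 24, 27, 56, 29, 37, 26, 78],
    "year_2014": [28, 74, 89, 33, 47, 77, 47, 16, 26, 51, 18, 56, 20, 94],
    "academic": [True, True, True, True, True, True, True,
                 False, False, False, False, False, False, False],
    "n_resection": [60, 175, 192, 23, 49, 187, 154, 65, 72, 179, 44, 102, 53, 209],
    "n_biopsy": [21, 54, 101, 62, 42, 68, 43, 25, 31, 54, 58, 19, 20, 147],
    "median_survival_months": [10.2, 11.4, 10.0, 14.9, 7.4, 10.8, 9.5, 10.3, 5.2, 10.7, 4.8, 12.0, 12.1, 10.3],
    "deaths_30d": [6, 6, 18, 4, 10, 10, 10, 6, 6, 9, 6, 11, 3, 14],
    "observable_30d": [77, 228, 277, 95, 116, 268, 196, 82, 102, 232, 103, 111, 73, 348],
    "survivors_2y": [3, 36, 39, 18, 11, 30, 28, 7, 0, 32, 5, 16, 8, 37],
    "observable_2y": [67, 210, 255, 78, 105, 236, 183, 78, 12, 211, 91, 93, 65, 317],
}

#: overall cohort summary statistics (not derivable per-hospital)
OVERALL_AGE_MEAN = 61.4
OVERALL_AGE_SD = 12.2
OVERALL_MEDIAN_SURVIVAL_MONTHS = 10.2
LOOKUP_DATE = "2016-03-01"
ACCRUAL_START = "2011-01-01"
ACCRUAL_END = "2014-12-31"


def hospital_counts() -> pd.DataFrame:
    """Return the per-hospital aggregate count table, indexed by hospital id."""
    df = pd.DataFrame(_COLUMNS).set_index("hospital_id")
    return df


def overall_counts() -> pd.Series:
    """Column sums of the count table (numeric count columns only)."""
    df = hospital_counts()
    count_cols = [c for c in df.columns
                  if c.startswith(("n_", "kps_", "year_"))
                  or c in ("deaths_30d", "observable_30d", "survivors_2y", "observable_2y")]
    return df[count_cols].sum()


def kps_distribution() -> pd.Series:
    """Overall KPS distribution over the 10..100 ladder as probabilities
    (missing values excluded from the denominator)."""
    tot = overall_counts()
    levels = [f"kps_{v}" for v in range(10, 110, 10)]
    counts = tot[levels].astype(float)
    probs = counts / counts.sum()
    probs.index = [int(c.split("_")[1]) for c in levels]
    return probs


def expand_to_patient_records(counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Expand the aggregate count table into a canonical patient-level frame.

    The reconstruction is the minimal registry consistent with the aggregate
    outcome counts: 30-day deaths die on day 20, later deaths on day 400,
    2-year survivors are censored at day 800 with full potential follow-up,
    patients unobservable at 2 years are censored at day 500, and excluded
    (incomplete) cases carry a missing KPS.  Surgery types are assigned to
    match the per-hospital biopsy/resection counts.  Running the registry
    pipeline on this frame reproduces every aggregate outcome statistic of
    the source table exactly.
    """
    if counts is None:
        counts = hospital_counts()
    rows = []
    for hosp, c in counts.iterrows():
        deaths30 = int(c["deaths_30d"])
        surv2y = int(c["survivors_2y"])
        late_dead = int(c["observable_2y"]) - surv2y - deaths30
        unobservable = int(c["n_complete"]) - int(c["observable_2y"])
        incomplete = int(c["n_total"]) - int(c["n_complete"])
        if min(late_dead, unobservable, incomplete) < 0:
            raise ValueError(f"inconsistent counts for hospital {hosp!r}")
        groups = (
            [(20, "dead", 800, False)] * deaths30
            + [(400, "dead", 800, False)] * late_dead
            + [(800, "censored", 800, False)] * surv2y
            + [(500, "censored", 500, False)] * unobservable
            + [(100, "censored", 800, True)] * incomplete
        )
        n_b, n_r = int(c["n_biopsy"]), int(c["n_resection"])
        for i, (time_days, status, potential, miss_kps) in enumerate(groups):
            surgery = ("biopsy" if i < n_b
                       else "resection" if i < n_b + n_r else None)
            rows.append({
                "patient_id": f"{hosp}-{i:04d}",
                "hospital_id": hosp,
                "age": float(c["age_mean"]),
                "kps": None if miss_kps else 80,
                "year": 2012,
                "gender": "male" if i % 2 == 0 else "female",
                "surgery_type": surgery,
                "surgery_date": None,
                "time_days": time_days,
                "status": status,
                "potential_followup_days": potential,
            })
    frame = pd.DataFrame(rows)
    frame["kps"] = frame["kps"].astype("Int64")
    return frame


def year_distribution() -> pd.Series:
    """Overall treatment-year distribution as probabilities."""
    tot = overall_counts()
    levels = [f"year_{y}" for y in range(2011, 2015)]
    counts = tot[levels].astype(float)
    probs = counts / counts.sum()
    probs.index = [int(c.split("_")[1]) for c in levels]
    return probs
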