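"""Risk standardization: patient-specific expected survival at hospital
random effect 0, hospital-level expected event counts and O/E ratios."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .hazard import PosteriorFit
from .registry import observable_at

log = logging.getLogger(__name__)

EVENT_KINDS = ("early_death", "late_survival")


def _covariate_matrix(fit: PosteriorFit, records: pd.DataFrame) -> np.ndarray:
    meta = fit.table_meta
    X = np.column_stack([
        (records["age"].to_numpy(dtype=float) - meta["age_center"]) / 10.0,
        (records["kps"].to_numpy(dtype=float) - meta["kps_center"]) / 10.0,
        (records["year"].to_numpy() == 2012).astype(float),
        (records["year"].to_numpy() == 2013).astype(float),
        (records["year"].to_numpy() == 2014).astype(float),
    ])
    if np.isnan(X).any():
        raise ValidationError("records must be complete-case for standardization")
    return X


def expected_survival_function(fit: PosteriorFit, X: np.ndarray, t: float
                               ) -> np.ndarray:
    """Per-draw survival probability S(t) at hospital random effect 0.

    ``X`` is (n_patients, n_covariates) on the model's scale; returns an
    array of shape (n_patients, n_draws) with
    S(t) = exp(-exp(x'beta) * Lambda0(t)), Lambda0 piecewise-linear in t.
    Times beyond the last break use the open-ended final hazard.
    """
    if t < 0:
        raise ValidationError("t must be nonnegative")
    beta = fit.flat("beta")[:, :np.asarray(X).shape[1]]
    loglam = fit.flat("log_lambda")  # (n_draws, K)
    lam0 = _cumulative_baseline(loglam, fit.breaks, t)  # (n_draws,)
    lp = np.asarray(X) @ beta.T  # (n_patients, n_draws)
    return np.exp(-np.exp(lp) * lam0[None, :])


def _cumulative_baseline(loglam_draws: np.ndarray, breaks, t: float) -> np.ndarray:
    """Lambda0(t) per draw: exact sum of lambda_k times interval overlap."""
    breaks = np.asarray(breaks, dtype=float)
    edges = np.append(breaks, np.inf)
    overlap = np.clip(t - edges[:-1], 0.0, edges[1:] - edges[:-1])
    return np.exp(loglam_draws) @ overlap


@dataclass(frozen=True)
class StandardizedRatio:
    """Observed vs model-expected events for one hospital and one outcome."""

    hospital_id: str
    kind: str  # early_death | late_survival
    observed: int
    expected: float
    flag: str = "within"       # within | outside_95 | outside_99
    direction: str = ""        # better | worse | ""

    @property
    def ratio(self) -> float:
        return self.observed / self.expected

    def __post_init__(self):
        if self.expected <= 0:
            raise ValidationError(
                f"hospital {self.hospital_id!r}: expected events must be positive")
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")


def expected_events(fit: PosteriorFit, records: pd.DataFrame, horizon: int,
                    kind: str, method: str = "median_of_sums") -> pd.DataFrame:
    """Per-hospital observed and expected event counts at a horizon.

    Restricts to patients observable at the horizon.  For ``early_death`` the
    per-patient probability is 1 - S(horizon); for ``late_survival`` it is
    S(horizon).  ``method='median_of_sums'`` (default) reports the posterior
    median of the per-draw hospital sums; ``'plugin'`` sums per-patient
    posterior-median probabilities.
    """
    if kind not in EVENT_KINDS:
        raise ValidationError(f"unknown event kind {kind!r}")
    obs = observable_at(records, horizon)
    empty = [h for h in records["hospital_id"].unique()
             if h not in set(obs["hospital_id"])]
    for h in empty:
        log.info("hospital %s has no observable patients at %d days; omitted",
                 h, horizon)

    X = _covariate_matrix(fit, obs)
    S = expected_survival_function(fit, X, float(horizon))  # (n_pat, n_draws)
    prob = (1.0 - S) if kind == "early_death" else S
    observed_event = obs["dead_by_horizon"].to_numpy() if kind == "early_death" \
        else ~obs["dead_by_horizon"].to_numpy()

    rows = []
    for hosp, idx in obs.groupby("hospital_id").indices.items():
        per_draw = prob[idx].sum(axis=0)
        if method == "median_of_sums":
            expected = float(np.median(per_draw))
        elif method == "plugin":
            expected = float(np.median(prob[idx], axis=1).sum())
        else:
            raise ValidationError(f"unknown method {method!r}")
        rows.append({"hospital_id": hosp,
                     "observed": int(observed_event[idx].sum()),
                     "expected": expected,
                     "n_observable": len(idx)})
    return pd.DataFrame(rows).set_index("hospital_id").sort_index()


def oe_ratios(counts: pd.DataFrame, kind: str) -> list[StandardizedRatio]:
    """Turn an observed/expected count table into StandardizedRatio objects
    (flags initialized to "within"; funnel flagging fills them in)."""
    out = []
    for hosp, row in counts.iterrows():
        if row["expected"] <= 0:
            raise ValidationError(
                f"hospital {hosp!r}: cannot form O/E ratio with expected = 0")
        out.append(StandardizedRatio(hospital_id=str(hosp), kind=kind,
                                     observed=int(row["observed"]),
                                     expected=float(row["expected"])))
    return out


def ratios_frame(ratios: list[StandardizedRatio]) -> pd.DataFrame:
    """Tabulate ratios (hospital, kind, observed, expected, ratio, flags)."""
    return pd.DataFrame([{
        "hospital_id": r.hospital_id, "kind": r.kind, "observed": r.observed,
        "expected": r.expected, "ratio": r.ratio, "flag": r.flag,
        "direction": r.direction,
    } for r in ratios])
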