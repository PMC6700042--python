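"""Univariate logistic regressions of patient outcomes on hospital
characteristics, and derived quantities (boundary volume, relative effects)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .errors import ValidationError

OUTCOME_KINDS = ("early_death", "late_survival")


@dataclass
class LogisticFit:
    """Maximum-likelihood univariate logistic fit.

    ``slope`` is the log odds ratio per unit of the (possibly transformed)
    covariate; ``separated`` flags (quasi-)complete separation, in which case
    the estimates are not finite MLEs.
    """

    covariate: str
    transform: str  # "identity" or "log"
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    p_value: float
    n: int
    n_events: int
    log_likelihood: float
    separated: bool = False

    @property
    def slope_ci(self) -> tuple[float, float]:
        q = 1.959963984540054
        return self.slope - q * self.slope_se, self.slope + q * self.slope_se


def patient_level_logistic(data: pd.DataFrame, outcome: str | None = None,
                           covariate: str = "x",
                           transform: str = "identity") -> LogisticFit:
    """Fit outcome ~ covariate by maximum likelihood.

    Accepts either patient-level rows (binary ``outcome`` column) or a
    binomially aggregated table with ``events`` and ``n`` columns; both
    representations give identical estimates and log-likelihood up to the
    fixed combinatorial constant, which is excluded.
    """
    aggregated = {"events", "n"}.issubset(data.columns)
    x = data[covariate].to_numpy(dtype=float)
    if transform == "log":
        if np.any(x <= 0):
            raise ValidationError(f"log transform needs positive {covariate!r}")
        x = np.log(x)
    elif transform != "identity":
        raise ValidationError(f"unknown transform {transform!r}")
    if np.ptp(x) == 0:
        raise ValidationError(f"covariate {covariate!r} has zero variance")

    if aggregated:
        events = data["events"].to_numpy(dtype=float)
        n = data["n"].to_numpy(dtype=float)
        if np.any(events > n):
            raise ValidationError("events exceed n in aggregated input")
        endog = np.column_stack([events, n - events])
        n_pat, n_ev = int(n.sum()), int(events.sum())
    else:
        if outcome is None:
            raise ValidationError("patient-level input needs an outcome column name")
        endog = data[outcome].to_numpy(dtype=float)
        n_pat, n_ev = len(endog), int(endog.sum())

    design = sm.add_constant(x)
    fit = sm.GLM(endog, design, family=sm.families.Binomial()).fit(
        tol=1e-12, maxiter=200)
    mu = fit.fittedvalues
    separated = bool(np.abs(fit.params).max() > 50
                     or np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10))
    return LogisticFit(
        covariate=covariate, transform=transform,
        intercept=float(fit.params[0]), slope=float(fit.params[1]),
        intercept_se=float(fit.bse[0]), slope_se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]), n=n_pat, n_events=n_ev,
        log_likelihood=float(fit.llf), separated=separated)


def hospital_factor_logistic(summary: pd.DataFrame, outcome_kind: str,
                             covariate: str,
                             volume_basis: str = "complete") -> LogisticFit:
    """Univariate logistic fit of an outcome on a hospital characteristic.

    ``summary`` is a per-hospital table (see ``registry.summarize_hospitals``
    or the built-in reference counts) with the observed event and observable
    counts.  ``covariate`` is one of ``log_volume``, ``academic``,
    ``biopsy_fraction``; volume is the number of patients over the registry
    period, on the ``complete``-case or ``total`` registration basis.
    """
    if outcome_kind not in OUTCOME_KINDS:
        raise ValidationError(f"unknown outcome kind {outcome_kind!r}")
    df = summary.drop(index="overall", errors="ignore").copy()
    if outcome_kind == "early_death":
        events, n = df["deaths_30d"], df["observable_30d"]
    else:
        events, n = df["survivors_2y"], df["observable_2y"]

    if covariate == "log_volume":
        if volume_basis == "complete":
            vol = df["n_complete"]
        elif volume_basis == "total":
            vol = df["n_total"]
        else:
            raise ValidationError(f"unknown volume basis {volume_basis!r}")
        data = pd.DataFrame({"events": events, "n": n, "volume": vol})
        return patient_level_logistic(data, covariate="volume", transform="log")
    if covariate == "academic":
        data = pd.DataFrame({"events": events, "n": n,
                             "academic": df["academic"].astype(float)})
        return patient_level_logistic(data, covariate="academic")
    if covariate in ("biopsy_fraction", "biopsy_pct"):
        frac = df.get("biopsy_fraction")
        if frac is None:
            frac = df["n_biopsy"] / (df["n_biopsy"] + df["n_resection"])
        data = pd.DataFrame({"events": events, "n": n, "biopsy_fraction": frac})
        return patient_level_logistic(data, covariate="biopsy_fraction")
    raise ValidationError(f"unknown covariate {covariate!r}")


def boundary_volume(fit: LogisticFit, reference_rate: float) -> float:
    """Volume at which the fitted logistic curve crosses a reference rate.

    Solves intercept + slope * log(v) = logit(reference_rate); only defined
    for log-volume fits with a nonzero slope.
    """
    if fit.transform != "log":
        raise ValidationError("boundary volume needs a log-transformed covariate")
    if fit.slope == 0:
        raise ValidationError("slope is zero: the curve never crosses the reference")
    if not 0 < reference_rate < 1:
        raise ValidationError("reference rate must be in (0, 1)")
    return float(np.exp((logit(reference_rate) - fit.intercept) / fit.slope))


def relative_effect(slope: float, volume_increase: float,
                    approximate: bool = False) -> float:
    """Relative change in event odds for a proportional volume increase.

    Exact convention: exp(slope * log(1 + delta)) - 1.  The small-delta
    approximation slope * delta is also in circulation; request it with
    ``approximate=True``.
    """
    if approximate:
        return slope * volume_increase
    return float(np.exp(slope * np.log1p(volume_increase)) - 1.0)


def predicted_rate(fit: LogisticFit, value: float) -> float:
    """Event probability at a covariate value on its original scale."""
    x = np.log(value) if fit.transform == "log" else value
    return float(expit(fit.intercept + fit.slope * x))
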