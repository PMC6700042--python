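"""Synthetic multi-hospital registry generator.

Event times are drawn from a piecewise-exponential proportional-hazards law

    h(t | x, u) = lambda_k * exp(x'beta + u_hospital),   t in interval k,

with administrative censoring at a lookup date, so the generator inverts the
exact model fitted downstream and every parameter is recoverable ground truth.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import datasets
from .errors import ValidationError

#: default interval breaks (days); must contain the 30- and 730-day horizons
DEFAULT_BREAKS = (0.0, 30.0, 90.0, 180.0, 270.0, 365.0, 545.0, 730.0, 1095.0, 1460.0)

DAYS_PER_MONTH = 30.44


@dataclass
class GeneratorConfig:
    """True parameters and cohort structure for registry simulation.

    Defaults mirror the built-in 14-hospital reference cohort: volumes,
    per-hospital age moments, the overall KPS ladder and treatment-year
    distributions, and biopsy fractions spanning 0.16-0.73.  The default
    regression coefficients are plausible published magnitudes (log 1.54 per
    decade of age, log 0.77 per 10 KPS points, year effects log 0.94 / 0.80 /
    0.78) used as simulation defaults, not as ground-truth claims.
    """

    hospital_ids: tuple[str, ...] = tuple(datasets.HOSPITALS)
    volumes: tuple[int, ...] = tuple(datasets._COLUMNS["n_total"])
    age_means: tuple[float, ...] | None = None      # default: overall mean everywhere
    age_sds: tuple[float, ...] | None = None
    age_mean: float = datasets.OVERALL_AGE_MEAN
    age_sd: float = datasets.OVERALL_AGE_SD
    age_min: float = 18.0
    kps_levels: tuple[int, ...] = tuple(range(10, 110, 10))
    kps_probs: tuple[float, ...] | None = None      # default: reference distribution
    year_probs: tuple[float, ...] | None = None     # over 2011..2014
    biopsy_fractions: tuple[float, ...] | None = None
    beta_age: float = float(np.log(1.54))           # per +10 years, centered at 61.4
    beta_kps: float = float(np.log(0.77))           # per +10 KPS points, centered at 80
    beta_year: tuple[float, float, float] = (
        float(np.log(0.94)), float(np.log(0.80)), float(np.log(0.78)))
    sigma_u: float = 0.0
    frailties: tuple[float, ...] | None = None      # explicit u_h overrides sigma_u draw
    breaks: tuple[float, ...] = DEFAULT_BREAKS
    baseline_hazards: tuple[float, ...] | None = None  # per-day; default: calibrated
    target_median_days: float = 10.2 * DAYS_PER_MONTH
    age_center: float = 61.4
    kps_center: float = 80.0
    accrual_start: str = datasets.ACCRUAL_START
    accrual_end: str = datasets.ACCRUAL_END
    lookup_date: str = datasets.LOOKUP_DATE
    missing_age_rate: float = 0.0
    missing_kps_rate: float = 0.0
    missing_gender_rate: float = 0.0

    def __post_init__(self):
        n = len(self.hospital_ids)
        if len(self.volumes) != n:
            raise ValidationError("volumes must match hospital_ids in length")
        if self.kps_probs is None:
            probs = datasets.kps_distribution()
            self.kps_levels = tuple(int(v) for v in probs.index)
            self.kps_probs = tuple(float(p) for p in probs.to_numpy())
        if self.year_probs is None:
            self.year_probs = tuple(float(p) for p in datasets.year_distribution().to_numpy())
        if self.biopsy_fractions is None:
            counts = datasets.hospital_counts()
            frac = (counts["n_biopsy"] / (counts["n_biopsy"] + counts["n_resection"]))
            default = float(frac.mean())
            self.biopsy_fractions = tuple(
                float(frac.get(h, default)) for h in self.hospital_ids)
        for name, probs in (("kps_probs", self.kps_probs), ("year_probs", self.year_probs)):
            if abs(sum(probs) - 1.0) > 1e-8 or min(probs) < 0:
                raise ValidationError(f"{name} must be a probability vector")
        if self.sigma_u < 0:
            raise ValidationError("sigma_u must be nonnegative")
        if list(self.breaks) != sorted(set(self.breaks)) or self.breaks[0] != 0:
            raise ValidationError("breaks must be strictly increasing from 0")
        if self.baseline_hazards is not None:
            if len(self.baseline_hazards) != len(self.breaks):
                raise ValidationError("need one hazard per interval (breaks are left "
                                      "edges; the last interval is open-ended)")
            if min(self.baseline_hazards) <= 0:
                raise ValidationError("baseline hazards must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def cumulative_hazard(t, breaks, hazards):
    """Exact piecewise-linear cumulative baseline hazard at times ``t``.

    ``breaks`` are interval left edges starting at 0; ``hazards[k]`` applies on
    ``[breaks[k], breaks[k+1])`` and the final hazard extends to infinity.
    """
    t = np.asarray(t, dtype=float)
    breaks = np.asarray(breaks, dtype=float)
    hazards = np.asarray(hazards, dtype=float)
    edges = np.append(breaks, np.inf)
    # overlap of [0, t] with each interval
    overlap = np.clip(t[..., None] - edges[:-1], 0.0, edges[1:] - edges[:-1])
    return overlap @ hazards


def _invert_cumulative(target, breaks, hazards):
    """Solve Lambda0(t) = target for t (vectorized)."""
    breaks = np.asarray(breaks, dtype=float)
    hazards = np.asarray(hazards, dtype=float)
    widths = np.diff(breaks)
    cum = np.concatenate([[0.0], np.cumsum(widths * hazards[:-1])])
    k = np.searchsorted(cum, target, side="right") - 1
    k = np.clip(k, 0, len(breaks) - 1)
    return breaks[k] + (target - cum[k]) / hazards[k]


def sample_piecewise_exponential(breaks, hazards, lp, rng, size=None):
    """Draw event times with survival ``exp(-exp(lp) * Lambda0(t))``.

    ``lp`` may be scalar or an array of per-subject log-linear predictors;
    ``size`` is only needed for scalar ``lp``.
    """
    breaks = np.asarray(breaks, dtype=float)
    hazards = np.asarray(hazards, dtype=float)
    if breaks[0] != 0 or np.any(np.diff(breaks) <= 0):
        raise ValidationError("breaks must be strictly increasing from 0")
    if len(hazards) != len(breaks):
        raise ValidationError("need one hazard per interval")
    if np.any(hazards <= 0):
        raise ValidationError("hazards must be positive")
    lp = np.asarray(lp, dtype=float)
    if lp.ndim == 0:
        lp = np.full(size if size is not None else 1, float(lp))
    exp_unit = rng.exponential(size=lp.shape)
    target = exp_unit / np.exp(lp)
    return _invert_cumulative(target, breaks, hazards)


def population_survival(t, config: GeneratorConfig, hazards, n_mc=20000, seed=12345):
    """Marginal survival S(t) averaged over covariates and frailty.

    Uses a fixed internal covariate sample so the result is a deterministic,
    quadrature-free function of the hazards (given the config).
    """
    rng = np.random.default_rng(seed)
    lp = _linear_predictors(_draw_covariates(config, n_mc, rng), config)
    if config.sigma_u > 0:
        lp = lp + rng.normal(0.0, config.sigma_u, size=lp.shape)
    lam = cumulative_hazard(np.asarray(t, dtype=float), config.breaks, hazards)
    out = np.mean(np.exp(-np.exp(lp)[None, ...] * np.atleast_1d(lam)[..., None]), axis=-1)
    return float(out[0]) if np.ndim(t) == 0 else out


def calibrate_baseline(config: GeneratorConfig, shape=None, n_mc=20000) -> tuple[float, ...]:
    """Scale a baseline-hazard shape so the marginal median survival matches
    ``config.target_median_days`` (numeric root-finding on the closed-form
    mixture survival)."""
    if shape is None:
        shape = np.ones(len(config.breaks))
    shape = np.asarray(shape, dtype=float)

    def median_gap(log_c):
        s = population_survival(config.target_median_days, config,
                                np.exp(log_c) * shape, n_mc=n_mc)
        return float(s - 0.5)

    log_c = brentq(median_gap, -12.0, 0.0, xtol=1e-10)
    return tuple(float(v) for v in np.exp(log_c) * shape)


def _draw_covariates(config: GeneratorConfig, n, rng, hospital_index=None):
    """Sample age/KPS/year for n patients; returns a dict of arrays."""
    if hospital_index is None:
        means = np.full(n, config.age_mean)
        sds = np.full(n, config.age_sd)
    else:
        am = config.age_means or tuple([config.age_mean] * len(config.hospital_ids))
        asd = config.age_sds or tuple([config.age_sd] * len(config.hospital_ids))
        means = np.asarray(am)[hospital_index]
        sds = np.asarray(asd)[hospital_index]
    age = rng.normal(means, sds)
    while True:  # truncate at adult age by redrawing
        low = age < config.age_min
        if not low.any():
            break
        age[low] = rng.normal(means[low], sds[low])
    kps = rng.choice(config.kps_levels, size=n, p=config.kps_probs)
    year = rng.choice(np.arange(2011, 2015), size=n, p=config.year_probs)
    return {"age": age, "kps": kps.astype(int), "year": year.astype(int)}


def _linear_predictors(cov, config: GeneratorConfig):
    lp = (config.beta_age * (cov["age"] - config.age_center) / 10.0
          + config.beta_kps * (cov["kps"] - config.kps_center) / 10.0)
    for j, yr in enumerate((2012, 2013, 2014)):
        lp = lp + config.beta_year[j] * (cov["year"] == yr)
    return lp


def generate_registry(config: GeneratorConfig | None = None, seed: int = 0
                      ) -> tuple[pd.DataFrame, dict]:
    """Simulate a registry; returns ``(records, truth)``.

    ``truth`` stores the config, the calibrated baseline hazards, the sampled
    per-hospital frailties and the seed, so downstream recovery tests have
    full ground truth.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)

    hazards = config.baseline_hazards
    if hazards is None:
        hazards = calibrate_baseline(config)

    n_h = len(config.hospital_ids)
    if config.frailties is not None:
        if len(config.frailties) != n_h:
            raise ValidationError("frailties must match hospital_ids in length")
        u = np.asarray(config.frailties, dtype=float)
    elif config.sigma_u > 0:
        u = rng.normal(0.0, config.sigma_u, size=n_h)
    else:
        u = np.zeros(n_h)

    n = int(np.sum(config.volumes))
    hosp_idx = np.repeat(np.arange(n_h), config.volumes)
    cov = _draw_covariates(config, n, rng, hospital_index=hosp_idx)

    # surgery date: uniform within the sampled treatment year, clipped to accrual
    accrual_start = dt.date.fromisoformat(config.accrual_start)
    accrual_end = dt.date.fromisoformat(config.accrual_end)
    lookup = dt.date.fromisoformat(config.lookup_date)
    surgery_dates = []
    for yr in cov["year"]:
        y0 = max(dt.date(int(yr), 1, 1), accrual_start)
        y1 = min(dt.date(int(yr), 12, 31), accrual_end)
        offset = rng.integers(0, (y1 - y0).days + 1)
        surgery_dates.append(y0 + dt.timedelta(days=int(offset)))
    potential = np.array([(lookup - d).days for d in surgery_dates])

    lp = _linear_predictors(cov, config) + u[hosp_idx]
    event_time = sample_piecewise_exponential(config.breaks, hazards, lp, rng)
    event_day = np.ceil(event_time).astype(int)  # survival analyzed in whole days
    dead = event_day <= potential
    time_days = np.where(dead, event_day, potential)

    gender = rng.choice(["male", "female"], size=n, p=[0.62, 0.38])
    biopsy_p = np.asarray(config.biopsy_fractions)[hosp_idx]
    surgery_type = np.where(rng.random(n) < biopsy_p, "biopsy", "resection")

    records = pd.DataFrame({
        "patient_id": [f"{config.hospital_ids[h]}-{i:05d}"
                       for i, h in enumerate(hosp_idx)],
        "hospital_id": [config.hospital_ids[h] for h in hosp_idx],
        "age": np.round(cov["age"], 1),
        "kps": cov["kps"],
        "year": cov["year"],
        "gender": gender,
        "surgery_type": surgery_type,
        "surgery_date": [d.isoformat() for d in surgery_dates],
        "time_days": time_days.astype(int),
        "status": np.where(dead, "dead", "censored"),
        "potential_followup_days": potential.astype(int),
    })

    for fld, rate in (("age", config.missing_age_rate), ("kps", config.missing_kps_rate),
                      ("gender", config.missing_gender_rate)):
        if rate > 0:
            mask = rng.random(n) < rate
            records.loc[mask, fld] = np.nan if fld == "age" else None
    if config.missing_kps_rate > 0:
        records["kps"] = records["kps"].astype("Int64")

    truth = {
        "seed": int(seed),
        "config": config.to_dict(),
        "baseline_hazards": [float(v) for v in hazards],
        "frailties": {h: float(v) for h, v in zip(config.hospital_ids, u)},
        "beta": {"age": config.beta_age, "kps": config.beta_kps,
                 "year_2012": config.beta_year[0], "year_2013": config.beta_year[1],
                 "year_2014": config.beta_year[2]},
        "sigma_u": float(config.sigma_u),
    }
    return records, truth


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2) + "\n")
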