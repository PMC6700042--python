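"""Piecewise-exponential proportional-hazards modelling.

The survival model is fitted through its log-Poisson counting-process
representation: each patient contributes one row per interval at risk, and

    events_k ~ Poisson(exposure * lambda_k * exp(x'beta + u_hospital))

with hospital random effects u ~ Normal(0, sigma_u^2).  The hierarchical fit
uses the package HMC sampler with vague priors; the fixed-effects variant
(used for hospital-characteristic hazard ratios) is a plain Poisson GLM and
must agree with a Cox partial-likelihood fit on fine breaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mcmc
from .diagnostics import diagnostics_table
from .errors import ConvergenceError, ValidationError
from .mcmc import SamplerConfig
from .simulate import DEFAULT_BREAKS

log = logging.getLogger(__name__)

PATIENT_COVARIATES = ("age_c", "kps_c", "year_2012", "year_2013", "year_2014")

#: minimal exposure assigned to zero-survival-time records
ZERO_TIME_EXPOSURE = 0.5


@dataclass
class Priors:
    """Vague priors: Normal(0, sd) on coefficients and interval log-hazards,
    half-Cauchy(scale) on the random-effect sd."""
    beta_sd: float = 10.0
    log_lambda_sd: float = 10.0
    sigma_u_scale: float = 2.5


@dataclass
class CountingProcessTable:
    """Patient-interval expansion of a registry.

    ``frame`` has one row per (patient, interval at risk) with exposure days,
    a 0/1 event indicator, scaled covariates and hospital index; per patient
    the exposures sum to time_days (0.5 for zero-time records) and at most the
    last row carries the event.
    """

    frame: pd.DataFrame
    breaks: tuple[float, ...]
    hospital_ids: tuple[str, ...]
    covariates: tuple[str, ...] = PATIENT_COVARIATES
    age_center: float = 61.4
    kps_center: float = 80.0
    n_zero_time: int = 0

    @property
    def n_intervals(self) -> int:
        return len(self.breaks)

    @property
    def n_hospitals(self) -> int:
        return len(self.hospital_ids)


def build_counting_process(records: pd.DataFrame,
                           breaks=DEFAULT_BREAKS,
                           age_center: float = 61.4,
                           kps_center: float = 80.0,
                           extra_covariates: pd.DataFrame | None = None
                           ) -> CountingProcessTable:
    """Expand registry records into (patient, interval) exposure rows.

    ``breaks`` are interval left edges starting at 0 and must contain the 30-
    and 730-day horizons so that horizon probabilities fall on hazard steps.
    ``extra_covariates`` (indexed by hospital_id) joins hospital-level columns
    onto each row, for the fixed-effects variant.
    """
    breaks = tuple(float(b) for b in breaks)
    if list(breaks) != sorted(set(breaks)) or breaks[0] != 0:
        raise ValidationError("breaks must be strictly increasing from 0")
    if 30.0 not in breaks or 730.0 not in breaks:
        raise ValidationError("breaks must contain the 30- and 730-day horizons")

    t = records["time_days"].to_numpy(dtype=float)
    dead = (records["status"] == "dead").to_numpy()
    n_zero = int((t == 0).sum())
    if n_zero:
        log.info("assigning %.1f-day exposure to %d zero-time records",
                 ZERO_TIME_EXPOSURE, n_zero)
        t = np.where(t == 0, ZERO_TIME_EXPOSURE, t)

    edges = np.asarray(breaks + (np.inf,))
    K = len(breaks)
    # exposure of each patient in each interval: overlap of [0, t] with it
    exposure = np.clip(t[:, None] - edges[:-1], 0.0, edges[1:] - edges[:-1])
    at_risk = exposure > 0
    last_k = np.maximum(at_risk.cumsum(axis=1).argmax(axis=1), 0)

    pat_idx, k_idx = np.nonzero(at_risk)
    event = (dead[pat_idx] & (k_idx == last_k[pat_idx])).astype(int)

    hospitals = tuple(sorted(records["hospital_id"].unique()))
    hosp_map = {h: i for i, h in enumerate(hospitals)}

    frame = pd.DataFrame({
        "patient_id": records["patient_id"].to_numpy()[pat_idx],
        "hospital_id": records["hospital_id"].to_numpy()[pat_idx],
        "hospital_index": records["hospital_id"].map(hosp_map).to_numpy()[pat_idx],
        "interval": k_idx,
        "exposure": exposure[pat_idx, k_idx],
        "event": event,
        "age_c": (records["age"].to_numpy(dtype=float)[pat_idx] - age_center) / 10.0,
        "kps_c": (records["kps"].to_numpy(dtype=float)[pat_idx] - kps_center) / 10.0,
    })
    years = records["year"].to_numpy()[pat_idx]
    for yr in (2012, 2013, 2014):
        frame[f"year_{yr}"] = (years == yr).astype(float)

    covs = PATIENT_COVARIATES
    if extra_covariates is not None:
        joined = frame.join(extra_covariates, on="hospital_id")
        for c in extra_covariates.columns:
            frame[c] = joined[c].to_numpy(dtype=float)
        covs = covs + tuple(extra_covariates.columns)

    if frame[list(covs)].isna().any().any():
        raise ValidationError("counting process requires complete covariates; "
                              "run complete_case_filter first")
    return CountingProcessTable(frame=frame, breaks=breaks, hospital_ids=hospitals,
                                covariates=covs, age_center=age_center,
                                kps_center=kps_center, n_zero_time=n_zero)


@dataclass
class PosteriorFit:
    """MCMC draws and summaries for the hierarchical fit.

    ``draws`` maps parameter block -> array with leading (chains, draws)
    axes.  ``summary()`` refuses to hand out numbers when diagnostics failed,
    unless called with ``force=True``.
    """

    draws: dict
    table_meta: dict
    priors: Priors
    sampler: SamplerConfig
    seed: int
    diagnostics: pd.DataFrame
    converged: bool
    rhat_threshold: float = 1.01

    @property
    def covariates(self):
        return tuple(self.table_meta["covariates"])

    @property
    def breaks(self):
        return tuple(self.table_meta["breaks"])

    @property
    def hospital_ids(self):
        return tuple(self.table_meta["hospital_ids"])

    def flat(self, name: str) -> np.ndarray:
        """Pooled draws with chains flattened: (chains*draws, ...)."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:]) if d.ndim > 2 else d.reshape(-1)

    def summary(self, force: bool = False) -> pd.DataFrame:
        """Posterior medians and central 95% credibility intervals."""
        if not self.converged and not force:
            raise ConvergenceError(
                "diagnostics failed (max R-hat "
                f"{self.diagnostics['rhat'].max():.3f} > {self.rhat_threshold}); "
                "inspect .diagnostics or call summary(force=True)")
        rows = []
        for name, labels in self._labels():
            x = self.flat(name)
            x = x[:, None] if x.ndim == 1 else x
            for j, label in enumerate(labels):
                med, lo, hi = np.percentile(x[:, j], [50, 2.5, 97.5])
                rows.append({"parameter": label, "median": med,
                             "q2.5": lo, "q97.5": hi})
        return pd.DataFrame(rows).set_index("parameter")

    def _labels(self):
        yield "beta", list(self.covariates)
        yield "log_lambda", [f"log_lambda[{k}]" for k in range(len(self.breaks))]
        yield "u", [f"u[{h}]" for h in self.hospital_ids]
        yield "sigma_u", ["sigma_u"]

    def hazard_ratios(self, force: bool = False) -> pd.DataFrame:
        """HR table for the regression coefficients (posterior medians, 95%
        credibility intervals and a two-sided posterior tail probability)."""
        if not self.converged and not force:
            raise ConvergenceError("diagnostics failed; call with force=True to override")
        beta = self.flat("beta")
        rows = []
        for j, name in enumerate(self.covariates):
            b = beta[:, j]
            med, lo, hi = np.exp(np.percentile(b, [50, 2.5, 97.5]))
            tail = min((b > 0).mean(), (b < 0).mean())
            rows.append({"covariate": name, "hr": med, "lo95": lo, "hi95": hi,
                         "p": min(1.0, 2 * tail)})
        return pd.DataFrame(rows).set_index("covariate")


def _model_arrays(table: CountingProcessTable):
    f = table.frame
    X = f[list(table.covariates)].to_numpy(dtype=float)
    y = f["event"].to_numpy(dtype=float)
    log_e = np.log(f["exposure"].to_numpy(dtype=float))
    k = f["interval"].to_numpy()
    h = f["hospital_index"].to_numpy()
    return X, y, log_e, k, h


def _make_logp(table: CountingProcessTable, priors: Priors):
    """Log joint density and gradient in the unconstrained parametrization
    theta = (beta, log_lambda, z, log_sigma) with u = sigma * z (non-centered)."""
    X, y, log_e, k, h = _model_arrays(table)
    p = X.shape[1]
    K = table.n_intervals
    H = table.n_hospitals
    gamma = priors.sigma_u_scale

    def logp_and_grad(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            return _logp_impl(theta)

    def _logp_impl(theta):
        beta = theta[:p]
        loglam = theta[p:p + K]
        z = theta[p + K:p + K + H]
        s = min(theta[-1], 300.0)
        sigma = np.exp(s)

        eta = X @ beta + loglam[k] + sigma * z[h] + log_e
        mu = np.exp(np.clip(eta, -700, 700))
        resid = y - mu

        lp = float(np.sum(y * eta - mu))
        lp += -0.5 * np.sum(beta ** 2) / priors.beta_sd ** 2
        lp += -0.5 * np.sum(loglam ** 2) / priors.log_lambda_sd ** 2
        lp += -0.5 * np.sum(z ** 2)
        # half-Cauchy(gamma) on sigma plus log|d sigma/d s| Jacobian
        lp += -np.log1p((sigma / gamma) ** 2) + s

        g_beta = X.T @ resid - beta / priors.beta_sd ** 2
        g_loglam = np.bincount(k, weights=resid, minlength=K) \
            - loglam / priors.log_lambda_sd ** 2
        g_z = sigma * np.bincount(h, weights=resid, minlength=H) - z
        g_s = sigma * float(z[h] @ resid) \
            - 2.0 * sigma ** 2 / (gamma ** 2 + sigma ** 2) + 1.0
        return lp, np.concatenate([g_beta, g_loglam, g_z, [g_s]])

    return logp_and_grad, (p, K, H)


def _map_start(table: CountingProcessTable, priors: Priors):
    """Crude mode finding for chain initialization: Poisson GLM on
    (beta, log_lambda) with z = 0, sigma fixed small."""
    from scipy.optimize import minimize

    logp_and_grad, (p, K, H) = _make_logp(table, priors)
    s0 = np.log(0.3)

    def neg(theta_sub):
        theta = np.concatenate([theta_sub, np.zeros(H), [s0]])
        lp, g = logp_and_grad(theta)
        return -lp, -g[:p + K]

    x0 = np.zeros(p + K)
    x0[p:] = np.log(max(table.frame["event"].sum(), 1.0)
                    / table.frame["exposure"].sum())
    res = minimize(neg, x0, jac=True, method="L-BFGS-B")
    return np.concatenate([res.x, np.zeros(H), [s0]])


def fit_hierarchical(table: CountingProcessTable,
                     priors: Priors | None = None,
                     sampler: SamplerConfig | None = None,
                     seed: int = 0,
                     rhat_threshold: float = 1.01) -> PosteriorFit:
    """Sample the hierarchical log-Poisson model.

    Non-convergence does not raise: the returned fit carries ``converged=False``
    and gates its ``summary()``/``hazard_ratios()`` accessors instead.
    """
    priors = priors or Priors()
    sampler = sampler or SamplerConfig()
    if table.n_hospitals < 2:
        raise ValidationError("hierarchical fit needs >= 2 hospitals "
                              "(random effect unidentifiable)")
    events = table.frame.groupby("patient_id")["event"].sum()
    if (events > 1).any():
        raise ValidationError("counting table has patients with > 1 event row")

    logp_and_grad, (p, K, H) = _make_logp(table, priors)
    x0 = _map_start(table, priors)
    res = mcmc.sample(logp_and_grad, x0, sampler, seed)
    theta = res["draws"]  # (chains, draws, dim)

    beta = theta[..., :p]
    loglam = theta[..., p:p + K]
    z = theta[..., p + K:p + K + H]
    sigma = np.exp(theta[..., -1])
    u = sigma[..., None] * z
    draws = {"beta": beta, "log_lambda": loglam, "u": u, "sigma_u": sigma}

    labels = (list(table.covariates)
              + [f"log_lambda[{k}]" for k in range(K)]
              + [f"u[{h}]" for h in table.hospital_ids] + ["sigma_u"])
    chains_matrix = np.concatenate(
        [beta, loglam, u, sigma[..., None]], axis=-1)
    diag = diagnostics_table(chains_matrix, labels, rhat_threshold=rhat_threshold)
    converged = bool(diag["pass"].all())
    if not converged:
        log.warning("convergence diagnostics failed: max R-hat %.3f",
                    diag["rhat"].max())

    meta = {"covariates": table.covariates, "breaks": table.breaks,
            "hospital_ids": table.hospital_ids,
            "age_center": table.age_center, "kps_center": table.kps_center}
    return PosteriorFit(draws=draws, table_meta=meta, priors=priors,
                        sampler=sampler, seed=seed, diagnostics=diag,
                        converged=converged, rhat_threshold=rhat_threshold)


def _check_collinearity(X: np.ndarray, names) -> None:
    constant = [n for n, col in zip(names, X.T) if np.ptp(col) == 0]
    if constant:
        raise ValidationError(f"constant covariate(s): {constant}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [(names[i], names[j])
                 for i in range(len(names)) for j in range(i + 1, len(names))
                 if abs(corr[i, j]) > 0.999999]
        raise ValidationError(f"collinear covariates: {pairs or names}")


def fit_fixed(records: pd.DataFrame,
              hospital_covariates: pd.DataFrame | None = None,
              breaks=DEFAULT_BREAKS,
              age_center: float = 61.4,
              kps_center: float = 80.0) -> pd.DataFrame:
    """Fixed-effects proportional-hazards fit (no hospital random effect).

    ``hospital_covariates`` is indexed by hospital_id with columns such as
    ``log_volume``, ``academic``, ``biopsy_fraction`` (a 0-1 fraction, so its
    HR reads per +100 percentage points).  Returns a HR table with Wald 95%
    intervals and p-values from the Poisson GLM maximum likelihood fit.
    """
    import statsmodels.api as sm

    table = build_counting_process(records, breaks=breaks, age_center=age_center,
                                   kps_center=kps_center,
                                   extra_covariates=hospital_covariates)
    f = table.frame
    X = f[list(table.covariates)].to_numpy(dtype=float)
    _check_collinearity(X, list(table.covariates))
    intervals = pd.get_dummies(f["interval"], prefix="interval", dtype=float)
    design = pd.concat(
        [pd.DataFrame(X, columns=list(table.covariates), index=f.index), intervals],
        axis=1)
    model = sm.GLM(f["event"].to_numpy(), design.to_numpy(),
                   family=sm.families.Poisson(),
                   offset=np.log(f["exposure"].to_numpy()))
    fit = model.fit()
    q = 1.959963984540054
    rows = []
    for j, name in enumerate(table.covariates):
        b, se = fit.params[j], fit.bse[j]
        rows.append({"covariate": name, "hr": np.exp(b),
                     "lo95": np.exp(b - q * se), "hi95": np.exp(b + q * se),
                     "p": fit.pvalues[j], "coef": b, "se": se})
    return pd.DataFrame(rows).set_index("covariate")
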