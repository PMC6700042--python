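import numpy as np
import pandas as pd
import pytest

from hospvar import ValidationError
from hospvar.hazard import PATIENT_COVARIATES, PosteriorFit, Priors
from hospvar.mcmc import SamplerConfig
from hospvar.standardize import (StandardizedRatio, _cumulative_baseline,
                                 expected_events, expected_survival_function,
                                 oe_ratios, ratios_frame)

from conftest import manual_records


def make_fit(log_lambda_draws, beta_draws=None, breaks=None,
             hospitals=("a", "b")):
    """Handcrafted PosteriorFit with fully known draws (1 chain)."""
    loglam = np.asarray(log_lambda_draws, float)[None, ...]
    n_draws = loglam.shape[1]
    if breaks is None:  # one break per hazard column
        breaks = (0.0, 30.0, 730.0, 1095.0, 1460.0, 2000.0)[:loglam.shape[2]]
    if beta_draws is None:
        beta_draws = np.zeros((n_draws, len(PATIENT_COVARIATES)))
    beta = np.asarray(beta_draws, float)[None, ...]
    u = np.zeros((1, n_draws, len(hospitals)))
    sigma = np.zeros((1, n_draws))
    meta = {"covariates": PATIENT_COVARIATES, "breaks": tuple(breaks),
            "hospital_ids": tuple(hospitals), "age_center": 61.4,
            "kps_center": 80.0}
    diag = pd.DataFrame({"rhat": [1.0], "ess_bulk": [n_draws],
                         "ess_tail": [n_draws], "pass": [True]},
                        index=["dummy"])
    return PosteriorFit(draws={"beta": beta, "log_lambda": loglam, "u": u,
                               "sigma_u": sigma},
                        table_meta=meta, priors=Priors(),
                        sampler=SamplerConfig(), seed=0, diagnostics=diag,
                        converged=True)


class TestExpectedSurvival:
    def test_t0_is_one_for_every_draw(self):
        fit = make_fit(np.log([[0.01, 0.002], [0.02, 0.001]]))
        S = expected_survival_function(fit, np.zeros((3, 5)), 0.0)
        assert np.all(S == 1.0)

    def test_single_interval_closed_form(self):
        lam = 0.013
        fit = make_fit(np.log([[lam, lam]]))  # flat hazard == one interval
        S = expected_survival_function(fit, np.zeros((1, 5)), 30.0)
        assert S[0, 0] == pytest.approx(np.exp(-30 * lam), rel=1e-12)

    def test_machine_precision_vs_exact_sum(self):
        # -log S(t) equals the exact overlap sum for random breaks/hazards
        rng = np.random.default_rng(4)
        for _ in range(20):
            k = int(rng.integers(1, 7))
            breaks = tuple(np.concatenate(
                [[0.0], np.sort(rng.uniform(1, 900, k - 1))]))
            loglam = rng.normal(-5, 1, size=(1, k))
            t = float(rng.uniform(0, 1200))
            edges = list(breaks) + [np.inf]
            exact = sum(np.exp(loglam[0, i])
                        * max(0.0, min(t, edges[i + 1]) - edges[i])
                        for i in range(k))
            got = _cumulative_baseline(loglam, breaks, t)[0]
            assert got == pytest.approx(exact, rel=1e-12)

    def test_monotone_in_t_per_draw(self):
        rng = np.random.default_rng(5)
        loglam = rng.normal(-5, 1, size=(8, 4))
        fit = make_fit(loglam, breaks=(0.0, 30.0, 200.0, 730.0))
        X = rng.normal(size=(6, 5))
        prev = expected_survival_function(fit, X, 0.0)
        for t in (10.0, 30.0, 100.0, 729.0, 730.0, 2000.0):
            cur = expected_survival_function(fit, X, t)
            assert np.all(cur <= prev + 1e-15)
            prev = cur

    def test_covariates_shift_survival(self):
        fit = make_fit(np.log([[0.01, 0.01]]))
        X_hi = np.array([[1.0, 0.0, 0.0, 0.0, 0.0]])
        beta = np.array([[0.5, 0.0, 0.0, 0.0, 0.0]])
        fit2 = make_fit(np.log([[0.01, 0.01]]), beta_draws=beta)
        s_base = expected_survival_function(fit2, np.zeros((1, 5)), 100.0)
        s_hi = expected_survival_function(fit2, X_hi, 100.0)
        assert s_hi[0, 0] < s_base[0, 0]


class TestExpectedEvents:
    def _records(self, n_per_hospital):
        rows = []
        for hosp, n in n_per_hospital.items():
            rows += [(hosp, 61.4, 80, 2011, 800, "censored", 800)] * n
        return manual_records(rows)

    def test_identical_patients_linear(self):
        lam = 0.005
        fit = make_fit(np.log([[lam, lam]]))
        records = self._records({"a": 4, "b": 9})
        counts = expected_events(fit, records, 30, "early_death")
        p = 1 - np.exp(-30 * lam)
        assert counts.loc["a", "expected"] == pytest.approx(4 * p, rel=1e-9)
        assert counts.loc["b", "expected"] == pytest.approx(9 * p, rel=1e-9)

    def test_low_volume_hospital_expected_below_one(self):
        # a hospital can have < 1 expected late survivor (e.g. 0.89)
        lam = np.log(0.12) / -730.0  # S(730) = 0.12
        fit = make_fit(np.log([[lam, lam]]))
        records = self._records({"a": 7, "b": 50})
        counts = expected_events(fit, records, 730, "late_survival")
        assert 0 < counts.loc["a", "expected"] < 1

    def test_additivity_over_hospitals(self):
        rng = np.random.default_rng(6)
        loglam = rng.normal(-5.5, 0.3, size=(15, 3))
        fit = make_fit(loglam, breaks=(0.0, 30.0, 730.0))
        rows = []
        for hosp in "abc":
            for i in range(20):
                rows.append((hosp, float(rng.uniform(40, 80)),
                             int(rng.choice([60, 70, 80, 90])),
                             int(rng.choice([2011, 2012])), 800, "censored", 800))
        records = manual_records(rows)
        split = expected_events(fit, records, 30, "early_death")
        pooled = records.assign(hospital_id="all")
        total = expected_events(fit, pooled, 30, "early_death")
        assert split["expected"].sum() == pytest.approx(
            total.loc["all", "expected"], rel=5e-2)  # medians are not additive
        # plug-in expectations are exactly additive
        split_p = expected_events(fit, records, 30, "early_death", method="plugin")
        total_p = expected_events(fit, pooled, 30, "early_death", method="plugin")
        assert split_p["expected"].sum() == pytest.approx(
            total_p.loc["all", "expected"], rel=1e-9)

    def test_unknown_kind_rejected(self):
        fit = make_fit(np.log([[0.01, 0.01]]))
        with pytest.raises(ValidationError):
            expected_events(fit, self._records({"a": 3}), 30, "whatever")


class TestOERatios:
    def test_ratio_one(self):
        counts = pd.DataFrame({"observed": [6], "expected": [6.0]},
                              index=pd.Index(["a"], name="hospital_id"))
        (r,) = oe_ratios(counts, "early_death")
        assert r.ratio == 1.0

    def test_zero_observed(self):
        counts = pd.DataFrame({"observed": [0], "expected": [0.89]},
                              index=pd.Index(["i"], name="hospital_id"))
        (r,) = oe_ratios(counts, "late_survival")
        assert r.ratio == 0.0

    def test_round_trip_reconstruction(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            obs = int(rng.integers(0, 40))
            exp = float(rng.uniform(0.2, 40))
            r = StandardizedRatio("x", "early_death", obs, exp)
            assert r.ratio * r.expected == pytest.approx(r.observed, rel=1e-12)

    def test_zero_expected_rejected(self):
        counts = pd.DataFrame({"observed": [1], "expected": [0.0]},
                              index=pd.Index(["a"], name="hospital_id"))
        with pytest.raises(ValidationError):
            oe_ratios(counts, "early_death")

    def test_frame_export(self):
        r = StandardizedRatio("a", "early_death", 3, 2.5)
        frame = ratios_frame([r])
        assert frame.loc[0, "ratio"] == pytest.approx(1.2)
        assert frame.loc[0, "flag"] == "within"
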