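import numpy as np
import pandas as pd
import pytest

from hospvar import ValidationError, generate_registry
from hospvar.diagnostics import diagnostics_table, gelman_rubin
from hospvar.hazard import (Priors, build_counting_process, fit_fixed,
                            fit_hierarchical)
from hospvar.mcmc import SamplerConfig

from conftest import FAST_SAMPLER, manual_records, small_null_config

BREAKS = (0.0, 30.0, 90.0, 180.0, 270.0, 365.0, 545.0, 730.0, 1095.0, 1460.0)


class TestCountingProcess:
    def test_death_day_45(self):
        df = manual_records([("a", 60, 80, 2012, 45, "dead", 1000)])
        table = build_counting_process(df, breaks=(0.0, 30.0, 90.0, 730.0))
        f = table.frame
        assert list(f["interval"]) == [0, 1]
        assert list(f["exposure"]) == [30.0, 15.0]
        assert list(f["event"]) == [0, 1]

    def test_censored_exactly_at_break(self):
        df = manual_records([("a", 60, 80, 2012, 30, "censored", 30)])
        table = build_counting_process(df, breaks=(0.0, 30.0, 730.0))
        f = table.frame
        assert len(f) == 1
        assert f.loc[0, "exposure"] == 30.0
        assert f.loc[0, "event"] == 0

    def test_exposure_conservation(self):
        records, _ = generate_registry(small_null_config(sigma_u=0.2), seed=6)
        table = build_counting_process(records)
        per_patient = table.frame.groupby("patient_id")["exposure"].sum()
        merged = records.set_index("patient_id")["time_days"].astype(float)
        pd.testing.assert_series_equal(per_patient.sort_index(),
                                       merged.sort_index(), check_names=False)
        assert table.frame["event"].sum() == (records["status"] == "dead").sum()

    def test_zero_time_death_gets_half_day(self):
        df = manual_records([("a", 60, 80, 2012, 0, "dead", 1000)])
        table = build_counting_process(df, breaks=(0.0, 30.0, 730.0))
        assert table.n_zero_time == 1
        assert table.frame["exposure"].iloc[0] == 0.5
        assert table.frame["event"].iloc[0] == 1

    def test_at_most_one_event_last_row(self):
        records, _ = generate_registry(small_null_config(), seed=2)
        table = build_counting_process(records)
        g = table.frame.groupby("patient_id")
        assert (g["event"].sum() <= 1).all()
        last = g.tail(1).set_index("patient_id")["event"]
        has_event = g["event"].sum()
        pd.testing.assert_series_equal(has_event.sort_index(),
                                       last.sort_index(), check_names=False)

    def test_breaks_must_include_horizons(self):
        df = manual_records([("a", 60, 80, 2012, 45, "dead", 1000)])
        with pytest.raises(ValidationError):
            build_counting_process(df, breaks=(0.0, 90.0))


class TestFitHierarchical:
    def test_single_hospital_rejected(self):
        df = manual_records([("a", 60, 80, 2012, 45, "dead", 1000)] * 30)
        table = build_counting_process(df)
        with pytest.raises(ValidationError, match="2 hospitals"):
            fit_hierarchical(table, seed=0)

    def test_interval_hazard_matches_poisson_mle(self):
        # all-zero covariates: under vague priors the interval log-hazard
        # posterior centers on the Poisson MLE log(events / exposure)
        rng = np.random.default_rng(12)
        times = np.maximum(1, np.ceil(rng.exponential(250.0, size=400)))
        rows = [("a" if i % 2 == 0 else "b", 61.4, 80, 2011, int(t),
                 "dead", 10 ** 6) for i, t in enumerate(times)]
        table = build_counting_process(manual_records(rows))
        fit = fit_hierarchical(table, sampler=FAST_SAMPLER, seed=3,
                               rhat_threshold=1.1)
        f = table.frame
        loglam = fit.flat("log_lambda")
        for k in range(3):
            sub = f[f["interval"] == k]
            mle = np.log(sub["event"].sum() / sub["exposure"].sum())
            draws = loglam[:, k]
            assert abs(np.median(draws) - mle) < 2 * draws.std()

    def test_null_frailties_cover_zero(self, null_fit):
        fit, _, _ = null_fit
        u = fit.flat("u")
        lo, hi = np.percentile(u, [2.5, 97.5], axis=0)
        covered = int(((lo <= 0) & (0 <= hi)).sum())
        assert covered >= 13

    def test_summary_gated_on_convergence(self, null_fit):
        import dataclasses

        from hospvar.errors import ConvergenceError
        fit, _, _ = null_fit
        bad = dataclasses.replace(fit, converged=False)
        with pytest.raises(ConvergenceError):
            bad.summary()
        assert not bad.summary(force=True).empty

    def test_median_invariant_to_doubling_draws(self):
        records, _ = generate_registry(
            small_null_config(volumes=tuple([40] * 14)), seed=30)
        table = build_counting_process(records)
        f1 = fit_hierarchical(table, sampler=SamplerConfig(chains=2, warmup=300,
                                                           draws=300),
                              seed=11, rhat_threshold=1.1)
        f2 = fit_hierarchical(table, sampler=SamplerConfig(chains=2, warmup=300,
                                                           draws=600),
                              seed=11, rhat_threshold=1.1)
        for name in ("age_c", "kps_c"):
            j = list(f1.covariates).index(name)
            d1, d2 = f1.flat("beta")[:, j], f2.flat("beta")[:, j]
            mcse = max(d1.std() / np.sqrt(f1.diagnostics.loc[name, "ess_bulk"]),
                       d2.std() / np.sqrt(f2.diagnostics.loc[name, "ess_bulk"]))
            assert abs(np.median(d1) - np.median(d2)) < 4 * mcse


class TestFitFixed:
    def test_constant_covariate_rejected(self):
        records, _ = generate_registry(small_null_config(), seed=1)
        covs = pd.DataFrame({"flat": 1.0},
                            index=sorted(records["hospital_id"].unique()))
        with pytest.raises(ValidationError, match="flat"):
            fit_fixed(records, hospital_covariates=covs)

    def test_collinear_covariates_named(self):
        records, _ = generate_registry(small_null_config(), seed=1)
        hospitals = sorted(records["hospital_id"].unique())
        x = np.arange(len(hospitals), dtype=float)
        covs = pd.DataFrame({"v1": x, "v2": 2 * x}, index=hospitals)
        with pytest.raises(ValidationError, match="collinear"):
            fit_fixed(records, hospital_covariates=covs)

    def test_recovers_patient_effects(self):
        records, truth = generate_registry(small_null_config(
            volumes=tuple([250] * 14)), seed=8)
        hr = fit_fixed(records)
        assert hr.loc["age_c", "lo95"] < np.exp(truth["beta"]["age"]) \
            < hr.loc["age_c", "hi95"]
        assert hr.loc["kps_c", "lo95"] < np.exp(truth["beta"]["kps"]) \
            < hr.loc["kps_c", "hi95"]

    def test_biopsy_fraction_effect_recovery(self):
        # hospital-level log-hazard log(2.09) per unit biopsy fraction,
        # injected through deterministic frailties
        cfg = small_null_config(volumes=tuple([360] * 14))
        frac = np.asarray(cfg.biopsy_fractions)
        beta_biopsy = float(np.log(2.09))
        cfg = small_null_config(
            volumes=tuple([360] * 14),
            frailties=tuple(beta_biopsy * (frac - frac.mean())))
        records, _ = generate_registry(cfg, seed=15)
        covs = pd.DataFrame({"biopsy_fraction": frac},
                            index=list(cfg.hospital_ids))
        hr = fit_fixed(records, hospital_covariates=covs)
        assert 1.7 < hr.loc["biopsy_fraction", "hr"] < 2.6

    def test_null_hospital_effect_coverage(self):
        # no true hospital effects: 95% intervals for log-volume and academic
        # should cover HR 1 in >= 90% of replicates
        hospitals = list("abcdefghijklmn")
        academic = np.array([1.0] * 7 + [0.0] * 7)
        covered = {"log_volume": 0, "academic": 0}
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            volumes = rng.integers(40, 120, size=14)
            cfg = small_null_config(volumes=tuple(int(v) for v in volumes))
            records, _ = generate_registry(cfg, seed=200 + rep)
            covs = pd.DataFrame({
                "log_volume": np.log(volumes.astype(float)),
                "academic": academic,
            }, index=hospitals)
            hr = fit_fixed(records, hospital_covariates=covs)
            for name in covered:
                if hr.loc[name, "lo95"] <= 1.0 <= hr.loc[name, "hi95"]:
                    covered[name] += 1
        assert covered["log_volume"] >= int(0.9 * n_rep)
        assert covered["academic"] >= int(0.9 * n_rep)


class TestDiagnostics:
    def test_identical_chains_rhat_exactly_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=500)
        chains = np.stack([chain, chain, chain])
        assert gelman_rubin(chains) == 1.0

    def test_divergent_chains_fail(self):
        rng = np.random.default_rng(0)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(5, 1, 500)])
        assert gelman_rubin(chains) > 1.1
        table = diagnostics_table(chains[:, :, None], ["theta"])
        assert not table.loc["theta", "pass"]

    def test_default_fit_passes(self, null_fit):
        fit, _, _ = null_fit
        assert (fit.diagnostics["rhat"] < 1.05).all()
        assert fit.diagnostics["ess_bulk"].min() > 50
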