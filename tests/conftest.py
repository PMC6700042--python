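import numpy as np
import pandas as pd
import pytest

from hospvar import GeneratorConfig, generate_registry
from hospvar.hazard import build_counting_process, fit_hierarchical
from hospvar.mcmc import SamplerConfig

SMALL_VOLUMES = (60, 55, 70, 45, 80, 50, 65, 40, 75, 58, 62, 48, 52, 68)

FAST_SAMPLER = SamplerConfig(chains=2, warmup=300, draws=300)


def small_null_config(**overrides):
    """14 small hospitals, no frailty, full 2-year observability."""
    base = dict(
        volumes=SMALL_VOLUMES,
        sigma_u=0.0,
        lookup_date="2017-03-01",  # accrual end + >730 d: everyone observable at 2 y
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def null_registry():
    """Default-size registry with zero frailty and full 2-year observability."""
    cfg = GeneratorConfig(sigma_u=0.0, lookup_date="2017-03-01")
    records, truth = generate_registry(cfg, seed=20)
    return records, truth


@pytest.fixture(scope="session")
def null_fit(null_registry):
    records, truth = null_registry
    table = build_counting_process(records)
    fit = fit_hierarchical(table, sampler=SamplerConfig(chains=2, warmup=400, draws=400),
                           seed=4, rhat_threshold=1.05)
    return fit, records, truth


def manual_records(rows):
    """Build a canonical registry frame from (hospital, age, kps, year, time,
    status, potential) tuples."""
    recs = []
    for i, (hosp, age, kps, year, time_days, status, potential) in enumerate(rows):
        recs.append({
            "patient_id": f"p{i:03d}", "hospital_id": hosp, "age": age,
            "kps": kps, "year": year, "gender": "female",
            "surgery_type": "resection", "surgery_date": None,
            "time_days": time_days, "status": status,
            "potential_followup_days": potential,
        })
    df = pd.DataFrame(recs)
    df["kps"] = df["kps"].astype("Int64")
    return df
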