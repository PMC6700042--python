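"""MCMC convergence diagnostics: potential scale reduction and effective
sample sizes."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws).  The estimate is floored at 1.0:
    values below 1 only arise from sampling noise in the between-chain term,
    so identical chains report exactly 1.
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if m < 2:
        raise ValueError("need >= 2 chains for R-hat")
    chain_means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return max(1.0, float(np.sqrt(var_plus / w)))


def effective_sample_size(chains: np.ndarray) -> tuple[float, float]:
    """Bulk and tail ESS via arviz (rank-normalized, Stan-style)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        arr = np.asarray(chains, dtype=float)
        bulk = float(az.ess(arr, method="bulk"))
        tail = float(az.ess(arr, method="tail"))
    return bulk, tail


def diagnostics_table(chains_matrix: np.ndarray, labels,
                      rhat_threshold: float = 1.01) -> pd.DataFrame:
    """Per-parameter R-hat and ESS for draws of shape (chains, draws, dim)."""
    chains_matrix = np.asarray(chains_matrix)
    rows = []
    for j, label in enumerate(labels):
        x = chains_matrix[:, :, j]
        rhat = gelman_rubin(x)
        bulk, tail = effective_sample_size(x)
        rows.append({"parameter": label, "rhat": rhat,
                     "ess_bulk": bulk, "ess_tail": tail,
                     "pass": rhat < rhat_threshold})
    return pd.DataFrame(rows).set_index("parameter")
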