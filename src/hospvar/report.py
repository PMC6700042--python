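"""End-to-end pipeline orchestration, Kaplan-Meier curves and report plots."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from . import funnel as funnel_mod
from . import simulate
from .errors import HospvarError, ValidationError
from .factors import hospital_factor_logistic
from .hazard import build_counting_process, fit_hierarchical
from .mcmc import SamplerConfig
from .registry import (complete_case_filter, read_registry, summarize_hospitals,
                       write_registry)
from .standardize import (expected_events, expected_survival_function,
                          oe_ratios, ratios_frame, _covariate_matrix)

log = logging.getLogger(__name__)

DAYS_PER_MONTH = simulate.DAYS_PER_MONTH


@dataclass
class PipelineConfig:
    out_dir: str = "hospvar_out"
    registry_path: str | None = None       # None: simulate with generator config
    generator: simulate.GeneratorConfig = field(default_factory=simulate.GeneratorConfig)
    academic: dict = field(default_factory=dict)
    breaks: tuple[float, ...] = simulate.DEFAULT_BREAKS
    funnel_method: str = "interpolated"
    horizons: tuple[int, int] = (30, 730)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        for h in self.horizons:
            if h <= 0 or float(h) not in [float(b) for b in self.breaks]:
                raise ValidationError(
                    f"horizon {h} must be positive and among the interval breaks")


def kaplan_meier(records: pd.DataFrame, by: str = "hospital_id") -> dict:
    """Product-limit survival per group.

    Returns ``{group: {"km": fitted KaplanMeierFitter, "median_days": float,
    "median_months": float}}``; empty groups are skipped with a log entry.
    """
    out = {}
    for group, sel in records.groupby(by):
        if sel.empty:
            log.info("group %s empty; skipped", group)
            continue
        km = KaplanMeierFitter(label=str(group))
        km.fit(sel["time_days"].to_numpy(),
               (sel["status"] == "dead").to_numpy())
        median = float(km.median_survival_time_)
        out[group] = {"km": km, "median_days": median,
                      "median_months": median / DAYS_PER_MONTH}
    return out


def km_plot(curves: dict, path, overall: pd.DataFrame | None = None) -> None:
    fig, ax = plt.subplots(figsize=(8, 6))
    for group, c in curves.items():
        sf = c["km"].survival_function_
        ax.step(sf.index / DAYS_PER_MONTH, sf.iloc[:, 0], where="post",
                label=str(group), lw=1)
    if overall is not None:
        km = KaplanMeierFitter()
        km.fit(overall["time_days"], overall["status"] == "dead")
        sf = km.survival_function_
        ax.step(sf.index / DAYS_PER_MONTH, sf.iloc[:, 0], where="post",
                color="black", lw=2, label="overall")
    ax.set_xlabel("months since surgery")
    ax.set_ylabel("survival probability")
    ax.legend(fontsize=7, ncol=2)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def funnel_plot(ratios: list, method: str, path) -> None:
    """Funnel of O/E ratios vs expected events, one panel per outcome kind."""
    frame = ratios_frame(ratios)
    kinds = sorted(frame["kind"].unique())
    fig, axes = plt.subplots(1, len(kinds), figsize=(6 * len(kinds), 5),
                             squeeze=False)
    for ax, kind in zip(axes[0], kinds):
        sub = frame[frame["kind"] == kind]
        lims = funnel_mod.funnel_curves(sub["expected"].max(), method=method)
        for level, (lo, hi) in lims.limits.items():
            style = "-" if level == 95 else ":"
            ax.plot(lims.expected_grid, np.maximum(lo, 1e-3), style, color="gray")
            ax.plot(lims.expected_grid, hi, style, color="gray")
        colors = {"within": "black", "": "black"}
        for _, row in sub.iterrows():
            color = ("green" if row["direction"] == "better" else "red") \
                if row["flag"] != "within" else "0.4"
            ax.plot(row["expected"], max(row["ratio"], 1e-3), "o", color=color)
            ax.annotate(row["hospital_id"], (row["expected"], max(row["ratio"], 1e-3)),
                        fontsize=7, xytext=(3, 3), textcoords="offset points")
        ax.axhline(1.0, color="black", lw=0.5)
        ax.set_yscale("log")
        ax.set_xlabel("expected events")
        ax.set_ylabel("observed / expected")
        ax.set_title(kind)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def observed_vs_expected_plot(fit, records: pd.DataFrame, path,
                              t_max: float | None = None) -> int:
    """Per-hospital observed KM vs expected (u = 0) and fitted (u = posterior
    median) survival curves, plus two pooled deviation panels.

    Returns the number of panels drawn (hospitals + 2).
    """
    hospitals = [h for h in fit.hospital_ids if (records["hospital_id"] == h).any()]
    n_panel = len(hospitals) + 2
    ncol = 4
    nrow = int(np.ceil(n_panel / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                             squeeze=False)
    flat_axes = axes.ravel()
    if t_max is None:
        t_max = float(records["time_days"].max())
    grid = np.linspace(0, t_max, 80)

    u_median = {h: float(np.median(fit.flat("u")[:, i]))
                for i, h in enumerate(fit.hospital_ids)}
    dev_rows = []
    for ax, hosp in zip(flat_axes, hospitals):
        sel = records[records["hospital_id"] == hosp]
        km = KaplanMeierFitter()
        km.fit(sel["time_days"], sel["status"] == "dead")
        ax.step(km.survival_function_.index / DAYS_PER_MONTH,
                km.survival_function_.iloc[:, 0], where="post",
                color="black", lw=1.5, label="observed")
        X = _covariate_matrix(fit, sel)
        exp_curve = [float(np.median(
            expected_survival_function(fit, X, t).mean(axis=0))) for t in grid]
        fit_curve = [float(np.median(
            (expected_survival_function(fit, X, t)
             ** np.exp(u_median[hosp])).mean(axis=0))) for t in grid]
        ax.plot(grid / DAYS_PER_MONTH, exp_curve, color="tab:blue", label="expected")
        ax.plot(grid / DAYS_PER_MONTH, fit_curve, color="black", lw=0.7,
                label="fitted")
        for guide in (30, 730):
            ax.axvline(guide / DAYS_PER_MONTH, color="0.8", lw=0.6)
        ax.set_title(str(hosp), fontsize=9)
        ax.set_ylim(0, 1)
        exp30 = float(np.median((1 - expected_survival_function(fit, X, 30.0))
                                .sum(axis=0)))
        obs30 = int(((sel["status"] == "dead") & (sel["time_days"] <= 30)).sum())
        dev_rows.append({"hospital_id": hosp, "observed": obs30, "expected": exp30})
    flat_axes[0].legend(fontsize=7)

    dev = pd.DataFrame(dev_rows)
    ax_abs, ax_ratio = flat_axes[len(hospitals)], flat_axes[len(hospitals) + 1]
    ax_abs.bar(dev["hospital_id"], dev["observed"] - dev["expected"])
    ax_abs.set_title("observed - expected deaths (30d)", fontsize=9)
    ax_ratio.bar(dev["hospital_id"], dev["observed"] / dev["expected"])
    ax_ratio.axhline(1.0, color="black", lw=0.5)
    ax_ratio.set_title("observed / expected deaths (30d)", fontsize=9)
    for ax in flat_axes[n_panel:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return n_panel


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate/load -> summarize -> fit -> standardize -> funnel ->
    explore -> plots; returns a manifest of produced artifacts.

    All numeric outputs are deterministic given ``config.seed``.  A failing
    stage aborts with the stage name; artifacts written so far are kept.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest = {"seed": config.seed, "config_hash": _config_hash(config)}
    stage = "setup"
    try:
        stage = "registry"
        if config.registry_path:
            records = read_registry(config.registry_path)
            truth = None
        else:
            records, truth = simulate.generate_registry(config.generator,
                                                        seed=config.seed)
            write_registry(records, out / "registry.csv")
            simulate.write_truth(truth, out / "truth.json")
        log.info("registry: %d records", len(records))

        stage = "summarize"
        kept, exclusions = complete_case_filter(records)
        summary = summarize_hospitals(kept, academic=config.academic or None,
                                      all_records=records)
        summary.to_csv(out / "table1.csv")
        exclusions.to_csv(out / "exclusions.csv", index=False)

        stage = "hazard_model"
        table = build_counting_process(kept, breaks=config.breaks)
        fit = fit_hierarchical(table, sampler=config.sampler, seed=config.seed)
        fit_summary = fit.summary(force=True)
        fit_payload = {
            "converged": fit.converged,
            "seed": fit.seed,
            "summary": json.loads(fit_summary.reset_index().to_json(orient="records")),
            "diagnostics": json.loads(
                fit.diagnostics.reset_index().to_json(orient="records")),
        }
        (out / "fit.json").write_text(json.dumps(fit_payload, indent=2) + "\n")

        stage = "standardize"
        ratios = []
        for kind, horizon in (("early_death", config.horizons[0]),
                              ("late_survival", config.horizons[1])):
            counts = expected_events(fit, kept, horizon, kind)
            ratios.extend(oe_ratios(counts, kind))

        stage = "funnel"
        ratios = funnel_mod.flag_outliers(ratios, method=config.funnel_method)
        rframe = ratios_frame(ratios)
        rframe.to_csv(out / "ratios.csv", index=False)
        rframe[rframe["flag"] != "within"].to_csv(out / "flags.csv", index=False)
        funnel_plot(ratios, config.funnel_method, out / "funnel.png")

        stage = "explore"
        explore = {}
        for kind in ("early_death", "late_survival"):
            for cov in ("log_volume", "academic", "biopsy_fraction"):
                if cov == "academic" and summary["academic"].isna().all():
                    continue
                lf = hospital_factor_logistic(summary, kind, cov)
                explore[f"{kind}:{cov}"] = {
                    "slope": lf.slope, "se": lf.slope_se, "p": lf.p_value}
        (out / "explore.json").write_text(json.dumps(explore, indent=2) + "\n")

        stage = "plots"
        curves = kaplan_meier(kept)
        km_plot(curves, out / "km.png", overall=kept)
        observed_vs_expected_plot(fit, kept, out / "observed_vs_expected.png")

        manifest.update({
            "n_records": len(records), "n_complete": len(kept),
            "converged": fit.converged,
            "artifacts": sorted({p.name for p in out.iterdir()}
                                | {"manifest.json"}),
        })
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest
    except HospvarError as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc
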