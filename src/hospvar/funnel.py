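"""Funnel-plot control limits from the Poisson distribution and outlier
flagging.

Two constructions ship:

* ``exact`` — integer Poisson quantiles at alpha/2 and 1 - alpha/2 divided by
  the expected count.  Guaranteed conservative, but for small expected counts
  the lower limit collapses to 0, so a hospital with 0 observed events can
  never fall below it.
* ``interpolated`` (default) — continuous gamma/chi-square quantiles, the
  usual smooth funnel for standardized ratios.  Its lower limit stays
  positive for any expected count, so 0 observed with 0.89 expected *is*
  flagged below the 99% limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .standardize import StandardizedRatio

METHODS = ("exact", "interpolated")
DEFAULT_LEVELS = (95.0, 99.0)


def poisson_limits(expected: float, level: float = 95.0,
                   method: str = "interpolated",
                   allow_any_level: bool = False) -> tuple[float, float]:
    """Lower and upper O/E-ratio control limits at one expected count."""
    if expected <= 0:
        raise ValidationError("expected must be positive")
    if level not in (95.0, 99.0) and not allow_any_level:
        raise ValidationError(f"level must be 95 or 99 (got {level}); "
                              "pass allow_any_level=True for arbitrary levels")
    alpha = 1.0 - level / 100.0
    if method == "exact":
        lo = float(stats.poisson.ppf(alpha / 2, expected))
        hi = float(stats.poisson.ppf(1 - alpha / 2, expected))
        return lo / expected, hi / expected
    if method == "interpolated":
        # gamma/chi-square continuous analogue of the Poisson quantiles; the
        # +1 shape on the upper side keeps coverage at or above nominal
        lo = float(stats.gamma.ppf(alpha / 2, a=expected))
        hi = float(stats.gamma.ppf(1 - alpha / 2, a=expected + 1.0))
        return lo / expected, hi / expected
    raise ValidationError(f"unknown method {method!r}")


@dataclass
class FunnelLimits:
    """Control-limit curves over a grid of expected-event precisions."""

    expected_grid: np.ndarray
    limits: dict  # level -> (lower array, upper array)
    method: str

    def frame(self) -> pd.DataFrame:
        cols = {"expected": self.expected_grid}
        for level, (lo, hi) in self.limits.items():
            cols[f"lower_{level:g}"] = lo
            cols[f"upper_{level:g}"] = hi
        return pd.DataFrame(cols)


def funnel_curves(max_expected: float, levels=DEFAULT_LEVELS,
                  method: str = "interpolated", n_grid: int = 200,
                  grid_min: float = 0.5) -> FunnelLimits:
    """Control-limit curves on a log-spaced precision grid
    (``grid_min`` .. 1.2 x max expected)."""
    if max_expected <= 0:
        raise ValidationError("max_expected must be positive")
    hi = max(1.2 * max_expected, grid_min * 1.01)
    grid = np.geomspace(grid_min, hi, n_grid)
    limits = {}
    for level in levels:
        pairs = [poisson_limits(e, level, method=method) for e in grid]
        limits[float(level)] = (np.array([p[0] for p in pairs]),
                                np.array([p[1] for p in pairs]))
    return FunnelLimits(expected_grid=grid, limits=limits, method=method)


def flag_outliers(ratios: list[StandardizedRatio],
                  method: str = "interpolated",
                  levels=DEFAULT_LEVELS) -> list[StandardizedRatio]:
    """Assign funnel flags to O/E ratios.

    A ratio strictly outside a limit is flagged (a point exactly on a limit
    stays "within").  Direction is outcome-specific: for early mortality a
    low ratio is "better"; for late survival a high ratio is "better".
    """
    import dataclasses

    out = []
    for r in ratios:
        flag, direction = "within", ""
        for level in sorted(levels):  # check 95 first, then upgrade to 99
            lo, hi = poisson_limits(r.expected, level, method=method)
            if r.ratio < lo or r.ratio > hi:
                flag = f"outside_{level:g}"
                low_side = r.ratio < lo
                if r.kind == "early_death":
                    direction = "better" if low_side else "worse"
                else:
                    direction = "worse" if low_side else "better"
        out.append(dataclasses.replace(r, flag=flag, direction=direction))
    return out
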