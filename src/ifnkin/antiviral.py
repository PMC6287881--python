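"""Antiviral-protection metrics from luciferase infection assays.

Relative infection is luciferase signal as a percentage of the untreated,
virus-infected control (set to 100).  EC90 is the dose achieving 90%
inhibition (10% residual infection); protection kinetics are summarised by
the earliest pre-treatment time reaching the target and the latest
post-infection treatment delay still reaching it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "relative_infection",
    "CrossingResult",
    "ec90",
    "time_to_protection",
    "post_infection_window",
    "four_pl",
]


def relative_infection(treated, control) -> float:
    """Luciferase signal as percent of the untreated infected control."""
    control = np.asarray(control, dtype=float)
    if np.any(control <= 0):
        raise ValueError("untreated control signal must be positive")
    return 100.0 * np.asarray(treated, dtype=float) / control


def four_pl(dose, top, bottom, ec50, slope):
    """Four-parameter logistic, decreasing in dose for slope > 0."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** slope)


@dataclass
class CrossingResult:
    """An interpolated crossing of a protection target; value None if unmet."""

    value: float | None
    reached: bool
    mode: str

    def __float__(self):
        if self.value is None:
            raise ValueError("target was not reached")
        return float(self.value)


def _interp_crossing(x, y, target, earliest=True):
    """First (or last) crossing of y(x) through ``target``, linear in x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    below = y <= target
    idx = range(len(x) - 1) if earliest else range(len(x) - 2, -1, -1)
    if earliest and below[0]:
        return float(x[0])
    for i in idx:
        if earliest and not below[i] and below[i + 1]:
            f = (target - y[i]) / (y[i + 1] - y[i])
            return float(x[i] + f * (x[i + 1] - x[i]))
        if not earliest and below[i] and not below[i + 1]:
            f = (target - y[i]) / (y[i + 1] - y[i])
            return float(x[i] + f * (x[i + 1] - x[i]))
    if not earliest and below[-1]:
        return float(x[-1])
    return None


def ec90(doses, infection_pct, target: float = 10.0,
         mode: str = "interp") -> CrossingResult:
    """Dose achieving the target residual infection (default 10%, i.e. EC90).

    ``interp`` (default) interpolates the first crossing of the target on a
    log-dose axis; ``4pl`` fits a four-parameter logistic and solves the
    fitted curve for the target analytically.  A curve that never reaches
    the target (e.g. partial protection plateauing above it) yields a
    "not reached" result.
    """
    doses = np.asarray(doses, dtype=float)
    infection = np.asarray(infection_pct, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive for log-dose interpolation")
    order = np.argsort(doses)
    doses, infection = doses[order], infection[order]
    if mode == "interp":
        logx = _interp_crossing(np.log10(doses), infection, target)
        value = None if logx is None else 10.0 ** logx
        return CrossingResult(value, value is not None, "interp")
    if mode == "4pl":
        p0 = (float(infection.max()), float(infection.min()),
              float(np.median(doses)), 1.0)
        lo = (-np.inf, -np.inf, 1e-12, 1e-3)
        hi = (np.inf, np.inf, np.inf, 100.0)
        try:
            popt, _ = curve_fit(four_pl, doses, infection,
                                p0=np.clip(p0, lo, hi), bounds=(lo, hi),
                                maxfev=20000)
        except RuntimeError:
            return CrossingResult(None, False, "4pl")
        top, bottom, ec50_, slope = popt
        if not (bottom < target < top) or slope <= 0 or ec50_ <= 0:
            return CrossingResult(None, False, "4pl")
        value = ec50_ * ((top - bottom) / (target - bottom) - 1.0) ** (1.0 / slope)
        return CrossingResult(float(value), True, "4pl")
    raise ValueError("mode must be 'interp' or '4pl'")


def time_to_protection(times, infection_pct,
                       target: float = 10.0) -> CrossingResult:
    """Earliest pre-treatment time reaching the target residual infection."""
    times = np.asarray(times, dtype=float)
    infection = np.asarray(infection_pct, dtype=float)
    order = np.argsort(times)
    value = _interp_crossing(times[order], infection[order], target,
                             earliest=True)
    return CrossingResult(value, value is not None, "interp")


def post_infection_window(delays, infection_pct,
                          target: float = 10.0) -> CrossingResult:
    """Latest post-infection treatment delay still reaching the target."""
    delays = np.asarray(delays, dtype=float)
    infection = np.asarray(infection_pct, dtype=float)
    order = np.argsort(delays)
    value = _interp_crossing(delays[order], infection[order], target,
                             earliest=False)
    return CrossingResult(value, value is not None, "interp")
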