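"""Profile-likelihood identifiability and approximate confidence bands.

A parameter's profile fixes it at values stepped away from the optimum and
re-optimises everything else; the increase of the objective,

    dchi2(theta) = wSSR_min(theta) - wSSR_min(theta_opt),

crossed against the chi-squared quantile Delta_alpha yields confidence
bounds.  A parameter is practically identifiable when both crossings exist
within the search box; a flat profile marks structural non-identifiability.

Prediction uncertainty uses the approximate band

    y_sim +/- t_{alpha, N-P} * sqrt(MSE * (1 + s (S'S)^{-1} s')),

with S the finite-difference sensitivity matrix of the observable; the
``mean`` kind drops the leading 1 (confidence band for the mean response
rather than a prediction band).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "chi2_threshold",
    "ProfileResult",
    "profile_parameter",
    "profile_all",
    "inactivation_contrast",
    "finite_difference_sensitivity",
    "sensitivity_matrix",
    "ConfidenceBand",
    "confidence_bands",
    "model_confidence_band",
]


def chi2_threshold(alpha: float, df: int = 1) -> float:
    """The alpha quantile of the chi-squared distribution with df degrees."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.ppf(alpha, df))


@dataclass
class ProfileResult:
    """Profile likelihood of one parameter."""

    name: str
    values: np.ndarray          # parameter grid (linear scale), ascending
    wssr: np.ndarray            # re-optimised wSSR per grid value
    wssr_opt: float
    threshold: float
    alpha: float
    lower: float | None = None  # None: open (not crossed within the box)
    upper: float | None = None
    flagged: list = field(default_factory=list)  # grid points whose re-opt failed

    @property
    def dchi2(self) -> np.ndarray:
        return self.wssr - self.wssr_opt

    @property
    def identifiability(self) -> str:
        span = float(np.max(self.dchi2)) if len(self.wssr) else 0.0
        if span < 0.02 * self.threshold:
            return "structurally non-identifiable"
        if self.lower is None or self.upper is None:
            return "practically non-identifiable"
        return "identifiable"

    @property
    def interval(self):
        return (self.lower, self.upper)

    def plot(self, ax=None):
        """Profile dchi2 against the parameter, with the threshold line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.values, self.dchi2, marker=".")
        ax.axhline(self.threshold, color="red", lw=1,
                   label=f"{100 * self.alpha:g}% threshold")
        ax.set_xscale("log")
        ax.set_xlabel(self.name)
        ax.set_ylabel(r"$\Delta\chi^2$")
        ax.legend()
        return ax


def profile_parameter(results, name: str, alpha: float = 0.95,
                      target_step: float = 0.3, max_steps: int = 50,
                      init_step: float = 0.05, max_step: float = 0.5,
                      df: int = 1, crossing_xtol: float = 1e-3) -> ProfileResult:
    """Stepwise profile likelihood of one free parameter.

    Steps the parameter away from its optimum in both directions in log10
    space, re-optimising all other free parameters warm-started from the
    neighbouring grid point, until dchi2 exceeds the chi-squared threshold
    or the box bound is reached.  The step size adapts toward a dchi2
    increment of ``target_step`` per step.  A grid point whose
    re-optimisation fails is flagged and profiling continues.  Once a
    crossing is bracketed it is refined by Brent root finding to
    ``crossing_xtol`` in log10-parameter units.
    """
    model = results.model
    if name not in model.param_names:
        raise KeyError(f"{name!r} is not a free parameter of this fit "
                       f"(free: {model.param_names})")
    j = model.param_names.index(name)
    theta_opt = results.theta
    lb = model.theta0 - model.bounds_decades
    ub = model.theta0 + model.bounds_decades
    threshold = chi2_threshold(alpha, df)

    points = [(theta_opt[j], results.wssr)]
    flagged = []
    bounds_hit = {}
    crossings = {}
    for direction in (-1.0, +1.0):
        x = theta_opt[j]
        warm = theta_opt.copy()
        step = init_step
        prev_d = 0.0
        hit_bound = False
        for _ in range(max_steps):
            x_new = x + direction * step
            if x_new <= lb[j] or x_new >= ub[j]:
                x_new = lb[j] if direction < 0 else ub[j]
                hit_bound = True
            try:
                th, w, _ = model._minimise(warm, lb, ub, fixed_index=j,
                                           fixed_value=x_new, ftol=1e-8,
                                           xtol=1e-8)
                warm = th
            except Exception:
                flagged.append(10.0 ** x_new)
                if hit_bound:
                    break
                x = x_new
                continue
            d = max(w - results.wssr, 0.0)
            points.append((x_new, w))
            if d > threshold:
                from scipy.optimize import brentq

                warm_ref = [warm]

                def excess(xv):
                    th_r, w_r, _ = model._minimise(
                        warm_ref[0], lb, ub, fixed_index=j, fixed_value=xv,
                        ftol=1e-8, xtol=1e-8)
                    warm_ref[0] = th_r
                    points.append((xv, w_r))
                    return w_r - results.wssr - threshold

                lo_x, hi_x = sorted((x, x_new))
                try:
                    crossings[direction] = brentq(excess, lo_x, hi_x,
                                                  xtol=crossing_xtol)
                except ValueError:
                    # warm-started re-optimisation can shift the bracket
                    f = (threshold - prev_d) / (d - prev_d)
                    crossings[direction] = x + f * (x_new - x)
                break
            if hit_bound:
                break
            # adapt the step toward the target dchi2 increment
            inc = d - prev_d
            if inc > 1e-12:
                step = float(np.clip(step * target_step / inc, init_step / 4,
                                     max_step))
            else:
                step = min(step * 2.0, max_step)
            x, prev_d = x_new, d
        bounds_hit[direction] = hit_bound

    points.sort(key=lambda t: t[0])
    grid = np.array([10.0 ** x for x, _ in points])
    wvals = np.array([w for _, w in points])
    lower = 10.0 ** crossings[-1.0] if -1.0 in crossings else None
    upper = 10.0 ** crossings[+1.0] if +1.0 in crossings else None
    return ProfileResult(name=name, values=grid, wssr=wvals,
                         wssr_opt=results.wssr, threshold=threshold,
                         alpha=alpha, lower=lower, upper=upper,
                         flagged=flagged)


def profile_all(results, names=None, **kw) -> dict[str, ProfileResult]:
    names = names or results.model.param_names
    return {name: profile_parameter(results, name, **kw) for name in names}


def inactivation_contrast(profile_III: ProfileResult,
                          profile_I: ProfileResult) -> dict:
    """Compare the two receptor-complex inactivation rate confidence intervals.

    Returns ``significant=True`` when the type III inactivation rate's upper
    bound lies below the type I rate's lower bound (disjoint intervals with
    the type III rate smaller), ``False`` when not, and ``None``
    (indeterminate) when either profile is open-ended.
    """
    open_ended = (profile_III.identifiability != "identifiable"
                  or profile_I.identifiability != "identifiable")
    if open_ended:
        significant = None
    else:
        significant = bool(profile_III.upper < profile_I.lower)
    return {
        "significant": significant,
        "interval_III": profile_III.interval,
        "interval_I": profile_I.interval,
        "indeterminate": open_ended,
    }


# --------------------------------------------------------------------------
# sensitivities and confidence bands
# --------------------------------------------------------------------------


def finite_difference_sensitivity(func, params, rel_step: float = 1e-4):
    """Central-difference Jacobian of ``func(params) -> y`` w.r.t. ``params``.

    Column p holds d y / d params[p]; the step for each parameter is
    ``rel_step * |value|`` (absolute ``rel_step`` for zero values).
    """
    params = np.asarray(params, dtype=float)
    y0 = np.asarray(func(params), dtype=float)
    S = np.empty((y0.size, params.size))
    for p in range(params.size):
        h = rel_step * abs(params[p]) if params[p] != 0 else rel_step
        up, dn = params.copy(), params.copy()
        up[p] += h
        dn[p] -= h
        S[:, p] = (np.asarray(func(up)) - np.asarray(func(dn))) / (2 * h)
    return S


def sensitivity_matrix(network, params, observable, times,
                       param_names=None, rel_step: float = 1e-4,
                       condition=None, rtol=1e-8, atol=1e-10):
    """Sensitivity of a simulated observable to the named rate constants.

    ``S[t, p] = d observable(t) / d param_p`` by central finite differences
    at ``params``.  ``observable`` is a species name (default the ISG fold
    change) and ``condition`` the stimulus to simulate.
    """
    from .simulate import simulate

    observable = observable or "ISG_FC"
    param_names = list(param_names or [])
    if not param_names:
        raise ValueError("param_names must list the parameters to perturb")

    def f(vec):
        p = params.updated(dict(zip(param_names, vec)))
        traj = simulate(network, p, condition, times, rtol=rtol, atol=atol)
        return traj.states[observable].to_numpy()

    x0 = np.array([params.get(n) for n in param_names], dtype=float)
    return finite_difference_sensitivity(f, x0, rel_step=rel_step)


@dataclass
class ConfidenceBand:
    """Pointwise approximate band around a simulated trajectory."""

    times: np.ndarray
    central: np.ndarray
    half_width: np.ndarray
    kind: str
    alpha: float

    @property
    def lower(self) -> np.ndarray:
        return self.central - self.half_width

    @property
    def upper(self) -> np.ndarray:
        return self.central + self.half_width

    def plot(self, ax=None):
        """Central trajectory with its shaded band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.central, color="C0")
        ax.fill_between(self.times, self.lower, self.upper, alpha=0.25,
                        color="C0", label=f"approx {100 * self.alpha:g}% "
                        f"{self.kind} band")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("ISG fold change")
        ax.legend()
        return ax


def confidence_bands(central, S, mse: float, n_obs: int, n_params: int,
                     alpha: float = 0.95, kind: str = "prediction",
                     times=None, ridge: float = 0.0) -> ConfidenceBand:
    """Approximate pointwise band from a sensitivity matrix.

    half-width_t = t_{alpha} * sqrt(MSE * (1 + s_t (S'S)^{-1} s_t'))

    with the leading 1 dropped for ``kind="mean"`` (band for the mean
    response).  ``t_{alpha}`` is the two-sided Student-t quantile with
    ``n_obs - n_params`` degrees of freedom.
    """
    central = np.asarray(central, dtype=float)
    S = np.asarray(S, dtype=float)
    if kind not in ("prediction", "mean"):
        raise ValueError("kind must be 'prediction' or 'mean'")
    if n_obs <= n_params:
        raise ValueError("need n_obs > n_params")
    if mse < 0:
        raise ValueError("MSE must be non-negative")
    # a parameter with exactly zero sensitivity contributes nothing to the
    # band; drop such columns (e.g. the other pathway's rates) rather than
    # failing on a trivially singular Gram matrix
    active = np.max(np.abs(S), axis=0) > 0
    S = S[:, active]
    gram = S.T @ S + ridge * np.eye(S.shape[1])
    try:
        gram_inv = np.linalg.inv(gram)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "S'S is singular (a parameter has no effect on the observable); "
            "retry with ridge > 0 or drop the parameter") from None
    lev = np.einsum("ij,jk,ik->i", S, gram_inv, S)
    base = (1.0 + lev) if kind == "prediction" else lev
    tq = stats.t.ppf(1.0 - (1.0 - alpha) / 2.0, n_obs - n_params)
    half = tq * np.sqrt(mse * base)
    t = np.arange(len(central)) if times is None else np.asarray(times, float)
    return ConfidenceBand(t, central, half, kind, alpha)


def model_confidence_band(results, condition, times, alpha: float = 0.95,
                          kind: str = "prediction", rel_step: float = 1e-4,
                          ridge: float = 0.0) -> ConfidenceBand:
    """Band around a fitted model's ISG fold-change prediction."""
    model = results.model
    names = model.param_names
    S = sensitivity_matrix(model.network, results.params, "ISG_FC", times,
                           param_names=names, rel_step=rel_step,
                           condition=condition, rtol=model.rtol,
                           atol=model.atol)
    traj = results.simulate(condition, times, rtol=model.rtol, atol=model.atol)
    return confidence_bands(traj.fold_change, S, results.mse, results.n,
                            results.k, alpha=alpha, kind=kind, times=times,
                            ridge=ridge)
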