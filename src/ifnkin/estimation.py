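"""Weighted nonlinear least-squares calibration of the signalling model.

The central objects follow the statsmodels convention: an
:class:`IfnKineticsModel` is built from a :class:`~ifnkin.datasets.TimeCourseDataset`
and a model variant, and its :meth:`~IfnKineticsModel.fit` returns an
:class:`IfnKineticsResults` carrying the optimised parameters, the weighted
sum of squared residuals (wSSR), the (n, k) bookkeeping for AICc, optimiser
diagnostics, and accessors for profiles, confidence bands and simulation.

The objective is

    wSSR = sum_i (y_sim_i - y_obs_i)^2 / sigma_i^2,

minimised over the variant's free parameters in log10 space with box
bounds, from multiple Latin-hypercube start points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .datasets import TimeCourseDataset
from .network import (DEFAULT_FREE_GROUPS, RateConstants, build_network,
                      parameter_layout)
from .simulate import SpeciesState, StimulusCondition, Trajectory, simulate

__all__ = ["wssr", "IfnKineticsModel", "IfnKineticsResults",
           "fit", "fit_overexpression", "OverexpressionFit"]


def wssr(simulated, observed, sigma2) -> float:
    """Weighted sum of squared residuals, ``sum (y_sim - y_obs)^2 / sigma^2``."""
    simulated = np.asarray(simulated, dtype=float)
    observed = np.asarray(observed, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if not (simulated.shape == observed.shape == sigma2.shape):
        raise ValueError("simulated, observed and sigma2 must have equal shapes")
    if np.any(sigma2 <= 0):
        raise ValueError("variances must be positive")
    return float(np.sum((simulated - observed) ** 2 / sigma2))


class IfnKineticsModel:
    """Kinetic model of ISG induction, bound to a fold-change dataset.

    Parameters
    ----------
    dataset : TimeCourseDataset
        Observations to calibrate against.
    variant : str or ModelVariant
        Parameter-sharing hypothesis (M1-M4).
    config : NetworkConfig, optional
        Structural options of the reaction network.
    free_groups : sequence of str
        Parameter groups estimated from the data; the variant decides which
        of them are pathway-specific.  Everything else is held at
        ``base_params``.
    base_params : RateConstants, optional
        Fixed values and the centre of the multi-start initialisation.
    bounds_decades : float
        Half-width of the box bounds around the initial guess, in decades.
    rtol, atol : float
        ODE solver tolerances used while fitting.
    """

    def __init__(self, dataset: TimeCourseDataset, variant="M3", config=None,
                 free_groups=DEFAULT_FREE_GROUPS, base_params=None,
                 bounds_decades: float = 4.0, rtol: float = 1e-6,
                 atol: float = 1e-9):
        if not isinstance(dataset, TimeCourseDataset):
            dataset = TimeCourseDataset(dataset)
        self.dataset = dataset
        self.network = build_network(variant, config)
        self.variant = self.network.variant
        self.free_groups = tuple(free_groups)
        self.layout = parameter_layout(self.variant, self.free_groups)
        self.param_names = [e.name for e in self.layout]
        self.base_params = base_params or RateConstants()
        self.bounds_decades = float(bounds_decades)
        self.rtol, self.atol = rtol, atol
        # group rows per condition once, preserving row order for residuals
        df = dataset.df
        self._obs = df["mean_fc"].to_numpy()
        self._sigma = np.sqrt(df["sigma2"].to_numpy())
        self._blocks = []
        for cid, sub in df.groupby("condition_id", sort=False):
            cond = StimulusCondition(sub["ifn_type"].iloc[0],
                                     float(sub["dose_nM"].iloc[0]))
            order = np.argsort(sub["time_h"].to_numpy())
            self._blocks.append((cond, sub["time_h"].to_numpy()[order],
                                 sub.index.to_numpy()[order]))
        n, k = dataset.n_points, len(self.layout)
        if n <= k + 1:
            raise ValueError(
                f"dataset has n={n} points but the variant estimates k={k} "
                "parameters; AICc requires n > k + 1")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, weight_mode: str = "literal",
                       **kwargs) -> "IfnKineticsModel":
        return cls(TimeCourseDataset(df, weight_mode=weight_mode), **kwargs)

    # -- parameter mapping ----------------------------------------------------
    @property
    def theta0(self) -> np.ndarray:
        """Initial guess in log10 space, from ``base_params``."""
        return np.log10([self.base_params.get(n) for n in self.param_names])

    def params_from_theta(self, theta, factors=(1.0, 1.0)) -> RateConstants:
        values = dict(zip(self.param_names, 10.0 ** np.asarray(theta, dtype=float)))
        p = self.base_params.updated(values)
        if factors != (1.0, 1.0):
            p = p.updated({"r_tot_I": p.r_tot_I * factors[0],
                           "r_tot_III": p.r_tot_III * factors[1]})
        return p

    # -- objective ------------------------------------------------------------
    def _predict(self, params: RateConstants, factors=(1.0, 1.0)) -> np.ndarray:
        if factors != (1.0, 1.0):
            params = params.updated({"r_tot_I": params.r_tot_I * factors[0],
                                     "r_tot_III": params.r_tot_III * factors[1]})
        # zero-stimulus fixed point is available in closed form
        y0 = SpeciesState(self.network.species, self.network.reference_state(params))
        pred = np.empty(len(self._obs))
        for cond, times, rows in self._blocks:
            traj = simulate(self.network, params, cond, times,
                            rtol=self.rtol, atol=self.atol, y0=y0)
            pred[rows] = traj.fold_change
        return pred

    def residuals(self, theta) -> np.ndarray:
        pred = self._predict(self.params_from_theta(theta))
        return (pred - self._obs) / self._sigma

    def wssr_at(self, params: RateConstants) -> float:
        return wssr(self._predict(params), self._obs, self._sigma ** 2)

    # -- optimisation ---------------------------------------------------------
    def _minimise(self, x0, lb, ub, fixed_index=None, fixed_value=None,
                  ftol=1e-9, xtol=1e-9):
        """One bounded local optimisation; optionally with one coordinate fixed."""
        if fixed_index is None:
            fun = self.residuals
            x0_red, lb_red, ub_red = x0, lb, ub
        else:
            keep = np.arange(len(x0)) != fixed_index

            def fun(th_red):
                th = np.empty(len(x0))
                th[keep] = th_red
                th[fixed_index] = fixed_value
                return self.residuals(th)

            x0_red, lb_red, ub_red = x0[keep], lb[keep], ub[keep]
        sol = least_squares(fun, np.clip(x0_red, lb_red, ub_red),
                            bounds=(lb_red, ub_red), method="trf",
                            ftol=ftol, xtol=xtol, gtol=1e-10)
        if fixed_index is not None:
            th = np.empty(len(x0))
            th[np.arange(len(x0)) != fixed_index] = sol.x
            th[fixed_index] = fixed_value
        else:
            th = sol.x
        return th, float(2.0 * sol.cost), sol

    def fit(self, n_starts: int = 20, seed: int | None = None,
            spread_decades: float = 1.0, ftol: float = 1e-9) -> "IfnKineticsResults":
        """Best of ``n_starts`` bounded local optimisations.

        Start points are a seeded Latin-hypercube in log10 space of half-width
        ``spread_decades`` around the initial guess (the first start is the
        guess itself); box bounds are ``bounds_decades`` wide.  Deterministic
        for a fixed seed.
        """
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        theta0 = self.theta0
        lb, ub = theta0 - self.bounds_decades, theta0 + self.bounds_decades
        starts = [theta0]
        if n_starts > 1:
            sampler = qmc.LatinHypercube(d=len(theta0), seed=seed)
            unit = sampler.random(n_starts - 1)
            starts += list(theta0 + (2 * unit - 1) * spread_decades)
        records, best = [], None
        for i, x0 in enumerate(starts):
            try:
                th, w, sol = self._minimise(np.asarray(x0), lb, ub, ftol=ftol)
                records.append({"start": i, "wssr": w, "success": bool(sol.success),
                                "nfev": int(sol.nfev), "message": sol.message})
                if best is None or w < best[1]:
                    best = (th, w)
            except Exception as err:
                records.append({"start": i, "wssr": np.inf, "success": False,
                                "nfev": 0, "message": str(err)})
        if best is None or not np.isfinite(best[1]):
            raise RuntimeError(f"no optimisation start converged: {records}")
        theta, w = best
        return IfnKineticsResults(self, theta, w, records, seed)


class IfnKineticsResults:
    """Optimised fit of one model variant: estimates, wSSR, AICc bookkeeping."""

    def __init__(self, model: IfnKineticsModel, theta, wssr_value, start_records,
                 seed=None):
        self.model = model
        self.theta = np.asarray(theta, dtype=float)
        self.wssr = float(wssr_value)
        self.start_records = start_records
        self.seed = seed
        self.n = model.dataset.n_points
        self.k = len(model.layout)
        self.params = model.params_from_theta(self.theta)

    @property
    def variant(self) -> str:
        return self.model.variant.name

    @property
    def estimates(self) -> pd.Series:
        return pd.Series(10.0 ** self.theta, index=self.model.param_names,
                         name="estimate")

    @property
    def aicc(self) -> float:
        from .selection import aicc
        return aicc(self.wssr, self.n, self.k)

    @property
    def mse(self) -> float:
        """wSSR / (n - k), the mean squared (weighted) error."""
        return self.wssr / (self.n - self.k)

    def simulate(self, condition: StimulusCondition, times, **kw) -> Trajectory:
        return simulate(self.model.network, self.params, condition, times, **kw)

    def profile(self, name, **kw):
        from .uncertainty import profile_parameter
        return profile_parameter(self, name, **kw)

    def confidence_band(self, condition, times, alpha=0.95, kind="prediction", **kw):
        from .uncertainty import model_confidence_band
        return model_confidence_band(self, condition, times, alpha=alpha,
                                     kind=kind, **kw)

    def plot_fit(self, times=None, ax=None):
        """Overlay the fitted trajectories on the calibration data."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(0.0, 24.0, 97) if times is None else times
        for cond, t_obs, rows in self.model._blocks:
            traj = self.simulate(cond, grid, rtol=self.model.rtol,
                                 atol=self.model.atol)
            line, = ax.plot(grid, traj.fold_change, label=cond.label())
            ax.errorbar(t_obs, self.model._obs[rows],
                        yerr=self.model._sigma[rows], fmt="o",
                        color=line.get_color())
        ax.set_xlabel("time (h)")
        ax.set_ylabel("ISG fold change")
        ax.legend(fontsize="x-small")
        return ax

    def summary(self) -> str:
        lines = [
            "IFN signalling kinetics — weighted least squares",
            "=" * 56,
            f"variant: {self.variant}    n points: {self.n}    "
            f"k params: {self.k}",
            f"wSSR: {self.wssr:.6g}    AICc: {self.aicc:.6g}    "
            f"MSE: {self.mse:.6g}",
            "-" * 56,
            f"{'parameter':<14s}{'estimate':>14s}{'log10':>10s}",
        ]
        for name, value, lg in zip(self.model.param_names,
                                   10.0 ** self.theta, self.theta):
            lines.append(f"{name:<14s}{value:>14.6g}{lg:>10.3f}")
        lines.append("-" * 56)
        n_ok = sum(1 for r in self.start_records if r["success"])
        lines.append(f"starts: {len(self.start_records)} "
                     f"({n_ok} converged), seed={self.seed}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({
            "variant": self.variant,
            "free_parameters": dict(zip(self.model.param_names,
                                        map(float, 10.0 ** self.theta))),
            "all_parameters": {k: float(v) for k, v in
                               self.params.to_dict().items()},
            "wssr": self.wssr, "n": self.n, "k": self.k,
            "aicc": self.aicc, "seed": self.seed,
            "starts": self.start_records,
        }, indent=2, default=str)


def fit(dataset, variant="M3", n_starts: int = 20, seed: int | None = None,
        **model_kwargs) -> IfnKineticsResults:
    """Convenience wrapper: build :class:`IfnKineticsModel` and fit it."""
    return IfnKineticsModel(dataset, variant=variant, **model_kwargs).fit(
        n_starts=n_starts, seed=seed)


@dataclass
class OverexpressionFit:
    """Receptor-abundance scaling factors fitted to overexpression data."""

    factor_I: float
    factor_III: float
    wssr: float
    n: int

    def summary(self) -> str:
        return (f"receptor overexpression re-fit: IFNAR x{self.factor_I:.3g}, "
                f"IFNLR x{self.factor_III:.3g} (wSSR {self.wssr:.4g}, "
                f"n {self.n})")


def fit_overexpression(base_results: IfnKineticsResults,
                       dataset: TimeCourseDataset,
                       free=("factor_I", "factor_III"),
                       bounds_decades: float = 2.0) -> OverexpressionFit:
    """Re-fit only the receptor abundances to an overexpression dataset.

    All kinetic rates stay frozen at the base fit's optimum; the only free
    quantities are the two multiplicative receptor-abundance factors.
    Requesting anything else in ``free`` is rejected.
    """
    if set(free) - {"factor_I", "factor_III"}:
        raise ValueError("only the receptor-abundance factors may be re-fit; "
                         "kinetic rates are frozen at the base optimum")
    if not isinstance(dataset, TimeCourseDataset):
        dataset = TimeCourseDataset(dataset)
    base_model = base_results.model
    model = IfnKineticsModel(
        dataset, variant=base_model.variant, config=base_model.network.config,
        free_groups=base_model.free_groups, base_params=base_results.params,
        rtol=base_model.rtol, atol=base_model.atol)

    free_I = "factor_I" in free
    free_III = "factor_III" in free
    obs = model._obs
    sig2 = model._sigma ** 2

    def objective(logf):
        i = 0
        fI = 10.0 ** logf[i] if free_I else 1.0
        i += free_I
        fIII = 10.0 ** logf[i] if free_III else 1.0
        pred = model._predict(base_results.params, factors=(fI, fIII))
        return (pred - obs) / model._sigma

    d = free_I + free_III
    sol = least_squares(objective, np.zeros(d),
                        bounds=(-bounds_decades * np.ones(d),
                                bounds_decades * np.ones(d)),
                        method="trf", ftol=1e-10, xtol=1e-10)
    i = 0
    fI = 10.0 ** sol.x[i] if free_I else 1.0
    i += free_I
    fIII = 10.0 ** sol.x[i] if free_III else 1.0
    return OverexpressionFit(float(fI), float(fIII), float(2 * sol.cost),
                             len(obs))
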