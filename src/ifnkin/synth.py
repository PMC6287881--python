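"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the study's designs: dose- and time-resolved Viperin
fold-change qPCR courses under type I IFN, type III IFN and a high-affinity
type III variant; a 132-gene ISG panel over 3/6/12/24 h with four planted
temporal groups; VSV-luciferase protection assays; and paired
baseline/receptor-overexpression time courses.  Every generator is a pure
function of its configuration (seed included) and stores its ground truth
for recovery experiments.

Replicate noise is Gaussian on the linear fold-change scale with standard
deviation mean x CV, truncated at zero — the noise model implied by the
variance-weighting recipe used in calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import TimeCourseDataset
from .network import RateConstants, build_network
from .simulate import EXPERIMENTAL_TIMES, SpeciesState, StimulusCondition, simulate

__all__ = [
    "GeneratorConfig",
    "generate_viperin_dataset",
    "generate_isg_panel",
    "generate_infection_assay",
    "generate_overexpression_dataset",
]

#: archetype kinetic templates over 3/6/12/24 h, one per temporal group
GROUP_TEMPLATES = {
    1: np.array([10.0, 5.0, 2.5, 1.5]),   # peak at 3 h
    2: np.array([4.0, 10.0, 5.0, 2.5]),   # peak at 6 h
    3: np.array([2.0, 5.0, 10.0, 6.0]),   # peak at 12 h
    4: np.array([1.5, 3.0, 6.0, 12.0]),   # continuous increase to 24 h
}


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic experiments.

    Defaults mirror the study design: working doses 0.33 nM (type I) and
    13.7 nM (type III), the 3/6/12/24 h sampling grid, triplicates with an
    average CV of 0.2, a 132-gene panel, and receptor-overexpression factors
    of 2.6 (IFNAR) and 1.5 (IFNLR).
    """

    seed: int = 0
    variant: str = "M3"
    truth: RateConstants = field(default_factory=RateConstants)
    doses_I: tuple = (0.01, 0.033, 0.1, 0.33)
    doses_III: tuple = (0.0137, 0.137, 1.37, 13.7)
    doses_H11: tuple = ()
    times: tuple = EXPERIMENTAL_TIMES
    n_rep: int = 3
    cv: float = 0.2
    # ISG panel
    panel_size: int = 132
    group_proportions: tuple = (0.25, 0.25, 0.25, 0.25)
    noninduced_fraction: float = 0.5
    amplitude_ratio_I_over_III: float = 3.0
    type_III_group4_bias: float = 0.6
    panel_cv: float = 0.1
    # infection assays
    ec90_I: float = 0.05         # nM
    ec90_III: float = 5.0        # nM
    hill_slope: float = 1.2
    plateau_III: float = 20.0    # % residual infection floor, type III
    assay_cv: float = 0.05
    protection_tau_I: float = 1.1     # h, pre-treatment protection kinetics
    protection_tau_III: float = 3.5
    postinfection_t50_I: float = 4.0  # h, latest effective delay midpoint
    postinfection_t50_III: float = 1.5
    # overexpression
    factor_I: float = 2.6
    factor_III: float = 1.5

    def __post_init__(self):
        if self.cv <= 0 or self.panel_cv < 0:
            raise ValueError("CV must be positive")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        if not 0 <= self.noninduced_fraction <= 1:
            raise ValueError("noninduced_fraction must be in [0, 1]")


def _noisy_replicates(rng, mean, cv, n_rep):
    """Truncated-Gaussian replicates with sd = mean * cv."""
    draws = rng.normal(mean, np.abs(mean) * cv, size=n_rep)
    return np.maximum(draws, 0.0)


def _conditions(config: GeneratorConfig):
    conds = []
    for d in config.doses_I:
        conds.append(StimulusCondition("I", d))
    for d in config.doses_III:
        conds.append(StimulusCondition("III", d))
    for d in config.doses_H11:
        conds.append(StimulusCondition("III-HA", d))
    return conds


def _simulate_dataset(config: GeneratorConfig, params: RateConstants,
                      rng) -> TimeCourseDataset:
    network = build_network(config.variant)
    y0 = SpeciesState(network.species, network.reference_state(params))
    times = np.asarray(config.times, dtype=float)
    records = []
    for cond in _conditions(config):
        traj = simulate(network, params, cond, times, y0=y0)
        for t, fc in zip(times, traj.fold_change):
            reps = _noisy_replicates(rng, fc, config.cv, config.n_rep)
            records.append({
                "condition_id": cond.label(), "ifn_type": cond.ifn_type,
                "dose_nM": cond.dose, "time_h": t,
                "mean_fc": float(np.mean(reps)), "n_rep": config.n_rep,
                "cv": config.cv,
            })
    df = pd.DataFrame.from_records(records)
    # replicate means can graze zero at high CV; keep weights definable
    df["mean_fc"] = df["mean_fc"].clip(lower=1e-6)
    return TimeCourseDataset(df)


def generate_viperin_dataset(config: GeneratorConfig | None = None) -> TimeCourseDataset:
    """Dose/time-resolved Viperin-like fold-change course from the truth model.

    Simulates the configured truth parameters for every (IFN, dose)
    condition on the experimental time grid and draws ``n_rep`` noisy
    replicates per point.  The truth is available as ``dataset.truth``.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    ds = _simulate_dataset(config, config.truth, rng)
    ds.truth = config.truth
    ds.config = config
    return ds


def generate_overexpression_dataset(config: GeneratorConfig | None = None):
    """Paired (baseline, receptor-overexpressing) datasets.

    The overexpressing arm scales the receptor abundances by the configured
    factors with every kinetic rate identical; both arms share the same
    noise stream, so with factors (1, 1) the pair is byte-identical.
    """
    config = config or GeneratorConfig()
    baseline = _simulate_dataset(config, config.truth,
                                 np.random.default_rng(config.seed))
    ox_truth = replace(config.truth,
                       r_tot_I=config.truth.r_tot_I * config.factor_I,
                       r_tot_III=config.truth.r_tot_III * config.factor_III)
    overexpressing = _simulate_dataset(config, ox_truth,
                                       np.random.default_rng(config.seed))
    for ds in (baseline, overexpressing):
        ds.config = config
    baseline.truth = config.truth
    overexpressing.truth = ox_truth
    overexpressing.true_factors = (config.factor_I, config.factor_III)
    return baseline, overexpressing


def generate_isg_panel(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """ISG panel over 3/6/12/24 h with four planted temporal groups.

    Induced genes draw a kinetic archetype (peaks at 3/6/12 h or monotone
    increase) and a log-normal amplitude; the type I arm is stronger than
    the type III arm by the configured factor, and the type III arm's
    archetypes are biased toward the late (group 4) pattern.  A configured
    fraction of genes stays non-induced (fold changes within the 2-fold
    band).  Columns: gene, ifn_type, time_h, fold_change, plus the planted
    labels ``true_group`` (per arm; 0 marks non-induced genes).
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.times, dtype=float)
    n = config.panel_size
    n_flat = int(round(n * config.noninduced_fraction))
    genes = [f"ISG{i + 1:03d}" for i in range(n)]
    induced = np.zeros(n, dtype=bool)
    induced[: n - n_flat] = True
    groups_I = rng.choice([1, 2, 3, 4], size=n, p=config.group_proportions)

    rows = []
    for i, gene in enumerate(genes):
        if not induced[i]:
            for ifn in ("I", "III"):
                profile = 1.0 + rng.uniform(-0.25, 0.25, size=len(times))
                for t, fc in zip(times, profile):
                    rows.append((gene, ifn, t, max(fc, 0.05), 0))
            continue
        g_I = int(groups_I[i])
        # type III arm: same gene, group biased toward the late pattern
        if g_I != 4 and rng.random() < config.type_III_group4_bias:
            g_III = 4
        else:
            g_III = g_I
        amp_I = float(np.exp(rng.normal(np.log(1.5), 0.5)))
        amp_III = amp_I / config.amplitude_ratio_I_over_III
        for ifn, g, amp in (("I", g_I, amp_I), ("III", g_III, amp_III)):
            base = GROUP_TEMPLATES[g] * amp
            noise = np.exp(rng.normal(0.0, np.log1p(config.panel_cv),
                                      size=len(times)))
            profile = base * noise if config.panel_cv > 0 else base
            for t, fc in zip(times, profile):
                rows.append((gene, ifn, t, float(fc), g))
    return pd.DataFrame(rows, columns=["gene", "ifn_type", "time_h",
                                       "fold_change", "true_group"])


def _four_pl(dose, top, bottom, ec50, slope):
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** slope)


def _ec50_from_ec90(ec90, top, bottom, slope, target=10.0):
    # solve 4PL(dose)=target for ec50 given the dose is the EC90
    ratio = (top - bottom) / (target - bottom) - 1.0
    return ec90 / ratio ** (1.0 / slope)


def generate_infection_assay(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """VSV-luciferase protection assays: dose-response and timing arms.

    The dose-response arm follows a four-parameter logistic with the
    configured EC90 per IFN; the type III arm plateaus above zero residual
    infection (partial protection).  The pre-treatment arm decays
    exponentially with the configured time constants (type I faster) and
    the post-infection arm rises logistically with the configured midpoint
    delays.  Columns: arm, ifn_type, x_value, x_unit,
    relative_infection_pct, n_rep.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    rows = []
    doses = np.geomspace(1e-4, 30.0, 25)
    for ifn, ec90, bottom in (("I", config.ec90_I, 0.0),
                              ("III", config.ec90_III, config.plateau_III)):
        ec50 = _ec50_from_ec90(ec90, 100.0, bottom, config.hill_slope) \
            if bottom < 10.0 else config.ec90_III
        for d in doses:
            mean = _four_pl(d, 100.0, bottom, ec50, config.hill_slope)
            reps = _noisy_replicates(rng, mean, config.assay_cv, config.n_rep)
            rows.append(("dose-response", ifn, d, "nM",
                         float(np.mean(reps)), config.n_rep))
    pre_times = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0])
    for ifn, tau in (("I", config.protection_tau_I),
                     ("III", config.protection_tau_III)):
        for t in pre_times:
            mean = 100.0 * np.exp(-t / tau)
            reps = _noisy_replicates(rng, mean, config.assay_cv, config.n_rep)
            rows.append(("pre-treatment", ifn, t, "h",
                         float(np.mean(reps)), config.n_rep))
    delays = np.array([0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0])
    for ifn, t50 in (("I", config.postinfection_t50_I),
                     ("III", config.postinfection_t50_III)):
        for d in delays:
            mean = 100.0 / (1.0 + np.exp(-(d - t50) / 0.5))
            reps = _noisy_replicates(rng, mean, config.assay_cv, config.n_rep)
            rows.append(("post-infection", ifn, d, "h",
                         float(np.mean(reps)), config.n_rep))
    return pd.DataFrame(rows, columns=["arm", "ifn_type", "x_value", "x_unit",
                                       "relative_infection_pct", "n_rep"])
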