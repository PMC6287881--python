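"""Two-pathway interferon signalling network.

Type I IFN signals through the IFNAR receptor complex, type III IFN through
the IFNLR complex.  Ligand-bound (active) receptor complexes drive STAT
phosphorylation; phosphorylated STAT (p-STAT) drives transcription of
interferon-stimulated genes (ISGs), reported as fold change over the
untreated steady state.  Active complexes desensitise (are inactivated) with
pathway-specific first-order kinetics and slowly recycle; receptors turn
over; extracellular IFN decays.  The four model variants M1-M4 share this
network and differ only in which kinetic rates are allowed to differ between
the two pathways (receptor abundance is pathway-specific in every variant).

Units: concentrations in nM, time in hours.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.integrate import odeint
from scipy.optimize import root

__all__ = [
    "cell_surface_area",
    "copies_to_nanomolar",
    "CellGeometry",
    "ModelVariant",
    "VARIANTS",
    "NetworkConfig",
    "RateConstants",
    "ParameterEntry",
    "parameter_layout",
    "ReactionNetwork",
    "build_network",
    "SpeciesState",
]

AVOGADRO = 6.02214076e23

#: default cell volume in liters
V_CELL = 2e-9


def cell_surface_area(volume: float) -> float:
    """Surface measure of a sphere-equivalent cell, ``(36*pi)**(1/3) * V**(2/3)``.

    Parameters
    ----------
    volume : float
        Cell volume in liters; must be positive.
    """
    if not np.all(np.asarray(volume) > 0):
        raise ValueError("cell volume must be positive")
    return (36.0 * math.pi) ** (1.0 / 3.0) * np.asarray(volume) ** (2.0 / 3.0)


def copies_to_nanomolar(copies: float, volume: float = V_CELL) -> float:
    """Convert receptor copies per cell to a cell-volume concentration in nM."""
    if not np.all(np.asarray(volume) > 0):
        raise ValueError("cell volume must be positive")
    return np.asarray(copies) / (AVOGADRO * volume) * 1e9


@dataclass(frozen=True)
class CellGeometry:
    """Cell volume (liters) and its derived surface measure."""

    volume: float = V_CELL

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")

    @property
    def area(self) -> float:
        return float(cell_surface_area(self.volume))


# --------------------------------------------------------------------------
# model variants
# --------------------------------------------------------------------------

#: parameter groups that may be split (pathway-specific) by a variant
SPLITTABLE_GROUPS = ("k_act", "k_inact", "k_stat", "isg_gain")

#: groups estimated by default (receptor abundance "R" is always split)
DEFAULT_FREE_GROUPS = ("R", "k_act", "k_inact", "isg_gain", "k_isg_deg")

#: rate-only estimation preset: receptor abundances held at their set values
#: (as in calibration against measured receptor levels) and one amplitude
#: parameter per chain; avoids the amplitude ridge of jointly free abundance
#: and transcription gain when the ISG response operates near-linearly
RATE_FREE_GROUPS = ("k_act", "k_inact", "isg_gain", "k_isg_deg",
                    "efficacy_III")


@dataclass(frozen=True)
class ModelVariant:
    """A parameter-sharing hypothesis between the two IFN pathways.

    ``split_groups`` lists the kinetic-rate groups that take independent
    values for the IFNAR and IFNLR pathways; everything else is shared.
    Receptor abundance is pathway-specific in every variant.
    """

    name: str
    split_groups: frozenset[str] = frozenset()

    def __post_init__(self):
        unknown = self.split_groups - set(SPLITTABLE_GROUPS)
        if unknown:
            raise ValueError(f"unknown splittable groups: {sorted(unknown)}")

    def n_free(self, free_groups=DEFAULT_FREE_GROUPS) -> int:
        return len(parameter_layout(self, free_groups))


VARIANTS: dict[str, ModelVariant] = {
    "M1": ModelVariant("M1", frozenset()),
    "M2": ModelVariant("M2", frozenset({"k_stat"})),
    "M3": ModelVariant("M3", frozenset({"k_act", "k_inact"})),
    "M4": ModelVariant("M4", frozenset({"isg_gain"})),
}


def get_variant(variant) -> ModelVariant:
    if isinstance(variant, ModelVariant):
        return variant
    try:
        return VARIANTS[str(variant)]
    except KeyError:
        raise ValueError(
            f"unknown model variant {variant!r}; expected one of {sorted(VARIANTS)}"
        ) from None


@dataclass(frozen=True)
class ParameterEntry:
    """One independently estimated parameter in a variant's layout."""

    name: str        # resolved attribute name on RateConstants
    group: str       # group it belongs to ("R", "k_act", ...)
    pathway: str     # "I", "III" or "shared"


def parameter_layout(variant, free_groups=DEFAULT_FREE_GROUPS) -> list[ParameterEntry]:
    """Ordered list of independently estimated parameters for a variant.

    The receptor abundance group ``R`` is always pathway-specific.  A kinetic
    group in ``variant.split_groups`` contributes one entry per pathway;
    otherwise a single shared entry.  The length of the returned list is the
    parameter count ``k`` entering the AICc.  Deterministic ordering:
    group order as listed in ``free_groups``, pathway I before III.
    """
    variant = get_variant(variant)
    layout: list[ParameterEntry] = []
    for group in free_groups:
        if group == "R":
            layout.append(ParameterEntry("r_tot_I", "R", "I"))
            layout.append(ParameterEntry("r_tot_III", "R", "III"))
        elif group in variant.split_groups:
            layout.append(ParameterEntry(f"{group}_I", group, "I"))
            layout.append(ParameterEntry(f"{group}_III", group, "III"))
        elif group in SPLITTABLE_GROUPS:
            # shared: stored on both pathway slots, estimated once
            layout.append(ParameterEntry(group, group, "shared"))
        else:
            layout.append(ParameterEntry(group, group, "shared"))
    # a variant split of a group held fixed otherwise frees the pathway-III
    # value (the pathway difference); the type I value stays structural
    for group in SPLITTABLE_GROUPS:
        if group in variant.split_groups and group not in free_groups:
            layout.append(ParameterEntry(f"{group}_III", group, "III"))
    return layout


# --------------------------------------------------------------------------
# rate constants
# --------------------------------------------------------------------------


@dataclass
class RateConstants:
    """Fully resolved per-pathway kinetic parameters (nM, hours).

    Pathway-splittable groups are stored resolved (``*_I``, ``*_III``); a
    shared group simply holds equal values in both slots.  Defaults are the
    package's reference parameterisation: an M3-style asymmetry with more
    abundant IFNAR complexes, slower activation and roughly ten-fold slower
    inactivation of the IFNLR complex, matching the qualitative structure the
    temporal ISG data support.
    """

    r_tot_I: float = 0.05      # IFNAR complex abundance, nM
    r_tot_III: float = 0.02    # IFNLR complex abundance, nM
    k_act_I: float = 10.0      # receptor activation, 1/(nM h)
    k_act_III: float = 8.0
    k_inact_I: float = 0.3     # active-complex inactivation (k11-like), 1/h
    k_inact_III: float = 0.03  # active-complex inactivation (k2-like), 1/h
    k_rec: float = 0.03        # desensitised-receptor recycling, 1/h
    k_rdeg: float = 0.02       # receptor turnover (synthesis/degradation), 1/h
    k_ifn_deg: float = 0.05    # extracellular IFN degradation, 1/h
    k_stat_I: float = 10.0     # STAT phosphorylation by active complexes, 1/(nM h)
    k_stat_III: float = 10.0
    k_dephos: float = 10.0     # p-STAT dephosphorylation, 1/h
    isg_gain_I: float = 200.0  # maximal fold-amplitude of ISG transcription
    isg_gain_III: float = 200.0
    k_isg_deg: float = 0.25    # ISG transcript decay, 1/h
    stat_tot: float = 1.0      # total STAT pool, nM
    K_pstat: float = 0.2       # half-saturation of p-STAT -> ISG driving, nM
    efficacy_III: float = 0.909  # IFNLR efficacy factor
    h11_scale: float = 3.0     # high-affinity type III variant, scales k_act_III
    fb_syn: float = 0.1        # feedback synthesis, 1/h (feedback networks only)
    fb_deg: float = 0.2        # feedback decay, 1/h
    fb_strength: float = 1.0   # feedback inhibition strength, 1/nM

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"rate constant {f.name} must be positive")

    # -- group access helpers -------------------------------------------------
    def get(self, name: str) -> float:
        if hasattr(self, name):
            return getattr(self, name)
        if name in SPLITTABLE_GROUPS:  # shared group: both slots equal
            return getattr(self, f"{name}_I")
        raise KeyError(name)

    def updated(self, values: dict[str, float]) -> "RateConstants":
        """Return a copy with named parameters replaced.

        A bare group name (e.g. ``"k_act"``) sets both pathway slots.
        """
        kwargs = {}
        for name, value in values.items():
            if name in SPLITTABLE_GROUPS:
                kwargs[f"{name}_I"] = value
                kwargs[f"{name}_III"] = value
            else:
                kwargs[name] = value
        return replace(self, **kwargs)

    def symmetric(self) -> "RateConstants":
        """Copy with all pathway-specific rates (not abundances) equalised."""
        return replace(
            self,
            k_act_III=self.k_act_I,
            k_inact_III=self.k_inact_I,
            k_stat_III=self.k_stat_I,
            isg_gain_III=self.isg_gain_I,
            efficacy_III=1.0,
        )

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "RateConstants":
        return cls(**d)


# --------------------------------------------------------------------------
# network
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkConfig:
    """Structural options of the reaction network.

    feedback
        Include an ISG-driven first-order inhibitor of STAT phosphorylation.
    hill_n
        Hill coefficient of the p-STAT -> ISG transcription term.
    stat_shared
        Single unphosphorylated STAT pool feeding both pathways (default) or
        duplicated per-pathway pools.
    receptor_turnover
        Receptor synthesis/degradation active; disabling it conserves total
        receptor mass per pathway.
    ifn_depletion
        Let receptor binding consume extracellular IFN (off: abundant bath).
    """

    feedback: bool = False
    hill_n: float = 1.0
    stat_shared: bool = True
    receptor_turnover: bool = True
    ifn_depletion: bool = False
    geometry: CellGeometry = field(default_factory=CellGeometry)


class SpeciesState(dict):
    """Named species concentrations (nM); a thin dict with array access."""

    def __init__(self, species: list[str], values):
        super().__init__(zip(species, np.asarray(values, dtype=float)))
        self.species = list(species)

    @property
    def array(self) -> np.ndarray:
        return np.array([self[s] for s in self.species], dtype=float)


class ReactionNetwork:
    """The reaction network for a given variant and structural configuration.

    Species and reactions are identical across variants M1-M4; variants only
    change the parameter-sharing map (hence the free-parameter layout used by
    estimation and model selection).
    """

    def __init__(self, variant="M3", config: NetworkConfig | None = None):
        self.variant = get_variant(variant)
        self.config = config or NetworkConfig()
        species = ["IFN_I", "IFN_III", "R_I", "R_III", "RA_I", "RA_III",
                   "RIN_I", "RIN_III"]
        if self.config.stat_shared:
            species += ["STAT"]
        else:
            species += ["STAT_I", "STAT_III"]
        species += ["PSTAT_I", "PSTAT_III", "ISG_FC"]
        if self.config.feedback:
            species += ["FB"]
        self.species = species
        self.index = {s: i for i, s in enumerate(species)}
        self.n_species = len(species)

    # -- layout ---------------------------------------------------------------
    def parameter_layout(self, free_groups=DEFAULT_FREE_GROUPS):
        return parameter_layout(self.variant, free_groups)

    # -- right-hand side ------------------------------------------------------
    def make_rhs(self, params: RateConstants, high_affinity: bool = False):
        """Return ``f(y, t) -> dy/dt`` with parameters bound as locals.

        ``high_affinity`` applies the affinity-scaling factor of the
        engineered high-affinity type III variant to the IFNLR activation
        rate; nothing else changes.
        """
        cfg = self.config
        p = params
        a_I = p.k_act_I
        a_III = p.k_act_III * (p.h11_scale if high_affinity else 1.0)
        ki_I, ki_III = p.k_inact_I, p.k_inact_III
        krec = p.k_rec
        krd = p.k_rdeg if cfg.receptor_turnover else 0.0
        kifn = p.k_ifn_deg
        ks_I = p.k_stat_I
        ks_III = p.k_stat_III * p.efficacy_III
        kd = p.k_dephos
        g_I, g_III = p.isg_gain_I, p.isg_gain_III
        kg = p.k_isg_deg
        Kp = p.K_pstat
        n = cfg.hill_n
        rt_I, rt_III = p.r_tot_I, p.r_tot_III
        stat_tot = p.stat_tot
        shared = cfg.stat_shared
        feedback = cfg.feedback
        depletion = cfg.ifn_depletion
        fbs, fbd, fbw = p.fb_syn, p.fb_deg, p.fb_strength
        nsp = self.n_species

        def rhs(y, t=0.0):
            (ifn_I, ifn_III, r_I, r_III, ra_I, ra_III, rin_I, rin_III) = y[:8]
            if shared:
                stat = y[8]
                ps_I, ps_III, isg = y[9], y[10], y[11]
                fb = y[12] if feedback else 0.0
            else:
                stat_I, stat_III = y[8], y[9]
                ps_I, ps_III, isg = y[10], y[11], y[12]
                fb = y[13] if feedback else 0.0

            bind_I = a_I * ifn_I * r_I
            bind_III = a_III * ifn_III * r_III

            dy = np.empty(nsp)
            dy[0] = -kifn * ifn_I - (bind_I if depletion else 0.0)
            dy[1] = -kifn * ifn_III - (bind_III if depletion else 0.0)
            dy[2] = krd * (rt_I - r_I) - bind_I + krec * rin_I
            dy[3] = krd * (rt_III - r_III) - bind_III + krec * rin_III
            dy[4] = bind_I - (ki_I + krd) * ra_I
            dy[5] = bind_III - (ki_III + krd) * ra_III
            dy[6] = ki_I * ra_I - (krec + krd) * rin_I
            dy[7] = ki_III * ra_III - (krec + krd) * rin_III

            inhib = 1.0 / (1.0 + fbw * fb) if feedback else 1.0
            if shared:
                phos_I = ks_I * ra_I * stat * inhib
                phos_III = ks_III * ra_III * stat * inhib
                dy[8] = -(phos_I + phos_III) + kd * (ps_I + ps_III)
                i0 = 9
            else:
                phos_I = ks_I * ra_I * stat_I * inhib
                phos_III = ks_III * ra_III * stat_III * inhib
                dy[8] = -phos_I + kd * ps_I
                dy[9] = -phos_III + kd * ps_III
                i0 = 10
            dy[i0] = phos_I - kd * ps_I
            dy[i0 + 1] = phos_III - kd * ps_III
            if n == 1.0:
                h_I = ps_I / (Kp + ps_I)
                h_III = ps_III / (Kp + ps_III)
            else:
                h_I = ps_I ** n / (Kp ** n + ps_I ** n)
                h_III = ps_III ** n / (Kp ** n + ps_III ** n)
            dy[i0 + 2] = kg * (1.0 + g_I * h_I + g_III * h_III - isg)
            if feedback:
                dy[i0 + 3] = fbs * (isg - 1.0) - fbd * fb
            return dy

        return rhs

    # -- steady state ---------------------------------------------------------
    def reference_state(self, params: RateConstants) -> np.ndarray:
        """Canonical zero-stimulus state used to seed steady-state search."""
        y = np.zeros(self.n_species)
        y[self.index["R_I"]] = params.r_tot_I
        y[self.index["R_III"]] = params.r_tot_III
        if self.config.stat_shared:
            y[self.index["STAT"]] = params.stat_tot
        else:
            y[self.index["STAT_I"]] = params.stat_tot
            y[self.index["STAT_III"]] = params.stat_tot
        y[self.index["ISG_FC"]] = 1.0
        return y

    def steady_state(self, params: RateConstants, tol: float = 1e-8,
                     horizon: float = 1e4) -> SpeciesState:
        """Zero-stimulus steady state of the network.

        Integrates over a long horizon from the canonical state, then applies
        a Newton polish on the derivative map.  The returned state satisfies
        ``max |dy/dt| < tol`` (nM/h) and has ISG fold change exactly 1.
        """
        rhs = self.make_rhs(params)
        y0 = self.reference_state(params)
        y = odeint(rhs, y0, [0.0, horizon], rtol=1e-10, atol=1e-12)[-1]
        sol = root(lambda v: rhs(v), y, method="hybr", tol=1e-13)
        if np.max(np.abs(rhs(sol.x))) < np.max(np.abs(rhs(y))):
            y = sol.x
        resid = float(np.max(np.abs(rhs(y))))
        if resid >= tol:
            raise RuntimeError(
                f"steady state did not converge: max |dy/dt| = {resid:.3e} nM/h"
            )
        return SpeciesState(self.species, y)

    def derivative_residual(self, params: RateConstants, state) -> float:
        """Max-norm of the derivative vector at ``state`` (zero stimulus)."""
        y = state.array if isinstance(state, SpeciesState) else np.asarray(state)
        return float(np.max(np.abs(self.make_rhs(params)(y))))

    # -- serialization --------------------------------------------------------
    def to_json(self, params: RateConstants | None = None) -> str:
        doc = {
            "variant": self.variant.name,
            "config": {
                "feedback": self.config.feedback,
                "hill_n": self.config.hill_n,
                "stat_shared": self.config.stat_shared,
                "receptor_turnover": self.config.receptor_turnover,
                "ifn_depletion": self.config.ifn_depletion,
                "volume_L": self.config.geometry.volume,
            },
            "units": {"concentration": "nM", "time": "h"},
        }
        if params is not None:
            doc["parameters"] = {k: repr(v) for k, v in params.to_dict().items()}
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str):
        doc = json.loads(text)
        cfg = doc.get("config", {})
        config = NetworkConfig(
            feedback=cfg.get("feedback", False),
            hill_n=cfg.get("hill_n", 1.0),
            stat_shared=cfg.get("stat_shared", True),
            receptor_turnover=cfg.get("receptor_turnover", True),
            ifn_depletion=cfg.get("ifn_depletion", False),
            geometry=CellGeometry(cfg.get("volume_L", V_CELL)),
        )
        network = cls(doc.get("variant", "M3"), config)
        params = None
        if "parameters" in doc:
            params = RateConstants.from_dict(
                {k: float(v) for k, v in doc["parameters"].items()}
            )
        return network, params


def build_network(variant="M3", config: NetworkConfig | None = None,
                  **config_kwargs) -> ReactionNetwork:
    """Construct the IFN signalling network for a model variant.

    ``config_kwargs`` are forwarded to :class:`NetworkConfig` when ``config``
    is not given (e.g. ``feedback=True``, ``hill_n=2``).
    """
    if config is None and config_kwargs:
        config = NetworkConfig(**config_kwargs)
    return ReactionNetwork(variant, config)
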