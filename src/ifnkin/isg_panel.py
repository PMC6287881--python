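"""ISG-panel processing: qPCR normalisation, induction filtering, capping,
temporal-group assignment and the type I vs type III comparison.

Fold changes are expressed relative to the untreated control at the same
time point after normalisation to two reference genes.  A gene is
significantly regulated when it moves more than 2-fold (up or down) at any
time point under any IFN.  For display, fold changes are clamped to a
preset range (cell lines: [0.05, 20]; organoids: [1/800, 800]).  Induced
genes fall into four temporal groups by the time of maximum induction:
3 h (group 1), 6 h (group 2), 12 h (group 3), and 24 h / continuous
increase (group 4).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "CAP_PRESETS",
    "ddct_fold_change",
    "filter_induced",
    "cap_fold_changes",
    "assign_temporal_groups",
    "peak_display_mask",
    "ifn_scatter",
]

#: capping presets (lo, hi) on the fold-change scale
CAP_PRESETS = {"cellline": (0.05, 20.0), "organoid": (1.0 / 800.0, 800.0)}

TIME_TO_GROUP = {3.0: 1, 6.0: 2, 12.0: 3, 24.0: 4}


def ddct_fold_change(ct_target, ct_refs, ct_target_untreated,
                     ct_refs_untreated) -> float:
    """Fold change by the delta-delta-Ct method with two reference genes.

    The two reference quantification cycles are aggregated by arithmetic
    mean of Ct (the geometric mean on the expression scale);
    fold change = 2**(-ddCt).
    """
    ct_refs = np.atleast_1d(np.asarray(ct_refs, dtype=float))
    ct_refs_u = np.atleast_1d(np.asarray(ct_refs_untreated, dtype=float))
    vals = np.concatenate([ct_refs, ct_refs_u, np.atleast_1d(ct_target),
                           np.atleast_1d(ct_target_untreated)])
    if not np.all(np.isfinite(vals)):
        raise ValueError("quantification cycles must all be finite")
    dct_treated = ct_target - np.mean(ct_refs)
    dct_untreated = ct_target_untreated - np.mean(ct_refs_u)
    return float(2.0 ** (-(dct_treated - dct_untreated)))


def filter_induced(panel: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Keep genes moving strictly more than ``threshold``-fold either way.

    A gene survives when its fold change exceeds ``threshold`` or falls
    below ``1/threshold`` at at least one time point under at least one IFN
    (strict comparisons on both sides).
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    if panel.empty:
        return panel.copy()
    if (panel["fold_change"] <= 0).any():
        raise ValueError("fold changes must be positive")
    fc = panel.groupby("gene")["fold_change"]
    hits = (fc.max() > threshold) | (fc.min() < 1.0 / threshold)
    keep = hits[hits].index
    return panel[panel["gene"].isin(keep)].reset_index(drop=True)


def cap_fold_changes(panel, hi: float | None = None, lo: float | None = None,
                     preset: str | None = None):
    """Clamp fold changes to [lo, hi] (idempotent display transform)."""
    if preset is not None:
        lo, hi = CAP_PRESETS[preset]
    if hi is None or lo is None:
        raise ValueError("provide hi and lo, or a preset name")
    if hi <= lo or lo <= 0:
        raise ValueError("need hi > lo > 0")
    if isinstance(panel, pd.DataFrame):
        out = panel.copy()
        out["fold_change"] = out["fold_change"].clip(lo, hi)
        return out
    return np.clip(np.asarray(panel, dtype=float), lo, hi)


def _wide_profiles(panel: pd.DataFrame) -> pd.DataFrame:
    wide = panel.pivot_table(index=["gene", "ifn_type"], columns="time_h",
                             values="fold_change", sort=True)
    if wide.isna().any().any():
        raise ValueError("panel has missing (gene, IFN, time) combinations")
    return wide


def assign_temporal_groups(panel: pd.DataFrame,
                           method: str = "peak") -> pd.DataFrame:
    """Temporal-group labels per (gene, IFN arm) on the 3/6/12/24 h grid.

    ``peak`` bins each profile by its argmax time (ties toward the earlier
    time): 3 h -> 1, 6 h -> 2, 12 h -> 3, 24 h -> 4 (a monotone rise peaks
    at 24 h and lands in group 4).  ``hierarchical`` clusters max-normalised
    profiles (average linkage, Euclidean distance) into four clusters and
    labels each cluster by the peak time of its mean profile.  Both methods
    are deterministic.
    """
    wide = _wide_profiles(panel)
    times = np.asarray(wide.columns, dtype=float)
    unknown = set(times) - set(TIME_TO_GROUP)
    if unknown:
        raise ValueError(f"panel times {sorted(unknown)} are off the "
                         "3/6/12/24 h grid")
    profiles = wide.to_numpy()
    if method == "peak":
        groups = [TIME_TO_GROUP[times[int(np.argmax(row))]] for row in profiles]
    elif method == "hierarchical":
        norm = profiles / profiles.max(axis=1, keepdims=True)
        if np.unique(np.round(norm, 12), axis=0).shape[0] < 4:
            raise ValueError("fewer than 4 distinct profiles; use the "
                             "'peak' method")
        Z = linkage(pdist(norm, metric="euclidean"), method="average")
        clusters = fcluster(Z, t=4, criterion="maxclust")
        labels = {}
        for c in np.unique(clusters):
            mean_profile = norm[clusters == c].mean(axis=0)
            labels[c] = TIME_TO_GROUP[times[int(np.argmax(mean_profile))]]
        groups = [labels[c] for c in clusters]
    else:
        raise ValueError("method must be 'peak' or 'hierarchical'")
    out = wide.reset_index()[["gene", "ifn_type"]]
    out["group"] = groups
    return out


def peak_display_mask(panel: pd.DataFrame) -> pd.DataFrame:
    """Heatmap peak display: keep only each profile's maximum, mask the rest."""
    wide = _wide_profiles(panel)
    arr = wide.to_numpy()
    mask = np.zeros_like(arr, dtype=bool)
    mask[np.arange(len(arr)), np.argmax(arr, axis=1)] = True
    masked = pd.DataFrame(np.where(mask, arr, np.nan), index=wide.index,
                          columns=wide.columns)
    return (masked.stack(future_stack=True).rename("fold_change")
            .reset_index().dropna().reset_index(drop=True))


def ifn_scatter(panel: pd.DataFrame) -> pd.DataFrame:
    """Paired log2 fold changes (type I vs type III) per gene and time.

    Rows lacking either IFN arm are omitted with a warning; equal induction
    by both IFNs falls on the identity line.
    """
    import warnings

    arms = panel.pivot_table(index=["gene", "time_h"], columns="ifn_type",
                             values="fold_change")
    for arm in ("I", "III"):
        if arm not in arms.columns:
            raise ValueError(f"panel lacks the type {arm} arm entirely")
    incomplete = arms[["I", "III"]].isna().any(axis=1)
    if incomplete.any():
        warnings.warn(f"omitting {int(incomplete.sum())} (gene, time) rows "
                      "missing one IFN arm", stacklevel=2)
    arms = arms[~incomplete]
    out = pd.DataFrame({
        "log2_fc_I": np.log2(arms["I"]),
        "log2_fc_III": np.log2(arms["III"]),
    }).reset_index()
    return out
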