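"""Small-sample Akaike model selection over fitted variants.

AICc = n (ln(2*pi*wSSR/n) + 1) + 2k + 2k(k+1)/(n-k-1), with n the number of
fitted points and k the number of estimated parameters; Akaike weights are
w_i = exp(-dAICc_i/2) / sum_r exp(-dAICc_r/2).  The variant with the
smallest AICc is the most parsimonious member of the candidate set.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["aicc", "akaike_weights", "rank_models"]


def aicc(wssr: float, n: int, k: int) -> float:
    """Corrected Akaike information criterion for a least-squares fit."""
    if wssr <= 0:
        raise ValueError("wSSR must be positive")
    if n <= k + 1:
        raise ValueError(f"AICc requires n > k + 1 (got n={n}, k={k})")
    return float(n * (math.log(2.0 * math.pi * wssr / n) + 1.0)
                 + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0))


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights of a candidate set, stabilised around the minimum."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def rank_models(results) -> pd.DataFrame:
    """AICc table over fitted variants, best (lowest AICc) first.

    All fits must share the dataset size n.  Ties in AICc are broken by
    smaller k, then by variant id.  The table records n and k per row so the
    point-counting convention is auditable.
    """
    if not results:
        raise ValueError("need at least one fitted model")
    ns = {r.n for r in results}
    if len(ns) > 1:
        raise ValueError(f"fits disagree on dataset size n: {sorted(ns)}")
    rows = [{"variant": r.variant, "wssr": r.wssr, "n": r.n, "k": r.k,
             "aicc": aicc(r.wssr, r.n, r.k)} for r in results]
    table = pd.DataFrame(rows)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    table["weight"] = akaike_weights(table["aicc"].to_numpy())
    table = table.sort_values(["aicc", "k", "variant"], kind="mergesort")
    return table.reset_index(drop=True)
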