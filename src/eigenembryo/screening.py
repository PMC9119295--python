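"""Component screening: which principal components separate the outcomes?

Each component's embryo scores are split by hCG outcome and compared
with the two-sample Kolmogorov–Smirnov test. Selection is at raw
p < alpha (default 0.05) with no multiplicity correction — the screen is
deliberately liberal, as is conventional for hypothesis-generating
eigenimage analyses — but Benjamini–Hochberg adjusted p-values are
always reported alongside so the cost of that choice is visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import kolmogorov
from statsmodels.stats.multitest import multipletests

from .eigen import EigenModel

__all__ = ["ComponentScreen", "ks_two_sample", "screen_components", "screen_frame"]


@dataclass(frozen=True)
class ComponentScreen:
    """KS screening result for one component (1-based index)."""

    component_index: int
    ks_D: float
    p_value: float
    p_adjusted: float
    selected: bool


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test (two-sided, asymptotic p).

    D is the supremum of |Fx - Fy| over the pooled sample points, with
    both empirical CDFs evaluated at every pooled value so ties are
    handled exactly. The p-value uses the asymptotic Kolmogorov
    distribution at effective size ne = n1*n2/(n1+n2):

        p = 2 * sum_{j>=1} (-1)^(j-1) exp(-2 j^2 ne D^2),

    clamped to [0, 1] — the standard large-sample approximation for
    groups of ~100.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    D = float(np.max(np.abs(cdf_x - cdf_y)))
    ne = x.size * y.size / (x.size + y.size)
    p = float(np.clip(kolmogorov(np.sqrt(ne) * D), 0.0, 1.0))
    return D, p


def screen_components(model: EigenModel, labels: np.ndarray,
                      alpha: float = 0.05) -> list[ComponentScreen]:
    """KS-screen every component's scores against a binary outcome.

    Parameters
    ----------
    labels
        Binary vector aligned to the model's score rows (1 = hCG
        positive). Both classes must be present.
    alpha
        Selection level on the *raw* p-value.

    Returns
    -------
    list of ComponentScreen, ordered by component index.
    """
    labels = np.asarray(labels).astype(int)
    if labels.shape != (model.n,):
        raise ValueError("labels not aligned to score rows")
    if not (0 < alpha <= 1) and alpha != 0:
        raise ValueError("alpha must be in [0, 1]")
    pos = labels == 1
    neg = labels == 0
    if not (pos.any() and neg.any()):
        raise ValueError("both outcome classes must be present")
    stats = [ks_two_sample(model.scores[pos, j], model.scores[neg, j])
             for j in range(model.k)]
    if not stats:
        return []
    raw_p = np.array([p for _, p in stats])
    adjusted = multipletests(raw_p, method="fdr_bh")[1]
    return [
        ComponentScreen(component_index=j + 1, ks_D=D, p_value=p,
                        p_adjusted=float(adj), selected=bool(p < alpha))
        for j, ((D, p), adj) in enumerate(zip(stats, adjusted))
    ]


def screen_frame(screens: list[ComponentScreen]) -> pd.DataFrame:
    """Screening results as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        [{"component_index": s.component_index, "ks_D": s.ks_D,
          "p_value": s.p_value, "p_adjusted": s.p_adjusted,
          "selected": s.selected} for s in screens])
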