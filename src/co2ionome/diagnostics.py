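"""Publication-bias diagnostics: funnel data and a size-bias regression.

Small studies with null or positive results are the ones most easily left
unpublished; if that happened, small-replicate entries would show
systematically different effects than large ones.  The funnel relates each
entry's standardized effect to its replicate count.  Because the database
lacks complete per-entry variances, the regression test uses
``1/sqrt(n_replicates)`` as the precision proxy (an adaptation of the
classic intercept-style small-study regression): a slope significantly
different from zero flags a size-dependent effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["FunnelPoint", "funnel_data", "size_bias_test", "funnel_frame"]


@dataclass(frozen=True)
class FunnelPoint:
    """One entry's standardized effect against its study-size proxy."""

    effect: float
    size_proxy: int

    def __post_init__(self) -> None:
        if self.size_proxy < 1:
            raise ValueError("size_proxy must be >= 1")


def funnel_data(frame: pd.DataFrame) -> list[FunnelPoint]:
    """One funnel point per standardized entry; count preserved."""
    return [
        FunnelPoint(effect=float(e), size_proxy=int(n))
        for e, n in zip(frame["adj_log_rr"], frame["n_replicates"])
    ]


def funnel_frame(points: Sequence[FunnelPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {"effect": [p.effect for p in points],
         "n_replicates": [p.size_proxy for p in points]}
    )


def size_bias_test(points: Sequence[FunnelPoint],
                   ) -> tuple[float, float, float]:
    """Regress effect on 1/sqrt(n_replicates).

    Returns ``(slope, intercept, p)`` with ``p`` the two-sided p-value of
    the slope under heteroscedasticity-robust (HC3) standard errors —
    funnel spread naturally shrinks with study size, so homoscedastic
    standard errors would over-reject.  Requires at least three points with
    at least two distinct replicate counts.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    sizes = np.array([p.size_proxy for p in points], dtype=float)
    if np.unique(sizes).size < 2:
        raise ValueError("need at least 2 distinct size_proxy values")
    effects = np.array([p.effect for p in points], dtype=float)
    x = sm.add_constant(1.0 / np.sqrt(sizes))
    fit = sm.OLS(effects, x).fit(cov_type="HC3")
    return float(fit.params[1]), float(fit.params[0]), float(fit.pvalues[1])
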