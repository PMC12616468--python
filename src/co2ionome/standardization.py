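"""Standardization of paired CO2-response observations to a common window.

Experiments measure a nutrient concentration at some ambient level ``A`` and
some elevated level ``E`` of CO2, but the (A, E) design varies widely across
studies.  Assuming the response is linear in CO2 concentration over the range
considered, every observation pair can be re-expressed as the log response
ratio the same linear response would show between common levels
``A* = 350 ppm`` and ``E* = 550 ppm``:

    r(x)       = rA * (1 + delta * (x - A) / (E - A))        (interpolant)
    L*         = ln( r(E*) / r(A*) )
               = ln( ((E - A) + delta*(E* - A)) /
                     ((E - A) + delta*(A* - A)) )

where ``delta = (rE - rA) / rA`` is the relative change.  ``L*`` depends only
on (delta, A, E, A*, E*), never on the absolute response scale.  When the
measured levels already equal the standard levels, ``L*`` reduces to the raw
log response ratio ``ln(rE / rA)``.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StandardizationConfig",
    "StandardizedEffect",
    "compute_delta",
    "log_response_ratio",
    "standardize_log_response",
    "percent_change",
    "standardize_effect",
    "standardize_entries",
]

#: Interpolated responses below RELATIVE_FLOOR * rA are treated as crossing
#: zero (log would be numerically undefined).
RELATIVE_FLOOR = 1e-12


@dataclass(frozen=True)
class StandardizationConfig:
    """Common CO2 window the effects are standardized to.

    Parameters
    ----------
    baseline_ppm : float
        The standard ambient level A* (default 350 ppm, within the 310-455
        ppm spread of ambient levels in enrichment experiments).
    elevated_ppm : float
        The standard elevated level E* (default 550 ppm; most enrichment
        experiments run at or above this level, so the adjustment is an
        interpolation at the elevated end).
    """

    baseline_ppm: float = 350.0
    elevated_ppm: float = 550.0

    def __post_init__(self) -> None:
        if not (0 < self.baseline_ppm < self.elevated_ppm):
            raise ValueError(
                "require 0 < baseline_ppm < elevated_ppm, got "
                f"({self.baseline_ppm}, {self.elevated_ppm})"
            )

    @property
    def window_ppm(self) -> float:
        return self.elevated_ppm - self.baseline_ppm


@dataclass(frozen=True)
class StandardizedEffect:
    """Effect measures for one observation pair.

    Attributes
    ----------
    delta : float
        Relative change (rE - rA) / rA.
    log_rr : float
        Raw log response ratio ln(rE / rA).
    adj_log_rr : float
        Log response ratio standardized to the (A*, E*) window.
    pct_change : float
        (exp(adj_log_rr) - 1) * 100, the reporting scale.
    """

    delta: float
    log_rr: float
    adj_log_rr: float
    pct_change: float


def compute_delta(r_ambient, r_elevated):
    """Relative change ``(rE - rA) / rA`` of the response.

    Raises ``ValueError`` if any ambient response is non-positive.
    """
    r_ambient = np.asarray(r_ambient, dtype=float)
    r_elevated = np.asarray(r_elevated, dtype=float)
    if np.any(r_ambient <= 0):
        raise ValueError("ambient response must be > 0")
    out = (r_elevated - r_ambient) / r_ambient
    return out.item() if out.ndim == 0 else out


def log_response_ratio(r_ambient, r_elevated):
    """Raw log response ratio ``ln(rE / rA)``.

    The natural log of the ratio is the standard symmetric effect metric for
    ratios: it bounds decreases at -100% while increases are unbounded, and
    reduces skew relative to the raw ratio.
    """
    r_ambient = np.asarray(r_ambient, dtype=float)
    r_elevated = np.asarray(r_elevated, dtype=float)
    if np.any(r_ambient <= 0) or np.any(r_elevated <= 0):
        raise ValueError("both responses must be > 0 for a log ratio")
    out = np.log(r_elevated / r_ambient)
    return out.item() if out.ndim == 0 else out


def standardize_log_response(delta, ambient_ppm, elevated_ppm,
                             config: StandardizationConfig | None = None):
    """Standardized log response ratio over the (A*, E*) window.

    Evaluates the linear interpolant of the response through the two measured
    points at A* and E* and returns the log of their ratio:

        L* = ln( ((E - A) + delta*(E* - A)) / ((E - A) + delta*(A* - A)) )

    Independent of the absolute response scale.  Raises ``ValueError`` when
    ``A >= E`` or when the interpolated response is non-positive at either
    standard level ("standardization crosses zero").
    """
    if config is None:
        config = StandardizationConfig()
    delta = np.asarray(delta, dtype=float)
    a = np.asarray(ambient_ppm, dtype=float)
    e = np.asarray(elevated_ppm, dtype=float)
    if np.any(a >= e):
        raise ValueError("elevated_ppm must exceed ambient_ppm")
    span = e - a
    # numerator/denominator are r(E*)/rA resp. r(A*)/rA times span
    num = span + delta * (config.elevated_ppm - a)
    den = span + delta * (config.baseline_ppm - a)
    floor = RELATIVE_FLOOR * span
    if np.any(num <= floor) or np.any(den <= floor):
        raise ValueError("standardization crosses zero: interpolated "
                         "response non-positive at a standard level")
    out = np.log(num / den)
    return out.item() if out.ndim == 0 else out


def percent_change(adj_log_rr):
    """Back-transform a log response ratio to percent change."""
    out = (np.exp(np.asarray(adj_log_rr, dtype=float)) - 1.0) * 100.0
    return out.item() if out.ndim == 0 else out


def standardize_effect(r_ambient, r_elevated, ambient_ppm, elevated_ppm,
                       config: StandardizationConfig | None = None,
                       ) -> StandardizedEffect:
    """Compute all effect measures for one observation pair."""
    delta = compute_delta(r_ambient, r_elevated)
    lrr = log_response_ratio(r_ambient, r_elevated)
    adj = standardize_log_response(delta, ambient_ppm, elevated_ppm, config)
    return StandardizedEffect(delta=delta, log_rr=lrr, adj_log_rr=adj,
                              pct_change=percent_change(adj))


def standardize_entries(frame: pd.DataFrame,
                        config: StandardizationConfig | None = None,
                        ) -> pd.DataFrame:
    """Augment an entry table with delta, log_rr, adj_log_rr, pct_change.

    Rows with ``response_elevated == 0`` are kept but flagged with
    ``excluded_zero_response=True`` and NaN effect columns: the log ratio is
    undefined there, but the record is preserved for audit.  Rows whose
    interpolant crosses zero inside the standard window are likewise flagged
    (``excluded_crosses_zero``) rather than aborting the whole table.
    """
    if config is None:
        config = StandardizationConfig()
    out = frame.copy()
    ra = out["response_ambient"].to_numpy(dtype=float)
    re = out["response_elevated"].to_numpy(dtype=float)
    a = out["ambient_ppm"].to_numpy(dtype=float)
    e = out["elevated_ppm"].to_numpy(dtype=float)
    ok = re > 0

    delta = np.full(len(out), np.nan)
    lrr = np.full(len(out), np.nan)
    adj = np.full(len(out), np.nan)
    delta[ok] = (re[ok] - ra[ok]) / ra[ok]
    lrr[ok] = np.log(re[ok] / ra[ok])
    span = e - a
    num = span + delta * (config.elevated_ppm - a)
    den = span + delta * (config.baseline_ppm - a)
    floor = RELATIVE_FLOOR * span
    valid = ok & (num > floor) & (den > floor)
    adj[valid] = np.log(num[valid] / den[valid])
    out["delta"] = delta
    out["log_rr"] = lrr
    out["adj_log_rr"] = adj
    out["pct_change"] = percent_change(adj)
    out["excluded_zero_response"] = ~ok
    out["excluded_crosses_zero"] = ok & ~valid
    return out
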