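"""Deterministic signal preprocessing.

Smile series are rounded to whole intensities and smoothed with a short
centered moving average (160 ms, i.e. four samples at 25 Hz) before
correlation. Heart-rate series are prewhitened: an autoregressive model is
fitted (Yule-Walker, order chosen by AIC) and replaced by its one-step-ahead
prediction errors, removing the autocorrelation that would otherwise inflate
cross-correlations between two smooth physiological signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.regression.linear_model import yule_walker

from .series import SignalSeries

__all__ = ["ARFit", "round_to_integers", "smooth_rolling_mean", "prewhiten_ar", "default_max_order"]


@dataclass
class ARFit:
    order: int
    coefficients: np.ndarray
    innovation_variance: float
    mean: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if self.innovation_variance < 0:
            raise ValueError("innovation_variance must be >= 0")
        if self.coefficients.size != self.order:
            raise ValueError("coefficient count must equal order")


def round_to_integers(s: SignalSeries) -> SignalSeries:
    """Round each value half-away-from-zero to an integer (smile intensities)."""
    v = s.values
    rounded = np.copysign(np.floor(np.abs(v) + 0.5), v)
    return s.replace(values=rounded)


def smooth_rolling_mean(s: SignalSeries, window_samples: int, edges: str = "shrink") -> SignalSeries:
    """Centered moving average of width ``window_samples``.

    ``edges="shrink"`` (default) keeps the output length equal to the input
    length by letting the window shrink at the boundaries; ``edges="trim"``
    leaves boundary samples where the full window does not fit as NaN, which
    mirrors tooling that drops incomplete windows. For an even window the
    label sits right of center (the window covers ``[i - w//2, i + (w-1)//2]``).
    """
    if s.n_samples == 0:
        raise ValueError("cannot smooth an empty series")
    if not 1 <= window_samples <= s.n_samples:
        raise ValueError(f"window_samples must be in [1, {s.n_samples}], got {window_samples}")
    if edges not in ("shrink", "trim"):
        raise ValueError("edges must be 'shrink' or 'trim'")
    min_periods = 1 if edges == "shrink" else window_samples
    smoothed = (
        pd.Series(s.values).rolling(window_samples, center=True, min_periods=min_periods).mean()
    )
    return s.replace(values=smoothed.to_numpy())


def default_max_order(n: int) -> int:
    """AIC search ceiling, floor(10 * log10(n)), capped so fitting is possible."""
    return min(int(np.floor(10.0 * np.log10(n))), n - 2)


def prewhiten_ar(s: SignalSeries, max_order: int | None = None) -> tuple[SignalSeries, ARFit]:
    """Fit an AR(p) by Yule-Walker with AIC order selection and return residuals.

    The order is chosen by AIC over 0..max_order (default ceiling
    ``floor(10*log10(n))``). Residuals are one-step-ahead prediction errors of
    the demeaned series for t >= order, so the residual series is shorter by
    ``order`` samples; order 0 degenerates to the demeaned series. A constant
    series has no autocovariance structure and raises.
    """
    x = s.values
    n = x.size
    if max_order is None:
        max_order = default_max_order(n)
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    if n < max_order + 2:
        raise ValueError(f"series of length {n} too short for max_order {max_order}")
    if np.ptp(x) == 0 or float(np.var(x)) == 0.0:
        raise ValueError("zero variance, cannot prewhiten")

    mean = float(np.mean(x))
    xc = x - mean
    # Yule-Walker with denominator-n autocovariances (the classic estimator);
    # sigma2 falls monotonically with order, AIC = n*log(sigma2) + 2*order.
    var0 = float(np.mean(xc**2))
    best = (n * np.log(var0), 0, np.empty(0), var0)
    for k in range(1, max_order + 1):
        rho, sigma = yule_walker(xc, order=k, method="mle", demean=False)
        sigma2 = float(sigma**2)
        if not np.isfinite(sigma2) or sigma2 <= 0:
            continue
        aic = n * np.log(sigma2) + 2.0 * k
        if aic < best[0]:
            best = (aic, k, np.asarray(rho, dtype=float), sigma2)

    _aic, order, coefs, sigma2 = best
    if order == 0:
        resid = xc.copy()
    else:
        resid = xc[order:].copy()
        for j, c in enumerate(coefs, start=1):
            resid -= c * xc[order - j : n - j]
    fit = ARFit(order=order, coefficients=coefs, innovation_variance=sigma2, mean=mean)
    return s.replace(values=resid), fit
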