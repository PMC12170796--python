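"""Per-pair synchrony estimation.

Global synchrony is the Pearson (or Spearman) correlation of two members'
full preprocessed series. The windowed cross-lagged correlation (WCLC)
slides a fixed window along the recording and, within each window, correlates
the two series across a symmetric grid of lags; the per-window *peak
synchrony* is the maximum correlation over lags, letting either member lead.

Sign convention: a positive lag means member B's signal follows member A's
(B mirrors A after the lag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .series import SignalSeries

__all__ = [
    "SynchronyRecord",
    "WCLCResult",
    "lagged_correlation",
    "global_synchrony",
    "smile_eligibility",
    "wclc",
    "peak_timecourse",
]


def _values(x) -> np.ndarray:
    if isinstance(x, SignalSeries):
        return x.values
    return np.asarray(x, dtype=float)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2:
        return np.nan
    sa = a - a.mean()
    sb = b - b.mean()
    va = float(sa @ sa)
    vb = float(sb @ sb)
    if va == 0.0 or vb == 0.0:
        return np.nan
    return float((sa @ sb) / np.sqrt(va * vb))


def lagged_correlation(a, b, lag_samples: int, method: str = "pearson") -> float:
    """Correlation of a[t] with b[t + lag] over the overlapping range.

    Returns NaN (undefined) when either overlapping slice has zero variance
    or fewer than two samples. Spearman is Pearson on average ranks.
    """
    av, bv = _values(a), _values(b)
    if av.size != bv.size:
        raise ValueError(f"length mismatch: {av.size} vs {bv.size}")
    n = av.size
    lag = int(lag_samples)
    if abs(lag) >= n:
        raise ValueError(f"|lag| must be < series length ({n}), got {lag}")
    if lag >= 0:
        x, y = av[: n - lag], bv[lag:]
    else:
        x, y = av[-lag:], bv[: n + lag]
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    return _pearson(x, y)


@dataclass
class SynchronyRecord:
    pair_id: str
    condition: str | None
    pair_type: str
    method: str
    prewhitened: bool
    r: float
    mean_a: float
    mean_b: float
    n_samples: int
    eligible: bool
    exclusion_reason: str | None = None

    @property
    def mean_pair(self) -> float:
        return (self.mean_a + self.mean_b) / 2.0

    def to_dict(self) -> dict:
        d = {
            "pair_id": self.pair_id,
            "condition": self.condition,
            "pair_type": self.pair_type,
            "method": self.method,
            "prewhitened": self.prewhitened,
            "r": self.r,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "mean_pair": self.mean_pair,
            "n_samples": self.n_samples,
            "eligible": self.eligible,
            "exclusion_reason": self.exclusion_reason,
        }
        return d


def global_synchrony(
    a: SignalSeries,
    b: SignalSeries,
    method: str = "pearson",
    prewhitened: bool = False,
    pair_id: str = "",
    pair_type: str = "real",
    mean_a: float | None = None,
    mean_b: float | None = None,
) -> SynchronyRecord:
    """Whole-recording correlation between two members' series.

    ``mean_a``/``mean_b`` default to the supplied series' means but can be
    passed explicitly so the record carries raw signal levels (average
    smiling, average HR) even when ``a``/``b`` are preprocessed residuals.
    """
    if a.n_samples != b.n_samples:
        raise ValueError(f"length mismatch: {a.n_samples} vs {b.n_samples}")
    if not np.isclose(a.rate_hz, b.rate_hz):
        raise ValueError(f"rate mismatch: {a.rate_hz} vs {b.rate_hz}")
    r = lagged_correlation(a, b, 0, method=method)
    eligible = bool(np.isfinite(r))
    return SynchronyRecord(
        pair_id=pair_id or f"{a.participant_id}|{b.participant_id}",
        condition=a.condition or b.condition,
        pair_type=pair_type,
        method=method,
        prewhitened=prewhitened,
        r=r,
        mean_a=float(np.mean(a.values)) if mean_a is None else float(mean_a),
        mean_b=float(np.mean(b.values)) if mean_b is None else float(mean_b),
        n_samples=a.n_samples,
        eligible=eligible,
        exclusion_reason=None if eligible else "zero variance",
    )


def smile_eligibility(a_raw, b_raw) -> tuple[bool, str | None]:
    """A dyad is eligible iff both members smiled at some point (raw series)."""
    a_ok = float(np.max(_values(a_raw))) > 0
    b_ok = float(np.max(_values(b_raw))) > 0
    if a_ok and b_ok:
        return True, None
    return False, "non-smiler"


@dataclass
class WCLCResult:
    window_starts_s: np.ndarray
    peak_r: np.ndarray
    peak_lag_s: np.ndarray
    all_negative: np.ndarray
    window_s: float
    step_s: float
    max_lag_s: float
    lag_step_samples: int
    method: str = "pearson"
    pair_id: str = ""
    condition: str | None = None
    pair_type: str = "real"

    @property
    def n_windows(self) -> int:
        return int(self.window_starts_s.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_id": self.pair_id,
                "condition": self.condition,
                "pair_type": self.pair_type,
                "window_start_s": self.window_starts_s,
                "peak_r": self.peak_r,
                "peak_lag_s": self.peak_lag_s,
                "all_negative": self.all_negative,
            }
        )


def _as_samples(value_s: float, rate_hz: float, name: str) -> int:
    n = value_s * rate_hz
    if abs(n - round(n)) > 1e-6:
        raise ValueError(f"{name} ({value_s} s) is not an integer number of samples at {rate_hz} Hz")
    return int(round(n))


def _lag_grid(max_lag_samples: int, lag_step_samples: int) -> np.ndarray:
    ks = np.arange(0, max_lag_samples + 1, lag_step_samples)
    return np.concatenate([-ks[:0:-1], ks])


def wclc(
    a: SignalSeries,
    b: SignalSeries,
    window_s: float,
    step_s: float,
    max_lag_s: float,
    lag_step_samples: int = 1,
    method: str = "pearson",
    pair_id: str = "",
    pair_type: str = "real",
) -> WCLCResult:
    """Windowed cross-lagged correlation.

    For every window start on the step grid (windows fully inside the
    recording), correlations are computed between the two members' window
    slices at every lag in the symmetric grid; ``peak_r`` is the maximum over
    defined lags and ``peak_lag_s`` the argmax lag (ties resolved toward the
    smallest |lag|, negative before positive). Windows where every lag is
    undefined (zero-variance slices) yield NaN. ``all_negative`` flags
    windows whose best correlation is still negative, so "maximum positive
    correlation" summaries can treat them separately without dropping them.
    """
    if a.n_samples != b.n_samples:
        raise ValueError(f"length mismatch: {a.n_samples} vs {b.n_samples}")
    if not np.isclose(a.rate_hz, b.rate_hz):
        raise ValueError(f"rate mismatch: {a.rate_hz} vs {b.rate_hz}")
    rate = a.rate_hz
    n = a.n_samples
    W = _as_samples(window_s, rate, "window_s")
    S = _as_samples(step_s, rate, "step_s")
    L = _as_samples(max_lag_s, rate, "max_lag_s")
    if not 1 <= W <= n:
        raise ValueError(f"window ({W} samples) must fit in the series ({n} samples)")
    if S < 1:
        raise ValueError("step_s must be at least one sample")
    if not 1 <= lag_step_samples <= max(L, 1):
        raise ValueError(f"lag_step_samples must be in [1, {max(L, 1)}]")
    if L >= W:
        raise ValueError("max lag must be smaller than the window")

    lags = _lag_grid(L, lag_step_samples)
    # tie-break order: |lag| ascending, negative before positive
    order = sorted(range(lags.size), key=lambda i: (abs(int(lags[i])), int(lags[i]) > 0))

    starts = np.arange(0, n - W + 1, S)
    peak_r = np.full(starts.size, np.nan)
    peak_lag = np.full(starts.size, np.nan)
    all_negative = np.zeros(starts.size, dtype=bool)
    av, bv = a.values, b.values
    for wi, s0 in enumerate(starts):
        aw = av[s0 : s0 + W]
        bw = bv[s0 : s0 + W]
        best_r, best_lag = -np.inf, None
        for i in order:
            k = int(lags[i])
            r = lagged_correlation(aw, bw, k, method=method)
            if np.isfinite(r) and r > best_r:
                best_r, best_lag = r, k
        if best_lag is not None:
            peak_r[wi] = best_r
            peak_lag[wi] = best_lag / rate
            all_negative[wi] = best_r < 0
    return WCLCResult(
        window_starts_s=starts / rate,
        peak_r=peak_r,
        peak_lag_s=peak_lag,
        all_negative=all_negative,
        window_s=window_s,
        step_s=step_s,
        max_lag_s=max_lag_s,
        lag_step_samples=lag_step_samples,
        method=method,
        pair_id=pair_id or f"{a.participant_id}|{b.participant_id}",
        condition=a.condition or b.condition,
        pair_type=pair_type,
    )


def peak_timecourse(results: list[WCLCResult]) -> pd.DataFrame:
    """Mean peak synchrony per window start, grouped by condition x pair type.

    The 95% CI half-width is 1.96 * SE of the defined peaks at that window
    start; with a single pair the CI is undefined (NaN) and flagged by
    ``n_pairs``. All results must share one window grid.
    """
    if not results:
        raise ValueError("no WCLC results supplied")
    grid = results[0].window_starts_s
    for res in results[1:]:
        if res.window_starts_s.size != grid.size or not np.allclose(res.window_starts_s, grid):
            raise ValueError("mixed window grids; all results must share one grid")
    frames = pd.concat([r.to_frame() for r in results], ignore_index=True)
    rows = []
    for (cond, ptype), g in frames.groupby(["condition", "pair_type"], dropna=False):
        for start, win in g.groupby("window_start_s"):
            peaks = win["peak_r"].dropna().to_numpy()
            npairs = peaks.size
            mean = float(np.mean(peaks)) if npairs else np.nan
            if npairs >= 2:
                ci = 1.96 * float(np.std(peaks, ddof=1)) / np.sqrt(npairs)
            else:
                ci = np.nan
            rows.append(
                {
                    "condition": cond,
                    "pair_type": ptype,
                    "window_start_s": float(start),
                    "mean_peak_r": mean,
                    "ci_halfwidth": ci,
                    "n_pairs": npairs,
                }
            )
    return pd.DataFrame(rows)
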