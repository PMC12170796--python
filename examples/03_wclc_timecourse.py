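"""Windowed cross-lagged correlation: where in time synchrony happens.

Runs the WCLC estimator (60-s window sliding in 1-s steps, lags up to +/-1 s
in 0.04-s steps) on one strongly coupled smile dyad and prints the peak
correlation and best lag per window.
"""

import numpy as np

import dyadsync as ds

cfg = ds.SimConfig(seed=3)
a, b = ds.simulate_smile_dyad(cfg, coupling=0.9, seed=3, nonsmiler=(False, False))
a = ds.smooth_rolling_mean(ds.round_to_integers(a), 4)
b = ds.smooth_rolling_mean(ds.round_to_integers(b), 4)

res = ds.wclc(a, b, window_s=60.0, step_s=1.0, max_lag_s=1.0, lag_step_samples=1)
print(f"{res.n_windows} windows of {res.window_s:.0f} s "
      f"({int(res.window_s * a.rate_hz)} samples each)")
for i in range(0, res.n_windows, 10):
    print(f"  t = {res.window_starts_s[i]:5.1f} s   peak r = {res.peak_r[i]:+.3f} "
          f"at lag {res.peak_lag_s[i]:+.2f} s")
print(f"mean peak synchrony: {np.nanmean(res.peak_r):.3f}")

# A positive lag means the second member's smile follows the first's. The
# peak over lags captures mimicry that a plain lag-0 correlation would
# underestimate whenever responses are delayed by a few hundred ms.
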