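"""Link synchrony and condition to relational outcomes.

Runs the full pipeline on a simulated heart-rate study: prewhitened HR
synchrony per real/pseudo pairing, the six Bonferroni-corrected
pair-vs-pseudo t-tests, per-condition HR-change models, and dyad-level
change-score regressions.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from dyadsync.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig.from_profile(
    "study2_hr", seed=12, sim=dict(n_participants=10, n_rounds=3, hr_coupling=0.5)
)
with tempfile.TemporaryDirectory() as d:
    out = run_pipeline(cfg, Path(d) / "run")
    tests = pd.read_csv(out / "ttests.csv")
    print("pair-vs-pseudo t-tests (Bonferroni threshold "
          f"{tests['threshold'].iloc[0]:.3f}):")
    print(tests[["contrast", "mean_a", "mean_b", "t", "df", "p", "significant"]]
          .to_string(index=False))
    hr = pd.read_csv(out / "hr_change.csv")
    print("\nHR change (final minus first bpm) per condition:")
    print(hr[["model", "estimate", "se", "p"]].to_string(index=False))
    manifest = json.loads((out / "manifest.json").read_text())
    print("\ncounts:", manifest["counts"])

# With hr_coupling = 0.5 the real-vs-pseudo contrasts come out positive and,
# at this sample size, typically significant for the coupled conditions; the
# HR-change intercepts are negative because every condition starts aroused
# and settles (about -10 bpm over the 2-min exercise).
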