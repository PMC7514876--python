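"""Recover importance degrees from gaze data alone.

The allocation map is scale-free: observed attention shares pin the
per-section values only up to a common factor, so one known importance
(the anchor) fixes the rest. This script simulates a short session and
inverts the empirical fixation shares back to a value profile.
"""

import numpy as np

from attnalloc import BAS_PROFILE, SessionConfig, recover_allocation, simulate_session

cfg = SessionConfig(profile=BAS_PROFILE, participants=14, duration_s=300.0, seed=7)
out = simulate_session(cfg)
empirical, recovered = recover_allocation(out)

print(f"{'section':>20}{'V true':>8}{'A model':>9}{'A empir.':>10}{'V recov.':>10}")
for i, label in enumerate(BAS_PROFILE.labels):
    print(
        f"{label:>20}{BAS_PROFILE.V[i]:8.2f}{out.true_allocation[i]:9.4f}"
        f"{empirical.fractions[i]:10.4f}{recovered.V[i]:10.4f}"
    )
err = np.abs(recovered.V - BAS_PROFILE.V).max()
print(f"\nmax |V_recovered - V_true| = {err:.4f} "
      "(anchored at the 0.9 section; error reflects fixation sampling noise)")
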