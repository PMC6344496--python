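"""Derived quantities for all packaged series.

Loads the 17 published IMAP1 parameter sets, recomputes the age of peak
performance, the normalized peak (fraction of fitted lifespan) and the
growth time constant tau = 1/alphar, and prints them next to the
published peaks.  Rows whose published peak cannot be reproduced from
their own published parameters (rounded or unit-ambiguous tables) are
marked inconsistent.
"""

import numpy as np

from ageperf import DegeneratePeakError, load_all_fixtures, normalized_peak, peak_age, time_constant

rows = []
for fixture in load_all_fixtures():
    try:
        peak = peak_age(fixture.shape)
        norm = 100.0 * normalized_peak(fixture.shape)
    except DegeneratePeakError:
        peak, norm = float("nan"), float("nan")
    rows.append((fixture.name, peak, fixture.peak_imap1_published, norm,
                 time_constant(fixture.shape), fixture.peak_consistent))

print(f"{'series':24s} {'peak (y)':>9s} {'published':>9s} {'peak/td %':>9s} {'tau (y)':>8s}  consistent")
for name, peak, pub, norm, tau, ok in rows:
    print(f"{name:24s} {peak:9.2f} {pub:9.2f} {norm:9.2f} {tau:8.3f}  {ok}")

consistent_norms = [100.0 * normalized_peak(f.shape) for f in load_all_fixtures()
                    if f.name not in ("Greyhound", "Facial recognition")]
print(f"\nmean normalized peak over the 15 unambiguous series: "
      f"{np.mean(consistent_norms):.2f}% (early life: well before mid-lifespan)")
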