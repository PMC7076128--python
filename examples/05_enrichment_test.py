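"""Permutation colocalization test of boundaries against a peak track.

Builds a 150-bin universe, places CTCF-like peaks preferentially near
three "boundary" bins, and tests whether the mean peak count over the
flanked boundaries exceeds what random bin sets achieve.
"""

import numpy as np
import pandas as pd

from tadbound import permutation_test

RES = 40_000
n_bins = 150
starts = np.arange(n_bins) * RES
universe = pd.DataFrame({"chrom": "chrS", "start": starts,
                         "end": starts + RES})
boundary_bins = [37, 75, 112]
targets = universe.iloc[boundary_bins]

rng = np.random.default_rng(5)
peak_starts = np.concatenate([
    # clusters of peaks at the boundaries ...
    np.repeat([b * RES + 5_000 for b in boundary_bins], 4),
    # ... plus background peaks anywhere
    rng.integers(0, n_bins * RES, 30),
])
track = pd.DataFrame({"chrom": "chrS", "start": peak_starts,
                      "end": peak_starts + 400})

report = permutation_test(targets, universe, track,
                          n_perm=2_000, seed=7, flank=50_000)
print(f"observed mean peaks per flanked boundary: {report.observed_mean:.2f}")
print(f"difference-of-means statistic:            {report.statistic:.3f}")
print(f"permutation p-value ({report.n_perm} draws):     "
      f"{report.p_value:.4f}")
print(f"depleted: {report.depleted}")
print("\nA small p-value means random bin sets almost never match the "
      "boundaries' peak density: the boundaries co-locate with the track.")
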