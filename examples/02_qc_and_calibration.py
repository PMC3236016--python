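"""Spot QC, replicate merging, and threshold calibration from self-self arrays.

Shows the exclusion rules (flag < 1, confidence < 0.3, replicate SD > 0.2)
acting on a simulated spot table, then derives gain/loss call thresholds
from pooled normal-vs-normal hybridizations.
"""

import numpy as np

from acghpipe import (
    SimulationConfig,
    calibrate_thresholds,
    filter_and_merge_spots,
    normalize,
    simulate_cohort,
    simulate_self_self,
)

clone_map, spots, _, _ = simulate_cohort(SimulationConfig(n_samples=2, seed=3))
profiles = [normalize(p) for p in filter_and_merge_spots(spots, clone_map)]
for p in profiles:
    missing = int(np.isnan(p.values).sum())
    print(f"{p.sample_id}: {missing} of {len(p.values)} clones missing after QC")

# thresholds from three self-self arrays at platform-typical noise
ss_map, ss_profiles = simulate_self_self(n_arrays=3, noise_sd=0.1, seed=11, clones_per_chrom=152)
th = calibrate_thresholds(ss_profiles, ss_map)
print(f"calibrated thresholds: gain > {th.gain}, loss < {th.loss}")
# With Gaussian platform noise the 0.1%/99.9% quantiles land close to the
# ±20% fold-change bounds log2(1.2)=+0.2630 / log2(0.8)=-0.3219, so the
# calibration snaps to those printed values.
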