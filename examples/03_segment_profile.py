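"""Segment one chromosome two ways: Gaussian HMM and DP smoother.

A 100-clone chromosome carries a 30-clone single-copy gain; both
segmenters should place the same two breakpoints.
"""

import numpy as np

from acghpipe import build_clone_map, SampleProfile, segment_profile_hmm, segment_profile_smooth

rng = np.random.default_rng(5)
values = rng.normal(0.0, 0.12, 100)
values[40:70] += 0.45  # planted single-copy gain

clone_map = build_clone_map(n_chroms=1, clones_per_chrom=100)
profile = SampleProfile("demo", values, np.full(100, 4))

for name, seg in (
    ("HMM   ", segment_profile_hmm(profile, clone_map, seed=1)),
    ("smooth", segment_profile_smooth(profile, clone_map)),
):
    desc = ", ".join(
        f"[{s.start_index}-{s.end_index}] mean {s.mean:+.3f}" for s in seg.segments
    )
    print(f"{name}: {desc}")
# Segment means near +0.45 mark the gain; means near 0 are neutral. The
# calling module turns these means into categorical calls.
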