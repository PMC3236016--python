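import numpy as np
import pandas as pd
import pytest

from acghpipe.io_formats import CloneMap
from acghpipe.preprocess import SampleProfile


@pytest.fixture
def tiny_map() -> CloneMap:
    """Three abutting 1-Mb clones on chromosome 1."""
    return CloneMap(
        pd.DataFrame(
            {
                "clone_id": ["c1", "c2", "c3"],
                "chrom": ["1", "1", "1"],
                "start_bp": [1, 1_000_001, 2_000_001],
                "end_bp": [1_000_000, 2_000_000, 3_000_000],
            }
        )
    )


@pytest.fixture
def two_chrom_map() -> CloneMap:
    """Ten clones on each of chromosomes 1 and 2."""
    rows = []
    for chrom in ("1", "2"):
        for i in range(10):
            rows.append((f"c{chrom}_{i}", chrom, i * 1_000_000 + 1, (i + 1) * 1_000_000))
    return CloneMap(pd.DataFrame(rows, columns=["clone_id", "chrom", "start_bp", "end_bp"]))


def make_profile(values, sample_id="S1") -> SampleProfile:
    values = np.asarray(values, dtype=float)
    return SampleProfile(
        sample_id=sample_id,
        values=values,
        n_spots_used=np.where(np.isfinite(values), 4, 0),
    )
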