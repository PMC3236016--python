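"""Categorical gain/loss calls and genome-instability statistics.

A clone's call comes from its fitted segment mean m and the threshold set:

* m > high_gain (0.9)              → +2 high-level gain
* gain (0.2630) < m ≤ high_gain    → +1 gain
* loss (−0.3219) ≤ m ≤ gain        →  0 neutral
* high_loss (−0.75) ≤ m < loss     → −1 loss
* m < high_loss                    → −2 high-magnitude deletion

Outer thresholds are strict, so boundary values fall to the milder
category. The fraction of genome altered (FGA) is clone-count weighted on
informative autosomal clones: FGA-gain counts calls ≥ +1, FGA-loss counts
calls ≤ −1, and FGA is their sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedFgaError, ValidationError
from .io_formats import CloneMap, Region, region_clone_indices
from .preprocess import Thresholds
from .segmentation import SegmentedProfile

log = logging.getLogger(__name__)

HIGH_LOSS, LOSS, NEUTRAL, GAIN, HIGH_GAIN = -2, -1, 0, 1, 2


@dataclass
class CallProfile:
    """Per-clone calls in {−2, −1, 0, +1, +2}; NaN where the clone is missing."""

    sample_id: str
    calls: np.ndarray


@dataclass(frozen=True)
class FgaStats:
    fga: float
    fga_gain: float
    fga_loss: float
    n_clones_informative: int
    has_high_level: bool


def call_value(m: float, th: Thresholds) -> int:
    if m > th.high_gain:
        return HIGH_GAIN
    if m > th.gain:
        return GAIN
    if m >= th.loss:
        return NEUTRAL
    if m >= th.high_loss:
        return LOSS
    return HIGH_LOSS


def call_clones(
    seg: SegmentedProfile,
    th: Thresholds = Thresholds(),
    clone_map: CloneMap | None = None,
    autosomes_only: bool = True,
) -> CallProfile:
    """Threshold a segmented profile's fitted values into categorical calls.

    Sex chromosomes are masked to missing by default — the reference is
    sex-matched but residual X/Y artifacts are the platform's known weak
    point — which requires the clone map.
    """
    fitted = np.asarray(seg.fitted, dtype=float)
    calls = np.full(len(fitted), np.nan)
    present = np.isfinite(fitted)
    calls[present] = [call_value(m, th) for m in fitted[present]]
    if autosomes_only and clone_map is not None:
        calls[~clone_map.autosomal_mask] = np.nan
    return CallProfile(sample_id=seg.sample_id, calls=calls)


def compute_fga(calls: CallProfile) -> FgaStats:
    """Clone-count-weighted alteration fractions over informative clones."""
    c = np.asarray(calls.calls, dtype=float)
    informative = np.isfinite(c)
    n = int(informative.sum())
    if n == 0:
        raise UndefinedFgaError(f"sample {calls.sample_id}: no informative clones")
    c = c[informative]
    fga_gain = float((c >= GAIN).sum()) / n
    fga_loss = float((c <= LOSS).sum()) / n
    return FgaStats(
        fga=fga_gain + fga_loss,
        fga_gain=fga_gain,
        fga_loss=fga_loss,
        n_clones_informative=n,
        has_high_level=bool((np.abs(c) == HIGH_GAIN).any()),
    )


def call_matrix(profiles: Sequence[CallProfile], clone_map: CloneMap) -> pd.DataFrame:
    """Clones × samples matrix of call codes (float with NaN for missing)."""
    return pd.DataFrame(
        {p.sample_id: p.calls for p in profiles}, index=clone_map.clone_ids
    )


def fga_table(profiles: Sequence[CallProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        s = compute_fga(p)
        rows.append((p.sample_id, s.fga, s.fga_gain, s.fga_loss,
                     s.n_clones_informative, s.has_high_level))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "fga", "fga_gain", "fga_loss",
                 "n_clones_informative", "has_high_level"],
    )


def regional_alteration_table(
    call_df: pd.DataFrame,
    regions: Sequence[Region],
    clone_map: CloneMap,
    rule: str = "majority",
    min_frac: float = 0.5,
) -> pd.DataFrame:
    """Per sample × region status in {'amplified', 'deleted', 'none'} (NaN if
    the region has no informative clone).

    Rules: ``majority`` — at least ``min_frac`` of informative clones
    called ≥ +1 (resp. ≤ −1); ``any`` — at least one such clone; ``all`` —
    every informative clone. When a region satisfies both directions,
    amplified takes precedence and the conflict is logged.
    """
    if rule not in ("majority", "any", "all"):
        raise ValidationError(f"unknown region rule {rule!r}")
    out = pd.DataFrame(index=call_df.columns, columns=[r.name for r in regions], dtype=object)
    for region in regions:
        rows = region_clone_indices(region, clone_map)
        sub = call_df.iloc[rows]
        for sid in call_df.columns:
            c = sub[sid].to_numpy(dtype=float)
            c = c[np.isfinite(c)]
            if len(c) == 0:
                out.loc[sid, region.name] = np.nan
                continue
            frac_amp = float((c >= GAIN).sum()) / len(c)
            frac_del = float((c <= LOSS).sum()) / len(c)
            if rule == "majority":
                amp, dele = frac_amp >= min_frac, frac_del >= min_frac
            elif rule == "any":
                amp, dele = frac_amp > 0, frac_del > 0
            else:
                amp, dele = frac_amp == 1.0, frac_del == 1.0
            if amp and dele:
                log.warning("region %s sample %s: both amplified and deleted; "
                            "amplified takes precedence", region.name, sid)
            out.loc[sid, region.name] = (
                "amplified" if amp else ("deleted" if dele else "none")
            )
    return out
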