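"""Spot-level QC, quadruplicate merging, normalization and threshold calibration.

Each clone is printed in quadruplicate on the array. A spot is excluded
when its quality flag is below 1 or its confidence below 0.3; after those
exclusions, a clone whose surviving replicates have sample standard
deviation above 0.2 is marked missing, otherwise its value is the plain
mean of the surviving replicate log2 ratios. QC failures therefore always
yield missing values, never exceptions.

Gain/loss call thresholds default to symmetric ±20% fold-change bounds,
log2(1.2) = +0.2630 and log2(0.8) = −0.3219 (4 decimals), with high-level
bounds at +0.9 / −0.75. ``calibrate_thresholds`` re-derives the primary
bounds from pooled self-self (normal vs normal) hybridizations via extreme
quantiles, snapping to the fold-change bounds when the data agree with
them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateCalibrationError, ValidationError
from .io_formats import CloneMap, validate_spot_table

log = logging.getLogger(__name__)

#: printed-precision defaults for the primary call thresholds
GAIN_DEFAULT = round(math.log2(1.2), 4)    # +0.2630
LOSS_DEFAULT = round(math.log2(0.8), 4)    # -0.3219
HIGH_GAIN_DEFAULT = 0.9
HIGH_LOSS_DEFAULT = -0.75


@dataclass
class SampleProfile:
    """Per-clone normalized log2 ratios for one sample (NaN = missing)."""

    sample_id: str
    values: np.ndarray
    n_spots_used: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.n_spots_used = np.asarray(self.n_spots_used, dtype=int)
        present = np.isfinite(self.values)
        if np.isinf(self.values[present]).any():
            raise ValidationError("profile values must be finite where present")


@dataclass(frozen=True)
class QcThresholds:
    """Spot exclusion rules: flag < flag_min or confidence < conf_min drops a
    spot; replicate sample SD > sd_max drops the clone."""

    flag_min: float = 1.0
    conf_min: float = 0.3
    sd_max: float = 0.2


@dataclass(frozen=True)
class Thresholds:
    """Log2-ratio bounds for the five-level call scheme."""

    gain: float = GAIN_DEFAULT
    loss: float = LOSS_DEFAULT
    high_gain: float = HIGH_GAIN_DEFAULT
    high_loss: float = HIGH_LOSS_DEFAULT

    def __post_init__(self):
        if not (self.loss < 0.0 < self.gain):
            raise ValidationError("thresholds must satisfy loss < 0 < gain")
        if not (self.high_loss < self.loss and self.high_gain > self.gain):
            raise ValidationError("high-level thresholds must bracket the primary ones")


DEFAULT_THRESHOLDS = Thresholds()


def filter_and_merge_spots(
    spots: pd.DataFrame,
    clone_map: CloneMap,
    qc: QcThresholds = QcThresholds(),
) -> list[SampleProfile]:
    """Apply spot QC and merge replicates into one profile per sample.

    The replicate SD rule uses the sample standard deviation (n−1
    denominator) of the replicates *surviving* the flag/confidence
    exclusions, so a single bad spot can be rescued by its mates. Clones
    with exactly one surviving spot are kept (SD undefined counts as a
    pass); clones with none are missing. Samples come back sorted by id.
    """
    validate_spot_table(spots, clone_map)
    ok = (spots["quality_flag"] >= qc.flag_min) & (spots["confidence"] >= qc.conf_min)
    surv = spots.loc[ok]
    agg = surv.groupby(["sample_id", "clone_id"], sort=True)["log2_ratio"].agg(
        ["mean", "std", "count"]
    )
    clone_ids = clone_map.clone_ids
    n = clone_map.n_clones
    profiles = []
    for sid in sorted(spots["sample_id"].unique()):
        values = np.full(n, np.nan)
        used = np.zeros(n, dtype=int)
        if sid in agg.index.get_level_values(0):
            sub = agg.loc[sid]
            keep = (sub["count"] == 1) | (sub["std"].fillna(0.0) <= qc.sd_max)
            sub = sub.loc[keep]
            idx = [clone_map.index_of(c) for c in sub.index]
            values[idx] = sub["mean"].to_numpy()
            used[idx] = sub["count"].to_numpy()
        profiles.append(SampleProfile(sample_id=str(sid), values=values, n_spots_used=used))
    return profiles


def normalize(
    profile: SampleProfile,
    method: str = "block_median",
    blocks: np.ndarray | None = None,
    intensity: np.ndarray | None = None,
    span: float = 0.3,
    iterations: int = 3,
) -> SampleProfile:
    """Center a profile by block median or block lowess.

    ``block_median`` subtracts each block's median. ``block_lowess``
    subtracts a locally weighted regression of the log2 ratio on mean spot
    intensity (or on array position when no intensity is available),
    fitted per block with the given span and robustness iterations.
    Blocks with fewer than 5 non-missing clones under lowess fall back to
    the median, logged. Missing values are untouched.
    """
    if method not in ("block_median", "block_lowess"):
        raise ConfigError(f"unknown normalization method {method!r}")
    values = profile.values.copy()
    n = len(values)
    if blocks is None:
        blocks = np.zeros(n, dtype=int)
    blocks = np.asarray(blocks)
    if len(blocks) != n:
        raise ConfigError("block labels must match profile length")
    covar = np.arange(n, dtype=float) if intensity is None else np.asarray(intensity, dtype=float)

    for b in np.unique(blocks):
        sel = blocks == b
        present = sel & np.isfinite(values)
        if not present.any():
            continue
        if method == "block_median" or present.sum() < 5:
            if method == "block_lowess" and present.sum() < 5:
                log.warning("block %s: <5 informative clones, lowess falls back to median", b)
            values[present] -= np.median(values[present])
        else:
            from statsmodels.nonparametric.smoothers_lowess import lowess

            fit = lowess(
                values[present],
                covar[present],
                frac=span,
                it=iterations,
                return_sorted=False,
            )
            values[present] -= fit
    return SampleProfile(profile.sample_id, values, profile.n_spots_used.copy())


def calibrate_thresholds(
    self_self: Sequence[SampleProfile] | None,
    clone_map: CloneMap | None = None,
    quantiles: tuple[float, float] = (0.001, 0.999),
    snap_tol: float = 0.05,
) -> Thresholds:
    """Derive gain/loss thresholds from pooled self-self hybridizations.

    Pools autosomal ratios across the supplied profiles and takes the
    configured extreme quantiles as candidate bounds; when both fall
    within ``snap_tol`` of the ±20% fold-change bounds log2(0.8)/log2(1.2)
    they snap to those printed defaults. With no input the defaults are
    returned unchanged. High-level bounds are never recalibrated.
    """
    if not self_self:
        return DEFAULT_THRESHOLDS
    pooled = []
    for prof in self_self:
        vals = prof.values
        if clone_map is not None:
            vals = vals[clone_map.autosomal_mask]
        pooled.append(vals[np.isfinite(vals)])
    x = np.concatenate(pooled)
    if x.size == 0 or np.ptp(x) == 0.0:
        raise DegenerateCalibrationError("self-self ratios have no spread")
    lo = float(np.quantile(x, quantiles[0]))
    hi = float(np.quantile(x, quantiles[1]))
    if abs(hi - GAIN_DEFAULT) <= snap_tol and abs(lo - LOSS_DEFAULT) <= snap_tol:
        gain, loss = GAIN_DEFAULT, LOSS_DEFAULT
    else:
        gain, loss = hi, lo
    if not (loss < 0.0 < gain):
        raise DegenerateCalibrationError(
            f"calibrated bounds do not bracket zero: ({loss:.4f}, {gain:.4f})"
        )
    return Thresholds(gain=gain, loss=loss)
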