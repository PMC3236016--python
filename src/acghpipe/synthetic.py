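"""Synthetic aCGH cohorts with known ground truth.

Emulates the structure of a 48-sample two-group (responder vs
non-responder) rectal-cancer cohort profiled on a ~1-Mb tiling array:
a clone map, quadruplicate replicate spots with injected QC failures,
region-level gains/losses drawn per sample as Bernoulli events with
group-specific frequencies, Gaussian clone- and replicate-level noise,
and a clinical table whose TRG / stage marginals follow the study-design
composition (21/48 responders; TRG grades 1/9/17/8/13 for grades 0–4;
47 of 48 evaluable for post-therapy stage).

Alterations are drawn at region granularity — a region is either wholly
altered in a sample or not — matching how regional frequencies are
tabulated; clone-level mosaicism, tumor purity and GC waves are out of
scope. One seed fully determines the output; per-sample RNG sub-streams
are derived from the seed so adding samples never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import CHROMOSOMES, CloneMap, Region, SPOT_COLUMNS
from .preprocess import DEFAULT_THRESHOLDS, SampleProfile

STATE_CODES = {"high_loss": -2, "loss": -1, "neutral": 0, "gain": 1, "high_gain": 2}

#: default true segment means per altered state (log2 ratio); single-copy
#: events clear the call thresholds with a margin of roughly 2× noise_sd
DEFAULT_SEGMENT_MEANS = {"gain": 0.45, "loss": -0.5, "high_gain": 1.1, "high_loss": -0.9}

# study-design marginals used for the simulated clinical table
_TRG_RESPONDER_WEIGHTS = {3: 8, 4: 13}
_TRG_NONRESPONDER_WEIGHTS = {0: 1, 1: 9, 2: 17}
_GENDER_WEIGHTS = {"M": 36, "F": 12}
_UT_WEIGHTS = {"2": 7, "3": 39, "4": 2}
_UN_WEIGHTS = {"0": 27, "+": 21}
_YPT_WEIGHTS = {"0": 14, "1": 6, "2": 11, "3": 16}
_YPN_WEIGHTS = {"0": 37, "+": 10}


@dataclass(frozen=True)
class Alteration:
    """A region-level event: clone ordinals (0-based inclusive) within one
    chromosome, an altered state and per-group Bernoulli frequencies."""

    name: str
    chrom: str
    start_clone: int
    end_clone: int
    state: str
    freq_responder: float
    freq_nonresponder: float

    def __post_init__(self):
        if self.state not in ("gain", "loss", "high_gain", "high_loss"):
            raise ConfigError(f"unknown alteration state {self.state!r}")
        for f in (self.freq_responder, self.freq_nonresponder):
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"frequency {f} outside [0, 1]")
        if self.end_clone < self.start_clone or self.start_clone < 0:
            raise ConfigError(f"alteration {self.name}: invalid clone range")

    @property
    def region(self) -> Region:
        return Region(self.name, self.chrom, self.start_clone, self.end_clone)


def default_alteration_spec(n_chroms: int = 22, clones_per_chrom: int = 14) -> list[Alteration]:
    """Group-differential regions echoing the frequencies reported for the
    extreme response classes, plus one common arm-scale gain; entries that
    do not fit the requested map are dropped."""
    catalog = [
        Alteration("2q21-like", "2", 8, 11, "gain", 0.00, 0.10),
        Alteration("3q29-like", "3", 9, 12, "gain", 0.00, 0.20),
        Alteration("7p22-like", "7", 1, 4, "gain", 0.08, 0.20),
        Alteration("8q23-like", "8", 8, 11, "gain", 0.15, 0.30),
        Alteration("13q12-like", "13", 2, 5, "gain", 0.15, 0.30),
        Alteration("13q34-like", "13", 9, 12, "high_gain", 0.15, 0.40),
        Alteration("17p13-like", "17", 1, 4, "loss", 0.08, 0.20),
        Alteration("18q23-like", "18", 9, 12, "loss", 0.00, 0.20),
        Alteration("20q-like", "20", 4, 11, "gain", 0.38, 0.38),
    ]
    keep = []
    for alt in catalog:
        if int(alt.chrom) <= n_chroms and alt.end_clone < clones_per_chrom:
            keep.append(alt)
    return keep


@dataclass
class SimulationConfig:
    n_samples: int = 48
    responder_fraction: float = 21 / 48
    n_chroms: int = 22
    clones_per_chrom: int = 14
    clone_width_bp: int = 1_000_000
    alteration_spec: list[Alteration] | None = None   # None -> default catalog
    segment_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEGMENT_MEANS))
    noise_sd: float = 0.12
    replicate_sd: float = 0.08
    qc_fail_rate: float = 0.02
    dye_bias_amplitude: float = 0.0
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ConfigError("responder_fraction outside [0, 1]")
        if not 1 <= self.n_chroms <= 22:
            raise ConfigError("n_chroms must be in 1..22 (autosomes)")
        if min(self.noise_sd, self.replicate_sd) < 0 or not 0 <= self.qc_fail_rate <= 1:
            raise ConfigError("noise/QC parameters out of range")
        if self.segment_means["gain"] <= DEFAULT_THRESHOLDS.gain:
            raise ConfigError("gain segment mean must clear the gain threshold")
        if self.segment_means["loss"] >= DEFAULT_THRESHOLDS.loss:
            raise ConfigError("loss segment mean must clear the loss threshold")

    def resolved_alterations(self) -> list[Alteration]:
        if self.alteration_spec is not None:
            return list(self.alteration_spec)
        return default_alteration_spec(self.n_chroms, self.clones_per_chrom)


@dataclass
class GroundTruth:
    """True per-clone states, true FGA and group label per sample."""

    states: pd.DataFrame        # clones × samples, integer codes
    fga: pd.Series              # sample -> true altered fraction
    groups: pd.Series           # sample -> responder flag

    def recount_fga(self) -> pd.Series:
        return (self.states != 0).mean(axis=0)


def build_clone_map(
    n_chroms: int = 22,
    clones_per_chrom: int = 14,
    clone_width_bp: int = 1_000_000,
    sex_chroms: bool = False,
) -> CloneMap:
    """Uniform tiling: ``clones_per_chrom`` abutting clones per chromosome."""
    chroms = list(CHROMOSOMES[:n_chroms]) + (["X", "Y"] if sex_chroms else [])
    rows = []
    for chrom in chroms:
        for i in range(clones_per_chrom):
            rows.append(
                (
                    f"clone_{chrom}_{i:03d}",
                    chrom,
                    i * clone_width_bp + 1,
                    (i + 1) * clone_width_bp,
                )
            )
    return CloneMap(pd.DataFrame(rows, columns=["clone_id", "chrom", "start_bp", "end_bp"]))


def _allocate(weights: dict, n: int) -> list:
    """Largest-remainder allocation of n items to labels with given weights."""
    labels = list(weights)
    total = float(sum(weights.values()))
    quotas = [n * weights[k] / total for k in labels]
    counts = [int(q) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(labels)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    out = []
    for lab, c in zip(labels, counts):
        out.extend([lab] * c)
    return out


def _clinical_table(n_samples: int, responder_fraction: float, rng: np.random.Generator) -> pd.DataFrame:
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    n_resp = int(round(responder_fraction * n_samples))
    responder = np.array([True] * n_resp + [False] * (n_samples - n_resp))
    rng.shuffle(responder)
    trg = np.empty(n_samples, dtype=int)
    resp_grades = _allocate(_TRG_RESPONDER_WEIGHTS, n_resp)
    nonresp_grades = _allocate(_TRG_NONRESPONDER_WEIGHTS, n_samples - n_resp)
    rng.shuffle(resp_grades)
    rng.shuffle(nonresp_grades)
    trg[responder] = resp_grades
    trg[~responder] = nonresp_grades

    def shuffled(weights, count):
        vals = _allocate(weights, count)
        rng.shuffle(vals)
        return vals

    n_eval = n_samples - 1 if n_samples >= 2 else n_samples
    ypt = shuffled(_YPT_WEIGHTS, n_eval) + [None] * (n_samples - n_eval)
    ypn = shuffled(_YPN_WEIGHTS, n_eval) + [None] * (n_samples - n_eval)
    df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "gender": shuffled(_GENDER_WEIGHTS, n_samples),
            "age": rng.integers(37, 83, size=n_samples),
            "ut": shuffled(_UT_WEIGHTS, n_samples),
            "un": shuffled(_UN_WEIGHTS, n_samples),
            "ypt": ypt,
            "ypn": ypn,
            "trg": trg,
            "responder": responder,
        }
    )
    # optional IHC covariates, missing in roughly a quarter of samples
    ki67 = rng.uniform(23, 93, size=n_samples).round(1)
    p21 = rng.uniform(0, 46, size=n_samples).round(1)
    miss = rng.random(n_samples) < 0.27
    df["ki67_pct"] = np.where(miss, np.nan, ki67)
    df["p21_pct"] = np.where(miss, np.nan, p21)
    return df


def simulate_cohort(config: SimulationConfig) -> tuple[CloneMap, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (CloneMap, spot table, clinical table, GroundTruth).

    Per sample: each configured region is altered with its group-specific
    probability; the per-clone log2 ratio is the true segment mean plus
    N(0, noise_sd); each clone is emitted as ``n_replicates`` spots with
    extra N(0, replicate_sd); a ``qc_fail_rate`` fraction of spots gets a
    random QC defect (low flag, low confidence, or an outlying ratio that
    inflates the replicate spread).
    """
    clone_map = build_clone_map(config.n_chroms, config.clones_per_chrom, config.clone_width_bp)
    alterations = config.resolved_alterations()
    # validate regions against the map up front
    from .errors import ValidationError
    from .io_formats import region_clone_indices

    try:
        region_rows = {alt.name: region_clone_indices(alt.region, clone_map) for alt in alterations}
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc

    cohort_rng = np.random.default_rng(np.random.SeedSequence(abs(int(config.seed)), spawn_key=(0,)))
    clinical = _clinical_table(config.n_samples, config.responder_fraction, cohort_rng)

    n_clones = clone_map.n_clones
    trend = (
        config.dye_bias_amplitude * np.linspace(-0.5, 0.5, n_clones)
        if config.dye_bias_amplitude
        else np.zeros(n_clones)
    )
    states = np.zeros((n_clones, config.n_samples), dtype=int)
    spot_frames = []
    for si, row in clinical.iterrows():
        rng = np.random.default_rng(
            np.random.SeedSequence(abs(int(config.seed)), spawn_key=(1, int(si)))
        )
        true_state = np.zeros(n_clones, dtype=int)
        means = np.zeros(n_clones)
        for alt in alterations:
            freq = alt.freq_responder if row["responder"] else alt.freq_nonresponder
            if rng.random() < freq:
                rows_idx = region_rows[alt.name]
                true_state[rows_idx] = STATE_CODES[alt.state]
                means[rows_idx] = config.segment_means[alt.state]
        states[:, si] = true_state
        clone_vals = means + trend
        if config.noise_sd > 0:
            clone_vals = clone_vals + rng.normal(0.0, config.noise_sd, size=n_clones)

        reps = np.repeat(clone_vals, config.n_replicates)
        if config.replicate_sd > 0:
            reps = reps + rng.normal(0.0, config.replicate_sd, size=reps.size)
        flags = np.full(reps.size, 1.5)
        confs = np.full(reps.size, 0.95)
        if config.qc_fail_rate > 0:
            fail = rng.random(reps.size) < config.qc_fail_rate
            modes = rng.integers(0, 3, size=reps.size)
            low_flag = fail & (modes == 0)
            low_conf = fail & (modes == 1)
            outlier = fail & (modes == 2)
            flags[low_flag] = rng.uniform(0.0, 0.99, size=int(low_flag.sum()))
            confs[low_conf] = rng.uniform(0.0, 0.29, size=int(low_conf.sum()))
            reps[outlier] = reps[outlier] + rng.normal(0.0, 0.5, size=int(outlier.sum()))
        spot_frames.append(
            pd.DataFrame(
                {
                    "sample_id": row["sample_id"],
                    "clone_id": np.repeat(clone_map.clone_ids, config.n_replicates),
                    "replicate": np.tile(np.arange(1, config.n_replicates + 1), n_clones),
                    "log2_ratio": reps,
                    "quality_flag": flags,
                    "confidence": confs,
                }
            )
        )
    spots = pd.concat(spot_frames, ignore_index=True)[SPOT_COLUMNS]
    states_df = pd.DataFrame(states, index=clone_map.clone_ids, columns=clinical["sample_id"])
    truth = GroundTruth(
        states=states_df,
        fga=(states_df != 0).mean(axis=0),
        groups=clinical.set_index("sample_id")["responder"],
    )
    return clone_map, spots, clinical, truth


def simulate_self_self(
    n_arrays: int,
    noise_sd: float,
    seed: int = 0,
    n_chroms: int = 22,
    clones_per_chrom: int = 14,
    sex_mismatch: bool = False,
) -> tuple[CloneMap, list[SampleProfile]]:
    """Normal-vs-normal control hybridizations.

    Autosomal clones are N(0, noise_sd). In sex-mismatch mode (female test
    DNA against male reference) the map gains X and Y clones offset by
    one-copy equivalents: X at +1 (two copies vs one) and Y at −1.
    """
    if n_arrays < 1:
        raise ConfigError("need at least one array")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    clone_map = build_clone_map(n_chroms, clones_per_chrom, sex_chroms=sex_mismatch)
    chrom = clone_map.chrom
    offsets = np.zeros(clone_map.n_clones)
    offsets[chrom == "X"] = 1.0
    offsets[chrom == "Y"] = -1.0
    profiles = []
    for a in range(n_arrays):
        rng = np.random.default_rng(np.random.SeedSequence(abs(int(seed)), spawn_key=(2, a)))
        vals = offsets.copy()
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=len(vals))
        profiles.append(
            SampleProfile(
                sample_id=f"selfself_{a + 1}",
                values=vals,
                n_spots_used=np.full(len(vals), 4),
            )
        )
    return clone_map, profiles
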