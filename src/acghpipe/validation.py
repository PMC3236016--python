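"""Validation experiments: oracle-equivalence and recovery studies.

These routines quantify, on synthetic cohorts with known truth, how well
the pipeline recovers what was planted: exact agreement of the Viterbi
decoder and the DP smoother with exhaustive enumeration at small sizes,
agreement of the Fisher test with exact hypergeometric enumeration,
end-to-end identity at zero noise, clone-level state recovery and
breakpoint localization at realistic noise, and the power to detect a
group-differential region. They are used by the test suite and the
reproduction script; each takes an explicit seed and problem size.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
import scipy.stats as st

from .calling import call_value
from .cohort import region_frequency_test
from .config import PipelineConfig
from .pipeline import call_and_tally, preprocess_profiles, segment_profiles
from .preprocess import Thresholds
from .segmentation import (
    HmmModel,
    fit_hmm,
    path_log_probability,
    smooth_cost,
    smooth_segment,
    viterbi_decode,
)
from .synthetic import Alteration, SimulationConfig, simulate_cohort
from .calling import regional_alteration_table


# ---------------------------------------------------------------------------
# exhaustive oracles
# ---------------------------------------------------------------------------

def _brute_best_path_logprob(model: HmmModel, x: np.ndarray) -> float:
    best = -np.inf
    K = model.K
    for path in itertools.product(range(K), repeat=len(x)):
        lp = math.log(model.startprob[path[0]]) if model.startprob[path[0]] > 0 else -np.inf
        for t, s in enumerate(path):
            v = model.variances[s]
            lp += -0.5 * ((x[t] - model.means[s]) ** 2 / v + math.log(2 * math.pi * v))
            if t > 0:
                a = model.transmat[path[t - 1], s]
                lp += math.log(a) if a > 0 else -np.inf
        best = max(best, lp)
    return best


def _brute_smooth_cost(x: np.ndarray, lam: float) -> float:
    n = len(x)
    best = np.inf
    for mask in range(2 ** (n - 1)):
        cost, start, nseg = 0.0, 0, 0
        for i in range(n):
            if i == n - 1 or (mask >> i) & 1:
                seg = x[start : i + 1]
                cost += float(((seg - seg.mean()) ** 2).sum())
                nseg += 1
                start = i + 1
        if cost + lam * (nseg - 1) < best:
            best = cost + lam * (nseg - 1)
    return best


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer hypergeometric enumeration."""
    n1, n2, k = a + c, b + d, a + b
    N = n1 + n2
    if k == 0 or k == N or n1 == 0 or n2 == 0:
        return 1.0
    w_obs = math.comb(n1, a) * math.comb(n2, k - a)
    total = 0
    for x in range(max(0, k - n2), min(k, n1) + 1):
        w = math.comb(n1, x) * math.comb(n2, k - x)
        if w <= w_obs:
            total += w
    return float(Fraction(total, math.comb(N, k)))


# ---------------------------------------------------------------------------
# oracle-equivalence suites
# ---------------------------------------------------------------------------

def viterbi_oracle_agreement(n_instances: int = 200, seed: int = 0) -> dict:
    """Fraction of random instances (n ≤ 8, K ≤ 3) where the Viterbi path's
    joint log probability equals the exhaustive maximum over all paths."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10,)))
    agree = 0
    for _ in range(n_instances):
        K = int(rng.integers(1, 4))
        n = int(rng.integers(2, 9))
        model = HmmModel(
            means=rng.normal(0, 1, K),
            variances=rng.uniform(0.05, 0.5, K),
            transmat=rng.dirichlet(np.ones(K) * 2, size=K),
            startprob=rng.dirichlet(np.ones(K)),
            log_likelihood=0.0,
            loglik_history=np.array([]),
            converged=True,
            n_obs=n,
        )
        x = rng.normal(0, 1, n)
        lp = path_log_probability(model, x, viterbi_decode(model, x))
        if abs(lp - _brute_best_path_logprob(model, x)) <= 1e-9:
            agree += 1
    return {"agreement": agree / n_instances, "n": n_instances}


def smoother_oracle_agreement(n_instances: int = 200, seed: int = 0, n_max: int = 14) -> dict:
    """Fraction of random instances where the DP cost equals the minimum over
    every breakpoint subset (exhaustive search, n ≤ n_max)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(2, n_max + 1))
        lam = float(rng.uniform(0.05, 1.0))
        x = rng.normal(0, 0.5, n)
        bounds, _ = smooth_segment(x, lam=lam, merge_tol=0.0)
        if abs(smooth_cost(x, bounds, lam) - _brute_smooth_cost(x, lam)) <= 1e-9:
            agree += 1
    return {"agreement": agree / n_instances, "n": n_instances}


def fisher_oracle_agreement(n_total_max: int = 30) -> dict:
    """Maximum |p_fisher − p_enumeration| over all 2×2 tables with N ≤ max."""
    worst = 0.0
    count = 0
    for N in range(1, n_total_max + 1):
        for a in range(N + 1):
            for b in range(N - a + 1):
                for c in range(N - a - b + 1):
                    d = N - a - b - c
                    if a + b + c + d != N:
                        continue
                    p = st.fisher_exact([[a, b], [c, d]])[1]
                    q = fisher_two_sided_exact(a, b, c, d)
                    worst = max(worst, abs(p - q))
                    count += 1
    return {"max_abs_diff": worst, "n": count}


# ---------------------------------------------------------------------------
# recovery studies
# ---------------------------------------------------------------------------

def _cohort_accuracy(config: PipelineConfig, seed: int) -> dict:
    sim = SimulationConfig(**{**config.simulation.__dict__, "seed": seed})
    clone_map, spots, clinical, truth = simulate_cohort(sim)
    profiles = preprocess_profiles(spots, clone_map, config)
    truth_mat = truth.states.to_numpy().astype(float)
    out = {}
    for approach in ("hmm", "smooth"):
        segs = segment_profiles(profiles, clone_map, config, seed, approach)
        call_df, fga_df = call_and_tally(segs, clone_map, config)
        calls = call_df.to_numpy()
        mask = np.isfinite(calls)
        pred_fga = fga_df.set_index("sample_id")["fga"].reindex(truth.fga.index).to_numpy()
        out[approach] = {
            "accuracy": float((calls[mask] == truth_mat[mask]).mean()),
            "n_compared": int(mask.sum()),
            "fga_max_abs_err": float(np.max(np.abs(pred_fga - truth.fga.to_numpy()))),
        }
    return out


def zero_noise_identity(n_samples: int = 48, seed: int = 0) -> dict:
    """End-to-end identity: with no noise, calls must equal truth exactly."""
    cfg = PipelineConfig()
    cfg.simulation = SimulationConfig(
        n_samples=n_samples, noise_sd=0.0, replicate_sd=0.0, qc_fail_rate=0.0, seed=seed
    )
    return _cohort_accuracy(cfg, seed)


def state_recovery(n_samples: int = 48, seed: int = 0) -> dict:
    """Clone-level state accuracy at the default noise level for both routes."""
    cfg = PipelineConfig()
    cfg.simulation = SimulationConfig(n_samples=n_samples, seed=seed)
    return _cohort_accuracy(cfg, seed)


def breakpoint_localization(n_seeds: int = 100, seed: int = 0, noise_sd: float = 0.05) -> dict:
    """Two-block chromosome (50 clones at 0, 50 at +0.6): fraction of seeds
    where each segmenter places exactly one breakpoint within ±2 clones of
    the true boundary."""
    ss = np.random.SeedSequence(seed, spawn_key=(12,))
    hits = {"hmm": 0, "smooth": 0}
    for child in ss.spawn(n_seeds):
        rng = np.random.default_rng(child)
        x = np.concatenate([rng.normal(0, noise_sd, 50), rng.normal(0.6, noise_sd, 50)])
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        fit = fit_hmm(x, K=2, seed=sub_seed)
        path = viterbi_decode(fit, x)
        changes = np.flatnonzero(np.diff(path)) + 1
        if len(changes) == 1 and abs(int(changes[0]) - 50) <= 2:
            hits["hmm"] += 1
        bounds, _ = smooth_segment(x)
        if len(bounds) == 2 and abs(bounds[1][0] - 50) <= 2:
            hits["smooth"] += 1
    return {k: v / n_seeds for k, v in hits.items()} | {"n": n_seeds}


def planted_region_detection(
    n_seeds: int = 100,
    seed: int = 0,
    freq_responder: float = 0.0,
    freq_nonresponder: float = 0.5,
    alpha: float = 0.01,
) -> dict:
    """Power study: a single gain region present in half the non-responders
    and no responders (24 + 24 samples); fraction of seeds where the
    patient-level Fisher test flags it below ``alpha``. The fast smoothing
    route carries the calls."""
    planted = Alteration("planted", "5", 4, 9, "gain", freq_responder, freq_nonresponder)
    detected = 0
    for i in range(n_seeds):
        cfg = PipelineConfig()
        cfg.simulation = SimulationConfig(
            n_samples=48,
            responder_fraction=0.5,
            alteration_spec=[planted],
            seed=int(np.random.SeedSequence(seed, spawn_key=(13, i)).generate_state(1)[0] % (2**31)),
        )
        clone_map, spots, clinical, truth = simulate_cohort(cfg.simulation)
        profiles = preprocess_profiles(spots, clone_map, cfg)
        segs = segment_profiles(profiles, clone_map, cfg, cfg.simulation.seed, "smooth")
        call_df, _ = call_and_tally(segs, clone_map, cfg)
        status = regional_alteration_table(call_df, [planted.region], clone_map)
        groups = clinical.set_index("sample_id")["responder"].map(
            {True: "responder", False: "non-responder"}
        )
        tests = region_frequency_test(status, groups)
        p_amp = min(t.p_value for t in tests if t.alteration == "amplified")
        if p_amp < alpha:
            detected += 1
    return {"detection_rate": detected / n_seeds, "n": n_seeds}


def em_monotonicity(n_instances: int = 50, seed: int = 0) -> dict:
    """Fraction of random EM fits whose log-likelihood never decreases by
    more than 1e-8 between iterations."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(14,)))
    ok = 0
    for i in range(n_instances):
        n = int(rng.integers(10, 60))
        x = rng.normal(0, 0.3, n) + rng.choice([0.0, 0.6], size=n)
        K = int(rng.integers(1, 4))
        K = min(K, len(np.unique(x)))
        fit = fit_hmm(x, K, n_restarts=2, seed=int(rng.integers(0, 2**31)))
        if (np.diff(fit.loglik_history) >= -1e-8).all():
            ok += 1
    return {"monotone_fraction": ok / n_instances, "n": n_instances}
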