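"""Per-chromosome segmentation of normalized log2-ratio profiles.

Two independent segmenters are provided, mirroring the two analysis
routes used for array-CGH copy-number profiles:

1. a Gaussian hidden Markov model fitted by Baum-Welch EM with multiple
   restarts, model order chosen by BIC over candidate state counts, and
   decoded by Viterbi; and
2. a penalized piecewise-constant smoother: the exact dynamic-programming
   minimizer of residual sum of squares plus a per-breakpoint penalty,
   followed by a merge pass on near-equal adjacent segment means.

Both operate on one chromosome at a time — copy-number events do not
cross chromosome boundaries — and both are label-free: categorical
gain/loss states are assigned afterwards from segment means by the
calling module, so the two routes are comparable under one calling rule.
Missing clones are skipped; an HMM transition simply bridges the gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DegenerateFitError
from .io_formats import CloneMap
from .preprocess import SampleProfile

VAR_FLOOR = 1e-4  # emission-variance floor; prevents EM singularity on repeats


@dataclass
class HmmModel:
    """Gaussian-emission HMM over ordered clones of one chromosome."""

    means: np.ndarray          # (K,) state means, log2 ratio
    variances: np.ndarray      # (K,) state variances, floored
    transmat: np.ndarray       # (K, K) row-stochastic
    startprob: np.ndarray      # (K,)
    log_likelihood: float
    loglik_history: np.ndarray
    converged: bool
    n_obs: int

    @property
    def K(self) -> int:
        return len(self.means)

    @property
    def n_parameters(self) -> int:
        # (K-1) start + K(K-1) transitions + K means + K variances
        return self.K * (self.K + 2) - 1

    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_parameters * math.log(self.n_obs)


@dataclass
class Segment:
    """Run of clones sharing one fitted level. Indices are global clone-map
    rows (inclusive); ``n_clones`` counts only the informative clones."""

    chrom: str
    start_index: int
    end_index: int
    mean: float
    n_clones: int
    state: int | None = None


@dataclass
class SegmentedProfile:
    sample_id: str
    segments: list[Segment] = field(default_factory=list)
    fitted: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Gaussian HMM: Baum-Welch, BIC selection, Viterbi
# ---------------------------------------------------------------------------

def _emission_log_pdf(x: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    d = x[:, None] - means[None, :]
    return -0.5 * (d * d / variances[None, :] + np.log(2.0 * np.pi * variances[None, :]))


def forward_log_likelihood(model: HmmModel, values: np.ndarray) -> float:
    """Scaled forward-pass log likelihood of observed values under a model."""
    x = np.asarray(values, dtype=float)
    logb = _emission_log_pdf(x, model.means, model.variances)
    m = logb.max(axis=1)
    b = np.exp(logb - m[:, None])
    alpha = model.startprob * b[0]
    c0 = alpha.sum()
    ll = math.log(c0) + m[0]
    alpha /= c0
    for t in range(1, len(x)):
        alpha = (alpha @ model.transmat) * b[t]
        ct = alpha.sum()
        ll += math.log(ct) + m[t]
        alpha /= ct
    return ll


def _em_once(
    x: np.ndarray,
    means: np.ndarray,
    variances: np.ndarray,
    transmat: np.ndarray,
    startprob: np.ndarray,
    max_iter: int,
    tol: float,
    var_floor: float,
) -> HmmModel:
    n, K = len(x), len(means)
    history = []
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        logb = _emission_log_pdf(x, means, variances)
        m = logb.max(axis=1)
        b = np.exp(logb - m[:, None])

        # scaled forward
        alpha = np.empty((n, K))
        c = np.empty(n)
        a = startprob * b[0]
        c[0] = a.sum()
        alpha[0] = a / c[0]
        for t in range(1, n):
            a = (alpha[t - 1] @ transmat) * b[t]
            c[t] = a.sum()
            alpha[t] = a / c[t]
        ll = float(np.log(c).sum() + m.sum())
        history.append(ll)

        # scaled backward
        beta = np.empty((n, K))
        beta[-1] = 1.0
        for t in range(n - 2, -1, -1):
            beta[t] = (transmat @ (b[t + 1] * beta[t + 1])) / c[t + 1]

        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)

        if K > 1 and n > 1:
            num = np.zeros((K, K))
            for t in range(n - 1):
                xi = (alpha[t][:, None] * transmat) * (b[t + 1] * beta[t + 1])[None, :] / c[t + 1]
                num += xi
            denom = gamma[:-1].sum(axis=0)
            new_A = np.where(denom[:, None] > 0, num / np.maximum(denom[:, None], 1e-300), transmat)
            new_A /= new_A.sum(axis=1, keepdims=True)
        else:
            new_A = transmat

        w = gamma.sum(axis=0)
        safe_w = np.maximum(w, 1e-300)
        new_means = np.where(w > 0, (gamma * x[:, None]).sum(axis=0) / safe_w, means)
        dev = (x[:, None] - new_means[None, :]) ** 2
        new_vars = np.where(w > 0, (gamma * dev).sum(axis=0) / safe_w, variances)
        new_vars = np.maximum(new_vars, var_floor)

        startprob = gamma[0]
        transmat, means, variances = new_A, new_means, new_vars

        if abs(ll - prev_ll) < tol * (1.0 + abs(ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    return HmmModel(
        means=means,
        variances=variances,
        transmat=transmat,
        startprob=startprob,
        log_likelihood=prev_ll,
        loglik_history=np.asarray(history),
        converged=converged,
        n_obs=n,
    )


def fit_hmm(
    values: np.ndarray,
    K: int,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    var_floor: float = VAR_FLOOR,
) -> HmmModel:
    """Fit a K-state Gaussian HMM to one chromosome's observed values.

    Restarts start from quantile-spread means (the first restart exactly
    at the K interior quantiles, later ones jittered); the best final
    likelihood wins. The EM log likelihood is non-decreasing across
    iterations up to the variance-floor projection.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < K:
        raise DegenerateFitError(f"need at least K={K} observations, got {n}")
    if len(np.unique(x)) < K:
        raise DegenerateFitError(f"K={K} exceeds the number of distinct values")
    rng = np.random.default_rng(np.random.SeedSequence(abs(int(seed))))
    spread = float(np.ptp(x))
    # spread initial means across the full value range so minority levels
    # (short altered segments) seed their own state
    base_means = (
        np.array([float(np.median(x))]) if K == 1 else np.quantile(x, np.linspace(0.0, 1.0, K))
    )
    var0 = max(float(np.var(x)), var_floor)
    best: HmmModel | None = None
    restarts = 1 if K == 1 else max(1, n_restarts)  # K=1 EM is closed-form
    for r in range(restarts):
        means = base_means.copy()
        if r > 0:
            means = means + rng.normal(0.0, 0.2 * max(spread, 1e-3), size=K)
        if K > 1:
            A = np.full((K, K), 0.1 / (K - 1))
            np.fill_diagonal(A, 0.9)
        else:
            A = np.ones((1, 1))
        pi = np.full(K, 1.0 / K)
        fit = _em_once(x, means, np.full(K, var0), A, pi, max_iter, tol, var_floor)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best


def select_model(fits: list[HmmModel]) -> HmmModel:
    """Pick the fit minimizing BIC; ties (within 1e-9) go to the smaller K."""
    if not fits:
        raise DegenerateFitError("no fits to select from")
    ordered = sorted(fits, key=lambda f: f.K)
    best = ordered[0]
    best_bic = best.bic()
    for fit in ordered[1:]:
        b = fit.bic()
        if b < best_bic - 1e-9:
            best, best_bic = fit, b
    return best


def viterbi_decode(model: HmmModel, values: np.ndarray) -> np.ndarray:
    """Maximum a-posteriori state path for observed values under a model."""
    x = np.asarray(values, dtype=float)
    n, K = len(x), model.K
    logb = _emission_log_pdf(x, model.means, model.variances)
    with np.errstate(divide="ignore"):
        logA = np.log(model.transmat)
        logpi = np.log(model.startprob)
    delta = logpi + logb[0]
    psi = np.zeros((n, K), dtype=int)
    for t in range(1, n):
        scores = delta[:, None] + logA
        psi[t] = scores.argmax(axis=0)
        delta = scores.max(axis=0) + logb[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def path_log_probability(model: HmmModel, values: np.ndarray, path: np.ndarray) -> float:
    """Joint log probability of one state path and the observations."""
    x = np.asarray(values, dtype=float)
    logb = _emission_log_pdf(x, model.means, model.variances)
    with np.errstate(divide="ignore"):
        lp = math.log(model.startprob[path[0]]) if model.startprob[path[0]] > 0 else -np.inf
        lp += logb[0, path[0]]
        for t in range(1, len(x)):
            a = model.transmat[path[t - 1], path[t]]
            lp += (math.log(a) if a > 0 else -np.inf) + logb[t, path[t]]
    return lp


# ---------------------------------------------------------------------------
# Penalized piecewise-constant smoother (exact DP)
# ---------------------------------------------------------------------------

def smooth_segment(
    values: np.ndarray,
    lam: float = 0.1,
    merge_tol: float = 0.1,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Exact minimizer of SSE + lam·(#breakpoints) on one chromosome.

    Returns ``(bounds, means)`` where bounds are (start, end) inclusive
    indices into the observed (non-missing) value vector. After the DP,
    adjacent segments whose means differ by less than ``merge_tol`` are
    merged greedily (closest pair first) and means recomputed.
    """
    if lam <= 0:
        raise ConfigError("breakpoint penalty lambda must be > 0")
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n == 0:
        raise ConfigError("need at least one non-missing clone")
    S = np.concatenate([[0.0], np.cumsum(x)])
    S2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i: int, j: int) -> float:  # x[i:j], half-open
        s = S[j] - S[i]
        return (S2[j] - S2[i]) - s * s / (j - i)

    # dp[j]: best cost of x[:j] with a lam charge per segment; subtracting
    # one lam at the end converts per-segment to per-breakpoint charging.
    dp = np.full(n + 1, np.inf)
    dp[0] = -lam
    back = np.zeros(n + 1, dtype=int)
    for j in range(1, n + 1):
        best, arg = np.inf, 0
        for i in range(j):
            c = dp[i] + sse(i, j) + lam
            if c < best:
                best, arg = c, i
        dp[j] = best
        back[j] = arg
    bounds: list[tuple[int, int]] = []
    j = n
    while j > 0:
        i = back[j]
        bounds.append((i, j - 1))
        j = i
    bounds.reverse()
    means = np.array([(S[b + 1] - S[a]) / (b - a + 1) for a, b in bounds])

    # merge near-equal neighbours, closest pair first
    while len(bounds) > 1:
        diffs = np.abs(np.diff(means))
        k = int(diffs.argmin())
        if diffs[k] >= merge_tol:
            break
        a0, _ = bounds[k]
        _, b1 = bounds[k + 1]
        bounds[k : k + 2] = [(a0, b1)]
        merged = (S[b1 + 1] - S[a0]) / (b1 - a0 + 1)
        means = np.concatenate([means[:k], [merged], means[k + 2 :]])
    return bounds, means


def smooth_cost(values: np.ndarray, bounds: list[tuple[int, int]], lam: float) -> float:
    """Objective value SSE + lam·(#breakpoints) of a given segmentation."""
    x = np.asarray(values, dtype=float)
    total = 0.0
    for a, b in bounds:
        seg = x[a : b + 1]
        total += float(((seg - seg.mean()) ** 2).sum())
    return total + lam * (len(bounds) - 1)


# ---------------------------------------------------------------------------
# Profile-level wrappers
# ---------------------------------------------------------------------------

def _segments_from_levels(
    chrom: str,
    positions: np.ndarray,
    obs: np.ndarray,
    level_id: np.ndarray,
    states: np.ndarray | None = None,
) -> list[Segment]:
    """Collapse runs of equal level id over the observed clones."""
    segs: list[Segment] = []
    start = 0
    for t in range(1, len(obs) + 1):
        if t == len(obs) or level_id[t] != level_id[start]:
            members = obs[start:t]
            segs.append(
                Segment(
                    chrom=chrom,
                    start_index=int(positions[start]),
                    end_index=int(positions[t - 1]),
                    mean=float(members.mean()),
                    n_clones=t - start,
                    state=int(states[start]) if states is not None else None,
                )
            )
            start = t
    return segs


def segment_profile_hmm(
    profile: SampleProfile,
    clone_map: CloneMap,
    k_max: int = 5,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SegmentedProfile:
    """HMM route: per chromosome, fit K = 1..k_max, select by BIC, decode."""
    fitted = np.full(clone_map.n_clones, np.nan)
    segments: list[Segment] = []
    for ci, (chrom, rows) in enumerate(clone_map.chrom_indices().items()):
        vals = profile.values[rows]
        present = np.isfinite(vals)
        if not present.any():
            continue
        obs = vals[present]
        positions = rows[present]
        kcap = min(k_max, len(np.unique(obs)), len(obs))
        fits = []
        rising = 0
        for K in range(1, kcap + 1):
            sub_seed = np.random.SeedSequence(abs(int(seed)), spawn_key=(ci, K)).generate_state(1)[0] % (2**31)
            fits.append(fit_hmm(obs, K, n_restarts=n_restarts, seed=int(sub_seed),
                                max_iter=max_iter, tol=tol))
            # stop scanning K once BIC has risen twice in a row
            if len(fits) > 1 and fits[-1].bic() > fits[-2].bic():
                rising += 1
                if rising >= 2:
                    break
            else:
                rising = 0
        model = select_model(fits)
        path = viterbi_decode(model, obs)
        segs = _segments_from_levels(chrom, positions, obs, path, states=path)
        for seg in segs:
            fitted[positions[(positions >= seg.start_index) & (positions <= seg.end_index)]] = seg.mean
        segments.extend(segs)
    return SegmentedProfile(sample_id=profile.sample_id, segments=segments, fitted=fitted)


def segment_profile_smooth(
    profile: SampleProfile,
    clone_map: CloneMap,
    lam: float = 0.1,
    merge_tol: float = 0.1,
) -> SegmentedProfile:
    """Smoothing route: exact DP per chromosome, then the merge pass."""
    fitted = np.full(clone_map.n_clones, np.nan)
    segments: list[Segment] = []
    for chrom, rows in clone_map.chrom_indices().items():
        vals = profile.values[rows]
        present = np.isfinite(vals)
        if not present.any():
            continue
        obs = vals[present]
        positions = rows[present]
        bounds, means = smooth_segment(obs, lam=lam, merge_tol=merge_tol)
        level = np.empty(len(obs), dtype=int)
        for sid, (a, b) in enumerate(bounds):
            level[a : b + 1] = sid
        segs = _segments_from_levels(chrom, positions, obs, level)
        for seg, m in zip(segs, means):
            seg.mean = float(m)
            sel = (positions >= seg.start_index) & (positions <= seg.end_index)
            fitted[positions[sel]] = seg.mean
        segments.extend(segs)
    return SegmentedProfile(sample_id=profile.sample_id, segments=segments, fitted=fitted)
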