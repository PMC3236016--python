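import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stn

from acghpipe.errors import ConfigError, DegenerateFitError
from acghpipe.segmentation import (
    HmmModel,
    fit_hmm,
    forward_log_likelihood,
    segment_profile_hmm,
    segment_profile_smooth,
    select_model,
    smooth_cost,
    smooth_segment,
    viterbi_decode,
)

from conftest import make_profile

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_best_path_logprob(means, variances, transmat, startprob, x):
    """Exhaustive maximum over all K^n state paths of the joint log density."""
    K, n = len(means), len(x)
    best = -np.inf
    for path in itertools.product(range(K), repeat=n):
        lp = math.log(startprob[path[0]]) if startprob[path[0]] > 0 else -np.inf
        for t in range(n):
            v = variances[path[t]]
            lp += -0.5 * ((x[t] - means[path[t]]) ** 2 / v + math.log(2 * math.pi * v))
            if t > 0:
                a = transmat[path[t - 1], path[t]]
                lp += math.log(a) if a > 0 else -np.inf
        best = max(best, lp)
    return best


def brute_force_smooth_cost(x, lam):
    """Minimum of SSE + lam·(#breakpoints) over all 2^(n-1) breakpoint sets."""
    n = len(x)
    best = np.inf
    for mask in range(2 ** (n - 1)):
        cost = 0.0
        start = 0
        nseg = 0
        for i in range(n):
            if i == n - 1 or (mask >> i) & 1:
                seg = x[start : i + 1]
                cost += float(((seg - seg.mean()) ** 2).sum())
                nseg += 1
                start = i + 1
        best = min(best, cost + lam * (nseg - 1))
    return best


def random_model(rng, K):
    A = rng.dirichlet(np.ones(K) * 2.0, size=K)
    pi = rng.dirichlet(np.ones(K))
    return HmmModel(
        means=rng.normal(0, 1, K),
        variances=rng.uniform(0.05, 0.5, K),
        transmat=A,
        startprob=pi,
        log_likelihood=0.0,
        loglik_history=np.array([]),
        converged=True,
        n_obs=0,
    )


# ---------------------------------------------------------------------------
# HMM fitting
# ---------------------------------------------------------------------------

class TestFitHmm:
    def test_constant_chromosome_closed_form(self):
        x = np.zeros(20)
        fit = fit_hmm(x, K=1)
        assert fit.means[0] == pytest.approx(0.0)
        # variance hits the floor; the likelihood is the single-Gaussian value
        expected = 20 * (-0.5 * math.log(2 * math.pi * 1e-4))
        assert fit.log_likelihood == pytest.approx(expected, rel=1e-6)

    def test_two_block_mean_recovery(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0, 0.05, 50), rng.normal(0.6, 0.05, 50)])
        fit = fit_hmm(x, K=2, seed=1)
        means = np.sort(fit.means)
        assert means[0] == pytest.approx(0.0, abs=0.03)
        assert means[1] == pytest.approx(0.6, abs=0.03)

    def test_k_exceeding_distinct_values_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_hmm(np.array([0.0, 0.0, 1.0, 1.0]), K=3)

    @given(seed=stn.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_em_loglikelihood_monotone(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(8, 40)
        x = rng.normal(0, 0.3, n) + rng.choice([0.0, 0.6], size=n)
        fit = fit_hmm(x, K=2, n_restarts=1, seed=seed)
        diffs = np.diff(fit.loglik_history)
        assert (diffs >= -1e-8).all()

    def test_forward_likelihood_matches_hmmlearn(self):
        from hmmlearn.hmm import GaussianHMM

        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 0.1, 30), rng.normal(0.5, 0.1, 30)])
        fit = fit_hmm(x, K=2, seed=2)
        ref = GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        ref.means_ = fit.means.reshape(-1, 1)
        ref.covars_ = fit.variances.reshape(-1, 1)
        ref.transmat_ = fit.transmat
        ref.startprob_ = fit.startprob
        assert ref.score(x.reshape(-1, 1)) == pytest.approx(fit.log_likelihood, abs=1e-6)
        assert forward_log_likelihood(fit, x) == pytest.approx(fit.log_likelihood, abs=1e-8)


class TestSelectModel:
    def test_constant_data_selects_one_state(self):
        x = np.zeros(30)
        fits = [fit_hmm(x, K=1)]
        assert select_model(fits).K == 1

    def test_two_block_selects_two_states(self):
        rng = np.random.default_rng(21)
        x = np.concatenate([rng.normal(0, 0.05, 50), rng.normal(0.6, 0.05, 50)])
        fits = [fit_hmm(x, K, seed=3) for K in (1, 2, 3)]
        best = select_model(fits)
        assert best.K == 2
        bics = {f.K: f.bic() for f in fits}
        assert bics[2] < bics[1] and bics[2] < bics[3]

    def test_bic_tie_prefers_smaller_k(self):
        def model(K, ll, n):
            return HmmModel(
                means=np.zeros(K), variances=np.ones(K),
                transmat=np.full((K, K), 1.0 / K), startprob=np.full(K, 1.0 / K),
                log_likelihood=ll, loglik_history=np.array([]), converged=True, n_obs=n,
            )

        n = 50
        m1 = model(1, -10.0, n)
        # give K=2 exactly the loglik that equalizes the two BICs
        p2 = 2 * (2 + 2) - 1
        ll2 = (-2.0 * m1.log_likelihood + (m1.n_parameters - p2) * math.log(n)) / -2.0
        m2 = model(2, ll2, n)
        assert abs(m1.bic() - m2.bic()) < 1e-9
        assert select_model([m1, m2]).K == 1


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------

class TestViterbi:
    def test_single_state_single_segment(self, tiny_map):
        prof = make_profile([0.1, 0.1, 0.1])
        seg = segment_profile_hmm(prof, tiny_map, k_max=1)
        assert len(seg.segments) == 1
        assert seg.segments[0].n_clones == 3

    def test_six_clone_path_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        model = random_model(rng, 3)
        x = rng.normal(0, 1, 6)
        path = viterbi_decode(model, x)
        from acghpipe.segmentation import path_log_probability

        lp = path_log_probability(model, x, path)
        best = brute_force_best_path_logprob(
            model.means, model.variances, model.transmat, model.startprob, x
        )
        assert lp == pytest.approx(best, abs=1e-9)

    @given(seed=stn.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_viterbi_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(1, 4))
        n = int(rng.integers(2, 9))
        model = random_model(rng, K)
        x = rng.normal(0, 1, n)
        from acghpipe.segmentation import path_log_probability

        lp = path_log_probability(model, x, viterbi_decode(model, x))
        best = brute_force_best_path_logprob(
            model.means, model.variances, model.transmat, model.startprob, x
        )
        assert lp == pytest.approx(best, abs=1e-9)

    def test_two_block_single_breakpoint_located(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = np.concatenate([rng.normal(0, 0.05, 50), rng.normal(0.6, 0.05, 50)])
            fit = fit_hmm(x, K=2, seed=seed)
            path = viterbi_decode(fit, x)
            changes = np.flatnonzero(np.diff(path)) + 1
            if len(changes) == 1 and abs(changes[0] - 50) <= 2:
                hits += 1
        assert hits >= 38  # ≥95%


# ---------------------------------------------------------------------------
# DP smoother
# ---------------------------------------------------------------------------

class TestSmoother:
    def test_constant_profile_has_no_breakpoints(self):
        bounds, means = smooth_segment(np.full(20, 0.2), lam=0.5)
        assert bounds == [(0, 19)]
        assert means[0] == pytest.approx(0.2)

    def test_step_profile_forced_single_breakpoint(self):
        x = np.concatenate([np.zeros(6), np.ones(6)])
        bounds, means = smooth_segment(x, lam=0.5)
        assert bounds == [(0, 5), (6, 11)]
        np.testing.assert_allclose(means, [0.0, 1.0])

    def test_twelve_clone_dp_matches_exhaustive(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 0.5, 12)
        bounds, _ = smooth_segment(x, lam=0.5, merge_tol=0.0)
        assert smooth_cost(x, bounds, 0.5) == pytest.approx(
            brute_force_smooth_cost(x, 0.5), abs=1e-9
        )

    @given(seed=stn.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_dp_equals_exhaustive_breakpoint_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        lam = float(rng.uniform(0.05, 1.0))
        x = rng.normal(0, 0.5, n)
        bounds, _ = smooth_segment(x, lam=lam, merge_tol=0.0)
        assert smooth_cost(x, bounds, lam) == pytest.approx(
            brute_force_smooth_cost(x, lam), abs=1e-9
        )

    def test_merge_pass_collapses_near_equal_segments(self):
        # two levels 0.04 apart survive the DP but are merged at tol 0.1
        x = np.concatenate([np.full(6, 0.0), np.full(6, 0.04)])
        bounds, means = smooth_segment(x, lam=1e-4, merge_tol=0.1)
        assert bounds == [(0, 11)]
        assert means[0] == pytest.approx(0.02)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ConfigError):
            smooth_segment(np.zeros(5), lam=0.0)


# ---------------------------------------------------------------------------
# profile-level wrappers
# ---------------------------------------------------------------------------

class TestProfileSegmentation:
    def test_segments_never_cross_chromosomes(self, two_chrom_map):
        prof = make_profile(np.full(20, 0.3))
        for seg in (
            segment_profile_smooth(prof, two_chrom_map),
            segment_profile_hmm(prof, two_chrom_map, k_max=2),
        ):
            assert len(seg.segments) == 2
            assert {s.chrom for s in seg.segments} == {"1", "2"}
            assert seg.segments[0].end_index == 9
            assert seg.segments[1].start_index == 10

    def test_missing_clones_are_bridged(self, two_chrom_map):
        vals = np.full(20, 0.1)
        vals[3] = np.nan
        seg = segment_profile_smooth(make_profile(vals), two_chrom_map)
        assert np.isnan(seg.fitted[3])
        chrom1 = [s for s in seg.segments if s.chrom == "1"]
        assert len(chrom1) == 1
        assert chrom1[0].n_clones == 9  # informative clones only

    def test_translation_equivariance(self, two_chrom_map):
        rng = np.random.default_rng(13)
        base = rng.normal(0, 0.1, 20)
        base[5:10] += 0.6
        shift = 0.25
        a = segment_profile_smooth(make_profile(base), two_chrom_map)
        b = segment_profile_smooth(make_profile(base + shift), two_chrom_map)
        np.testing.assert_allclose(b.fitted, a.fitted + shift, atol=1e-9)
        ah = segment_profile_hmm(make_profile(base), two_chrom_map, seed=17)
        bh = segment_profile_hmm(make_profile(base + shift), two_chrom_map, seed=17)
        np.testing.assert_allclose(bh.fitted, ah.fitted + shift, atol=1e-6)
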