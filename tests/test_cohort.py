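import io
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as stn

from acghpipe.cohort import (
    assign_response,
    chi_square_association,
    cluster_from_distance,
    cohort_report,
    dendrogram_to_newick,
    extreme_response,
    hierarchical_cluster,
    kruskal_wallis,
    pairwise_call_distance,
    region_frequency_test,
)
from acghpipe.errors import JoinError, ValidationError
from acghpipe.io_formats import validate_cohort

import scipy.stats as st


# ---------------------------------------------------------------------------
# independent Fisher oracle: exact hypergeometric enumeration with integers
# ---------------------------------------------------------------------------

def fisher_two_sided_exact(table) -> float:
    (a, b), (c, d) = table
    n1, n2 = a + c, b + d
    k = a + b
    N = n1 + n2
    if k == 0 or k == N or n1 == 0 or n2 == 0:
        return 1.0

    def weight(x):  # numerator of P(X = x), common denominator C(N, k)
        return math.comb(n1, x) * math.comb(n2, k - x)

    w_obs = weight(a)
    total = sum(weight(x) for x in range(max(0, k - n2), min(k, n1) + 1) if weight(x) <= w_obs)
    return float(Fraction(total, math.comb(N, k)))


class TestResponse:
    @pytest.mark.parametrize("trg,expected", [(0, False), (1, False), (2, False), (3, True), (4, True)])
    def test_responder_cut(self, trg, expected):
        assert assign_response(trg) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            assign_response(5)
        with pytest.raises(ValidationError):
            assign_response(-1)

    def test_extreme_class_variant(self):
        assert extreme_response(4) is True
        assert extreme_response(0) is False and extreme_response(1) is False
        assert extreme_response(2) is None and extreme_response(3) is None


class TestClustering:
    def test_hand_run_average_linkage(self):
        # d(A,B)=1, d(A,C)=5, d(B,C)=5: A,B merge first, final height 5
        dist = np.array([1.0, 5.0, 5.0])  # condensed order: AB, AC, BC
        dend = cluster_from_distance(dist, ["A", "B", "C"], linkage="average", k=2)
        Z = dend.linkage_matrix
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(5.0)
        assert dend.clusters["A"] == dend.clusters["B"] != dend.clusters["C"]

    def test_identical_profiles_merge_at_zero(self):
        calls = pd.DataFrame({"A": [1, 0, -1], "B": [1, 0, -1], "C": [0, 1, 1]}, dtype=float)
        dend = hierarchical_cluster(calls, k=2)
        assert dend.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert dend.clusters["A"] == dend.clusters["B"]

    def test_na_aware_hamming_normalizes_by_comparable_clones(self):
        calls = pd.DataFrame(
            {"A": [1, 0, np.nan, 0], "B": [1, 1, 1, np.nan]}, dtype=float
        )
        d = pairwise_call_distance(calls, metric="hamming")
        assert d[0] == pytest.approx(0.5)  # 1 mismatch over 2 comparable clones

    def test_heights_non_decreasing_under_average_linkage(self):
        rng = np.random.default_rng(3)
        calls = pd.DataFrame(
            rng.choice([-1, 0, 0, 0, 1], size=(40, 10)).astype(float),
            columns=[f"S{i}" for i in range(10)],
        )
        dend = hierarchical_cluster(calls, k=3)
        heights = dend.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_k_larger_than_n_rejected(self):
        calls = pd.DataFrame({"A": [1.0], "B": [0.0]})
        with pytest.raises(ValidationError):
            hierarchical_cluster(calls, k=3)

    def test_newick_export_is_parseable(self):
        from Bio import Phylo

        dist = np.array([1.0, 5.0, 5.0])
        dend = cluster_from_distance(dist, ["A", "B", "C"], k=2)
        tree = Phylo.read(io.StringIO(dendrogram_to_newick(dend)), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["A", "B", "C"]


class TestFisher:
    def test_degenerate_table_gives_p_one(self):
        tests = region_frequency_test(
            pd.DataFrame({"r": ["none"] * 23}, index=[f"S{i}" for i in range(23)]),
            pd.Series(["g1"] * 10 + ["g2"] * 13, index=[f"S{i}" for i in range(23)]),
        )
        assert all(t.p_value == pytest.approx(1.0) for t in tests)

    def test_known_small_tables(self):
        assert st.fisher_exact([[1, 0], [9, 13]])[1] == pytest.approx(10 / 23, abs=1e-12)
        assert st.fisher_exact([[4, 0], [6, 13]])[1] == pytest.approx(
            fisher_two_sided_exact([[4, 0], [6, 13]]), abs=1e-12
        )
        assert fisher_two_sided_exact([[4, 0], [6, 13]]) == pytest.approx(0.0237, abs=5e-4)

    @given(
        a=stn.integers(0, 12), b=stn.integers(0, 12),
        c=stn.integers(0, 12), d=stn.integers(0, 12),
    )
    @settings(max_examples=150, deadline=None)
    def test_fisher_matches_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p_scipy = st.fisher_exact([[a, b], [c, d]])[1]
        assert p_scipy == pytest.approx(fisher_two_sided_exact([[a, b], [c, d]]), abs=1e-12)

    def test_invariance_under_group_and_row_swaps(self):
        t = [[3, 1], [7, 12]]
        p = st.fisher_exact(t)[1]
        assert st.fisher_exact([[1, 3], [12, 7]])[1] == pytest.approx(p, abs=1e-12)
        assert st.fisher_exact([[7, 12], [3, 1]])[1] == pytest.approx(p, abs=1e-12)


class TestRegionFrequency:
    def test_counts_percentages_and_p(self):
        idx = [f"S{i}" for i in range(23)]
        status = pd.DataFrame({"r": ["amplified"] * 4 + ["none"] * 19}, index=idx)
        groups = pd.Series(["g1"] * 10 + ["g2"] * 13, index=idx)
        tests = {(t.region, t.alteration): t for t in region_frequency_test(status, groups)}
        amp = tests[("r", "amplified")]
        assert (amp.k1, amp.n1, amp.k2, amp.n2) == (4, 10, 0, 13)
        assert amp.freq1_pct == 40 and amp.freq2_pct == 0
        assert amp.p_value == pytest.approx(fisher_two_sided_exact([[4, 0], [6, 13]]), abs=1e-12)

    def test_empty_group_rejected(self):
        status = pd.DataFrame({"r": ["none", "none"]}, index=["a", "b"])
        with pytest.raises(ValidationError):
            region_frequency_test(status, pd.Series(["g1", "g1"], index=["a", "b"]))


class TestKruskalWallis:
    def test_complete_tie_symmetry(self):
        res = kruskal_wallis([1, 2, 1, 2], ["a", "a", "b", "b"])
        assert res.h == pytest.approx(0.0)

    def test_separated_groups_hand_value(self):
        res = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.h == pytest.approx(3.8571, abs=1e-4)
        assert res.p_exact == pytest.approx(2 / 20)

    def test_invariant_under_monotone_transform(self):
        x = np.array([0.3, 1.2, 0.7, 2.5, 1.9, 0.1])
        g = ["a", "a", "b", "b", "a", "b"]
        r1 = kruskal_wallis(x, g)
        r2 = kruskal_wallis(np.exp(x), g)
        assert r1.h == pytest.approx(r2.h, abs=1e-12)

    def test_matches_scipy_with_ties(self):
        x = [1.0, 1.0, 2.0, 3.0, 3.0, 4.0, 5.0]
        g = ["a", "b", "a", "b", "a", "b", "a"]
        res = kruskal_wallis(x, g)
        h, p = st.kruskal(
            [xi for xi, gi in zip(x, g) if gi == "a"],
            [xi for xi, gi in zip(x, g) if gi == "b"],
        )
        assert res.h == pytest.approx(h) and res.p_value == pytest.approx(p)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])


class TestChiSquare:
    def test_independent_table(self):
        chi2, p = chi_square_association([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        chi2, _ = chi_square_association([[20, 10], [10, 20]])
        assert chi2 == pytest.approx(6.6667, abs=1e-4)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_association([[5, 5]])

    def test_zero_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            chi2, _ = chi_square_association([[10, 5, 0], [5, 10, 0]])
        ref, _ = chi_square_association([[10, 5], [5, 10]])
        assert chi2 == pytest.approx(ref)


class TestReport:
    def make_cohort(self, n_resp=2, n_nonresp=2):
        rows = []
        for i in range(n_resp):
            rows.append((f"R{i}", 4))
        for i in range(n_nonresp):
            rows.append((f"N{i}", 1))
        return validate_cohort(pd.DataFrame(rows, columns=["sample_id", "trg"]))

    def test_forced_cluster_separation(self):
        cohort = self.make_cohort()
        calls = pd.DataFrame(
            {
                "R0": np.zeros(30), "R1": np.zeros(30),
                "N0": np.ones(30), "N1": np.ones(30),
            }
        )
        fga = pd.DataFrame(
            {"sample_id": ["R0", "R1", "N0", "N1"], "fga": [0.0, 0.0, 1.0, 1.0]}
        )
        dend = hierarchical_cluster(calls, k=2)
        report = cohort_report(cohort, fga, dendrogram=dend)
        fracs = sorted(c["responder_pct"] for c in report["clusters"])
        assert fracs == [0, 100]

    def test_zero_variance_fga_reports_h0_p1(self):
        cohort = self.make_cohort()
        fga = pd.DataFrame({"sample_id": ["R0", "R1", "N0", "N1"], "fga": [0.1] * 4})
        report = cohort_report(cohort, fga)
        assert report["fga_by_response"]["h"] == 0.0
        assert report["fga_by_response"]["p_value"] == 1.0

    def test_percentages_are_integers(self):
        cohort = self.make_cohort(n_resp=1, n_nonresp=2)
        fga = pd.DataFrame({"sample_id": ["R0", "N0", "N1"], "fga": [0.0, 0.1, 0.2]})
        report = cohort_report(cohort, fga)
        assert report["responder_pct"] == 33
        assert report["nonresponder_pct"] == 67

    def test_sample_mismatch_raises_join_error(self):
        cohort = self.make_cohort()
        fga = pd.DataFrame({"sample_id": ["R0", "R1", "N0", "OTHER"], "fga": [0.1] * 4})
        with pytest.raises(JoinError, match="OTHER"):
            cohort_report(cohort, fga)
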