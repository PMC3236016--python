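"""Cohort-level analyses.

Response grouping by tumor regression grade (TRG, Dworak 0–4): TRG 3–4
are responders, TRG 0–2 non-responders; the extreme-class variant opposes
TRG 4 to TRG 0–1 and excludes the middle grades. Call profiles are
clustered by NA-aware agglomerative clustering, regional alteration
frequencies are compared between response groups with Fisher's exact test
(or Pearson chi-square), and the fraction of genome altered (FGA) is
related to response and stage with the Kruskal-Wallis rank test.

The standard statistics are delegated to scipy (``fisher_exact``,
``kruskal``, ``chi2_contingency``, ``cluster.hierarchy``); this module
owns the NA-aware distances, the exact-permutation option and the report
assembly. Raw p values are reported without multiple-testing correction
by default; Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st

from .errors import JoinError, ValidationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Response grouping
# ---------------------------------------------------------------------------

def assign_response(trg: int) -> bool:
    """Responder flag from TRG: grades 3–4 respond, 0–2 do not."""
    t = int(trg)
    if not 0 <= t <= 4:
        raise ValidationError(f"TRG must be in 0..4, got {trg}")
    return t >= 3


def extreme_response(trg: int) -> bool | None:
    """Extreme-class variant: TRG4 → True, TRG0-1 → False, TRG2-3 → None."""
    t = int(trg)
    if not 0 <= t <= 4:
        raise ValidationError(f"TRG must be in 0..4, got {trg}")
    if t == 4:
        return True
    if t <= 1:
        return False
    return None


# ---------------------------------------------------------------------------
# Hierarchical clustering of call profiles
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray          # scipy (n-1, 4) merge list
    labels: list[str]
    leaf_order: list[str]
    clusters: pd.Series                 # sample_id -> cluster id (1..k)
    k: int


def pairwise_call_distance(call_df: pd.DataFrame, metric: str = "hamming") -> np.ndarray:
    """Condensed NA-aware distance over samples (columns of ``call_df``).

    Each pair is compared on the clones informative in both samples and
    normalized by that count: hamming is the mismatch fraction, euclidean
    the root mean squared difference.
    """
    if metric not in ("hamming", "euclidean"):
        raise ValidationError(f"unknown metric {metric!r}")
    X = call_df.to_numpy(dtype=float).T  # samples × clones
    n = X.shape[0]
    out = np.empty(n * (n - 1) // 2)
    idx = 0
    finite = np.isfinite(X)
    for i in range(n):
        for j in range(i + 1, n):
            both = finite[i] & finite[j]
            m = int(both.sum())
            if m == 0:
                raise ValidationError(
                    f"samples {call_df.columns[i]} and {call_df.columns[j]} share no informative clones"
                )
            d = X[i, both] - X[j, both]
            out[idx] = (d != 0).mean() if metric == "hamming" else math.sqrt((d * d).mean())
            idx += 1
    return out


def cluster_from_distance(
    dist: np.ndarray,
    labels: Sequence[str],
    linkage: str = "average",
    k: int = 5,
) -> Dendrogram:
    """Agglomerate a condensed distance matrix and cut at k clusters."""
    n = len(labels)
    if n < 2:
        raise ValidationError("clustering needs at least 2 samples")
    if k > n:
        raise ValidationError(f"cannot cut {n} samples into k={k} clusters")
    Z = sch.linkage(dist, method=linkage)
    assignment = sch.fcluster(Z, t=k, criterion="maxclust")
    order = [labels[i] for i in sch.leaves_list(Z)]
    return Dendrogram(
        linkage_matrix=Z,
        labels=list(labels),
        leaf_order=order,
        clusters=pd.Series(assignment, index=list(labels), name="cluster"),
        k=k,
    )


def hierarchical_cluster(
    call_df: pd.DataFrame,
    metric: str = "hamming",
    linkage: str = "average",
    k: int = 5,
) -> Dendrogram:
    """Unsupervised clustering of samples by their call profiles."""
    if call_df.isna().all(axis=0).any():
        bad = call_df.columns[call_df.isna().all(axis=0)].tolist()
        raise ValidationError(f"all-NA samples cannot be clustered: {bad}")
    dist = pairwise_call_distance(call_df, metric=metric)
    return cluster_from_distance(dist, list(call_df.columns), linkage=linkage, k=k)


def dendrogram_to_newick(dend: Dendrogram) -> str:
    """Serialize the merge tree as Newick with height-difference branch lengths."""
    tree = sch.to_tree(dend.linkage_matrix)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{dend.labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# Regional frequency comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionTest:
    region: str
    alteration: str          # "amplified" | "deleted"
    group_names: tuple[str, str]
    k1: int
    n1: int
    k2: int
    n2: int
    freq1_pct: int
    freq2_pct: int
    p_value: float
    test: str


def region_frequency_test(
    status_df: pd.DataFrame,
    groups: pd.Series,
    test: str = "fisher",
    bh_correct: bool = False,
) -> list[RegionTest]:
    """Compare per-region alteration frequencies between two groups.

    ``status_df`` is the sample × region status table; ``groups`` maps
    sample_id to one of exactly two labels. For each region and each
    alteration type a 2×2 table (altered vs not × group) is built and the
    two-sided Fisher exact p (probability-mass rule) or Pearson
    chi-square p computed. Frequencies are reported as integer-rounded
    percentages of each group's evaluable samples.
    """
    if test not in ("fisher", "chi2"):
        raise ValidationError(f"unknown test {test!r}")
    groups = groups.reindex(status_df.index)
    labels = sorted(groups.dropna().unique(), key=str)
    if len(labels) != 2:
        raise ValidationError(f"need exactly two groups, got {labels}")
    g1 = status_df.index[groups == labels[0]]
    g2 = status_df.index[groups == labels[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValidationError("both groups must be nonempty")
    results: list[RegionTest] = []
    for region in status_df.columns:
        col = status_df[region]
        for alteration in ("amplified", "deleted"):
            s1 = col.loc[g1].dropna()
            s2 = col.loc[g2].dropna()
            k1, n1 = int((s1 == alteration).sum()), len(s1)
            k2, n2 = int((s2 == alteration).sum()), len(s2)
            table = np.array([[k1, k2], [n1 - k1, n2 - k2]])
            if test == "fisher":
                p = float(st.fisher_exact(table, alternative="two-sided")[1])
            else:
                p = chi_square_association(table)[1]
            results.append(
                RegionTest(
                    region=str(region),
                    alteration=alteration,
                    group_names=(str(labels[0]), str(labels[1])),
                    k1=k1, n1=n1, k2=k2, n2=n2,
                    freq1_pct=round(100.0 * k1 / n1) if n1 else 0,
                    freq2_pct=round(100.0 * k2 / n2) if n2 else 0,
                    p_value=p,
                    test=test,
                )
            )
    if bh_correct:
        results = _apply_bh(results)
    return results


def _apply_bh(results: list[RegionTest]) -> list[RegionTest]:
    from statsmodels.stats.multitest import multipletests

    p = [r.p_value for r in results]
    adj = multipletests(p, method="fdr_bh")[1]
    return [
        RegionTest(**{**r.__dict__, "p_value": float(q), "test": r.test + "+bh"})
        for r, q in zip(results, adj)
    ]


# ---------------------------------------------------------------------------
# Rank and chi-square tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KruskalResult:
    h: float
    p_value: float           # chi-square approximation, df = groups - 1
    p_exact: float | None    # full-enumeration permutation p when available


def _kw_h(ranks: np.ndarray, labels: np.ndarray, tie_correction: float) -> float:
    N = len(ranks)
    h = 0.0
    for g in np.unique(labels):
        r = ranks[labels == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    return h / tie_correction if tie_correction > 0 else 0.0


def kruskal_wallis(
    values: Sequence[float],
    labels: Sequence,
    exact_max_n: int = 10,
) -> KruskalResult:
    """Kruskal-Wallis H with tie correction; chi-square p, plus an exact
    permutation p by full enumeration of group assignments when the total
    sample size is at most ``exact_max_n``."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    if np.ptp(values) == 0.0:
        return KruskalResult(h=0.0, p_value=1.0, p_exact=1.0 if len(values) <= exact_max_n else None)
    samples = [values[labels == g] for g in uniq]
    h, p = st.kruskal(*samples)
    p_exact = None
    N = len(values)
    if N <= exact_max_n:
        ranks = st.rankdata(values)
        _, counts = np.unique(values, return_counts=True)
        tie_c = 1.0 - (counts**3 - counts).sum() / (N**3 - N)
        h_obs = _kw_h(ranks, labels, tie_c)
        sizes = [int((labels == g).sum()) for g in uniq]
        total, at_least = 0, 0
        for perm in _group_assignments(N, sizes):
            total += 1
            if _kw_h(ranks, perm, tie_c) >= h_obs - 1e-12:
                at_least += 1
        p_exact = at_least / total
    return KruskalResult(h=float(h), p_value=float(p), p_exact=p_exact)


def _group_assignments(N: int, sizes: list[int]):
    """Yield every distinct assignment of N items to groups of the given sizes."""
    indices = set(range(N))

    def rec(remaining: frozenset, gi: int, current: np.ndarray):
        if gi == len(sizes) - 1:
            out = current.copy()
            out[list(remaining)] = gi
            yield out
            return
        for combo in itertools.combinations(sorted(remaining), sizes[gi]):
            nxt = current.copy()
            nxt[list(combo)] = gi
            yield from rec(remaining - set(combo), gi + 1, nxt)

    yield from rec(frozenset(indices), 0, np.zeros(N, dtype=int))


def chi_square_association(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on an r×c table.

    Zero-margin rows/columns are dropped with a warning before testing;
    a table smaller than 2×2 (before or after dropping) is an error.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError(f"need an r×c table with r,c >= 2, got shape {t.shape}")
    if (t < 0).any():
        raise ValidationError("counts must be non-negative")
    row_ok = t.sum(axis=1) > 0
    col_ok = t.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns before chi-square test")
        t = t[row_ok][:, col_ok]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("table degenerate after dropping zero margins")
    chi2, p, _, _ = st.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def _pct(k: float, n: float) -> int:
    return int(round(100.0 * k / n)) if n else 0


def _kw_or_none(values: pd.Series, labels: pd.Series) -> dict | None:
    mask = values.notna() & labels.notna()
    if mask.sum() < 2 or labels[mask].nunique() < 2:
        return None
    res = kruskal_wallis(values[mask].to_numpy(), labels[mask].to_numpy())
    return {"h": res.h, "p_value": res.p_value}


def cohort_report(
    cohort_df: pd.DataFrame,
    fga_df: pd.DataFrame,
    dendrogram: Dendrogram | None = None,
    region_tests: list[RegionTest] | None = None,
) -> dict:
    """Assemble the cohort-level results: group percentages, FGA rank tests
    against response and post-therapy stage, per-cluster responder
    fractions and the regional frequency table. Percentages are rounded
    to integers, matching the usual tabular presentation."""
    cohort_ids = set(cohort_df["sample_id"])
    fga_ids = set(fga_df["sample_id"])
    if cohort_ids != fga_ids:
        offenders = sorted(cohort_ids ^ fga_ids)
        raise JoinError(f"cohort/FGA sample_id mismatch: {offenders}")
    df = cohort_df.merge(fga_df, on="sample_id")
    n = len(df)
    n_resp = int(df["responder"].sum())

    report: dict = {
        "n_samples": n,
        "responder_pct": _pct(n_resp, n),
        "nonresponder_pct": _pct(n - n_resp, n),
        "trg_pct": {
            int(g): _pct((df["trg"] == g).sum(), n) for g in sorted(df["trg"].unique())
        },
    }
    for col in ("ypt", "ypn", "ut", "un"):
        if col in df.columns:
            known = df[col].dropna()
            report[f"{col}_pct"] = {
                str(v): _pct((known == v).sum(), len(known)) for v in sorted(known.unique(), key=str)
            }
    report["fga_mean_pct"] = float(100.0 * df["fga"].mean())
    report["fga_by_response"] = _kw_or_none(df["fga"], df["responder"])
    for col in ("trg", "ypt", "ypn"):
        if col in df.columns:
            report[f"fga_by_{col}"] = _kw_or_none(df["fga"], df[col])

    if dendrogram is not None:
        merged = df.set_index("sample_id")
        clusters = []
        for cid in sorted(dendrogram.clusters.unique()):
            members = dendrogram.clusters.index[dendrogram.clusters == cid]
            sub = merged.loc[merged.index.intersection(members)]
            clusters.append(
                {
                    "cluster": int(cid),
                    "n": len(sub),
                    "pct_of_cohort": _pct(len(sub), n),
                    "responder_pct": _pct(int(sub["responder"].sum()), len(sub)) if len(sub) else None,
                }
            )
        report["clusters"] = clusters

    if region_tests is not None:
        report["region_tests"] = [
            {
                "region": r.region,
                "alteration": r.alteration,
                "groups": list(r.group_names),
                "freq_pct": [r.freq1_pct, r.freq2_pct],
                "counts": [[r.k1, r.n1], [r.k2, r.n2]],
                "p_value": r.p_value,
                "test": r.test,
            }
            for r in region_tests
        ]
    return report


def write_report(report: dict, outdir: str | Path) -> None:
    """Serialize the report: JSON, plus TSVs for clusters and region tests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "cohort_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    if "clusters" in report:
        pd.DataFrame(report["clusters"]).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    if "region_tests" in report:
        rows = [
            (r["region"], r["alteration"], r["freq_pct"][0], r["freq_pct"][1], r["p_value"], r["test"])
            for r in report["region_tests"]
        ]
        pd.DataFrame(
            rows, columns=["region", "alteration", "freq_group1_pct", "freq_group2_pct", "p_value", "test"]
        ).to_csv(outdir / "region_tests.tsv", sep="\t", index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
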