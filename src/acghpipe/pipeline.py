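"""End-to-end orchestration: simulate → QC/normalize → segment (both
routes) → call → FGA → cohort report. Used by the CLI and by scripts; all
randomness flows from one seed."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import calling, cohort as cohort_mod, io_formats, preprocess, segmentation
from .config import PipelineConfig
from .synthetic import SimulationConfig, simulate_cohort

log = logging.getLogger(__name__)


def sample_seed(seed: int, sample_index: int) -> int:
    """Deterministic per-sample sub-seed below 2^31."""
    return int(
        np.random.SeedSequence(abs(int(seed)), spawn_key=(3, sample_index)).generate_state(1)[0]
        % (2**31)
    )


def preprocess_profiles(spots: pd.DataFrame, clone_map, config: PipelineConfig):
    profiles = preprocess.filter_and_merge_spots(spots, clone_map, config.qc)
    return [
        preprocess.normalize(p, method=config.normalize_method, span=config.lowess_span)
        for p in profiles
    ]


def segment_profiles(profiles, clone_map, config: PipelineConfig, seed: int, approach: str):
    """Segment every profile with one approach ('hmm' or 'smooth')."""
    out = []
    for i, prof in enumerate(profiles):
        if approach == "hmm":
            out.append(
                segmentation.segment_profile_hmm(
                    prof,
                    clone_map,
                    k_max=config.k_max,
                    n_restarts=config.n_restarts,
                    seed=sample_seed(seed, i),
                    max_iter=config.hmm_max_iter,
                    tol=config.hmm_tol,
                )
            )
        elif approach == "smooth":
            out.append(
                segmentation.segment_profile_smooth(
                    prof, clone_map, lam=config.smooth_lambda, merge_tol=config.merge_tol
                )
            )
        else:
            raise ValueError(f"unknown approach {approach!r}")
    return out


def call_and_tally(segs, clone_map, config: PipelineConfig):
    calls = [calling.call_clones(s, config.thresholds, clone_map) for s in segs]
    return calling.call_matrix(calls, clone_map), calling.fga_table(calls)


def run_all(config: PipelineConfig, outdir: str | Path, seed: int | None = None) -> dict:
    """Run the whole pipeline on a simulated cohort and write all outputs.

    Returns the in-memory results keyed by stage; files mirror them under
    ``outdir`` (SEG per approach, call matrices, FGA tables, cohort
    report, config echo).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config.simulation = SimulationConfig(**{**config.simulation.__dict__, "seed": seed})
    seed = config.simulation.seed
    config.echo_json(outdir / "config_echo.json")

    clone_map, spots, clinical, truth = simulate_cohort(config.simulation)
    io_formats.write_clone_map(clone_map, outdir / "clone_map.bed")
    io_formats.write_spot_table(spots, outdir / "spots.tsv")
    io_formats.write_cohort_table(clinical, outdir / "cohort.csv")
    io_formats.write_call_matrix(truth.states, outdir / "truth_states.tsv")
    regions = [alt.region for alt in config.simulation.resolved_alterations()]
    io_formats.write_regions(regions, outdir / "regions.tsv")

    profiles = preprocess_profiles(spots, clone_map, config)
    io_formats.write_profile_matrix(profiles, clone_map, outdir / "profiles.tsv")

    results: dict = {"clone_map": clone_map, "clinical": clinical, "truth": truth}
    for approach in ("hmm", "smooth"):
        segs = segment_profiles(profiles, clone_map, config, seed, approach)
        io_formats.write_seg(segs, clone_map, outdir / f"segments.{approach}.seg")
        call_df, fga_df = call_and_tally(segs, clone_map, config)
        io_formats.write_call_matrix(call_df, outdir / f"calls.{approach}.tsv")
        fga_df.to_csv(outdir / f"fga.{approach}.tsv", sep="\t", index=False)
        results[approach] = {"segments": segs, "calls": call_df, "fga": fga_df}

    # cohort analyses on the HMM route (the clustering/testing input)
    call_df = results["hmm"]["calls"]
    fga_df = results["hmm"]["fga"]
    dend = cohort_mod.hierarchical_cluster(
        call_df,
        metric=config.cluster_metric,
        linkage=config.cluster_linkage,
        k=min(config.cluster_k, len(call_df.columns)),
    )
    (outdir / "dendrogram.nwk").write_text(cohort_mod.dendrogram_to_newick(dend))
    status = calling.regional_alteration_table(call_df, regions, clone_map, rule=config.region_rule)
    status.to_csv(outdir / "region_status.tsv", sep="\t")
    groups = clinical.set_index("sample_id")["responder"].map(
        {True: "responder", False: "non-responder"}
    )
    tests = cohort_mod.region_frequency_test(status, groups, test=config.region_test)
    report = cohort_mod.cohort_report(clinical, fga_df, dendrogram=dend, region_tests=tests)
    cohort_mod.write_report(report, outdir)
    results["report"] = report
    results["dendrogram"] = dend
    results["region_tests"] = tests
    return results
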