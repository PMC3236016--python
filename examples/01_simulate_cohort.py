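"""Simulate a 48-sample aCGH cohort with known ground truth.

Builds the default 22-autosome, 308-clone map, draws region-level gains
and losses with group-specific frequencies, and emits quadruplicate
replicate spots with QC failures.
"""

from acghpipe import SimulationConfig, simulate_cohort

config = SimulationConfig(n_samples=48, seed=7)
clone_map, spots, clinical, truth = simulate_cohort(config)

print(f"clone map: {clone_map.n_clones} clones on {len(set(clone_map.chrom))} chromosomes")
print(f"spot table: {len(spots)} replicate spots ({config.n_replicates} per clone per sample)")
print(f"responders: {clinical['responder'].sum()}/{len(clinical)} "
      f"(TRG counts {clinical['trg'].value_counts().sort_index().to_dict()})")
print("true FGA per sample (first 5):")
print(truth.fga.head().round(4).to_string())
# Each FGA value is the fraction of the sample's clones whose true copy
# number state is not neutral — the quantity the pipeline must recover.
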