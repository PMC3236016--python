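# Methods

## The measurement model

Array CGH measures tumor-vs-reference DNA copy number as per-clone log2
fluorescence ratios on an ordered genomic tiling (~1 Mb per BAC clone;
the default synthetic map uses 22 autosomes × 14 clones = 308 clones, a
desk-scale stand-in for a ~3,000-clone genome-wide array). A ratio of 0
means two copies; a single-copy gain in a diploid, pure sample would sit
at log2(3/2) ≈ +0.58 and a single-copy loss at log2(1/2) = −1, but
biopsy admixture and hybridization compression pull observed segment
levels toward zero, which is why calling thresholds are derived
empirically from control hybridizations rather than from first
principles.

## Spot QC and merging

Each clone is printed in quadruplicate. Spots with quality flag < 1 or
confidence < 0.3 are excluded first; then, if the sample standard
deviation (n−1 denominator) of the *surviving* replicates exceeds 0.2,
the clone is marked missing, otherwise its value is the unweighted mean
of survivors. Applying the spread rule after the flag/confidence
exclusions lets a single bad spot be rescued by its mates. Clones with
exactly one surviving spot are kept (an undefined SD counts as a pass)
and logged as low-support: dropping them would discard roughly 2% of the
genome at the default failure rate. QC never raises; it only produces
missing values, so downstream stages must be (and are) NA-aware.

## Normalization

`block_median` subtracts each block's median (the whole array is one
block when no print-block labels are given); it is idempotent and
equivariant under additive shifts. `block_lowess` subtracts a locally
weighted regression (span 0.3, 3 robustness iterations, statsmodels) of
the ratio on mean spot intensity, or on array position when intensity is
unavailable; blocks with fewer than 5 informative clones fall back to
the median, logged.

## Call thresholds

Defaults are the symmetric ±20% fold-change bounds, rounded to four
decimals: gain > log2(1.2) = +0.2630, loss < log2(0.8) = −0.3219, with
high-level gain > +0.9 and high-magnitude deletion < −0.75.
`calibrate_thresholds` re-derives the primary bounds from pooled
autosomal ratios of self-self (normal vs normal) hybridizations via the
0.1%/99.9% quantiles, snapping to the fold-change bounds when both
quantiles fall within 0.05 of them — for Gaussian platform noise of
SD 0.1 the 99.9% quantile is 3.09σ ≈ 0.31, so the snap engages. The
quantile-plus-snap rule is this package's documented inference about how
such bounds arise from control arrays, not a measured property of any
particular platform. All-constant input raises a degenerate-calibration
error; calibration always returns loss < 0 < gain or fails.

## Segmentation

Both segmenters operate per chromosome (alteration processes do not
cross chromosome ends) and per sample, and both are label-free; calls
come later from segment means, so the two routes are comparable under
one calling rule. Missing clones are skipped and transitions bridge the
gap.

**Gaussian HMM.** K hidden copy-number levels with Gaussian emissions
(state-specific mean and variance), row-stochastic transitions, fitted
by Baum–Welch EM with scaled forward–backward. Numerical choices: an
emission-variance floor of 1e-4 (prevents singularity on repeated
values; the floor is the one projection that can formally break EM
monotonicity, which is why monotonicity is asserted to a 1e-8 slack);
convergence at a relative log-likelihood change below 1e-6, capped at
500 iterations (non-convergence returns the best iterate, flagged);
5 restarts with initial means at quantiles spanning the full value
range — minority levels from short altered runs must seed their own
state, which interior quantiles fail to do — jittered after the first
restart; sticky transition initialization (0.9 on the diagonal). Model
order is chosen over K = 1..5 by BIC with p = K(K+2)−1 free parameters,
ties to smaller K; the scan stops early after two consecutive BIC
increases. Decoding is exact Viterbi; runs of equal state collapse into
segments whose mean is the mean of member clones.

**Penalized piecewise-constant smoother.** The exact O(n²) dynamic
program minimizing SSE + λ·(#breakpoints), followed by a greedy merge of
adjacent segments whose means differ by less than `merge_tol` (default
0.1, closest pair first). The published smoothing approach this mirrors
used a stochastic local-search optimizer; an exact DP for the same
objective class is deterministic and testable against brute force, and
at array resolution (hundreds of clones per chromosome) it is instant.
The penalty default λ = 0.1 is bracketed by two requirements: it must be
smaller than the SSE reduction from isolating a single-clone single-copy
event at a segment boundary (≈ Δ²·ℓ/(ℓ+1) ≈ 0.16 for Δ = 0.45 next to a
4-clone run), or real events get absorbed; and larger than the
noise-scale reduction of a spurious split (≈ 2σ²·ln n ≈ 0.08 at
σ = 0.12, n = 14). λ and `merge_tol` are exposed in the config.

## Calling and FGA

Per clone, the fitted segment mean m maps to {−2, −1, 0, +1, +2} with
strict outer inequalities (a mean exactly at a threshold falls to the
milder category). Sex chromosomes are excluded from calls, FGA and
regional tables by default: the reference is sex-matched, but residual
X/Y artifacts are the platform's known weak point. FGA is clone-count
weighted (on a uniform 1-Mb grid this coincides with base-pair
weighting); FGA = FGA-gain + FGA-loss holds exactly. A region counts as
amplified/deleted in a sample when ≥ 50% of its informative clones are
called in that direction (`any` and `all` rules selectable); when both
directions qualify, amplified takes precedence and the conflict is
logged.

## Cohort statistics

Responders are TRG 3–4, non-responders TRG 0–2 (Dworak grading; the
extreme-class variant opposes TRG 4 to TRG 0–1). Clustering uses
NA-aware distances — Hamming mismatch fraction on call codes by default
(the clustered object is categorical), normalized by the number of
clones informative in both samples; Euclidean-on-log2 is available —
with average linkage (robust with categorical distances; the cut
defaults to k = 5 clusters). Regional frequencies are compared between
groups by two-sided Fisher exact tests under the probability-mass rule
(scipy), verified in tests against exact integer hypergeometric
enumeration; frequencies are reported as integer-rounded percentages of
each group's evaluable samples. FGA is tested against response and stage
by Kruskal–Wallis with tie correction (chi-square p; an exact
full-enumeration permutation p is added when total n ≤ 10). Raw p values
are reported by default, with optional Benjamini–Hochberg correction.

Patient-level 2×2 tests on regional frequencies of this size cannot
produce p-values below ~1e-3; published region tables for comparable
cohorts sometimes print far smaller values, which implies a different
(e.g. clone-level) testing unit. This package deliberately tests at the
patient level and makes no attempt to reproduce such values.

## The synthetic cohort

The generator emulates the structure of a 48-sample two-group study:
region-level alterations drawn per sample as Bernoulli events with
group-specific frequencies (a region is wholly altered or not —
clone-level mosaicism is out of scope), true segment means of +0.45
(gain), −0.5 (loss), +1.1 (high gain), −0.9 (deep loss) so single-copy
events clear the thresholds with a margin of about 2× the clone noise;
clone-level Gaussian noise (SD 0.12) plus replicate-level noise
(SD 0.08); 2% of spots get a random QC defect (low flag, low
confidence, or an outlying ratio). The default region catalog mirrors
the kind of group-differential frequencies reported for extreme response
classes (e.g. a gain present in 20–40% of non-responders and 0–15% of
responders) plus one common arm-scale gain shared by both groups. The
clinical table reproduces the study-design marginals deterministically
(21/48 responders; TRG grades 1/9/17/8/13; 47 of 48 evaluable for
post-therapy stage with ypT 14/6/11/16; gender 36/12) by
largest-remainder allocation, shuffled by the seed. One seed determines
everything; per-sample RNG streams are keyed by sample index so growing
the cohort never perturbs earlier samples.

What the generator does **not** model: tumor purity and subclonality,
GC-content waves, spatial array artifacts (beyond one optional
intensity-style linear trend), dye-swap pairing, and clone-level
mosaicism. Passing recovery tests therefore demonstrates correctness of
the algorithms under idealized piecewise-constant truth, not performance
on real hybridizations, where segment levels are compressed and noise is
structured. The per-clone noise SD is a free simulation parameter, not a
claim about any platform.

## Validation design

Implemented checks (tests and `scripts/acceptance.py` compute all of
these; nothing below is asserted without being recomputed):
exhaustive-oracle equivalence — Viterbi vs all K^n paths (n ≤ 8,
K ≤ 3), DP smoother vs all 2^(n−1) breakpoint subsets (n ≤ 14), Fisher
vs integer hypergeometric enumeration (all 2×2 tables with N ≤ 30);
zero-noise end-to-end identity (calls equal truth exactly; FGA equal up
to one ulp from summing the gain and loss fractions); clone-level state
recovery at default noise on a 48-sample, 308-clone cohort for both
routes; breakpoint localization within ±2 clones on the documented
two-block instance (50+50 clones, step 0.6, noise SD 0.05) over 100
seeds; EM log-likelihood monotonicity on random fits; and detection of a
planted region (0% vs 50% carrier frequency, 24+24 samples) by the
patient-level Fisher test at p < 0.01 over 100 seeds. Problem sizes were
chosen so a full run takes minutes on one CPU.

## Known limitations

The HMM assigns states per chromosome independently, so a level shared
across chromosomes is re-estimated each time; joint multi-sample or
genome-wide fitting is out of scope. The smoother's merge pass is greedy
and can, in principle, differ from a globally optimal merge. The Newick
export encodes merge heights as branch-length differences and is meant
for visualization, not phylogenetic inference. GEO ingestion of real
array data is not implemented; readers accept the package's own TSV/SEG
schemas.
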