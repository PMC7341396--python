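# Methods

This note documents the models and procedures `adgraph` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and the known limits of what the synthetic cohort can
demonstrate.

## Pipeline model

The analysis treats each subject as a T×N matrix of ROI time series and
proceeds: Pearson correlation → sparsity-threshold binarization over a
sweep → five global graph attributes per threshold → AUC per attribute →
group inference → subnetwork decomposition → stage-trajectory
classification. Preprocessing of raw images (realignment, normalization,
filtering, nuisance regression) is out of scope; the pipeline starts at
extracted time series.

### Binarization

At sparsity S the k = round(S·N(N−1)/2) strongest edges are kept
(round-half-up, so edge counts are bit-reproducible). Edges are ranked by
**signed** correlation by default — the common convention in
sparsity-threshold studies of AAL connectomes — with an `absolute` mode
exposed (`rank` switch). Ties are broken deterministically by (value
descending, then lexicographic (i, j)), which makes the sweep monotone:
the edge set at S₁ < S₂ is a subset of the edge set at S₂. A sparsity
keeping zero edges yields a flagged-empty graph rather than an error.

### Sweep range

The default sweep is S ∈ [0.08, 0.52] in steps of 0.01 (45 points).
Alternatively `select_sparsity_range` derives the range from the
normal-control group as the maximal contiguous grid run where (a) mean
degree ≥ 2·log N — natural log by default, giving a lower bound of
2·ln(90)/89 ≈ 0.101 for N = 90, with a log₁₀ switch — and (b) the NC
group-mean small-worldness ≥ 1.1. Criterion (a) is applied per subject
(it is in fact subject-independent, since mean degree = S(N−1) exactly);
criterion (b) on the group mean.

### Graph attributes

Characteristic path length averages hop counts over **reachable pairs
only**, and every result carries a connectedness flag: binary graphs at
low sparsity are routinely disconnected, and the alternative (infinite
Char) would void the whole low-S end of the sweep. Efficiency needs no
special case (1/∞ = 0). C_i is defined as 0 for nodes of degree < 2
(standard convention). Transitivity with no connected triple is defined
as 0 with a warning.

Small-worldness normalizes by an ensemble of 100 graphs drawn uniformly
among all graphs with the same node count and edge count — matching
"same size and density" — rather than by degree-preserving rewiring;
`n_random` and the seed are exposed. Because the reference depends on the
graph only through (N, k), one ensemble per (N, k) serves every subject
at a given sparsity (`ReferenceCache`); this is statistically identical
to per-subject ensembles and removes most of the sweep's cost. For very
small subnetworks at very low k the reference ensemble can contain no
triangle (C₀ = 0); small-worldness is then undefined and recorded as NaN
at that grid point.

AUC uses the trapezoidal rule. Each metric's AUC integrates over its own
maximal contiguous finite run ending at the dense end of the grid, so a
degenerate low-S point shrinks that metric's integration range instead of
poisoning it; the valid range is recorded per network.

### Subnetworks

Subnetwork graphs are built from each network's **own** correlation block
with its own edge budget k = round(S·|n|(|n|−1)/2) — the natural reading
of building the RSN's binary network from the RSN's regions — with a
`restrict` mode (cut the whole-brain binary graph down to the network's
ROIs) exposed as the alternative. The global sparsity grid is inherited
by all subnetworks rather than re-derived per network. Inter-network FC
is the plain mean correlation over all region pairs spanning the two
networks; the pair-count-weighted block means reconstruct the global
off-diagonal mean exactly.

### Inference

Metric AUCs are compared by a nonparametric permutation test (group
labels reallocated preserving group sizes; default 10,000 relabelings for
metric families) with the +1 correction p = (1 + #extreme)/(B + 1).
Three tail modes exist. The **two-tailed** mode is the default for all
pipeline inference. A fixed-direction one-tailed mode
(`one_tailed_greater`) is available when a direction is prespecified.
The sign-adaptive one-tailed mode (`one_tailed_directional`, direction
chosen from the observed difference) is retained for direction-agnostic
screening but is *not* used for inference: choosing the tail after seeing
the data makes its null p-values uniform on (0, 0.5), i.e. type-I error
2α. This is verified by a characterization test; it is the reason the
default deviates from a naive "one-tailed at 95%" reading.

Edge weights (optionally Fisher-z transformed, with |r| clipped at
1 − 1e−7) and network-pair FC are compared by Welch's unequal-variance
t-test — group sizes differ — with edges of zero variance in both groups
flagged and given p = 1. FDR uses Benjamini–Hochberg step-up
(q(i) = min over the tail of m·p(j)/j), applied as one family per
contrast per analysis level (global metrics; subnetwork metrics; all
edges; all network pairs) — the most conservative family definition.
An optional per-sparsity testing mode runs the permutation test at every
grid point with BH across the grid. MMSE correlations are plain Pearson
r with the two-sided t-distribution p (n − 2 df), computed per stage for
global and subnetwork AUCs.

Per-feature permutation seeds are derived by hashing (level, feature,
contrast, base seed), so runs are byte-reproducible and independent of
evaluation order.

### Trajectory classification

A trajectory is the 4-vector of stage means of one (network, metric)
AUC. Labels: TEMPERATURE_INVERSION (rise beyond tol to an EMCI maximum,
then decline), MONOTONOUS_DECLINE (every step falls, total drop beyond
tol), U_SHAPED (interior minimum, final rise beyond tol), else OTHER.
The tolerance defaults to 0.25 × the pooled standard error of the four
stage means: the pattern dichotomy is traditionally judged by eye from
trajectory plots, and a noise-scaled tol makes the rule quantitative and
testable; an absolute-tol mode exists. This criterion is this package's
own construction. A network's pattern is the majority label across its
five metrics (ties → OTHER); networks sharing a pattern form the
"homogeneous evolving" groups.

## Synthetic cohort

The generator emulates the study conditions the analysis assumes: four
stages with group sizes 35/37/33/25, 90 ROIs, 130 time points (140
volumes minus 10 discarded for magnetization equilibrium), MMSE drawn
per stage from N(28.89, 1.21²), N(28.08, 1.74²), N(27.85, 1.64²),
N(22.72, 2.41²), rounded to integers and clipped to [0, 30].

Signals are zero-mean multivariate Gaussian with a block correlation
matrix: within-network pairs at a stage-dependent target `within_r`,
everything else at `between_r` = 0.05. Default trajectories across
NC→EMCI→LMCI→AD: (0.30, 0.45, 0.35, 0.20) for the inversion networks
(AUD, DMN, VIS, SUB) and (0.45, 0.38, 0.30, 0.22) for the decline
networks (SEN, ATT) — ordered to encode the two patterns, with
magnitudes in the range typical of resting-state within-network
correlations. The Gaussian choice is deliberate: the analysis consumes
only Pearson correlations, which the covariance controls exactly.
Temporal autocorrelation is off by default (an AR(1) knob exists; the
AR filter is variance-normalized so cross-correlation targets are
unchanged). Covariances are validated positive definite at build time;
a near-singular matrix triggers a flagged nearest-PD repair, a gross
violation an error naming the blocks.

The default 90-ROI partition uses contiguous blocks
DMN 20, ATT 16, SUB 12, AUD 10, VIS 16, SEN 16 — sizes in the range of
published AAL-to-RSN assignments, with DMN largest and AUD smallest.
The literature's actual AAL→RSN mapping is not standardized in print, so
real-data runs must supply their own partition file. (The source
analysis counts "five" RSNs but names six; this package implements the
six named networks.)

**What the generator does not emulate:** scanner noise, head motion,
physiological confounds, hemodynamics, spatial autocorrelation between
neighbouring parcels, heavy-tailed or nonstationary signals, and any
within-block correlation heterogeneity. Passing tests on this cohort
demonstrate that the pipeline's machinery is correct and calibrated —
not that real fMRI effects of these sizes would be detected.

### Known limitation: what a fixed-edge-count graph can see

Binarization at sparsity S keeps exactly k edges regardless of the
overall correlation level, so a *uniform* shift of within-block
correlation changes the binarized topology only through the geometry of
sample-correlation noise (an equicorrelated block is a one-factor model;
higher `within_r` concentrates strong sample correlations on
high-loading nodes). Empirically, clustering, transitivity and
small-worldness increase with `within_r` and recover the encoded
patterns for the larger networks; characteristic path length and
efficiency *decrease* slightly (the correlated core shortens reachable
paths while stranding peripheral nodes), so their trajectories appear
U-shaped where the generator encodes an inverted U. Across 20 seeds at
the default conditions, trajectory labels match the generated pattern
for 211/600 (network, metric) pairs — clustering 75/120, transitivity
70/120, small-worldness 63/120, path length 0/120, efficiency 3/120 —
and the small networks (AUD, SUB) are noise-limited even on the
clustering side. Recovering all five metrics' patterns simultaneously
would require a generator that perturbs the *pattern* of within-block
correlations (e.g. modular or lattice-like block structure), not just
their level; that is outside the block-constant covariance this
generator intentionally implements.

## Problem sizes used in tests

The unit suite runs on scaled-down cohorts (30 ROIs, 60 time points,
5 subjects per stage) and coarse grids; the acceptance-style end-to-end
checks use the full default cohort with 1,000 permutations for the null
calibration and the 45-point grid for pattern recovery. The metric
oracle suite checks 200 random graphs with N ≤ 12 against brute-force
enumeration at 1e−10.

## Command-line interface

`adgraph simulate` writes a cohort (subject TSVs, manifest, partition),
`adgraph run` executes a study from a manifest and YAML config,
`adgraph demo` chains both, `adgraph metrics` scores a single
connectivity matrix. All outputs are TSV tables stamped with the config
hash, plus a JSON run-metadata file; trajectory panel plots are an
optional extra (`--plots`), not part of the reported results.
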