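# Methods

This note documents the models, numerical choices, and limitations of
the cohnet pipeline in the order the method runs.

## Synthetic study data

The generator emulates a within-subject isometric arm-exertion study:
12 subjects × 5 exertion levels (extremely light → extremely hard) ×
3 trials, 3 s epochs of 84-ROI source activity at 250 Hz, plus a
behavioral table of exerted force (N), maximum voluntary contraction
(MVC, N) and perceived physical comfort (RPPC, 0–10).

**ROI atlas.** Nodes are 42 Brodmann areas × 2 hemispheres, ordered by
area number with left before right. The area list, lobe assignments and
centroid coordinates are nominal, documented stand-ins — no computation
depends on anatomy, and a user-supplied atlas CSV overrides the default
everywhere an atlas is accepted. Coordinates exist only to satisfy the
BrainNet Viewer `.node` export format and are labeled approximate.

**Source model.** Each ROI is a linear mixture
x_i(t) = Σ_k a_ik s_k(t) + σ_i n_i(t), where every latent component s_k
is unit-variance white noise band-passed to its band by a zero-phase
order-4 Butterworth filter (`sosfiltfilt`), and n_i is unit-variance
white noise. The filter family is fixed because the coherence oracle
needs the realized power transfer: forward–backward filtering has power
gain |H(f)|⁴, computed numerically with `sosfreqz`. For two ROIs sharing
a single component, the per-frequency coherence is

    C_ij(f) = (a_i a_j P(f))² / ((a_i² P(f) + σ_i²)(a_j² P(f) + σ_j²)),

with P(f) = |H(f)|⁴; the band value is the mean over an in-band grid,
mirroring how the estimator averages per-bin coherence. Flat white-noise
spectra cancel, so only relative powers matter. `noise_sd_for_target`
inverts the equal-power case c = (S/(S+σ²))² to place expected coherence
at chosen targets. Condition effects are injected by a per-level gain on
designated components; the built-in "strong alpha frontoparietal"
scenario couples all frontal and parietal ROIs through one alpha
component with gains 0.55 → 1.6 from lightest to hardest level, on unit
noise (expected member-pair alpha coherence ≈ 0.04 → ≈ 0.47).

**Behavioral model.** force_slt = μ_level + b_s + ε_slt with
b_s ~ N(0, subject_sd²) and ε ~ N(0, residual_sd²), re-drawn when a draw
falls below 0 N; RPPC is analogous, re-drawn into [0, 10]. Default level
means are the published descriptive means of the motivating study
(force: 8.04 … 67.35 N; comfort: 8.80 … 3.90). Default dispersions
(subject 10 N / 0.99 points, residual 12 N / 1.28 points per trial) put
the block and error variance components on the scale the published ANOVA
implies while keeping truncation rare; truncation still biases the
lightest-level force mean slightly upward, which is accepted as the
price of physical plausibility. MVC is drawn once per subject
(N(115, 47.6²) N, floored at 20 N; max of three noisy maxima) and used
only for %MVC normalization.

**What the generator does not emulate:** volume conduction and inverse-
solution leakage, 1/f background spectra, nonstationarity, artifacts,
and level-dependent noise. Passing tests therefore demonstrate that the
estimation and inference machinery is correct under the stated mixing
model, not that real EEG effects of this size would be detected.

## Spectral estimation

Welch cross-spectra: segments of 250 samples (1 s → 1 Hz bins; the 5 Hz
alpha band spans 5 bins) with 50 % overlap, per-segment mean removal,
periodic Hann taper, one-sided density scaling. A 10 % cosine (Tukey)
taper is available behind a flag as the alternative reading of a
"Hanning window with 10 % onset"; full Hann is the default. Segments of
all trials of one subject × condition pool into a single estimate, so
each subject contributes one matrix per condition and band. Per-bin
coherence divides |W_xy|² by the power product; zero-power bins yield 0
with a warning, the diagonal is 1, and a single-segment estimate is
flagged (its off-diagonal coherence is identically 1). Band values
average per-bin coherence (not coherence of band-averaged spectra),
keeping every contribution in [0, 1]; band intervals are
closed-left/open-right so alpha and beta are disjoint at 13 Hz.

The magnitude-squared coherence estimator is biased upward by ~1/K for K
averaged segments under independence; tests verify both the level and
its decay with K. With 3 s epochs the 15 segments per subject ×
condition put this bias near 0.07 — a known property of the study design
being modeled, not removed by the pipeline.

## Network construction

Proportional thresholding keeps m = round(s · n(n−1)/2) strongest
upper-triangle entries (round = half-up, for bit-reproducible counts).
Ties at the cutoff break by ascending (row, column), which makes results
deterministic and edge sets nested along the sparsity grid. The default
grid is 0.05–0.50 in steps of 0.05, covering both the 5–50 % and
10–50 % conventions; disconnected networks are retained with a flag and
a warning rather than discarded, since sparsity grids are usually chosen
to avoid disconnection but no discard rule is standard.

## Graph measures

All measures operate on binary undirected graphs. Clustering, Brandes
betweenness (raw unordered-pair counts; normalized behind a flag),
double-edge-swap surrogates and Louvain come from networkx; distances
from scipy's csgraph BFS. Choices where conventions diverge:

* **Global efficiency** is the Latora–Marchiori mean inverse distance,
  not 1/L: only that form is well defined on flagged disconnected
  networks. 1/L is reported alongside as `inverse_path_length`.
* **Characteristic path length** on a disconnected network averages
  reachable pairs and warns.
* **Small-worldness**: the literal C/L ratio is reported for
  completeness, but σ = (C/⟨C_rand⟩)/(L/⟨L_rand⟩) over degree-preserving
  Maslov–Sneppen surrogates (default 100 nulls, 10 swaps per edge,
  seeded) is the quantity compared against 1. σ is opt-in in the bundled
  per-network metric computation because the surrogate ensemble
  dominates runtime across a 1,200-network sweep.
* **Modularity** is Newman–Girvan Q optimized by seeded Louvain, best of
  20 restarts. Modularity maximization is NP-hard; on adversarial tiny
  graphs the greedy optimizer can stop below the exhaustive optimum (one
  in fifteen random 7-node graphs in our test ensemble), which the tests
  document rather than hide.
* **Hubs**: top round(f · n) nodes by the chosen centrality (default
  f = 0.30 → 25 of 84 nodes), ties broken by ascending node index.

Metric tables are tidy CSV over the full sparsity grid; an
area-under-curve summary (trapezoid over sparsity) is emitted alongside
per-grid-value curves, and group comparisons run per grid value.

## Statistical inference

**Permutation test for metric differences.** Pooled relabeling
preserving group sizes; exhaustive enumeration replaces sampling
whenever C(n_a+n_b, n_a) ≤ n_perm (exact p), otherwise sampled p uses
the add-one rule (b+1)/(n_perm+1) so p > 0. One-tailed tests are fixed
upper-tail — group order encodes the hypothesized direction, and the
null's 95th percentile is the critical value; both one-sided p-values
are always reported. A data-dependent tail (choosing the direction from
the observed sign) would double the type-I error and is deliberately not
offered as the headline p. Pooled (unpaired) relabeling is used even
though the design is within-subject, reproducing the stated procedure of
the motivating study; this is conservative when subject effects are
present.

**Edge-wise comparison.** Unpaired two-sample t per upper-triangle edge
(again a faithful-reproduction choice despite the repeated-measures
design); each permutation relabels whole subjects and records max |t|
over edges; the 95th percentile of that maximum is the familywise
threshold, and significant edges are signed by the observed direction.
FWER-corrected per-edge p-values use the add-one rule against the max
null.

**Behavioral analysis.** Trial-level responses are averaged to one value
per subject × level cell before a two-way additive (randomized-block)
ANOVA, because a 12 × 5 design then yields the canonical df
(11, 4, 44, 59); both factors are tested against the error mean square.
Tukey HSD uses SE = √(2·MSE/n), simultaneous CIs of half-width
q(0.95, k, df)/√2 · SE with q from scipy's studentized-range
distribution (validated against the published intervals), adjusted p
from the same distribution, and a compact letter display built from
maximal cliques of the non-significance graph, lettered in descending
order of level means.

## Pipeline and reproducibility

A single master seed derives one independent 31-bit seed per stage via
`SeedSequence.spawn` in a fixed stage order; the run manifest records
the config snapshot, stage seeds and SHA-256 hashes of every output, so
two runs with one seed are hash-identical. Stage outputs are plain-text
CSV/TSV (plus BrainNet Viewer `.node`/`.edge` exports), and each CLI
subcommand consumes the previous stage's files, so real coherence
matrices can enter at the network stage. Per-epoch source CSVs are
opt-in (`write_sources`) because they dominate disk usage; nodal
permutation comparisons are likewise opt-in because 84 nodes × grid ×
bands multiplies the test count.

Problem sizes in the test suite and acceptance script are chosen to keep
a full run in the low minutes: 200-segment recoveries for coherence
targets, 1,000 null replicates at 1,000 permutations for type-I
calibration, 200 replicates on 20-node matrices for FWER, 20 scenario
replicates (12 subjects, two extreme levels, 2,000 permutations) for
end-to-end effect recovery, and 20-surrogate ensembles for σ checks.

## Known limitations

* The synthetic atlas and coordinates are placeholders; anatomical
  claims cannot be made from exports.
* Coherence, not lagged/imaginary variants: zero-lag leakage common to
  inverse solutions would inflate real-data coherence and is neither
  simulated nor corrected.
* The closed-form coherence oracle covers at most one shared component
  per ROI pair; richer coupling topologies are generated correctly but
  validated only through weaker invariants.
* Louvain Q is a heuristic lower bound on the optimal modularity.
* The permutation machinery treats subjects as exchangeable units
  (unpaired), which loses power relative to a paired design.
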