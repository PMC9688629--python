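# cohnet

Source-space EEG functional connectivity networks and their statistics:
band-limited magnitude-squared coherence between 84 Brodmann-area regions
of interest, proportional sparsity thresholding into binary graphs,
global and local graph-theoretic characterization, and nonparametric
permutation inference — built for studies that ask how task demand (here,
graded isometric arm exertion) reorganizes the functional brain network.

The package is aimed at researchers who have ROI-level source time series
(e.g., from an eLORETA inverse solution) or precomputed coherence
matrices, and want a reproducible, tested path from those inputs to
network statistics. A synthetic coupled-oscillator generator with a
closed-form coherence oracle makes every stage testable end to end
without any recordings.

## The method

**Coherence.** For ROI signals *x*, *y*, cross-spectra are estimated by
Welch averaging of Hann-tapered, 50 %-overlapping segments, and

&nbsp;&nbsp;&nbsp;&nbsp;C<sub>xy</sub>(f) = |W<sub>xy</sub>(f)|² / (W<sub>x</sub>(f) · W<sub>y</sub>(f)) ∈ [0, 1],

averaged over the bins of each band (alpha 8–13 Hz, beta 13–30 Hz;
closed-left/open-right, so the bands are disjoint at 13 Hz). One matrix
is produced per subject × condition × band, pooling segments over trials.

**Networks.** Each 84 × 84 coherence matrix is binarized by keeping the
round(s · n(n−1)/2) strongest edges at each sparsity s of a grid
(default 0.05–0.50 in 0.05 steps), with deterministic tie-breaking, so
edge sets are nested along the grid.

**Graph measures.** Global: mean clustering coefficient C, characteristic
path length L, global efficiency E<sub>glob</sub> (mean inverse
distance), mean local efficiency E<sub>loc</sub>, modularity Q (Louvain,
seeded restarts), and small-worldness — both the literal C/L ratio and
σ = (C/⟨C<sub>rand</sub>⟩)/(L/⟨L<sub>rand</sub>⟩) against
degree-preserving rewired surrogates, with σ > 1 indicating small-world
organization. Local: degree, betweenness, and nodal efficiency; hubs are
the top 30 % of nodes by degree.

**Inference.** Group differences in network measures are tested by
pooled-relabeling permutation tests (default 30,000 permutations; the
null's 95th percentile is the one-tailed critical value; exhaustive
enumeration is used automatically when feasible). Edge-wise two-sample
t-tests are familywise-corrected by the permutation distribution of the
maximal statistic (default 5,000 randomizations). Nodal comparisons are
Bonferroni corrected. Behavioral force and comfort data are analysed with
a randomized-block ANOVA (participant + exertion level, trial-averaged
cells) and Tukey HSD with simultaneous intervals and compact letter
display; forces can be normalized to %MVC.

## Worked example

Simulate the built-in strong-effect scenario — an alpha-band component
coupling frontal and parietal ROIs whose strength rises with exertion —
for 12 subjects at the two extreme exertion levels, and test the
alpha-band clustering-coefficient contrast:

```python
import numpy as np
from cohnet import (ExperimentDesign, SpectralConfig, coherence_matrices,
                    generate_sources, scenario_strong_alpha_frontoparietal,
                    binarize_by_sparsity, clustering_coefficients,
                    permutation_mean_difference)

design = ExperimentDesign(n_subjects=12,
                          levels=("extremely_light", "extremely_hard"),
                          n_trials=3)
spec = scenario_strong_alpha_frontoparietal()
epochs = generate_sources(design, spec, seed=1)

by_cell = {}
for e in epochs:
    by_cell.setdefault((e.subject, e.level), []).append(e)

clustering = {"extremely_light": [], "extremely_hard": []}
for (subj, level), eps in sorted(by_cell.items()):
    coh = coherence_matrices(eps, SpectralConfig())["alpha"]
    net = binarize_by_sparsity(coh, sparsity=0.2)
    _, c = clustering_coefficients(net)
    clustering[level].append(c)

res = permutation_mean_difference(clustering["extremely_hard"],
                                  clustering["extremely_light"],
                                  n_perm=2000, tail="one", seed=1)
print(f"mean C (extremely hard)  = {np.mean(clustering['extremely_hard']):.3f}")
print(f"mean C (extremely light) = {np.mean(clustering['extremely_light']):.3f}")
print(f"observed difference      = {res.observed:.3f}")
print(f"null 95th percentile     = {res.null_quantile_95:.3f}")
print(f"one-tailed p             = {res.p_value:.4f}")
```

Output:

```
mean C (extremely hard)  = 0.449
mean C (extremely light) = 0.296
observed difference      = 0.153
null 95th percentile     = 0.055
one-tailed p             = 0.0005
```

The injected coupling raises alpha-band clustering at the hard level; the
observed mean difference (0.153) far exceeds the permutation null's 95th
percentile (0.055), so the contrast is significant.

The same analysis, end to end with all interchange files and a
reproducibility manifest:

```bash
cohnet run --seed 1 --outdir my_run        # or: python -m cohnet.cli ...
```

Individual stages (`simulate`, `coherence`, `network`, `metrics`,
`behavior`, `compare`, `report`) are also exposed so externally computed
coherence matrices or behavior tables can enter mid-pipeline.

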