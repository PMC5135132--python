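# Methods

## Model and statistics

`kshuff` treats a gene library as a point set in sequence space, observed
only through the pairwise evolutionary distances `d_ij` (substitutions per
site) of all `N` sequences across all libraries. Every statistic in the
package is a functional of empirical distance CDFs:

- the intra K-function `K_l(r)` of library `S_l` is the empirical CDF of
  the `n_l (n_l - 1)` ordered within-library distances (the ordered-pair
  normalization is retained as stated, though it coincides with the
  unordered CDF for symmetric distances);
- the cross K-function `K_ab(r)` of two libraries is the empirical CDF of
  the `n_a n_b` between-library pair distances.

Both use the inclusive indicator `d_ij <= r`, making `K` right-continuous;
tied distances stack into a single breakpoint, and zero distances
(identical sequences) are legal breakpoints at `r = 0`.

The scalar indices are areas on the distance domain `[0, r_max]`:

- `I_kf = r_max - ∫ K_l dr` (structural diversity). With the default
  `r_max = 1` and distances in `[0, 1]` this equals the mean within-library
  pairwise distance exactly — the package's primary correctness oracle, and
  the reason `r_max = 1` is the default rather than an unbounded domain: it
  keeps the index on the interpretable 0–1 scale of evolutionary distances.
  Matrices containing distances above `r_max` are rejected with a pointer
  to the `rmax` setting; with an override the index is still the mean
  distance on the enlarged domain but no longer lives on the unit scale.
- `C_kf = ∫ |K_ab - K_a| dr + ∫ |K_ab - K_b| dr` (compositional
  dissimilarity), symmetric in the pair by construction.

Homogeneity is tested with functional-ANOVA-type statistics: the
structural statistic `T_l = Σ_l n_l ∫ (K_l - Kbar)^2 dr`, where
`Kbar = Σ_l n_l K_l / N` is the size-weighted mean IKF, and the pairwise
compositional statistic `T_c = ∫ (K_ab - (n_a K_a + n_b K_b)/(n_a+n_b))^2 dr`.

### Exact step-function integration

Every K-function is piecewise constant, so all integrals are computed
exactly: the integrand is evaluated on the union of the participating
CDFs' breakpoints (plus 0) and summed as rectangles up to `r_max`. There
is no quadrature, no grid parameter, and no integration error beyond
float rounding. The test suite checks this against an independent
dense-grid integrator and brute-force pair counting at 1e-6.

### Monte Carlo inference

Null distributions come from reallocating sequences to libraries uniformly
at random with library sizes preserved; distances are fixed, so each
shuffle only re-indexes the one matrix. The p-value uses the
add-the-observed rule `p = (1 + #{T* >= T_obs}) / (B + 1)`: it is bounded
below by `1/(B+1)`, never zero, and never anti-conservative. A `>=`
comparison rather than strict `>` is used; the statistics are effectively
continuous, so ties are measure-zero and the choice only affects degenerate
matrices (where it makes the test conservative, which is correct — a fully
exchangeable matrix yields p = 1).

Scopes: the global structural test shuffles across all `L` libraries; the
pairwise structural and compositional tests shuffle only the two libraries
under comparison, so each pairwise p-value is self-contained and does not
depend on which other libraries happen to share the matrix. Both scopes are
exposed (`scope={"global","pairwise","both"}`). Default `B = 999`. No
multiple-testing correction is applied by default; a Benjamini–Hochberg
adjustment over the pairwise family is available (`--bh`, delegating to
`scipy.stats.false_discovery_control`).

Reproducibility contract: one integer seed drives a single `numpy`
Generator stream; identical inputs and seed give byte-identical outputs.
The observed indices are computed outside the shuffling stream and are
seed-independent.

## Synthetic data generator

`simulate.generate_community` emulates the clustered structure of 16S
libraries: each cluster is a star phylogeny — an ancestor sequence whose
offspring are mutated independently at a per-site substitution rate
(`divergence`, valid in [0, 0.75)). Cluster ancestors are derived from a
shared root at a per-site rate solved in closed form so that the expected
JC-corrected distance between two ancestors equals `between_divergence`.
Distances are Jukes–Cantor-corrected p-distances capped at 1.0 (to respect
the unit analysis domain); a raw p-distance mode exists. The alignment
length is a single community-level field because p-distances require
equal-length sequences.

Two standard regimes are used in the tests and the acceptance script:

- a *separation* pool — two tight clusters (within rate 0.024, so
  within-cluster distances ≈ 0.05) with ancestors at JC distance 0.8 — the
  construction for calibration and power experiments, where the signal must
  be unambiguous;
- a *realistic* community — 15 clusters of 10 sequences, within rate 0.01,
  between-ancestor distance 0.35 — mimicking a real soil/sediment library
  (many OTUs, `I_kf` ≈ 0.35, on the scale observed for natural
  communities). This is the regime for the subsampling experiments: with
  only two clusters the subsample `I_kf` distribution is strongly skewed by
  the cluster-composition draw, which destabilizes small-replicate standard
  errors, whereas real libraries (and the many-cluster community) are well
  behaved.

What the generator does **not** model: sequencing error, chimeras,
alignment uncertainty, unequal evolutionary rates, or realistic abundance
distributions (cluster weights are available but default to uniform).
Passing tests therefore demonstrate the statistics' correctness and
calibration on clustered distance structures, not robustness to platform
artifacts.

### Mixing power design

From two disjoint source pools A and B, a pair of `N`-member libraries is
built: library 1 takes `round(omega*N)` sequences from A (half-up rounding,
so power tables are exactly reproducible) and the rest from B; library 2 is
the mirror image; all draws are without replacement. `omega = 0.5` is the
null (both libraries are identically composed blends); `omega = 1.0` gives
pure libraries. Power at each `(omega, N)` is the fraction of replicate
pairs with `p <= alpha`, reported with the binomial standard error
`sqrt(p(1-p)/reps)`.

Default experiment sizes (chosen to resolve the behavior cleanly at desk
scale): `N = 50`, 50–200 replicates, `B = 199` permutations for simulation
studies, `B = 999` for single analyses. Type-I calibration uses 200
random 50/50 splits of one 100-sequence pool and checks the rejection rate
against the exact binomial 95% interval at `alpha = 0.05`.

## File formats

PHYLIP distance matrices are accepted in square and lower-triangular
dialects (the latter with or without an explicit zero diagonal), with
auto-detection from row lengths when each taxon occupies one line; the
explicit dialects also accept wrapped rows. Labels are
whitespace-delimited and unrestricted in length; the writer pads labels of
≤ 10 characters to the classic fixed-width field and otherwise falls back
to the relaxed dialect. Matrices are validated on read: asymmetry below
1e-8 is averaged away (float noise from upstream writers), anything larger
is an error; negative, non-finite or nonzero-diagonal entries are errors.
Values are written with 12 significant digits, so round-trips are lossless
to well below 1e-10.

The control file is a minimal `key = value` grammar (`matrix`, `libraries`,
`sizes` or `members_<name>`, `permutations`, `seed`, `alpha`, `rmax`),
documented in `matrix_io`. Block sizes partition consecutive matrix rows in
order; explicit member lists match by label. Unknown keys warn rather than
fail. This grammar is a clean-room design, not a bug-for-bug clone of any
earlier tool's format.

## Conventional diversity indices

For side-by-side reporting, `conventional_indices` computes OTU-abundance
indices: richness `S`; Shannon `H = -Σ (n_i/N) ln(n_i/N)`; Simpson
`D = Σ n_i(n_i-1) / (N(N-1))` with its reciprocal (reported as infinite
when `D = 0`, i.e. all singletons); and Chao1 `S + n1^2/(2 n2)` with the
Chao (1987) log-normal 95% interval. Edge conventions: `n1 = 0` gives
Chao1 = S; `n2 = 0` with `n1 > 0` uses `S + n1(n1-1)/2` (the convention of
mothur/EstimateS).

## Known limitations

- Distances are taken as given; no correction for alignment or
  distance-estimation error is attempted, and the tool does not build
  matrices from raw reads.
- Permutation cost grows as `B` times the per-shuffle sort of
  `O(n^2)` pooled pair distances; pairs with a few hundred sequences and
  `B = 999` take seconds, but very large libraries should be subsampled
  (the sample-size invariance of `I_kf`/`C_kf` makes this statistically
  safe).
- `I_kf` compresses a whole CDF to one number: different structures can
  share an `I_kf` (equal mean distances), so significant structural
  differences should be read from the test, not from the index alone.
- With literal duplicate sequences across two libraries, cross pairs at
  distance zero make the CKF differ from the IKFs by O(1/n) even for
  "identical" libraries; `C_kf = 0` is attained exactly only when the
  three CDFs coincide.
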