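# Methods

## Data model

A *prescription record* is the deduplicated set of acupoints one
practitioner selected for one clinical case; (practitioner, case) pairs are
unique within a dataset. Free-text names are mapped to WHO standard codes
(meridian prefix + point number, e.g. `ST36`; extra points `EX-<region><n>`)
before any counting. Matching is case-insensitive and ignores whitespace and
hyphens; tokens already shaped like codes are canonicalised structurally,
including common non-WHO meridian abbreviations (`LIV→LR`, `Ren→CV`,
`Du→GV`, `SJ/TB→TE`, `UB→BL`, `P→PC`, `KD→KI`, `H→HT`), and point numbers
are validated against each meridian's range. Everything else must appear in
the alias table. The bundled table is a reconstruction covering the codes,
pinyin (with and without diacritics) and Korean romanisations that appear in
the published summary tables of this kind of survey; it is not an original
study artifact, and users with real data should extend it. In batch mode
unknown tokens are dropped and itemised in a normalization report (the
algorithmic stand-in for manual typo cleaning, which has no faithful
re-implementation); strict mode aborts on the first unknown token.

## Probability and z-score profiling

Analysis is restricted to the K most frequent acupoints overall (default
K = 30; ties at rank K break lexicographically, and a vocabulary smaller
than K is used whole, with a warning). Within case *c*:

    P(c, a) = n(c, a) / Σ_{b ∈ topK} n(c, b)

so each case's K probabilities sum to one and their mean is exactly the
chance level 1/K. Z-scores standardise each case's profile using the sample
standard deviation (denominator K−1; the population variant is available via
`ddof=0`). The threshold 1.96 is a descriptive cutoff — "about two standard
deviations above the case's average acupoint" — not a calibrated test, so no
multiplicity correction is applied. Because standardisation absorbs the
per-case scaling, z-scores computed from raw counts and from probabilities
are identical; a property test asserts this.

Two standardisation axes are meaningful and both are implemented:

* `axis="case"` (default): compares an acupoint against the *other
  acupoints of the same case* — prominence within the case's mix.
* `axis="acupoint"`: compares an acupoint's use in one case against its use
  in the *other cases* — specificity to the case.

A uniform profile (zero standard deviation) raises a degenerate-case error
naming the offending case, as does a case with zero total count over the
top-K set.

## Ward clustering

Cases are clustered on their z-score vectors over the global top-K set.
Agglomeration follows Ward's minimum-variance criterion; the recorded merge
height is the criterion increase Δ(i,j) = nᵢnⱼ/(nᵢ+nⱼ)·‖cᵢ−cⱼ‖², which is
monotone non-decreasing (no dendrogram inversions). The raw squared distance
between merged centroids — Δ without the size factor — is reported alongside
in the merge table, since dendrogram y-axes are drawn in either unit
depending on software. The implementation delegates to scipy's Ward linkage
and converts its cophenetic heights h via Δ = h²/2; a brute-force
recomputation of the within-cluster sum of squares for every candidate pair
at every step serves as the test oracle on all instances up to 8 cases.
Exact ties between candidate merges resolve by scipy's deterministic
internal order (runs are bit-reproducible; with continuous profiles exact
ties have measure zero). Cutting at k undoes the last k−1 merges; cluster
labels 'A', 'B', ... follow the smallest contained leaf index, so labels are
stable across re-runs but arbitrary with respect to any planted labelling.
The default k = 3 is a convention of the analysis, not an automatic choice;
no cluster-number selection is performed. Dendrograms export to newick with
branch length = parent height − own height, so root-to-leaf distances equal
the root merge height.

## Co-occurrence network

Each record with n ≥ 2 acupoints distributes total weight 1 equally over its
C(n,2) unordered pairs; single-point records contribute their node but no
edge (the sharing rule is undefined at n = 1). Pre-filter total edge weight
therefore equals the number of contributing records — a conservation
identity tested to 1e-9. Edge filtering keeps weights strictly greater than
the mean over all positive-weight edges (so an all-equal network empties);
the mean is accumulated with compensated summation so hairline comparisons
are reproducible. Centrality is computed after filtering, on the weighted
adjacency of the largest connected component (size ties go to the component
containing the lexicographically smallest node; nodes outside score 0).

Power iteration runs on A + cI with c the maximum weighted degree: the shift
leaves eigenvectors unchanged while making the Perron eigenvalue strictly
dominant in magnitude, so the iteration also converges on bipartite
components, where the unshifted spectrum is symmetric and plain power
iteration oscillates. The start vector is uniform positive, convergence is
an L2 tolerance of 1e-10 between successive normalised iterates (default cap
10 000 iterations; exceeding it raises a numerical error carrying the
iteration count and residual), and the vector is rescaled so the maximum
node scores exactly 1. An unweighted (binary adjacency) variant is available
via `weighted=False`. Per-cluster networks repeat build → filter →
centrality independently on each cluster's records.

## Synthetic generator

The generator emulates a virtual-diagnosis study at its published scale: 80
practitioners × 10 cases = 800 records, cases partitioned into three latent
disease clusters (A = {4,6,8}, B = {3,7,9}, C = {1,2,5,10}). Four disjoint
pools drive each prescription, each member included independently
(Bernoulli):

| pool | default contents | p | expected total count |
|---|---|---|---|
| core | CV12, LI4, LR3, PC6, SP6, ST36 | 0.60 | 480 per point |
| cluster-specific | 4 / 3 / 3 points per cluster | 0.40 | 96–128 |
| case-specific | 1 point per case | 0.50 | 40 |
| background | BL60, GV14, LI11, TE5 | 0.05 | 40 |

Prescription sizes outside 3–12 are repaired by resampling only the
background inclusions (up to 100 attempts), then by deterministic
lexicographic truncation/padding, so planted structure is never disturbed.
All randomness flows from a single integer seed; identical configuration and
seed give byte-identical output files.

The default vocabulary is deliberately exactly 30 distinct points, so the
top-30 analysis set always contains every planted point. This is forced by
the default rates: a case-specific point (p = 0.5 in one case's 80 records)
and a background point (p = 0.05 in all 800) have the same expected total
of 40, so any larger vocabulary would turn top-30 membership of planted
points into a coin flip between identical binomial means and recovery tests
would measure that lottery rather than the statistics.

What the generator does *not* emulate: inter-acupoint dependence within a
prescription (inclusion is independent given the pools), practitioner
covariates or skill heterogeneity, a realistic long tail of rare points
(real surveys reach ~47+ distinct points), and free-text noise (the CSV it
writes is already normalised). Passing recovery tests therefore show the
pipeline recovers *this* kind of planted structure, not that real records
satisfy the independence assumptions.

### A structural limit of per-case z-scores under the default rates

With six core points at p = 0.6 in every case, a case's probability profile
always carries six points above its case-specific point (expected counts
48 vs 40). Maximising the case-specific z-score over all feasible background
configurations gives ≈ 1.4 < 1.96 (e.g. profile 6×48, 3×32, 1×40, rest 0:
sd = 0.049, z = 1.25), and binomial noise (sd ≈ 0.2 on the z scale) cannot
bridge the gap: under the default generator no per-case z-score of a planted
case-specific point exceeds 1.96 in practice. The per-case axis answers
"does this point dominate the case's mix" — and under these rates the core
does. Case specificity is instead detectable on the `axis="acupoint"`
standardisation, where each planted case-specific point scores z ≈ 2.85 in
its own case with 10 cases; the regular suite asserts that property. The
acceptance suite additionally asserts the per-case-axis criterion as
specified, and it fails for the structural reason above — kept failing
rather than redefined.

## Pipeline and CLI

`run_all` executes simulate/ingest → stats → cluster → global and
per-cluster networks, writing each stage's artifacts (CSV/JSON/newick/
GraphML) under one output directory plus a run report (record digests, top-K
list, significant acupoints, assignment, network summaries, version, seed,
timestamps). A stage failure leaves earlier artifacts intact. Reports are
identical across re-runs up to timestamps. The `acunet` CLI exposes each
stage and `run-all`; exit codes are 0 (success), 2 (validation or
configuration error), 3 (numerical error). All study defaults (K = 30,
z-threshold 1.96, k = 3 clusters) are config keys.

## Problem sizes used in the tests

Oracle equivalence suites run 200 random instances (Ward up to 8 cases;
centrality on graphs up to 12 nodes against a dense eigensolver, tolerance
1e-6); conservation runs 100 random datasets; recovery runs the full
pipeline over 40 seeds at the default 800-record scale. The whole suite
completes in well under a minute on one CPU.
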