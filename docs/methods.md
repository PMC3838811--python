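# Methods

## Problem setting

Each of n proteins is described by d continuous functional-enrichment
features (GO terms, KEGG pathways) and annotated with a non-empty subset of
q phenotype categories. The yeast deletion-phenotype setting this package
targets has q = 11 categories over 1,462 proteins carrying 2,400 tag
assignments in total — a mean multiplicity of ≈ 1.64 tags per protein with
a strongly skewed per-tag prevalence (from 536 proteins down to 14). The
predictor must therefore produce a complete ranking of all q phenotypes per
query, and accuracy is assessed per rank (order-i accuracy), not as a
single-label hit rate.

## Model and procedure

**Standardization.** Features are z-scored with the population std
(ddof = 0). The convention matters only for bit-stable tests: Pearson
correlation is invariant to the affine map, and the downstream
discretization re-estimates its own cutoffs. Zero-variance features are
dropped and recorded rather than propagated as NaN.

**Correlation pre-filter (threshold 0.1).** The multi-label target has no
single "target vector", so the per-feature statistic is the aggregated
|Pearson r| over the q binary label columns. The default aggregation is the
max — a feature informative for even one phenotype is retained — with mean
as a configurable alternative. Features with statistic ≥ 0.1 are kept
(discard strictly-below). A constant label column cannot define a
correlation; it is skipped with a warning and contributes 0.

**mRMR.** The ranking operates on a 3-state coarsening of each feature
(below mean − σ·s / within / above mean + σ·s, `sigma_mult` defaulting to
1.0) and uses the plug-in mutual-information estimate in bits. Relevance of
a feature to the multi-label class is again the max (default) or mean of
its MI with the binary label columns, consistent with the pre-filter. The
greedy order is the MID (difference) form: the seed feature is the MaxRel
top; each further pick maximizes relevance minus the mean MI with the
already-selected set. All ties — here and everywhere in the package —
break by ascending index, so both tables are exactly reproducible.

**kNNA.** Cosine similarity; the k largest cosines become the neighbor
weights, used as-is (negative cosines are not clipped; the label scores are
treated as unnormalized votes, and only their order matters). A zero-norm
vector — possible after aggressive feature subsetting — yields cosine 0
with a warning instead of an error, so a jackknife run cannot abort on a
degenerate query.

**Evaluation.** Jackknife: the feature standardization, 0.1 filter, and
mRMR ranking are computed once on the full dataset before the
leave-one-out loop. This mirrors the protocol under which the reference
accuracy profile was reported, and it carries the usual selection-bias
caveat: the held-out protein has influenced its own feature selection. A
nested mode (`nested_ifs_search`, CLI `--nested`) recomputes
standardization, filter, and ranking inside each fold; it is substantially
more expensive and intended for bias studies on small data.

**IFS.** The grid covers every k in the grid × every prefix length n of
the ranked list; the best cell maximizes A¹ with ties resolved toward
smaller n then smaller k (parsimony first). The k grid defaults to 1..31
(configurable); all tests and the acceptance script use smaller grids
matched to their problem sizes.

**RPC baseline.** A protein enters the (a, b) training subset iff it
carries exactly one of the two tags. Empty subsets are legal on small data;
their classifier abstains (casts no vote) rather than guessing, so the
per-query vote total equals the number of non-abstaining pairs
(≤ q(q−1)/2). The binary learner is a plug-in satisfying a two-method
fit/predict contract; the default is nearest-centroid under cosine
similarity — deterministic, parameter-free, and adequate for the baseline
comparisons the package makes. Reproducing specific heavyweight learners
(bagging ensembles, random forests, SMO-style SVMs) is out of scope.

## Synthetic study conditions

The generator emulates the benchmark's shape: defaults are n = 1462,
d = 4682, q = 11, mean multiplicity 2400/1462, and the benchmark's skewed
per-tag prevalence profile (a geometric decay is used for other q). Label
multiplicities are allocated exactly — round(n·mean) total assignments, one
guaranteed tag per protein, the surplus drawn without replacement from
per-protein capacity slots — so the realized density matches the target to
within rounding for every seed; the conservation-law tests depend on known
label mass. Each planted informative feature is tied to one tag c (tags
cycled) and distributed as `signal_strength · 1[tag c] + noise_sd · N(0,1)`;
the remaining features are pure noise. All randomness derives from the
single config seed.

What the generator does *not* emulate: correlated GO-term features
(ontology ancestry induces strong feature redundancy in real enrichment
matrices), heavy-tailed enrichment-score distributions, and label
correlations beyond what the prevalence profile induces. Passing tests
therefore demonstrate that the machinery is correct and recovers planted
structure, not that the reported real-data accuracy (62.38% first-order at
k = 17 with 651 features) is attainable on an arbitrary dataset —
reproducing that figure requires the original enrichment matrix, which is
version-dependent and not redistributable.

## Test and acceptance problem sizes

Unit and property tests run on 2–200 proteins and ≤ 50 features — large
enough for the analytic checks (normal-tail discretization frequencies,
t-distribution null rate of the correlation filter, Monte-Carlo order
accuracies) to have power at 3σ, small enough for brute-force oracles.
The acceptance script uses n = 80–150, d = 30–60, with 5–10 planted
features; the strong-signal condition (5 informative of 50 features at
10× the noise sd, k = 5) and the zero-signal condition are those under
which recovery and null behavior are asserted.

The null-signal comparison against the most-frequent-label prior is made
at k = 40 of n = 100. The reduction "no signal ⇒ A¹ ≈ prevalence of the
commonest tag" holds where neighbor votes concentrate on the global
frequency order, which requires a moderately large k: at k = 5 the
majority vote over a skewed label distribution is systematically
conservative (measured A¹ ≈ 0.47 vs a prior of 0.54 — a real small-sample
voting effect, not noise), and at k = n − 1 the summed cosines of random
vectors center on zero and destroy the ordering. k = 40 sits inside the
concentration regime on both counts.

## Numerical choices

- Ties: ascending index everywhere (neighbors, label scores, feature
  ranks, best IFS cell after the n-then-k rule).
- MI uses log₂ (bits); the base affects scores, never ranks.
- |r| is snapped to 1.0 within 1e-12 so a feature identical to a label
  survives a threshold of exactly 1.
- Missing values in input tables are a hard error; no imputation rule is
  defined.
- File dialect: UTF-8 TSV, mandatory header, "." decimal separator; floats
  are written with 17 significant digits (exact round-trip), prediction
  scores with 6 decimals.
- Tag order is lexicographic unless an explicit tag list is supplied
  (needed to pin a non-lexicographic category order such as T1..T11).

## Known limitations

- The default (non-nested) protocol shares feature selection across
  jackknife folds; accuracies are optimistically biased on small data.
- The plug-in MI estimator is biased upward at small n; this shifts scores,
  and can shift ranks between near-tied features, but both tables remain
  deterministic.
- The RPC default learner is intentionally simple; vote-count ties at the
  top of a ranking are common for small q and resolve by tag index.
- The IFS grid is exhaustive over (k, n) — O(|k-grid| · N · n²) cosine
  computations — and is the dominant cost everywhere; scale N and the grid
  to the problem.
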