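# Methods

## The perturbation statistic

Each sample's expression profile is reduced to within-sample ranks
(ascending; ties get the average of the positions they span, so each column
of the rank matrix sums to G(G+1)/2 exactly). For a network edge (A, B),
stored with A lexicographically before B, the delta rank is
δ = R_A − R_B ∈ [−(G−1), G−1]. The benchmark δ̄ is the delta-rank vector of
the pseudo-sample formed by averaging all normal profiles gene-wise —
mean-then-rank, not the mean of per-sample delta ranks; with a single normal
the benchmark is that sample's own delta-rank vector. The perturbation is
Δ = δ − δ̄ ∈ [−2(G−1), 2(G−1)].

Assumptions and consequences:

- Ranking within samples makes Δ invariant to monotone transforms of a
  single profile. The *mean* across normals is not: the benchmark is computed
  on whatever scale the inputs carry, and inputs are expected on the log2
  scale (log2 TPM or comparable). This is documented rather than enforced.
- Edge orientation is fixed lexicographically. Any fixed orientation works
  because every comparison is within-edge; flipping an edge's orientation
  negates its δ and Δ rows.
- Half-integer ranks from ties are kept exactly; all delta arithmetic is
  integer/half-integer and the oracle tests assert element-wise equality
  with no tolerance.
- The normal cohort's own perturbation (used for feature selection and the
  tumor/normal contrast) is computed against the same benchmark as tumors.

Networks are canonicalized on load: self-loops dropped, pairs oriented
lexicographically, duplicate unordered pairs collapsed to the **maximum**
confidence (conservative retention), and only edges with confidence
**strictly greater** than the threshold (default 0.7) kept. An optional gene
universe (e.g. an immune-gene list) restricts edges to genes inside it. Exact
symbol matching is required throughout; no aliasing is attempted.

## Feature selection

Per edge, a two-sided Wilcoxon rank-sum test compares tumor and normal Δ
values. Both groups ≤ 8 samples: the p-value is computed by full enumeration
of all C(n1+n2, n1) group assignments over the pooled tie-averaged ranks.
Larger groups: normal approximation with tie-corrected permutation variance
and a 0.5 continuity correction. Since Δ differs from δ by a per-edge
constant, the test is identical on either matrix (asserted by a test).

The discrimination list takes the K_p smallest p (ties broken by larger
absolute standardized statistic, then edge id); the heterogeneity list takes
the K_sd largest tumor SDs (denominator n−1; ties by edge id). The clustering
features are their intersection, ordered by edge id — deterministic given the
inputs, monotone in K, and invariant to sample order. No multiplicity
adjustment is applied: selection is a ranking, not a significance claim.
K_p = K_sd = 4000 is the genome-scale default; on the synthetic network
(~3000 edges) the reference runs use 1500 so that the intersection is an
actual selection rather than saturation.

## Consensus clustering

Samples are points in the selected-edge Δ space under unscaled Euclidean
distance; Δ rows already share the common rank-difference scale, so no
feature standardization is applied. PAM is implemented directly: BUILD picks
medoids greedily by total-distance reduction, SWAP repeatedly applies the
best cost-reducing (medoid, candidate) exchange until none improves; exact
cost ties are resolved to the lowest candidate index, so PAM is
deterministic.

Each repetition draws ⌈0.8·S⌉ samples without replacement and runs PAM for
every k in 2..9 on that draw. The consensus value of a pair is its co-cluster
count divided by its co-draw count (never co-drawn pairs score 0 and are
counted in a logged warning). The final assignment at each k cuts an
average-linkage tree on 1 − consensus. The number of clusters is chosen by
the delta-area rule: with area(k) the trapezoid area under the empirical CDF
of upper-triangle consensus values on the grid 0, 0.01, …, 1, the relative
increase (area(k) − area(k−1)) / area(k−1) (and area(k_min) itself at k_min)
must reach the stability threshold (default 0.1); the largest such k is
chosen. The rule automates the usual visual CDF/delta-area inspection and can
be overridden with an explicit `k` in the run configuration. The subsample
fraction, linkage choice and threshold are conventions of the widely used
consensus-clustering tooling, all configurable.

Reference runs and the test suite use 250 repetitions: on the default
synthetic study the consensus matrices are effectively binary well before
that, and the planted four subtypes are recovered at ARI 1.0 with k = 4
chosen by the delta-area rule. Production-scale defaults remain 1000.

## Signatures and nearest-template prediction

Signature derivation is this package's own concrete procedure for the loosely
specified "differential expression per subtype" step: per subtype, one-vs-rest
two-sided rank-sum tests across genes with Benjamini–Hochberg adjustment
within the subtype; candidates need adjusted p < 0.05 and positive effect
(mean log2 expression in subtype minus rest); a gene may mark only the
subtype where its effect is largest (lists are disjoint by construction); the
top 300 per subtype by effect are kept — echoing a 4 × 300 signature set.

NTP standardizes each gene across the cohort's samples (a caller-supplied
reference mean/sd is required for single-sample use), builds one binary
template per subtype over the signature-gene union (1 on that subtype's
markers), and assigns each sample to the template with the smallest cosine
distance. The null rebuilds templates from random gene sets of the same
sizes drawn from all measured genes; the nominal p is the add-one fraction of
null distances at most the observed one, so p ∈ [1/(n_resample+1), 1]; BH
adjustment runs across samples and the confidence gate is FDR ≤ 0.2.
Non-confident samples keep their nearest label with `confident=False` so
downstream consumers can filter. Missing signature genes are dropped with a
warning; below 50% coverage the classification refuses to run.

## Correspondence test

The subclass-mapping check is deliberately simplified to the yes/no question
it answers: for each (subtype in A, subtype in B) pair, the statistic is the
Spearman correlation of the two subtype centroids over the shared signature
genes, with each cohort gene-standardized internally. Cohort B's labels are
permuted (A fixed) to build the null; nominal p is the add-one upper-tail
fraction, BH-adjusted across all pairs, significant at adjusted p < 0.05.
The statistic matrix transposes exactly under a cohort swap (p-values are
re-estimated). This is a methodological substitution for the original
mutual-enrichment subclass-mapping algorithm, not a reimplementation of it.

## Synthetic studies

The generator's defaults define the package's reference conditions: 1000
genes; Barabási–Albert attachment 3 grown from a complete 3-clique (edge
count exactly 3·(n−3) + 3, connected, scale-free-like with hubs); 100
normals, 200 tumors; subtype proportions (0.25, 0.28, 0.26, 0.21); 60
dysregulated genes per subtype; shift 3.0 log2 units with a per-gene sign
fixed at generation; noise sd 0.5 (normals) / 1.0 (tumors); exponential
survival with hazards (0.10, 0.14, 0.12, 0.05) — the fourth subtype has the
best prognosis — and exponential censoring at rate 0.3. Gene baselines are
Uniform(2, 10) on the log2 scale. Dysregulated genes are drawn without
replacement with probability proportional to degree: shifting a hub perturbs
many edges, which is exactly why edge perturbation is informative, and the
bias makes planted structure expressible at realistic shift sizes.

Validation cohorts are drawn from the **same frozen design** (network,
baselines, dysregulated sets, signs) with new labels and noise
(`simulate_validation_cohort`); without that reuse the subtypes of two
cohorts would not correspond and neither NTP agreement nor the
correspondence test would be meaningful.

What the generator does not emulate: platform/batch effects, heavy-tailed or
count-level noise, correlated gene modules beyond the planted shifts,
non-proportional hazards. Passing tests therefore demonstrate correctness of
the machinery and recoverability of planted structure under Gaussian
log-scale noise — not performance on real cross-platform cohorts.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` seeds carried in
  configs; every stochastic stage is bit-reproducible given its seed, and the
  run manifest records config plus SHA-256 digests of the key outputs so two
  runs can be compared by a single digest.
- PAM's `seed` argument is accepted for interface symmetry but unused: ties
  are broken structurally (lowest index) instead.
- Rank-sum SD tie-breaks and edge-id ordering make feature selection fully
  deterministic; mergesort (stable) is used wherever order matters.
- Degenerate inputs: constant genes get unit sd in standardization (zero
  signal, no NaN); zero-variance rank-sum rows give p = 1; empty networks,
  empty groups, sub-minimal cohorts and coverage shortfalls raise early with
  named offenders.
- Known limitation: under the exponential-censoring survival model at the
  default rates, censoring is heavy (only ~20–25% of samples experience
  events), so two-group log-rank power at hazards 0.10 vs 0.05 with 100+100
  samples sits near 0.55–0.60; detecting such a hazard ratio reliably needs
  lighter censoring or larger cohorts. The four-subtype comparison on the
  default study is nevertheless significant in the reference runs.
- The library is used from Python; the examples/ scripts are the runnable
  interface and there is no console entry point.
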