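# Methods

## Trait space

A genome's metabolism is represented as a directed graph whose nodes are
metabolite compounds and whose edges link substrates to products. Each
unique directed edge observed anywhere in the collection defines a binary
trait; direction matters (A→B and B→A are distinct capabilities). Trait
columns are labeled `substrate->product` and ordered lexicographically,
so the matrix is a pure function of the input edge sets and independent
of file or insertion order. Any compartment filtering (e.g., restricting
models to cytoplasmic reactions) is assumed to have happened upstream;
the package takes edge lists at face value.

Constant columns are retained by default: they contribute nothing to any
pairwise Euclidean distance, so keeping them changes no downstream
result. `drop_constant_traits` is an explicit opt-in for compactness, and
the distance invariance is tested exhaustively on random matrices.

## Diffusion map

Genomes are compared by Euclidean distance between trait rows. Each
genome is linked to its k nearest neighbors (k = 10 by default; distance
ties are broken by input row order with a stable sort) with weight
w = 1/d, and the directed relation is symmetrized by the elementwise
maximum, which preserves "every node has at least k positive-weight
neighbors" and keeps the graph better connected than mutual-kNN. A
Gaussian kernel exp(−d²/σ²) with σ equal to the median kNN distance is
available as an alternative; the inverse-distance default is
parameter-free and monotone in distance. Duplicate rows are rejected
(their weight would be infinite); `deduplicate_genomes` merges them to
one representative and reports the grouping so results can be re-expanded.

From the weighted adjacency W the row-normalized Laplacian
L = I − D⁻¹W is formed (D = diag of row sums). Its eigenvectors are the
diffusion variables, ordered by ascending non-zero eigenvalue; the zero
eigenvalue's constant eigenvector is discarded. Eigenpairs are computed
on the symmetric conjugate L_sym = I − D^(−1/2)WD^(−1/2) with a dense
symmetric solver and back-transformed (v = D^(−1/2)u), which guarantees
a real spectrum in [0, 2] and stable numerics; residuals ‖Lv − λv‖∞ are
checked in the tests at 1e−8. A dense solver is used because the intended
collections (hundreds to a few thousand genomes) are comfortably within
its range. Eigenvector sign is mathematically arbitrary; it is fixed so
each variable's largest-magnitude entry is negative (first occurrence on
ties), making the whole pipeline bit-deterministic. Tests that do not
target the sign rule use sign-invariant assertions.

A disconnected graph (repeated near-zero eigenvalue, tolerance 1e−8) is
an error by default with the advice to raise k; with
`allow_disconnected=True` the additional near-zero eigenvectors are
returned, but they indicate components, not strategies.

Per-variable localization is quantified by the inverse participation
ratio Σvᵢ⁴ of the unit-norm entries, ranging from 1/N (perfectly flat)
to 1 (a delta). Localized variables mark small clusters of genomes with
unique shared capabilities.

Diffusion distances are Euclidean over the retained variable entries
("flat", the default). An "inverse_eigenvalue" mode divides each
variable by its eigenvalue first, emphasizing slow diffusive modes;
which weighting is preferable depends on how strongly one wants early
variables to dominate, so both are exposed.

## Enrichment at variable extrema

For one variable, genomes are ranked by entry in descending order and
every metabolite defines the set of genomes whose networks contain it as
a node (sets smaller than 5 or larger than N−5 are dropped as
uninformative). The enrichment score is the signed extreme of a running
sum that rises by |stat|^exponent (normalized over the set's members) at
members and falls by 1/(N−|S|) otherwise; positive ES means enrichment
toward the positive extremum. The exponent defaults to 1 (entry-weighted
steps); exponent 0 gives the equal-step walk whose worked examples are
analytic and frozen in the tests.

The null distribution draws random same-size genome sets; the p-value is
the add-one estimator over sign-matched null scores, so p ≥ 1/(n_perm+1)
and enrichment toward either extremum can be detected in a single pass.
Benjamini–Hochberg correction is applied across the metabolites tested
for one variable (the family is per-variable; a global family can be had
by concatenating tables before adjustment), with significance at
adjusted p < 0.05. The generator is seeded; identical seeds give
identical tables, and output rows are sorted by (p_adj, metabolite_id).

## Phylogeny comparison

Cophenetic (patristic) distances are summed branch lengths between
leaves, computed via dendropy. The Mantel statistic is the Pearson
correlation of the condensed upper triangles of the two distance
matrices; the null jointly permutes the rows and columns of the second
matrix. The p-value is one-sided for positive association by default
(the directional hypothesis of interest — related taxa share metabolic
strategies), with a two-sided option; 999 permutations and the add-one
estimator by default. Note the permutation p is *not* invariant to
monotone transforms of the distances, since Pearson is not rank-based.
Genome/leaf identifier sets must match exactly; mismatches raise an
error listing both directions rather than silently subsetting.

## Community fingerprints

A niche is operationally the set of n = 10 genomes at one extremum
(negative or positive, ties broken lexicographically) of one diffusion
variable; the first 50 variables give 100 extremal strategy sets. A
census occupies a niche if at least one of its taxa maps — through a
precomputed top-hit match table, one genome per taxon, at ≥ 97 %
identity (inclusive) — to a niche member. Occupancy is presence-based;
abundances are ignored. Ecosystem fingerprints are per-ecosystem
occupancy proportions, and rows are clustered with Ward's
minimum-variance criterion on Euclidean distances (scipy's deterministic
nearest-neighbor chain). Sequence extraction and alignment are outside
the package: the match table is the input contract, which keeps the
module testable without sequence databases.

## Synthetic data

The generators plant exactly the geometry the analysis is meant to
detect, with analytically tractable noise:

- **Clusters** (`make_clustered_traits`): a shared trait core, one
  private trait block per cluster, optional background genomes carrying
  only the core, and independent Bernoulli bit flips. Default test
  fixtures use 25–60 genomes, cluster size 5, 20–25 private traits, and
  flip probability 0.02 — small enough that the full pipeline runs in
  seconds, structured enough that separation margins are comfortably
  positive. Cluster sizes are kept below k so the kNN graph stays
  connected across the k ∈ {5, 10, 15} robustness checks. With
  `force_unique` each genome gains one private trait, ruling out
  duplicate rows at low noise.
- **Branches** (`make_branching_traits`): quasi-1D branches accrete
  traits stepwise from one shared root genome; Hamming distance within a
  branch is exactly |Δstep|·traits_per_step.
- **Trees and trait evolution**: Yule (pure-birth) trees via dendropy
  with a final exponential holding time added to the tip edges (the
  simulator stops exactly at the nth split, which would otherwise leave
  a zero-length cherry). Traits evolve independently as two-state
  continuous-time Markov chains (gain and loss rates per unit branch
  length); leaf marginals follow the closed form
  P(1|parent) = π₁ + (state − π₁)e^(−(gain+loss)t), which the tests
  check at Monte-Carlo precision. Trees are rescaled to unit depth in
  the signal-recovery fixtures so that rates of 0.5/0.5 are "moderate":
  enough change to differentiate clades, far from saturation.
- **Communities** (`make_communities`): each sample occupies each niche
  independently with its ecosystem's probability by drawing one member
  genome's pseudo-taxon. Extremal niches share genomes, so occupancy of
  overlapping niches is correlated; round-trip tests therefore design
  their profiles on pairwise-disjoint niches, where per-niche occupancy
  is exactly binomial and the 3·√(p(1−p)/n) recovery bound applies. An
  always-occupied shared niche guarantees nonempty censuses (a sample
  with no taxa is an error by construction).

All generators are pure functions of spec + seed.

What the generators deliberately omit: correlated trait noise, varying
genome sizes, horizontal transfer, abundance structure in communities,
and any realistic biochemistry. Passing tests therefore demonstrate that
the algorithms recover the structure they assume, not that real genomes
exhibit that structure.

## Design notes and limitations

- The similarity kernel and symmetrization of the underlying kNN
  diffusion-map construction admit several choices; inverse-distance
  weights with union symmetrization are the defaults here, and both are
  configurable. Orderings along variables (the operative quantity for
  extrema and rankings) are insensitive to eigenvector normalization;
  entries are reported unit-norm.
- `diffusion_eigs` takes the neighbor graph rather than a precomputed
  Laplacian: the stable symmetric-conjugate route needs W and D
  separately, which the Laplacian alone does not expose. The
  row-normalized Laplacian remains available as `row_normalized_laplacian`
  and the eigenpair contract is verified against it.
- Permutation tests (enrichment, Mantel) use the add-one estimator, so
  reported p-values are conservative at small permutation counts.
- Ward clustering of a handful of fingerprint rows is descriptive; no
  uncertainty is attached to the dendrogram.
- The enrichment family is per variable. Scanning many variables and
  collecting all significant metabolites inflates the family-wise error
  across variables; adjust globally for such scans.
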