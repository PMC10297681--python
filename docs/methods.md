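# Methods

This note documents the models, conventions and numerical choices behind
voicechain, and what the packaged fixtures and synthetic generators do and
do not exercise.

## Chain search

The pathway ensemble is held as a gene→pathway inverted index; the
pathway-overlap graph (nodes = pathways, edge iff the gene sets intersect)
is implicit and never materialized. Linkage is binary: the number of shared
genes does not weight an edge. The level-1 chainlink set is
`S ∩ (∪ head pathways)`; the level-2 set collects genes of `S` on non-head
pathways that intersect a head pathway. Because a chain may not repeat a
pathway and intermediate nodes must not contain the head gene, this
two-step closure is exhaustive for levels ≤ 2, and `max_level` is hard-capped
at 2 — beyond that, chained influences cannot be disambiguated and, in
realistic collections, overlap density makes deeper chains nearly universal
(see the chance model below).

Conventions, each switchable:

* **Exclusive levels (default).** A gene already reported at level 1 is not
  re-reported at level 2, so the two counts partition the chainlink genes,
  matching how the reference table prints separate per-level counts. The
  inclusive convention reports each level independently.
* **Connectivity (default union, head included).** Connectivity of a gene
  set is the number of distinct ensemble pathways containing at least one
  of its genes. The reference table's caption says "additional" pathways,
  but its own printed value for a gene connected *only* to the head pathway
  is 1 — head pathways are therefore counted by default; `sum` mode
  (per-gene counts added) and head exclusion are available as flags.
* **Multiple head pathways.** All operations take the union over every
  pathway containing the head gene. The motivating collection happens to
  have exactly one (the 63-gene ACC pathway).
* All reported gene sets serialize in lexicographic order; witness chains
  order by (head id, intermediate id). Results are byte-stable across runs.

## Phenotype categories and cohort statistics

Reported speech effects are mapped to the closed taxonomy {normal, apraxic,
dysarthric, impaired, delayed, absent, idiosyncratic} by word-bounded,
case-insensitive code tokens (Del, Imp, Norm, Abs, Apr, Dys, Idio), their
written-out forms ("dysarthric", …), and a small phrase map for rows with
no code token ("No significant …", "Sensorineural hearing loss" → normal
speech, as hearing loss alone is not a speech-production anomaly). Texts
with no recognizable content yield the empty category set and the record is
excluded from the cohort as unanalyzable. No further NLP is attempted.

Cohort construction merges rows describing the same region (the reference
table splits two regions into symptom-defined sub-rows with identical gene
content): categories, implicated genes and effects text are unioned, the
chain counts kept once; duplicate names with *different* counts raise an
integrity error.

Per-category statistics use the level-2 chainlink count and connectivity
only — level-1 sets hold one or two genes and are too small to model. A
syndrome contributes to every anomaly category its effects list.
Conventions:

* **Idiosyncratic folds into apraxic** by default (an apraxia-adjacent
  presentation); a flag keeps it separate.
* **Normal is exclusive** by default: the normal-speech group contains only
  syndromes whose *sole* reported outcome is normal speech. A row such as
  "Norm or Del" is evidence of delayed speech in part of the reported
  population, not evidence of a no-anomaly syndrome. On the packaged table
  this convention yields a 6-member normal group whose mean chainlink count
  (32) and mean connectivity (404) match the reference analysis exactly;
  the inclusive alternative is available as a flag.
* Means are reported rounded to the nearest integer; medians use the
  midpoint of the middle two values for even group sizes. The severity rank
  ordering sorts by unrounded mean chainlink count, ties broken by mean
  connectivity.

A reproducibility caveat: the reference analysis derives its per-category
table from a more detailed appendix table that the packaged transcription
does not include. From the packaged table the absent-speech row (n=19,
mean count 60, median 46, mean connectivity 902, median 718), the
normal-speech means, the delayed (n=51) and dysarthric (n=11) group sizes
and the apraxic mean connectivity (675) all reproduce exactly, but the
impaired group reconstructs with 32 members (reference: 31) and mean count
47.8, which lands *above* delayed (46.9) instead of just below it. The
impaired/delayed adjacent pair of the printed severity ordering is
therefore not reproducible from the packaged data; the surrounding
ordering (normal least, apraxic < dysarthric by the connectivity
tie-break, absent greatest) is.

## Conway–Maxwell–Poisson modelling

Chainlink counts and connectivities are over-dispersed; both are modelled
with the CMP family `P(n) = λ^n (n!)^{-ν} / Z(λ,ν)`, λ, ν > 0 (ν = 1 is
Poisson; ν < 1 over-dispersed). Numerical choices:

* **Normalizer.** `log Z` by term-wise log-space summation, stopping once
  past the mode with the next term below 1e−12 of the partial sum, hard
  cap 1e5 terms. Connectivity values reach ~3000, far beyond naive
  factorial range, so everything stays in logs. The ν→0, λ≥1 region is a
  divergence guard (geometric limit).
* **Fitting.** L-BFGS-B over (log λ, log ν), bounds log λ ∈ [−30, 60],
  ν ∈ [1e−3, 1e3], iteration cap 500, two deterministic starts — a
  moment-matched point (ν₀ = mean/variance clipped to [1e−2, 1e2],
  λ₀ = mean^ν₀) and the Poisson point (mean, 1) — keeping the better
  likelihood. Degenerate inputs (fewer than two distinct values) are
  rejected.
* **Code distance.** The pairwise metric is the *excess-bits* orientation
  `D = Σ_{C_i} log2(P̂_i/P̂_j) + Σ_{C_j} log2(P̂_j/P̂_i)`: symmetric,
  exactly zero for identical sets, non-negative in expectation (a plug-in
  estimate of `n_i·KL(P_i‖P_j) + n_j·KL(P_j‖P_i)`). The formula as often
  written with the opposite ratio orientation would be negative in
  expectation, contradicting its verbal definition as an excess coding
  cost; a flag restores the flipped sign for comparison. Underflowed
  probabilities are floored at `e^{-700}` with a logged warning.
* Exact reference distance-matrix values are not reproducible — they
  depend on unstated estimator details — so the package's tests check the
  qualitative structure instead: symmetry, zero diagonal, large-sample
  agreement with the plug-in KL expectation, and the normal-speech row
  dominating every column of the upper-triangular matrix.

## Chance model

With `n_linked_genes` distinct genes on pathways linked to the head
pathway(s) and a symbol universe of `n_universe`, a uniformly random gene
is level-2 chainlink material with `p = n_linked_genes/n_universe`, and a
random k-gene region has a level-2 chain with `1 − (1−p)^k` (independence
across genes). The census excludes genes occurring *only* in head pathways
by default (they are level-1, not level-2, material; a flag includes
them). The universe size is always an explicit input (default 42,764, the
HGNC symbol count of the motivating study) — a GMT file covers only
pathway genes and must not define the universe.

## Synthetic data

The generators are pure functions of (spec, seed), one named RNG stream
each. `generate_ensemble` draws pathway sizes uniformly from a range and
forces, for each pathway pair independently with probability
`overlap_density`, one shared gene; remaining slots are filled with unused
universe genes. Density 0 gives pairwise-disjoint pathways, density 1
links every pair; at high density the forced shares can push a pathway
slightly past the top of its size range. The head gene lives in pathway 0
only. `plant_region` samples disjoint gene classes — head-pathway genes
(level-1 truth), genes on linked-but-not-head pathways (exclusive level-2
truth), and genes on neither (inert background) — and returns the labels
alongside the region.

What this emulates is the overlap structure that drives chain search, not
real pathway collections: real pathway sizes are heavy-tailed, gene
multiplicities are far from uniform, and symbols carry aliasing issues the
generator never produces. Passing the oracle-equivalence and
planted-recovery sweeps therefore validates the *algorithm*, not any
biological claim about real data.

The brute-force oracle enumerates every pathway sequence of length ≤ 2
satisfying the chain definitions literally and is restricted to ≤ 50
pathways; the equivalence sweep runs 100 seeded instances (5–40 pathways,
overlap density 0–0.35, regions of 1–11 genes) under both level
conventions. CMP sampling is inverse-CDF over the truncated support;
parameter-recovery checks use 2000 draws per seed over 20 seeds — sizes
chosen to keep the full suite fast while leaving the statistical checks
well-powered.

## Known limitations

* Terminal-set gene lists must use the same symbol vocabulary as the GMT;
  only trim/uppercase normalization is applied (an alias-map hook ships
  empty).
* The packaged table is a transcription of a printed summary; its
  per-category statistics inherit the printed table's granularity (see the
  reproducibility caveat above).
* No joint count+connectivity model and no alternative count families
  (e.g. negative binomial) are provided.
* The chance model assumes genes are drawn independently and uniformly;
  real microdeletion regions are contiguous cytogenetic segments, and gene
  co-location correlates with shared pathway membership.
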