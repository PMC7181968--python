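# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `gemscreen`, and what the synthetic-data generators do and do not
emulate.

## Metabolic model and FBA

A model is a set of metabolites (with compartments), reactions (signed
stoichiometries, flux bounds, boolean GPR rules) and one biomass objective
reaction. The steady-state balance `S v = 0` applies to **every**
metabolite; boundary exchange is modeled by explicit single-metabolite
exchange reactions, never by excluding metabolites from the balance. This
keeps metabolic-task constraints expressible as plain exchange-bound
overrides.

FBA solves `max c·v s.t. S v = 0, lb ≤ v ≤ ub` with HiGHS (via
`scipy.optimize.linprog`). Every optimal solution is verified in-process:
steady-state residual ≤ 1e-6 and bound satisfaction within 1e-6; the
reported-objective comparison tolerance used throughout is 1e-6. Default
bounds when a file omits them: (0, 1000) irreversible, (−1000, 1000)
reversible — conventional large finite bounds that avoid unbounded LPs.
Repeated solves return the same objective value; flux vectors may differ
under degeneracy and are never asserted on.

GPR grammar: case-insensitive `and`/`or`, parentheses, gene ids as
non-whitespace tokens, `and` binding tighter than `or` (the common SBML-fbc
text rendering). An empty rule is a spontaneous reaction and always
evaluates true. A knockout closes exactly the reactions whose rule
evaluates false.

I/O: SBML Level 3 + fbc (gene-product associations, flux-bound parameters,
objective) through python-libsbml, and a human-writable tabular TSV dialect
for fixtures (sections `[model]`, `[metabolites]`, `[reactions]` with
equation strings like `2 A + B => C`, `<=>` for reversible). Round trips
preserve stoichiometry, bounds and GPRs; bounds are written at full double
precision in the tabular dialect and at libsbml's default double precision
in SBML.

## Logic transformation (LTM)

The knockout scan first rewrites the model so each reaction carries exactly
one gene label. Each GPR is converted to disjunctive normal form; a
reaction with d > 1 disjuncts becomes d parallel duplicates, each labeled
by its disjunct (a single gene, or a composite pseudo-gene `a&b` for an AND
conjunction whose knockout is triggered by any constituent). Duplicates
share the source reaction's capacity through a coupling pseudo-metabolite:
every duplicate additionally produces one unit of `_cap_<rxn>`, drained by
an unlabeled reaction carrying the original bounds. Pure duplication with
independent bounds would multiply pathway capacity; the coupling makes the
transformation exactly growth-preserving, which the tests assert at 1e-6
for the wild type and for every single-gene knockout against the direct
GPR-evaluation route.

DNF size is capped (default 64 disjuncts). A reaction exceeding the cap
keeps its original rule and is evaluated directly during knockouts — a
per-reaction fallback rather than a failure, since deeply nested GPRs can
explode combinatorially.

Essentiality: gene g is essential when knockout growth < threshold ×
wild-type growth. The threshold default is 1e-3 — "growth effectively
abolished" — and is config-exposed; raising it can only grow the essential
set (monotonicity is tested). One LP instance is reused across the scan
with bound updates only; results are identical to fresh per-gene solves.

Consensus across an ensemble reports two tallies per gene, since a gene may
be absent from some member models: `fraction` counts absence as
non-essential, `fraction_present` conditions on the models containing the
gene. Both are exported; the consensus set uses fraction 1.0.

## Ensemble merge and clustering

The Hamming distance between two models is the size of the symmetric
difference of their reaction-id sets; it is a metric, which the tests check
(triangle inequality on random ensembles, plus a bit-vector oracle).
Clustering is agglomerative on the distance matrix with complete linkage by
default (average/single selectable); the two-group partition comes from
undoing the final merge ("top split"). The implementation is an explicit
O(n³) agglomeration with a deterministic tie-break — among minimal-distance
cluster pairs, the pair with the lexicographically smallest member indices
merges first — and is cross-checked against scipy's linkage on matrices
with distinct distances. In the fully degenerate all-zero matrix this
tie-break chains from the lowest index upward, so the top split is the last
model versus the rest. Distances are not normalized before clustering;
linkage and everything else is config-exposed.

Merging unions metabolites, reactions and genes; a shared reaction id keeps
the widest bounds seen and the OR of the distinct member GPRs (deduplicated
by normalized rule string — a reaction is available if any patient context
supports it). Identical ids with different stoichiometries are a merge
conflict error. If member objectives disagree the most frequent biomass id
wins with a warning (disagreement indicates fixture errors, as ensembles
from one reconstruction pipeline share one biomass). Components are
canonically sorted, so merging is order-invariant, and the merged optimum
dominates every member's (member fluxes extend by zeros).

## Metabolic tasks and the toxicity screen

A task lists allowed inputs (uptake intervals) and required outputs
(production intervals). Checking closes **all** boundary exchanges, adds a
temporary uptake reaction per input and a sink per output with the stated
bounds, and tests LP feasibility; the model itself is never mutated between
tasks. A task naming a metabolite absent from the model is `untestable`, a
distinct status never counted as a pass. `should_fail` tasks inverted the
raw feasibility. Task files are a flat TSV (one row per constrained
metabolite) — an importable flattening of the spreadsheet layouts used for
published task lists; fields beyond input/output bounds and `should_fail`
are out of scope.

"Reactions coupled to a gene" defaults to knockout-consistent coupling
(reactions whose GPR fails when the gene alone is knocked out), matching
the knockout semantics on the tumor side; a stricter "all listing
reactions" mode is selectable. The screen runs each candidate independently
from the intact healthy model (order cannot matter; asserted), aborts if
the unmodified model fails its own battery, and treats candidates absent
from the healthy model as non-toxic by definition (flagged `absent`). The
shortlist is essential ∧ non-toxic, sorted by knockout growth ratio.

## Survival stratification and differential expression

Only patients with vital status "dead" enter the stratification. Quantiles
use linear interpolation (type 7) with **strict** inequalities at the cut
points: low = days < Q(1/3), high = days > Q(2/3), middle tertile
discarded. Coinciding cut points are an error, not a silent empty group.

DE results are consumed as a (gene, log2fc, p) table with a **declared
orientation**; under the default high-vs-low contrast, log2fc < 0 means
upregulated in the low-survival group, and the up/down split is
significant (p < α, default 0.05, raw p by design) with the corresponding
sign; log2fc = 0 rows join neither set. The built-in `simple_de` — a
per-gene Welch t-test on log2 expression with log2fc = mean(high) −
mean(low) — is a stand-in for synthetic runs only; externally supplied DE
tables (e.g. from a negative-binomial count model) are never recomputed.
Zero-variance genes get p = 1 by convention.

Dependency validation reports each target's median CRISPR dependency score
across cell lines and a two-sided one-sample t-test of its scores against
the mean of all genes' medians; targets absent from the matrix are listed
as skipped, not failed.

## Co-expression

Pearson correlations over all gene pairs (≥ 3 samples required; constant
genes yield flagged NaN entries excluded downstream). The network keeps
pairs with r ≥ cutoff (default 0.99, signed — "top correlated", not |r|);
an alternative quantile mode keeps the top fraction of pairs, since a 0.99
threshold and "top 1% of pairs" are different readings of the same
convention. Communities come from igraph's Walktrap (walk length 4, the
algorithm's customary default). Cluster filtering keeps clusters with ≥ 5
genes and mean pairwise correlation > 0.5 computed on the **full**
correlation matrix — on edge weights the filter would be vacuous above a
0.99 cutoff; whether mean, median or minimum is intended by convention is
genuinely open, so the statistic threshold is configurable. Neighborhood
queries return up to n = 8 genes above r = 0.9, ranked descending.

## Reporter metabolites and subnetworks

The gene–metabolite graph joins gene g to metabolite m when some reaction
involving m carries g in its GPR. Twenty ubiquitous currency metabolites
(H2O, CO2, O2, H+, HCO3−, Na+, CoA, Pi, PPi, AMP, ADP, ATP, NAD+, NADH,
NADP+, NADPH, PAP, PAPS, FAD, FADH2) are removed by default, matched by
name across compartments, case-insensitively, with the unicode minus
normalized — they connect unrelated reactions and would dominate any
topology-based score.

Per-gene z-scores come from directional p-values: for the "up" run,
z = Φ⁻¹(1 − p/2) when the gene moves in the up direction and Φ⁻¹(p/2)
otherwise (p clamped to [1e-15, 1 − 1e-15]). The analysis is run twice (up
and down) rather than once signed, so both rankings are available. A
metabolite with k scored neighbors gets z_raw = Σz/√k, corrected by a
Monte-Carlo background of random size-k sets drawn from **all** scored
genes (default 10 000 samples per distinct k, cached; with-replacement
sampling is used when k is below a tenth of the pool — the variance
deflation is under 1% there — and exact without-replacement sampling
otherwise). z_corr = (z_raw − μ_k)/σ_k with an upper-tail normal p. Under a
uniform null this is calibrated: variance of z_corr near 1 and type-I error
near α, which the tests assert within [0.8, 1.2] and [0.03, 0.07].

The reporter subnetwork maximizes Σz/√(number of genes) over connected
subgraphs (connectivity in the gene projection: genes adjacent when they
share a metabolite). The search is greedy seeded expansion from the
top-scoring gene followed by simulated annealing (add/remove moves that
preserve connectivity, geometric cooling from T₀ = 1 to ~1e-3 over 2000
steps, seeded and deterministic). The literature does not pin down this
search, so correctness is defined by planted-recovery tests (node recall ≥
0.9 over 20 seeds), not by exact output. Every included metabolite's
within-subnetwork gene degree is reported for neighborhood summaries.

## Synthetic data: what it emulates, and what it does not

* **Toy GEMs** are linear biosynthesis pathways (default 3–4 pathways,
  chain length 3) feeding one biomass reaction, with GPRs drawn as single
  genes / OR isozyme pairs / AND complex pairs (default mix 0.4/0.3/0.3).
  Because each chain is the unique route to its precursor, the essential
  set is known by construction: single-step genes and both AND genes, never
  lone OR isozymes.
* **Ensembles** (default 30 members, 40 variable dead-end side reactions,
  archetypes separated by 10 reactions, 5% presence-flip noise) plant a
  two-cluster structure mirroring a patient cohort in which a subgroup of
  models differs visibly in reaction content; variable reactions never
  touch the biomass path, so every member grows.
* **Expression** is normal on the log2 scale (the pipeline consumes
  normalized expression; a count mode is not simulated) with exponential
  survival times (median 350 days, all-dead cohort by default, censoring
  ignored as only dead patients are stratified), planted DE genes shifted
  by ±2 log2 units between survival tertiles, and co-expression blocks
  driven by a shared latent factor at pairwise correlation block_rho.
* **Task batteries** pair importable substrates with reachable products
  (feasible) or with products whose only routes start from other, closed
  substrates (infeasible), with the expected status recorded.
* **Dependency matrices** draw essential genes from N(−1, sd) and the rest
  from N(0, sd) over 31 cell lines, sd = 0.1 by default.
* The **target scenario** plants a tumor model whose essential genes split
  into toxic (also sole-route catalysts in the healthy model) and non-toxic
  (absent from the healthy model), so the screen's shortlist has an exact
  expected answer.

All generators are deterministic given their seed, and the planted truth is
serialized (JSON) next to the data. What passing these tests shows is that
every algorithmic step is implemented correctly against its contract; what
they cannot show is performance on real tissue reconstructions — genome-
scale network topology, GPR depth, correlated reaction presence, RNA-seq
count noise, batch effects and censored survival are all outside the
generators' scope.

## Pipeline, seeds and problem sizes

The pipeline derives one seed per stage from the master seed by hashing the
stage name (logged in each stage manifest alongside input checksums and
runtime), so reruns with the same config reproduce outputs exactly. Unknown
config keys are rejected before any stage runs; the effective config is
serialized into the run directory.

The acceptance script sizes its simulations for a single CPU: 50 random
models (≤ 30 reactions) for the LP-oracle comparison, 8 models for the
logic-transformation cross-check, ensembles of 30 for clustering, a
2000-gene pool with 1000 metabolite neighborhoods for the reporter null
calibration, and a 600-gene, 120-sample cohort for the DE round trip. These
sizes make the Monte-Carlo estimates stable across seeds while the whole
script completes in well under a minute.

## Known limitations

* No flux variability analysis, parsimonious FBA, thermodynamic
  constraints, gap-filling or model reconstruction — ensembles are
  consumed, not built.
* Single-gene knockouts only; double/synthetic-lethal scans are out of
  scope.
* Task semantics cover input/output bounds and an expected-failure flag;
  richer task spreadsheet fields (allowed-reaction lists, flux equalities)
  are reported as unsupported rather than silently dropped.
* The DE stand-in is a Welch t-test on log expression, not a count model;
  multiple-testing correction is pass-through only (the split thresholds
  raw p by design).
* Enrichment analysis is external by design: the package exports plain
  gene lists.
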