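# Methods

## Model and sampling

The pipeline operates on a steady-state stoichiometric model: metabolites ×
reactions matrix `S`, flux bounds `alpha <= v <= beta` in mmol/gDCW/h, and a
biomass pseudo-reaction. Uptake exchange fluxes are negative by convention.
Measured fluxes come in two classes — isotope-traced intracellular fluxes
(`C13`) and culture rates such as growth and substrate uptake (`FMT`) — each
as a mean and standard deviation per condition (`control` / `perturbed`).

Each flux sample draws one randomized target per measured reaction from a
normal distribution truncated to one standard deviation around the mean.
Truncation implements the requirement that simulated measurement errors stay
within the reported standard error; it is done by rejection sampling rather
than clipping so no probability mass piles up at the interval endpoints. A
zero sigma degenerates to the mean exactly (how knocked-out reactions are
measured as zero).

The reconciliation LP minimizes the L1 distance between model fluxes and the
randomized targets subject to `S v = 0` and the bounds, using standard
positive/negative deviation variables (HiGHS through scipy). The L1 optimum
generally leaves unmeasured fluxes degenerate, so a secondary LP fixes the
measured fluxes at their achieved values and minimizes the total absolute
flux. This parsimony tie-break is a design choice: the sampling variability
of the flux matrix then comes only from the randomized targets, not from
solver vertex selection, and whole runs become bit-reproducible. There is no
biomass maximization in the sampling LP — growth rate is itself a measured
constraint. Targets are re-drawn jointly each iteration. Per-column
generators are seeded with the (master seed, condition, sample index) triple,
so either condition can be regenerated independently.

Fluxes with |v| < 1e-6 are treated as zero throughout (activity calls,
pattern ties); rows are called duplicates when they agree within 1e-9 in
max-norm ("exactly the same" up to LP output noise), with transitive closure
over the relation.

## Core selection

Three filters in order: (1) two-sided paired t-test per reaction, pairing
control and perturbed samples by index, threshold P < 1e-2 with no
multiplicity correction — both choices exposed as configuration; the test is
two-sided because the direction of a perturbation response is not known a
priori. Zero-variance difference rows get p = 1 (no change) or p = 0 (a
deterministic shift). (2) Activity: strictly more than 95% non-zero samples
in at least one condition. (3) Duplicate collapse to the lexicographically
smallest member; removed members are kept in the bookkeeping and reinserted
into their representative's module after clustering.

## Modularization

The flux-pattern encoding maps consecutive (permuted) sample pairs to the
sign of the flux change, with changes below the zero tolerance as 0. Many
independent uniform random permutations (default 300) are adjoined; because
squared Euclidean distances add across concatenated blocks, pairwise
distances are accumulated permutation-by-permutation and the full adjoined
matrix is never materialized (contract: identical to the naive construction,
tested).

Clustering is average-linkage on these distances. The flat cut uses the
depth-2 inconsistency coefficient at cutoff 1.0, reproducing Matlab's
`clusterdata` semantics for cutoffs <= 2: raw Euclidean distances on
adjoined pattern rows are orders of magnitude above 1.0, so a raw-distance
cut at 1.0 would produce only singletons. A `distance` criterion is kept for
sensitivity analysis. Cluster ids are renumbered 1..C by smallest member row
index so module numbers are reproducible.

A property of depth-2 inconsistency cutting worth knowing: a link merging
two singleton leaves has no descendant links, its inconsistency is 0, and it
is therefore always accepted — isolated singleton groups are intrinsically
unstable under this criterion. The synthetic fixture is designed so that no
true module is a singleton (see below).

## Bayesian networks

All sampled fluxes (both conditions, one pooled sample set) are discretized
once by the equal-frequency method into 4 bins; the same discretization
backs local networks, the global network and all MI/TMI values, keeping them
mutually consistent. Bin edges sit at the empirical quartiles; values equal
to an edge fall in the lower bin so ties never split. Variables with fewer
separable values collapse to fewer bins with a warning (typical for knocked
reactions: half the samples are exactly zero).

The structure score is MDL in bits: `log2(M)/2` per free parameter plus the
maximum-likelihood code length `M * H(X_i | Pa_i)`. ML counts (no smoothing)
are used inside the score, as MDL theory assumes; the reported conditional
probability tables use Laplace (+1) smoothing. The search is score-based
local search over DAG space with add/delete/reverse arc moves, cycle
rejection, a tabu list (length 10) of inverse moves with best-ever
aspiration, acceptance of the best non-tabu neighbour even when worsening,
and random restarts (default 3: empty start plus random DAGs). The
proprietary "tabu order" variant referenced by BN tools is unpublished; this
is the standard tabu search over the same move set, which attains the
exhaustive-search optimum on all tested 3-variable datasets. Parent sets are
capped at 4 to bound conditional-table support on ~2000 samples.

TMI of a module member is the sum of its pairwise empirical mutual
informations (base 2) against the other members, computed from the
discretized data; the member with maximal TMI is the representative, ties
broken lexicographically. Computing MI from empirical frequencies rather
than from the fitted local-network joint is a documented choice — the two
agree for the dominant coupled pairs, and the empirical version is
estimator-independent.

## Essentiality

`e = clamp(1 - g_del/g_ref, 0, 1)` where both growth rates are LP maxima of
the biomass flux. Deletions that increase growth clamp to 0; infeasible
deletion LPs score 1. Measured constraints enter these FBA problems as
`[mu - sigma, mu + sigma]` intervals intersected with the model bounds,
except the growth-rate measurement itself, which is removed: with growth
pinned, maximizing it is vacuous and every deletion is either neutral or
infeasible, so no graded essentiality could arise.

## The synthetic fixture

`make_toy_model` emulates the statistical structure the pipeline assumes: a
substrate uptake split across parallel stoichiometrically coupled chains
converging on biomass. Measured constraints (branch splits, class `C13`;
uptake, class `FMT`) are jointly achievable by construction — the last chain
is unmeasured and absorbs the balance — so the LAD residual is exactly 0 and
every sampled flux stays within one sigma of its mean. Within a module,
fluxes are exactly proportional (correlation 1): one ×2 stoichiometric
amplification per chain keeps members pattern-identical without being exact
duplicates, while one unit-coupled pair per chain is an exact duplicate and
exercises the collapse/reinsert path. Transport and biomass come as
proportional pairs so no true cluster is a singleton. The perturbed
condition knocks out the first chain's entry reaction and shifts the
measured means (uptake drops ~7%, surviving measured branches rise 30%),
rerouting flux into the unmeasured chain.

What the fixture does **not** emulate: genome-scale topology (cofactor
coupling, loops, alternate optima), residual-bearing inconsistent
measurements, reversible-flux sign changes, and modules with merely high
(not perfect) internal correlation. Passing tests therefore demonstrate the
pipeline's mechanics and its exact behaviour under clean conditions, not
recovery rates on noisy genome-scale data. Default test scale is 3 modules ×
4 reactions, 100–200 samples per condition and 20 permutations; the package
defaults (1000 samples, 300 permutations) are the method's reference
operating point and are used when running on genome-scale inputs.

## Numerical choices and degenerate inputs

- LPs: scipy `linprog(method="highs")`; infeasibility raises a typed error
  naming the constrained reactions.
- Zero tolerance 1e-6 (absolute) everywhere; duplicate tolerance 1e-9
  max-norm; LAD-vs-oracle agreement asserted at 1e-8.
- Single-row clustering input yields one singleton cluster, not an error;
  empty core sets raise (the pipeline cannot proceed).
- Equal-frequency bins are relabelled to consecutive integers over occupied
  bins; cardinalities used by MDL are the occupied-bin counts.
- Manifest determinism: the run manifest excludes the output directory and
  timestamps, records all other parameters plus SHA-256 digests of every
  artifact, and is byte-identical across same-seed runs.

## Known limitations

- Pairing the t-test by sample index is exchangeable but arbitrary; any
  index pairing of independently drawn columns is equally valid.
- The inconsistency-coefficient cut inherits the singleton instability noted
  above; on real data isolated reactions may attach to a neighbouring module.
- Score-equivalent DAGs (same skeleton, covered edges) are not
  distinguished; learned arc directions within an equivalence class are not
  causal claims on their own.
- Essentiality uses reaction-level deletions; gene-level (GPR-mediated)
  deletions, double knockouts and MOMA/ROOM-style deletion models are out of
  scope, as are flux-variability analysis and uniform polytope sampling.
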