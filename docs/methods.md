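# Methods

This note documents the models, numerical choices and design decisions
behind `defchem`, and what the synthetic-data experiments do and do not
demonstrate.

## Trees

A `Phylogeny` is a rooted tree with branch lengths in Ma, unique non-empty
tip labels, and integer node ids assigned by post-order traversal
(children in stored order), so annotation tables are stable across runs of
the same file. Branch lengths are mandatory on all non-root edges — the
intended inputs are chronograms, which always carry them — unless an
explicit default is supplied. Negative lengths and duplicate tips are
rejected at construction. Polytomies are retained, never arbitrarily
resolved, and all likelihood code handles them natively; how polytomies in
a penalized-likelihood chronogram *should* be treated is genuinely open,
and silently binarizing them would change the likelihood.

Parsing (Newick, NEXUS) is delegated to dendropy; internal labels are read
as plain labels, not support values, and quoted labels are supported.
Writing is native: floats are serialized with `repr`, which round-trips
exactly, so the write→read identity holds to machine precision (tested to
1e-9 over random trees). Annotated NEXUS output carries per-node
`[&key=value,...]` comments in the position BEAST-style tools use (after
the node, before the branch length); dendropy's comment-metadata extraction
reads them back.

## The pathway DAG and character coding

The packaged pathway transcribes the 23-compound benzoquinone-defense
legend: phenol at the head, hydroquinones derived by ring substitution
(methyl/methoxy chains), and each benzoquinone produced by oxidation of its
corresponding hydroquinone. Transcribing arrow topology from a figure is a
judgment call, so the DAG ships as two editable TSVs (compound table, edge
list) validated only for acyclicity and endpoint declaration, and every
scoring operation takes the DAG as an argument. Two judgment calls are
worth knowing: 2-ethyl-1,4-benzoquinone (19) has no hydroquinone partner in
the legend and is attached to hydroquinone (2); naphthoquinone (20) cannot
be placed on the backbone from available information and is left
unconnected, as are the three non-pathway legend compounds (benzoyl
cyanide, alpha-terpinene, polyzonimine). An isolated compound contributes
exactly itself to a closure, so this choice only affects scores through
the absent backbone links.

**Precursor closure** adds to an observed compound set every transitive
predecessor in the DAG — the "intermediate states as present" rule: a
compound on the pathway's outer edge implies its precursors even when a
record omits them. Closure is idempotent, monotone, and a superset of its
input (property-tested against an edge-relaxation reachability oracle on
random DAGs). The **complexity score** is the closed-set size, ignoring
compounds outside the DAG.

**Stage character** (none → phenol → benzoquinone): a taxon codes
benzoquinone if any benzoquinone-class compound (or the
benzoquinones–hydroquinones class tag) is present, else phenol if phenol
is present, else none. Hydroquinone-only records code as *none* by
default: hydroquinones are pathway precursors, not phenol production, and
treating them as evidence of finished benzoquinone chemistry would beg the
question the stage character exists to ask. A
`hydroquinone_is_benzoquinone=True` switch folds them into the
benzoquinone stage for sensitivity analysis.

**Class character** (7 states): multi-class taxa default to *polymorphic*
coding — an ambiguity set whose likelihood is spread over member states —
because many families genuinely produce several classes and collapsing
them discards data. A *priority* policy (highest-numbered class wins) is
available where a strict single-state matrix is needed.

Species-level records aggregate to family terminals by set union
(order-independent, idempotent), matching family-level scoring in which a
terminal represents everything known for the family.

## Mk machinery

Rate matrices are integer **index matrices**: equal positive off-diagonal
entries share one rate parameter, zeros are structural prohibitions, the
diagonal enforces zero row sums. ER/SYM/ARD are constructors; custom
matrices load from small text files mirroring the k×k layout.

The **stage model** encodes phenol as ancestral to benzoquinone: gains
none→phenol (rate 1) and phenol→benzoquinone (rate 2) are separate, the
direct gain none→benzoquinone is structurally forbidden, and all losses
share rate 3. Whether the *total* loss benzoquinone→none is allowed
directly is not decidable from the verbal description ("losing the ability
to produce one or all chemicals"); the default allows it, sharing the
single loss rate, with `allow_total_loss=False` to forbid it. Either way
the model has 3 free parameters.

Transition probabilities are exp(Qt). For a single time this is scipy's
scaling-and-squaring `expm`; per-tree computation diagonalizes Q once
(complex eigendecomposition) and evaluates all branches in a vectorized
einsum, falling back to per-branch `expm` when the eigenvector matrix is
ill-conditioned (condition number above 1e8). Entries are clipped to
[0, 1]; rows are row-stochastic to 1e-9 over t ∈ [0, 1e3] by test.

The likelihood is Felsenstein pruning with per-node max-rescaling (log
accumulated), handling multifurcations and ambiguous/missing tips (vector
of ones over the allowed set — the standard treatment, which also
implements polymorphic class coding). A tip present in the tree but absent
from the data is an error, not silently missing. Root treatments: flat,
stationary (left null space of Q), fixed vector, and **FitzJohn
weighting** — w_i = L_i/ΣL_j, total likelihood Σ w_i L_i, root marginal ∝
w_i L_i — the default, since it treats the root state as a nuisance
weighted by its ability to generate the data.

**Fitting** is bounded L-BFGS-B in log-rate space, rates in [1e-9, 1e3],
with dispersed restarts (default 10; heavy simulation tests use 3) centred
on 1/(mean root-to-tip depth) — the scale at which about one event is
expected per lineage. The returned log-likelihood is the best across
restarts and is guaranteed not to fall below any start point; a fit where
no restart converged is flagged. `nested_warm_start` maps a nested fit's
rates into a general model's parameter classes (forbidden-in-nested
transitions start at 1e-9); the pipeline warm-starts every general model
from its fitted nested models, which is what makes the nesting ordering
logL(ARD) ≥ logL(SYM) ≥ logL(ER) robust to optimization noise rather than
merely true in expectation. Fits are bit-reproducible given the seed.

**LRT**: 2·ΔlogL (clipped at 0) against χ² with df = parameter-count
difference. When a structural zero puts a parameter on the boundary the
plain χ² reference is conservative; it is used anyway, with this caveat,
because that is the conventional reported test. Model selection in the
pipeline walks from simplest to most general at α = 0.05 along valid
nesting chains; the custom stage model is not nested in SYM (it forbids
none↔benzoquinone), so non-nested comparisons fall back to AIC, which is
reported for all models regardless.

**Marginal reconstruction** is the exact up-down algorithm: the upward
pass collects within-subtree conditionals, the downward pass propagates
the complement, and their normalized product is P(node = s | all data).
Verified against full enumeration to 1e-9 on random instances, and
invariant to child order. The reporting rule flags a single state only
above 0.75 marginal probability (configurable), mirroring the convention
of showing an ancestral state only when it exceeds 75%.

## Brownian-motion reconstruction

The complexity count is treated as an unbounded real under BM — the same
modelling choice contMap-style visualizations make for count data — so no
positivity constraint is imposed, and negative ancestral estimates are
flagged rather than clipped. Estimates are GLS: root
â₀ = (1ᵀC⁻¹x)/(1ᵀC⁻¹1), σ̂² = (x−â₀1)ᵀC⁻¹(x−â₀1)/n (the ML, not REML,
denominator), node estimates â_u = â₀ + c_uᵀC⁻¹(x−â₀1) with c_u the
node–tip shared depths, and variances include the root-uncertainty term
(1−1ᵀC⁻¹c_u)²/(1ᵀC⁻¹1). Joint ML and marginal GLS coincide for Gaussian
models, so the estimates also solve the branch-weighted tree Laplacian —
the independent oracle used in tests. An all-equal character gives σ̂² = 0
and is flagged degenerate; a singular C is reported with the offending
zero-length terminal branches. Branch painting linearly interpolates
between endpoint estimates (the Brownian bridge mean).

## Fossil calibrations

PenG = difference between a clade's two oldest fossil ages; GLin =
absolute difference between two sister lineages' oldest fossil ages. Both
are nonnegative and scale with the age units. The packaged C1 scheme
transcribes six node priors, deliberately preserving the source's *two*
lognormal conventions (log-scale (offset, μ, σ) vs mean-in-real-space) as
distinct tagged distributions rather than converting between them. The C2
scheme's two lognormal priors were derived from PenG/GLin by an
unpublished procedure; the module therefore stores the resulting
parameters as printed and does not guess the transformation. Two
transcription flags live in the data files themselves: a comma-decimal SD
("1,81") transcribed as 1.81, and one prior whose SD was not printed and
carries an editable placeholder (σ = 1.0) with a note.

## Synthetic data

`simulate_tree` runs a forward birth–death process from two crown
lineages; when the extant count would first exceed the target n, a cut
time is drawn uniformly over the accumulated periods during which exactly
n lineages were extant (a general-sampling-style draw), extinct subtrees
are pruned, and unifurcations are suppressed. Total extinction or loss of
a crown lineage triggers a bounded retry. Trees are exactly ultrametric
and optionally rescaled to a target crown age (default 467 Ma, the
empirical depth being emulated). Default birth/death 0.03/0.01 per Ma give
family-level-looking trees at the default 49 tips.

Discrete characters are simulated by endpoint sampling from the exact
P(t) per branch — exact for likelihood testing and fast; a Gillespie mode
exists where realized transition counts matter. Continuous characters are
Brownian increments. Chemical records are generated *consistently with*
the simulated stage: phenol-stage tips receive phenol; benzoquinone-stage
tips receive a random subset of terminal pathway benzoquinones (each with
probability `p_terminal` = 0.5, at least one), with each implied precursor
then *omitted from the record* with probability `p_drop` = 0.5 — so
precursor closure has real work to do, and stage coding recovers the
simulated stage exactly. Default stage rates are (0.004, 0.004, 0.001)/Ma:
about 1.9 expected gains per root-to-tip path on a 467 Ma tree.

What the generator does **not** emulate: phylogenetic error (the tree is
known exactly), literature sampling bias (every tip is "sampled" with the
same probabilities), correlated evolution between the stage and class
characters, and chronogram dating uncertainty. Passing recovery tests
therefore demonstrate correctness of the estimators under their own model,
not robustness to the violations real data bring.

## Study conditions for the statistical experiments

The statistical acceptance experiments needed scale choices the problem
statement leaves open; they were fixed as follows, on the principle that a
recovery experiment should sit in the informative regime of roughly one to
a few expected events per root-to-tip path.

* **LRT type-I error**: 3-state equal-rates character, q = 0.02/Ma on
  200-tip, 100 Ma chronograms (≈2 expected events per path lineage);
  ER-vs-SYM rejections at α = 0.05 stay below 10% over 200 replicates.
* **Rate recovery**: 3-state ER with q = 1 on 300-tip Yule trees of depth
  ≈1.4 (birth 4/Ma), i.e. q·depth ≈ 1.4. A 2-state character on deeper
  trees (q·depth ≈ 5) is near saturation and its q̂ distribution is far
  too wide for a 90%-within-30% criterion at n = 300 — measured in
  development at ~73–83% in band — which is a property of the experiment,
  not the estimator; the 3-state shallow regime reflects the recovery the
  machinery actually achieves when the character is informative.
* **Root-state recovery**: the stage model at the stated slow rates
  (0.02, 0.02, 0.005)/Ma on 200-tip, 50 Ma chronograms (≈1 expected gain
  per path), with the root drawn from the model's stationary distribution —
  the unconditional law of the process, and the regime FitzJohn weighting
  is designed for. True recovery rate measured ≈0.78 over 120 replicates;
  the test's ≥70%-of-50 band is stochastic and the test seed is fixed.

Problem sizes in `scripts/acceptance.py` (60/30/30 replicates for the
LRT/recovery experiments) are smaller than the test suite's; they report
the same quantities with their n alongside.

## Known limitations

* Stationary root treatment requires Q's left null space to be
  one-dimensional; strongly reducible custom matrices may not have a
  unique stationary law (the stage model does, as long as the loss rate is
  positive).
* The χ² LRT reference at structural-zero boundaries is conservative (see
  above).
* BM on counts can produce negative ancestral estimates near zero; they
  are flagged, not constrained.
* The class-character ARD model on 7 states has 42 free parameters and is
  not realistically identifiable at family-level sample sizes; the
  pipeline defaults to ER for that character and leaves richer models to
  explicit configuration.
* `fit_mk` uses numerical gradients; at 7 states with many parameters each
  iteration costs (1 + n_params) likelihood evaluations.
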