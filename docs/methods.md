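# Methods

This note documents the models, estimators and numerical choices
behind each component, the design decisions that were genuinely open,
and what the synthetic-data generators do and do not emulate.

## Trees and tree samples

The core containers are a rooted tree with finite non-negative branch
lengths on every non-root edge, and a chronogram (ultrametric tree
with node ages, tips at age 0).  Branch lengths absent from the input
are an error, not silently zero: all downstream arithmetic needs them.
Polytomies parse but are rejected by every likelihood operation, which
assumes fully bifurcating trees.  Zero-length terminal branches are
accepted (they arise in posterior samples); zero-length *internal*
branches are rejected only where they break an estimator (NPRS).

Ultrametricity is checked as (max − min) root-to-tip path length
within a relative tolerance of the mean path, default `1e-6`,
overridable.  Newick/NEXUS parsing (translate blocks, quoted labels,
bracket comments) is delegated to dendropy; the writer emits plain
Newick at 10 significant digits by default and 17 for round-trip
fidelity.

## Posterior utilities

* **Burn-in** removes the first `ceil(fraction · n)` trees; the
  ceiling convention is a documented choice (samplers report only the
  percentage).
* **MCC tree**: the *member* of the sample maximising the sum of log
  clade frequencies over its internal clades; ties break to the
  earliest index.  No consensus tree is built and node heights are the
  winning tree's own (re-annotation with mean or median heights across
  the sample is a known alternative, deliberately not done so that the
  returned object is an actually-sampled tree).
* **ESS** uses `n / (1 + 2 Σ ρ̂_k)` with empirical autocorrelations
  truncated at the first non-positive term (the simple
  initial-positive rule).  No cap is applied, so an anticorrelated
  trace can legitimately exceed `n`.
* **HPD**: the shortest window of `ceil(mass · n)` consecutive order
  statistics; equal-width ties resolve to the lower window.

## Binary-trait (Mk) machinery

The trait evolves by a 2-state continuous-time Markov chain with rates
`q01, q10` per unit branch time (the branch units are the chronogram's
relative time, so rates are events per relative-time unit).  The
transition kernel is the binary closed form
`P01(t) = (q01/s)(1 − e^{−st})`, `s = q01 + q10`.  The likelihood is
Felsenstein pruning with per-node rescaling; marginal ancestral states
come from a standard inside/outside pass and sum to one at every node.

*Root prior.*  Uniform `(½, ½)` by default, with the stationary prior
available by flag; the choice is recorded in outputs because the two
can disagree noticeably on small trees.

*Fitting.*  Rates are optimised on a log scale in `[1e-8, 1e3]`: a
23-point grid plus five bounded local searches for ER, and
multi-start Nelder–Mead (seeded with the ER optimum, which guarantees
the nesting inequality `lnL_ARD ≥ lnL_ER`) for ARD.  The likelihood
surface flattens for near-constant traits, hence the multi-start; a
constant trait triggers a boundary warning and a rate at the lower
bound.

*Batch path.*  Simulation studies evaluate thousands of trait
replicates on one fixed tree, so the pruning core is also vectorised
across replicates.  Batch fitting uses per-replicate golden-section
search (ER) followed by coordinate descent plus a damped Newton polish
(ARD); the Newton step matters because coordinate descent alone crawls
along the correlated `(q01, q10)` ridge.  The batch and scalar fits
are cross-checked against each other in the test suite.

*Model comparison.*  Both the likelihood-ratio test
(`D = 2 ΔlnL` against χ² with 1 df) and AIC are reported; the choice
between them is left to the user.

## DEC and DIVA

Range states are all non-empty subsets of the area set up to an
optional maximum size, plus an absorbing empty state.  Anagenetic
rates: range `r` gains area `a` at `d · Σ_{b∈r} m(b,a)` (multiplier
matrix `m` defaults to all ones) and loses any resident area at `e`.
At nodes, the classic cladogenetic scenarios (identical inheritance
for single-area ranges; subset sympatry and one-area-versus-rest
vicariance otherwise) each receive equal probability — weighting
variants exist, and the equal-probability convention is stated
because results depend on it.  The root prior is flat over non-empty
states; conditioning on survival is out of scope.

Branch propagators `e^{Qt}` are computed by eigendecomposition reused
across branches (with a `scipy.linalg.expm` fallback if the
eigenbasis is ill-conditioned); rows of the propagator are verified to
sum to 1 within `1e-10`.  Marginal ancestral ranges use an
inside/outside pass whose outside messages fold in the cladogenetic
sum; both the likelihood and the marginals are tested against full
history enumeration on small instances.

DIVA is implemented as Sankoff dynamic programming over the same range
states with event costs: dispersal and extinction 1 per area,
vicariance (any bipartition of a multi-area range) and duplication 0.
All minimum-cost range assignments per node are recovered with a
min-plus outside pass.  The "Bayesian" flavour of DIVA is approximated
by applying the parsimony over a random draw of posterior trees and
tabulating per-clade range frequencies — a sample-and-summarise
design, not a reimplementation of any particular program's internals.
Clades below a configurable 5% presence threshold are suppressed in
reports; DEC summaries refit `d, e` per tree unless fixed rates are
supplied.

## Geminate asynchrony

For each named pair the tMRCA is read off every posterior tree in
order.  The older-than fraction counts ties as ½ (measure-zero for
continuous ages; this makes the fraction antisymmetric), and the ln
Bayes factor uses the exact fraction, never a rounded percentage, with
prior odds 1 — a priori either node is equally likely to be older.  At
`p ∈ {0, 1}` the lnBF is reported as a signed boundary together with
the largest resolvable value for the sample size, `ln((n − ½)/½)`.
The pairing is the point of the method: node ages are strongly
correlated within a tree, so the paired fraction can be decisive even
when the marginal HPD intervals overlap.  Age vectors are never
sorted.

## Corrected distances and saturation

Distances are ML branch lengths between two sequences under a
GTR-family model, with site rates from a proportion of invariant
sites plus a discrete gamma (4 categories, median rule, renormalised
to mean rate 1 so distances are expected substitutions per site).
Named constrained families (TIM, TPM, ...) are expressed as GTR with
the corresponding exchangeabilities rather than as named submodels.
Plain JC69 uses the closed form `d = −¾ ln(1 − 4p/3)`; everything else
minimises the pattern-count negative log-likelihood in `t` by bounded
search plus a Newton polish on the score, which brings the generic
path within `1e-12` of the closed form where both exist.  Pattern
counts are symmetrised (valid under time reversibility) so
`d(a,b) == d(b,a)` exactly.  If the observed p-distance reaches the
model's asymptotic bound `(1 − I)(1 − Σ π²)` the pair is reported as
saturated rather than given a divergent estimate.  Ambiguity codes
other than N are treated as N; columns with a gap or N in either
sequence are skipped pairwise.

Partitioned ("combined") distances share a single `t` across
partitions, each under its own model — the natural definition when
loci are assumed to share one divergence time.

The saturation diagnostic is deliberately transparent rather than
entropy-based: per codon-position class, the ratio of mean p-distance
to mean corrected distance.  Multiple hits flatten p while the
corrected distance keeps growing, so the ratio decays from 1 towards 0
as a class saturates; a class is flagged when the mean per-pair ratio
within the most divergent quartile of pairs falls below a threshold
(default 0.5).  This reproduces the qualitative expectation — fast
third positions lose signal first, and only at deep divergences — but
is not numerically comparable to entropy-index statistics.

## NPRS

Node ages minimise `Σ (r_parent − r_child)²` over all
parent-branch/child-branch pairs at internal non-root nodes (the root
has no parent branch and contributes no terms), with `r = branch
length / duration`.  Ages are parameterised as logistic fractions of
the parent age, which enforces the ordering constraint without
explicit bounds; optimisation is L-BFGS-B from three starts
(node-depth heuristic, equal splits, seeded random).  Internally the
rates are scaled by the mean branch length for conditioning and the
reported objective is unscaled.  The output timescale is relative
(root age fixed, default 1); no calibrations and no penalised-
likelihood smoothing parameter.  Exactly clock-like input yields
objective 0 and ages proportional to depths.

## Synthetic data

Generators are pure functions of their arguments; a configuration
bundle derives named RNG substreams from one root seed so adding a
generator never perturbs another's draws.

* **Yule trees** grow from two lineages with Exponential(kλ) waits; on
  reaching `n` tips one further Exponential(nλ) stretch separates the
  youngest node from the present (otherwise that node would sit at age
  exactly 0).  Mean root age is therefore `Σ_{k=2}^{n−1} 1/(kλ) +
  1/(nλ)`, which the tests assert.
* **Mk traits** evolve root-to-tip with the closed-form kernel.
* **DEC ranges** evolve by Gillespie simulation of the anagenetic
  chain with uniform cladogenetic inheritance; each branch is
  conditioned on survival (redrawn if the lineage hits the empty
  range, with a cap), which slightly biases histories away from
  extinction-heavy paths — acceptable for recovery studies, and stated
  here because it is a conditioning, not the unconditional process.
* **Alignments** draw a root sequence from the stationary
  frequencies, per-site rates once from the I+Γ mixture (shared across
  the tree), and evolve by the model propagators.
* **Emulated posteriors** multiply node ages by correlated lognormal
  noise: one tree-level and one per-node factor, each with log-scale
  variance `sd²/2`, mimicking the within-tree age correlation of real
  posteriors.  Order-violating draws are resampled per tree, so at
  large jitter relative to inter-node gaps the realised distribution
  is truncated.  Optional age-respecting NNI swaps supply topological
  variation.  The emulation does *not* reproduce sampler
  autocorrelation, model-driven age covariance structure, or
  topology-age interactions; passing tests demonstrate correctness of
  the estimators under these controlled conditions, not robustness to
  every pathology of real MCMC output.

## Problem sizes and tolerances in the checks

The acceptance checks use 1000 random 4–8-tip instances for the Mk
enumeration oracle (tolerance `1e-10`), 2–3-tip/2–3-area instances for
the DEC oracle (`1e-8`, limited by the series-expansion reference),
100 data sets on a 300-tip tree for ER rate recovery (median within
15%), 2000 replicates for the LRT type-I calibration (expected in
[0.03, 0.07] at α = 0.05), 50 data sets on 200-tip trees for DEC
dispersal recovery (median within 25% — extinction is only weakly
identified from extant ranges and is not asserted), 100 kb pairs for
GTR+Γ distance recovery (2%), and 10,000-tree emulated posteriors for
the asynchrony closed form (±0.03 around Φ(1/√2)).  These sizes keep
each property in its asymptotic regime while the whole suite runs in
minutes.

## Known limitations

* DEC omits founder-event speciation and time-stratified dispersal.
* Extinction rates from extant-only range data are weakly identified;
  only dispersal recovery is asserted.
* Pairwise distances ignore shared tree structure (no tree-path
  distances); the two estimators differ at deep divergences.
* The trait machinery is strictly binary; no correlated characters or
  stochastic mapping.
* NPRS provides no confidence measure on ages; it is a transformation,
  not an inference with uncertainty.
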