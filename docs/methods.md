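# Methods

This note records the models implemented, the conventions and numerical
choices behind them, what the synthetic data do and do not emulate, and the
known limitations.

## Trees

All trees are rooted `dendropy` trees; Newick and NEXUS (with TRANSLATE
tables) I/O goes through dendropy with strict validation on top: unique tip
labels, nonnegative branch lengths, balanced parentheses, a terminal
semicolon.  Missing branch lengths default to 1.0 with a logged warning
(root edges silently to 0).  Branch-length units are contextual —
substitutions/site, thousands of years (ky), or coalescent units — and no
conversion is ever implicit.

Polytomies are resolved randomly from a mandatory seed, inserting
zero-length edges so tip depths and total tree length are unchanged and
likelihoods of continuous-time models are unaffected.

`scale_to_age` linearly rescales an ultrametric tree (tolerance 1e-6
relative) so all tip depths equal the requested root age.  Non-ultrametric
trees are rejected unless the caller opts into per-path stretching, which
moves a node at depth d with residual height h to depth `age·d/(d+h)`.
That preserves node order along every path but is *not* a dating method —
analyses that need a time tree should supply one.  The reference root age
of 220 ky is taken directly as configuration; it is never derived from a
substitution rate.

## Divergence models and the DC test

Population-divergence hypotheses are rooted trees over region labels with
divergence depths in coalescent units (1 unit = 2Nₑ generations).  Six
presets cover the classic refugium scenarios; the REFUGIA model is a hard
5-way polytomy (simultaneous fragmentation) and is scored as such — no
arbitrary resolution.  The JAPAN/CAS chains mirror the SRM chain rooted at
JAP/CAS, with the I/II variants swapping the two terminal-most splits;
because the original scenarios were published only as figures, the presets
are labelled best-effort defaults and any explicit Newick over the regions
overrides them.  Default depths (5, 4, 3, 2 units) put every divergence in
the strong-sorting regime; the test procedure deliberately avoids absolute
Nₑ or time estimates, so depths are free configuration.

The multispecies-coalescent simulator draws exponential waiting times at
rate k(k−1)/2 per coalescent unit within each population branch (optionally
scaled by a per-branch width), merges surviving lineages into parent
populations at divergence depths, and extends the root population to
infinity.  No migration, recombination, or serial sampling.  An
integer/bitmask core records only merge order, times, and population
masks; the deep-coalescence cost of a simulated genealogy is computed
directly from the (child-mask, parent-mask) pairs of its edges, so a
10,000-replicate null costs about a second at the 46-tip reference design.

Deep coalescence follows the LCA-mapping convention: each gene node maps to
the most recent population-tree node containing its descendant populations;
each non-root population branch contributes (lineages exiting rootward − 1);
branch lengths are ignored.  The test simulates gene trees *within* each
candidate model and scores them against that same model — the standard
workflow for this class of test — with a lower-tail, add-one-corrected
p-value, `p = (1 + #{null ≤ observed}) / (1 + n)`, ties counting toward the
tail (conservative).  A model is supported at p < α (default 0.05).

Calibration: DC is integer-valued, so its p-values are discrete.  A
Kolmogorov–Smirnov comparison of the p-values against Uniform(0,1)
converges, as the null sample grows, to the largest point mass of the null
DC distribution; approximate uniformity therefore requires conditions under
which DC takes many values.  The calibration check uses shallow divergences
(0.2–0.05 units) at the 46-tip design, where the null DC has a standard
deviation near 5 and a maximal point mass near 0.07 — below the KS
rejection threshold for 200 repetitions.  At deep divergences the DC null
concentrates near zero and the test's support calls are vacuous; users
should pick model depths shallow enough that the null has spread.

## Stratified DEC

The range state space is the null range plus all subsets of the area list
up to `max_range_size` (default 2, giving 16 states over 5 areas), in
size-then-index order.  The anagenetic generator has gains
`rate(R→R∪{a}) = Σ_{b∈R} d·D[b,a]` and losses `rate(R→R∖{a}) = e`, the null
range absorbing.  Strata tile the model span down to the present, each with
its own dispersal-constraint matrix; per-branch transition matrices are
products of per-segment `expm(QΔt)` factors in rootward→tipward order, with
the per-stratum Q and full-stratum segment exponentials cached.
Likelihood pruning rescales partials per node (log-scale bookkeeping) so
100-tip trees at high rates do not underflow.

Cladogenesis uses the classic DEC scenario set, equiprobable over ordered
daughter pairs: singletons inherit sympatrically; widespread ranges split
by single-area vicariance (a | R∖a) or subset sympatry (a | R), both
orders; widespread sympatry (R, R) is excluded.  A consequence worth
knowing: discordant singleton tips are reachable with d = e = 0 through
vicariance from a widespread root (a 2-tip {A}/{B} tree has likelihood 1/6
per widespread root state), so a zero-dispersal model is not automatically
impossible for allopatric data.

The root likelihood is the unweighted sum of root conditional likelihoods
over allowed nonempty ranges; per-root-range entries in the fit table are
the constrained `−ln L_R`, which therefore can never beat the global value,
and a single dominant root range makes the two equal.  Model comparison
flags fits within two log-likelihood units of the best.

ML fitting optimises (log d, log e) with L-BFGS-B under bounds (default
1e-9 to 100 per time unit) from a seeded multistart anchored near one
expected event per lineage per model span — starting rates too close to
the lower bound strand the optimiser on the flat impossible-data plateau.

Forward simulation draws the root range uniformly from allowed nonempty
states (or a fixed root), samples cladogenesis at nodes, and runs a
Gillespie walk along branches honouring stratum boundaries.  A lineage
absorbed into the null range is extinct; its branch walk is resimulated
(per-branch retry, count logged), which conditions every branch on
survival.  The matching estimator option `condition_on_survival=True`
renormalises each branch transition kernel on non-extinction,
`P'[i,j] = P[i,j]/(1 − P[i,0])`; with it the likelihood is exactly the
simulator's sampling distribution (verified by 2-tip enumeration).  Without
it, fitting simulated data systematically drives e to the boundary, because
lowering e also raises the survival probability the unconditional model
silently includes.

Extinction is weakly identified in DEC even so: every cladogenetic event
produces a singleton daughter, so singleton-rich tip data are explained
almost as well by cladogenesis plus dispersal alone.  Parameter-recovery
checks therefore use a design where e leaves a recoverable signature —
five areas with no range-size cap, tree depth 6, d = 0.4, e = 0.25 per
lineage per time unit — under which 20 seeded 100-tip replicates give
median relative errors near 9% (d) and 28% (e).  With `max_range_size=2`
(the reference analysis setting) e should be interpreted qualitatively.

The five preset glacial-cycle models stratify 240 ky as interglacials
(240–190, 130–90, 10–0 ky) and glacials (190–130, 90–10 ky; dispersal
matrix zero).  Interglacial matrices follow the adjacency chain
NAI–NAC–BER–CAS–JAP with per-scenario directionality (SRM westward from
NAI; BER outward from Beringia; JAP/CAS eastward chains; REF blocks all
dispersal before the Holocene and then allows both directions).  The exact
matrices of the original figure-only models are not recoverable, so these
are defaults and fully user-overridable through the JSON model config.
Rates are reported in the tree's time units (per ky for the 220-ky
reference design).

## Ancestral-state reconstruction

Characters are binary, with missing data marginalised.  The CTMC is
symmetric by default (stationary bias fixed at 0.5; an optional bias value
can be supplied), with overall rate r: transition probability
`P(same) = π_same + π_other·e^{−rt}`.

The per-character rate prior is gamma(shape α, scale β), moment-matched to
an MCMC sample of the rate posterior: Metropolis on log-rate, flat rate
prior on (0, rate_max), likelihood averaged over the posterior tree sample.
`rate_max` defaults to 10 per unit tree depth: beyond that a binary
character is fully randomised (transition probabilities within 5e-5 of
1/2), so the data cannot order larger rates and an unbounded flat prior
would let the posterior mean drift into the saturated plateau.  The MCMC
was checked against direct numeric integration of the posterior mean.
Single binary characters carry limited rate information: fitted prior
means scatter around the truth with ~30–50% relative spread at 46 tips.

The reconstruction computes the exact marginal posterior of the state at
the clade MRCA by a down-pass (conditional likelihoods) and an up-pass
(outside likelihoods), for every tree in the sample and `n_draws` rates
drawn from the prior, then averages.  Trees in which the clade is not
monophyletic contribute the state at the MRCA of the tip set (which then
subtends extra tips); their count is reported.  Significance is a posterior
above 0.95 (0.90 used as a secondary shading threshold in reports).  The
sensitivity scan scales the prior *mean* by 0.1× and 10× through β (α
fixed) and flags whether any significance call changes.  Full
stochastic-mapping realisations are not sampled: only node-state marginals
are consumed downstream, and the pruning marginal is exact for that
purpose.

## Synthetic data

The generator emulates the reference study design: 46 tips over five
regions (NAI 15, NAC 6, BER 11, CAS 11, JAP 3); an observed gene tree
simulated under a chosen divergence model (default SRM) and scaled to a
220-ky root age; tip ranges forward-simulated under a stratified
glacial-cycle DEC model from an NAI root with d = 0.02 and e = 0.005 per
ky (order-of-magnitude choices that leave visible but unsaturated dispersal
signal across the 80 ky of interglacial time in the tree); sixteen binary
characters named for the leaf/stem/sepal/petal traits of the cushion-
saxifrage literature, evolved at rates drawn from gamma priors of the
magnitudes reported for such characters; and a posterior-like tree sample
built by coalescent re-simulation, scaled to unit depth.

What the bundle does *not* emulate: the tree sample is coalescent
re-simulation, not MCMC output, so its topological spread is wider than a
real posterior and inflates apparent character rates; ranges and gene-tree
geography are simulated independently, so a tip's sampled region need not
appear in its simulated range; and no sequence-level data exist anywhere.
Passing tests on the bundle demonstrate the estimators' internal
correctness and calibration, not performance on real posteriors.

All randomness fans out from one master seed through named sub-seeds
recorded in the manifest, together with true parameters and file hashes;
regeneration from the same seed is byte-identical.

## Numerical conventions

- Branch-transition row sums are within 1e-10 of 1; generator rows sum to
  0 within 1e-12.
- Pruning likelihoods agree with full enumeration within 1e-8 relative
  (DEC) and 1e-10 absolute (binary ASR marginals) on enumerable instances.
- Impossible data return +inf negative log-likelihood; the optimiser sees
  a large finite plateau value (1e10).
- The DEC rate upper bound (100) matches the convention of reporting
  boundary fits at that value; hitting it signals a degenerate fit, not a
  biological estimate.
- Ages within a 1e-9 relative tolerance of the model span are clamped to
  the span to absorb floating-point drift in deep trees.

## Limitations

- DC depths and Nₑ are unitless configuration; reproducing any specific
  published DC null requires the original simulation settings, which are
  typically unreported.  The package reports its own nulls alongside the
  observed values instead.
- DEC extinction is weakly identified at `max_range_size=2`; the +J
  founder-event extension, fossil constraints, and multi-tree DEC are out
  of scope.
- ASR covers binary characters only; correlated evolution and
  stochastic-map dwelling times are out of scope.
- Per-path stretching of non-ultrametric trees is a convenience, not a
  dating method; published time-calibrated analyses should be reproduced
  with their original chronograms.
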