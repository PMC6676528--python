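# Methods

## The model

A genome's gene population evolves through a small number of
whole-genome multiplications (doublings, WGD; triplings, WGT) separated
by intervals of *fractionation*, the progressive loss of the duplicate
copies. `wgdfrac` models this as a discrete-generation branching
process. Event `i` of ploidy `r_i` replaces every gene by `r_i` copies;
the number of copies that survive to the next event is drawn,
independently per gene, from a survival distribution
`u^(i) = (u_0, ..., u_{r_i})`. The distribution is a per-interval
survival law, not a literal offspring law: a WGD is instantaneous on
evolutionary time scales, and everything that happens between two events
is summarized by `u^(i)`. Generations are therefore synchronous and the
model is deliberately not a continuous-time birth-death process.

Event *times* (My before present) are not part of the branching process;
they are attached to events as metadata and only enter when rates are
computed or similarities synthesized.

Two observed genes form an *i-pair* when their most recent common
ancestor was replaced at generation `i`; within one genome these are
paralogs, across two genomes orthologs. An observed gene with no
surviving partner is *unpaired*.

## Closed-form expectations

All expectations are products of per-event moments (linearity of
expectation plus independence of sibling subtrees), never multinomial
enumerations:

* survivor mean per gene: `mu_i = sum k u_k^(i)`;
* surviving sibling pairs per gene: `pf_i = sum_{k>=2} C(k,2) u_k^(i)`;
* population size: `E(M_n) = M1 * prod mu_i`;
* i-pairs: `E(N_i) = M1 * prod_{j<i} mu_j * pf_i * prod_{j>i} mu_j^2`
  (the square because the two sides of a pair fractionate
  independently);
* unpaired genes: `E(M*) = M1 * prod u_1^(i)`.

For all-doubling schedules with `u_0 = 0` the pair formula reduces to
the familiar `prod(1+u_2)`-form; with constant `u_2 = u` across `n`
doublings it collapses to `E(N_i) = u (1+u)^(2n-i-1)`. Note the
convention: `n` here counts *doubling events*. Reading it as the
observation-generation index would contradict the general product form
(check one doubling, `i = 1`: the expected pair count is plainly `u`),
so the event-count convention is the one implemented and tested.

The exhaustive enumeration over survivor-count histories (the
multinomial law implemented in `history_probability` /
`enumerate_histories`) is retained purely as a test oracle; a second,
stronger oracle in the test suite enumerates full lineage outcomes by
convolution and verifies every closed form to 1e-9 on mixed
doubling/tripling schedules.

**Caveat on `E(M*)`.** The product formula counts root lineages that
pass through every event as a single copy. It is exact under
`u_0 = 0` ("no lineage extinction"). When `u_0 > 0` a gene can also
lose all its partners to extinct side branches, so the formula is a
lower bound; the simulator counts true unpaired genes and the test
suite demonstrates the gap.

## Speciation and ortholog pairs

A speciation at generation `s` copies every gene into daughter genomes A
and B, which then fractionate (and possibly re-duplicate)
independently. The package derives the ortholog constants from the
event structure rather than hard-coding them. Let `q_X` be the marginal
probability that genome X retains a gene through the first
post-speciation interval, and `amp_X` the product of survivor means of
the branch-X WGDs. Then

* `E(O_i) = 2 * N_i^(s) * q_A amp_A * q_B amp_B` for `i < s`, where
  `N_i^(s)` is the expected i-pair count at speciation (factor 2: the
  two genome assignments of the pair's two sides);
* `E(O_s) = M_s * B * amp_A amp_B`, where `B` is the probability that
  both genomes keep a gene.

Two retention models are supported:

* **coupled** -- the speciation event carries an r=2 survival law;
  `u_2` is the both-copy survival, a lone survivor lands in either
  genome with probability 1/2, so `q = u_2 + u_1/2` and `B = u_2`;
* **independent** -- each branch declares a pair-equivalent copy
  survival `u^X(s)`; then `q_X = (1 + u^X(s))/2` and `B = q_A q_B`,
  which reproduces the 1/2 and 1/4 constants of the
  amplification-factor form `E(O_s) = 1/4 * M_s * F_A F_B` with
  `F_X = (1 + u^X(s)) * prod_branch (1 + u_2)`.

Both are verified against simulation to Monte-Carlo precision.

**Unpaired genes across genomes.** For ortholog comparisons a gene is
unpaired when its whole root family left no descendant in the other
genome. With `G` the composed generating function of the family size at
speciation, `E[U] = M1 * (alpha_A G'(c_B) amp_A + alpha_B G'(c_A)
amp_B)`, where `c_X` is the per-gene probability of leaving no X-copy
and `alpha_X` the probability of keeping an X-copy while leaving no
other-genome copy. This reduces to the chain formula for single-genome
schedules and is exactly what makes one-pre-WGD scenarios identifiable
when the unpaired count is supplied. It assumes branch WGDs have
`u_0 = 0`.

## Simulation

The simulator draws survivor counts directly from the categorical
survival law (which of the `r` progeny survive is irrelevant to pair
counting by most recent common ancestor, and subgenome identity is out
of scope). Two layers share the model: an object layer producing
inspectable gene trees with Newick export, and a vectorized batch layer
that runs 1e5 replicates in a few seconds by propagating flat parent /
replicate-id arrays forward and descendant counts backward. Pairs with
MRCA at a given gene are counted as `(S^2 - sum c^2)/2` over its
children's descendant counts (cross-products only), and ortholog pairs
as `S_A S_B - sum c_A c_B`. Unpaired genes are the members of root
families reduced to a single leaf (or, across genomes, of families
leaf-less in the other genome).

## The observation model and the synthetic-data generator

Observed data are similarity scores, not labelled pairs. A pair of age
`t` My has expected similarity `p(t) = C exp(-lambda t)` (clipped above
at 1; deliberately not clipped below -- remote events may decay beneath
detectability, and the generator lets that happen). Defaults:
`C = 1.0` (a zero-age pair is identical) and `lambda = 0.009` per My,
i.e. twice a typical plant nuclear substitution rate of ~4.5e-3 per site
per My, which keeps two- and three-event histories within the detectable
similarity range. Empirical trend fits sometimes prefer a larger
amplitude and steeper rates; both are plain configuration.

Component standard deviations are linear in the component mean,
`sd = 0.075 - 0.06 * mean` by default (about 0.02 at mean 0.9, 0.05 at
mean 0.4), emulating the observed narrowing of recent components. The
coefficients are synthesis defaults only; inference treats every
component sd as a free parameter and assumes no mean-variance
relationship.

`synthesize_dataset` realizes pair counts per origin event with the
batch simulator (scaling `M1` to hit a target pair count), assigns each
origin its decay mean and sd, and samples similarities from normals
*truncated* to (0, 1] -- truncated, not clipped, so no probability mass
piles at the bounds. Ground truth (component table, per-origin counts,
unpaired-gene count) is returned for recovery studies. Truncation makes
the sample mean a slightly biased estimator of the nominal component
mean near the upper boundary: the bias is ~0.29 sd at mean 0.95 with
sd 0.05 and negligible (< 0.005) in the interior; the tests document
both regimes.

What the generator does *not* emulate: noise and contamination from
non-syntenic pairs, similarity-dependent data quality, assembly and
annotation artifacts, and overlap between biological and technical
modes. Passing recovery tests on synthetic data therefore demonstrate
correctness of the inference chain under the stated observation model,
not robustness to everything real comparisons contain.

## Mode detection and the constrained mixture fit

Component means are estimated as local modes of the binned, smoothed
similarity histogram (means cannot be estimated by averaging because the
components overlap). Defaults: bin width 0.01, 5-bin moving-average
smoothing, minimum peak prominence 5% of the tallest smoothed bin --
configurable, echoed into every output header. Equal-height plateaus
resolve to the leftmost bin. Narrow bins locate modes precisely but
proliferate spurious ones; the test suite demonstrates the trend on
structureless data. When several comparisons share events,
`shared_mode_alignment` pools per-sample modes and single-linkage
clusters them (threshold 0.02 by default), returning median consensus
means -- the package's concrete rendering of reconciling shared events
across comparisons.

With means fixed at the modes, an EM iteration estimates the sds and
weights only (convergence at log-likelihood gain < 1e-8 or 500
iterations; sds floored at 1e-4 and flagged on collapse). Holding the
means fixed is a deliberate guard against the spurious components that
unconstrained decompositions produce on this kind of data; an optional
refinement pass lets means drift up to a configured distance from their
anchors, and an optional uniform background component can absorb
unstructured noise (both off by default). Component counts are
`weight * n`.

## Survival and rate estimation

Component counts (plus, optionally, the unpaired-gene count) are treated
as one multinomial observation whose cell probabilities are the
normalized closed-form expected counts of a skeleton model (event order,
ploidies and times fixed; survivals free). The likelihood is maximized
by bounded L-BFGS-B in `(0, 1]^k` with 10 seeded random restarts --
cheap, since each evaluation is a product formula, and a guard against
the flat ridges that appear when components overlap. Identifiability is
checked up front: `k` free parameters require at least `k` independent
proportions, and the error names the deficit. Triplings are fitted
under `u_3 = u_2^2`; `u_0 = 0` is imposed throughout estimation. For
scenarios, post-speciation branch WGD survivals multiply every ortholog
category equally and cancel from the proportions; they are therefore not
estimable this way and stay at their skeleton values. The estimator for
them is the amplification regression: counts in comparisons against the
amplified species, regressed through the origin on counts against an
unamplified outgroup, have slope `F_A`.

Rates follow from the exponential survival law `u(t) = exp(-rho t)`:
`rho = -ln(u) / dt` over each inter-event interval, reported per My.
When a coupled speciation survival spans branches whose first events
differ in time, the same `u` is reported once per branch (the model
presumes `rho = rho_A = rho_B`); `rate_consistency_report` quantifies
how well that presumption holds across comparisons (range and CV per
interval, flagged above a configurable CV threshold, default 0.25).

## Numerical choices

* Survival vectors must sum to 1 within 1e-9; inputs inside the
  tolerance are renormalized, anything further off is rejected.
* Extinction probabilities come from the companion-matrix roots of
  `f(s) - s` polished by Newton iteration. A bracketed solver was
  considered and rejected: the bracket degenerates at the near-critical
  double root, where the polynomial route stays robust. Fast paths:
  `u_0 = 0` gives 0, `mu <= 1` with `u_0 > 0` gives 1.
* The EM log-likelihood uses full normal densities (not truncated);
  truncation corrections are negligible for interior components and the
  single-component closed form then matches the plain ML estimate.
* Tie-breaks and floors (leftmost mode, sd floor 1e-4) are stated in the
  API documentation and flagged in outputs when triggered.

## Problem sizes

Simulation-based tests and the acceptance checks use 1e5 replicates for
structural constants (Monte-Carlo standard errors ~0.003 on ratios near
0.5), 3e4 replicates for routine oracle agreement, and synthetic samples
of 2e4 pairs for pipeline recovery (10 seeds per schedule). These sizes
were chosen so that 3-standard-error acceptance bands sit well below the
effect sizes being verified.

## Known limitations

* No within-genome positional or syntenic structure: pairs are
  WGD-generated by construction, which is precisely what synteny-based
  screening of real data tries to guarantee.
* No sequence-level model: the package consumes similarity scores; Ks or
  4DTv computation from sequences is out of scope.
* Expectations only: no variance formulas for pair counts; uncertainty
  is assessed by simulation.
* The unpaired-count cell and the cross-genome unpaired definition are
  this package's resolution of an ambiguity in the underlying framework;
  both are documented above and checked against the simulator.
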