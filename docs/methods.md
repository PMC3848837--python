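# Methods

## The DEC model

Geographic ranges are subsets of a fixed set of areas. The default
geography has three areas — Amazon (A), Andes (B), Atlantic Forest (C) —
with the Amazon as the only connection between regions (adjacency A–B and
A–C only) and ranges limited to at most two areas, giving five non-empty
states {A, B, C, AB, AC} plus an absorbing empty state.

Along branches, ranges evolve as a continuous-time Markov chain with two
rates:

- dispersal *d* (area gains per Ma): range R gains area a at rate
  d × (number of areas in R adjacent to a), only into allowed states;
- extinction *e* (area losses per Ma): R loses each of its areas at rate
  e; a singleton decays to the empty range.

The empty range is absorbing, contributes zero likelihood at the tips, and
no conditioning on survival is applied — the standard DEC convention.

At each node, a cladogenetic outcome set splits the ancestor range: a
single-area ancestor passes its range to both daughters; a two-area
ancestor {a,b} either divides by vicariance (one daughter a, the other b,
both orders) or by peripheral-isolate sympatry (one daughter a singleton
of the range, the other the full range). All outcomes of a given ancestor
state are weighted equally (1/n each); for a two-area ancestor n = 6. The
per-node outcome probabilities therefore sum to one, which keeps the tree
likelihood a proper probability.

The likelihood is computed by Felsenstein pruning over range states with
per-node rescaling; branch transition matrices are exp(Q·t), evaluated
through an eigendecomposition of Q (with a dense scaling-and-squaring
fallback when Q is near-defective). Root states are summed with equal
weight over allowed non-empty states, optionally restricted to a single
constrained state; a constrained optimum can therefore never beat the
unconstrained one. The likelihood is invariant to rescaling branch
lengths by k while dividing (d, e) by k.

Fitting maximises the likelihood over (log d, log e) by Nelder–Mead from
five jittered starts on a {0.001, 0.01, 0.1} grid, with 1e-8 tolerance on
−lnL. For ancestral states, every cladogenetic scenario at every node is
scored by the likelihood of the whole tree conditional on that split
(an inside–outside computation linear in tree size); relative
probabilities at a node sum to one, scenarios within 2 log-likelihood
units of the node best are flagged retained, and per-daughter-branch range
marginals below 0.1 are reported but flagged sub-threshold. Ties between
equally likely scenarios are broken by state-space order. Both windowing
parameters are configurable. The 2-unit window is applied per node; the
global optimum is recorded separately on the results object. Polytomies
are rejected (the cladogenetic outcome set is defined for two daughters);
trees must be resolved before fitting.

Correctness is established against an independent oracle: on trees of 2–5
tips the pruning likelihood equals an exhaustive sum over every assignment
of (ancestor state, cladogenetic outcome) to every internal node, to 1e-8
relative, across random rate draws and both adjacency schemes; scenario
relative probabilities equal the enumerated posterior fractions.

## Transition calling

Reconstruction marginals give, per branch, the probability that the
lineage occupied each range immediately after the speciation event at the
branch's origin; terminal branches are called by the observed tip range. A
call is *certain* when its best range has probability ≥ 0.75 (the
threshold is the conventional cut for an unambiguous reconstruction; ties
break by state-space order, and a marginal exactly at the threshold counts
as certain).

A transition is emitted wherever a branch's called range differs from its
parent branch's call in focal-region membership (Amazon/Andes by default).
When both daughters of a node show the identical change, the change is
placed on the parent branch as a single anagenetic event for the whole
daughter clade; otherwise it is tied to the differing daughter
(cladogenetic). Complete shifts (A→B), expansions (A→AB) and contractions
(AB→B) are all emitted, distinguished by an event-kind flag, since range
expansions into the other region are part of the exchange record.

Polarity is read from the nearest certain ancestor call, walking at most
three branches rootward (attribution depth i/ii/iii). If no certain call
is found within three branches the polarity is *uncertain*, unless every
positive-probability candidate range of the nearest ancestor implies the
same polarity — and none implies "no transition here" — in which case the
polarity is promoted with a note. The event window runs from the stem age
of the branch carrying the attributed origin call (the earliest point the
change could have begun) down to the descendant clade's crown age; on
simulated single-event histories this window brackets the true event age.

Ages map to three bins tied to the region's geological history: type 1
(> 7.5 Ma, Andean uplift phase), type 2 (2.5–7.5 Ma, regression of the
Pebas wetland system), type 3 (≤ 2.5 Ma, Plio-Pleistocene climate
cycling, either polarity). Bin edges are inclusive above (2.5 Ma is
type 3, 7.5 Ma is type 2), which is the assignment required for the bin
counts of the packaged compendium to reproduce its published tallies. The
bins partition [0, ∞); typing uses the event-window midpoint by default
(configurable to either bound).

## Compendium statistics

Ages are normalised by fixed rules before any statistic: a range "x–y"
takes its midpoint, "< 1 Ma" becomes 0.5 Ma, a percent divergence defers
to its parenthesised Ma conversion, and undated records are excluded from
age-based statistics while still counting in polarity tallies.

Confidence intervals use the t distribution with n−1 df
(mean ± t₀.₉₇₅·sd/√n); normal-quantile intervals do not reproduce the
published interval for the Andes-origin ages, t-based ones do. The
two-sample comparison is Welch's t with Satterthwaite df. The polarity
test is a goodness-of-fit χ² against a 50:50 null with a Monte-Carlo
p-value from Binomial(total, ½) resampling using the (r+1)/(N+1)
estimator; at 10⁶ replicates the simulated p agrees with the exact
binomial two-tail probability to < 0.005. Display rounding is half-up,
2 d.p. for statistics and 1 d.p. for ages. The 2%/Ma cytochrome-*b*
conversion divides percent divergence by the rate and rounds half-up to
one decimal for display (the exact value is retained internally).

One caveat worth recording: the packaged table's ages give Welch
t = 1.268 (1.27 at 2 d.p.); some published summaries of the same
comparison print 1.28. The df (58.3) matches exactly, and both values
round to 1.3 at one decimal. The package reports the value computed from
the table.

## Alignment diagnostics

IUPAC ambiguity codes and gaps are treated as missing for distances and
base counts — the conservative choice when polymorphisms from degraded
samples are coded as ambiguities. Pairwise deletion uses, per pair, the
sites where both sequences carry an unambiguous A/C/G/T; this means the
distance denominator excludes ambiguities as well as gaps (flagged here
because conventions differ). Pairs sharing no usable site get an undefined
(NaN) distance, never 0. Saturation tables count raw mismatches at
unambiguous sites without separating transitions from transversions, and
no asymptote test is performed — the table is for visual assessment.

Base-composition heterogeneity is a contingency χ² of the taxa × 4 count
table against the pooled expectation, df = (taxa−1)×3. The g₁ test samples
topologies uniformly by random sequential addition, computes Fitch
parsimony lengths with bitmask state sets (ambiguities participate as
their full compatible-state sets), and reports the moment skewness
m₃/m₂^1.5 of the length distribution; since published critical-value
tables are not reproduced here, a column-shuffle null (which destroys
hierarchical signal) is available as an internal reference.

## Synthetic data

The generators emulate the study conditions rather than any particular
data set: 22-tip Yule trees (birth rate 0.25/Ma gives a crown age near
13 Ma at that size, matching the depth of a mid-Miocene arboreal
radiation, and can be rescaled to an exact crown age), three areas with
Amazon-hub adjacency, forward DEC simulation at d = 0.05, e = 0.02 from an
Amazonian root, mitochondrial-like GTR+Γ sequences (transition-biased
exchangeabilities, AT-rich frequencies, α = 0.5 with 4 discrete
categories, 1140 bp), and compendia of 52 Amazon-origin vs 35 Andes-origin
records with lognormal ages (σ = 0.8; location parameters 1.20/1.45 chosen
so the two polarities' mean ages sit near 4.6 and 5.9 Ma), 10% emitted as
symmetric midpoint-preserving ranges and 2% undated. All generators are
deterministic under a seed.

Survival conditioning. Forward DEC simulation can absorb lineages into
the empty range. By default such replicates are only flagged; for
closed-loop experiments each branch is instead redrawn until its endpoint
is non-empty (`condition_on_survival=True`), with rejection counts
recorded. Replicate-level rejection is not viable at realistic sizes: at
200 tips the total tree length is ~800 Ma, so the chance that no lineage
is absorbed at e = 0.02 is ~e⁻¹³. Branch-level rejection keeps every tip
observable at the cost of a small, local bias toward survival.

What the simulations do not emulate: rate heterogeneity among lineages,
fossil calibration uncertainty, indels, within-species sampling, or
non-stationary geography (the adjacency matrix is static, as in the
analysis the package implements). Passing the closed-loop tests therefore
shows internal consistency of the machinery under the model's own
assumptions, not robustness to their violation on real data.

## Known limitations

- **Extinction-rate identifiability.** On data generated by the model
  itself, the ML estimate of e collapses to the boundary: profiling −lnL
  in e at the true d shows a monotone preference for e → 0, because any
  range contraction the data require is available free through
  cladogenetic subset/vicariance outcomes, while anagenetic loss adds
  probability flux into the likelihood-dead empty state. Median relative
  error for ê in the simulate-and-refit experiment is ~100% (d̂ recovers
  to within ~10%). This is the well-documented extinction-rate pathology
  of DEC-type models, not an artifact of this implementation (the
  likelihood is enumeration-verified); treat ê as qualitative.
- Time-stratified adjacency matrices, founder-event speciation and
  alternative cladogenetic weightings are out of scope.
- The transition caller's window semantics place the earliest bound at
  the stem of the branch carrying the attributed origin call; published
  tables assembled by hand sometimes tighten these windows using
  information the algorithm does not use (e.g. which subclade a dispersal
  must postdate).
- Uniform-topology sampling for g₁ uses random sequential addition, which
  is uniform over labeled topologies but not over tree shapes; the
  reported skewness is comparable across data sets analysed the same way.
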