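# transandes

Tools for studying biogeographic exchange between the tropical Andes and
Amazonia — the two richest centers of endemism in South America — from
time-calibrated molecular phylogenies.

Lineages distributed across both regions carry a record of *ex situ*
diversification: an Andean species nested inside a lowland radiation
implies an Amazon-to-Andes colonisation, and vice versa. Resolving the
**polarity** (which region the ancestor occupied) and the **timing** of
such transitions requires reconstructing ancestral geographic ranges on an
ultrametric tree. `transandes` implements that pipeline end to end:

- **`timetree`** — read, validate, prune and query ultrametric time trees
  (ages in Ma before present) via Newick.
- **`dec`** — the dispersal–extinction–cladogenesis (DEC) model: a
  continuous-time Markov chain over geographic range states (subsets of
  areas) with dispersal rate *d* (area gains/Ma) and extinction rate *e*
  (area losses/Ma) acting along branches, plus vicariance and
  peripheral-isolate sympatry at nodes. `DECModel(tree, tip_ranges).fit()`
  maximises the pruning likelihood over (log *d*, log *e*);
  `results.ancestral_splits()` scores every cladogenetic scenario at every
  node by the conditional likelihood of the whole tree and reports relative
  probabilities and per-branch range marginals.
- **`transitions`** — turn reconstructions into discrete transition calls:
  certainty at a 0.75 marginal-probability threshold, polarity from the
  nearest certain ancestor (attribution depth i/ii/iii, at most three
  branches rootward), a bracketing time window, and the age typology
  type 1 (> 7.5 Ma), type 2 (2.5–7.5 Ma), type 3 (≤ 2.5 Ma).
- **`compendium`** — statistics over a packaged cross-taxon table of dated
  Andes↔Amazon transitions compiled from published phylogenies of mammals,
  birds, amphibians and insects (one row per transition, ages kept as
  printed): polarity counts, mean ages with t-based 95% CIs, a Welch
  two-sample test, a Monte-Carlo χ² against a 50:50 polarity null, per-bin
  rates, and the 2%/Ma cytochrome-*b* divergence-to-age conversion.
- **`seqdiag`** — alignment diagnostics run before concatenating gene data
  sets: site masking, uncorrected-*p* distances with pairwise deletion,
  saturation tables, base-composition heterogeneity χ², parsimony-
  informative site counts, and the g₁ tree-length skewness test.
- **`simulate`** — seeded generators for every input: Yule trees, forward
  DEC range histories with recorded ground truth, GTR+Γ alignments, and
  synthetic compendia.

## Worked example

Summarise the packaged transition compendium:

```python
import transandes as ta

records = ta.load_transitions()
print(ta.compendium.summary_report(records, replicates=10_000, seed=42))
```

```
Andes-Amazon transition compendium
==============================================
dated transitions:     87 (52 Amazon-origin, 35 Andes-origin)
Andes-origin ages:     mean 5.87 Ma, 95% CI (4.12, 7.62)
Amazon-origin ages:    mean 4.59 Ma, 95% CI (3.54, 5.64)
polarity chi-square:   3.32, simulated p = 0.085 (10000 reps, seed 42)
Welch t:               1.27, df = 58.3, p = 0.210
type 3 Andes->Amazon  n=9   (10%, 3.6/Ma)
type 3 Amazon->Andes  n=16  (18%, 6.4/Ma)
type 2 Andes->Amazon  n=19  (22%, 3.8/Ma)
type 2 Amazon->Andes  n=32  (37%, 6.4/Ma)
type 1 Andes->Amazon  n=7   (8%)
type 1 Amazon->Andes  n=4   (5%)
```

Of 87 dated transitions, more originate in the Amazon (52) than the Andes
(35), but the χ² of 3.32 is not significant under a 50:50 null (simulated
p = 0.085), and mean ages do not differ between polarities (Welch
t = 1.27, df = 58.3) — reciprocal exchange rather than a one-way street.

Fit the DEC model on a simulated 22-taxon tree and call transitions
between Amazon (A) and Andes (B):

```python
tree = ta.simulate_yule_tree(22, 0.25, crown_age=13.3, seed=7)
hist = ta.simulate_dec_history(tree, None, ta.DECParams(0.05, 0.02), "A",
                               seed=7, condition_on_survival=True)
res = ta.DECModel(tree, hist.tip_ranges).fit(seed=0)
print(res.summary())
recon = res.ancestral_splits(window=2.0, floor=0.1)
calls = ta.classify_branch_ranges(recon, threshold=0.75)
for ev in ta.detect_transitions(calls, tree, ("A", "B")):
    print(ev.label, ev.polarity, ev.depth, ev.kind,
          f"{ev.earliest:.2f}-{ev.latest:.2f} Ma", "type",
          ta.assign_type(ev).label)
```

```
DEC model fit
==============================================
tips:                22
areas:               A,B,C (max range 2)
states:              5 non-empty
dispersal d:         0.0511848 /Ma
extinction e:        6.29637e-16 /Ma
-lnL:                22.2176
converged:           True (5 starts)
T1 A->B ii expansion 5.28-0.00 Ma type 2
T2 A->B ii shift 5.28-0.00 Ma type 2
T3 A->none i contraction 11.45-0.00 Ma type 2
T4 A->B i expansion 8.92-0.00 Ma type 2
T5 uncertain None contraction 13.30-9.67 Ma type 1
T6 uncertain None contraction 13.30-11.45 Ma type 1
```

The fitted dispersal rate recovers the simulating value (0.051 vs 0.05);
the extinction rate sits at the boundary, a known identifiability
limitation of DEC discussed in `docs/methods.md`. Each transition line
gives the polarity (`A->B` is Amazon-to-Andes; `A->none` marks a move out
of the focal pair, here into the Atlantic Forest), the attribution depth
(`i` = the origin call is certain on the stem branch, `ii` = two branches
back), the bracketing time window, and the age-typology bin.

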