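# Methods

This note records the statistical procedures the package implements, the
assumptions behind them, and the design choices made where the analysis it
re-implements left details open.

## Scope and stage order

The pipeline consumes the output of Bayesian phylogenetic MCMC runs (tree
samples per genome, Newick lists or NEXUS trees blocks with translate
tables) — it does not re-run tree inference. Stages:

1. **Burn-in** — drop the first `floor(fraction · N)` trees of each
   sample (default fraction 0.25). The floor convention is exact for the
   1000-sample runs the defaults are modelled on and deterministic for
   awkward N. Burn-in is guarded against double application.
2. **Reduction to shared taxa** — trees are pruned to the label set
   present in both genomes before any cross-genome comparison; induced
   branch lengths are summed across suppressed nodes.
3. **Per-genome consensus** — 50% majority-rule consensus (MRC), edges
   annotated with split frequencies (posterior probabilities).
4. **Pooled consensus with internode certainty** — both genomes' samples
   pooled with equal weight, combined MRC built, every internal edge
   annotated with IC.
5. **Supported-conflict detection and classification** — per species.
6. **Tanglegram export** and machine-readable reports (TSV/JSON).

All trees are treated as unrooted for bipartition work regardless of how
they are written: consensus and IC are functions of splits, and the
rooting of MCMC output is arbitrary.

## Consensus conventions

A split enters the MRC iff its pooled frequency is **strictly greater**
than the threshold (default 0.5). Splits at exactly 0.5 are added
greedily in descending frequency where compatible, ties broken
lexicographically on the canonical mask, so output is deterministic. The
strict-vs-non-strict inequality is exposed as a flag
(`strict_greater`) since either convention occurs in practice. Strict and
semi-strict (combinable-component) consensus are provided for combining
the two genome analyses; neither is used by the classifier.

Pooling weights default to ½, ½ per genome regardless of sample counts, so
each analysis contributes equally even when post-burn-in sample sizes
differ.

## Internode certainty

IC uses only the single most prevalent conflicting split (two-term
entropy, base-2 logarithm):

    IC = 1 + p1·log2(p1) + p2·log2(p2),  p1 = f(b) / (f(b) + f(b')).

With no observed conflict IC = 1; equal prevalence gives IC = 0 at any
absolute frequency. The 100%/50% worked configuration pools to
0.75 vs 0.25 and evaluates to 0.1887; outputs report four decimals and
tests compare printed two-decimal values at |Δ| ≤ 0.01. Frequencies are
compared with absolute tolerance 1e−12 where "equal prevalence" matters,
since pooled values are floating-point sums.

## Node displacement

The source analysis counts "nodes different in the positions of the
species" without defining the procedure, so the metric here is declared
and validated on constructed regrafts:

* the species is removed from the target tree;
* its **actual** attachment edge is located, as is the edge whose
  subtended leaf set has maximal Jaccard overlap with the species'
  sibling context in the source tree (ties resolved to the nearest edge);
* displacement = line-graph distance (edges sharing a node are one step
  apart) between the two, minimised over tied candidates;
* the final value is the maximum over the two directions
  (A-context measured on B, B-context measured on A), making the metric
  symmetric; it is 0 iff the contexts match exactly.

The sibling context is rooting-invariant: of the neighbour subtrees at
the leaf's attachment node, the largest is treated as the "rest of the
tree" and the context is the union of the others. A single
nearest-neighbour regraft scores 1 and a k-step regraft scores k, which
grounds the two classification categories: displacement 1 is compatible
with incomplete lineage sorting at a short internode, displacement ≥ 2 is
taken as evidence of genomic exchange via hybridisation. Branch lengths
are never used by the category rule — the underlying analysis offers only
a verbal "branch lengths are relatively short" cue, with no quantitative
rule to implement.

## Supported conflict and per-species attribution

A conflicting split pair (one per genome tree, incompatible) witnesses a
species when deleting that species from both splits makes them
compatible — i.e. the species' placement is what the pair disagrees
about. Both splits must exceed the posterior threshold (default 0.95);
requiring only one side is available as a flag (`both_sides=False`), the
two-sided rule being the stricter reading.

One captured species perturbs splits shared with its neighbours, so
per-species attribution is iterative: among all supported conflicting
pairs, flag the species whose deletion resolves the most pairs, prune it
from both trees, recompute, repeat until no supported conflict remains.
Each flagged species' displacement is then measured on trees pruned of
the *other* flagged species, scoring each event against an otherwise
agreeing background. Unflagged species are congruent by definition.

Multi-accession species are collapsed to a single species leaf only when
their accessions are monophyletic (unrooted sense) in **both** genome
trees; otherwise every accession keeps its own terminal and is classified
separately — the pattern of a single captured accession among congruent
conspecifics.

## Parsimony and the ILD test

Tree lengths are Fitch small-parsimony counts: IUPAC ambiguity codes are
state sets, gaps and unknowns are missing data (the full state set), so
all-gap columns cost nothing. Excluded alignment columns (1-based
inclusive ranges, e.g. `494-548`) never contribute to lengths or to
parsimony-informative counts. A column is parsimony-informative iff at
least two distinct unambiguous states each occur in at least two taxa.

Searches are exhaustive over all (2n−5)!! unrooted topologies for ≤ 9
taxa; beyond that, stepwise random addition (default 10 replicates) with
NNI or SPR swapping to a local optimum, retaining up to `maxtrees`
(default 100) equally best trees, deterministic given the seed. NNI/SPR
stands in for the TBR swapping classic parsimony programs use; at the
taxon counts where the ILD statistic is computed here the search is
exact, so the swap set does not affect the statistic. The settings record
accompanies every result.

The ILD statistic is D = L(A+B) − L(A) − L(B); the null repartitions the
pooled included columns without replacement into the original partition
sizes. The p-value uses the +1/+1 correction, p = (1 + #{D_rep ≥ D_obs})
/ (1 + R), so R = 100 replicates bounds p below by 1/101 ≈ 0.0099 — the
raw proportion is reported alongside, since either convention may be
quoted. Within the exact-search regime the per-topology, per-column
length matrix is computed once and every observed or replicate search is
a subset sum over its columns, which is what makes the 200-simulation
null calibration run in seconds.

## The synthetic-data generator

The generator builds *capture scenarios*: a base ("nuclear") topology, a
derived ("chloroplast") topology obtained by regrafting chosen species,
posterior-like samples for both, paired alignments, a taxon map and a
truth table.

* **Species trees** are Yule: a uniformly chosen lineage splits after a
  unit-exponential waiting time until the target taxon count; labels are
  randomly permuted so the labelled-topology distribution stays
  exchangeable. Branch lengths are in arbitrary coalescent-free units —
  only the alignment simulator consumes them, as expected substitutions
  per site at its `subst_rate`.
* **Posterior emulation** applies, per internal edge and sample, a random
  NNI with probability `perturb_rate` (uniform over the three
  resolutions). A true split therefore survives with probability
  1 − ⅔·rate, an analytically checkable support level — the reason for
  emulating rather than running real MCMC. What this does **not**
  emulate: autocorrelation between successive samples, branch-length
  posteriors, or topology-dependent noise; passing tests show the
  consensus/IC/classification contracts behave correctly at known signal
  levels, not that real MCMC output is this well-behaved.
* **Capture events** are leaf regrafts whose realized displacement is
  measured with the classifier's own metric at injection time. Events
  are constrained so the ground truth is identifiable from topology
  alone: the moved species must have a sibling clade of ≥ 2 leaves, the
  destination edge must subtend ≥ 2 leaves, no other single leaf's
  removal may reconcile the trees (otherwise a 1-step move is perfectly
  symmetric between two leaves and *no* method could name the mover),
  and successive events must not share context leaves. Not every Yule
  draw can host every displacement set under these rules, so the base
  tree is redrawn (bounded, seed-derived) until placement succeeds.
* **Alignments** evolve under Jukes–Cantor with Poisson substitution
  counts per branch; the post-k-jump identity probability
  ¼ + ¾(−⅓)^k is sampled directly.
* **Multi-accession terminals** split a species leaf into k accession
  leaves on near-zero branches, with accession names shared between the
  genomes as terminal names are in practice.

Study-condition defaults: 16 taxa, two events (displacements 1 and 3),
500 trees per genome, 300 alignment columns. Validation problem sizes
were chosen to keep each property readable as a single run: noise-free
exactness over 100 random configurations (14–24 taxa, 1–2 events,
displacements 1–4), noisy recovery over 100 replicates at perturbation
rate 0.05 with 500 trees per genome, and ILD calibration over 200
simulations of 100+100 columns on 6-taxon trees with 100 permutation
replicates each.

## Numerical and degenerate-input conventions

* Bipartitions are canonicalised to the side excluding the
  lexicographically smallest label; compatibility reduces to
  nested-or-disjoint masks. Trees of < 4 leaves have no non-trivial
  splits.
* Consensus trees are assembled by clade nesting rooted at the reference
  leaf; the construction rejects incompatible split sets.
* Polytomies passed to Fitch are resolved deterministically
  (left-to-right caterpillar) first; exact lengths are guaranteed only
  for binary inputs.
* All randomness flows from one top-level seed through
  `numpy.random.default_rng`; identical inputs and seed give
  byte-identical reports (the pipeline log additionally records input
  digests, so it differs across directories by design).
* Tanglegram untangling is hill climbing over child-order flips with a
  fixed seed and iteration budget; it never increases the crossing count
  but makes no optimality claim (exact minimisation is NP-hard and
  irrelevant to the statistics).

## Known limitations

* The displacement metric is one defensible operationalisation of
  "nodes different"; counts from visual inspection of published figures
  may differ for species whose placement is poorly supported.
* Greedy conflict attribution can, in principle, mis-rank species when
  many capture events overlap in one neighbourhood; the generator's
  separation constraints define the regime in which exact recovery is
  guaranteed, and dense-event regimes should be read with care.
* The ILD test inherits its known sensitivity to rate heterogeneity
  between partitions; a significant result is evidence of combined-data
  strain, not of hybridisation specifically.
* Maximum-clade-credibility summarisation is not implemented; all
  downstream steps run on majority-rule consensus trees.
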