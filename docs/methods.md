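# Methods

## The grafting model

The package builds a posterior distribution of regionally complete,
time-calibrated phylogenies from two kinds of Bayesian output that were
estimated separately:

* a **backbone posterior**: genus-level chronograms in absolute time
  (Ma), fossil-calibrated, with a fixed topology and posterior
  uncertainty in node ages only;
* per-unit **subclade posteriors**: densely sampled trees in *relative*
  time (branch lengths proportional to time, unanchored), each with 2–4
  outgroups and free ingroup topology, the ingroup constrained to be
  monophyletic.

One replicate pairs one backbone sample with one sample per unit and,
for each unit:

1. resolves the unit's **crown node** on the backbone from anchor tip
   labels (`mrca`, `mrca_excluding`, `split`, or `crown_of_unit` — see
   below);
2. applies tip substitutions, verifies ingroup monophyly, removes the
   outgroups and any listed early-diverging taxa from the subclade
   sample;
3. rescales the sample so its crown depth equals the backbone crown age
   of the resolved node;
4. deletes *all* backbone lineages below the crown node and attaches
   the rescaled sample there, keeping only the **stem branch**, whose
   new length is stem age − crown age.

Consequences, asserted on every replicate: the grafted crown age equals
the backbone crown age exactly (≤1e-9 relative); the root age and every
branch outside replaced clades are untouched; ultrametricity is
preserved; the result is independent of the order units are processed.
Age ratios *within* a grafted subclade equal the sample's relative
ratios times the crown age — the subclade posterior contributes shape,
the backbone posterior contributes scale.

Attachment modes map the rules used in regional grafting studies:
`mrca` (anchors span the clade), `mrca_excluding` (leave an
early-diverging relict in place: crown = MRCA of the clade tips minus
exclusions), `split` (two sister clades grafted as one unit at their
common parent), and `crown_of_unit` (crown = MRCA of the unit's ingroup
labels that exist in the backbone). All backbone descendants of the
resolved node are removed — anchors only *locate* the node.

Substitution routing: a substitution whose old label is a backbone tip
renames the backbone before resolution (the placeholder-genus rule —
using a congener's backbone position for the regional species);
otherwise it renames the subclade sample.

## Pairing and the replicate loop

Replicate *i* takes the *i*-th post burn-in sample of every stream
(`indexed` pairing, the default: deterministic, reproducible); seeded
uniform draws (`random`) are available for sensitivity checks.  When a
trace holds more samples than replicates, evenly spaced subsampling
(first sample, then a fixed stride) is used, which also reduces
autocorrelation.  Monophyly violations abort the run by default
(`skip_bad_replicates` drops the replicate with a log entry); traces
whose monophyly was enforced a priori can never trigger this.

Burn-in: the first `floor(f·n)` trees of a trace are dropped at load
time.  The default fraction is 0.10 — a convention, recorded in the
trace and the run log, since source analyses rarely state theirs.
Combining runs requires burn-in to have been applied per run.

## Consensus and node ages

Support is counted over **rooted clades** (descendant tip sets), not
unrooted bipartitions: all inputs are rooted chronograms, and support on
a dated tree refers to the clade.  The majority-rule consensus contains
exactly the clades with frequency strictly greater than 0.5 (ties at
exactly half are excluded); such clades are pairwise compatible, so
construction cannot fail, with multifurcations where no majority clade
resolves a region.

Clade ages are summarized as the **median** with a central 95% interval.
The default convention (`common_ancestor`) collects the MRCA age of the
clade's tips in *every* tree, present or not — it uses all samples and
is the standard for dated summaries; `conditional` (only trees
containing the clade) is exposed as an option since either convention is
defensible.  Consensus branch lengths are parent − child median ages,
floored at 0 with a logged count; flooring can occur because medians of
different clades are not jointly order-constrained.

## The synthetic-study generator

Real studies of this design depend on multi-day MCMC runs; the generator
reproduces the *artifact structure* of those outputs at desk scale with
known truth, so the whole pipeline is testable end to end.

* **Trees** come from a forward birth–death simulation conditioned on
  the tip count by rejection (runs that die out are discarded).  The
  simulation is frozen at a uniform point within the first inter-event
  interval having *n* extant lineages, so every pendant branch is
  strictly positive.  Defaults: speciation 0.12, extinction 0.06 per
  lineage per Ma — a net diversification and turnover that put a
  200-tip backbone crown in the ~50–150 Ma range typical of family-level
  insect clades.
* **Posterior age jitter** multiplies each internal node age by a
  lognormal factor (log-scale sd `jitter_sd`, default 0.05, i.e., ~5%
  age uncertainty), resampled root-to-tip with truncation into
  (max original child age, new parent age) so every sample is a valid
  chronogram without rejection loops.  Near-coincident node ages make
  the truncation active and bias the jittered mean; recovery oracles
  therefore use fixtures with well-separated ages (adjacent age ratios
  ≤ 0.7), and this boundary effect is a known property of the scheme.
* **Topology uncertainty** is one random nearest-neighbour interchange
  per sample with probability `topology_shuffle_prob` (default 0.25).
  Backbone traces set this to 0 (fixed backbone topology, as in the
  source design); subclade traces shuffle only within the ingroup,
  because outgroups are attached afterwards.
* **Outgroups** attach successively rootward at 1.3×, 1.6×, 1.9×
  (, 2.2×) the ingroup crown age — arbitrary but fixed multipliers that
  guarantee ingroup monophyly by construction.
* **Relative time**: each emitted subclade sample is divided by its own
  ingroup crown depth, so the ingroup crown sits at exactly 1.0.  The
  normalization constant is irrelevant downstream (grafting rescales by
  crown depth), while within-subclade age ratios keep their jitter.
* **Seeding**: a master seed spawns independent per-unit substreams, so
  editing one unit leaves all others byte-identical; identical seeds
  give byte-identical study directories.

What the generator does **not** emulate: sequence data and gene-specific
rate heterogeneity, MCMC autocorrelation, calibration-prior uncertainty
structure (jitter is i.i.d. across nodes given ordering), or label
errors.  Passing recovery tests therefore show the *pipeline* is
correct and calibrated under the stated noise model — not that any real
posterior satisfies that model.

## Supermatrix rules

Per taxon and gene, the winning sequence is the one with the most
non-missing characters (`-`, `?`, `N` do not count); length ties go to
preferred-region records, remaining ties to the smallest source id —
a total order, so selection is permutation-invariant.  Missing
whole-gene blocks are `?` (unknown), distinct from the alignment gap
`-`.  Charset ranges are 1-based inclusive; codon charsets are the
three stride-3 interleaves of a gene's range, which tile any fragment
length exactly once.  `coding_in_frame` asserts that a gene's first
column is codon position 1; fragment lengths need not be multiples of
three (the study's own fragments mostly are not).

## Numerical choices

* Ultrametricity tolerance: 1e-9 relative (max minus min root-to-tip
  depth over height); crown depth is defined as the *max* root-to-tip
  path, stable for slightly corrupted inputs.
* Branch lengths serialize with 12 significant digits — below
  floating-point noise, far above biological meaning.
* Labels are preserved verbatim in both directions (no underscore/space
  conversion); labels with spaces are single-quoted on output.
* Ages are "time before present, tips at 0"; conversion from branch
  lengths happens in one place (`node_ages`).
* Degenerate inputs: pruning below 2 tips, rescaling zero-depth trees,
  grafting a subclade older than its stem, and outgroup intrusion all
  raise typed errors naming the offending labels/ages.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full design at desk
scale: a 200-tip backbone with 12 units of 5–14 ingroup tips at the
published 1000 replicates for the structural run; 120-tip backbone, 12
units, 500 replicates for parameter recovery; 50 seeded random studies
for graft invariants; 100 random small traces for the consensus oracle.
These sizes are the package's chosen operating point for reproducible
desk verification; the algorithms have no intrinsic limits near them.

## Known limitations

* Grafting assumes the backbone's attachment clades are disjoint and
  topologically fixed across samples; a backbone posterior with varying
  topology around anchor clades would need per-sample re-anchoring
  diagnostics that are out of scope.
* The common-ancestor age convention can place a clade's interval wider
  than the conditional one when the clade is weakly supported; neither
  variant is claimed to replicate any particular published figure's
  exact ages.
* No maximum-clade-credibility summary, no non-ultrametric (phylogram)
  inputs, no polytomy resolution on input (polytomies are preserved).
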