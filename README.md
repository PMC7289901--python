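# phylograft

Regionally complete, time-calibrated phylogenies by grafting.

## The problem

Species-level phylogenies restricted to one region are asymmetrically
sampled: estimating topology and divergence times from the regional taxa
alone biases both.  A robust alternative estimates each densely sampled
subclade separately — in *relative* time, with outgroups and an enforced
monophyletic ingroup — and grafts those subclade posteriors onto a
fossil-calibrated, genus-level **backbone** posterior whose node ages
carry the absolute time scale.  `phylograft` implements that procedure
as a tested, reusable pipeline for anyone assembling a complete dated
tree of a regional fauna or flora from separately estimated Bayesian
tree distributions, together with the consensus summaries and the
multi-gene supermatrix bookkeeping such a study needs.

## The procedure

For backbone sample *B* and one posterior sample *S_u* of each unit
*u* with crown node *c_u* on *B* (located from anchor tips by MRCA,
MRCA-with-exclusions, a split between sister clades, or the unit's own
crown):

1. remove the outgroups (and any listed early-diverging taxa) from
   *S_u*, requiring ingroup monophyly;
2. rescale *S_u* so its crown depth equals the backbone crown age
   *t(c_u)*;
3. delete all descendants of *c_u* in *B* and attach the rescaled
   *S_u* at *c_u*, keeping the stem branch with new length
   *t(parent(c_u)) − t(c_u)*.

Repeating over paired posterior samples yields a posterior distribution
of complete chronograms, summarized as a strict majority-rule consensus
(rooted-clade support > 50%, in percent) with per-clade median ages and
central 95% intervals.  Root age, ultrametricity and all branches
outside replaced clades are preserved exactly; within a grafted clade,
relative ages are the subclade sample's, scaled by the backbone crown
age.

A synthetic-study generator (birth–death trees, lognormal posterior age
jitter, NNI topology moves, outgroup attachment, relative-time
normalization) produces the same artifact structure with recorded
ground truth, so the whole pipeline runs and verifies at desk scale.

## Worked example

```python
from phylograft import (SimulationParams, run_replicates,
                        majority_rule_consensus, summarize_clade_ages)
from phylograft.synthetic_data import make_study
from phylograft.tree_ops import tip_labels

config, truth = make_study(
    n_backbone_tips=60,
    unit_sizes={"swallowtails": 6, "skippers": 8, "blues": 5},
    n_samples=200,
    params=SimulationParams(seed=42, jitter_sd=0.05, topology_shuffle_prob=0.25),
)
trace = run_replicates(config)                      # 200 grafted chronograms
summary = summarize_clade_ages(trace, majority_rule_consensus(trace))

for u in config.units:
    crown = frozenset(tip_labels(truth.true_subclade_trees[u.name]))
    a = summary.ages[crown]
    print(f"{u.name:14s} true={truth.true_crown_ages[u.name]:.2f}  "
          f"support={summary.support[crown]:.1f}%  median={a.median:.2f}  "
          f"95% [{a.lower:.2f}, {a.upper:.2f}]")
```

prints

```
swallowtails   true=2.60  support=100.0%  median=2.61  95% [2.36, 2.86]
skippers       true=19.44  support=100.0%  median=19.49  95% [17.48, 21.25]
blues          true=2.65  support=100.0%  median=2.64  95% [2.43, 2.91]
```

Each grafted unit keeps 100% clade support (the backbone topology is
fixed and ingroup monophyly is enforced), and the median consensus crown
age recovers the generating crown age within the posterior interval —
the interval width reflects the 5% age jitter injected by the study
generator.

The same workflow is available from the shell:

```sh
phylograft simulate --units "a=6,b=8,c=5" --backbone-tips 60 \
    --samples 200 --seed 42 --out study/
phylograft run study/ --out run/
phylograft consensus run/grafted.nwk --out consensus
phylograft trace-info run/grafted.trees
phylograft supermatrix genes/*.fasta --codon --out matrix
```

`phylograft.reference` records the 12-unit design of the European
butterfly study this pipeline operationalizes — unit sizes
(36–187 ingroup taxa), outgroups, attachment rules (including the
relict-exclusion and sister-clade-split cases), the 12-gene panel with
fragment lengths summing to 8427 columns, and the table of 18 newly
sequenced endemic species.

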