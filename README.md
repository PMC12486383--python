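# synopsin

Synteny-anchored reconstruction of the duplication history of vertebrate
visual opsins.

## The problem

Vertebrates see with five visual opsin subtypes — LWS, SWS1, SWS2, RH2
and the rod pigment RH1 — whose origin predates the vertebrate
radiation. Two classes of scenario have been proposed for how they
arose: a series of pre-vertebrate **tandem duplications** producing a
gene cluster, or a single tandem pair expanded by the early vertebrate
**whole-genome duplications** (WGDs). Resolving this is hard because
sequence-only phylogenies are confounded by rate variation among genes
and lineages, and because jawless vertebrates (lampreys, hagfish) did
not share all WGDs with jawed vertebrates: both lineages share one round
(1R), after which jawed vertebrates duplicated again (2R) while the
jawless lineage underwent an independent genome triplication — jawless
genomes are ancient hexaploids.

`synopsin` implements the chromosome-level evidence chain that can
resolve such histories, as a tested, fully simulated pipeline:

1. **Synthetic genomes with a truth ledger** (`synopsin.simulate`):
   species trees with WGD/triplication events, tandem duplications,
   losses and translocations, plus protein evolution under a 20-state
   equal-exchangeability model with per-gene and per-branch rate
   multipliers. Every event is recorded, so downstream inference can be
   scored against known truth.
2. **Tandem-pair detection** (`synopsin.tandem`): same-chromosome,
   same-strand pairs of different subtypes, split at a 100-kbp
   proximal/distal boundary (distal pairs act as a control class).
3. **Subtype classification** (`synopsin.classify`): bootstrapped
   distance placement against reference alignments, with an explicit
   non-visual outgroup class and a 0.95 support acceptance threshold.
4. **Anchor families** (`synopsin.homology`): reciprocal-best-hit
   orthogroups with in-paralog linking, then selection of gene families
   that flank opsins on at least two opsin-bearing chromosomes of the
   focal species and at least three chromosomes overall.
5. **Paralogon phylogenetics** (`synopsin.paralogon`): anchor-family
   alignments concatenated into a supermatrix keyed by
   *(species, chromosome)* rather than by species, analysed with
   neighbor joining and nonparametric bootstrap, rooted on an outgroup —
   the tree's deep clades identify which chromosomes descend from the
   same 1R copy.
6. **Event parsimony** (`synopsin.scenarios`): given the observed opsin
   arrangements, the paralogon clade assignments and the fixed WGD
   structure, an exact search for the minimum-cost history of tandem
   duplications, losses and translocations under each candidate
   hypothesis about the pre-WGD gene arrangement.

The cost of a scenario is `Σ w_e · n_e` over event kinds
(tandem duplication, loss, translocation; default weights 1), with
WGD/triplication conditioned on at cost 0, subject to the constraint
that every subtype's surviving copies form a clade of the chromosome
copy tree.

## Worked example

Ranking the three ancestral-arrangement hypotheses
(`python examples/rank_hypotheses.py`):

```
jawed-vertebrate pattern only (LWS+SWS2 tandem; SWS1, RH2, RH1 alone):
                    hypothesis  cost  n_tandem  n_loss  n_transloc  co_optimal_count
        single_tandem_two_gene   2.0         0       2           0                 6
tandem_cluster_rh_split_at_wgd   7.0         0       7           0                 2
            stepwise_five_gene  10.0         0      10           0                 6

jawless-inclusive pattern (lamprey RH1+LWS and RH2+SWS2 tandems,
translocated SWS1, plus paralogon clade ids):
                    hypothesis  cost  n_tandem  n_loss  n_transloc  co_optimal_count
tandem_cluster_rh_split_at_wgd  20.0         0      19           1                 3
        single_tandem_two_gene   inf         0       0           0                 0
            stepwise_five_gene   inf         0       0           0                 0
```

On jawed genomes alone, the two-gene model (LWS plus a single ancestor
of the other four subtypes) needs only 2 losses, while a five-gene
pre-WGD cluster would require 10 — the classic argument against the
purely tandem scenario. Adding the jawless evidence reverses the
verdict: the lamprey RH1+LWS and RH2+SWS2 tandem pairs, the translocated
lamprey SWS1 and the paralogon clade assignments are explained only by a
pre-WGD tandem cluster whose RH gene split into RH1/RH2 at the shared
WGD (19 losses + 1 translocation); the two competitors cannot produce
the observed arrangements at all without invoking gene movement inside
the paralogon.

The other example scripts each exercise one capability
(`examples/simulate_genomes.py`, `scan_tandem_pairs.py`,
`classify_opsins.py`, `paralogon_tree.py`, `run_pipeline.py`), and the
`synopsin` command line runs the whole pipeline
(`synopsin run --outdir run --seed 1`, then `synopsin report run`).

## Documentation

`docs/methods.md` describes the simulation model, the default study
conditions, the numerical conventions of every stage, and the design
choices and limitations of the event-parsimony engine.
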