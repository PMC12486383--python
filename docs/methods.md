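# Methods

This note documents the models, default parameters, numerical
conventions and design decisions behind `synopsin`, and what the
simulation-based validation does and does not establish.

## 1. Genome simulator

**Structural model.** A rooted species tree (Newick, labelled internal
nodes; a branch is named by its child node) carries whole-genome
duplications (WGD, factor 2) and triplications (factor 3) on named
branches. The ancestral genome is an ordered list of (family, strand)
genes per chromosome. Along each branch, events apply at the **start**
of the branch, in the order: WGD/triplication events, scripted
(deterministic) events, then stochastic events. Start-of-branch timing
matters: a WGD on the stem below a speciation must precede the
speciation, so the duplicated copies accumulate independent sequence
change along the rest of the stem — this is what gives the cross-lineage
1R chromosome clades a positive stem branch in the paralogon tree.

Stochastic events are drawn per branch with Poisson counts: tandem
duplications with mean `rate × branch length`, losses and translocations
with mean `rate × branch length × gene count`, each placed uniformly
over eligible genes. A tandem duplication inserts the copy immediately
downstream of its source on the same strand; a translocation moves one
gene to a uniformly chosen other chromosome at a uniform position with
random strand. Chromosome ids encode their copy path (`O` → `O_A`,
`O_B`; after a triplication `O_A_A`, `O_A_B`, `O_A_C`), and gene ids
encode their duplication path, so the truth ledger is string-parseable.
A configurable cap on the expected extant genome size (default 10,000
genes) rejects runaway duplication rates up front.

**Sequence model.** Proteins evolve under a 20-state continuous-time
model with equal exchangeabilities and equal equilibrium frequencies and
no indels. The expected substitutions per site on a branch are
`branch length × branch multiplier × per-family multiplier`; the exact
endpoint transition probability is used per site, with the probability
of differing from the ancestor after distance *d* equal to
`(19/20)(1 − e^{−(20/19)d})`. The matching distance correction
`d = −(19/20) ln(1 − (20/19)p)` is used throughout the pipeline
(`poisson_distance`), so simulator and estimator share one model by
construction. No-indel evolution means same-family sequences are
trivially aligned; the profile aligner is exercised by the classifier
and by tests, not needed for within-family alignment of simulated data.

**Coordinates.** Genes are laid out left to right with a fixed
intergenic gap (default 5,000 bp; gene span = 3 bp per amino acid). All
in-memory coordinates are 0-based half-open; GFF3 output is 1-based
inclusive; BED stays 0-based half-open.

## 2. Default study conditions

The preset scenario (`synopsin.presets.paper_scenario`) encodes the
qualitative history supported by comparative lamprey genomics:

* Species tree: three jawless species, three jawed species, one pre-WGD
  outgroup ("amphioxus"). Branch lengths (substitutions/site at rate
  multiplier 1): terminals 0.15, jawless and jawed stems 0.25, shared
  vertebrate stem 0.3, outgroup 0.7. One WGD (1R) on the shared stem, a
  triplication on the jawless stem (hexaploidy), a WGD (2R) on the
  jawed stem.
* Ancestral opsin chromosome `O`: tandem cluster (RH, LWS, SWS2, SWS1,
  all `+`) flanked by seven anchor families F1–F7, transducin-alpha
  relatives GNAT and GNAI, and parapinopsin PP; a background chromosome
  `X` with three unrelated families and the non-visual opsin OPN3.
* Configured (scripted) losses on the two stems leave the extant
  arrangements: jawless RH1+LWS on one 1R-copy chromosome and RH2+SWS2
  on the other, SWS1 translocated to chromosome `X`; jawed LWS+SWS2 on
  one chromosome and RH1, RH2, SWS1 alone on three others. Two anchor
  losses create realistic missing-data gaps. RH resolves to RH1 on
  1R-copy A and RH2 on copy B; the outgroup's unsplit RH has no subtype.
* Per-family rate multipliers: opsins 1.0; anchors spread from 0.35 to
  1.25 (slow and fast families, the rate-heterogeneity confound); GNAI
  slowest at 0.5. Opsins and non-visual opsins are 150 aa, anchors
  60–110 aa.
* One jawless and one jawed species are designated reference species:
  their genes form the subtype reference alignments, so every classifier
  query is compared against rows from *different* terminal branches, as
  with curated reference sets in practice. Within-subtype query-to-
  reference divergence is ≈ 0.3 substitutions/site at these settings.

These values were chosen once as a realistic regime for the questions
the pipeline asks (deep WGD clades, moderate within-subtype divergence,
heterogeneous anchors); they are configuration, not fitted quantities.

## 3. Tandem-pair statistic

A pair event is an unordered pair of genes with **different** accepted
subtypes on the same species, chromosome and strand. The separation is
the inter-gene gap (nearest ends; 0 for overlapping genes), not
start-to-start — separation phrasing is robust to gene-length
differences; a start-to-start mode exists for sensitivity checks.
`proximal` means gap **strictly** less than the window (default
100,000 bp); equality lands in the distal (control) class. Same-subtype
pairs (e.g. species-specific LWS–LWS expansions) are excluded. Summaries
count every qualifying gene pair once by default; a per-species
collapsed mode is available since the natural counting unit is
debatable. Taxon-group percentages are shares of events per distance
class.

## 4. Subtype classifier

Queries are profile-aligned (global, affine gaps, BLOSUM62, open 10,
extend 1, ties preferring match > delete > insert) into the shared
column space of the reference database; insertions relative to the
references are dropped. Each of ≥100 column-bootstrap replicates votes
for the subtype with the smallest mean corrected distance over its
reference rows; support is the modal vote share, and a call is accepted
at support ≥ 0.95. This is a deliberate, desk-scale stand-in for
constrained maximum-likelihood placement; the 0.95 threshold mirrors the
common ultrafast-bootstrap reliability convention (the dual
aLRT/bootstrap convention collapses to a single support channel here —
the mapping is approximate). The non-visual outgroup class (OPN3 +
parapinopsin rows) makes "not a visual opsin" an explicit outcome.
Queries covering under half of the reference columns are reported
unalignable. A pre-WGD outgroup opsin, which predates the RH1/RH2
split, may still attract a confident call in some realizations — deep
outgroup placement by distances is genuinely unreliable, which is why
visual-opsin analyses restrict to ingroup queries.

## 5. Orthogroups and anchor selection

Orthogroup edges are cross-species reciprocal best hits by global
alignment score plus within-species pairs (in-paralog linking — without
it, WGD paralogs can never join their family). An edge requires both
alignment identity ≥ 0.3 **and** normalized score ≥ 0.1 (alignment
score over the smaller self-score): optimal global alignment inflates
percent identity between unrelated sequences of unequal length, and the
normalized score separates cleanly where identity does not. Orthogroups
are connected components — a deterministic, oracle-checkable
approximation to graph-clustering orthology pipelines, adequate here
because orthogroups serve only as the substrate for anchor selection.

An anchor family passes selection iff its focal-species members occupy
≥ 2 distinct opsin-bearing chromosomes and its members across the
jawless group occupy ≥ 3 distinct chromosomes, pooled across species
(per-species counting available via a flag). "Present on a chromosome"
means ≥ 1 member with that seq_id; scaffolds are not distinguished from
chromosomes.

## 6. Paralogon supermatrix and tree

Family alignments are concatenated keyed by *(species, chromosome)*;
a family absent from a chromosome contributes an all-gap segment, and a
chromosome carrying two members of one family keeps the member closest
to the family consensus (logged). Distances are corrected p-distances
over pairwise-comparable (both non-gap) columns — supermatrices are
gap-rich by construction, so pairwise deletion is the only workable
convention; pairs with no comparable columns in a bootstrap replicate
get the distance ceiling (5.0). Rows sharing < 10% of columns with some
partner are dropped greedily (worst offender first — a single gap-rich
row would otherwise condemn all its partners). Trees are canonical
neighbor joining with negative branch lengths clamped to 0 and Q-matrix
ties broken by lexicographically smallest taxon pair; supports are the
fraction of ≥ 100 column-bootstrap replicates containing each
bipartition of the full-data tree; rooting places the root mid-edge on
the branch separating a monophyletic outgroup. NJ + bootstrap replaces
likelihood inference deliberately: it is exact on additive matrices,
fast enough for tens of replicated experiments, and sufficient for the
clade questions asked of it.

## 7. Event-parsimony engine

The engine conditions on the WGD structure (shared WGD; per-lineage
WGD/triplication; cost 0, because genome-duplication history is
established by independent evidence) and searches histories of:

* pre-WGD tandem duplications (adjacent same-strand copies; post-WGD
  tandem expansions are out of scope),
* losses on any branch of the chromosome copy tree (one event removes
  the gene from every descendant copy; loss placement is Dollo-minimal),
* translocations on terminal branches.

Three semantic commitments make the comparison meaningful:

1. **Subtype clade consistency.** The surviving copies assigned one
   subtype must form a clade of the copy tree within a single ancestral
   gene instance. This is the arrangement-level meaning of "these genes
   are orthologous across lineages"; without it a one-ancestor
   hypothesis can relabel its copies freely and explains anything.
2. **Translocations target background chromosomes only** (default).
   Gene movement accounts for genes observed *outside* the paralogon;
   arrangements on paralogon chromosomes must be explained by descent
   and loss. Lifting this (`transloc_targets="any"`) lets competitors
   reconstruct conserved tandem adjacencies by ad-hoc gene movement,
   which weakens synteny evidence to the point where hypotheses tie.
3. **Paralogon clade ids are part of the observation.** The
   jawless-inclusive pattern carries the 1R-copy assignment of each
   chromosome as established by the paralogon tree. This is the decisive
   piece of evidence: the jawed LWS+SWS2 chromosome belongs to one 1R
   clade and the jawless SWS2-bearing chromosome to the other, which
   forces the SWS2 ancestor below the shared WGD and eliminates an
   otherwise co-optimal "SWS1/SWS2 split at 1R" alternative.

The search is exact within a declared envelope (≤ 5 pre-WGD genes ≤ 6
genes per observed chromosome, ≤ 3 tandem duplications, ≤ 3
translocations, ≤ 2 per chromosome); tandem expansions of single-subtype
labels are pruned because an extra copy could never carry a subtype and
would always be an immediate loss. Observed chromosomes may match in
either overall orientation (assembly orientation is arbitrary). All
co-optimal scenarios are reported, up to exchange of interchangeable
duplicate copies (leaves under the same stem); the unresolvable source
copy of a translocated gene (e.g. the lamprey SWS1) therefore appears as
multiple co-optimal scenarios rather than an arbitrary pick. Two
independent oracles back the engine in the test suite: literal
enumeration of event sets (tiny instances) and exhaustive enumeration of
survival patterns with brute-force loss counting.

Event weights default to 1 for tandem duplication, loss and
translocation; the optimality criterion is a weighted event count, with
the weights exposed in configuration because no principled calibration
exists at this scale.

## 8. Pipeline

Stages communicate only via files in the run directory (FASTA, GFF3,
TSV, Newick, YAML), so each stage is independently runnable and
testable. The manifest records the config digest, seed, package version,
per-stage statistics and a checksum for every output; reruns with the
same configuration are byte-identical. The orthogroup stage runs on a
three-species subset (focal jawless, one jawed, the outgroup) — enough
to select anchors while keeping the all-vs-all alignment cost small; the
paralogon stage then gathers anchor members across all species by family
annotation. The observed arrangement for the scenario stage is taken
from one representative species per group; chromosomes with no selected
anchor family are marked background, and clade ids are read off the two
ingroup children of the rooted paralogon tree.

## 9. Validation experiments and their scope

The validation suite (and `scripts/acceptance.py`) measures, on
synthetic data with known truth: exact agreement of the pair scanner
with a literal-definition oracle (100 random annotations); recovery of
the lineage-specific proximal-pair patterns over 20 simulation seeds;
the 6×/4× chromosome copy-number law; classifier accuracy of accepted
calls (≥ 99% at ≈ 0.3 substitutions/site within-subtype divergence);
exact neighbor-joining recovery on 200 random additive matrices (≤ 8
taxa); the concatenation advantage over 50 replicates (both 1R clades
reliable from the supermatrix while single anchor families fail in a
large fraction of attempts); scenario-engine/oracle agreement across an
envelope battery; and the hypothesis-ranking results shown in the
README. Problem sizes (seven species, ~460 genes, 10 anchor families,
≤ 1,000 supermatrix columns, 50 replicates) were chosen so the full
suite replays in minutes on one CPU.

What passing these experiments shows: the implementations are correct
against independent oracles and the method chain recovers a known
history under realistic rate heterogeneity. What it does not show: the
generator produces no indels, no assembly errors or scaffold breaks, no
pseudogenes, no teleost-style lineage-specific tandem expansions and no
incomplete lineage sorting, so performance on real assemblies —
where gene curation and completeness assessment dominate the effort —
is not established by these tests.

## 10. Known limitations

* Inversions are not modeled; a conserved pair on opposite strands
  (as produced by some assembly artifacts) does not count as a tandem
  pair and cannot be generated by the engine.
* Translocation search is terminal-branch only; a pre-triplication
  translocation hypothesis is expressible in replay but not searched.
* The classifier's single support channel approximates a dual
  aLRT/bootstrap convention; borderline calls may differ from a
  likelihood-based classifier.
* The hypothesis stepwise order is itself part of the hypothesis; an
  order permutation is a different hypothesis and must be scored
  separately.
* Scenario costs are event counts, not probabilities; no attempt is
  made to model rate differences between losses and translocations
  beyond user-set weights.
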