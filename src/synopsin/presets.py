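"""Default study conditions: the vertebrate opsin-paralogon scenario.

The default simulation emulates the qualitative history supported by
comparative lamprey/jawed-vertebrate genomics:

* a pre-WGD chromosome carrying a tandem opsin cluster
  (RH, LWS, SWS2, SWS1, all on the + strand) flanked by anchor gene
  families (F1..F7), transducin-alpha relatives (GNAT, GNAI) and a
  parapinopsin (PP);
* one WGD (1R) shared by jawless and jawed vertebrates, applied on the
  stem below their split;
* an independent genome triplication on the jawless stem (hexaploidy)
  and an independent WGD (2R) on the jawed stem;
* lineage-specific gene losses leaving the arrangements seen in extant
  genomes: a RH1+LWS tandem pair and a RH2+SWS2 tandem pair in jawless
  species (SWS1 translocated to another chromosome), and a single
  LWS+SWS2 tandem pair in jawed species with SWS1, RH2, RH1 alone on
  their own chromosomes;
* per-family substitution-rate multipliers (rate heterogeneity across
  genes, the standard confound for sequence-only phylogenies).

Species: three jawless, three jawed, plus a pre-WGD outgroup
("amphioxus"-like) that carries a single copy of every family.  One
species per side ("ref_*") supplies the subtype reference alignments, so
queries are classified against references from a different terminal
branch, as with curated reference sets in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import ReferenceDB
from .genomeio import TaxonTable
from .scenarios import (
    AncestralHypothesis,
    ObservedArrangement,
    ObservedChrom,
    VERTEBRATE_WGD,
    WGD,
    WgdStructure,
)
from .simulate import (
    AncestralGenome,
    EventRates,
    GenomeSet,
    ScriptedEvent,
    SpeciesTreeSpec,
    TruthHistory,
    evolve_sequences,
    random_root_proteins,
    simulate_history,
)

JAWLESS_SPECIES = ("sea_lamprey", "pouched_lamprey", "ref_jawless")
JAWED_SPECIES = ("spotted_gar", "chicken", "ref_jawed")
OUTGROUP_SPECIES = "amphioxus"
REFERENCE_SPECIES = ("ref_jawless", "ref_jawed")

VISUAL_FAMILIES = ("RH", "LWS", "SWS2", "SWS1")
ANCHOR_FAMILIES = ("F1", "F2", "F3", "F4", "F5", "F6", "F7")
NONVISUAL_LABEL = "nonvisual"

#: substitution-rate multiplier per family (opsins at 1.0; anchors spread
#: from slow to fast — the rate-heterogeneity confound)
DEFAULT_GENE_RATES: dict[str, float] = {
    "RH": 1.0, "LWS": 1.0, "SWS2": 1.0, "SWS1": 1.0,
    "GNAT": 0.8, "GNAI": 0.5, "PP": 0.9, "OPN3": 0.7,
    "F1": 0.35, "F2": 0.5, "F3": 0.65, "F4": 0.8, "F5": 0.95,
    "F6": 1.1, "F7": 1.25,
    "B1": 0.7, "B2": 0.7, "B3": 0.7,
}

GENE_LENGTHS: dict[str, int] = {
    "RH": 150, "LWS": 150, "SWS2": 150, "SWS1": 150,
    "OPN3": 150, "PP": 150, "GNAT": 120, "GNAI": 120,
    "F1": 60, "F2": 70, "F3": 80, "F4": 90, "F5": 100, "F6": 110, "F7": 75,
    "B1": 80, "B2": 80, "B3": 80,
}


def default_tree(divergence_scale: float = 1.0) -> SpeciesTreeSpec:
    s = divergence_scale
    newick = (
        f"({OUTGROUP_SPECIES}:{0.7 * s},"
        f"((sea_lamprey:{0.15 * s},pouched_lamprey:{0.15 * s},ref_jawless:{0.15 * s})jawless:{0.25 * s},"
        f"(spotted_gar:{0.15 * s},chicken:{0.15 * s},ref_jawed:{0.15 * s})jawed:{0.25 * s})vert:{0.3 * s}"
        f")anc;"
    )
    return SpeciesTreeSpec(
        newick=newick,
        wgd_events=(("vert", "WGD"), ("jawless", "TRIPLICATION"), ("jawed", "WGD")),
    )


def default_ancestor(intergene_gap_bp: int = 5000) -> AncestralGenome:
    return AncestralGenome(
        chromosomes={
            "O": (
                ("F1", "+"), ("GNAT", "+"),
                ("RH", "+"), ("LWS", "+"), ("SWS2", "+"), ("SWS1", "+"),
                ("F2", "+"), ("F3", "-"), ("GNAI", "+"), ("F4", "+"),
                ("F5", "-"), ("PP", "+"), ("F6", "+"), ("F7", "+"),
            ),
            "X": (("B1", "+"), ("OPN3", "+"), ("B2", "-"), ("B3", "+")),
        },
        gene_lengths=dict(GENE_LENGTHS),
        intergene_gap_bp=intergene_gap_bp,
    )


def _loss(branch: str, chrom: str, family: str) -> ScriptedEvent:
    return ScriptedEvent(branch=branch, kind="LOSS", chrom=chrom, family=family)


def default_scripted_events() -> tuple[ScriptedEvent, ...]:
    """Configured losses and the jawless SWS1 translocation.

    Applied after the triplication (jawless stem) / second WGD (jawed
    stem), so they are shared by every species of each side."""
    ev: list[ScriptedEvent] = []
    # jawless side: keep RH1+LWS on O_A_A, RH2+SWS2 on O_B_A,
    # move SWS1 from O_A_A to chromosome X_A_A
    ev.append(
        ScriptedEvent(
            branch="jawless", kind="TRANSLOCATION", chrom="O_A_A",
            family="SWS1", target_chrom="X_A_A", position=2, strand="+",
        )
    )
    ev.append(_loss("jawless", "O_A_A", "SWS2"))
    for fam in VISUAL_FAMILIES:
        ev.append(_loss("jawless", "O_A_B", fam))
        ev.append(_loss("jawless", "O_A_C", fam))
        ev.append(_loss("jawless", "O_B_B", fam))
        ev.append(_loss("jawless", "O_B_C", fam))
    ev.append(_loss("jawless", "O_B_A", "LWS"))
    ev.append(_loss("jawless", "O_B_A", "SWS1"))
    # a couple of anchor gaps (partial data, as in real assemblies)
    ev.append(_loss("jawless", "O_A_C", "F7"))
    ev.append(_loss("jawless", "O_B_B", "F5"))
    # jawed side: RH1 alone (O_A_A), LWS+SWS2 tandem (O_A_B),
    # RH2 alone (O_B_A), SWS1 alone (O_B_B)
    for fam in ("LWS", "SWS2", "SWS1"):
        ev.append(_loss("jawed", "O_A_A", fam))
    for fam in ("RH", "SWS1"):
        ev.append(_loss("jawed", "O_A_B", fam))
    for fam in ("LWS", "SWS2", "SWS1"):
        ev.append(_loss("jawed", "O_B_A", fam))
    for fam in ("RH", "LWS", "SWS2"):
        ev.append(_loss("jawed", "O_B_B", fam))
    return tuple(ev)


def truth_subtype(gene_id: str, family: str | None) -> str | None:
    """Truth subtype of a simulated gene.

    RH resolves to RH1/RH2 by its first WGD copy letter (the shared WGD
    copy the lineage descends from); LWS/SWS1/SWS2 are their own
    subtypes; everything else (and the pre-WGD outgroup's unsplit RH)
    has no visual subtype."""
    if family in ("LWS", "SWS1", "SWS2"):
        return family
    if family == "RH":
        parts = gene_id.split(".")
        if len(parts) < 2 or parts[1] not in ("A", "B"):
            return None
        return "RH1" if parts[1] == "A" else "RH2"
    return None


@dataclass
class ScenarioBundle:
    """Everything the default simulation produces."""

    tree: SpeciesTreeSpec
    ancestor: AncestralGenome
    truth: TruthHistory
    genomes: GenomeSet
    taxa: TaxonTable
    gene_rates: dict[str, float]
    root_proteins: dict[str, str] = field(default_factory=dict)
    reference_db: ReferenceDB | None = None

    def truth_subtypes(self, species: str) -> dict[str, str]:
        """gene_id -> truth subtype for one species (visual opsins only)."""
        out = {}
        for g in self.genomes.species[species]:
            s = truth_subtype(g.gene_id, g.family)
            if s is not None:
                out[g.gene_id] = s
        return out

    def labelled_genes(self, species: str | None = None, use_truth: bool = True):
        """Gene records with truth subtype labels attached (copies)."""
        from dataclasses import replace

        species_list = [species] if species else sorted(self.genomes.species)
        out = []
        for sp in species_list:
            labels = self.truth_subtypes(sp)
            for g in self.genomes.species[sp]:
                out.append(replace(g, subtype=labels.get(g.gene_id)))
        return out


def default_taxa() -> TaxonTable:
    groups = {sp: "jawless" for sp in JAWLESS_SPECIES}
    groups.update({sp: "non-teleost jawed" for sp in JAWED_SPECIES})
    groups[OUTGROUP_SPECIES] = "outgroup"
    return TaxonTable(groups)


def make_reference_db(bundle: ScenarioBundle) -> ReferenceDB:
    """Build subtype reference alignments from the designated reference
    species (one jawless, one jawed), plus a non-visual outgroup class
    from OPN3 and parapinopsin sequences.

    The simulator produces no indels, so same-length rows are already
    aligned."""
    subtypes: dict[str, dict[str, str]] = {}
    for sp in REFERENCE_SPECIES:
        labels = bundle.truth_subtypes(sp)
        for g in bundle.genomes.species[sp]:
            if g.protein is None:
                continue
            sub = labels.get(g.gene_id)
            if sub is not None:
                subtypes.setdefault(sub, {})[f"{sp}.{g.gene_id}"] = g.protein
            elif g.family in ("OPN3", "PP"):
                subtypes.setdefault(NONVISUAL_LABEL, {})[
                    f"{sp}.{g.gene_id}"
                ] = g.protein
    return ReferenceDB(subtypes)


def paper_scenario(
    seed: int,
    divergence_scale: float = 1.0,
    with_sequences: bool = True,
    rates: EventRates = EventRates(),
    intergene_gap_bp: int = 5000,
) -> ScenarioBundle:
    """Simulate the default vertebrate opsin-paralogon scenario.

    Structural events are the configured (scripted) ones plus any
    stochastic ``rates``; sequence evolution, root proteins and any
    stochastic placement derive from ``seed``."""
    tree = default_tree(divergence_scale)
    ancestor = default_ancestor(intergene_gap_bp)
    truth, genomes = simulate_history(
        tree, ancestor, rates, seed=seed, scripted=default_scripted_events()
    )
    bundle = ScenarioBundle(
        tree=tree,
        ancestor=ancestor,
        truth=truth,
        genomes=genomes,
        taxa=default_taxa(),
        gene_rates=dict(DEFAULT_GENE_RATES),
    )
    if with_sequences:
        root_proteins = random_root_proteins(
            ancestor.families, ancestor.gene_lengths, seed=seed + 10_007
        )
        bundle.root_proteins = root_proteins
        bundle.genomes = evolve_sequences(
            truth, root_proteins, DEFAULT_GENE_RATES, seed=seed + 20_011
        )
        bundle.reference_db = make_reference_db(bundle)
    return bundle


# ---------------------------------------------------------------------------
# hypotheses and observed patterns for the scenario engine


def hypothesis_stepwise() -> AncestralHypothesis:
    """Five separate pre-WGD opsin genes, one per extant subtype
    (the sequence-phylogeny-inspired scenario)."""
    return AncestralHypothesis.build(
        "stepwise_five_gene",
        order=[("LWS", "+"), ("SWS1", "+"), ("SWS2", "+"), ("RH2", "+"), ("RH1", "+")],
        mapping={
            "LWS": ["LWS"], "SWS1": ["SWS1"], "SWS2": ["SWS2"],
            "RH2": ["RH2"], "RH1": ["RH1"],
        },
    )


def hypothesis_single_tandem() -> AncestralHypothesis:
    """One pre-WGD tandem pair: LWS plus a single ancestor of the four
    other subtypes, which then diversified in the WGDs
    (the jawed-vertebrate synteny scenario)."""
    return AncestralHypothesis.build(
        "single_tandem_two_gene",
        order=[("LWS", "+"), ("AO", "+")],
        mapping={"LWS": ["LWS"], "AO": ["SWS1", "SWS2", "RH2", "RH1"]},
    )


def hypothesis_tandem_cluster() -> AncestralHypothesis:
    """Pre-WGD tandem cluster of four genes with the rod/green opsin
    split occurring at the shared WGD (RH -> RH1/RH2)."""
    return AncestralHypothesis.build(
        "tandem_cluster_rh_split_at_wgd",
        order=[("RH", "+"), ("LWS", "+"), ("SWS2", "+"), ("SWS1", "+")],
        mapping={
            "RH": ["RH1", "RH2"], "LWS": ["LWS"],
            "SWS2": ["SWS2"], "SWS1": ["SWS1"],
        },
    )


def default_hypotheses() -> list[AncestralHypothesis]:
    return [
        hypothesis_stepwise(),
        hypothesis_single_tandem(),
        hypothesis_tandem_cluster(),
    ]


JAWED_ONLY_WGD = WgdStructure(shared=(WGD,), groups=(("jawed", (WGD,)),))


def observed_jawed_only() -> ObservedArrangement:
    """The jawed-vertebrate pattern: one LWS+SWS2 tandem pair; SWS1, RH2
    and RH1 alone on three other paralogon chromosomes."""
    return ObservedArrangement.from_dict(
        {
            "jawed": [
                ObservedChrom("ja1", (("LWS", "+"), ("SWS2", "+"))),
                ObservedChrom("ja2", (("SWS1", "+"),)),
                ObservedChrom("ja3", (("RH2", "+"),)),
                ObservedChrom("ja4", (("RH1", "+"),)),
            ]
        }
    )


def observed_vertebrate() -> ObservedArrangement:
    """The jawless-inclusive pattern: lamprey RH1+LWS and RH2+SWS2 tandem
    pairs with SWS1 on a background chromosome (translocated), plus the
    jawed pattern.

    Chromosomes carry the paralogon-clade identities established by the
    chromosome-keyed supermatrix tree: the RH1-bearing chromosomes of
    both lineages and the jawed LWS+SWS2 chromosome belong to one
    shared-WGD clade ("A"), the RH2-bearing and jawed SWS1 chromosomes
    to the other ("B").  The jawless SWS1 chromosome is outside the
    paralogon (translocation target), so it carries no clade."""
    return ObservedArrangement.from_dict(
        {
            "jawless": [
                ObservedChrom("jl1", (("RH1", "+"), ("LWS", "+")), clade="A"),
                ObservedChrom("jl2", (("RH2", "+"), ("SWS2", "+")), clade="B"),
                ObservedChrom("jl3", (("SWS1", "+"),), background=True),
            ],
            "jawed": [
                ObservedChrom("ja1", (("LWS", "+"), ("SWS2", "+")), clade="A"),
                ObservedChrom("ja2", (("SWS1", "+"),), clade="B"),
                ObservedChrom("ja3", (("RH2", "+"),), clade="B"),
                ObservedChrom("ja4", (("RH1", "+"),), clade="A"),
            ],
        }
    )
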