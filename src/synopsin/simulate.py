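"""Synthetic genome simulator with an explicit duplication-history ledger.

Generates annotated genomes (gene coordinates + protein sequences) for a
set of species under a configurable history of whole-genome duplications
(WGD), genome triplications, tandem duplications, gene losses and
single-gene translocations.  Every event is recorded in a ``TruthHistory``
ledger so downstream inference stages can be scored against known truth.

Model conventions
-----------------
* The species tree is a rooted Newick string with labelled internal nodes;
  a branch is identified by the label of its child node.  The root node's
  own edge is a usable branch (for events shared by all species).
* Events listed for a branch are applied at the START of that branch,
  before the branch's sequence evolution: duplication copies are
  identical at creation and then diverge along the remainder of the
  branch.  (A WGD on the stem below a speciation therefore precedes the
  speciation, as it must.)  Chromosome ids encode their copy path
  (``chr1`` -> ``chr1_A``, ``chr1_B`` [, ``chr1_C``]).
* Stochastic events are drawn per branch with Poisson counts
  (rate x branch length, losses and translocations additionally x gene
  count) and uniform placement over eligible genes.  Deterministic
  "scripted" events can be given instead of, or in addition to, rates;
  they are applied after the branch's WGDs in the order given.
* Protein evolution uses a 20-state continuous-time model with equal
  exchangeabilities and equal equilibrium frequencies; the probability
  that a site differs from its ancestor after d expected substitutions
  per site is (19/20) * (1 - exp(-(20/19) d)).  No indels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomeio import (
    GeneRecord,
    read_fasta,
    read_gff3,
    write_fasta,
    write_gff3,
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

WGD = "WGD"
TRIPLICATION = "TRIPLICATION"
TANDEM_DUP = "TANDEM_DUP"
LOSS = "LOSS"
TRANSLOCATION = "TRANSLOCATION"

_COPY_LETTERS = "ABC"


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# inputs


@dataclass(frozen=True)
class SpeciesTreeSpec:
    """Rooted species tree plus the WGD events placed on its branches."""

    newick: str
    wgd_events: tuple[tuple[str, str], ...] = ()
    branch_rate_multipliers: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class AncestralGenome:
    """Gene content of the pre-duplication ancestor.

    ``chromosomes`` maps chromosome id to an ordered list of
    (family label, strand); family labels must be unique genome-wide.
    ``gene_lengths`` are protein lengths in amino acids (>= 50).
    """

    chromosomes: Mapping[str, tuple[tuple[str, str], ...]]
    gene_lengths: Mapping[str, int]
    intergene_gap_bp: int = 5000

    def __post_init__(self):
        seen: set[str] = set()
        for chrom, genes in self.chromosomes.items():
            for fam, strand in genes:
                if fam in seen:
                    raise SimulationError(f"family label {fam!r} not unique in ancestor")
                seen.add(fam)
                if strand not in ("+", "-"):
                    raise SimulationError(f"bad strand {strand!r} for {fam}")
                if fam not in self.gene_lengths:
                    raise SimulationError(f"no gene length for family {fam!r}")
        for fam, L in self.gene_lengths.items():
            if L < 50:
                raise SimulationError(f"gene length for {fam!r} must be >= 50 aa")
        if self.intergene_gap_bp <= 0:
            raise SimulationError("intergene_gap_bp must be positive")

    @property
    def families(self) -> list[str]:
        return [fam for genes in self.chromosomes.values() for fam, _ in genes]


@dataclass(frozen=True)
class EventRates:
    """Per-branch stochastic event rates (all >= 0, per unit branch length)."""

    tandem_dup: float = 0.0  # expected tandem duplications per branch-length unit
    loss: float = 0.0  # per gene per branch-length unit
    translocation: float = 0.0  # per gene per branch-length unit

    def __post_init__(self):
        for name in ("tandem_dup", "loss", "translocation"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise SimulationError(f"rate {name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class ScriptedEvent:
    """A deterministic event placed on a named branch.

    The gene is selected by (chromosome id, family); the selector must be
    unambiguous at the time the event applies.  ``kind`` is one of
    TANDEM_DUP, LOSS, TRANSLOCATION; translocations additionally name the
    target chromosome, insertion index and strand.
    """

    branch: str
    kind: str
    chrom: str
    family: str
    target_chrom: str | None = None
    position: int | None = None
    strand: str | None = None


# ---------------------------------------------------------------------------
# internal tree


@dataclass
class _SimNode:
    node_id: str
    length: float
    children: list["_SimNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


def _parse_species_tree(spec: SpeciesTreeSpec) -> _SimNode:
    import dendropy

    tree = dendropy.Tree.get(
        data=spec.newick, schema="newick", suppress_internal_node_taxa=False
    )
    counter = [0]

    def convert(nd) -> _SimNode:
        if nd.taxon is not None:
            label = nd.taxon.label
        elif nd.label:
            label = nd.label
        else:
            counter[0] += 1
            label = f"node{counter[0]}"
        length = nd.edge.length if nd.edge.length is not None else 0.0
        out = _SimNode(label.replace(" ", "_"), float(length))
        for ch in nd.child_nodes():
            out.children.append(convert(ch))
        return out

    root = convert(tree.seed_node)
    ids = [n.node_id for n in _preorder(root)]
    if len(set(ids)) != len(ids):
        raise SimulationError(f"duplicate branch ids in species tree: {ids}")
    for branch, kind in spec.wgd_events:
        if branch not in ids:
            raise SimulationError(f"WGD event on unknown branch {branch!r}")
        if kind not in (WGD, TRIPLICATION):
            raise SimulationError(f"unknown WGD kind {kind!r}")
    for branch, mult in spec.branch_rate_multipliers.items():
        if branch not in ids:
            raise SimulationError(f"rate multiplier on unknown branch {branch!r}")
        if not mult > 0:
            raise SimulationError(f"rate multiplier for {branch!r} must be > 0")
    return root


def _preorder(node: _SimNode):
    yield node
    for c in node.children:
        yield from _preorder(c)


# ---------------------------------------------------------------------------
# truth ledger and genome containers


@dataclass
class SimGene:
    gene_id: str
    family: str
    strand: str


Genome = dict[str, list[SimGene]]  # chromosome id -> ordered genes


@dataclass
class Event:
    kind: str
    branch: str
    affected: tuple[str, ...]
    resulting: tuple[str, ...]
    detail: str = ""


@dataclass
class TruthHistory:
    """Complete ledger of the simulated history.

    Beyond the event list and ancestry maps, it retains the per-node genome
    snapshots and duplication maps needed to evolve sequences along the
    same history.
    """

    events: list[Event]
    gene_ancestry: dict[str, str]
    chromosome_ancestry: dict[str, tuple[str, tuple[str, ...]]]
    ancestor: AncestralGenome
    tree_spec: SpeciesTreeSpec
    _tree: _SimNode
    _node_genomes: dict[str, Genome]
    _dup_sources: dict[str, dict[str, str]]  # branch -> new gene id -> source id

    def leaf_species(self) -> list[str]:
        return [n.node_id for n in _preorder(self._tree) if n.is_leaf]

    def genome_of(self, species: str) -> Genome:
        return self._node_genomes[species]

    def copy_path(self, chrom_id: str) -> tuple[str, ...]:
        return self.chromosome_ancestry[chrom_id][1]

    def events_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [e.kind for e in self.events],
                "branch": [e.branch for e in self.events],
                "affected": [",".join(e.affected) for e in self.events],
                "resulting": [",".join(e.resulting) for e in self.events],
                "detail": [e.detail for e in self.events],
            }
        )

    def family_copy_number(self, species: str, family: str) -> int:
        return sum(
            1
            for genes in self.genome_of(species).values()
            for g in genes
            if g.family == family
        )

    def chromosome_copies(self, species: str, root_chrom: str) -> list[str]:
        return sorted(
            c
            for c in self.genome_of(species)
            if self.chromosome_ancestry[c][0] == root_chrom
        )


@dataclass
class GenomeSet:
    """Extant annotated genomes, one gene table per species."""

    species: dict[str, list[GeneRecord]]
    chromosome_lengths: dict[str, dict[str, int]]

    def proteomes(self) -> dict[str, dict[str, str]]:
        return {
            sp: {g.gene_id: g.protein or "" for g in genes}
            for sp, genes in self.species.items()
        }


# ---------------------------------------------------------------------------
# structural simulation


def _expected_leaf_sizes(
    root: _SimNode, n0: int, rates: EventRates, wgd_by_branch: dict[str, list[str]]
) -> float:
    """Loss-free upper bound on expected extant gene counts (runaway guard)."""

    def rec(node: _SimNode, n: float) -> float:
        n = n + rates.tandem_dup * node.length
        for kind in wgd_by_branch.get(node.node_id, []):
            n *= 2 if kind == WGD else 3
        if node.is_leaf:
            return n
        return max(rec(c, n) for c in node.children)

    return rec(root, float(n0))


def _sorted_genes(genome: Genome) -> list[tuple[str, int, SimGene]]:
    out = []
    for chrom in sorted(genome):
        for i, g in enumerate(genome[chrom]):
            out.append((chrom, i, g))
    return out


def simulate_history(
    tree: SpeciesTreeSpec,
    ancestor: AncestralGenome,
    rates: EventRates,
    seed: int,
    scripted: Sequence[ScriptedEvent] = (),
    max_expected_genes: int = 10_000,
) -> tuple[TruthHistory, GenomeSet]:
    """Simulate the structural history; sequences are placeholders (None).

    Returns the truth ledger and a coordinate-complete GenomeSet whose
    proteins are filled in later by :func:`evolve_sequences`.
    """
    root = _parse_species_tree(tree)
    rng = np.random.default_rng(seed)

    wgd_by_branch: dict[str, list[str]] = {}
    for branch, kind in tree.wgd_events:
        wgd_by_branch.setdefault(branch, []).append(kind)
    scripted_by_branch: dict[str, list[ScriptedEvent]] = {}
    for ev in scripted:
        scripted_by_branch.setdefault(ev.branch, []).append(ev)

    n0 = len(ancestor.families)
    exp_size = _expected_leaf_sizes(root, n0, rates, wgd_by_branch)
    if exp_size > max_expected_genes:
        raise SimulationError(
            f"expected extant genome size {exp_size:.0f} exceeds cap "
            f"{max_expected_genes} (runaway duplication)"
        )

    events: list[Event] = []
    gene_parent: dict[str, str] = {}
    chrom_anc: dict[str, tuple[str, tuple[str, ...]]] = {}
    node_genomes: dict[str, Genome] = {}
    dup_sources: dict[str, dict[str, str]] = {}
    tandem_counter = [0]

    root_genome: Genome = {}
    for chrom, genes in ancestor.chromosomes.items():
        root_genome[chrom] = [SimGene(fam, fam, strand) for fam, strand in genes]
        chrom_anc[chrom] = (chrom, ())

    def apply_wgd(genome: Genome, kind: str, branch: str) -> Genome:
        ncopies = 2 if kind == WGD else 3
        new: Genome = {}
        affected, resulting = [], []
        for chrom in sorted(genome):
            for letter in _COPY_LETTERS[:ncopies]:
                new_chrom = f"{chrom}_{letter}"
                rootc, path = chrom_anc[chrom]
                chrom_anc[new_chrom] = (rootc, path + (letter,))
                copy = []
                for g in genome[chrom]:
                    gid = f"{g.gene_id}.{letter}"
                    gene_parent[gid] = g.gene_id
                    dup_sources[branch][gid] = g.gene_id
                    copy.append(SimGene(gid, g.family, g.strand))
                    resulting.append(gid)
                new[new_chrom] = copy
            affected.extend(g.gene_id for g in genome[chrom])
        events.append(Event(kind, branch, tuple(affected), tuple(resulting)))
        return new

    def find_gene(genome: Genome, chrom: str, family: str) -> int:
        if chrom not in genome:
            raise SimulationError(f"scripted event: no chromosome {chrom!r}")
        hits = [i for i, g in enumerate(genome[chrom]) if g.family == family]
        if len(hits) != 1:
            raise SimulationError(
                f"scripted event selector ({chrom!r}, {family!r}) matched {len(hits)} genes"
            )
        return hits[0]

    def do_tandem(genome: Genome, chrom: str, idx: int, branch: str) -> None:
        g = genome[chrom][idx]
        tandem_counter[0] += 1
        gid = f"{g.gene_id}.t{tandem_counter[0]}"
        gene_parent[gid] = g.gene_id
        dup_sources[branch][gid] = g.gene_id
        genome[chrom].insert(idx + 1, SimGene(gid, g.family, g.strand))
        events.append(Event(TANDEM_DUP, branch, (g.gene_id,), (gid,), detail=chrom))

    def do_loss(genome: Genome, chrom: str, idx: int, branch: str) -> None:
        g = genome[chrom].pop(idx)
        events.append(Event(LOSS, branch, (g.gene_id,), (), detail=chrom))

    def do_transloc(
        genome: Genome, chrom: str, idx: int, branch: str,
        target: str, position: int, strand: str,
    ) -> None:
        g = genome[chrom].pop(idx)
        moved = SimGene(g.gene_id, g.family, strand)
        genome.setdefault(target, []).insert(position, moved)
        events.append(
            Event(TRANSLOCATION, branch, (g.gene_id,), (g.gene_id,),
                  detail=f"{chrom}->{target}:{position}:{strand}")
        )

    def process(node: _SimNode, parent_genome: Genome) -> None:
        branch = node.node_id
        dup_sources[branch] = {}
        genome: Genome = {c: list(gs) for c, gs in parent_genome.items()}
        for kind in wgd_by_branch.get(branch, []):
            genome = apply_wgd(genome, kind, branch)
        for ev in scripted_by_branch.get(branch, []):
            idx = find_gene(genome, ev.chrom, ev.family)
            if ev.kind == LOSS:
                do_loss(genome, ev.chrom, idx, branch)
            elif ev.kind == TANDEM_DUP:
                do_tandem(genome, ev.chrom, idx, branch)
            elif ev.kind == TRANSLOCATION:
                if ev.target_chrom is None or ev.strand is None:
                    raise SimulationError("scripted translocation needs target_chrom and strand")
                pos = ev.position
                tgt_len = len(genome.get(ev.target_chrom, []))
                if pos is None or pos > tgt_len:
                    pos = tgt_len
                do_transloc(genome, ev.chrom, idx, branch, ev.target_chrom, pos, ev.strand)
            else:
                raise SimulationError(f"unknown scripted event kind {ev.kind!r}")
        L = node.length
        if L > 0 and (rates.tandem_dup or rates.loss or rates.translocation):
            ngenes = sum(len(gs) for gs in genome.values())
            n_td = rng.poisson(rates.tandem_dup * L)
            n_loss = rng.poisson(rates.loss * L * ngenes)
            n_tr = rng.poisson(rates.translocation * L * ngenes)
            for _ in range(n_td):
                flat = _sorted_genes(genome)
                if not flat:
                    break
                chrom, idx, _g = flat[rng.integers(len(flat))]
                do_tandem(genome, chrom, idx, branch)
            for _ in range(n_loss):
                flat = _sorted_genes(genome)
                if not flat:
                    break
                chrom, idx, _g = flat[rng.integers(len(flat))]
                do_loss(genome, chrom, idx, branch)
            for _ in range(n_tr):
                flat = _sorted_genes(genome)
                others_exist = len(genome) > 1
                if not flat or not others_exist:
                    break
                chrom, idx, _g = flat[rng.integers(len(flat))]
                targets = sorted(c for c in genome if c != chrom)
                target = targets[rng.integers(len(targets))]
                pos = int(rng.integers(len(genome[target]) + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                do_transloc(genome, chrom, idx, branch, target, pos, strand)
        node_genomes[branch] = genome
        for child in node.children:
            process(child, genome)

    process(root, root_genome)

    gene_ancestry: dict[str, str] = {}

    def resolve_root(gid: str) -> str:
        cur = gid
        while cur in gene_parent:
            cur = gene_parent[cur]
        return cur

    for node in _preorder(root):
        if node.is_leaf:
            for genes in node_genomes[node.node_id].values():
                for g in genes:
                    gene_ancestry[g.gene_id] = resolve_root(g.gene_id)

    truth = TruthHistory(
        events=events,
        gene_ancestry=gene_ancestry,
        chromosome_ancestry=chrom_anc,
        ancestor=ancestor,
        tree_spec=tree,
        _tree=root,
        _node_genomes=node_genomes,
        _dup_sources=dup_sources,
    )
    return truth, _layout_genomes(truth, sequences=None)


def _layout_genomes(
    truth: TruthHistory, sequences: dict[str, dict[str, str]] | None
) -> GenomeSet:
    """Assign coordinates: genes left-to-right with fixed intergenic gaps."""
    anc = truth.ancestor
    gap = anc.intergene_gap_bp
    species_tables: dict[str, list[GeneRecord]] = {}
    chrom_lengths: dict[str, dict[str, int]] = {}
    for sp in truth.leaf_species():
        genes_out: list[GeneRecord] = []
        lengths: dict[str, int] = {}
        genome = truth.genome_of(sp)
        for chrom in sorted(genome):
            pos = gap
            for g in genome[chrom]:
                aa_len = anc.gene_lengths[g.family]
                bp_len = aa_len * 3
                prot = None
                if sequences is not None:
                    prot = sequences[sp][g.gene_id]
                genes_out.append(
                    GeneRecord(
                        gene_id=g.gene_id,
                        species=sp,
                        seq_id=chrom,
                        start=pos,
                        end=pos + bp_len,
                        strand=g.strand,
                        protein=prot,
                        family=g.family,
                    )
                )
                pos += bp_len + gap
            lengths[chrom] = pos
        species_tables[sp] = genes_out
        chrom_lengths[sp] = lengths
    return GenomeSet(species=species_tables, chromosome_lengths=chrom_lengths)


# ---------------------------------------------------------------------------
# sequence evolution


def encode_protein(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[a] for a in seq], dtype=np.uint8)
    except KeyError as exc:
        raise SimulationError(f"unknown amino-acid symbol {exc.args[0]!r}") from None


def decode_protein(codes: np.ndarray) -> str:
    return "".join(AA_ALPHABET[int(i)] for i in codes)


def p_differ(d: float) -> float:
    """Expected fraction of differing sites after d substitutions per site
    under the equal-exchangeability 20-state model."""
    return (19.0 / 20.0) * (1.0 - math.exp(-(20.0 / 19.0) * d))


def _evolve_codes(codes: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    if d <= 0:
        return codes.copy()
    p = p_differ(d)
    mask = rng.random(codes.shape[0]) < p
    out = codes.copy()
    n = int(mask.sum())
    if n:
        # uniform over the 19 other states
        offsets = rng.integers(1, 20, size=n, dtype=np.uint8)
        out[mask] = (out[mask] + offsets) % 20
    return out


def evolve_sequences(
    truth: TruthHistory,
    root_proteins: Mapping[str, str],
    per_gene_rates: Mapping[str, float],
    seed: int,
) -> GenomeSet:
    """Evolve proteins along the simulated history and return the complete
    GenomeSet (coordinates + sequences).

    ``root_proteins`` maps family label -> ancestral protein;
    ``per_gene_rates`` maps family label -> rate multiplier (missing
    families default to 1.0).  The expected substitutions per site on a
    branch are branch length x branch multiplier x gene multiplier.
    """
    rng = np.random.default_rng(seed)
    anc = truth.ancestor
    for fam in anc.families:
        if fam not in root_proteins:
            raise SimulationError(f"no root protein for family {fam!r}")
        if len(root_proteins[fam]) != anc.gene_lengths[fam]:
            raise SimulationError(
                f"root protein length for {fam!r} does not match gene_lengths"
            )
    for mult in per_gene_rates.values():
        if not mult > 0:
            raise SimulationError("per-gene rate multipliers must be > 0")

    branch_mult = dict(truth.tree_spec.branch_rate_multipliers)
    leaf_seqs: dict[str, dict[str, str]] = {}

    root_codes = {fam: encode_protein(root_proteins[fam]) for fam in anc.families}

    def process(node: _SimNode, parent_seqs: dict[str, np.ndarray]) -> None:
        branch = node.node_id
        bmult = branch_mult.get(branch, 1.0)
        genome = truth._node_genomes[branch]
        dup = truth._dup_sources.get(branch, {})

        def start_seq(gid: str) -> np.ndarray:
            # the branch's events apply at its start: a duplicate seeds
            # from its source's start-of-branch sequence
            cur = gid
            while cur not in parent_seqs:
                cur = dup[cur]
            return parent_seqs[cur]

        seqs: dict[str, np.ndarray] = {}
        for chrom in sorted(genome):
            for g in genome[chrom]:
                gmult = per_gene_rates.get(g.family, 1.0)
                d = node.length * bmult * gmult
                seqs[g.gene_id] = _evolve_codes(start_seq(g.gene_id), d, rng)
        if node.is_leaf:
            leaf_seqs[branch] = {gid: decode_protein(c) for gid, c in seqs.items()}
        for child in node.children:
            process(child, seqs)

    process(truth._tree, root_codes)
    return _layout_genomes(truth, sequences=leaf_seqs)


# ---------------------------------------------------------------------------
# file output


def write_genome_set(gs: GenomeSet, truth: TruthHistory, outdir: str | Path) -> None:
    """Write one protein FASTA + one GFF3 per species, plus the truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp, genes in gs.species.items():
        write_gff3(genes, outdir / f"{sp}.gff3")
        seqs = {g.gene_id: g.protein for g in genes if g.protein is not None}
        write_fasta(seqs, outdir / f"{sp}.faa")
    truth.events_df().to_csv(outdir / "truth_events.tsv", sep="\t", index=False)


def read_genome_set(outdir: str | Path) -> GenomeSet:
    """Re-read what :func:`write_genome_set` wrote (coordinates + proteins)."""
    outdir = Path(outdir)
    species: dict[str, list[GeneRecord]] = {}
    chrom_lengths: dict[str, dict[str, int]] = {}
    for gff in sorted(outdir.glob("*.gff3")):
        sp = gff.stem
        genes = read_gff3(gff, species=sp)
        faa = outdir / f"{sp}.faa"
        seqs = read_fasta(faa) if faa.exists() else {}
        for g in genes:
            g.protein = seqs.get(g.gene_id)
        species[sp] = genes
        lengths: dict[str, int] = {}
        for g in genes:
            lengths[g.seq_id] = max(lengths.get(g.seq_id, 0), g.end)
        chrom_lengths[sp] = lengths
    return GenomeSet(species=species, chromosome_lengths=chrom_lengths)


def random_root_proteins(
    families: Sequence[str], lengths: Mapping[str, int], seed: int
) -> dict[str, str]:
    """Independent uniform-random root proteins, one per family."""
    rng = np.random.default_rng(seed)
    return {
        fam: decode_protein(rng.integers(0, 20, size=lengths[fam]).astype(np.uint8))
        for fam in families
    }
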