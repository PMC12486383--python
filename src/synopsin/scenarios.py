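"""Event-parsimony reconstruction of tandem-duplication / WGD histories.

Given the observed arrangement of opsin subtypes on paralogon chromosomes
in two vertebrate lineages and a FIXED whole-genome-duplication structure
(one shared WGD; an extra WGD in one lineage, a triplication in the
other), find the minimum-cost history of pre-WGD tandem duplications,
gene losses and single-gene translocations that explains the observation
under a given hypothesis about the pre-WGD ancestral gene cluster.

Model
-----
* The WGD structure is conditioned on, not inferred: WGD/triplication
  events carry cost 0.  The copy tree of the ancestral chromosome is
  fixed by the structure: a root chromosome, its shared-WGD copies, then
  per-lineage stem branches and per-lineage WGD/triplication copies
  (the extant "leaves").
* A hypothesis supplies the pre-WGD ancestral gene order (each gene an
  "instance" with a label and strand) and a mapping from labels to the
  extant subtypes they may give rise to.
* Searched events: TANDEM_DUP (pre-WGD only: inserts an adjacent
  same-strand copy), LOSS (any branch of the copy tree; one event
  deletes the gene from every descendant copy), TRANSLOCATION (moves one
  extant gene copy to another chromosome; restricted to terminal
  branches in the search, unrestricted in replay).
* Subtype assignments must be clade-consistent: the surviving copies
  assigned one subtype must form a clade of the copy tree within a
  single gene instance (this is what "orthologous subtypes" means here).
* Chromosomes are compared as ordered, strand-aware gene lists; an
  observed chromosome may match in either overall orientation (assembly
  orientation is arbitrary).  Co-optimal scenarios are all reported, up
  to exchange of interchangeable duplicate copies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

WGD = "WGD"
TRIPLICATION = "TRIPLICATION"
TANDEM_DUP = "TANDEM_DUP"
LOSS = "LOSS"
TRANSLOCATION = "TRANSLOCATION"

DEFAULT_WEIGHTS: dict[str, float] = {TANDEM_DUP: 1.0, LOSS: 1.0, TRANSLOCATION: 1.0}

_COPY_LETTERS = "ABC"


def _flip_strand(s: str) -> str:
    return "-" if s == "+" else "+"


def flip_arrangement(genes: Sequence[tuple[str, str]]) -> tuple[tuple[str, str], ...]:
    """Reverse a chromosome and flip every strand (opposite assembly
    orientation of the same physical arrangement)."""
    return tuple((lab, _flip_strand(st)) for lab, st in reversed(genes))


# ---------------------------------------------------------------------------
# structures


@dataclass(frozen=True)
class WgdStructure:
    """Fixed WGD history: shared events, then per-group lineage events."""

    shared: tuple[str, ...]
    groups: tuple[tuple[str, tuple[str, ...]], ...]

    def group_names(self) -> list[str]:
        return [g for g, _ in self.groups]

    def group_events(self, group: str) -> tuple[str, ...]:
        for g, ev in self.groups:
            if g == group:
                return ev
        raise KeyError(group)


#: 1R shared by all vertebrates; 2R on the jawed stem; a genome
#: triplication on the jawless (cyclostome) stem.
VERTEBRATE_WGD = WgdStructure(
    shared=(WGD,),
    groups=(("jawed", (WGD,)), ("jawless", (TRIPLICATION,))),
)


@dataclass(frozen=True)
class ObservedChrom:
    """One opsin-bearing chromosome of a species group.

    ``genes`` is the ordered list of (subtype, strand).  ``clade``
    optionally constrains which shared-WGD copy the chromosome descends
    from (a copy-path prefix such as "A").  ``background`` marks a
    chromosome outside the opsin paralogon (genes on it must be
    explained by translocation)."""

    chrom_id: str
    genes: tuple[tuple[str, str], ...]
    clade: str | None = None
    background: bool = False


@dataclass(frozen=True)
class ObservedArrangement:
    groups: tuple[tuple[str, tuple[ObservedChrom, ...]], ...]

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[ObservedChrom]]) -> "ObservedArrangement":
        return cls(tuple((g, tuple(chroms)) for g, chroms in sorted(d.items())))

    def group(self, name: str) -> tuple[ObservedChrom, ...]:
        for g, chroms in self.groups:
            if g == name:
                return chroms
        raise KeyError(name)

    def group_names(self) -> list[str]:
        return [g for g, _ in self.groups]

    def subtypes(self) -> set[str]:
        return {
            lab for _, chroms in self.groups for c in chroms for lab, _ in c.genes
        }


@dataclass(frozen=True)
class AncestralHypothesis:
    """Pre-WGD gene order and the subtypes each ancestral gene may yield."""

    name: str
    order: tuple[tuple[str, str], ...]  # (label, strand)
    mapping: tuple[tuple[str, frozenset[str]], ...]

    @classmethod
    def build(
        cls,
        name: str,
        order: Sequence[tuple[str, str]],
        mapping: Mapping[str, Iterable[str]],
    ) -> "AncestralHypothesis":
        return cls(
            name=name,
            order=tuple(order),
            mapping=tuple(sorted((k, frozenset(v)) for k, v in mapping.items())),
        )

    def subtypes_of(self, label: str) -> frozenset[str]:
        for lab, subs in self.mapping:
            if lab == label:
                return subs
        raise KeyError(label)

    def all_subtypes(self) -> set[str]:
        return set().union(*(subs for _, subs in self.mapping)) if self.mapping else set()


# ---------------------------------------------------------------------------
# the copy tree


_COPY_TREE_CACHE: dict[WgdStructure, "CopyTree"] = {}


def copy_tree(wgd: WgdStructure) -> "CopyTree":
    """Shared CopyTree instance per (immutable) WgdStructure."""
    if wgd not in _COPY_TREE_CACHE:
        _COPY_TREE_CACHE[wgd] = CopyTree(wgd)
    return _COPY_TREE_CACHE[wgd]


class CopyTree:
    """The fixed tree of chromosome copies induced by a WgdStructure."""

    def __init__(self, wgd: WgdStructure):
        self.root = "pre1R"
        self.parent: dict[str, str | None] = {self.root: None}
        self.children: dict[str, list[str]] = {self.root: []}
        self.path: dict[str, str] = {self.root: ""}
        self.leaves_by_group: dict[str, list[str]] = {}

        level = [self.root]
        for kind in wgd.shared:
            n = 2 if kind == WGD else 3
            nxt = []
            for node in level:
                for letter in _COPY_LETTERS[:n]:
                    p = (self.path[node] + "_" + letter).lstrip("_")
                    cid = f"shared:{p}"
                    self._add(cid, node, p)
                    nxt.append(cid)
            level = nxt
        for group, events in wgd.groups:
            glevel = []
            for node in level:
                stem = f"{group}-stem:{self.path[node] or 'root'}"
                self._add(stem, node, self.path[node])
                glevel.append(stem)
            for kind in events:
                n = 2 if kind == WGD else 3
                nxt = []
                for node in glevel:
                    for letter in _COPY_LETTERS[:n]:
                        p = (self.path[node] + "_" + letter).lstrip("_")
                        cid = f"{group}:{p}"
                        self._add(cid, node, p)
                        nxt.append(cid)
                glevel = nxt
            self.leaves_by_group[group] = list(glevel)
        self.leaf_group = {
            l: g for g, ls in self.leaves_by_group.items() for l in ls
        }
        self.all_leaves = sorted(self.leaf_group)
        # traversal caches (the tree is small and immutable)
        self._anc: dict[str, list[str]] = {}
        for n in self.parent:
            chain = [n]
            while self.parent[chain[-1]] is not None:
                chain.append(self.parent[chain[-1]])  # type: ignore[arg-type]
            self._anc[n] = chain
        self._under: dict[str, list[str]] = {}

        def _collect(n: str) -> list[str]:
            if not self.children[n]:
                out = [n] if n in self.leaf_group else []
            else:
                out = []
                for c in self.children[n]:
                    out.extend(_collect(c))
            self._under[n] = out
            return out

        _collect(self.root)
        self._inst_cache: dict[tuple, tuple[float, list[str]] | None] = {}

    def _add(self, cid: str, parent: str, path: str) -> None:
        self.parent[cid] = parent
        self.children[parent].append(cid)
        self.children[cid] = []
        self.path[cid] = path

    def ancestors(self, node: str) -> list[str]:
        return list(self._anc[node])

    def lca(self, nodes: Iterable[str]) -> str:
        its = [self._anc[n] for n in nodes]
        common = set(its[0])
        for a in its[1:]:
            common &= set(a)
        for n in its[0]:
            if n in common:
                return n
        raise AssertionError("no common ancestor")

    def leaves_under(self, node: str) -> list[str]:
        return list(self._under[node])

    def dollo_losses(self, present: set[str]) -> list[str]:
        """Branches carrying one loss each so that exactly ``present``
        leaves retain the gene (minimum-loss placement)."""
        if not present:
            return [self.root]
        has: dict[str, bool] = {}

        def mark(n: str) -> bool:
            if not self.children[n]:
                has[n] = n in present
            else:
                has[n] = any([mark(c) for c in self.children[n]])
            return has[n]

        mark(self.root)
        losses: list[str] = []

        def walk(n: str) -> None:
            for c in self.children[n]:
                if self.children[c] or c in self.leaf_group:
                    if not has[c]:
                        if self.leaves_under(c):
                            losses.append(c)
                    else:
                        walk(c)

        walk(self.root)
        return losses


# ---------------------------------------------------------------------------
# events and scenarios


@dataclass(frozen=True)
class ScenarioEvent:
    kind: str
    branch: str
    gene: str  # instance id
    source_chrom: str | None = None  # TRANSLOCATION: leaf the gene came from
    target_chrom: str | None = None  # TRANSLOCATION: destination chromosome
    position: int | None = None
    strand: str | None = None


@dataclass(frozen=True)
class EventScenario:
    """An ordered event set explaining an ObservedArrangement.

    ``assignment`` maps (group, chromosome id, instance id) to the
    subtype the surviving copy carries; ``chrom_map`` maps each observed
    chromosome to the copy-tree leaf (or background chromosome name) it
    was matched to, with its matched orientation."""

    hypothesis: str
    events: tuple[ScenarioEvent, ...]
    cost: float
    assignment: tuple[tuple[tuple[str, str, str], str], ...]
    chrom_map: tuple[tuple[tuple[str, str], tuple[str, bool]], ...]

    def event_counts(self) -> dict[str, int]:
        out = {TANDEM_DUP: 0, LOSS: 0, TRANSLOCATION: 0}
        for e in self.events:
            out[e.kind] += 1
        return out

    def assignment_dict(self) -> dict[tuple[str, str, str], str]:
        return dict(self.assignment)

    def chrom_map_dict(self) -> dict[tuple[str, str], tuple[str, bool]]:
        return dict(self.chrom_map)


@dataclass(frozen=True)
class ScenarioSearchResult:
    hypothesis: str
    cost: float
    scenarios: tuple[EventScenario, ...]

    @property
    def feasible(self) -> bool:
        return math.isfinite(self.cost)

    @property
    def best(self) -> EventScenario:
        if not self.scenarios:
            raise ValueError("infeasible: no scenario")
        return self.scenarios[0]


# ---------------------------------------------------------------------------
# replay


def _initial_instances(
    hyp: AncestralHypothesis,
) -> list[tuple[str, str, str]]:
    return [
        (f"{lab}.{i}", lab, strand) for i, (lab, strand) in enumerate(hyp.order)
    ]


def replay(
    hyp: AncestralHypothesis,
    events: Sequence[ScenarioEvent],
    wgd: WgdStructure,
) -> dict[str, dict[str, list[tuple[str, str, str]]]]:
    """Deterministic forward replay of an event list over the copy tree.

    Returns, per group, the arrangement of every chromosome present in
    that group's extant genome: copy-tree leaves (keyed by leaf id) plus
    any chromosomes created by translocation.  Each gene is
    (instance id, label, strand).
    """
    ct = copy_tree(wgd)
    by_branch: dict[str, list[ScenarioEvent]] = {}
    for e in events:
        by_branch.setdefault(e.branch, []).append(e)

    # state per copy-tree leaf: the P-chromosome arrangement there
    state: dict[str, list[tuple[str, str, str]]] = {}

    def apply_events(node: str, chrom: list) -> None:
        for e in by_branch.get(node, []):
            if e.kind == TANDEM_DUP:
                idx = [i for i, g in enumerate(chrom) if g[0] == e.gene]
                if not idx:
                    raise ValueError(f"tandem source {e.gene!r} absent at {node}")
                src = chrom[idx[0]]
                new_id = e.target_chrom or f"{e.gene}.t"
                chrom.insert(idx[0] + 1, (new_id, src[1], src[2]))
            elif e.kind == LOSS:
                chrom[:] = [g for g in chrom if g[0] != e.gene]
            elif e.kind == TRANSLOCATION:
                if node not in ct.leaf_group:
                    raise ValueError(
                        "replay supports translocations on terminal branches "
                        "only; got branch " + node
                    )
                # applied genome-wide after all leaves exist

    def walk(node: str, chrom: list) -> None:
        chrom = list(chrom)
        apply_events(node, chrom)
        if node in ct.leaf_group:
            state[node] = chrom
            return
        for c in ct.children[node]:
            walk(c, chrom)

    # pre-WGD arrangement: initial order plus pre-WGD events
    chrom0: list[tuple[str, str, str]] = list(_initial_instances(hyp))
    apply_events(ct.root, chrom0)
    if ct.children[ct.root]:
        for c in ct.children[ct.root]:
            walk(c, chrom0)
    else:  # degenerate: no WGDs at all
        state[ct.root] = chrom0

    # genome-wide terminal translocations, per group
    out: dict[str, dict[str, list]] = {}
    for group, leaves in ct.leaves_by_group.items():
        genome: dict[str, list] = {leaf: list(state[leaf]) for leaf in leaves}
        moves = [
            e
            for leaf in leaves
            for e in by_branch.get(leaf, [])
            if e.kind == TRANSLOCATION
        ]
        for e in sorted(moves, key=lambda e: (e.target_chrom or "", e.position or 0)):
            src = e.source_chrom or e.branch
            hits = [g for g in genome.get(src, []) if g[0] == e.gene]
            if not hits:
                raise ValueError(
                    f"translocation source {e.gene!r} absent on {src}"
                )
            gene = hits[0]
            genome[src] = [g for g in genome[src] if g[0] != e.gene]
            target = e.target_chrom or src
            dest = genome.setdefault(target, [])
            pos = e.position if e.position is not None else len(dest)
            dest.insert(min(pos, len(dest)), (gene[0], gene[1], e.strand or gene[2]))
        out[group] = genome
    return out


# ---------------------------------------------------------------------------
# the search


def _expansions(n: int, max_tandems: int):
    """Yield per-position copy counts (each >= 1) with sum(extra) <= max_tandems,
    in order of increasing total tandem count."""
    for total_extra in range(max_tandems + 1):
        for extra in _compositions(total_extra, n):
            yield tuple(1 + e for e in extra)


def _compositions(total: int, parts: int):
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def _expand_instances(
    hyp: AncestralHypothesis, counts: tuple[int, ...]
) -> tuple[list[tuple[str, str, str]], list[ScenarioEvent]]:
    instances: list[tuple[str, str, str]] = []
    events: list[ScenarioEvent] = []
    for i, ((lab, strand), c) in enumerate(zip(hyp.order, counts)):
        base = f"{lab}.{i}"
        instances.append((base, lab, strand))
        prev = base
        for r in range(1, c):
            new = f"{base}.t{r}"
            events.append(
                ScenarioEvent(TANDEM_DUP, "pre1R", prev, target_chrom=new)
            )
            instances.append((new, lab, strand))
            prev = new
    return instances, events


def _embeddings(
    genes: Sequence[tuple[str, str]],
    instances: Sequence[tuple[str, str, str]],
    hyp: AncestralHypothesis,
    max_transloc: int,
):
    """All ways to explain an observed gene list on a paralogon copy:
    an order-preserving injection into the instance list (subtype within
    the label's mapping, strand equal) for "descent" genes, the rest
    marked translocated-in.  Yields (embedding dict pos->inst idx,
    translocated position tuple)."""

    n = len(genes)

    def rec(p: int, k: int, emb: dict[int, int], moved: list[int]):
        if len(moved) > max_transloc:
            return
        if p == n:
            yield dict(emb), tuple(moved)
            return
        subtype, strand = genes[p]
        for j in range(k, len(instances)):
            iid, lab, istrand = instances[j]
            if istrand == strand and subtype in hyp.subtypes_of(lab):
                emb[p] = j
                yield from rec(p + 1, j + 1, emb, moved)
                del emb[p]
        moved.append(p)
        yield from rec(p + 1, k, emb, moved)
        moved.pop()

    yield from rec(0, 0, {}, [])


def _side_assignments(ct: CopyTree, group: str, chroms: Sequence[ObservedChrom]):
    """Canonical injective assignments of non-background observed
    chromosomes to copy-tree leaves, up to exchange of leaves that are
    interchangeable (same parent stem)."""
    real = [c for c in chroms if not c.background]
    leaves = ct.leaves_by_group[group]
    by_parent: dict[str, list[str]] = {}
    for l in leaves:
        by_parent.setdefault(ct.parent[l] or "", []).append(l)
    parents = sorted(by_parent)

    def rec(i: int, used: set[str], acc: list[str]):
        if i == len(real):
            yield list(acc)
            return
        c = real[i]
        for par in parents:
            # leaves sharing a parent stem are interchangeable: take the
            # first unused one satisfying the clade constraint
            leaf = next(
                (
                    l
                    for l in by_parent[par]
                    if l not in used
                    and (c.clade is None or _clade_ok(ct.path[l], c.clade))
                ),
                None,
            )
            if leaf is None:
                continue
            used.add(leaf)
            acc.append(leaf)
            yield from rec(i + 1, used, acc)
            acc.pop()
            used.discard(leaf)
        return

    yield from rec(0, set(), [])


def _clade_ok(path: str, clade: str) -> bool:
    return path == clade or path.startswith(clade + "_")


@dataclass
class _ChromChoice:
    chrom: ObservedChrom
    group: str
    leaf: str | None  # None for background
    flipped: bool
    work_genes: tuple[tuple[str, str], ...]
    embedding: dict[int, int]
    moved: tuple[int, ...]


def min_cost_scenario(
    obs: ObservedArrangement,
    hyp: AncestralHypothesis,
    weights: Mapping[str, float] | None = None,
    wgd: WgdStructure = VERTEBRATE_WGD,
    max_tandems: int = 3,
    max_transloc_per_chrom: int = 2,
    max_transloc: int = 3,
    transloc_targets: str = "background",
) -> ScenarioSearchResult:
    """Exact branch-and-bound search for the cheapest event history
    within the search envelope (at most ``max_tandems`` pre-WGD tandem
    duplications and ``max_transloc`` translocations).

    By default (``transloc_targets="background"``) translocations only
    account for genes observed on background (off-paralogon)
    chromosomes; arrangements on paralogon chromosomes must be explained
    by descent and loss.  ``transloc_targets="any"`` also lets genes be
    translocated into paralogon chromosomes, which can make ancestral
    adjacencies reconstructible by gene movement instead of descent —
    a weaker notion of synteny evidence, off by default.

    Returns all co-optimal scenarios (up to exchange of interchangeable
    duplicate copies); an infeasible instance yields cost = inf and an
    empty scenario tuple, never an exception.
    """
    if transloc_targets not in ("background", "any"):
        raise ValueError(f"unknown transloc_targets {transloc_targets!r}")
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    for k, v in w.items():
        if not v > 0:
            raise ValueError(f"event weight {k} must be positive")
    if len(hyp.order) > 5:
        raise ValueError("pre-WGD gene order longer than 5 is out of the search envelope")
    for g, chroms in obs.groups:
        for c in chroms:
            if len(c.genes) > 6:
                raise ValueError(f"observed chromosome {c.chrom_id} has > 6 genes")
    if not obs.subtypes() <= hyp.all_subtypes():
        return ScenarioSearchResult(hyp.name, math.inf, ())

    ct = copy_tree(wgd)
    group_names = [g for g, _ in obs.groups]
    for g in group_names:
        if g not in ct.leaves_by_group:
            raise ValueError(f"observed group {g!r} absent from the WGD structure")

    best_cost = [math.inf]
    found: dict[tuple, EventScenario] = {}

    for counts in _expansions(len(hyp.order), max_tandems):
        # an extra copy of a single-subtype label can never carry a
        # subtype (one instance owns each subtype), so it would always be
        # created and immediately lost: strictly worse, prune
        if any(
            c > 1 and len(hyp.subtypes_of(hyp.order[i][0])) < 2
            for i, c in enumerate(counts)
        ):
            continue
        instances, tandem_events = _expand_instances(hyp, counts)
        base_cost = len(tandem_events) * w[TANDEM_DUP]
        if base_cost > best_cost[0]:
            continue

        # embeddings per (chromosome, orientation), shared by all leaf maps
        emb_cache: dict[tuple[str, str, bool], list[tuple[dict, tuple]]] = {}

        def chrom_options(group: str, c: ObservedChrom, leaf: str | None):
            if c.background:
                work = tuple(c.genes)
                return [
                    _ChromChoice(c, group, None, False, work, {}, tuple(range(len(work))))
                ]
            per_chrom_cap = (
                0 if transloc_targets == "background" else max_transloc_per_chrom
            )
            opts = []
            for flipped in (False, True):
                key = (group, c.chrom_id, flipped)
                if key not in emb_cache:
                    work = flip_arrangement(c.genes) if flipped else tuple(c.genes)
                    emb_cache[key] = [
                        (emb, moved)
                        for emb, moved in _embeddings(
                            work, instances, hyp, per_chrom_cap
                        )
                    ]
                work = flip_arrangement(c.genes) if flipped else tuple(c.genes)
                for emb, moved in emb_cache[key]:
                    opts.append(_ChromChoice(c, group, leaf, flipped, work, emb, moved))
            return opts

        def group_choices(group: str, chroms: Sequence[ObservedChrom]):
            real = [c for c in chroms if not c.background]
            bg = [c for c in chroms if c.background]
            for leaf_assign in _side_assignments(ct, group, chroms):
                per_chrom_opts = [
                    chrom_options(group, c, leaf)
                    for c, leaf in zip(real, leaf_assign)
                ]
                if any(not o for o in per_chrom_opts):
                    continue
                for c in bg:
                    per_chrom_opts.append(chrom_options(group, c, None))
                yield from itertools.product(*per_chrom_opts)

        group_iters = [list(group_choices(g, obs.group(g))) for g in group_names]
        for combo in itertools.product(*group_iters):
            choices: list[_ChromChoice] = [ch for grp in combo for ch in grp]
            n_moved = sum(len(ch.moved) for ch in choices)
            if n_moved > max_transloc:
                continue
            lower = base_cost + n_moved * w[TRANSLOCATION]
            if lower > best_cost[0]:
                continue
            _evaluate(
                choices, instances, tandem_events, hyp, ct, w,
                base_cost, best_cost, found,
            )

    if not found:
        return ScenarioSearchResult(hyp.name, math.inf, ())
    scens = tuple(sorted(found.values(), key=lambda s: repr(s.events)))
    return ScenarioSearchResult(hyp.name, best_cost[0], scens)


def _inst_cost(
    ct: CopyTree,
    descent: dict[str, str],
    extras: tuple[tuple[str, str], ...],
) -> tuple[float, list[str]] | None:
    """Loss count and loss branches for one instance given its descent
    presence and translocation-source presences; None when the subtype
    assignment is not clade-consistent."""
    leafmap = dict(descent)
    for leaf, subtype in extras:
        if leaf in leafmap:
            return None
        leafmap[leaf] = subtype
    key = tuple(sorted(leafmap.items()))
    if key in ct._inst_cache:
        return ct._inst_cache[key]
    result = _inst_cost_uncached(ct, leafmap)
    ct._inst_cache[key] = result
    return result


def _inst_cost_uncached(
    ct: CopyTree, leafmap: dict[str, str]
) -> tuple[float, list[str]] | None:
    subtypes_here = set(leafmap.values())
    if len(subtypes_here) > 1:
        for s in subtypes_here:
            s_leaves = [l for l, ss in leafmap.items() if ss == s]
            node = ct.lca(s_leaves)
            for l in ct.leaves_under(node):
                if l in leafmap and leafmap[l] != s:
                    return None
    branches = ct.dollo_losses(set(leafmap))
    return float(len(branches)), branches


def _evaluate(
    choices: list[_ChromChoice],
    instances: list[tuple[str, str, str]],
    tandem_events: list[ScenarioEvent],
    hyp: AncestralHypothesis,
    ct: CopyTree,
    w: Mapping[str, float],
    base_cost: float,
    best_cost: list[float],
    found: dict,
) -> None:
    """Complete one candidate configuration.

    Translocation-source placement decomposes per instance: once each
    translocated gene is assigned to an instance, the source-copy choice
    only affects that instance's own loss count, so per-instance optima
    (with all co-optimal source sets) multiply together."""
    # presence by descent: instance -> leaf -> subtype
    presence: dict[str, dict[str, str]] = {}
    owner: dict[str, str] = {}  # subtype -> instance
    for ch in choices:
        for pos, j in ch.embedding.items():
            iid = instances[j][0]
            subtype = ch.work_genes[pos][0]
            if owner.setdefault(subtype, iid) != iid:
                return
            leaf = ch.leaf
            assert leaf is not None
            if leaf in presence.setdefault(iid, {}):
                return
            presence[iid][leaf] = subtype

    moved_items = [(ch, pos) for ch in choices for pos in ch.moved]
    trans_cost = len(moved_items) * w[TRANSLOCATION]
    if base_cost + trans_cost > best_cost[0]:
        return

    # assign each translocated gene to an instance (subtype-ownership
    # consistent); source leaves are optimized per instance afterwards
    def assign(k: int, item_inst: list[str]):
        if k == len(moved_items):
            yield list(item_inst)
            return
        ch, pos = moved_items[k]
        subtype = ch.work_genes[pos][0]
        for iid, lab, _st in instances:
            if subtype not in hyp.subtypes_of(lab):
                continue
            prev = owner.get(subtype)
            if prev is not None and prev != iid:
                continue
            had = subtype in owner
            owner[subtype] = iid
            item_inst.append(iid)
            yield from assign(k + 1, item_inst)
            item_inst.pop()
            if not had:
                del owner[subtype]

    for item_inst in assign(0, []):
        # per-instance: moved items it received
        items_of: dict[str, list[int]] = {}
        for k, iid in enumerate(item_inst):
            items_of.setdefault(iid, []).append(k)
        total_loss = 0.0
        per_inst_opts: dict[str, list[tuple[tuple, list[str]]]] = {}
        feasible = True
        for iid, _lab, _st in instances:
            descent = presence.get(iid, {})
            items = items_of.get(iid, [])
            if not items:
                r = _inst_cost(ct, descent, ())
                if r is None:
                    feasible = False
                    break
                total_loss += r[0]
                per_inst_opts[iid] = [((), r[1])]
                continue
            # enumerate source-leaf tuples for this instance's items
            best_c: float = math.inf
            opts: list[tuple[tuple, list[str]]] = []
            pools = [
                ct.leaves_by_group[moved_items[k][0].group] for k in items
            ]
            for leaves in itertools.product(*pools):
                if len(set(leaves)) != len(leaves):
                    continue
                extras = tuple(
                    (leaf, moved_items[k][0].work_genes[moved_items[k][1]][0])
                    for leaf, k in zip(leaves, items)
                )
                r = _inst_cost(ct, descent, extras)
                if r is None:
                    continue
                if r[0] < best_c:
                    best_c = r[0]
                    opts = [(extras, r[1])]
                elif r[0] == best_c:
                    opts.append((extras, r[1]))
            if not opts:
                feasible = False
                break
            total_loss += best_c
            per_inst_opts[iid] = opts
        if not feasible:
            continue
        cost = base_cost + trans_cost + total_loss * w[LOSS]
        if cost > best_cost[0]:
            continue
        if cost < best_cost[0]:
            best_cost[0] = cost
            found.clear()
        _emit_scenarios(
            choices, instances, tandem_events, hyp, moved_items, item_inst,
            per_inst_opts, cost, found,
        )


def _emit_scenarios(
    choices, instances, tandem_events, hyp, moved_items, item_inst,
    per_inst_opts, cost, found,
) -> None:
    inst_ids = [iid for iid, _l, _s in instances]
    option_lists = [per_inst_opts[iid] for iid in inst_ids]
    for picks in itertools.product(*option_lists):
        losses: list[tuple[str, str]] = []
        source_of: dict[int, str] = {}
        for iid, (extras, branches) in zip(inst_ids, picks):
            for branch in branches:
                losses.append((iid, branch))
            for (leaf, _subtype), k in zip(
                extras, [k for k, ii in enumerate(item_inst) if ii == iid]
            ):
                source_of[k] = leaf
        events: list[ScenarioEvent] = list(tandem_events)
        for iid, branch in sorted(losses):
            events.append(ScenarioEvent(LOSS, branch, iid))
        assignment: dict[tuple[str, str, str], str] = {}
        chrom_map: dict[tuple[str, str], tuple[str, bool]] = {}
        for ch in choices:
            target = ch.leaf if ch.leaf is not None else f"bg:{ch.chrom.chrom_id}"
            chrom_map[(ch.group, ch.chrom.chrom_id)] = (target, ch.flipped)
            for pos, j in ch.embedding.items():
                assignment[(ch.group, target, instances[j][0])] = ch.work_genes[pos][0]
        ok = True
        for k, (ch, pos) in enumerate(moved_items):
            target = ch.leaf if ch.leaf is not None else f"bg:{ch.chrom.chrom_id}"
            subtype, strand = ch.work_genes[pos]
            iid = item_inst[k]
            key = (ch.group, target, iid)
            if key in assignment and assignment[key] != subtype:
                ok = False
                break
            assignment[key] = subtype
            events.append(
                ScenarioEvent(
                    TRANSLOCATION,
                    branch=source_of[k],
                    gene=iid,
                    source_chrom=source_of[k],
                    target_chrom=target,
                    position=pos,
                    strand=strand,
                )
            )
        if not ok:
            continue
        scen = EventScenario(
            hypothesis=hyp.name,
            events=tuple(events),
            cost=cost,
            assignment=tuple(sorted(assignment.items())),
            chrom_map=tuple(sorted(chrom_map.items())),
        )
        key = (scen.events, scen.assignment)
        found.setdefault(key, scen)


# ---------------------------------------------------------------------------
# verification and comparison


def verify_scenario(
    scen: EventScenario,
    obs: ObservedArrangement,
    hyp: AncestralHypothesis,
    wgd: WgdStructure = VERTEBRATE_WGD,
) -> bool:
    """Soundness check: replaying the scenario reproduces the observation
    exactly (up to the recorded per-chromosome orientations)."""
    pred = replay(hyp, scen.events, wgd)
    amap = scen.assignment_dict()
    cmap = scen.chrom_map_dict()
    for group, chroms in obs.groups:
        genome = {k: list(v) for k, v in pred[group].items()}
        for c in chroms:
            if (group, c.chrom_id) not in cmap:
                return False
            target, flipped = cmap[(group, c.chrom_id)]
            genes = genome.pop(target, [])
            want = flip_arrangement(c.genes) if flipped else tuple(c.genes)
            got = []
            for iid, lab, strand in genes:
                sub = amap.get((group, target, iid))
                if sub is None:
                    return False
                got.append((sub, strand))
            if tuple(got) != want:
                return False
        # every unmatched chromosome must be empty
        leaves = set(copy_tree(wgd).leaves_by_group[group])
        for chrom_id, genes in genome.items():
            if genes:
                return False
    return True


def compare_hypotheses(
    obs: ObservedArrangement,
    hyps: Sequence[AncestralHypothesis],
    weights: Mapping[str, float] | None = None,
    wgd: WgdStructure = VERTEBRATE_WGD,
    max_tandems: int = 3,
) -> pd.DataFrame:
    """Rank hypotheses by minimum event cost (ascending, ties by name).

    Columns: hypothesis, cost, n_tandem, n_loss, n_transloc,
    co_optimal_count.  Infeasible hypotheses appear with cost = inf.
    """
    if len(hyps) < 2:
        raise ValueError("need at least two hypotheses to compare")
    rows = []
    results = {}
    for hyp in hyps:
        res = min_cost_scenario(obs, hyp, weights=weights, wgd=wgd, max_tandems=max_tandems)
        results[hyp.name] = res
        if res.feasible:
            counts = res.best.event_counts()
        else:
            counts = {TANDEM_DUP: 0, LOSS: 0, TRANSLOCATION: 0}
        rows.append(
            {
                "hypothesis": hyp.name,
                "cost": res.cost,
                "n_tandem": counts[TANDEM_DUP],
                "n_loss": counts[LOSS],
                "n_transloc": counts[TRANSLOCATION],
                "co_optimal_count": len(res.scenarios),
            }
        )
    df = pd.DataFrame(rows).sort_values(["cost", "hypothesis"]).reset_index(drop=True)
    df.attrs["results"] = results
    return df


# ---------------------------------------------------------------------------
# brute-force oracle (reference implementation for small instances)


def brute_force_min_cost(
    obs: ObservedArrangement,
    hyp: AncestralHypothesis,
    wgd: WgdStructure = VERTEBRATE_WGD,
    weights: Mapping[str, float] | None = None,
    max_events: int = 2,
    max_tandems: int = 0,
    transloc_targets: str = "background",
) -> float:
    """Literal-definition oracle: enumerate every loss/translocation event
    set up to ``max_events`` events (optionally after pre-WGD tandem
    expansions), replay it, and test the outcome against the observation
    by direct comparison.  Exponential; tiny instances only."""
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    ct = copy_tree(wgd)
    best = math.inf
    for counts in _expansions(len(hyp.order), max_tandems):
        instances, tandem_events = _expand_instances(hyp, counts)
        base = len(tandem_events) * w[TANDEM_DUP]
        slots: list[ScenarioEvent] = []
        nodes = [n for n in ct.parent]  # every branch incl. root and leaves
        for iid, _lab, _st in instances:
            for n in nodes:
                slots.append(ScenarioEvent(LOSS, n, iid))
        # translocation slots: any instance from any leaf to any observed
        # chromosome at any position/strand it could occupy
        for group, chroms in obs.groups:
            for c in chroms:
                if transloc_targets == "background" and not c.background:
                    continue
                for pos in range(len(c.genes)):
                    subtype, strand = c.genes[pos]
                    for iid, lab, _st in instances:
                        if subtype not in hyp.subtypes_of(lab):
                            continue
                        for leaf in ct.leaves_by_group[group]:
                            for target, flipped in _targets_for(ct, group, c):
                                wpos = (
                                    len(c.genes) - 1 - pos if flipped else pos
                                )
                                wstrand = (
                                    _flip_strand(strand) if flipped else strand
                                )
                                slots.append(
                                    ScenarioEvent(
                                        TRANSLOCATION, leaf, iid,
                                        source_chrom=leaf, target_chrom=target,
                                        position=wpos, strand=wstrand,
                                    )
                                )
        slots = sorted(set(slots), key=repr)
        for k in range(0, max_events + 1):
            for evset in itertools.combinations(slots, k):
                cost = base + sum(w[e.kind] for e in evset)
                if cost >= best:
                    continue
                if _replay_matches(hyp, list(tandem_events) + list(evset), wgd, obs, instances, ct):
                    best = cost
    return best


def _min_losses_bruteforce(ct: CopyTree, present: frozenset[str]) -> int:
    """Smallest number of branch losses leaving exactly ``present`` leaves,
    found by enumerating loss subsets of increasing size (oracle-grade,
    independent of the Dollo recursion)."""
    nodes = sorted(ct.parent)
    leaves = ct.all_leaves

    def leaves_after(losses: tuple[str, ...]) -> frozenset[str]:
        lost = set()
        for leaf in leaves:
            anc = set(ct.ancestors(leaf))
            if anc & set(losses):
                lost.add(leaf)
        return frozenset(l for l in leaves if l not in lost)

    for k in range(len(nodes) + 1):
        for combo in itertools.combinations(nodes, k):
            if leaves_after(combo) == present:
                return k
    raise AssertionError("unreachable")


_loss_cache: dict[tuple, int] = {}


def _min_losses_cached(ct: CopyTree, key: tuple, present: frozenset[str]) -> int:
    k = (key, present)
    if k not in _loss_cache:
        _loss_cache[k] = _min_losses_bruteforce(ct, present)
    return _loss_cache[k]


def survival_oracle(
    obs: ObservedArrangement,
    hyp: AncestralHypothesis,
    wgd: WgdStructure = VERTEBRATE_WGD,
    weights: Mapping[str, float] | None = None,
    max_tandems: int = 2,
    max_transloc: int = 2,
    bound: float = math.inf,
    transloc_targets: str = "background",
) -> float:
    """Independent minimum-cost oracle by exhaustive enumeration of
    survival patterns.

    Enumerates every assignment of observed chromosomes to copy-tree
    leaves, every chromosome orientation, every translocated-gene subset
    (with every source copy) and every gene-to-instance map; checks
    order, strand and subtype-clade consistency literally; counts losses
    by brute-force subset search.  Branches with partial cost >= the
    running best (capped at ``bound``) are pruned; returns the minimum
    cost found, inf when nothing beats the bound.
    """
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    if not obs.subtypes() <= hyp.all_subtypes():
        return math.inf
    ct = copy_tree(wgd)
    wgd_key = (wgd.shared, wgd.groups)
    state = {"found": math.inf, "cap": bound}

    group_list = obs.group_names()
    chrom_list = [(g, c) for g, chroms in obs.groups for c in chroms]

    def cap() -> float:
        return min(state["found"], state["cap"])

    for counts in _expansions(len(hyp.order), max_tandems):
        if any(
            c > 1 and len(hyp.subtypes_of(hyp.order[i][0])) < 2
            for i, c in enumerate(counts)
        ):
            continue
        instances, tandem_events = _expand_instances(hyp, counts)
        base = len(tandem_events) * w[TANDEM_DUP]
        if base >= cap():
            continue

        def leaf_maps(group: str):
            real = [c for c in obs.group(group) if not c.background]
            leaves = ct.leaves_by_group[group]
            for perm in itertools.permutations(leaves, len(real)):
                if any(
                    c.clade is not None and not _clade_ok(ct.path[l], c.clade)
                    for c, l in zip(real, perm)
                ):
                    continue
                yield dict(zip([c.chrom_id for c in real], perm))

        flip_space = [
            (False, True) if not c.background else (False,)
            for _g, c in chrom_list
        ]
        for maps in itertools.product(*(leaf_maps(g) for g in group_list)):
            leaf_of = {k: v for m in maps for k, v in m.items()}
            for flips in itertools.product(*flip_space):
                entries = []
                for (g, c), fl in zip(chrom_list, flips):
                    genes = flip_arrangement(c.genes) if fl else tuple(c.genes)
                    for p, (subtype, strand) in enumerate(genes):
                        entries.append(
                            {
                                "group": g,
                                "chrom": c.chrom_id,
                                "background": c.background,
                                "pos": p,
                                "subtype": subtype,
                                "strand": strand,
                            }
                        )
                forced = [k for k, e in enumerate(entries) if e["background"]]
                if transloc_targets == "background":
                    free = []
                else:
                    free = [k for k, e in enumerate(entries) if not e["background"]]
                max_extra = max(0, max_transloc - len(forced))
                for extra in range(max_extra + 1):
                    for extra_T in itertools.combinations(free, extra):
                        T = set(forced) | set(extra_T)
                        n_tr = len(T)
                        if base + n_tr * w[TRANSLOCATION] >= cap():
                            continue
                        _oracle_assign(
                            entries, T, instances, hyp, ct, wgd_key,
                            leaf_of, base, n_tr, w, state, bound,
                        )
    return state["found"]


def _oracle_assign(
    entries, T, instances, hyp, ct, wgd_key, leaf_of, base, n_tr, w, state, bound,
) -> None:
    inst_index = {iid: k for k, (iid, _l, _s) in enumerate(instances)}

    def cap() -> float:
        return min(state["found"], state["cap"])

    def compatible(e, translocated):
        out = []
        for iid, lab, istrand in instances:
            if e["subtype"] not in hyp.subtypes_of(lab):
                continue
            if not translocated and istrand != e["strand"]:
                continue
            out.append(iid)
        return out

    def score(phi: list[str], sources: list[str]) -> None:
        # per-chromosome instance order for descent genes must increase
        last: dict[str, int] = {}
        for k, e in enumerate(entries):
            if k in T:
                continue
            idx = inst_index[phi[k]]
            if idx <= last.get(e["chrom"], -1):
                return
            last[e["chrom"]] = idx
        presence: dict[str, dict[str, str]] = {}
        for k, e in enumerate(entries):
            presence.setdefault(phi[k], {})[sources[k]] = e["subtype"]
        for iid, leafmap in presence.items():
            for s in set(leafmap.values()):
                s_leaves = {l for l, ss in leafmap.items() if ss == s}
                if not any(
                    set(ct.leaves_under(n)) & set(leafmap) == s_leaves
                    for n in ct.parent
                ):
                    return
        n_loss = 0
        for iid, _lab, _st in instances:
            present = frozenset(presence.get(iid, {}))
            n_loss += _min_losses_cached(ct, wgd_key, present)
        cost = base + n_tr * w[TRANSLOCATION] + n_loss * w[LOSS]
        if cost < cap():
            state["found"] = cost

    def rec(k: int, phi: list[str], sources: list[str],
            used: set[tuple[str, str]], owner: dict[str, str]) -> None:
        if k == len(entries):
            score(phi, sources)
            return
        e = entries[k]
        translocated = k in T
        for iid in compatible(e, translocated):
            prev = owner.get(e["subtype"])
            if prev is not None and prev != iid:
                continue
            src_opts = (
                ct.leaves_by_group[e["group"]]
                if translocated
                else [leaf_of[e["chrom"]]]
            )
            for src in src_opts:
                if (iid, src) in used:
                    continue
                phi.append(iid)
                sources.append(src)
                used.add((iid, src))
                had = e["subtype"] in owner
                owner[e["subtype"]] = iid
                rec(k + 1, phi, sources, used, owner)
                if not had:
                    del owner[e["subtype"]]
                used.discard((iid, src))
                sources.pop()
                phi.pop()

    rec(0, [], [], set(), {})


def _targets_for(ct: CopyTree, group: str, c: ObservedChrom):
    if c.background:
        return [(f"bg:{c.chrom_id}", False)]
    out = []
    for leaf in ct.leaves_by_group[group]:
        out.append((leaf, False))
        out.append((leaf, True))
    return out


def _replay_matches(
    hyp: AncestralHypothesis,
    events: list[ScenarioEvent],
    wgd: WgdStructure,
    obs: ObservedArrangement,
    instances: list[tuple[str, str, str]],
    ct: CopyTree,
) -> bool:
    """Does any subtype assignment make the replayed arrangements equal to
    the observation?  Checked literally: per group, try every bijection
    between non-empty predicted chromosomes and observed chromosomes in
    both orientations, then demand a globally consistent, clade-compatible
    subtype assignment."""
    try:
        pred = replay(hyp, events, wgd)
    except ValueError:
        return False
    # a translocated copy's position in the duplication history is its
    # source leaf, not its destination chromosome
    moves = {
        e.gene: e.source_chrom or e.branch
        for e in events
        if e.kind == TRANSLOCATION
    }

    # collect per-group matching constraints via backtracking over
    # chromosome bijections (literal content comparison prunes hard)
    def match_group(group: str, chroms: Sequence[ObservedChrom]):
        genome = {k: v for k, v in pred[group].items() if v}
        if len(genome) != len(chroms):
            return
        names = sorted(genome)

        def chrom_fits(c: ObservedChrom, name: str, flipped: bool):
            want = flip_arrangement(c.genes) if flipped else tuple(c.genes)
            genes = genome[name]
            if len(genes) != len(want):
                return None
            out = []
            for (iid, lab, strand), (subtype, wstrand) in zip(genes, want):
                if strand != wstrand or subtype not in hyp.subtypes_of(lab):
                    return None
                out.append((iid, name, subtype))
            return out

        def rec(i: int, used: set[str], acc: list):
            if i == len(chroms):
                yield list(acc)
                return
            for name in names:
                if name in used:
                    continue
                for flipped in (False, True):
                    part = chrom_fits(chroms[i], name, flipped)
                    if part is None:
                        continue
                    used.add(name)
                    acc.extend(part)
                    yield from rec(i + 1, used, acc)
                    del acc[len(acc) - len(part):]
                    used.discard(name)

        yield from rec(0, set(), [])

    groups = obs.groups
    iters = [list(match_group(g, chroms)) for g, chroms in groups]
    if any(not it for it in iters):
        return False
    for combo in itertools.product(*iters):
        assigns: list[tuple[str, str, str]] = [a for trial in combo for a in trial]
        owner: dict[str, str] = {}
        by_inst: dict[str, dict[str, str]] = {}
        ok = True
        for iid, chrom, subtype in assigns:
            if owner.setdefault(subtype, iid) != iid:
                ok = False
                break
            prev = by_inst.setdefault(iid, {}).get(chrom)
            if prev is not None and prev != subtype:
                ok = False
                break
            by_inst[iid][chrom] = subtype
        if not ok:
            continue
        # clade compatibility, checked by exhaustive node scan
        good = True
        for iid, chrom_map in by_inst.items():
            leafmap = {
                (moves[iid] if iid in moves else c): s
                for c, s in chrom_map.items()
                if iid in moves or c in ct.leaf_group
            }
            for s in set(leafmap.values()):
                s_leaves = {l for l, ss in leafmap.items() if ss == s}
                found_node = False
                for node in ct.parent:
                    under = set(ct.leaves_under(node)) & set(leafmap)
                    if under == s_leaves:
                        found_node = True
                        break
                if not found_node:
                    good = False
                    break
            if not good:
                break
        if good:
            return True
    return False
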