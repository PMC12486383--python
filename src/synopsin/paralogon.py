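"""Chromosome-keyed supermatrix phylogenetics.

Anchor-family alignments are concatenated into one matrix whose rows are
(species, chromosome) pairs rather than species — the signal of interest
is the duplication history of chromosomes, not the species tree.  Trees
are inferred by neighbor joining on corrected pairwise-deletion protein
distances, with nonparametric column-bootstrap supports and outgroup
rooting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomeio import GeneRecord
from .homology import GAP, percent_identity, poisson_distance
from .trees import Node, bipartitions, support_of_bipartition

logger = logging.getLogger(__name__)

RowKey = tuple[str, str]  # (species, seq_id)


def row_label(key: RowKey) -> str:
    return f"{key[0]}@{key[1]}"


def parse_row_label(label: str) -> RowKey:
    sp, _, chrom = label.partition("@")
    return (sp, chrom)


@dataclass
class Supermatrix:
    """Per-chromosome concatenated alignment with a partition table."""

    rows: dict[RowKey, str]
    partitions: dict[str, tuple[int, int]]  # family -> [start, end) columns

    def __post_init__(self):
        L = self.n_columns
        for key, row in self.rows.items():
            if len(row) != L:
                raise ValueError(f"row {key} length {len(row)} != {L}")
        cover = sorted(self.partitions.values())
        pos = 0
        for start, end in cover:
            if start != pos:
                raise ValueError("partition intervals must tile the columns")
            pos = end
        if cover and pos != L:
            raise ValueError("partitions do not cover all columns")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def segment(self, key: RowKey, family: str) -> str:
        start, end = self.partitions[family]
        return self.rows[key][start:end]

    def write(self, fasta_path: str | Path, partition_path: str | Path) -> None:
        from .genomeio import write_alignment

        write_alignment({row_label(k): v for k, v in self.rows.items()}, fasta_path)
        pd.DataFrame(
            [(fam, s, e) for fam, (s, e) in sorted(self.partitions.items())],
            columns=["family", "start", "end"],
        ).to_csv(partition_path, sep="\t", index=False)


def _consensus(rows: Iterable[str]) -> str:
    arr = np.array([np.frombuffer(r.encode(), dtype="S1") for r in rows])
    out = []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        col = col[col != b"-"]
        if len(col) == 0:
            out.append("-")
            continue
        vals, counts = np.unique(col, return_counts=True)
        out.append(vals[np.argmax(counts)].decode())
    return "".join(out)


def build_supermatrix(
    family_msas: Mapping[str, Mapping[str, str]],
    genes: Sequence[GeneRecord],
) -> Supermatrix:
    """Concatenate family alignments keyed by (species, chromosome).

    ``family_msas`` maps family -> {"species:gene_id": aligned row} (the
    same member-key convention as orthogroups).  Each row is placed on
    the (species, seq_id) of its gene; a family absent from a chromosome
    contributes an all-gap segment.  If a chromosome carries more than
    one member of a family, the member closest to the family consensus
    is kept and the exclusion is logged.
    """
    gene_index: dict[str, GeneRecord] = {}
    for g in genes:
        gene_index[f"{g.species}:{g.gene_id}"] = g
    families = sorted(family_msas)
    lengths: dict[str, int] = {}
    for fam in families:
        msa = family_msas[fam]
        ls = {len(r) for r in msa.values()}
        if len(ls) != 1:
            raise ValueError(f"family {fam!r} alignment rows of unequal length")
        lengths[fam] = ls.pop()

    chosen: dict[str, dict[RowKey, str]] = {}
    row_keys: set[RowKey] = set()
    for fam in families:
        members: dict[RowKey, list[str]] = {}
        for gid in family_msas[fam]:
            if gid not in gene_index:
                raise ValueError(f"aligned sequence {gid!r} has no gene record")
            g = gene_index[gid]
            members.setdefault((g.species, g.seq_id), []).append(gid)
        picked: dict[RowKey, str] = {}
        for key, gids in members.items():
            row_keys.add(key)
            if len(gids) == 1:
                picked[key] = gids[0]
                continue
            cons = _consensus([family_msas[fam][g] for g in sorted(gids)])
            scored = sorted(
                ((-percent_identity(family_msas[fam][g], cons), g) for g in gids)
            )
            picked[key] = scored[0][1]
            for _, g in scored[1:]:
                logger.warning(
                    "family %s: chromosome %s carries multiple members; excluding %s",
                    fam, row_label(key), g,
                )
        chosen[fam] = {k: family_msas[fam][g] for k, g in picked.items()}

    partitions: dict[str, tuple[int, int]] = {}
    pos = 0
    for fam in families:
        partitions[fam] = (pos, pos + lengths[fam])
        pos += lengths[fam]
    rows: dict[RowKey, str] = {}
    for key in sorted(row_keys):
        parts = []
        for fam in families:
            parts.append(chosen[fam].get(key, GAP * lengths[fam]))
        rows[key] = "".join(parts)
    return Supermatrix(rows=rows, partitions=partitions)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dist: pd.DataFrame) -> Node:
    """Canonical neighbor joining on a symmetric distance matrix.

    Negative branch lengths are clamped to 0; Q-matrix ties break by the
    lexicographically smallest taxon-name pair.  Returns an unrooted tree
    (top-level trifurcation for >= 4 taxa)."""
    labels = [str(x) for x in dist.index]
    D = dist.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or list(dist.columns) != list(dist.index):
        raise ValueError("distance matrix must be square with matching labels")
    if np.isnan(D).any():
        raise ValueError("NaN in distance matrix")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if (D < 0).any():
        raise ValueError("negative off-diagonal distances")
    n = len(labels)
    if n < 3:
        raise ValueError("need >= 3 taxa")

    nodes: list[Node] = [Node(name=lab) for lab in labels]
    names: list[str] = list(labels)  # lexicographic tie-break keys
    D = D.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        # canonical pair per tie, pick lexicographically smallest name pair
        cand = []
        for i, j in ties:
            if i < j:
                cand.append((tuple(sorted((names[i], names[j]))), i, j))
        _, i, j = min(cand)
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2 * (m - 2))
        lj = d_ij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = Node(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        d_new = 0.5 * (D[i] + D[j] - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        D_next = np.zeros((m - 1, m - 1))
        D_next[:-1, :-1] = D[np.ix_(keep, keep)]
        D_next[-1, :-1] = D_next[:-1, -1] = d_new[keep]
        D = D_next
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [min(names[i], names[j])]
    # final three-point join
    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        l0 = max(0.0, 0.5 * (d01 + d02 - d12))
        l1 = max(0.0, 0.5 * (d01 + d12 - d02))
        l2 = max(0.0, 0.5 * (d02 + d12 - d01))
        for node, ln in zip(nodes, (l0, l1, l2)):
            node.length = ln
        return Node(children=list(nodes))
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# bootstrap supports


@dataclass
class SupportTree:
    """A tree whose internal nodes carry bootstrap supports in [0, 1]."""

    root: Node
    threshold: float = 0.95
    rooted: bool = False

    def reliable_bipartitions(self) -> set[frozenset[str]]:
        out = set()
        for side in bipartitions(self.root):
            s = support_of_bipartition(self.root, side)
            if s is not None and s >= self.threshold:
                out.add(side)
        return out

    def newick(self) -> str:
        return self.root.to_newick()


def _pairwise_masks(rows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.array([np.frombuffer(r.encode(), dtype="S1") for r in rows])
    nongap = arr != b"-"
    n = arr.shape[0]
    comp = np.zeros((n, n, arr.shape[1]), dtype=bool)
    match = np.zeros_like(comp)
    for i in range(n):
        for j in range(i + 1, n):
            c = nongap[i] & nongap[j]
            mm = c & (arr[i] == arr[j])
            comp[i, j] = comp[j, i] = c
            match[i, j] = match[j, i] = mm
    return comp, match


def _distance_matrix(
    comp: np.ndarray, match: np.ndarray, cols: np.ndarray | None, ceiling: float = 5.0
) -> np.ndarray:
    if cols is None:
        c = comp.sum(axis=2)
        mm = match.sum(axis=2)
    else:
        c = comp[:, :, cols].sum(axis=2)
        mm = match[:, :, cols].sum(axis=2)
    n = c.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if c[i, j] == 0:
                d = ceiling
            else:
                p = 1.0 - mm[i, j] / c[i, j]
                d = poisson_distance(float(p), ceiling=ceiling)
            D[i, j] = D[j, i] = d
    return D


def bootstrap_tree(
    sm: Supermatrix,
    n_boot: int = 100,
    seed: int = 0,
    threshold: float = 0.95,
    min_comparable: float = 0.10,
    ceiling: float = 5.0,
) -> SupportTree:
    """NJ tree of the supermatrix with column-bootstrap bipartition supports.

    Distances are corrected p-distances over pairwise comparable (both
    non-gap) columns.  Rows sharing fewer than ``min_comparable`` of the
    columns with some partner are dropped with a warning.  Supports are
    the fraction of replicates whose NJ tree contains each bipartition of
    the full-data tree.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    keys = sorted(sm.rows)
    rows = [sm.rows[k] for k in keys]
    ncols = sm.n_columns
    comp, match = _pairwise_masks(rows)
    frac = comp.sum(axis=2) / max(ncols, 1)
    np.fill_diagonal(frac, 1.0)
    # drop the worst offender at a time: one gap-rich row makes all its
    # partners look bad, so removal must be greedy
    keep = list(range(len(keys)))
    while len(keep) > 1:
        sub = frac[np.ix_(keep, keep)]
        n_bad = (sub < min_comparable).sum(axis=1)
        if n_bad.max() == 0:
            break
        worst = keep[int(np.argmax(n_bad))]
        logger.warning(
            "dropping row %s: <%.0f%% comparable columns with some partner",
            row_label(keys[worst]), 100 * min_comparable,
        )
        keep.remove(worst)
    if len(keep) < len(keys):
        keys = [keys[i] for i in keep]
        comp = comp[np.ix_(keep, keep)]
        match = match[np.ix_(keep, keep)]
    if len(keys) < 4:
        raise ValueError("fewer than 4 usable rows")
    labels = [row_label(k) for k in keys]

    D_full = _distance_matrix(comp, match, None, ceiling)
    full = nj_tree(pd.DataFrame(D_full, index=labels, columns=labels))
    want = bipartitions(full)
    hits = {side: 0 for side in want}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        cols = rng.integers(0, ncols, size=ncols)
        D = _distance_matrix(comp, match, cols, ceiling)
        rep = nj_tree(pd.DataFrame(D, index=labels, columns=labels))
        rep_bips = bipartitions(rep)
        for side in want:
            if side in rep_bips:
                hits[side] += 1

    # annotate supports on the full tree's internal nodes
    all_leaves = frozenset(labels)
    ref = min(all_leaves)

    def annotate(node: Node, is_top: bool) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name or ""])
        below = frozenset().union(*(annotate(c, False) for c in node.children))
        if not is_top and 1 < len(below) < len(all_leaves) - 1:
            side = below if ref not in below else all_leaves - below
            node.support = hits[side] / n_boot
        return below

    annotate(full, True)
    return SupportTree(root=full, threshold=threshold, rooted=False)


# ---------------------------------------------------------------------------
# rooting


class OutgroupError(ValueError):
    pass


def root_tree(t: SupportTree, outgroup_labels: Iterable[str]) -> SupportTree:
    """Root on the branch separating the outgroup from the ingroup.

    The outgroup must be present and monophyletic in the unrooted tree;
    otherwise an OutgroupError reports the offending split.  Edge supports
    are carried over unchanged (a bipartition keeps its support)."""
    out = frozenset(outgroup_labels)
    tree = t.root
    leaves = frozenset(tree.leaf_names())
    if not out:
        raise OutgroupError("empty outgroup")
    missing = out - leaves
    if missing:
        raise OutgroupError(f"outgroup labels not in tree: {sorted(missing)}")
    if out == leaves:
        raise OutgroupError("outgroup cannot be all taxa")

    # undirected edge list; supports live on edges
    node_ids: dict[int, Node] = {}
    adj: dict[int, list[tuple[int, float, float | None]]] = {}
    leafsets: dict[int, frozenset[str]] = {}

    def index(node: Node) -> frozenset[str]:
        node_ids[id(node)] = node
        adj.setdefault(id(node), [])
        if node.is_leaf:
            leafsets[id(node)] = frozenset([node.name or ""])
        else:
            below = frozenset()
            for c in node.children:
                below |= index(c)
                adj[id(node)].append((id(c), c.length, c.support))
                adj.setdefault(id(c), []).append((id(node), c.length, c.support))
            leafsets[id(node)] = below
        return leafsets[id(node)]

    index(tree)

    # the outgroup edge: a non-top node whose leafset (or complement) is out
    target = None
    for nid, ls in leafsets.items():
        if node_ids[nid] is tree:
            continue
        if ls == out or leaves - ls == out:
            target = nid
            break
    if target is None:
        best = leaves
        for ls in leafsets.values():
            if out <= ls and len(ls) < len(best):
                best = ls
        raise OutgroupError(
            f"outgroup not monophyletic: smallest containing clade is {sorted(best)}"
        )

    # the neighbor on the far side of the outgroup edge (target's parent in
    # the original orientation, i.e. the side whose leafset grows)
    for other, length, support in adj[target]:
        if not (leafsets[other] < leafsets[target]):
            parent_id, edge_len, edge_sup = other, length, support
            break
    else:  # pragma: no cover
        raise OutgroupError("could not locate outgroup edge")

    half = edge_len / 2.0

    def build(nid: int, came_from: int | None, length: float,
              support: float | None) -> Node:
        orig = node_ids[nid]
        kids = [
            build(other, nid, l, s)
            for other, l, s in adj[nid]
            if other != came_from
        ]
        return Node(
            name=orig.name if orig.is_leaf else None,
            length=length,
            support=None if not kids else support,
            children=kids,
        )

    og_side = build(target, parent_id, half, edge_sup)
    in_side = build(parent_id, target, half, edge_sup)
    root = Node(children=[og_side, in_side])
    return SupportTree(root=root, threshold=t.threshold, rooted=True)


def unroot(tree: Node) -> Node:
    """Collapse a root bifurcation into a trifurcation (round-trip helper)."""
    t = tree.copy()
    if len(t.children) != 2:
        return t
    a, b = t.children
    if b.is_leaf and not a.is_leaf:
        a, b = b, a
    if b.is_leaf:
        return t
    merged = Node(children=[a] + b.children)
    a.length = a.length + b.length
    return merged
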