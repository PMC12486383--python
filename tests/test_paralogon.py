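"""Supermatrix construction, neighbor joining, bootstrap, rooting."""

import numpy as np
import pandas as pd
import pytest

from synopsin.genomeio import GeneRecord
from synopsin.paralogon import (
    OutgroupError,
    Supermatrix,
    bootstrap_tree,
    build_supermatrix,
    nj_tree,
    root_tree,
    row_label,
    unroot,
)
from synopsin.trees import Node, bipartitions, parse_newick, support_of_bipartition


def gene(gid, sp, chrom):
    return GeneRecord(
        gene_id=gid, species=sp, seq_id=chrom, start=0, end=10, strand="+"
    )


class TestSupermatrix:
    def test_two_by_two_arithmetic(self):
        genes = [
            gene("f1a", "s", "c1"), gene("f1b", "s", "c2"),
            gene("f2a", "s", "c1"), gene("f2b", "s", "c2"),
        ]
        msas = {
            "fam1": {"s:f1a": "A" * 100, "s:f1b": "C" * 100},
            "fam2": {"s:f2a": "D" * 150, "s:f2b": "E" * 150},
        }
        sm = build_supermatrix(msas, genes)
        assert len(sm.rows) == 2
        assert sm.n_columns == 250
        assert sm.partitions == {"fam1": (0, 100), "fam2": (100, 250)}
        assert sm.rows[("s", "c1")] == "A" * 100 + "D" * 150

    def test_absent_family_is_all_gap(self):
        genes = [
            gene("f1a", "s", "c1"), gene("f1b", "s", "c2"),
            gene("f2a", "s", "c1"),
        ]
        msas = {
            "fam1": {"s:f1a": "AA", "s:f1b": "CC"},
            "fam2": {"s:f2a": "DD"},
        }
        sm = build_supermatrix(msas, genes)
        assert sm.segment(("s", "c2"), "fam2") == "--"

    def test_duplicate_member_resolved_by_consensus(self, caplog):
        genes = [
            gene("x1", "s", "c1"), gene("x2", "s", "c1"), gene("y", "s", "c2"),
        ]
        msas = {"fam": {"s:x1": "AAAA", "s:x2": "AACC", "s:y": "AAAA"}}
        import logging

        with caplog.at_level(logging.WARNING, logger="synopsin.paralogon"):
            sm = build_supermatrix(msas, genes)
        # consensus is AAA/AAAA-like; x1 matches it better than x2
        assert sm.segment(("s", "c1"), "fam") == "AAAA"
        assert any("multiple members" in r.message for r in caplog.records)

    def test_ragged_family_rejected(self):
        genes = [gene("a", "s", "c1"), gene("b", "s", "c2")]
        with pytest.raises(ValueError, match="unequal"):
            build_supermatrix({"fam": {"s:a": "AAA", "s:b": "AA"}}, genes)

    def test_row_count_matches_truth(self, skeleton_bundle):
        b = skeleton_bundle
        species = ("sea_lamprey", "pouched_lamprey", "ref_jawless")
        genes = [g for sp in species for g in b.genomes.species[sp]]
        anchors = ("F1", "F2", "F3", "GNAT")
        msas = {
            fam: {
                f"{g.species}:{g.gene_id}": "A" * 50
                for g in genes
                if g.family == fam
            }
            for fam in anchors
        }
        sm = build_supermatrix(msas, genes)
        expected = {
            (g.species, g.seq_id) for g in genes if g.family in anchors
        }
        assert set(sm.rows) == expected


def random_tree_distances(rng, n_taxa):
    """A random rooted binary tree with positive branch lengths and its
    exact path-length (additive) distance matrix."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [Node(name=l, length=float(rng.uniform(0.05, 2.0))) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = Node(children=[nodes[i], nodes[j]],
                      length=float(rng.uniform(0.05, 2.0)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = nodes[0]

    dist = {}

    def walk(node, acc):
        if node.is_leaf:
            dist[node.name] = acc
            return
        for c in node.children:
            walk(c, acc + [(c, c.length)])

    paths = {}

    def collect(node, path):
        if node.is_leaf:
            paths[node.name] = path
            return
        for c in node.children:
            collect(c, path + [c])

    collect(root, [])
    D = pd.DataFrame(0.0, index=labels, columns=labels)
    for a in labels:
        for b in labels:
            if a == b:
                continue
            pa, pb = paths[a], paths[b]
            shared = 0
            for x, y in zip(pa, pb):
                if x is y:
                    shared += 1
                else:
                    break
            D.loc[a, b] = sum(n.length for n in pa[shared:]) + sum(
                n.length for n in pb[shared:]
            )
    return root, D


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        t = nj_tree(D)
        lengths = {c.name: c.length for c in t.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,C:3,D:4) as an unrooted additive matrix
        D = pd.DataFrame(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 0o7, 0],
            ],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        t = nj_tree(D)
        assert bipartitions(t) == {frozenset({"C", "D"})} or bipartitions(t) == {
            frozenset({"A", "B"})
        }
        # all pairwise path lengths reproduced exactly
        assert _tree_distance(t, "A", "B") == pytest.approx(3.0)
        assert _tree_distance(t, "C", "D") == pytest.approx(7.0)
        assert _tree_distance(t, "A", "D") == pytest.approx(6.0)

    @pytest.mark.parametrize("trial", range(200))
    def test_additive_matrices_recovered_exactly(self, trial):
        """NJ is consistent on additive matrices: topology and branch
        lengths of random trees (<= 8 taxa) are recovered exactly."""
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 9))
        true_tree, D = random_tree_distances(rng, n)
        est = nj_tree(D)
        assert bipartitions(est) == bipartitions(unroot(true_tree))
        for a in D.index[:3]:
            for b in D.columns:
                if a != b:
                    assert _tree_distance(est, a, b) == pytest.approx(
                        D.loc[a, b], abs=1e-9
                    )

    def test_taxon_permutation_leaves_topology_unchanged(self):
        rng = np.random.default_rng(77)
        _, D = random_tree_distances(rng, 6)
        base = bipartitions(nj_tree(D))
        perm = list(D.index)[::-1]
        assert bipartitions(nj_tree(D.loc[perm, perm])) == base

    def test_cross_check_against_scikit_bio(self):
        """Independent implementation agreement on non-additive matrices."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(123)
        for _ in range(10):
            n = 6
            M = rng.uniform(0.1, 2.0, size=(n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0.0)
            labels = [f"t{i}" for i in range(n)]
            D = pd.DataFrame(M, index=labels, columns=labels)
            ours = bipartitions(nj_tree(D))
            sk = skbio_nj(DistanceMatrix(M, ids=labels))
            theirs = set()
            for node in sk.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < n - 1:
                    all_l = frozenset(labels)
                    ref = min(all_l)
                    theirs.add(side if ref not in side else all_l - side)
            assert ours == theirs

    @pytest.mark.parametrize(
        "bad",
        [
            pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB")),
            pd.DataFrame(
                [[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]],
                index=list("ABC"), columns=list("ABC"),
            ),
            pd.DataFrame(
                [[0, 1, -2], [1, 0, 1], [-2, 1, 0]],
                index=list("ABC"), columns=list("ABC"),
            ),
        ],
    )
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValueError):
            nj_tree(bad)


def _tree_distance(tree, a, b):
    # path length between two leaves
    def path(node, target, acc):
        if node.is_leaf:
            return acc + [node] if node.name == target else None
        for c in node.children:
            r = path(c, target, acc + [node])
            if r:
                return r
        return None

    pa = path(tree, a, [])
    pb = path(tree, b, [])
    shared = 0
    for x, y in zip(pa, pb):
        if x is y:
            shared += 1
        else:
            break
    return sum(n.length for n in pa[shared:]) + sum(n.length for n in pb[shared:])


def clade_supermatrix():
    """Four rows in two clades separated by many substitutions."""
    a = "A" * 60
    b = "C" * 30 + "D" * 30
    rows = {
        ("s", "c1"): a, ("s", "c2"): a,
        ("s", "c3"): b, ("s", "c4"): b,
    }
    return Supermatrix(rows=rows, partitions={"fam": (0, 60)})


class TestBootstrap:
    def test_forced_bipartition_gets_full_support(self):
        st = bootstrap_tree(clade_supermatrix(), n_boot=100, seed=0)
        side = frozenset({row_label(("s", "c1")), row_label(("s", "c2"))})
        other = frozenset({row_label(("s", "c3")), row_label(("s", "c4"))})
        sup = support_of_bipartition(st.root, side) or support_of_bipartition(
            st.root, other
        )
        assert sup == 1.0
        assert st.reliable_bipartitions()

    def test_reproducible_with_fixed_seed(self):
        t1 = bootstrap_tree(clade_supermatrix(), n_boot=100, seed=5).newick()
        t2 = bootstrap_tree(clade_supermatrix(), n_boot=100, seed=5).newick()
        assert t1 == t2

    def test_too_few_rows_rejected(self):
        sm = Supermatrix(
            rows={("s", "c1"): "AA", ("s", "c2"): "AA", ("s", "c3"): "CC"},
            partitions={"f": (0, 2)},
        )
        with pytest.raises(ValueError, match="fewer than 4|>= 100"):
            bootstrap_tree(sm, n_boot=100, seed=0)

    def test_gap_rich_row_dropped(self):
        rows = dict(clade_supermatrix().rows)
        rows[("s", "c5")] = "-" * 59 + "A"
        sm = Supermatrix(rows=rows, partitions={"fam": (0, 60)})
        st = bootstrap_tree(sm, n_boot=100, seed=0, min_comparable=0.10)
        assert row_label(("s", "c5")) not in st.root.leaf_names()


class TestRooting:
    def make_support_tree(self):
        st = bootstrap_tree(clade_supermatrix(), n_boot=100, seed=1)
        return st

    def test_root_on_outgroup_pendant(self):
        st = self.make_support_tree()
        out = row_label(("s", "c1"))
        rooted = root_tree(st, {out})
        assert len(rooted.root.children) == 2
        sides = [frozenset(c.leaf_names()) for c in rooted.root.children]
        assert frozenset({out}) in sides

    def test_outgroup_clade_rooting_preserves_supports(self):
        st = self.make_support_tree()
        og = {row_label(("s", "c1")), row_label(("s", "c2"))}
        rooted = root_tree(st, og)
        side = frozenset(og)
        assert support_of_bipartition(rooted.root, side) == 1.0

    def test_all_taxa_outgroup_rejected(self):
        st = self.make_support_tree()
        with pytest.raises(OutgroupError, match="all taxa"):
            root_tree(st, set(st.root.leaf_names()))

    def test_non_monophyletic_outgroup_reports_clade(self):
        st = self.make_support_tree()
        og = {row_label(("s", "c1")), row_label(("s", "c3"))}
        with pytest.raises(OutgroupError, match="not monophyletic"):
            root_tree(st, og)

    def test_root_then_unroot_restores_bipartitions(self):
        st = self.make_support_tree()
        before = bipartitions(st.root)
        rooted = root_tree(st, {row_label(("s", "c1"))})
        after = bipartitions(unroot(rooted.root))
        assert after == before


class TestNewickParsing:
    def test_round_trip(self):
        t = parse_newick("((A:1,B:2)0.9:0.5,C:3,D:4);")
        assert sorted(t.leaf_names()) == ["A", "B", "C", "D"]
        back = parse_newick(t.to_newick())
        assert bipartitions(back) == bipartitions(t)
        inner = [n for n in t.preorder() if not n.is_leaf and n is not t]
        assert inner[0].support == 0.9
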