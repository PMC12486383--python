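"""Alignment, distances, orthogroups, anchor-family selection."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synopsin import presets
from synopsin.genomeio import GeneRecord
from synopsin.homology import (
    AlignParams,
    Orthogroup,
    SATURATION_P,
    _blosum_array,
    build_orthogroups,
    msa_profile,
    percent_identity,
    poisson_distance,
    profile_align,
    select_anchor_families,
)
from synopsin.simulate import (
    AA_ALPHABET,
    AncestralGenome,
    EventRates,
    SpeciesTreeSpec,
    evolve_sequences,
    random_root_proteins,
    simulate_history,
)

AA = st.sampled_from(AA_ALPHABET)
PROTEIN = st.text(alphabet=AA_ALPHABET, min_size=1, max_size=12)


# ---------------------------------------------------------------------------
# independent oracle: exhaustive global affine-gap alignment


def brute_force_profile_score(query, freqs, S, go, ge):
    """Enumerate every global alignment as a path of (match/delete/insert)
    moves; return the optimal affine-gap score.  Exponential: tiny only."""
    from functools import lru_cache

    aa_index = {a: i for i, a in enumerate(AA_ALPHABET)}
    m, L = len(query), freqs.shape[0]

    best = [-math.inf]

    def sub(i, j):
        return float(S[aa_index[query[i]]] @ freqs[j])

    def rec(i, j, score, last):
        if i == m and j == L:
            best[0] = max(best[0], score)
            return
        if i < m and j < L:
            rec(i + 1, j + 1, score + sub(i, j), "M")
        if j < L:  # delete: gap in query
            pen = ge if last == "X" else go
            rec(i, j + 1, score - pen, "X")
        if i < m:  # insert: gap in reference
            pen = ge if last == "Y" else go
            rec(i + 1, j, score - pen, "Y")

    rec(0, 0, 0.0, "")
    return best[0]


class TestProfileAlign:
    def test_query_identical_to_reference_row(self):
        msa = {"r1": "MKVL", "r2": "MKIL"}
        pa = profile_align("MKVL", msa)
        assert pa.query_on_reference() == "MKVL"
        assert percent_identity(pa.query_row, pa.ref_rows["r1"]) == 1.0

    def test_single_column_profile_single_residue(self):
        pa = profile_align("M", {"r": "M"})
        S = _blosum_array("BLOSUM62")
        expected = S[AA_ALPHABET.index("M"), AA_ALPHABET.index("M")]
        assert pa.score == pytest.approx(expected)
        assert pa.query_row == "M"

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle_on_tiny_instances(self, seed):
        rng = np.random.default_rng(seed)
        q = "".join(rng.choice(list(AA_ALPHABET), size=8))
        rows = {
            f"r{k}": "".join(rng.choice(list(AA_ALPHABET), size=10))
            for k in range(3)
        }
        params = AlignParams()
        pa = profile_align(q, rows, params)
        freqs = msa_profile(rows)
        S = _blosum_array(params.matrix)
        oracle = brute_force_profile_score(
            q, freqs, S, params.gap_open, params.gap_extend
        )
        assert pa.score == pytest.approx(oracle, abs=1e-9)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            profile_align("", {"r": "M"})

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            profile_align("MX", {"r": "MK"})

    def test_score_never_below_all_gap_alignment(self):
        params = AlignParams()
        rng = np.random.default_rng(1)
        for _ in range(5):
            q = "".join(rng.choice(list(AA_ALPHABET), size=6))
            rows = {"r": "".join(rng.choice(list(AA_ALPHABET), size=9))}
            pa = profile_align(q, rows, params)
            m, L = len(q), 9
            all_gap = -(params.gap_open + params.gap_extend * (L - 1)) - (
                params.gap_open + params.gap_extend * (m - 1)
            )
            assert pa.score >= all_gap


class TestPercentIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("MKVL", "MKVL", 1.0),
            ("A-C", "AGC", 1.0),
            ("AAC", "AGC", 2 / 3),
            ("---", "AG-", 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert percent_identity(a, b) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            percent_identity("AB", "ABC")

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_naive_column_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        alpha = list(AA_ALPHABET + "-")
        a = "".join(rng.choice(alpha, size=n))
        b = "".join(rng.choice(alpha, size=n))
        comp = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
        naive = (
            sum(1 for x, y in comp if x == y) / len(comp) if comp else 0.0
        )
        assert percent_identity(a, b) == pytest.approx(naive)


class TestPoissonDistance:
    def test_zero(self):
        assert poisson_distance(0.0) == 0.0

    def test_formula_at_half(self):
        assert poisson_distance(0.5) == pytest.approx(
            -0.95 * math.log(1 - 10 / 19)
        )

    def test_saturation_returns_ceiling_with_flag(self):
        d, sat = poisson_distance(0.96, ceiling=7.5, with_flag=True)
        assert d == 7.5 and sat

    def test_strictly_increasing(self):
        ps = np.linspace(0, SATURATION_P - 1e-6, 200)
        ds = [poisson_distance(float(p), ceiling=math.inf) for p in ps]
        assert all(b > a for a, b in zip(ds, ds[1:]))

    def test_round_trip_with_simulator_closed_form(self):
        from synopsin.simulate import p_differ

        for d in (0.05, 0.3, 0.9, 1.5):
            assert poisson_distance(p_differ(d), ceiling=math.inf) == pytest.approx(d)


def _two_species_proteomes():
    rng = np.random.default_rng(0)
    fam1 = "".join(rng.choice(list(AA_ALPHABET), size=80))
    fam2 = "".join(rng.choice(list(AA_ALPHABET), size=80))
    return {
        "sp1": {"a1": fam1, "b1": fam2},
        "sp2": {"a2": fam1, "b2": fam2},
    }


class TestOrthogroups:
    def test_mutual_best_single_pair(self):
        p = _two_species_proteomes()
        groups = build_orthogroups(
            {"sp1": {"a1": p["sp1"]["a1"]}, "sp2": {"a2": p["sp2"]["a2"]}}
        )
        assert len(groups) == 1
        assert groups[0].members == frozenset({"sp1:a1", "sp2:a2"})

    def test_unrelated_genes_stay_singletons(self):
        rng = np.random.default_rng(4)
        proteomes = {
            "sp1": {"x": "".join(rng.choice(list(AA_ALPHABET), size=90))},
            "sp2": {"y": "".join(rng.choice(list(AA_ALPHABET), size=90))},
        }
        groups = build_orthogroups(proteomes, min_identity=0.3)
        assert sorted(len(g.members) for g in groups) == [1, 1]

    def test_species_order_invariance(self):
        p = _two_species_proteomes()
        g1 = build_orthogroups(p)
        g2 = build_orthogroups(dict(reversed(list(p.items()))))
        assert [g.members for g in g1] == [g.members for g in g2]

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_orthogroups({"sp1": {}, "sp2": {"a": "MKV"}})

    def test_recovers_truth_families_on_simulated_data(self):
        """No-loss, moderate-divergence simulation: orthogroups equal the
        truth families exactly (adjusted Rand index 1)."""
        from sklearn.metrics import adjusted_rand_score

        anc = AncestralGenome(
            chromosomes={"c1": (("A", "+"), ("B", "+"), ("C", "+"))},
            gene_lengths={"A": 200, "B": 200, "C": 200},
        )
        spec = SpeciesTreeSpec(
            newick="((sp1:0.15,sp2:0.15)inner:0.0)root;",
            wgd_events=(("inner", "WGD"),),
        )
        truth, _ = simulate_history(spec, anc, EventRates(), 0)
        roots = random_root_proteins(["A", "B", "C"], anc.gene_lengths, 8)
        gs = evolve_sequences(truth, roots, {}, seed=8)
        proteomes = {
            sp: {g.gene_id: g.protein for g in gs.species[sp]}
            for sp in gs.species
        }
        fam_of = {
            f"{sp}:{g.gene_id}": g.family
            for sp in gs.species
            for g in gs.species[sp]
        }
        groups = build_orthogroups(proteomes, min_identity=0.3)
        labels_true, labels_pred = [], []
        for gi, og in enumerate(groups):
            for m in sorted(og.members):
                labels_true.append(fam_of[m])
                labels_pred.append(gi)
        assert adjusted_rand_score(labels_true, labels_pred) == 1.0


def _selector_fixture():
    """Focal species chromosomes: opsin-bearing {o1, o2}; other chr {n1, n2}."""
    genes = []

    def add(sp, gid, chrom):
        genes.append(
            GeneRecord(gene_id=gid, species=sp, seq_id=chrom, start=0, end=10,
                       strand="+")
        )

    # famA: on both opsin chromosomes of focal + a third chromosome: passes
    add("focal", "A1", "o1"); add("focal", "A2", "o2"); add("focal", "A3", "n1")
    # famB: only one opsin chromosome: fails rule (a)
    add("focal", "B1", "o1"); add("focal", "B2", "n1"); add("focal", "B3", "n2")
    # famC: two opsin chromosomes but only two chromosomes total: fails (b)
    add("focal", "C1", "o1"); add("focal", "C2", "o2")
    groups = [
        Orthogroup("famA", frozenset({"focal:A1", "focal:A2", "focal:A3"})),
        Orthogroup("famB", frozenset({"focal:B1", "focal:B2", "focal:B3"})),
        Orthogroup("famC", frozenset({"focal:C1", "focal:C2"})),
    ]
    return groups, genes


class TestAnchorSelection:
    def test_rule_on_constructed_fixture(self):
        groups, genes = _selector_fixture()
        sel = select_anchor_families(
            groups, genes, focal_species="focal", opsin_chromosomes={"o1", "o2"}
        )
        assert sel == ["famA"]

    def test_single_opsin_chromosome_excluded(self):
        groups, genes = _selector_fixture()
        sel = select_anchor_families(
            groups, genes, focal_species="focal", opsin_chromosomes={"o1"}
        )
        assert sel == []

    def test_pooled_counting_across_group_species(self):
        groups, genes = _selector_fixture()
        genes = genes + [
            GeneRecord(gene_id="C3", species="other", seq_id="n9", start=0,
                       end=10, strand="+")
        ]
        groups = groups[:2] + [
            Orthogroup("famC", frozenset({"focal:C1", "focal:C2", "other:C3"}))
        ]
        sel = select_anchor_families(
            groups, genes, focal_species="focal", opsin_chromosomes={"o1", "o2"}
        )
        # pooled across species, famC now spans three chromosomes
        assert sel == ["famA", "famC"]

    def test_monotone_in_both_thresholds(self):
        groups, genes = _selector_fixture()
        base = set(
            select_anchor_families(
                groups, genes, "focal", {"o1", "o2"},
                min_opsin_chroms=1, min_species_chroms=1,
            )
        )
        for mo, ms in itertools.product((1, 2, 3), (1, 2, 3, 4)):
            sel = set(
                select_anchor_families(
                    groups, genes, "focal", {"o1", "o2"},
                    min_opsin_chroms=mo, min_species_chroms=ms,
                )
            )
            assert sel <= base
            tighter = set(
                select_anchor_families(
                    groups, genes, "focal", {"o1", "o2"},
                    min_opsin_chroms=mo + 1, min_species_chroms=ms,
                )
            )
            assert tighter <= sel

    def test_empty_opsin_chromosomes_rejected(self):
        groups, genes = _selector_fixture()
        with pytest.raises(ValueError, match="non-empty"):
            select_anchor_families(groups, genes, "focal", set())

    def test_selector_matches_truth_on_simulation(self, skeleton_bundle):
        """On the default scenario, the families satisfying the rule can be
        enumerated from the truth ledger; the selector (fed truth-family
        orthogroups) returns exactly those."""
        b = skeleton_bundle
        focal = "sea_lamprey"
        genes = [g for sp in b.genomes.species for g in b.genomes.species[sp]]
        labels = b.truth_subtypes(focal)
        opsin_chroms = {
            g.seq_id for g in b.genomes.species[focal] if g.gene_id in labels
        }
        jawless = set(presets.JAWLESS_SPECIES)
        fam_members = {}
        for sp in jawless:
            for g in b.genomes.species[sp]:
                fam_members.setdefault(g.family, set()).add(f"{sp}:{g.gene_id}")
        groups = [
            Orthogroup(fam, frozenset(m)) for fam, m in sorted(fam_members.items())
        ]
        expected = set()
        for fam in fam_members:
            focal_chroms = {
                g.seq_id
                for g in b.genomes.species[focal]
                if g.family == fam and g.seq_id in opsin_chroms
            }
            pooled = {
                g.seq_id
                for sp in jawless
                for g in b.genomes.species[sp]
                if g.family == fam
            }
            if len(focal_chroms) >= 2 and len(pooled) >= 3:
                expected.add(fam)
        sel = select_anchor_families(
            groups,
            [g for sp in jawless for g in b.genomes.species[sp]],
            focal_species=focal,
            opsin_chromosomes=opsin_chroms,
            group_species=jawless,
        )
        assert set(sel) == expected

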