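"""Reproducible simulation experiments over the default study conditions.

Each function generates its own inputs with the synthetic-genome
simulator, runs one pipeline capability on them, and returns summary
statistics.  They are the backbone of the validation suite and of the
repository's results-reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import presets
from .classify import classify_subtype
from .paralogon import build_supermatrix, bootstrap_tree
from .simulate import EventRates, simulate_history
from .tandem import scan_pairs
from .trees import support_of_bipartition


def pattern_recovery(seeds, window: int = 100_000) -> dict:
    """Fraction of simulation seeds whose proximal tandem pairs match the
    expected lineage patterns exactly (jawless: RH1+LWS and RH2+SWS2;
    jawed: LWS+SWS2), using truth subtype labels."""
    hits = 0
    for seed in seeds:
        b = presets.paper_scenario(seed=seed, with_sequences=False)
        jl = {
            e.subtype_pair
            for sp in presets.JAWLESS_SPECIES
            for e in scan_pairs(b.labelled_genes(sp), window=window)
            if e.proximal
        }
        ja = {
            e.subtype_pair
            for sp in presets.JAWED_SPECIES
            for e in scan_pairs(b.labelled_genes(sp), window=window)
            if e.proximal
        }
        ok = jl == {("LWS", "RH1"), ("RH2", "SWS2")} and ja == {("LWS", "SWS2")}
        hits += ok
    return {"n_seeds": len(list(seeds)), "n_recovered": hits,
            "rate": hits / max(len(list(seeds)), 1)}


def chromosome_copy_numbers(seed: int = 0) -> dict:
    """Chromosome copy counts per ancestral chromosome under the default
    WGD structure with no gene loss, read from the truth ledger."""
    tree = presets.default_tree()
    ancestor = presets.default_ancestor()
    truth, _ = simulate_history(tree, ancestor, EventRates(), seed=seed)
    jawless = {
        len(truth.chromosome_copies(sp, chrom))
        for sp in presets.JAWLESS_SPECIES
        for chrom in ancestor.chromosomes
    }
    jawed = {
        len(truth.chromosome_copies(sp, chrom))
        for sp in presets.JAWED_SPECIES
        for chrom in ancestor.chromosomes
    }
    return {
        "jawless_copies": sorted(jawless),
        "jawed_copies": sorted(jawed),
    }


def classifier_recovery(seed: int = 0, n_boot: int = 200) -> dict:
    """Accuracy of accepted subtype assignments against simulator truth,
    for query species classified against the reference species' rows."""
    b = presets.paper_scenario(seed=seed)
    db = b.reference_db
    assert db is not None
    total = correct = 0
    sum_dev = 0.0
    queries = [
        sp
        for sp in list(presets.JAWLESS_SPECIES) + list(presets.JAWED_SPECIES)
        if sp not in presets.REFERENCE_SPECIES
    ]
    for i, sp in enumerate(queries):
        labels = b.truth_subtypes(sp)
        genes = {g.gene_id: g for g in b.genomes.species[sp]}
        for j, (gid, true_sub) in enumerate(sorted(labels.items())):
            res = classify_subtype(
                genes[gid].protein, db, n_boot=n_boot,
                seed=(seed * 7919 + i * 131 + j) % (2**31 - 1),
                gene_id=gid,
            )
            sum_dev += abs(sum(res.support_by_subtype.values()) - 1.0)
            if res.accepted:
                total += 1
                correct += res.subtype == true_sub
    return {
        "n_accepted": total,
        "n_correct": correct,
        "accuracy": correct / total if total else float("nan"),
        "max_support_sum_deviation": sum_dev,
    }


@dataclass
class _CladeCheck:
    both_reliable: bool
    supports: tuple[float | None, float | None]


def _check_1r_clades(tree_root, threshold: float) -> _CladeCheck:
    leaves = set(tree_root.leaf_names())
    A = frozenset(l for l in leaves if "@O_A" in l)
    B = frozenset(l for l in leaves if "@O_B" in l)
    sA = support_of_bipartition(tree_root, A) if len(A) > 1 else None
    sB = support_of_bipartition(tree_root, B) if len(B) > 1 else None
    ok = (
        sA is not None and sA >= threshold and sB is not None and sB >= threshold
    )
    return _CladeCheck(ok, (sA, sB))


def paralogon_signal(
    n_replicates: int = 50,
    seed: int = 0,
    n_boot: int = 100,
    threshold: float = 0.95,
    divergence_scale: float = 1.0,
) -> dict:
    """The anchor-concatenation advantage.

    Per replicate: simulate the default scenario, build the
    chromosome-keyed supermatrix over the jawless species plus the
    pre-WGD outgroup, and test whether both shared-WGD chromosome clades
    are recovered with reliable support — for the concatenated matrix
    and for each anchor family alone."""
    anchors = list(presets.ANCHOR_FAMILIES)
    extra = ["GNAT", "GNAI", "PP"]
    concat_ok = 0
    family_trials = family_fails = 0
    for r in range(n_replicates):
        b = presets.paper_scenario(
            seed=seed + 1000 + r, divergence_scale=divergence_scale
        )
        rows_species = list(presets.JAWLESS_SPECIES) + [presets.OUTGROUP_SPECIES]
        genes = [g for sp in rows_species for g in b.genomes.species[sp]]
        msas = {
            fam: {
                f"{g.species}:{g.gene_id}": g.protein
                for g in genes
                if g.family == fam and g.protein
            }
            for fam in anchors + extra
        }
        sm = build_supermatrix(msas, genes)
        st = bootstrap_tree(sm, n_boot=n_boot, seed=seed + r, threshold=threshold)
        if _check_1r_clades(st.root, threshold).both_reliable:
            concat_ok += 1
        for fam in anchors:
            family_trials += 1
            smf = build_supermatrix({fam: msas[fam]}, genes)
            try:
                stf = bootstrap_tree(
                    smf, n_boot=n_boot, seed=seed + r, threshold=threshold
                )
            except ValueError:
                family_fails += 1
                continue
            if not _check_1r_clades(stf.root, threshold).both_reliable:
                family_fails += 1
    return {
        "n_replicates": n_replicates,
        "concat_recovery_rate": concat_ok / n_replicates,
        "single_family_failure_rate": family_fails / family_trials,
    }
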