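"""File-based orchestration of the full analysis.

Stages communicate only through files in the run directory, so each
stage is independently runnable and testable:

    simulate   genomes/<sp>.faa + .gff3, taxa.tsv, refdb/, truth ledger
    classify   assignments/<sp>.tsv
    scan       pairs.tsv, pair_summary.tsv
    families   orthogroups.tsv, selected_families.tsv
    paralogon  supermatrix.faa + partitions.tsv, paralogon_tree.nwk
    scenarios  observed_arrangement.tsv, hypothesis_ranking.tsv, scenario_events.tsv

A manifest (config hash, seed, versions, per-stage row counts, output
checksums) makes reruns byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, presets
from .classify import (
    ReferenceDB,
    assignments_to_tsv,
    classify_proteome,
    read_assignments,
    VISUAL_SUBTYPES,
)
from .genomeio import (
    GeneRecord,
    read_gff3,
    read_fasta,
    read_taxon_table,
    write_taxon_table,
)
from .homology import build_orthogroups, select_anchor_families
from .paralogon import build_supermatrix, bootstrap_tree, root_tree, row_label
from .scenarios import (
    ObservedArrangement,
    ObservedChrom,
    VERTEBRATE_WGD,
    compare_hypotheses,
)
from .simulate import write_genome_set
from .tandem import events_to_tsv, scan_pairs, summarize_pairs, summary_to_tsv

logger = logging.getLogger(__name__)

STAGES = ("simulate", "classify", "scan", "families", "paralogon", "scenarios")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All knobs of one reproducible run."""

    outdir: str = "run"
    seed: int = 1
    window_bp: int = 100_000
    support_threshold: float = 0.95
    min_identity: float = 0.3
    n_boot_classify: int = 200
    n_boot_tree: int = 100
    divergence_scale: float = 1.0
    counting_unit: str = "pairs"
    max_tandems: int = 3
    event_weights: dict = field(
        default_factory=lambda: {"TANDEM_DUP": 1.0, "LOSS": 1.0, "TRANSLOCATION": 1.0}
    )
    focal_species: str = "sea_lamprey"
    jawless_representative: str = "sea_lamprey"
    jawed_representative: str = "spotted_gar"
    families_species: tuple = ("sea_lamprey", "ref_jawed", "amphioxus")
    classify_length_band: tuple = (0.7, 1.3)
    stages: tuple = STAGES

    def validate(self) -> None:
        if self.window_bp <= 0:
            raise PipelineError(f"window_bp must be positive, got {self.window_bp}")
        if not 0 < self.support_threshold <= 1:
            raise PipelineError("support_threshold must be in (0, 1]")
        if not 0 <= self.min_identity <= 1:
            raise PipelineError("min_identity must be in [0, 1]")
        if self.n_boot_classify < 100 or self.n_boot_tree < 100:
            raise PipelineError("bootstrap replicate counts must be >= 100")
        if self.counting_unit not in ("pairs", "species"):
            raise PipelineError(f"unknown counting_unit {self.counting_unit!r}")
        for k, v in self.event_weights.items():
            if v <= 0:
                raise PipelineError(f"event weight {k} must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["families_species"] = list(self.families_species)
        d["classify_length_band"] = list(self.classify_length_band)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("families_species", "classify_length_band", "stages"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def _read_genomes(outdir: Path) -> dict[str, list[GeneRecord]]:
    gdir = outdir / "genomes"
    out = {}
    for gff in sorted(gdir.glob("*.gff3")):
        sp = gff.stem
        genes = read_gff3(gff, species=sp)
        seqs = read_fasta(gdir / f"{sp}.faa")
        for g in genes:
            g.protein = seqs.get(g.gene_id)
        out[sp] = genes
    if not out:
        raise PipelineError(f"no genomes found under {gdir}")
    return out


def _require(outdir: Path, *paths: str) -> None:
    missing = [p for p in paths if not (outdir / p).exists()]
    if missing:
        raise PipelineError(f"missing stage inputs: {missing}")


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    bundle = presets.paper_scenario(
        seed=cfg.seed, divergence_scale=cfg.divergence_scale
    )
    write_genome_set(bundle.genomes, bundle.truth, outdir / "genomes")
    write_taxon_table(bundle.taxa, outdir / "taxa.tsv")
    assert bundle.reference_db is not None
    bundle.reference_db.to_dir(outdir / "refdb")
    rows = []
    for sp in sorted(bundle.genomes.species):
        for gid, sub in sorted(bundle.truth_subtypes(sp).items()):
            rows.append({"species": sp, "gene_id": gid, "subtype": sub})
    pd.DataFrame(rows).to_csv(outdir / "truth_subtypes.tsv", sep="\t", index=False)
    n_genes = sum(len(v) for v in bundle.genomes.species.values())
    return {"species": len(bundle.genomes.species), "genes": n_genes}


def stage_classify(cfg: RunConfig, outdir: Path) -> dict:
    _require(outdir, "genomes", "refdb", "taxa.tsv")
    genomes = _read_genomes(outdir)
    db = ReferenceDB.from_dir(outdir / "refdb")
    ref_len = db.n_columns
    lo, hi = cfg.classify_length_band
    adir = outdir / "assignments"
    adir.mkdir(exist_ok=True)
    n = 0
    for i, (sp, genes) in enumerate(sorted(genomes.items())):
        proteome = {
            g.gene_id: g.protein
            for g in genes
            if g.protein and lo * ref_len <= len(g.protein) <= hi * ref_len
        }
        assigns = classify_proteome(
            proteome,
            db,
            n_boot=cfg.n_boot_classify,
            seed=cfg.seed + 1000 * (i + 1),
            threshold=cfg.support_threshold,
        )
        assignments_to_tsv(assigns, adir / f"{sp}.tsv")
        n += len(assigns)
    return {"classified": n}


def _labelled_genes(cfg: RunConfig, outdir: Path) -> list[GeneRecord]:
    genomes = _read_genomes(outdir)
    out = []
    for sp, genes in sorted(genomes.items()):
        path = outdir / "assignments" / f"{sp}.tsv"
        if not path.exists():
            raise PipelineError(f"missing stage inputs: ['assignments/{sp}.tsv']")
        assigns = read_assignments(path)
        for g in genes:
            a = assigns.get(g.gene_id)
            if a is not None and a.accepted and a.subtype in VISUAL_SUBTYPES:
                out.append(replace(g, subtype=a.subtype))
            else:
                out.append(replace(g, subtype=None))
    return out


def stage_scan(cfg: RunConfig, outdir: Path) -> dict:
    _require(outdir, "genomes", "assignments", "taxa.tsv")
    genes = _labelled_genes(cfg, outdir)
    taxa = read_taxon_table(outdir / "taxa.tsv")
    events = scan_pairs(
        [g for g in genes if g.subtype is not None], window=cfg.window_bp
    )
    events_to_tsv(events, outdir / "pairs.tsv")
    summary = summarize_pairs(events, taxa, counting_unit=cfg.counting_unit)
    summary_to_tsv(summary, outdir / "pair_summary.tsv")
    pct_rows = [
        {"distance_class": klass, "group": grp, "percent": pct}
        for klass, shares in summary.group_percentages.items()
        for grp, pct in sorted(shares.items())
    ]
    pd.DataFrame(
        pct_rows, columns=["distance_class", "group", "percent"]
    ).to_csv(outdir / "pair_group_percentages.tsv", sep="\t", index=False)
    return {"pair_events": len(events)}


def stage_families(cfg: RunConfig, outdir: Path) -> dict:
    _require(outdir, "genomes", "assignments", "taxa.tsv")
    genomes = _read_genomes(outdir)
    taxa = read_taxon_table(outdir / "taxa.tsv")
    missing = [sp for sp in cfg.families_species if sp not in genomes]
    if missing:
        raise PipelineError(f"families_species not in genomes: {missing}")
    proteomes = {
        sp: {g.gene_id: g.protein for g in genomes[sp] if g.protein}
        for sp in cfg.families_species
    }
    groups = build_orthogroups(proteomes, min_identity=cfg.min_identity)
    og_rows = [
        {"family_id": og.family_id, "members": ";".join(sorted(og.members))}
        for og in groups
    ]
    pd.DataFrame(og_rows).to_csv(outdir / "orthogroups.tsv", sep="\t", index=False)

    labelled = _labelled_genes(cfg, outdir)
    opsin_chroms = sorted(
        {
            g.seq_id
            for g in labelled
            if g.species == cfg.focal_species and g.subtype is not None
        }
    )
    if not opsin_chroms:
        raise PipelineError(
            f"no opsin-bearing chromosomes found in {cfg.focal_species!r}"
        )
    jawless = set(taxa.species_in("jawless")) & set(cfg.families_species)
    all_genes = [g for sp in cfg.families_species for g in genomes[sp]]
    selected = select_anchor_families(
        groups,
        all_genes,
        focal_species=cfg.focal_species,
        opsin_chromosomes=opsin_chroms,
        group_species=jawless or None,
    )
    # name each selected orthogroup by the majority annotated family label
    by_id = {og.family_id: og for og in groups}
    gene_fam = {f"{g.species}:{g.gene_id}": g.family for g in all_genes}
    rows = []
    for fid in selected:
        fams = [gene_fam.get(m) for m in sorted(by_id[fid].members)]
        fams = [f for f in fams if f]
        label = max(sorted(set(fams)), key=fams.count) if fams else fid
        rows.append({"family_id": fid, "label": label, "n_members": len(by_id[fid].members)})
    pd.DataFrame(rows, columns=["family_id", "label", "n_members"]).to_csv(
        outdir / "selected_families.tsv", sep="\t", index=False
    )
    return {"orthogroups": len(groups), "selected_families": len(selected)}


def stage_paralogon(cfg: RunConfig, outdir: Path) -> dict:
    _require(outdir, "genomes", "selected_families.tsv", "taxa.tsv")
    genomes = _read_genomes(outdir)
    taxa = read_taxon_table(outdir / "taxa.tsv")
    sel = pd.read_csv(outdir / "selected_families.tsv", sep="\t")
    families = sorted(set(sel["label"]))
    if not families:
        raise PipelineError("no selected families to concatenate")
    rows_species = (
        taxa.species_in("jawless")
        + taxa.species_in("non-teleost jawed")
        + taxa.species_in("teleost")
        + taxa.species_in("outgroup")
    )
    rows_species = [sp for sp in rows_species if sp in genomes]
    genes = [g for sp in rows_species for g in genomes[sp]]
    msas = {}
    for fam in families:
        rows = {
            f"{g.species}:{g.gene_id}": g.protein
            for g in genes
            if g.family == fam and g.protein
        }
        if rows:
            msas[fam] = rows
    sm = build_supermatrix(msas, genes)
    sm.write(outdir / "supermatrix.faa", outdir / "partitions.tsv")
    st = bootstrap_tree(
        sm, n_boot=cfg.n_boot_tree, seed=cfg.seed, threshold=cfg.support_threshold
    )
    outgroup = {
        row_label((g.species, g.seq_id))
        for g in genes
        if g.species in taxa.species_in("outgroup")
        and (g.species, g.seq_id) in sm.rows
    }
    rooted = root_tree(st, outgroup) if outgroup else st
    (outdir / "paralogon_tree.nwk").write_text(rooted.newick() + "\n")
    reliable = rooted.reliable_bipartitions()
    pd.DataFrame(
        {"bipartition": ["|".join(sorted(b)) for b in sorted(reliable, key=sorted)]}
    ).to_csv(outdir / "reliable_clades.tsv", sep="\t", index=False)
    return {"rows": len(sm.rows), "columns": sm.n_columns, "reliable_clades": len(reliable)}


def _paralogon_clades(outdir: Path, taxa) -> dict[tuple[str, str], str]:
    """Shared-WGD clade id ("A"/"B") per (species, chromosome), read off
    the rooted paralogon tree: the two children of the ingroup node.
    Empty when the tree is absent or the ingroup does not bifurcate."""
    from .paralogon import parse_row_label
    from .trees import parse_newick

    tree_path = outdir / "paralogon_tree.nwk"
    if not tree_path.exists():
        return {}
    tree = parse_newick(tree_path.read_text())
    outgroup_species = set(taxa.species_in("outgroup"))
    if len(tree.children) != 2:
        return {}
    sides = []
    for child in tree.children:
        rows = {parse_row_label(l) for l in child.leaf_names()}
        sides.append(rows)
    og_side = [i for i, rows in enumerate(sides)
               if all(sp in outgroup_species for sp, _ in rows)]
    if len(og_side) != 1:
        logger.warning("cannot identify outgroup side of the paralogon tree")
        return {}
    ingroup = tree.children[1 - og_side[0]]
    if len(ingroup.children) != 2:
        logger.warning("paralogon ingroup does not bifurcate; no clade ids")
        return {}
    out: dict[tuple[str, str], str] = {}
    # letter assignment is arbitrary but must be consistent across groups,
    # which it is: both lineages' rows sit inside the same two clades
    for letter, clade in zip("AB", ingroup.children):
        for label in clade.leaf_names():
            out[parse_row_label(label)] = letter
    return out


def _observed_from_run(cfg: RunConfig, outdir: Path) -> ObservedArrangement:
    labelled = _labelled_genes(cfg, outdir)
    taxa = read_taxon_table(outdir / "taxa.tsv")
    clades = _paralogon_clades(outdir, taxa)
    sel = pd.read_csv(outdir / "selected_families.tsv", sep="\t")
    anchor_families = set(sel["label"])
    groups: dict[str, list[ObservedChrom]] = {}
    for group, rep in (
        ("jawless", cfg.jawless_representative),
        ("jawed", cfg.jawed_representative),
    ):
        sp_genes = [g for g in labelled if g.species == rep]
        by_chrom: dict[str, list[GeneRecord]] = {}
        for g in sp_genes:
            by_chrom.setdefault(g.seq_id, []).append(g)
        chroms = []
        for chrom in sorted(by_chrom):
            opsins = sorted(
                (g for g in by_chrom[chrom] if g.subtype is not None),
                key=lambda g: g.start,
            )
            if not opsins:
                continue
            has_anchor = any(
                g.family in anchor_families for g in by_chrom[chrom]
            )
            chroms.append(
                ObservedChrom(
                    chrom_id=chrom,
                    genes=tuple((g.subtype, g.strand) for g in opsins),
                    clade=clades.get((rep, chrom)),
                    background=not has_anchor,
                )
            )
        groups[group] = chroms
    return ObservedArrangement.from_dict(groups)


def stage_scenarios(cfg: RunConfig, outdir: Path) -> dict:
    _require(outdir, "genomes", "assignments", "selected_families.tsv")
    obs = _observed_from_run(cfg, outdir)
    rows = []
    for group, chroms in obs.groups:
        for c in chroms:
            rows.append(
                {
                    "group": group,
                    "chrom": c.chrom_id,
                    "genes": ";".join(f"{s}{st}" for s, st in c.genes),
                    "clade": c.clade or "",
                    "background": c.background,
                }
            )
    pd.DataFrame(rows).to_csv(
        outdir / "observed_arrangement.tsv", sep="\t", index=False
    )
    hyps = presets.default_hypotheses()
    table = compare_hypotheses(
        obs,
        hyps,
        weights=cfg.event_weights,
        wgd=VERTEBRATE_WGD,
        max_tandems=cfg.max_tandems,
    )
    table.to_csv(outdir / "hypothesis_ranking.tsv", sep="\t", index=False)
    results = table.attrs["results"]
    best_name = table.iloc[0]["hypothesis"]
    best = results[best_name]
    ev_rows = []
    if best.feasible:
        for e in best.best.events:
            ev_rows.append(
                {
                    "hypothesis": best_name,
                    "kind": e.kind,
                    "branch": e.branch,
                    "gene": e.gene,
                    "target_chrom": e.target_chrom or "",
                    "position": "" if e.position is None else e.position,
                    "strand": e.strand or "",
                }
            )
    pd.DataFrame(
        ev_rows,
        columns=["hypothesis", "kind", "branch", "gene", "target_chrom", "position", "strand"],
    ).to_csv(outdir / "scenario_events.tsv", sep="\t", index=False)
    return {
        "hypotheses": len(hyps),
        "best_hypothesis": str(best_name),
        "best_cost": float(table.iloc[0]["cost"]),
    }


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "classify": stage_classify,
    "scan": stage_scan,
    "families": stage_families,
    "paralogon": stage_paralogon,
    "scenarios": stage_scenarios,
}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the configured stages; returns the run directory.

    A failing stage halts the run with the stage named; outputs of
    completed stages are retained.  Re-running with the same config
    reproduces all outputs byte-identically."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    stage_stats: dict[str, dict] = {}
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        logger.info("stage %s (seed=%d)", stage, cfg.seed)
        try:
            stage_stats[stage] = _STAGE_FUNCS[stage](cfg, outdir)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "version": __version__,
        "stages": stage_stats,
        "outputs": {str(p.relative_to(outdir)): _checksum(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def make_report(outdir: str | Path) -> str:
    """Summarize a completed run as Markdown; missing stage outputs are
    listed explicitly rather than failing."""
    outdir = Path(outdir)
    lines = ["# synopsin run report", ""]
    missing = []

    summary_path = outdir / "pair_summary.tsv"
    if summary_path.exists():
        df = pd.read_csv(summary_path, sep="\t")
        lines.append("## Tandem subtype pairs (counts by distance class)")
        lines.append("")
        if len(df):
            lines.append(df.to_string(index=False))
        else:
            lines.append("No subtype pairs detected.")
        lines.append("")
        pct = outdir / "pair_group_percentages.tsv"
        if pct.exists():
            pdf = pd.read_csv(pct, sep="\t")
            if len(pdf):
                lines.append("Taxon-group shares per distance class:")
                lines.append(pdf.to_string(index=False))
                lines.append("")
    else:
        missing.append("pair_summary.tsv")

    tree_path = outdir / "paralogon_tree.nwk"
    if tree_path.exists():
        lines.append("## Paralogon tree (chromosome-keyed supermatrix)")
        lines.append("")
        lines.append("```\n" + tree_path.read_text().strip() + "\n```")
        rel = outdir / "reliable_clades.tsv"
        if rel.exists():
            rdf = pd.read_csv(rel, sep="\t")
            lines.append(f"Reliably supported bipartitions: {len(rdf)}")
        lines.append("")
    else:
        missing.append("paralogon_tree.nwk")

    rank_path = outdir / "hypothesis_ranking.tsv"
    if rank_path.exists():
        lines.append("## Ancestral-arrangement hypothesis ranking")
        lines.append("")
        lines.append(pd.read_csv(rank_path, sep="\t").to_string(index=False))
        lines.append("")
    else:
        missing.append("hypothesis_ranking.tsv")

    if missing:
        lines.append("## Missing stage outputs")
        lines.extend(f"- {m}" for m in missing)
        lines.append("")
    text = "\n".join(lines)
    (outdir / "report.md").write_text(text)
    return text
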