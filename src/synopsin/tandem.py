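"""Detection and summary of same-chromosome, same-strand opsin subtype pairs.

The core statistic: for every unordered pair of genes with different
accepted subtypes on the same chromosome and strand of one species, the
inter-gene gap (nearest ends, 0 for overlapping genes) classifies the
pair as proximal (< window, default 100 kbp) or distal (>= window, the
control class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genomeio import GeneRecord, TaxonTable

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 100_000


@dataclass(frozen=True)
class PairEvent:
    """One same-chromosome, same-strand different-subtype gene pair."""

    species: str
    seq_id: str
    gene_a: str  # lexicographically first
    gene_b: str
    subtype_pair: tuple[str, str]  # sorted labels
    gap_bp: int
    proximal: bool


def pair_gap_bp(a: GeneRecord, b: GeneRecord, mode: str = "gap") -> int:
    """Genomic separation of two genes.

    ``gap`` (default): distance between nearest ends, 0 when the
    intervals overlap.  ``start``: absolute start-to-start distance
    (sensitivity-check mode)."""
    if mode == "start":
        return abs(a.start - b.start)
    earlier, later = (a, b) if a.start <= b.start else (b, a)
    return max(0, later.start - earlier.end)


def scan_pairs(
    genes: Sequence[GeneRecord],
    window: int = DEFAULT_WINDOW_BP,
    gap_mode: str = "gap",
) -> list[PairEvent]:
    """Emit one PairEvent per unordered pair of genes with different
    subtypes on the same species, chromosome and strand.

    Genes without a subtype label are skipped with a logged warning.
    ``proximal`` is strict: gap < window.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    labelled = [g for g in genes if g.subtype is not None]
    n_skipped = len(genes) - len(labelled)
    if n_skipped:
        logger.warning("%d genes lack a subtype label; skipped", n_skipped)
    events = []
    by_group: dict[tuple[str, str, str], list[GeneRecord]] = {}
    for g in labelled:
        by_group.setdefault((g.species, g.seq_id, g.strand), []).append(g)
    for (species, seq_id, _strand), members in sorted(by_group.items()):
        for a, b in combinations(sorted(members, key=lambda g: g.gene_id), 2):
            if a.subtype == b.subtype:
                continue
            gap = pair_gap_bp(a, b, mode=gap_mode)
            events.append(
                PairEvent(
                    species=species,
                    seq_id=seq_id,
                    gene_a=min(a.gene_id, b.gene_id),
                    gene_b=max(a.gene_id, b.gene_id),
                    subtype_pair=tuple(sorted((a.subtype, b.subtype))),
                    gap_bp=gap,
                    proximal=gap < window,
                )
            )
    events.sort(key=lambda e: (e.species, e.seq_id, e.gene_a, e.gene_b))
    return events


@dataclass
class PairSummary:
    """Counts per subtype pair x distance class, plus taxon-group shares."""

    pair_counts: pd.DataFrame  # index: subtype pair label; columns: proximal, distal
    group_percentages: dict[str, dict[str, float]]  # distance class -> group -> %
    counting_unit: str = "pairs"

    def count(self, subtype_pair: tuple[str, str], distance_class: str) -> int:
        label = "-".join(sorted(subtype_pair))
        if label not in self.pair_counts.index:
            return 0
        return int(self.pair_counts.loc[label, distance_class])


def summarize_pairs(
    events: Sequence[PairEvent],
    taxa: TaxonTable,
    counting_unit: str = "pairs",
) -> PairSummary:
    """Tabulate pair events by subtype combination and distance class.

    ``counting_unit='pairs'`` counts every qualifying gene pair once;
    ``'species'`` collapses to one count per (species, subtype pair,
    distance class).  Group percentages are shares of events per distance
    class attributed to each taxon group; no percentages are emitted for
    an empty distance class.
    """
    if counting_unit not in ("pairs", "species"):
        raise ValueError(f"unknown counting unit {counting_unit!r}")
    for e in events:
        taxa.group_of(e.species)  # raises for unknown species
    rows = [
        {
            "species": e.species,
            "pair": "-".join(e.subtype_pair),
            "klass": "proximal" if e.proximal else "distal",
        }
        for e in events
    ]
    df = pd.DataFrame(rows, columns=["species", "pair", "klass"])
    if counting_unit == "species":
        df = df.drop_duplicates()
    counts = (
        df.groupby(["pair", "klass"]).size().unstack(fill_value=0)
        if len(df)
        else pd.DataFrame()
    )
    for col in ("proximal", "distal"):
        if col not in counts.columns:
            counts[col] = 0
    counts = counts[["proximal", "distal"]].astype(int)
    counts.index.name = "subtype_pair"

    group_pct: dict[str, dict[str, float]] = {}
    for klass in ("proximal", "distal"):
        sub = df[df["klass"] == klass] if len(df) else df
        if not len(sub):
            continue
        shares = (
            sub.assign(group=[taxa.group_of(s) for s in sub["species"]])
            .groupby("group")
            .size()
        )
        total = shares.sum()
        group_pct[klass] = {g: 100.0 * n / total for g, n in shares.items()}
    return PairSummary(
        pair_counts=counts, group_percentages=group_pct, counting_unit=counting_unit
    )


def events_to_tsv(events: Sequence[PairEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "species": [e.species for e in events],
            "seq_id": [e.seq_id for e in events],
            "gene_a": [e.gene_a for e in events],
            "gene_b": [e.gene_b for e in events],
            "subtype_pair": ["-".join(e.subtype_pair) for e in events],
            "gap_bp": [e.gap_bp for e in events],
            "proximal": [e.proximal for e in events],
        }
    ).to_csv(path, sep="\t", index=False)


def summary_to_tsv(summary: PairSummary, path: str | Path) -> None:
    summary.pair_counts.to_csv(path, sep="\t")
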