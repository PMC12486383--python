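"""Reading and writing the standard formats the pipeline touches.

All in-memory coordinates are 0-based half-open; only the file boundary
converts.  GFF3 is 1-based inclusive, BED is already 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneRecord",
    "TaxonTable",
    "read_annotations",
    "write_gff3",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_newick",
    "write_newick",
    "read_taxon_table",
    "write_taxon_table",
]

VALID_STRANDS = frozenset({"+", "-"})


class AnnotationError(ValueError):
    """Raised for malformed annotation input (coordinates, strand, ids)."""


@dataclass
class GeneRecord:
    """One annotated gene.

    ``start``/``end`` are 0-based half-open base-pair coordinates on
    ``seq_id``.  ``protein``, ``subtype`` and ``family`` are optional
    payloads filled in by the simulator or downstream stages.
    """

    gene_id: str
    species: str
    seq_id: str
    start: int
    end: int
    strand: str
    protein: str | None = None
    subtype: str | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"{self.gene_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise AnnotationError(f"{self.gene_id}: missing or invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TaxonTable:
    """Species -> taxon-group label (teleost, non-teleost jawed, jawless, outgroup)."""

    groups: dict[str, str] = field(default_factory=dict)

    def group_of(self, species: str) -> str:
        try:
            return self.groups[species]
        except KeyError:
            raise KeyError(f"species {species!r} missing from taxon table") from None

    def species_in(self, group: str) -> list[str]:
        return sorted(s for s, g in self.groups.items() if g == group)


# ---------------------------------------------------------------------------
# annotations


def _check_unique(records: list[GeneRecord]) -> list[GeneRecord]:
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.species, r.gene_id)
        if key in seen:
            raise AnnotationError(f"duplicate gene_id {r.gene_id!r} for species {r.species!r}")
        seen.add(key)
    return records


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise AnnotationError(f"malformed GFF3 attribute {part!r}")
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path, species: str | None = None) -> list[GeneRecord]:
    """Read ``gene`` features from a flat GFF3 file into GeneRecords.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    ``species`` defaults to the file stem.
    """
    path = Path(path)
    sp = species if species is not None else path.stem
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seq_id, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "gene":
                continue
            if strand not in VALID_STRANDS:
                raise AnnotationError(f"{path}:{lineno}: missing strand")
            a = _parse_gff3_attributes(attrs)
            if "ID" not in a:
                raise AnnotationError(f"{path}:{lineno}: gene feature without ID attribute")
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise AnnotationError(f"{path}:{lineno}: end < start")
            records.append(
                GeneRecord(
                    gene_id=a["ID"],
                    species=sp,
                    seq_id=seq_id,
                    start=start_i - 1,
                    end=end_i,
                    strand=strand,
                    subtype=a.get("subtype"),
                    family=a.get("family"),
                )
            )
    return _check_unique(records)


def read_bed(path: str | Path, species: str | None = None) -> list[GeneRecord]:
    """Read a BED6 file (0-based half-open, passed through unchanged)."""
    path = Path(path)
    sp = species if species is not None else path.stem
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["seq_id", "start", "end", "name", "score", "strand"],
        dtype={"seq_id": str, "name": str, "strand": str},
    )
    records = []
    for row in df.itertuples(index=False):
        if row.strand not in VALID_STRANDS:
            raise AnnotationError(f"{path}: missing strand for {row.name}")
        records.append(
            GeneRecord(
                gene_id=str(row.name),
                species=sp,
                seq_id=str(row.seq_id),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
            )
        )
    return _check_unique(records)


def read_annotations(path: str | Path, species: str | None = None) -> list[GeneRecord]:
    """Dispatch on file extension: .gff3/.gff -> GFF3, .bed -> BED."""
    path = Path(path)
    if path.suffix.lower() in {".gff3", ".gff"}:
        return read_gff3(path, species)
    if path.suffix.lower() == ".bed":
        return read_bed(path, species)
    raise AnnotationError(f"unrecognized annotation format: {path.name}")


def write_gff3(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Write GeneRecords as flat GFF3 ``gene`` features (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for r in records:
        attrs = [f"ID={r.gene_id}"]
        if r.family is not None:
            attrs.append(f"family={r.family}")
        if r.subtype is not None:
            attrs.append(f"subtype={r.subtype}")
        lines.append(
            "\t".join(
                [
                    r.seq_id,
                    "synopsin",
                    "gene",
                    str(r.start + 1),
                    str(r.end),
                    ".",
                    r.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# sequences and alignments


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise AnnotationError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA file; all rows must have equal length."""
    seqs = read_fasta(path)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise AnnotationError(f"ragged alignment rows in {path}: lengths {sorted(lengths)}")
    return seqs


def write_alignment(rows: Mapping[str, str], path: str | Path) -> None:
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise AnnotationError(f"refusing to write ragged alignment: lengths {sorted(lengths)}")
    write_fasta(rows, path)


# ---------------------------------------------------------------------------
# trees

def read_newick(text_or_path: str | Path) -> dendropy.Tree:
    """Parse Newick (from a path or a literal string) into a dendropy Tree.

    Internal node labels that parse as numbers are kept as labels; support
    interpretation is left to the caller.
    """
    s = str(text_or_path)
    if "(" in s:
        src = {"data": s}
    else:
        src = {"path": str(text_or_path)}
    return dendropy.Tree.get(schema="newick", **src)


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# taxon tables


def read_taxon_table(path: str | Path) -> TaxonTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["species", "group"]:
        raise AnnotationError("taxon table must have columns: species, group")
    dup = df["species"][df["species"].duplicated()]
    if len(dup):
        raise AnnotationError(f"duplicate species in taxon table: {sorted(dup)}")
    return TaxonTable(dict(zip(df["species"], df["group"])))


def write_taxon_table(taxa: TaxonTable, path: str | Path) -> None:
    pd.DataFrame(
        {"species": list(taxa.groups), "group": list(taxa.groups.values())}
    ).to_csv(path, sep="\t", index=False)
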