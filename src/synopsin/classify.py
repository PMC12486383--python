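"""Distance-based opsin subtype classification with bootstrap support.

Each query protein is aligned into the shared column space of a reference
database (one aligned set of rows per subtype, including a non-visual
outgroup class), and assigned to the subtype with the smallest mean
corrected distance.  Support is the fraction of column-bootstrap
replicates voting for the winning subtype; an assignment is accepted only
when support reaches the threshold (default 0.95, mirroring the common
ultrafast-bootstrap reliability convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genomeio import read_alignment, write_alignment
from .homology import AlignParams, poisson_distance, profile_align

logger = logging.getLogger(__name__)

VISUAL_SUBTYPES = ("LWS", "SWS1", "SWS2", "RH2", "RH1")
UNALIGNABLE = "unalignable"


@dataclass
class ReferenceDB:
    """Aligned reference rows per subtype, all in one shared column space."""

    subtypes: dict[str, dict[str, str]]  # subtype -> row name -> gapped sequence

    def __post_init__(self):
        lengths = {
            len(row) for rows in self.subtypes.values() for row in rows.values()
        }
        if len(lengths) > 1:
            raise ValueError(f"reference rows not congruent: lengths {sorted(lengths)}")
        for subtype, rows in self.subtypes.items():
            if len(rows) < 2:
                raise ValueError(f"subtype {subtype!r} needs >= 2 reference rows")

    @property
    def n_columns(self) -> int:
        rows = next(iter(self.subtypes.values()))
        return len(next(iter(rows.values())))

    def all_rows(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for subtype in sorted(self.subtypes):
            for name, row in self.subtypes[subtype].items():
                out[f"{subtype}|{name}"] = row
        return out

    @classmethod
    def from_dir(cls, path: str | Path) -> "ReferenceDB":
        """Load a directory of aligned FASTA files, one per subtype
        (file stem = subtype label)."""
        path = Path(path)
        subtypes = {}
        for f in sorted(path.glob("*.fa*")):
            subtypes[f.stem] = read_alignment(f)
        if not subtypes:
            raise ValueError(f"no reference alignments found in {path}")
        return cls(subtypes)

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for subtype, rows in self.subtypes.items():
            write_alignment(rows, path / f"{subtype}.faa")


@dataclass
class SubtypeAssignment:
    gene_id: str
    subtype: str
    support: float
    accepted: bool
    support_by_subtype: dict[str, float] = field(default_factory=dict)


def classify_subtype(
    query: str,
    db: ReferenceDB,
    n_boot: int = 200,
    seed: int = 0,
    threshold: float = 0.95,
    min_coverage: float = 0.5,
    gene_id: str = "query",
    params: AlignParams = AlignParams(),
) -> SubtypeAssignment:
    """Classify one protein against the reference database.

    The query is profile-aligned into the reference column space; each
    bootstrap replicate resamples alignment columns with replacement and
    votes for the subtype with the smallest mean corrected distance over
    its reference rows (ties vote for the lexicographically smallest
    subtype).  A query covering fewer than ``min_coverage`` of the
    reference columns is reported as unalignable.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    pa = profile_align(query, db.all_rows(), params=params)
    qref = pa.query_on_reference()
    ncols = len(qref)
    nongap = sum(1 for c in qref if c != "-")
    if nongap < min_coverage * ncols:
        return SubtypeAssignment(gene_id, UNALIGNABLE, 0.0, False, {})

    subtype_names = sorted(db.subtypes)
    qarr = np.frombuffer(qref.encode(), dtype="S1")
    # per reference row: comparable and matching column masks
    row_subtype: list[int] = []
    comp_rows, match_rows = [], []
    for k, subtype in enumerate(subtype_names):
        for name, row in sorted(db.subtypes[subtype].items()):
            rarr = np.frombuffer(row.encode(), dtype="S1")
            comparable = (qarr != b"-") & (rarr != b"-")
            match = comparable & (qarr == rarr)
            comp_rows.append(comparable)
            match_rows.append(match)
            row_subtype.append(k)
    comp = np.array(comp_rows)  # (R, ncols)
    match = np.array(match_rows)
    row_subtype_arr = np.array(row_subtype)

    rng = np.random.default_rng(seed)
    votes = np.zeros(len(subtype_names), dtype=int)
    for _ in range(n_boot):
        idx = rng.integers(0, ncols, size=ncols)
        c = comp[:, idx].sum(axis=1)
        mm = match[:, idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(c > 0, 1.0 - mm / np.maximum(c, 1), 1.0)
        d = np.array([poisson_distance(float(pi)) for pi in p])
        means = np.array(
            [d[row_subtype_arr == k].mean() for k in range(len(subtype_names))]
        )
        votes[int(np.argmin(means))] += 1  # argmin: first (lex-smallest) on ties
    support_by = {name: votes[k] / n_boot for k, name in enumerate(subtype_names)}
    win = int(np.argmax(votes))
    subtype = subtype_names[win]
    support = votes[win] / n_boot
    return SubtypeAssignment(
        gene_id=gene_id,
        subtype=subtype,
        support=support,
        accepted=support >= threshold,
        support_by_subtype=support_by,
    )


def classify_proteome(
    proteome: Mapping[str, str],
    db: ReferenceDB,
    n_boot: int = 200,
    seed: int = 0,
    threshold: float = 0.95,
    params: AlignParams = AlignParams(),
) -> list[SubtypeAssignment]:
    """Classify every protein in a proteome (deterministic per-gene seeds)."""
    out = []
    for i, gid in enumerate(sorted(proteome)):
        out.append(
            classify_subtype(
                proteome[gid],
                db,
                n_boot=n_boot,
                seed=(seed * 100_003 + i) % (2**31 - 1),
                threshold=threshold,
                gene_id=gid,
                params=params,
            )
        )
    return out


def assignments_to_tsv(assignments: list[SubtypeAssignment], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in assignments],
            "subtype": [a.subtype for a in assignments],
            "support": [a.support for a in assignments],
            "accepted": [a.accepted for a in assignments],
        }
    ).to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> dict[str, SubtypeAssignment]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.gene_id)] = SubtypeAssignment(
            gene_id=str(row.gene_id),
            subtype=str(row.subtype),
            support=float(row.support),
            accepted=bool(row.accepted),
        )
    return out
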