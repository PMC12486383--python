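"""Alignment, distance and orthogroup machinery.

Self-contained equivalents of the heavyweight external steps a comparable
real-data study would run: query-to-profile global alignment with affine
gaps (in place of a full MSA program), alignment percent identity (in
place of all-versus-all BLASTP identities), a 20-state equal-rates
distance correction matched to the simulator's substitution model, and
reciprocal-best-hit (RBH) orthogroups (in place of an MCL-based
orthology pipeline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .genomeio import GeneRecord
from .simulate import AA_ALPHABET, _AA_INDEX

__all__ = [
    "AlignParams",
    "ProfileAlignment",
    "Orthogroup",
    "profile_align",
    "percent_identity",
    "poisson_distance",
    "SATURATION_P",
    "build_orthogroups",
    "select_anchor_families",
]

GAP = "-"
SATURATION_P = 19.0 / 20.0


@dataclass(frozen=True)
class AlignParams:
    """Protein alignment scoring parameters (standard defaults)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0


def _blosum_array(name: str) -> np.ndarray:
    m = substitution_matrices.load(name)
    out = np.zeros((20, 20))
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            out[i, j] = m[a][b]
    return out


@dataclass
class ProfileAlignment:
    """A query aligned end-to-end against a column-frequency profile.

    ``columns`` maps every alignment column to a reference-column index or
    None for a query insertion; ``query_row`` is the gapped query over the
    same columns.  ``ref_rows`` (when built from an MSA) are the reference
    rows expanded to the same column space.
    """

    columns: list[int | None]
    query_row: str
    score: float
    ref_freqs: np.ndarray  # (n_ref_columns, 20)
    ref_names: list[str] = field(default_factory=list)
    ref_rows: dict[str, str] = field(default_factory=dict)

    @property
    def n_ref_columns(self) -> int:
        return self.ref_freqs.shape[0]

    def query_on_reference(self) -> str:
        """Query residues over reference columns only (insertions dropped)."""
        out = []
        for col, q in zip(self.columns, self.query_row):
            if col is not None:
                out.append(q)
        return "".join(out)


def msa_profile(msa: Mapping[str, str]) -> np.ndarray:
    """Per-column amino-acid frequencies of an alignment (gaps ignored;
    an all-gap column gets the uniform distribution)."""
    rows = list(msa.values())
    if not rows:
        raise ValueError("empty alignment")
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("ragged alignment rows")
    freqs = np.zeros((L, 20))
    for r in rows:
        for j, a in enumerate(r):
            if a == GAP:
                continue
            if a not in _AA_INDEX:
                raise ValueError(f"unknown amino-acid symbol {a!r}")
            freqs[j, _AA_INDEX[a]] += 1.0
    sums = freqs.sum(axis=1, keepdims=True)
    uniform = np.full(20, 1.0 / 20.0)
    out = np.where(sums > 0, freqs / np.where(sums == 0, 1, sums), uniform)
    return out


def profile_align(
    query: str,
    ref_msa: Mapping[str, str],
    params: AlignParams = AlignParams(),
) -> ProfileAlignment:
    """Global (end-to-end) affine-gap alignment of ``query`` against the
    column profile of ``ref_msa``, maximizing the summed expected
    substitution score.  Ties prefer match > delete (gap in query) >
    insert (gap in reference)."""
    if not query:
        raise ValueError("empty query")
    qcodes = np.array([_AA_INDEX.get(a, -1) for a in query])
    if (qcodes < 0).any():
        bad = query[int(np.argmax(qcodes < 0))]
        raise ValueError(f"unknown amino-acid symbol {bad!r} in query")
    freqs = msa_profile(ref_msa)
    S = _blosum_array(params.matrix)
    # expected score of each query residue against each profile column
    # sub[i, j] = sum_x freqs[j, x] * S[q_i, x]
    sub = S[qcodes] @ freqs.T  # (m, L)
    m, L = sub.shape
    go, ge = params.gap_open, params.gap_extend
    NEG = -1e30

    # Gotoh: M (match), X (gap in query / delete ref col), Y (gap in ref / insert)
    M = np.full((m + 1, L + 1), NEG)
    X = np.full((m + 1, L + 1), NEG)
    Y = np.full((m + 1, L + 1), NEG)
    M[0, 0] = 0.0
    for j in range(1, L + 1):
        X[0, j] = -(go + ge * (j - 1))
    for i in range(1, m + 1):
        Y[i, 0] = -(go + ge * (i - 1))
    for i in range(1, m + 1):
        for j in range(1, L + 1):
            s = sub[i - 1, j - 1]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i, j - 1] - go, X[i, j - 1] - ge, Y[i, j - 1] - go)
            Y[i, j] = max(M[i - 1, j] - go, X[i - 1, j] - go, Y[i - 1, j] - ge)

    # traceback, preferring match > delete > insert at every tie
    i, j = m, L
    state = max(("M", "X", "Y"), key=lambda st: {"M": M, "X": X, "Y": Y}[st][i, j])
    # prefer M on ties:
    best = max(M[i, j], X[i, j], Y[i, j])
    for st in ("M", "X", "Y"):
        if {"M": M, "X": X, "Y": Y}[st][i, j] == best:
            state = st
            break
    score = best
    cols: list[int | None] = []
    qrow: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = sub[i - 1, j - 1]
            cols.append(j - 1)
            qrow.append(query[i - 1])
            prev = M[i - 1, j - 1] + s
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if mat[i - 1, j - 1] + s == M[i, j]:
                    state = st
                    break
            i, j = i - 1, j - 1
        elif state == "X":
            cols.append(j - 1)
            qrow.append(GAP)
            cur = X[i, j]
            if M[i, j - 1] - go == cur:
                state = "M"
            elif X[i, j - 1] - ge == cur:
                state = "X"
            else:
                state = "Y"
            j -= 1
        else:  # Y: insertion column
            cols.append(None)
            qrow.append(query[i - 1])
            cur = Y[i, j]
            if M[i - 1, j] - go == cur:
                state = "M"
            elif X[i - 1, j] - go == cur:
                state = "X"
            else:
                state = "Y"
            i -= 1
    cols.reverse()
    qrow.reverse()
    query_row = "".join(qrow)

    ref_rows = {}
    for name, row in ref_msa.items():
        expanded = []
        for col in cols:
            expanded.append(row[col] if col is not None else GAP)
        ref_rows[name] = "".join(expanded)
    return ProfileAlignment(
        columns=cols,
        query_row=query_row,
        score=float(score),
        ref_freqs=freqs,
        ref_names=list(ref_msa),
        ref_rows=ref_rows,
    )


def percent_identity(a: str, b: str) -> float:
    """Identical column pairs / columns where both sequences are non-gap.

    Returns 0.0 when no comparable column exists."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    comparable = ident = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        comparable += 1
        if x == y:
            ident += 1
    return ident / comparable if comparable else 0.0


def poisson_distance(
    p: float, ceiling: float = 5.0, with_flag: bool = False
) -> float | tuple[float, bool]:
    """Equal-rates 20-state distance correction of an observed difference
    fraction: d = -(19/20) ln(1 - (20/19) p).

    Saturated inputs (p >= 19/20) return ``ceiling`` (flagged when
    ``with_flag``)."""
    if p < 0:
        raise ValueError(f"difference fraction must be >= 0, got {p}")
    if p >= SATURATION_P:
        return (ceiling, True) if with_flag else ceiling
    d = -SATURATION_P * math.log(1.0 - p / SATURATION_P)
    d = min(d, ceiling)
    return (d, False) if with_flag else d


# ---------------------------------------------------------------------------
# orthogroups


@dataclass
class Orthogroup:
    family_id: str
    members: frozenset[str]  # "species:gene_id"


def _pairwise_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = "global"
    return aligner


def _alignment_identity(alignment) -> float:
    a, b = str(alignment[0]), str(alignment[1])
    return percent_identity(a, b)


def build_orthogroups(
    proteomes: Mapping[str, Mapping[str, str]],
    min_identity: float = 0.3,
    min_norm_score: float = 0.1,
    params: AlignParams = AlignParams(),
) -> list[Orthogroup]:
    """Reciprocal-best-hit orthogroups with in-paralog linking.

    Edges are (a) reciprocal best hits by global alignment score between
    every species pair and (b) within-species gene pairs; an edge is
    kept when the alignment identity reaches ``min_identity`` AND the
    normalized score (alignment score over the smaller self-alignment
    score) reaches ``min_norm_score``.  The normalized-score criterion
    rejects the spuriously high identities that optimal alignment
    produces between unrelated sequences of different lengths.
    Orthogroups are the connected components; the within-species edges
    attach WGD/tandem paralogs to their family, which cross-species best
    hits alone cannot do.  Every gene appears in exactly one orthogroup
    (singletons included).  Deterministic: best-hit ties break by
    lexicographic gene id and the result is invariant to species order.
    """
    species = sorted(proteomes)
    if len(species) < 2:
        raise ValueError("need at least two species")
    for sp in species:
        if not proteomes[sp]:
            raise ValueError(f"empty proteome for species {sp!r}")
    aligner = _pairwise_aligner(params)
    self_score: dict[tuple[str, str], float] = {}
    for sp in species:
        for gid, seq in proteomes[sp].items():
            self_score[(sp, gid)] = float(aligner.align(seq, seq)[0].score)

    def node(sp: str, gid: str) -> str:
        return f"{sp}:{gid}"

    # Score every cross-species pair once; best hits in each direction with
    # ties broken by lexicographically smallest target gene id.
    best: dict[tuple[str, str, str], tuple[str, float, float]] = {}
    for si, s in enumerate(species):
        for t in species[si + 1:]:
            ids_s, ids_t = sorted(proteomes[s]), sorted(proteomes[t])
            scores = np.zeros((len(ids_s), len(ids_t)))
            idents = np.zeros_like(scores)
            norms = np.zeros_like(scores)
            for a, gs in enumerate(ids_s):
                for b, gt in enumerate(ids_t):
                    aln = aligner.align(proteomes[s][gs], proteomes[t][gt])[0]
                    scores[a, b] = aln.score
                    idents[a, b] = _alignment_identity(aln)
                    norms[a, b] = aln.score / min(
                        self_score[(s, gs)], self_score[(t, gt)]
                    )
            for a, gs in enumerate(ids_s):
                b = int(np.argmax(scores[a]))  # argmax takes first (lex-smallest) tie
                best[(s, gs, t)] = (ids_t[b], idents[a, b], norms[a, b])
            for b, gt in enumerate(ids_t):
                a = int(np.argmax(scores[:, b]))
                best[(t, gt, s)] = (ids_s[a], idents[a, b], norms[a, b])

    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            if rx > ry:
                rx, ry = ry, rx
            parent[ry] = rx

    for sp in species:
        for gid in proteomes[sp]:
            parent[node(sp, gid)] = node(sp, gid)

    for (s, gs, t), (gt, ident, norm) in sorted(best.items()):
        back = best.get((t, gt, s))
        if (
            back is not None
            and back[0] == gs
            and ident >= min_identity
            and norm >= min_norm_score
        ):
            union(node(s, gs), node(t, gt))

    # in-paralog edges: within-species pairs above both cutoffs
    for sp in species:
        ids = sorted(proteomes[sp])
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                aln = aligner.align(proteomes[sp][ids[a]], proteomes[sp][ids[b]])[0]
                norm = aln.score / min(
                    self_score[(sp, ids[a])], self_score[(sp, ids[b])]
                )
                if _alignment_identity(aln) >= min_identity and norm >= min_norm_score:
                    union(node(sp, ids[a]), node(sp, ids[b]))

    comps: dict[str, set[str]] = {}
    for sp in species:
        for gid in proteomes[sp]:
            comps.setdefault(find(node(sp, gid)), set()).add(node(sp, gid))
    groups = []
    for i, root in enumerate(sorted(comps, key=lambda r: sorted(comps[r]))):
        groups.append(Orthogroup(family_id=f"OG{i:04d}", members=frozenset(comps[root])))
    return groups


def select_anchor_families(
    groups: Sequence[Orthogroup],
    genes: Sequence[GeneRecord],
    focal_species: str,
    opsin_chromosomes: Iterable[str],
    min_opsin_chroms: int = 2,
    min_species_chroms: int = 3,
    group_species: Iterable[str] | None = None,
    per_species: bool = False,
) -> list[str]:
    """Select anchor families by chromosomal spread.

    A family passes iff (a) its ``focal_species`` members occupy at least
    ``min_opsin_chroms`` distinct chromosomes among ``opsin_chromosomes``
    and (b) its members across ``group_species`` (default: all species in
    ``genes``) occupy at least ``min_species_chroms`` distinct
    chromosomes, pooled across those species (or within at least one
    species when ``per_species``)."""
    opsin_chroms = set(opsin_chromosomes)
    if not opsin_chroms:
        raise ValueError("opsin_chromosomes must be non-empty")
    by_key = {(g.species, g.gene_id): g for g in genes}
    if not any(sp == focal_species for sp, _ in by_key):
        raise ValueError(f"focal species {focal_species!r} absent from gene table")
    if group_species is None:
        group_set = {g.species for g in genes}
    else:
        group_set = set(group_species)
    selected = []
    for og in groups:
        focal_chroms: set[str] = set()
        pooled: dict[str, set[str]] = {}
        for member in og.members:
            sp, gid = member.split(":", 1)
            rec = by_key.get((sp, gid))
            if rec is None:
                continue
            if sp == focal_species and rec.seq_id in opsin_chroms:
                focal_chroms.add(rec.seq_id)
            if sp in group_set:
                pooled.setdefault(sp, set()).add(rec.seq_id)
        if len(focal_chroms) < min_opsin_chroms:
            continue
        if per_species:
            ok = any(len(ch) >= min_species_chroms for ch in pooled.values())
        else:
            ok = len(set().union(*pooled.values()) if pooled else set()) >= min_species_chroms
        if ok:
            selected.append(og.family_id)
    return sorted(selected)
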