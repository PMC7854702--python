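"""Smith–Waterman local alignment of protein sequences, EMBOSS-Water
conventions.

Used to quantify how similar two phytochrome sequences are (e.g. pea phyA
vs Arabidopsis phyB), which underwrites transferring structural knowledge
between homologs.  Conventions follow the EMBOSS ``water`` program:

- affine gaps: a gap of length L costs ``gap_open + (L-1) * gap_extend``
  (the opening penalty covers the first gapped residue);
- identity % = identical columns / alignment length (gap columns count in
  the denominator);
- similarity % = columns whose substitution score is positive / alignment
  length;

defaults BLOSUM62, gap_open 10, gap_extend 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "ProteinSequence",
    "LocalAlignment",
    "read_fasta",
    "smith_waterman",
]

_AMBIGUOUS_FALLBACK = 0.0  # score for residues absent from the matrix


@dataclass
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LocalAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float
    start_a: int   # 1-based, inclusive
    end_a: int
    start_b: int
    end_b: int

    @property
    def length(self) -> int:
        return len(self.aligned_a)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return [ProteinSequence(id=r.id, residues=str(r.seq)) for r in records]


def _score_lookup(matrix, warn: set) -> "callable":
    alphabet = matrix.alphabet

    def score(x: str, y: str) -> float:
        if x in alphabet and y in alphabet:
            return float(matrix[x, y])
        key = x if x not in alphabet else y
        if key not in warn:
            warn.add(key)
        return _AMBIGUOUS_FALLBACK

    return score


def smith_waterman(
    a: ProteinSequence,
    b: ProteinSequence,
    matrix: str | object = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> LocalAlignment:
    """Affine-gap local alignment by the three-state dynamic program.

    States: H (best local score ending at i,j), E (gap in ``a``, i.e.
    consuming ``b``), F (gap in ``b``).  The traceback starts at the maximum
    H cell (smallest end coordinates among ties) and prefers diagonal, then
    gap-in-b, then gap-in-a at score ties, stopping at the first zero.
    """
    if gap_open < 0 or gap_extend < 0:
        raise ValueError("gap penalties must be non-negative")
    if isinstance(matrix, str):
        matrix = substitution_matrices.load(matrix)
    unknown: set = set()
    score = _score_lookup(matrix, unknown)
    sa, sb = a.residues, b.residues
    n, m = len(sa), len(sb)

    # substitution scores as an n x m array (row = residue of a)
    alphabet = matrix.alphabet
    idx = {c: i for i, c in enumerate(alphabet)}
    mat = np.asarray(matrix, dtype=float)
    ia = np.array([idx.get(c, -1) for c in sa])
    ib = np.array([idx.get(c, -1) for c in sb])
    sub = np.where(
        (ia[:, None] >= 0) & (ib[None, :] >= 0),
        mat[np.maximum(ia, 0)[:, None], np.maximum(ib, 0)[None, :]],
        _AMBIGUOUS_FALLBACK,
    )
    unknown.update(c for c in sa + sb if c not in idx)
    if unknown:
        import logging
        logging.getLogger(__name__).warning(
            "residues %s absent from matrix; scored %.1f",
            sorted(unknown), _AMBIGUOUS_FALLBACK)

    NEG = -np.inf
    h_prev = np.zeros(m + 1)
    f_prev = np.full(m + 1, NEG)
    # pointers: 0 stop, 1 diagonal, 2 up (gap in b), 3 left (gap in a)
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1: opened from H, 0: extended
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best, best_ij = 0.0, (0, 0)
    for i in range(1, n + 1):
        h_row = np.zeros(m + 1)
        f_row = np.empty(m + 1)
        f_row[0] = NEG
        # F: gap in b (vertical), depends on previous row only
        open_f = h_prev[1:] - gap_open
        ext_f = f_prev[1:] - gap_extend
        f_row[1:] = np.maximum(open_f, ext_f)
        ptr_f[i, 1:] = (open_f >= ext_f).astype(np.uint8)
        e = NEG
        subs = sub[i - 1]
        for j in range(1, m + 1):
            open_e = h_row[j - 1] - gap_open
            ext_e = e - gap_extend
            if open_e >= ext_e:
                e = open_e
                ptr_e[i, j] = 1
            else:
                e = ext_e
            diag = h_prev[j - 1] + subs[j - 1]
            f = f_row[j]
            # tie order: diagonal > gap-in-b (up) > gap-in-a (left) > stop
            h = diag
            p = 1
            if f > h:
                h, p = f, 2
            if e > h:
                h, p = e, 3
            if h <= 0.0:
                h, p = 0.0, 0
            h_row[j] = h
            ptr_h[i, j] = p
            if h > best:
                best, best_ij = h, (i, j)
        h_prev, f_prev = h_row, f_row

    if best == 0.0:
        raise ValueError("no positive-scoring local alignment")

    # traceback
    i, j = best_ij
    end_a, end_b = i, j
    frag_a: list[str] = []
    frag_b: list[str] = []
    state = "H"
    while True:
        if state == "H":
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                frag_a.append(sa[i - 1])
                frag_b.append(sb[j - 1])
                i, j = i - 1, j - 1
            elif p == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in b, consume a
            frag_a.append(sa[i - 1])
            frag_b.append("-")
            opened = ptr_f[i, j]
            i -= 1
            if opened:
                state = "H"
        else:  # E: gap in a, consume b
            frag_a.append("-")
            frag_b.append(sb[j - 1])
            opened = ptr_e[i, j]
            j -= 1
            if opened:
                state = "H"
        if i == 0 or j == 0:
            break
    aligned_a = "".join(reversed(frag_a))
    aligned_b = "".join(reversed(frag_b))
    start_a, start_b = i + 1, j + 1

    length = len(aligned_a)
    ident = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    simil = sum(
        x != "-" and y != "-" and score(x, y) > 0
        for x, y in zip(aligned_a, aligned_b)
    )
    return LocalAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(best),
        identity_pct=round(100.0 * ident / length, 1),
        similarity_pct=round(100.0 * simil / length, 1),
        start_a=start_a, end_a=end_a, start_b=start_b, end_b=end_b,
    )
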