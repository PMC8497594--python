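"""Protein-guided codon alignment and gap-window column cleaning.

The Ka/Ks pipeline aligns the two amino-acid sequences globally (affine-gap
Needleman-Wunsch/Gotoh), back-translates the protein alignment onto the coding
sequences, and then removes every codon column that has an alignment gap
within three columns on either side.  Cleaned alignments are only used when
they are longer than 150 aa and cover at least half of both proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .codons import split_codons

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
GAP3 = "---"

_NEG = -1e9


@dataclass(frozen=True)
class ProteinAlignment:
    """A pairwise global protein alignment (gapped strings of equal length)."""

    a: str
    b: str
    score: float

    def __post_init__(self):
        if len(self.a) != len(self.b):
            raise ValueError("aligned sequences must have equal lengths")

    @property
    def length(self) -> int:
        return len(self.a)

    @property
    def ungapped_len_a(self) -> int:
        return len(self.a) - self.a.count("-")

    @property
    def ungapped_len_b(self) -> int:
        return len(self.b) - self.b.count("-")


@dataclass(frozen=True)
class CodonAlignment:
    """Two in-frame codon-column sequences mirroring a protein alignment.

    ``columns_a[k]``/``columns_b[k]`` is either a codon triplet or ``---``.
    ``source_len_a``/``source_len_b`` record the ungapped protein lengths (aa)
    of the two input sequences, which the coverage filter needs even after
    columns have been removed.
    """

    columns_a: tuple[str, ...]
    columns_b: tuple[str, ...]
    id_a: str = "a"
    id_b: str = "b"
    source_len_a: int = 0
    source_len_b: int = 0

    def __post_init__(self):
        if len(self.columns_a) != len(self.columns_b):
            raise ValueError("codon alignment columns must pair up")
        for col in (*self.columns_a, *self.columns_b):
            if len(col) != 3:
                raise ValueError(f"codon column {col!r} is not a triplet or 3-gap")

    @property
    def n_columns(self) -> int:
        return len(self.columns_a)

    def gap_free_mask(self) -> np.ndarray:
        return np.array(
            [ca != GAP3 and cb != GAP3 for ca, cb in zip(self.columns_a, self.columns_b)],
            dtype=bool,
        )


def _encode(seq: str, index: dict[str, int], name: str) -> np.ndarray:
    try:
        return np.array([index[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"{name}: invalid residue {exc.args[0]!r}") from None


def load_substitution_matrix(name: str = "BLOSUM62") -> tuple[np.ndarray, dict[str, int]]:
    """A substitution matrix as a dense array plus residue->row index."""
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    index = {c: i for i, c in enumerate(alphabet)}
    return np.array(mat, dtype=float), index


def global_protein_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> ProteinAlignment:
    """Optimal global alignment under affine gap penalties (Gotoh).

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  Ties are
    broken deterministically: diagonal (match) over gap-in-b (up) over
    gap-in-a (left), so the same inputs always give the same path.
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("global alignment requires two non-empty sequences")
    for s, name in ((a, "a"), (b, "b")):
        for c in s:
            if c not in PROTEIN_ALPHABET:
                raise ValueError(f"{name}: invalid residue {c!r}")

    sub, index = load_substitution_matrix(matrix)
    ea, eb = _encode(a, index, "a"), _encode(b, index, "b")
    m, n = len(a), len(b)

    M = np.full((m + 1, n + 1), _NEG)
    Ix = np.full((m + 1, n + 1), _NEG)  # gap in b (vertical / "up")
    Iy = np.full((m + 1, n + 1), _NEG)  # gap in a (horizontal / "left")
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        Ix[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, n + 1):
        Iy[0, j] = -gap_open - (j - 1) * gap_extend

    # Row-wise vectorized recursion: M and Ix depend only on the previous
    # row; Iy's within-row scan is resolved with a prefix-max trick.
    js = np.arange(1, n + 1, dtype=float)
    for i in range(1, m + 1):
        srow = sub[ea[i - 1], eb]  # scores vs every b residue
        prev_best = np.maximum.reduce([M[i - 1], Ix[i - 1], Iy[i - 1]])
        M[i, 1:] = prev_best[:-1] + srow
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] - gap_open, Ix[i - 1, 1:] - gap_extend)
        # Iy[i, j] = max_{k < j} (source[i, k]) - gap cost, source = max(M, Ix)
        source = np.maximum(M[i], Ix[i])
        cand = source[:-1] + gap_extend * np.arange(n, dtype=float)
        run = np.maximum.accumulate(cand)
        Iy[i, 1:] = run - gap_open - gap_extend * (js - 1)

    # Traceback (tie preference: diagonal, then up, then left).
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = m, n
    best = max(M[m, n], Ix[m, n], Iy[m, n])
    if M[m, n] >= Ix[m, n] and M[m, n] >= Iy[m, n]:
        state = "M"
    elif Ix[m, n] >= Iy[m, n]:
        state = "X"
    else:
        state = "Y"
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            s = sub[ea[i - 1], eb[j - 1]]
            prev = M[i, j] - s
            if abs(M[i - 1, j - 1] - prev) < eps:
                nxt = "M"
            elif abs(Ix[i - 1, j - 1] - prev) < eps:
                nxt = "X"
            else:
                nxt = "Y"
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            state = nxt
        elif state == "X":
            if i == 0:
                raise AssertionError("traceback left the matrix")
            if abs(Ix[i, j] - (M[i - 1, j] - gap_open)) < eps:
                nxt = "M"
            else:
                nxt = "X"
            out_a.append(a[i - 1])
            out_b.append("-")
            i = i - 1
            state = nxt
        else:  # Y
            src = Iy[i, j]
            if abs(src - (M[i, j - 1] - gap_open)) < eps:
                nxt = "M"
            elif abs(src - (Ix[i, j - 1] - gap_open)) < eps:
                nxt = "X"
            else:
                nxt = "Y"
            out_a.append("-")
            out_b.append(b[j - 1])
            j = j - 1
            state = nxt
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    return ProteinAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), float(best))


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS (trailing stop allowed and dropped)."""
    codons = split_codons(cds)
    return str(Seq("".join(codons)).translate())


def backtranslate_alignment(
    paln: ProteinAlignment,
    cds_a: str,
    cds_b: str,
    id_a: str = "a",
    id_b: str = "b",
) -> CodonAlignment:
    """Thread the coding sequences through a protein alignment.

    Each amino-acid column becomes the matching codon column; protein gaps
    become 3-nucleotide gaps.  Raises if a CDS does not translate to its
    aligned protein.
    """
    codons_a = split_codons(cds_a)
    codons_b = split_codons(cds_b)
    prot_a = paln.a.replace("-", "")
    prot_b = paln.b.replace("-", "")
    if translate_cds(cds_a) != prot_a:
        raise ValueError(f"{id_a}: CDS does not translate to the aligned protein")
    if translate_cds(cds_b) != prot_b:
        raise ValueError(f"{id_b}: CDS does not translate to the aligned protein")

    cols_a: list[str] = []
    cols_b: list[str] = []
    ia = ib = 0
    for ca, cb in zip(paln.a, paln.b):
        if ca == "-":
            cols_a.append(GAP3)
        else:
            cols_a.append(codons_a[ia])
            ia += 1
        if cb == "-":
            cols_b.append(GAP3)
        else:
            cols_b.append(codons_b[ib])
            ib += 1
    return CodonAlignment(
        tuple(cols_a),
        tuple(cols_b),
        id_a=id_a,
        id_b=id_b,
        source_len_a=len(prot_a),
        source_len_b=len(prot_b),
    )


def clean_alignment_columns(
    caln: CodonAlignment,
    flank: int = 3,
    clip_ends: bool = True,
) -> CodonAlignment:
    """Keep only columns whose +-``flank`` neighborhood is gap-free.

    A column is retained iff it is itself gap-free and every *existing*
    column within ``flank`` positions on each side is gap-free.  With
    ``clip_ends=True`` (default) the window is clipped at the alignment ends,
    so a fully gap-free alignment is preserved intact; with
    ``clip_ends=False`` a column additionally needs the full window to exist
    (the first and last ``flank`` columns are always dropped).
    """
    gap_free = caln.gap_free_mask()
    n = caln.n_columns
    keep = np.zeros(n, dtype=bool)
    for k in range(n):
        lo, hi = k - flank, k + flank
        if not clip_ends and (lo < 0 or hi >= n):
            continue
        lo, hi = max(lo, 0), min(hi, n - 1)
        keep[k] = bool(gap_free[lo : hi + 1].all())
    idx = np.flatnonzero(keep)
    return CodonAlignment(
        tuple(caln.columns_a[i] for i in idx),
        tuple(caln.columns_b[i] for i in idx),
        id_a=caln.id_a,
        id_b=caln.id_b,
        source_len_a=caln.source_len_a,
        source_len_b=caln.source_len_b,
    )


def alignment_passes_filters(
    caln: CodonAlignment,
    min_len_aa: int = 150,
    min_cov: float = 0.5,
) -> bool:
    """Length/coverage gate applied to a *cleaned* codon alignment.

    Passes iff the cleaned length is strictly greater than ``min_len_aa``
    codons and covers at least ``min_cov`` of the ungapped length of *both*
    source proteins.
    """
    length = caln.n_columns
    if length <= min_len_aa:
        return False
    if caln.source_len_a <= 0 or caln.source_len_b <= 0:
        raise ValueError("source protein lengths must be recorded for the coverage filter")
    return length / caln.source_len_a >= min_cov and length / caln.source_len_b >= min_cov
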