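"""Molecular-mimicry scanning: align a candidate autoreactive peptide
against a viral proteome and annotate the match.

Scoring uses the Gonnet PAM250 substitution matrix.  Each aligned column is
annotated two ways, following the Clustal and Jalview conventions:

* a **similarity symbol** — ``*`` identical residues, ``:`` strongly similar
  (matrix score > 0.5), ``.`` weakly similar (score in (0, 0.5]), space
  otherwise (including gap columns);
* a **physicochemical conservation score 0–11** — 11 for identical residues,
  otherwise the number of the ten standard amino-acid property classes
  (hydrophobic, polar, small, proline, tiny, aliphatic, aromatic, positive,
  negative, charged) on which the pair agrees — shared or jointly absent.

Two scan modes: ``ungapped_window`` slides the query across every position
of every target protein and sums per-column matrix scores; ``local`` runs
Smith–Waterman with the same matrix and affine gap penalties (a gap of
length k costs open + (k-1)·extend; defaults 10 and 0.2, the Clustal-style
values on the Gonnet scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import AlphabetError, PreconditionError
from .io import AA_ALPHABET

GAP_CHARS = "-"  # alignment gap character

# The ten standard physicochemical property classes (Taylor's classification,
# as used by Jalview's conservation annotation).
PROPERTY_TABLE: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("ACFGHIKLMTVWY"),
    "polar": frozenset("CDEHKNQRSTWY"),
    "small": frozenset("ACDGNPSTV"),
    "proline": frozenset("P"),
    "tiny": frozenset("AGS"),
    "aliphatic": frozenset("ILV"),
    "aromatic": frozenset("FHWY"),
    "positive": frozenset("HKR"),
    "negative": frozenset("DE"),
    "charged": frozenset("DEHKR"),
}


@lru_cache(maxsize=None)
def gonnet_pam250():
    """The published Gonnet PAM250 substitution matrix (20x20, symmetric)."""
    return substitution_matrices.load("GONNET1992")


@lru_cache(maxsize=None)
def _matrix_with_x():
    """Gonnet matrix extended with an X row/column scoring 0 everywhere."""
    m = gonnet_pam250()
    alphabet = m.alphabet + "X"
    ext = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in m.alphabet:
        for b in m.alphabet:
            ext[a, b] = m[a, b]
    return ext


def _check_residue(a: str) -> None:
    if a not in AA_ALPHABET and a != "X":
        raise AlphabetError(f"unknown residue {a!r}")


def pair_score(a: str, b: str, matrix=None) -> float:
    """Substitution-matrix score of a residue pair (X scores 0 against all)."""
    _check_residue(a)
    _check_residue(b)
    if "X" in (a, b):
        return 0.0
    m = matrix if matrix is not None else gonnet_pam250()
    return float(m[a, b])


def pair_symbol(a: str, b: str, matrix=None) -> str:
    """Clustal similarity symbol for one aligned column.

    ``*`` identical; ``:`` score > 0.5; ``.`` score in (0, 0.5]; space
    otherwise.  Gap columns always map to space.
    """
    if a in GAP_CHARS or b in GAP_CHARS:
        return " "
    _check_residue(a)
    _check_residue(b)
    if a == b and a != "X":
        return "*"
    s = pair_score(a, b, matrix)
    if s > 0.5:
        return ":"
    if s > 0:
        return "."
    return " "


def column_conservation(a: str, b: str, property_table=None) -> int:
    """Physicochemical conservation of one column, 0–11.

    11 iff the residues are identical; otherwise the number of property
    classes on which the pair agrees (both members or both non-members),
    at most 10.  Gap columns and X score 0.
    """
    if a in GAP_CHARS or b in GAP_CHARS:
        return 0
    _check_residue(a)
    _check_residue(b)
    if "X" in (a, b):
        return 0
    if a == b:
        return 11
    table = property_table if property_table is not None else PROPERTY_TABLE
    agree = sum(1 for members in table.values() if (a in members) == (b in members))
    return min(agree, 10)


@dataclass(frozen=True)
class AlignmentHit:
    """One scored locus of the proteome scan, with per-column annotations."""

    protein_id: str
    offset: int                 # 0-based target offset of the alignment start
    score: float
    query_aln: str              # aligned query segment (gapped in local mode)
    target_aln: str
    symbols: str                # Clustal symbol per column
    conservation: tuple[int, ...]  # 0-11 per column

    @property
    def conservation_string(self) -> str:
        """Conservation per column as characters: '*' = 11, '+' = 10, else digit."""
        out = []
        for c in self.conservation:
            out.append("*" if c == 11 else "+" if c == 10 else str(c))
        return "".join(out)


def _annotate(query_aln: str, target_aln: str, matrix) -> tuple[str, tuple[int, ...]]:
    symbols = "".join(pair_symbol(a, b, matrix) for a, b in zip(query_aln, target_aln))
    cons = tuple(column_conservation(a, b) for a, b in zip(query_aln, target_aln))
    return symbols, cons


def _encode(seq: str, alphabet: str) -> np.ndarray:
    lut = np.full(128, -1, dtype=np.int32)
    for i, ch in enumerate(alphabet):
        lut[ord(ch)] = i
    codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = seq[int(np.nonzero(codes < 0)[0][0])]
        raise AlphabetError(f"unknown residue {bad!r}")
    return codes


def _ungapped_hits(query: str, proteome: pd.DataFrame, matrix, top_k: int) -> list[AlignmentHit]:
    alphabet = str(matrix.alphabet)
    mat = np.asarray(matrix)
    q = _encode(query, alphabet)
    hits = []
    for pid, row in proteome.iterrows():
        t = _encode(row.aa_seq, alphabet)
        if len(t) < len(q):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(t, len(q))
        scores = mat[q[None, :], windows].sum(axis=1)
        for off in range(len(scores)):
            hits.append((float(scores[off]), str(pid), off))
    hits.sort(key=lambda h: (-h[0], h[1], h[2]))
    hits = hits[:top_k]
    return [
        AlignmentHit(
            protein_id=pid,
            offset=off,
            score=score,
            query_aln=query,
            target_aln=proteome.loc[pid, "aa_seq"][off : off + len(query)],
            symbols="",
            conservation=(),
        )
        for score, pid, off in hits
    ]


def _local_aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def scan_proteome(
    query: str,
    proteome: pd.DataFrame,
    matrix=None,
    mode: str = "ungapped_window",
    top_k: int = 5,
    gap_open: float = 10.0,
    gap_extend: float = 0.2,
) -> list[AlignmentHit]:
    """Scan a peptide against every protein of a proteome.

    Returns the ``top_k`` hits ranked by score, ties broken by
    (protein_id, offset), each with full per-column symbol and conservation
    annotation.  ``mode="ungapped_window"`` slides the query gaplessly;
    ``mode="local"`` runs Smith–Waterman with affine gaps.
    """
    query = query.upper()
    if len(query) < 8:
        raise PreconditionError("query must be at least 8 residues")
    if len(proteome) == 0:
        raise PreconditionError("empty proteome")
    m = matrix if matrix is not None else _matrix_with_x()
    if mode == "ungapped_window":
        hits = _ungapped_hits(query, proteome, m, top_k)
    elif mode == "local":
        aligner = _local_aligner(m, gap_open, gap_extend)
        raw = []
        for pid, row in proteome.iterrows():
            alns = aligner.align(query, row.aa_seq)
            if len(alns) == 0:
                continue
            aln = alns[0]
            t_start = int(aln.aligned[1][0][0]) if len(aln.aligned[1]) else 0
            raw.append(
                (float(aln.score), str(pid), t_start, str(aln[0]), str(aln[1]))
            )
        raw.sort(key=lambda h: (-h[0], h[1], h[2]))
        hits = [
            AlignmentHit(
                protein_id=pid, offset=off, score=score,
                query_aln=qa, target_aln=ta, symbols="", conservation=(),
            )
            for score, pid, off, qa, ta in raw[:top_k]
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    annotated = []
    for h in hits:
        symbols, cons = _annotate(h.query_aln, h.target_aln, m)
        annotated.append(
            AlignmentHit(
                protein_id=h.protein_id, offset=h.offset, score=h.score,
                query_aln=h.query_aln, target_aln=h.target_aln,
                symbols=symbols, conservation=cons,
            )
        )
    return annotated


def hits_to_frame(hits: list[AlignmentHit]) -> pd.DataFrame:
    """Hit table for serialization: one row per hit with annotation strings."""
    return pd.DataFrame(
        {
            "protein_id": [h.protein_id for h in hits],
            "offset": [h.offset for h in hits],
            "score": [h.score for h in hits],
            "query_aln": [h.query_aln for h in hits],
            "target_aln": [h.target_aln for h in hits],
            "symbol_string": [h.symbols for h in hits],
            "conservation_string": [h.conservation_string for h in hits],
        }
    )
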