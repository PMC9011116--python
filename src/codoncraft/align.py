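"""Needleman–Wunsch global DNA alignment with affine gap penalties.

Implements the Gotoh three-state dynamic program with the gap model used by
EMBOSS needle: a gap of length L costs ``gap_open + (L-1) * gap_extend``, and
default scoring follows needle's DNA defaults (match +5, mismatch -4,
gap_open 10, gap_extend 0.5 — the EDNAFULL values for canonical bases).
Percent identity follows the needle report convention: exact base matches
divided by the full alignment length, gap columns included.

Traceback is deterministic: score ties are resolved with fixed priority
diagonal > up (gap in the second sequence) > left.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .records import SequenceRecord

_NEG = float("-inf")


@dataclass(frozen=True)
class ScoringParams:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are non-negative costs")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment of two sequences.

    ``aligned_a``/``aligned_b`` are equal-length gapped strings; stripping
    ``-`` recovers the inputs. ``identity_pct`` = 100 * matches /
    alignment_length, full precision (round only for display).
    """

    aligned_a: str
    aligned_b: str
    score: float
    matches: int
    alignment_length: int
    identity_pct: float


# state codes: 0 = M (diagonal), 1 = X (up: gap in b), 2 = Y (left: gap in a)


def global_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    params: ScoringParams | None = None,
) -> AlignmentResult:
    """Optimal global alignment of two DNA sequences under affine gaps."""
    if params is None:
        params = ScoringParams()
    sa = a.seq if isinstance(a, SequenceRecord) else a
    sb = b.seq if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("global alignment requires non-empty sequences")
    n, m = len(sa), len(sb)
    go, ge = params.gap_open, params.gap_extend

    # score[i][j][state], pointer[i][j][state] -> predecessor state
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    PM = [[0] * (m + 1) for _ in range(n + 1)]
    PX = [[0] * (m + 1) for _ in range(n + 1)]
    PY = [[0] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(go + (i - 1) * ge)
        PX[i][0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0][j] = -(go + (j - 1) * ge)
        PY[0][j] = 0 if j == 1 else 2

    for i in range(1, n + 1):
        ca = sa[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        PMi, PXi, PYi = PM[i], PX[i], PY[i]
        for j in range(1, m + 1):
            s = params.match if ca == sb[j - 1] else params.mismatch
            # diagonal state: predecessor priority M > X > Y on ties
            best, ptr = Mp[j - 1], 0
            if Xp[j - 1] > best:
                best, ptr = Xp[j - 1], 1
            if Yp[j - 1] > best:
                best, ptr = Yp[j - 1], 2
            Mi[j] = best + s
            PMi[j] = ptr
            # up state (consume a, gap in b)
            best, ptr = Mp[j] - go, 0
            if Xp[j] - ge > best:
                best, ptr = Xp[j] - ge, 1
            if Yp[j] - go > best:
                best, ptr = Yp[j] - go, 2
            Xi[j] = best
            PXi[j] = ptr
            # left state (consume b, gap in a)
            best, ptr = Mi[j - 1] - go, 0
            if Xi[j - 1] - go > best:
                best, ptr = Xi[j - 1] - go, 1
            if Yi[j - 1] - ge > best:
                best, ptr = Yi[j - 1] - ge, 2
            Yi[j] = best
            PYi[j] = ptr

    state = 0
    score = M[n][m]
    if X[n][m] > score:
        state, score = 1, X[n][m]
    if Y[n][m] > score:
        state, score = 2, Y[n][m]

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            prev = PM[i][j]
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            prev = PX[i][j]
            out_a.append(sa[i - 1])
            out_b.append("-")
            i -= 1
        else:
            prev = PY[i][j]
            out_a.append("-")
            out_b.append(sb[j - 1])
            j -= 1
        state = prev
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    length = len(aligned_a)
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        matches=matches,
        alignment_length=length,
        identity_pct=100.0 * matches / length,
    )


def identity_matrix(
    seqs: list[SequenceRecord], params: ScoringParams | None = None
) -> pd.DataFrame:
    """All-vs-all percent-identity matrix from pairwise global alignments.

    Symmetric with a 100.0 diagonal; values are full precision (round to one
    decimal for display). Ids must be unique.
    """
    if len(seqs) < 2:
        raise ValueError("identity matrix needs at least 2 sequences")
    ids = [r.id for r in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sequence ids: {sorted({i for i in ids if ids.count(i) > 1})}")
    mat = pd.DataFrame(100.0, index=ids, columns=ids, dtype=float)
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            pct = global_align(seqs[i], seqs[j], params).identity_pct
            mat.iloc[i, j] = pct
            mat.iloc[j, i] = pct
    return mat


def format_identity_matrix(mat: pd.DataFrame) -> str:
    """TSV rendering with identities rounded to one decimal."""
    return mat.round(1).to_csv(sep="\t", float_format="%.1f")
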