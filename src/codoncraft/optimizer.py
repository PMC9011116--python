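"""Strict most-abundant-codon back-translation with constraint repair.

The optimization strategy mirrors how codon optimization against the usage of
a host's most highly expressed genes works in practice: every residue is first
assigned its family's most-used codon (so CAI = 1 by construction), then
sequence-level constraints — restriction-site motifs on either strand,
homopolymer runs, local and global GC content — are repaired by substituting
single synonymous codons, choosing at each step the substitution with the
smallest relative-adaptiveness loss. Repair sweeps left to right and is fully
deterministic; when no single substitution clears the leftmost violation, a
bounded depth-first search over short substitution chains is tried before
declaring the constraints infeasible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple

from .records import (
    CODON_TO_AA,
    DesignResult,
    STOP_SYMBOL,
    SYNONYM_FAMILIES,
    SequenceRecord,
    gc_fraction,
    reverse_complement,
    translate_cds,
)
from .usage_table import CodonUsageTable, cai

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: restriction sites avoided by default; NotI is included because optimized
#: inserts are cloned into NotI-digested vectors.
DEFAULT_MOTIFS = ("GGTCTC", "GAATTC", "GGATCC", "GCGGCCGC")  # BsaI EcoRI BamHI NotI


class ConstraintInfeasibleError(RuntimeError):
    """Raised when repair cannot satisfy the constraints; carries the
    residual violation report."""

    def __init__(self, message: str, report: list["Violation"]):
        super().__init__(message)
        self.report = report


class Violation(NamedTuple):
    kind: str  # motif | homopolymer | gc_window | global_gc
    start: int  # 0-based nt offset
    end: int  # exclusive
    detail: str


@dataclass(frozen=True)
class ConstraintSet:
    """Design constraints governing optimization.

    ``forbidden_motifs`` are IUPAC DNA motifs checked on both strands.
    ``max_homopolymer`` caps single-nucleotide run length. ``gc_window`` is
    (width nt, min_gc, max_gc) for a 1-nt-step sliding window; ``global_gc``
    an optional (min, max) on the whole sequence. Any field may be disabled
    with ``None`` / an empty motif list.
    """

    forbidden_motifs: tuple[str, ...] = DEFAULT_MOTIFS
    max_homopolymer: int | None = 8
    gc_window: tuple[int, float, float] | None = (50, 0.30, 0.65)
    global_gc: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for m in self.forbidden_motifs:
            if not m or set(m) - set(IUPAC_DNA):
                raise ValueError(f"motif {m!r} not an IUPAC DNA string")
        if self.max_homopolymer is not None and self.max_homopolymer < 1:
            raise ValueError("max_homopolymer must be positive")
        if self.gc_window is not None:
            width, lo, hi = self.gc_window
            if width < 10:
                raise ValueError("gc window width must be >= 10 nt")
            if not (0 <= lo < hi <= 1):
                raise ValueError("need 0 <= min_gc < max_gc <= 1")
        if self.global_gc is not None:
            lo, hi = self.global_gc
            if not (0 <= lo < hi <= 1):
                raise ValueError("need 0 <= min_gc < max_gc <= 1")


def _motif_regex(motif: str) -> re.Pattern[str]:
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=(" + "".join(
        c if len(IUPAC_DNA[c]) == 1 else "[" + IUPAC_DNA[c] + "]" for c in motif
    ) + "))")


def scan_violations(seq: SequenceRecord | str, constraints: ConstraintSet) -> list[Violation]:
    """Report every constraint breach, sorted by start coordinate.

    Motifs are matched on the forward strand and as reverse complements
    (restriction enzymes cut double-stranded DNA); intervals are 0-based,
    half-open, in forward-strand nucleotide coordinates. Homopolymer entries
    cover each maximal over-cap run; GC-window entries cover each violating
    window at 1-nt step. The report is empty iff the sequence is compliant.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    out: list[Violation] = []
    seen: set[tuple[int, int, str]] = set()
    for motif in constraints.forbidden_motifs:
        for pattern, label in (
            (_motif_regex(motif), motif),
            (_motif_regex(reverse_complement(motif)), f"revcomp({motif})"),
        ):
            for m in pattern.finditer(s):
                start, end = m.start(), m.start() + len(motif)
                key = (start, end, motif)
                if key not in seen:
                    seen.add(key)
                    out.append(Violation("motif", start, end, label))
    if constraints.max_homopolymer is not None:
        cap = constraints.max_homopolymer
        for m in re.finditer(r"(.)\1*", s):
            if m.end() - m.start() > cap:
                out.append(
                    Violation(
                        "homopolymer", m.start(), m.end(),
                        f"{m.group(1)}x{m.end() - m.start()} > cap {cap}",
                    )
                )
    if constraints.gc_window is not None and s:
        width, lo, hi = constraints.gc_window
        if len(s) >= width:
            gc_is = [1 if c in "GC" else 0 for c in s]
            run = sum(gc_is[:width])
            for i in range(len(s) - width + 1):
                if i:
                    run += gc_is[i + width - 1] - gc_is[i - 1]
                frac = run / width
                if frac < lo or frac > hi:
                    out.append(
                        Violation("gc_window", i, i + width, f"GC {frac:.3f}")
                    )
    if constraints.global_gc is not None and s:
        lo, hi = constraints.global_gc
        frac = gc_fraction(s)
        if frac < lo or frac > hi:
            out.append(Violation("global_gc", 0, len(s), f"GC {frac:.3f}"))
    out.sort(key=lambda v: (v.start, v.end, v.kind, v.detail))
    return out


def back_translate_strict(
    protein: SequenceRecord, table: CodonUsageTable
) -> SequenceRecord:
    """Encode every residue with its family-maximal-weight codon.

    Ties within a family break lexicographically by codon text. A terminal
    stop is appended using the table's highest-count stop codon.
    """
    if protein.alphabet != "protein":
        raise ValueError("back-translation expects a protein record")
    codons = [table.max_weight_codon(aa) for aa in protein.residues]
    codons.append(table.preferred_stop())
    return SequenceRecord(protein.id, "".join(codons), "dna", protein.description)


def _candidates(
    codons: list[str], table: CodonUsageTable, v: Violation
) -> list[tuple[float, int, str]]:
    """Single-codon substitutions at positions overlapping ``v``, ordered by
    smallest weight loss, then leftmost position, then codon text."""
    first = v.start // 3
    last = (v.end - 1) // 3
    cands: list[tuple[float, int, str]] = []
    for p in range(first, min(last, len(codons) - 1) + 1):
        cur = codons[p]
        for alt in SYNONYM_FAMILIES[CODON_TO_AA[cur]]:
            if alt == cur:
                continue
            loss = table.weight[cur] - table.weight[alt]
            cands.append((loss, p, alt))
    cands.sort()
    return cands


def _acceptable(report: list[Violation], v: Violation) -> bool:
    """Repair acceptance: the violation is gone and nothing ends earlier.

    A new violation ending at the same coordinate is tolerated — repairing a
    long homopolymer run necessarily proceeds through residual runs sharing
    the original right edge."""
    for w in report:
        if w.end < v.end:
            return False
        if (w.kind, w.start, w.end) == (v.kind, v.start, v.end):
            return False
    return True


def optimize(
    protein: SequenceRecord,
    table: CodonUsageTable,
    constraints: ConstraintSet | None = None,
    backtrack_depth: int = 3,
    max_iterations: int | None = None,
    _max_nodes: int = 20000,
) -> DesignResult:
    """Back-translate strictly, then repair constraint violations.

    Deterministic: starting from the strict encoding, the leftmost violation
    is repaired by the acceptable single-codon substitution with the smallest
    weight loss; if none suffices, chains of up to ``backtrack_depth``
    substitutions are searched depth-first in the same order. Translation is
    preserved by construction (only synonymous substitutions, including
    stop-to-stop swaps at the terminal codon). Raises
    :class:`ConstraintInfeasibleError` with the residual report when the
    budget is exhausted.
    """
    if constraints is None:
        constraints = ConstraintSet()
    strict = back_translate_strict(protein, table)
    codons = [strict.seq[i : i + 3] for i in range(0, len(strict.seq), 3)]
    try:
        cai_before = cai(strict, table)
    except ValueError:  # only single-codon families: CAI undefined
        cai_before = None
    trace: list[dict] = []
    if max_iterations is None:
        max_iterations = 4 * len(strict.seq) + 100

    for _ in range(max_iterations):
        report = scan_violations("".join(codons), constraints)
        if not report:
            break
        v = report[0]
        chain = _repair(codons, table, constraints, v, backtrack_depth, [_max_nodes])
        if chain is None:
            raise ConstraintInfeasibleError(
                f"cannot repair {v.kind} at [{v.start},{v.end}) in {protein.id!r}",
                report,
            )
        for p, alt in chain:
            trace.append(
                {
                    "position": p,
                    "from": codons[p],
                    "to": alt,
                    "reason": f"{v.kind} [{v.start},{v.end}) {v.detail}",
                }
            )
            codons[p] = alt
    else:
        report = scan_violations("".join(codons), constraints)
        if report:
            raise ConstraintInfeasibleError(
                f"iteration budget exhausted for {protein.id!r}", report
            )

    dna = SequenceRecord(f"{protein.id}_IhOP", "".join(codons), "dna", protein.description)
    assert translate_cds(dna.seq) == protein.residues
    try:
        cai_after = cai(dna, table)
    except ValueError:
        cai_after = None
    return DesignResult(
        record=dna,
        translation=SequenceRecord(protein.id, protein.residues, "protein"),
        trace=trace,
        cai_before=cai_before,
        cai_after=cai_after,
    )


def _repair(
    codons: list[str],
    table: CodonUsageTable,
    constraints: ConstraintSet,
    v: Violation,
    depth: int,
    budget: list[int],
    current: Violation | None = None,
) -> list[tuple[int, str]] | None:
    """Find the first acceptable substitution chain (length <= depth) for the
    leftmost violation ``v``; returns codon-index/new-codon pairs or None.

    Candidates are drawn from positions overlapping ``current`` (the
    violation blocking acceptance at this search node), but acceptance is
    always judged against the original ``v``."""
    if depth == 0 or budget[0] <= 0:
        return None
    if current is None:
        current = v
    for _, p, alt in _candidates(codons, table, current):
        budget[0] -= 1
        if budget[0] <= 0:
            return None
        saved = codons[p]
        codons[p] = alt
        report = scan_violations("".join(codons), constraints)
        if _acceptable(report, v):
            codons[p] = saved
            return [(p, alt)]
        if depth > 1:
            # recurse on the leftmost violation still blocking acceptance
            blocking = [
                w for w in report
                if w.end < v.end or (w.kind, w.start, w.end) == (v.kind, v.start, v.end)
            ]
            target = blocking[0] if blocking else current
            rest = _repair(
                codons, table, constraints, v, depth - 1, budget, current=target
            )
            if rest is not None:
                codons[p] = saved
                return [(p, alt)] + rest
        codons[p] = saved
    return None
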