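"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately implemented on different principles from the
library path it checks (recursion/enumeration instead of iterative dynamic
programming, naive rescans instead of incremental scans) so agreement is
evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

from codoncraft.records import (
    CODON_TO_AA,
    SINGLE_CODON_AAS,
    STOP_SYMBOL,
    SYNONYM_FAMILIES,
    reverse_complement,
)


def brute_force_alignment_score(
    a: str, b: str, match: float, mismatch: float, gap_open: float, gap_extend: float
) -> float:
    """Maximum global-alignment score by exhaustive top-down recursion.

    Explores every alignment (diagonal / gap-in-b / gap-in-a at each step),
    charging gap_open for the first residue of a gap run and gap_extend for
    each subsequent one; memoized on (i, j, previous move).
    """

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "d"))
        if i < len(a):
            cost = gap_extend if prev == "u" else gap_open
            best = max(best, -cost + rec(i + 1, j, "u"))
        if j < len(b):
            cost = gap_extend if prev == "l" else gap_open
            best = max(best, -cost + rec(i, j + 1, "l"))
        return best

    return rec(0, 0, "d")


def enumerate_alignment_scores(
    a: str, b: str, match: float, mismatch: float, gap_open: float, gap_extend: float
):
    """Yield the score of every global alignment, with no memoization.

    Exponential; only usable on very short strings. Validates the memoized
    oracle above on a subset of cases.
    """

    def walk(i: int, j: int, prev: str, acc: float):
        if i == len(a) and j == len(b):
            yield acc
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            yield from walk(i + 1, j + 1, "d", acc + s)
        if i < len(a):
            cost = gap_extend if prev == "u" else gap_open
            yield from walk(i + 1, j, "u", acc - cost)
        if j < len(b):
            cost = gap_extend if prev == "l" else gap_open
            yield from walk(i, j + 1, "l", acc - cost)

    yield from walk(0, 0, "d", 0.0)


def lcs_length(a: str, b: str) -> int:
    """Longest-common-subsequence length, straightforward DP."""
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, 1):
            cur.append(max(prev[j], cur[-1], prev[j - 1] + (1 if x == y else 0)))
        prev = cur
    return prev[-1]


def naive_scan(seq: str, constraints) -> list[tuple]:
    """O(n*m) position-by-position rescan of every constraint.

    Returns (kind, start, end) triples, sorted, for comparison against
    scan_violations (details dropped — coordinates and kinds must agree).
    """
    from codoncraft.optimizer import IUPAC_DNA

    found: set[tuple] = set()
    for motif in constraints.forbidden_motifs:
        for pat in {motif, reverse_complement(motif)}:
            for i in range(len(seq) - len(pat) + 1):
                if all(seq[i + k] in IUPAC_DNA[c] for k, c in enumerate(pat)):
                    found.add(("motif", i, i + len(motif)))
    if constraints.max_homopolymer is not None:
        cap = constraints.max_homopolymer
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            if j - i > cap:
                found.add(("homopolymer", i, j))
            i = j
    if constraints.gc_window is not None:
        width, lo, hi = constraints.gc_window
        for i in range(len(seq) - width + 1):
            win = seq[i : i + width]
            gc = (win.count("G") + win.count("C")) / width
            if gc < lo or gc > hi:
                found.add(("gc_window", i, i + width))
    if constraints.global_gc is not None and seq:
        lo, hi = constraints.global_gc
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        if gc < lo or gc > hi:
            found.add(("global_gc", 0, len(seq)))
    return sorted(found)


def enumerate_synonymous_encodings(protein: str, include_stop: bool = True):
    """Yield every DNA encoding of ``protein`` (optionally x every stop)."""
    families = [SYNONYM_FAMILIES[aa] for aa in protein]
    if include_stop:
        families.append(SYNONYM_FAMILIES[STOP_SYMBOL])
    for combo in itertools.product(*families):
        yield "".join(combo)


def cai_product(dna: str, table) -> float:
    """CAI by direct product in the log domain (oracle for the library cai)."""
    logs = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        aa = CODON_TO_AA[codon]
        if aa == STOP_SYMBOL or aa in SINGLE_CODON_AAS:
            continue
        logs.append(math.log(table.weight[codon]))
    return math.exp(sum(logs) / len(logs))


def best_compliant_cai(protein: str, table, constraints) -> float | None:
    """Maximum CAI over all compliant synonymous encodings, or None if no
    encoding satisfies the constraints (exhaustive search)."""
    from codoncraft.optimizer import scan_violations

    best = None
    for dna in enumerate_synonymous_encodings(protein):
        if scan_violations(dna, constraints):
            continue
        score = cai_product(dna, table)
        if best is None or score > best:
            best = score
    return best
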