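"""Synthetic fixture generator: CDS sets with controlled codon bias.

Stands in for a real set of highly expressed genes: coding sequences are
drawn codon-by-codon from a stated per-amino-acid codon frequency vector, so
usage-table estimation and optimizer behaviour can be exercised and verified
without any external data. The default bias is strongly skewed (geometric
decay within each synonym family), emulating the sharply biased usage of
highly expressed genes; it makes no attempt to mimic any real genome beyond
that skew.

All randomness flows through a single numpy Generator seeded from the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optimizer import ConstraintSet, scan_violations
from .records import (
    CODON_TO_AA,
    STOP_SYMBOL,
    SYNONYM_FAMILIES,
    SequenceRecord,
    translate_cds,
)

AMINO_ACIDS = tuple(sorted(aa for aa in SYNONYM_FAMILIES if aa != STOP_SYMBOL))


def skewed_bias(decay: float = 0.35) -> dict[str, dict[str, float]]:
    """Per-family codon frequencies with geometric decay.

    Within each synonym family (codons in lexicographic order) codon ``i``
    gets probability proportional to ``decay**i``: the first codon dominates,
    mimicking the usage skew of highly expressed genes. ``decay`` in (0, 1).
    """
    if not (0 < decay < 1):
        raise ValueError("decay must lie in (0, 1)")
    bias: dict[str, dict[str, float]] = {}
    for aa, fam in SYNONYM_FAMILIES.items():
        raw = [decay**i for i in range(len(fam))]
        total = sum(raw)
        bias[aa] = {c: w / total for c, w in zip(fam, raw)}
    return bias


@dataclass
class BiasSpec:
    """Generation recipe: codon bias, gene count, length range, seed.

    ``frequencies`` maps each amino acid (and ``*`` for stops) to a codon
    frequency vector summing to 1 over its synonym family. Lengths are in
    codons of the encoded protein (initiator Met included), drawn uniformly
    from [min_codons, max_codons]. ``composition`` optionally reweights
    amino-acid choice (uniform over the 20 by default).
    """

    frequencies: dict[str, dict[str, float]] = field(default_factory=skewed_bias)
    n_genes: int = 100
    min_codons: int = 100
    max_codons: int = 400
    seed: int = 0
    composition: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.min_codons < 10:
            raise ValueError("min_codons must be >= 10")
        if self.max_codons < self.min_codons:
            raise ValueError("max_codons < min_codons")
        for aa, fam in SYNONYM_FAMILIES.items():
            vec = self.frequencies.get(aa)
            if vec is None or set(vec) != set(fam):
                raise ValueError(f"frequencies for family {aa!r} incomplete")
            s = sum(vec.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"family {aa!r} frequencies sum to {s}, not 1")
            if any(p < 0 for p in vec.values()):
                raise ValueError(f"family {aa!r} has negative frequency")
            if max(vec.values()) == 0:
                raise ValueError(f"family {aa!r} has zero total probability")


def _draw_codon(rng: np.random.Generator, vec: dict[str, float]) -> str:
    codons = sorted(vec)
    p = np.array([vec[c] for c in codons])
    return codons[rng.choice(len(codons), p=p / p.sum())]


def generate_cds_set(spec: BiasSpec) -> list[SequenceRecord]:
    """Sample a reproducible CDS set from the bias spec.

    Each CDS starts with ATG, ends with a stop drawn from the stop-family
    frequencies, and contains no internal stop (residues are drawn from the
    20 amino acids only).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.composition is not None:
        aas = sorted(spec.composition)
        comp = np.array([spec.composition[a] for a in aas], dtype=float)
        comp = comp / comp.sum()
    else:
        aas = list(AMINO_ACIDS)
        comp = np.full(len(aas), 1.0 / len(aas))
    out: list[SequenceRecord] = []
    for g in range(spec.n_genes):
        n = int(rng.integers(spec.min_codons, spec.max_codons + 1))
        codons = ["ATG"]
        for _ in range(n - 1):
            aa = aas[rng.choice(len(aas), p=comp)]
            codons.append(_draw_codon(rng, spec.frequencies[aa]))
        codons.append(_draw_codon(rng, spec.frequencies[STOP_SYMBOL]))
        out.append(SequenceRecord(f"synth{g:04d}", "".join(codons), "dna"))
    return out


def generate_expression_table(
    ids: list[str], seed: int = 0
) -> dict[str, float]:
    """Distinct pseudo-expression values (log-normal-ish ranks) for a gene
    set, for exercising expression ranking without real RNA-seq data."""
    rng = np.random.default_rng(seed)
    values = np.sort(rng.lognormal(mean=3.0, sigma=1.5, size=len(ids)))[::-1]
    order = rng.permutation(len(ids))
    return {ids[i]: float(values[k]) for k, i in enumerate(order)}


def generate_violating_sequence(
    kind: str,
    params: dict | None = None,
    seed: int = 0,
    constraints: ConstraintSet | None = None,
) -> tuple[SequenceRecord, SequenceRecord]:
    """Emit a CDS guaranteed to contain exactly one class of violation.

    ``kind`` is ``motif``, ``homopolymer`` or ``gc_window``. Returns the DNA
    record and its translation (for optimizer round-trip tests). The result
    is verified internally with :func:`scan_violations`: at least one
    violation of the requested class and none of any other class, under the
    given (default) constraint set.
    """
    params = dict(params or {})
    if constraints is None:
        constraints = ConstraintSet()
    if kind not in ("motif", "homopolymer", "gc_window"):
        raise ValueError(f"unknown violation kind {kind!r}")
    if kind == "homopolymer":
        cap = constraints.max_homopolymer
        run = int(params.get("run", (cap or 8) + 4))
        if cap is None or run <= cap:
            raise ValueError(f"requested run {run} does not exceed cap {cap}")

    for attempt in range(64):
        rng = np.random.default_rng((seed + attempt * 7919) % 2**31)
        rec = _build_case(kind, params, rng, constraints)
        report = scan_violations(rec, constraints)
        kinds = {v.kind for v in report}
        if kinds == {kind}:
            return rec, SequenceRecord(rec.id, translate_cds(rec.seq), "protein")
    raise RuntimeError(f"could not construct a clean {kind} case (seed {seed})")


# alternating GC-rich / AT-rich codons averaging ~50% GC, no long runs;
# chosen to stay clear of the default restriction motifs on either strand
_FILLER = ("GAC", "GTT", "CTG", "ACT", "AGC", "CAT")


def _filler(rng: np.random.Generator, n: int) -> list[str]:
    prev = ""
    out = []
    for _ in range(n):
        choices = [c for c in _FILLER if c != prev]
        c = choices[int(rng.integers(len(choices)))]
        out.append(c)
        prev = c
    return out


def _build_case(
    kind: str, params: dict, rng: np.random.Generator, constraints: ConstraintSet
) -> SequenceRecord:
    pad = int(params.get("pad_codons", 25))
    head = ["ATG"] + _filler(rng, pad)
    tail = _filler(rng, pad) + ["TAA"]
    if kind == "motif":
        motif = params.get("motif") or (
            constraints.forbidden_motifs[0] if constraints.forbidden_motifs else "GAATTC"
        )
        # pad the motif to whole codons with A/C, avoiding stop codons
        payload = motif + "C" * (-len(motif) % 3)
        codons = [payload[i : i + 3] for i in range(0, len(payload), 3)]
        codons = [("GCC" if CODON_TO_AA[c] == STOP_SYMBOL else c) for c in codons]
        mid = codons
    elif kind == "homopolymer":
        run = int(params.get("run", constraints.max_homopolymer + 4))
        base = params.get("base", "A")
        payload = base * run
        payload += {"A": "C", "C": "A", "G": "C", "T": "C"}[base] * (-len(payload) % 3)
        mid = ["GGC"] if base != "G" else ["CAC"]
        mid += [payload[i : i + 3] for i in range(0, len(payload), 3)]
        mid += ["CGC"] if base != "C" else ["GAG"]
    else:  # gc_window
        width = constraints.gc_window[0] if constraints.gc_window else 50
        # an AT-rich stretch spanning more than one window drives GC below min
        n = width // 3 + 8
        at_rich = ("AAT", "ATT", "ACT", "TAT")
        mid = []
        prev = ""
        for _ in range(n):
            choices = [c for c in at_rich if c != prev]
            c = choices[int(rng.integers(len(choices)))]
            mid.append(c)
            prev = c
    seq = "".join(head + mid + tail)
    return SequenceRecord(f"violation_{kind}", seq, "dna")
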