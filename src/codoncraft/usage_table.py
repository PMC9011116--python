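"""Codon-usage tables from expression-ranked CDS sets, and CAI scoring.

The central object is :class:`CodonUsageTable`: per-codon counts over a gene
set, per-amino-acid synonym-family frequencies, and relative-adaptiveness
weights (frequency divided by the family maximum). Tables are typically built
from the coding sequences of the most highly expressed genes of the host, the
reference set the codon-adaptation index (CAI) is defined against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import (
    ALL_CODONS,
    CODON_TO_AA,
    SINGLE_CODON_AAS,
    STOP_SYMBOL,
    SYNONYM_FAMILIES,
    SequenceRecord,
    codons_of,
)


class FrameError(ValueError):
    """CDS length not divisible by 3."""


class TableFormatError(ValueError):
    """Malformed or inconsistent serialized usage table."""


def rank_top_genes(table: pd.DataFrame | Mapping[str, float], n: int) -> list[str]:
    """Return the ``n`` gene ids with highest expression.

    ``table`` is either a mapping gene id -> expression value or a two-column
    DataFrame (id, value). Ordering is deterministic: descending expression,
    ties broken by lexicographic gene id. A tie at the rank-``n`` boundary is
    resolved the same way, so the output always has exactly ``n`` ids.
    """
    if isinstance(table, pd.DataFrame):
        if table.shape[1] < 2:
            raise ValueError("expression table needs (gene id, value) columns")
        ids = table.iloc[:, 0].astype(str).tolist()
        values = table.iloc[:, 1].astype(float).tolist()
    else:
        ids = [str(k) for k in table.keys()]
        values = [float(v) for v in table.values()]
    if not ids:
        raise ValueError("empty expression table")
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids: {dupes}")
    for g, v in zip(ids, values):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"gene {g!r}: expression value {v} not finite and >= 0")
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(ids):
        raise ValueError(f"requested top {n} of only {len(ids)} genes")
    ranked = sorted(zip(ids, values), key=lambda gv: (-gv[1], gv[0]))
    return [g for g, _ in ranked[:n]]


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a two-column (gene id, expression) table; TSV or CSV, header
    auto-detected (a header is assumed when the second field of the first
    row does not parse as a number)."""
    text = Path(path).read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    first = text.splitlines()[0].split(sep)
    header = 0
    try:
        float(first[1])
        header = None
    except (ValueError, IndexError):
        pass
    df = pd.read_csv(path, sep=sep, header=header)
    df.columns = ["gene", "expression"][: df.shape[1]]
    return df


@dataclass
class CodonUsageTable:
    """Counts, family frequencies and relative-adaptiveness weights.

    Attributes
    ----------
    counts : dict
        codon -> non-negative integer, over all 64 codons (stops included).
    freq : dict
        codon -> frequency in [0, 1], normalized within each synonym family.
    weight : dict
        codon -> freq / max family freq, in (0, 1]. Families with zero
        observations get uniform freq and weight 1/|family| (never zero, so
        CAI stays finite) and are listed in ``unobserved``.
    source : str
        Provenance text (gene-set id, number of CDSs).
    """

    counts: dict[str, int]
    freq: dict[str, float] = field(default_factory=dict)
    weight: dict[str, float] = field(default_factory=dict)
    source: str = ""
    unobserved: frozenset[str] = frozenset()
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(ALL_CODONS) - set(self.counts)
        if missing:
            raise TableFormatError(f"missing codons: {sorted(missing)}")
        extra = set(self.counts) - set(ALL_CODONS)
        if extra:
            raise TableFormatError(f"unknown codons: {sorted(extra)}")
        if not self.freq or not self.weight:
            self._derive()

    def _derive(self) -> None:
        freq: dict[str, float] = {}
        weight: dict[str, float] = {}
        unobserved = set()
        for aa, fam in SYNONYM_FAMILIES.items():
            total = sum(self.counts[c] for c in fam)
            if total == 0:
                unobserved.add(aa)
                for c in fam:
                    freq[c] = 1.0 / len(fam)
                    weight[c] = 1.0 / len(fam)
                continue
            for c in fam:
                freq[c] = self.counts[c] / total
            fmax = max(freq[c] for c in fam)
            for c in fam:
                # unseen codons of an observed family get the conventional
                # 0.01 floor so weights stay in (0,1] and log-weights finite
                weight[c] = (freq[c] / fmax) if self.counts[c] else 0.01
        self.freq = freq
        self.weight = weight
        self.unobserved = frozenset(unobserved)

    def is_complete(self) -> bool:
        """True when every amino-acid family was observed at least once."""
        return not (self.unobserved - {STOP_SYMBOL})

    def max_weight_codon(self, aa: str) -> str:
        """Family-maximal-weight codon for ``aa``; ties broken by codon text."""
        fam = SYNONYM_FAMILIES[aa]
        return max(fam, key=lambda c: (self.weight[c], [-ord(x) for x in c]))

    def preferred_stop(self) -> str:
        """Highest-count stop codon, ties broken lexicographically."""
        return max(STOP_CODON_ORDER, key=lambda c: (self.counts[c], [-ord(x) for x in c]))


STOP_CODON_ORDER = SYNONYM_FAMILIES[STOP_SYMBOL]


def compute_usage_table(
    cds: Iterable[SequenceRecord], frame_check: bool = True, source: str = ""
) -> CodonUsageTable:
    """Count codons across a CDS set and derive frequencies and weights.

    With ``frame_check`` on, a record whose length is not a multiple of 3
    raises :class:`FrameError` naming the record (otherwise the trailing
    partial codon is dropped). An internal stop codon is recorded as a
    provenance note; counting continues.
    """
    counts = {c: 0 for c in ALL_CODONS}
    notes: list[str] = []
    n = 0
    for rec in cds:
        if rec.alphabet != "dna":
            raise ValueError(f"record {rec.id!r}: expected dna alphabet")
        if len(rec.seq) % 3:
            if frame_check:
                raise FrameError(
                    f"record {rec.id!r}: length {len(rec.seq)} not divisible by 3"
                )
            seq = rec.seq[: len(rec.seq) - len(rec.seq) % 3]
        else:
            seq = rec.seq
        cods = codons_of(seq)
        for i, c in enumerate(cods[:-1]):
            if CODON_TO_AA[c] == STOP_SYMBOL:
                notes.append(f"internal stop {c} in {rec.id} at codon {i}")
        for c in cods:
            counts[c] += 1
        n += 1
    return CodonUsageTable(counts=counts, source=source or f"computed from {n} CDSs", notes=notes)


def cai(seq: SequenceRecord, table: CodonUsageTable) -> float:
    """Codon adaptation index: geometric mean of relative-adaptiveness weights.

    Stop codons and the single-codon families (Met/ATG, Trp/TGG) are excluded
    per the standard convention. Raises if no includable codon remains.
    """
    if seq.alphabet != "dna":
        raise ValueError("CAI is defined on DNA coding sequences")
    log_sum = 0.0
    k = 0
    for codon in codons_of(seq.seq):
        aa = CODON_TO_AA[codon]
        if aa == STOP_SYMBOL or aa in SINGLE_CODON_AAS:
            continue
        log_sum += math.log(table.weight[codon])
        k += 1
    if k == 0:
        raise ValueError(f"record {seq.id!r}: no includable codons, CAI undefined")
    return math.exp(log_sum / k)


def write_usage_table(table: CodonUsageTable, path: str | Path | None = None) -> str:
    """Serialize as tab-separated text: codon, amino acid, count, freq, weight
    (one row per 64 codons; ``#``-prefixed provenance header)."""
    lines = [f"# source: {table.source}"]
    for note in table.notes:
        lines.append(f"# note: {note}")
    if table.unobserved:
        lines.append(f"# unobserved families: {','.join(sorted(table.unobserved))}")
    lines.append("# codon\tamino_acid\tcount\tfreq\tweight")
    for codon in ALL_CODONS:
        lines.append(
            f"{codon}\t{CODON_TO_AA[codon]}\t{table.counts[codon]}"
            f"\t{table.freq[codon]:.6f}\t{table.weight[codon]:.6f}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_usage_table(source: str | Path) -> CodonUsageTable:
    """Parse the TSV format written by :func:`write_usage_table`.

    Validates codon completeness and per-family frequency normalization
    (families must sum to 1 within rounding of the 6-decimal format).
    """
    if isinstance(source, Path) or ("\n" not in str(source) and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    counts: dict[str, int] = {}
    freq: dict[str, float] = {}
    weight: dict[str, float] = {}
    provenance = ""
    unobserved: set[str] = set()
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("# source:"):
                provenance = line.split(":", 1)[1].strip()
            if line.startswith("# unobserved families:"):
                unobserved = set(line.split(":", 1)[1].strip().split(","))
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise TableFormatError(f"malformed row: {raw!r}")
        codon, aa, cnt, fq, wt = parts
        if codon not in CODON_TO_AA:
            raise TableFormatError(f"unknown codon {codon!r}")
        if CODON_TO_AA[codon] != aa:
            raise TableFormatError(f"codon {codon} is {CODON_TO_AA[codon]}, row says {aa}")
        if codon in counts:
            raise TableFormatError(f"duplicate codon {codon}")
        counts[codon] = int(cnt)
        freq[codon] = float(fq)
        weight[codon] = float(wt)
    if set(counts) != set(ALL_CODONS):
        raise TableFormatError(
            f"expected 64 codons, got {len(counts)}: missing {sorted(set(ALL_CODONS) - set(counts))}"
        )
    for aa, fam in SYNONYM_FAMILIES.items():
        s = sum(freq[c] for c in fam)
        if abs(s - 1.0) > 1e-4:
            raise TableFormatError(f"family {aa} frequencies sum to {s:.4f}, not 1")
    return CodonUsageTable(
        counts=counts, freq=freq, weight=weight, source=provenance,
        unobserved=frozenset(unobserved),
    )


def build_table_from_top_genes(
    expression: pd.DataFrame | Mapping[str, float],
    cds_by_id: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
    n: int = 100,
) -> CodonUsageTable:
    """Convenience pipeline: rank the top-``n`` expressed genes and build the
    usage table from their coding sequences (the table the strict optimizer
    runs against)."""
    if not isinstance(cds_by_id, Mapping):
        cds_by_id = {r.id: r for r in cds_by_id}
    top = rank_top_genes(expression, n)
    missing = [g for g in top if g not in cds_by_id]
    if missing:
        raise ValueError(f"no CDS for top-ranked genes: {missing[:5]}")
    return compute_usage_table(
        [cds_by_id[g] for g in top], source=f"top {n} expressed genes"
    )
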