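"""Sequence records and genetic-code helpers shared across the toolkit.

The universal I/O unit is :class:`SequenceRecord`: an identifier plus an
upper-case DNA or protein sequence. DNA ingest converts U to T so mRNA
accessions can be used directly as coding sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from Bio.Data import CodonTable
from Bio.Seq import Seq

DNA_LETTERS = frozenset("ACGT")
PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")
STOP_SYMBOL = "*"

# Standard nuclear genetic code (NCBI translation table 1); the host organism
# (Yarrowia lipolytica) uses it.
_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid (stop codons map to "*")
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = STOP_SYMBOL

#: amino acid (or "*") -> sorted tuple of synonymous codons
SYNONYM_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in sorted(CODON_TO_AA):
    SYNONYM_FAMILIES.setdefault(CODON_TO_AA[_codon], tuple())
SYNONYM_FAMILIES = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in SYNONYM_FAMILIES
}

ALL_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
STOP_CODONS: tuple[str, ...] = SYNONYM_FAMILIES[STOP_SYMBOL]

#: single-codon families excluded from CAI by convention
SINGLE_CODON_AAS = frozenset(
    aa for aa, fam in SYNONYM_FAMILIES.items() if len(fam) == 1 and aa != STOP_SYMBOL
)


class AlphabetError(ValueError):
    """Sequence contains characters outside the declared alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """Identifier + sequence with an explicit alphabet tag.

    Parameters
    ----------
    id : str
        Record identifier (FASTA-style, no whitespace required).
    seq : str
        Sequence text; upper-cased on construction. For DNA, U is
        converted to T on ingest.
    alphabet : {"dna", "protein"}
        Which residue alphabet ``seq`` must satisfy. Protein sequences may
        carry a single terminal ``*`` stop symbol.
    description : str
        Optional free-text description carried through FASTA round trips.
    """

    id: str
    seq: str
    alphabet: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        seq = self.seq.upper()
        if self.alphabet == "dna":
            seq = seq.replace("U", "T")
            bad = set(seq) - DNA_LETTERS
            if bad:
                raise AlphabetError(
                    f"record {self.id!r}: non-DNA characters {sorted(bad)}"
                )
        else:
            body, stops = seq, ""
            if STOP_SYMBOL in seq:
                if not seq.endswith(STOP_SYMBOL) or seq.count(STOP_SYMBOL) > 1:
                    raise AlphabetError(
                        f"record {self.id!r}: '*' permitted only as terminal stop"
                    )
                body = seq[:-1]
            bad = set(body) - PROTEIN_LETTERS
            if bad:
                raise AlphabetError(
                    f"record {self.id!r}: non-protein characters {sorted(bad)}"
                )
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def residues(self) -> str:
        """Protein residues without any terminal stop symbol."""
        return self.seq.rstrip(STOP_SYMBOL) if self.alphabet == "protein" else self.seq


@dataclass
class DesignResult:
    """An engineered sequence plus a provenance trace of edits.

    ``trace`` entries are dicts; codon-level edits carry 0-based codon
    ``position``, ``from`` and ``to`` codons and a ``reason``; splice events
    carry nucleotide and residue junction coordinates.
    """

    record: SequenceRecord
    translation: SequenceRecord
    trace: list[dict[str, Any]] = field(default_factory=list)
    cai_before: float | None = None
    cai_after: float | None = None


def codons_of(dna: str) -> list[str]:
    """Split an in-frame DNA string into codons; length must be 3n."""
    if len(dna) % 3:
        raise ValueError(f"length {len(dna)} not divisible by 3")
    return [dna[i : i + 3] for i in range(0, len(dna), 3)]


def translate_cds(dna: str) -> str:
    """Translate an in-frame CDS with the standard code.

    A single terminal stop codon is dropped; internal stops appear as ``*``
    in the output so callers can detect them.
    """
    protein = str(Seq(dna).translate(table=1))
    if protein.endswith(STOP_SYMBOL):
        protein = protein[:-1]
    return protein


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def gc_fraction(dna: str) -> float:
    if not dna:
        return 0.0
    return (dna.count("G") + dna.count("C")) / len(dna)
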