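"""FASTA/GenBank readers and writers and flat configuration files.

All parsing goes through Biopython's SeqIO; this module only adapts records
to :class:`~codoncraft.records.SequenceRecord`, infers alphabets, and applies
the ingest rules (U -> T for mRNA-style DNA, duplicate-id rejection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord as _BioRecord
from Bio.Seq import Seq

from .optimizer import ConstraintSet
from .records import DNA_LETTERS, PROTEIN_LETTERS, AlphabetError, SequenceRecord

log = logging.getLogger("codoncraft")


def infer_alphabet(seq: str) -> str:
    """Infer dna/protein: sequences over {A,C,G,T,U} are taken as DNA (by
    convention; pass an explicit alphabet to force protein), anything else
    over the canonical amino-acid letters (optionally ``*``-terminated) is
    protein."""
    letters = set(seq.upper())
    if letters <= (DNA_LETTERS | {"U"}):
        return "dna"
    if letters - {"*"} <= PROTEIN_LETTERS:
        return "protein"
    bad = sorted(letters - PROTEIN_LETTERS - {"*"})
    raise AlphabetError(f"cannot infer alphabet; offending characters {bad}")


def read_fasta(path: str | Path, alphabet: str = "auto") -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords.

    ``alphabet`` is "auto", "dna" or "protein". Duplicate ids are rejected;
    U in DNA records is converted to T with a logged notice.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        alpha = infer_alphabet(seq) if alphabet == "auto" else alphabet
        if alpha == "dna" and "U" in seq:
            log.info("record %s: U converted to T on ingest", rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(rec.id, seq, alpha, desc))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    if not records:
        raise ValueError("no records to write")
    bio = [
        _BioRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def extract_cds(genbank_path: str | Path) -> list[SequenceRecord]:
    """Extract coding sequences from a GenBank flat file.

    One record per CDS feature, spliced (join locations concatenated) and
    strand-resolved (minus-strand features reverse-complemented); id is the
    locus_tag, falling back to protein_id, gene, then a positional name.
    An empty result is logged as a warning, not an error.
    """
    out: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(genbank_path), "genbank"):
        for k, feat in enumerate(rec.features):
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            name = (
                quals.get("locus_tag", quals.get("protein_id", quals.get("gene", [None])))[0]
                or f"{rec.id}_CDS{k}"
            )
            try:
                seq = str(feat.extract(rec.seq))
            except Exception as exc:  # e.g. locations off the contig
                raise ValueError(f"unsupported CDS location for {name!r}: {exc}") from exc
            out.append(SequenceRecord(name, seq, "dna"))
    if not out:
        log.warning("no CDS features found in %s", genbank_path)
    return out


@dataclass
class ToolConfig:
    """Flat tool configuration (paths plus defaults for the CLI)."""

    table: str | None = None
    constraints: str | None = None
    out_dir: str = "."
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")


def load_config(path: str | Path) -> ToolConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return ToolConfig(**data)


def load_constraints(path: str | Path) -> ConstraintSet:
    """Read a flat YAML constraint document.

    Keys: ``forbidden_motifs`` (list), ``max_homopolymer`` (int or null),
    ``gc_window`` ({width, min_gc, max_gc} or null), ``global_gc``
    ({min_gc, max_gc} or null). Missing keys fall back to the defaults.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "forbidden_motifs" in data:
        kwargs["forbidden_motifs"] = tuple(data["forbidden_motifs"])
    if "max_homopolymer" in data:
        kwargs["max_homopolymer"] = data["max_homopolymer"]
    if "gc_window" in data:
        gw = data["gc_window"]
        kwargs["gc_window"] = None if gw is None else (
            int(gw["width"]), float(gw["min_gc"]), float(gw["max_gc"])
        )
    if "global_gc" in data:
        gg = data["global_gc"]
        kwargs["global_gc"] = None if gg is None else (
            float(gg["min_gc"]), float(gg["max_gc"])
        )
    return ConstraintSet(**kwargs)


def write_constraints(constraints: ConstraintSet, path: str | Path) -> None:
    data: dict = {
        "forbidden_motifs": list(constraints.forbidden_motifs),
        "max_homopolymer": constraints.max_homopolymer,
    }
    if constraints.gc_window is not None:
        w, lo, hi = constraints.gc_window
        data["gc_window"] = {"width": w, "min_gc": lo, "max_gc": hi}
    else:
        data["gc_window"] = None
    if constraints.global_gc is not None:
        lo, hi = constraints.global_gc
        data["global_gc"] = {"min_gc": lo, "max_gc": hi}
    else:
        data["global_gc"] = None
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
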