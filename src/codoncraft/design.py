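"""Protein/gene engineering operators: truncation, fusion, domain swaps.

Three operations used when deploying membrane-anchored enzymes in a yeast
host: deleting an N-terminal transmembrane (NTM) segment, joining two enzymes
into a translational fusion through a Gly-Ser-Gly linker, and building
chimeric coding sequences whose 5' NTM-encoding segment comes from a
different (e.g. differently codon-optimized) gene, spliced at an exact codon
boundary so the reading frame is preserved by construction.

Residue coordinates are 1-based inclusive throughout, matching the
delta-notation used for truncations (Δ1-37 deletes residues 1..37);
nucleotide coordinates in traces are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import (
    CODON_TO_AA,
    DesignResult,
    STOP_SYMBOL,
    SequenceRecord,
    translate_cds,
)


class RangeError(ValueError):
    """Residue range outside the sequence or removing the C-terminus."""


class JunctionError(ValueError):
    """Splice would corrupt the reading frame or create an internal stop."""


@dataclass(frozen=True)
class DomainBoundary:
    """1-based inclusive index of the final residue of the NTM domain.

    The boundary itself is an input (domain prediction is upstream of this
    toolkit); ``last_ntm_residue`` must lie strictly inside the protein.
    """

    record_id: str
    last_ntm_residue: int

    def __post_init__(self) -> None:
        if self.last_ntm_residue < 1:
            raise ValueError("last_ntm_residue must be >= 1")


def truncate_n(
    protein: SequenceRecord,
    delete_from: int,
    delete_to: int,
    keep_initial_met: bool = False,
) -> SequenceRecord:
    """Delete residues ``delete_from..delete_to`` (1-based, inclusive).

    With ``keep_initial_met`` and ``delete_from == 1`` the deletion starts at
    residue 2 instead, preserving the initiator methionine (the Δ2-37 form).
    The output id is suffixed ``Δ<from>-<to>`` with the effective range.
    Deleting through the C-terminus is refused.
    """
    if protein.alphabet != "protein":
        raise ValueError("truncation operates on protein records")
    body = protein.residues
    stop = protein.seq[len(body):]
    n = len(body)
    if keep_initial_met:
        if delete_from not in (1, 2):
            raise ValueError("keep_initial_met only applies when deletion starts at residue 1 or 2")
        if delete_from == 1:
            delete_from = 2
    if not (1 <= delete_from <= delete_to):
        raise RangeError(f"invalid range {delete_from}-{delete_to}")
    if delete_to >= n:
        raise RangeError(
            f"range {delete_from}-{delete_to} reaches the C-terminus of a {n}-residue protein"
        )
    new_seq = body[: delete_from - 1] + body[delete_to:] + stop
    return SequenceRecord(
        f"{protein.id}Δ{delete_from}-{delete_to}", new_seq, "protein",
        protein.description,
    )


def fuse(
    upstream: SequenceRecord,
    downstream: SequenceRecord,
    linker_motif: str = "GSG",
    repeats: int = 1,
) -> SequenceRecord:
    """Translational fusion: upstream + linker_motif x repeats + downstream.

    Any terminal stop symbol on the upstream partner is removed before
    joining; the downstream sequence is used exactly as given (whether its
    initial Met is present is the caller's choice — an N-terminally truncated
    partner typically has none). ``repeats = 0`` gives a direct fusion.
    """
    for rec in (upstream, downstream):
        if rec.alphabet != "protein":
            raise ValueError(
                f"record {rec.id!r}: fusion operates on proteins; fuse DNA via the chimera path"
            )
    if repeats < 0:
        raise ValueError("repeats must be >= 0")
    linker = linker_motif * repeats
    seq = upstream.residues + linker + downstream.seq
    mid = f"-{linker_motif}x{repeats}-" if repeats != 1 else f"-{linker_motif}-"
    if repeats == 0:
        mid = "-"
    return SequenceRecord(f"{upstream.id}{mid}{downstream.id}", seq, "protein")


def _protein_length(cds: SequenceRecord) -> int:
    if len(cds.seq) % 3:
        raise JunctionError(f"record {cds.id!r}: CDS length {len(cds.seq)} not divisible by 3")
    n = len(cds.seq) // 3
    if CODON_TO_AA[cds.seq[-3:]] == STOP_SYMBOL:
        n -= 1
    return n


def swap_ntm(
    recipient_cds: SequenceRecord,
    donor_cds: SequenceRecord,
    recipient_boundary: DomainBoundary,
    donor_boundary: DomainBoundary,
) -> DesignResult:
    """Replace the recipient's NTM-encoding 5' segment with the donor's.

    The chimera is donor codons ``1..donor_boundary`` followed by recipient
    codons ``recipient_boundary+1..end``; the splice sits at exact codon
    boundaries (residue r maps to nucleotide 3r) so the frame is preserved by
    construction and no junction re-optimization is performed. The trace
    records the junction in both nucleotide and residue units.
    """
    for rec in (recipient_cds, donor_cds):
        if rec.alphabet != "dna":
            raise ValueError(f"record {rec.id!r}: chimera construction needs DNA CDSs")
    n_rec = _protein_length(recipient_cds)
    n_don = _protein_length(donor_cds)
    rb, db = recipient_boundary.last_ntm_residue, donor_boundary.last_ntm_residue
    if not (1 <= db < n_don):
        raise RangeError(f"donor boundary {db} outside protein of {n_don} residues")
    if not (1 <= rb < n_rec):
        raise RangeError(f"recipient boundary {rb} outside protein of {n_rec} residues")
    head = donor_cds.seq[: 3 * db]
    tail = recipient_cds.seq[3 * rb :]
    chimera_dna = head + tail
    protein = translate_cds(chimera_dna)
    donor_pept = translate_cds(donor_cds.seq)[:db]
    recip_pept = translate_cds(recipient_cds.seq)[rb:]
    if STOP_SYMBOL in protein:
        if STOP_SYMBOL not in donor_pept and STOP_SYMBOL not in recip_pept:
            raise JunctionError(
                f"internal stop created at the {donor_cds.id}/{recipient_cds.id} junction"
            )
    record = SequenceRecord(
        f"{recipient_cds.id}_NTMswap_{donor_cds.id}", chimera_dna, "dna"
    )
    trace = [
        {
            "kind": "splice",
            "donor": donor_cds.id,
            "recipient": recipient_cds.id,
            "junction_nt": 3 * db,
            "donor_segment_nt": [0, 3 * db],
            "recipient_segment_nt": [3 * rb, len(recipient_cds.seq)],
            "donor_segment_residues": [1, db],
            "recipient_segment_residues": [rb + 1, n_rec],
        }
    ]
    return DesignResult(
        record=record,
        translation=SequenceRecord(record.id, protein, "protein"),
        trace=trace,
    )
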