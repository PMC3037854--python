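"""Per-locus multiple alignments via a two-stage, protein-guided protocol.

Coding DNA aligns far more reliably through its translation: codon
structure is preserved and distant homology is visible at the protein
level.  Stage 1 therefore translates all full-length coding sequences,
aligns the proteins, and back-propagates the protein gap structure onto
the DNA as 3-base gaps.  Stage 2 profile-aligns the remaining partial (or
frame-unknown) DNA sequences against the stage-1 alignment, which can
stretch the stage-1 rows only by columns gapped in every one of them.  If
no full-length sequences exist for a locus, stage 1 is skipped and all
sequences are aligned together at the DNA level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq

from . import msa
from .consensus import ConsensusSequence

__all__ = ["LocusAlignment", "translate", "back_align", "align_locus",
           "InternalStopWarning"]

_GAP = "-"


class InternalStopWarning(UserWarning):
    """A translation contains an internal stop codon."""


@dataclass
class LocusAlignment:
    locus: str
    rows: dict[int, str]  # taxid -> gapped DNA
    stage1_taxa: set[int] = field(default_factory=set)
    codon_partitioned: bool = False

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths in {self.locus}: {lengths}")
        if not self.stage1_taxa <= set(self.rows):
            raise ValueError("stage1_taxa must be a subset of row taxa")


def translate(dna: str, genetic_code_id: int = 1, frame: int = 0) -> str:
    """Translate DNA from ``frame``; the trailing stop (if any) is stripped.

    Internal stops are retained in the output (as ``*``) and flagged with
    :class:`InternalStopWarning` — callers exclude such records from
    protein-guided alignment.
    """
    if len(dna) < 3:
        raise ValueError(f"sequence of length {len(dna)} cannot be translated")
    sub = dna[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    protein = str(Seq(sub).translate(table=genetic_code_id))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        warnings.warn(
            f"internal stop codon in translation ({protein.count('*')} stops)",
            InternalStopWarning, stacklevel=2,
        )
    return protein


def back_align(dna_ungapped: str, protein_row_gapped: str,
               frame: int = 0) -> str:
    """Impose a gapped protein row's structure onto its coding DNA.

    Each residue maps to its codon, each protein gap to ``---``.  DNA
    beyond the translated region (a stripped terminal stop codon) is
    dropped.  Degapping the output reproduces the translated span of the
    input exactly.
    """
    n_res = sum(1 for c in protein_row_gapped if c != _GAP)
    dna = dna_ungapped[frame:]
    if n_res * 3 > len(dna):
        raise ValueError(
            f"protein row has {n_res} residues but DNA provides only "
            f"{len(dna) // 3} codons (residue {len(dna) // 3 + 1} unmappable)"
        )
    out = []
    pos = 0
    for c in protein_row_gapped:
        if c == _GAP:
            out.append("---")
        else:
            out.append(dna[pos:pos + 3])
            pos += 3
    return "".join(out)


def align_locus(
    sequences: Sequence[ConsensusSequence],
    coding: bool = True,
    genetic_code_id: int = 1,
    quick: bool = False,
) -> LocusAlignment:
    """Align one locus's consensus sequences with the two-stage protocol.

    ``sequences`` must all belong to the same locus, one per taxon.  A
    single input sequence is returned ungapped.
    """
    if not sequences:
        raise ValueError("no sequences for locus alignment")
    loci = {s.locus for s in sequences}
    if len(loci) != 1:
        raise ValueError(f"sequences span multiple loci: {loci}")
    locus = sequences[0].locus
    taxids = [s.taxid for s in sequences]
    if len(set(taxids)) != len(taxids):
        raise ValueError("duplicate taxid in locus alignment input")

    if len(sequences) == 1:
        only = sequences[0]
        stage1 = {only.taxid} if (coding and only.full_length) else set()
        return LocusAlignment(locus, {only.taxid: only.dna}, stage1,
                              codon_partitioned=bool(stage1))

    # stage 1: full-length coding sequences with clean translations
    stage1: list[ConsensusSequence] = []
    stage2: list[ConsensusSequence] = []
    proteins: dict[int, str] = {}
    for s in sorted(sequences, key=lambda s: s.taxid):
        if coding and s.full_length and len(s.dna) >= 3:
            protein = translate(s.dna, genetic_code_id)
            if "*" in protein:
                warnings.warn(
                    f"taxon {s.taxid} locus {locus}: internal stop, "
                    "excluded from protein-guided stage",
                    InternalStopWarning, stacklevel=2,
                )
                stage2.append(s)
            elif not protein:
                stage2.append(s)
            else:
                proteins[s.taxid] = protein
                stage1.append(s)
        else:
            stage2.append(s)

    rows: dict[int, str] = {}
    stage1_rows: list[str] = []
    stage1_ids: list[int] = []
    if stage1:
        prot_alignment = msa.align_sequences(
            [proteins[s.taxid] for s in stage1], is_protein=True, quick=quick
        )
        for s, prot_row in zip(stage1, prot_alignment):
            stage1_rows.append(back_align(s.dna, prot_row))
            stage1_ids.append(s.taxid)

    if stage1 and stage2:
        updated, added = msa.add_to_alignment(
            stage1_rows, [s.dna for s in stage2], is_protein=False
        )
        for taxid, row in zip(stage1_ids, updated):
            rows[taxid] = row
        for s, row in zip(stage2, added):
            rows[s.taxid] = row
    elif stage1:
        for taxid, row in zip(stage1_ids, stage1_rows):
            rows[taxid] = row
    else:
        dna_alignment = msa.align_sequences(
            [s.dna for s in stage2], is_protein=False, quick=quick
        )
        for s, row in zip(stage2, dna_alignment):
            rows[s.taxid] = row

    return LocusAlignment(
        locus,
        rows,
        stage1_taxa=set(stage1_ids),
        codon_partitioned=bool(stage1) and not stage2,
    )
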