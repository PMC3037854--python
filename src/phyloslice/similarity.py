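"""Similarity-based locus assignment for unannotated sequences.

Records that lack usable annotation (typically ESTs) are assigned to loci
by local-alignment search against the set of annotated sequences, with a
per-locus score threshold.  Because loci evolve at different rates, one
global threshold would over-collect fast loci and under-collect slow ones;
instead each locus's threshold is calibrated empirically as the score of
the match between that locus's sequences in two reference species chosen
to span more divergence than any in-group comparison — any genuine in-group
homolog should then score at least as high.

The default engine is an in-process local aligner (protein level, BLOSUM62,
affine gaps, for coding loci; nucleotide +1/-2 otherwise).  An external
BLAST+ can substitute for it, but thresholds must always be computed with
the same engine used for the search — the calibration logic depends on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .records import SequenceRecord
from .registry import LocusRegistry

__all__ = [
    "SimilarityScorer",
    "CutoffTable",
    "compute_locus_cutoffs",
    "assign_by_similarity",
    "six_frame_translations",
]


def _protein_aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -11
    aln.extend_gap_score = -1
    return aln


def _nucleotide_aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "local"
    aln.match_score = 1
    aln.mismatch_score = -2
    aln.open_gap_score = -5
    aln.extend_gap_score = -2
    return aln


def six_frame_translations(dna: str, table: int = 1) -> list[str]:
    """All six reading-frame translations, stops replaced by X."""
    out = []
    seq = Seq(dna)
    for strand_seq in (seq, seq.reverse_complement()):
        for frame in range(3):
            sub = strand_seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) >= 3:
                out.append(str(sub.translate(table=table)).replace("*", "X"))
    return out


class SimilarityScorer:
    """Scores sequence pairs at the protein level (coding loci, best of six
    frames when the query frame is unknown) or nucleotide level (RNA loci,
    best of both strands)."""

    def __init__(self) -> None:
        self._prot = _protein_aligner()
        self._nuc = _nucleotide_aligner()

    def score_protein(self, query_dna: str, subject_dna: str,
                      query_frame_known: bool = False, table: int = 1) -> float:
        subject = six_frame_translations(subject_dna, table)[0]
        if not subject:
            return 0.0
        if query_frame_known:
            queries = six_frame_translations(query_dna, table)[:1]
        else:
            queries = six_frame_translations(query_dna, table)
        best = 0.0
        for q in queries:
            if q:
                best = max(best, float(self._prot.score(q, subject)))
        return best

    def score_nucleotide(self, query_dna: str, subject_dna: str) -> float:
        fwd = float(self._nuc.score(query_dna, subject_dna))
        rev = float(self._nuc.score(str(Seq(query_dna).reverse_complement()),
                                    subject_dna))
        return max(fwd, rev)

    def score(self, query: SequenceRecord, subject: SequenceRecord,
              coding: bool, table: int = 1) -> float:
        if coding:
            return self.score_protein(
                query.dna, subject.dna, query.frame_known, table
            )
        return self.score_nucleotide(query.dna, subject.dna)


@dataclass
class CutoffTable:
    """Per-locus similarity score thresholds for locus assignment."""

    thresholds: dict[str, float] = field(default_factory=dict)
    default_threshold: float = 50.0
    warnings: list[str] = field(default_factory=list)

    def threshold(self, locus: str) -> float:
        return self.thresholds.get(locus, self.default_threshold)


def _best_reference(records: Sequence[SequenceRecord]) -> SequenceRecord:
    # longest sequence, ties broken by accession, for determinism
    return max(records, key=lambda r: (len(r.dna), r.accession))


def compute_locus_cutoffs(
    annotated: Sequence[SequenceRecord],
    ref_a: int,
    ref_b: int,
    registry: LocusRegistry,
    default_threshold: float = 50.0,
    scorer: Optional[SimilarityScorer] = None,
) -> CutoffTable:
    """Calibrate one threshold per locus from two reference species.

    For each locus the threshold is the alignment score between the two
    reference species' sequences for that locus (protein-level for coding
    loci, nucleotide for RNA loci).  Loci lacking either reference fall back
    to ``default_threshold`` with a warning.
    """
    scorer = scorer or SimilarityScorer()
    table = CutoffTable(default_threshold=default_threshold)
    by_locus: dict[str, dict[int, list[SequenceRecord]]] = {}
    for rec in annotated:
        if rec.locus is not None and rec.taxid in (ref_a, ref_b):
            by_locus.setdefault(rec.locus, {}).setdefault(rec.taxid, []).append(rec)

    if not by_locus:
        raise ValueError("no references: neither reference taxon has any "
                         "annotated sequence for any locus")
    for locus_name in registry.locus_names:
        refs = by_locus.get(locus_name, {})
        if ref_a in refs and ref_b in refs:
            rec_a = _best_reference(refs[ref_a])
            rec_b = _best_reference(refs[ref_b])
            locus = registry[locus_name]
            if locus.coding:
                score = scorer.score_protein(
                    rec_a.dna, rec_b.dna, query_frame_known=rec_a.frame_known,
                    table=locus.genetic_code_id,
                )
            else:
                score = scorer.score_nucleotide(rec_a.dna, rec_b.dna)
            table.thresholds[locus_name] = score
        else:
            msg = (
                f"locus {locus_name!r}: reference sequence missing for "
                f"{'both taxa' if not refs else 'one taxon'}; "
                f"using default threshold {default_threshold}"
            )
            table.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
    return table


def _dedupe(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Exact-duplicate removal of the search set (same locus + sequence)."""
    seen: set[tuple[str, str]] = set()
    out = []
    for rec in sorted(records, key=lambda r: r.accession):
        key = (rec.locus or "", rec.dna)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def assign_by_similarity(
    unassigned: Sequence[SequenceRecord],
    annotated: Sequence[SequenceRecord],
    cutoffs: CutoffTable,
    registry: LocusRegistry,
    scorer: Optional[SimilarityScorer] = None,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Assign unannotated records to loci by best-hit search.

    Each record is scored against every annotated sequence and assigned the
    locus of its best hit if and only if that score reaches the locus's
    threshold.  Ties are broken by highest score, then lowest subject
    accession.  Returns ``(assigned, leftovers)``; assigned records carry
    ``provenance="similarity"``.
    """
    if unassigned and not annotated:
        raise ValueError("annotated search set is empty")
    scorer = scorer or SimilarityScorer()
    subjects = [r for r in _dedupe(annotated) if r.locus is not None]
    assigned: list[SequenceRecord] = []
    leftovers: list[SequenceRecord] = []
    for query in unassigned:
        best: Optional[tuple[float, str, str]] = None  # (score, accession, locus)
        for subj in subjects:
            locus = registry[subj.locus]
            score = scorer.score(query, subj, locus.coding, locus.genetic_code_id)
            key = (score, subj.accession)
            if best is None or score > best[0] or (
                score == best[0] and subj.accession < best[1]
            ):
                best = (score, subj.accession, subj.locus)
        if best is not None and best[0] >= cutoffs.threshold(best[2]):
            query.locus = best[2]
            query.provenance = "similarity"
            assigned.append(query)
        else:
            leftovers.append(query)
    return assigned, leftovers
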