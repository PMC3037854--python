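"""End-to-end dataset assembly: files in, consensus grid out.

Thin orchestration over the ingest, similarity and consensus stages, used
by the CLI, the examples and the acceptance checks.  All decisions live in
the underlying modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import ingest, similarity
from .consensus import Dataset, build_dataset
from .records import Rejection, SequenceRecord
from .registry import LocusRegistry
from .taxonomy import TaxonomyTree

__all__ = ["AssemblyResult", "assemble_dataset"]


@dataclass
class AssemblyResult:
    dataset: Dataset
    records: list[SequenceRecord]
    rejections: list[Rejection]
    leftovers: list[SequenceRecord] = field(default_factory=list)
    cutoffs: Optional[similarity.CutoffTable] = None

    @property
    def n_gathered(self) -> int:
        return len(self.records)


def assemble_dataset(
    registry: LocusRegistry,
    tree: TaxonomyTree,
    genbank_paths: Sequence = (),
    fasta_paths: Sequence = (),
    allowed_taxa: Optional[set[int]] = None,
    ref_taxa: Optional[tuple[int, int]] = None,
    default_threshold: float = 50.0,
    min_overlap: int = 40,
    min_identity: float = 0.95,
) -> AssemblyResult:
    """Import all files, assign unannotated records, build every consensus.

    When ``ref_taxa`` is given, per-locus cutoffs are calibrated from those
    two reference species and unannotated FASTA records are assigned by
    similarity; otherwise unannotated records are dropped as leftovers.
    """
    records: list[SequenceRecord] = []
    rejections: list[Rejection] = []
    unassigned: list[SequenceRecord] = []
    for path in genbank_paths:
        report = ingest.import_genbank(path, registry, tree, allowed_taxa)
        records.extend(report.records)
        rejections.extend(report.rejections)
    for path in fasta_paths:
        report = ingest.import_fasta(path, registry, tree, allowed_taxa)
        records.extend(report.records)
        rejections.extend(report.rejections)
        unassigned.extend(report.unassigned)

    leftovers: list[SequenceRecord] = []
    cutoffs = None
    if unassigned and ref_taxa is not None:
        cutoffs = similarity.compute_locus_cutoffs(
            records, ref_taxa[0], ref_taxa[1], registry,
            default_threshold=default_threshold,
        )
        assigned, leftovers = similarity.assign_by_similarity(
            unassigned, records, cutoffs, registry)
        records.extend(assigned)
    else:
        leftovers = unassigned

    dataset = build_dataset(records, registry, tree.label,
                            min_overlap=min_overlap,
                            min_identity=min_identity)
    return AssemblyResult(dataset, records, rejections, leftovers, cutoffs)
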