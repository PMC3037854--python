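"""Import sequences from GenBank and FASTA files.

GenBank flat files (plain or gzipped, including bulk release files) are
scanned feature-by-feature: gene/CDS/rRNA features whose gene name resolves
against the locus registry yield one record each, spliced and oriented to
the coding strand.  Every record is screened against the allowed taxon set
so whole-division release files can be processed without accumulating
out-of-scope organisms.

FASTA import expects a simple tagged header schema::

    >accession locus=<name> taxid=<int>

Records without a ``locus`` tag (or whose tag does not resolve) are
returned unassigned, queued for similarity-based assignment.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO

from Bio import SeqIO
from Bio.SeqFeature import ExactPosition

from .records import Rejection, SequenceRecord
from .registry import LocusRegistry
from .taxonomy import TaxonomyTree

__all__ = ["import_genbank", "import_fasta", "ImportReport",
           "GENOME_DESCRIPTION_PATTERNS"]

# description substrings marking a record as genome-derived (case-insensitive)
GENOME_DESCRIPTION_PATTERNS = ("complete genome", "whole genome shotgun",
                               "chromosome")

_FEATURE_TYPES = ("CDS", "rRNA", "gene")


@dataclass
class ImportReport:
    """Accepted records plus per-feature rejections."""

    records: list[SequenceRecord] = field(default_factory=list)
    rejections: list[Rejection] = field(default_factory=list)
    #: records awaiting similarity-based locus assignment (FASTA only)
    unassigned: list[SequenceRecord] = field(default_factory=list)

    def write_rejections_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("accession\treason\tdetail\n")
            for r in self.rejections:
                fh.write(f"{r.accession}\t{r.reason}\t{r.detail}\n")


def _open_maybe_gzip(path) -> TextIO:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _taxon_allowed(taxid: int, tree: TaxonomyTree,
                   allowed: Optional[Iterable[int]]) -> bool:
    if allowed is None:
        return True
    if taxid not in tree:
        return False
    return any(tree.is_descendant(taxid, of=a) for a in allowed)


def _source_taxid(record) -> Optional[int]:
    for feat in record.features:
        if feat.type == "source":
            for xref in feat.qualifiers.get("db_xref", []):
                if xref.startswith("taxon:"):
                    return int(xref.split(":", 1)[1])
    return None


def _is_genome_derived(description: str) -> bool:
    desc = description.casefold()
    return any(p in desc for p in GENOME_DESCRIPTION_PATTERNS)


def _is_complete(feature) -> bool:
    """A feature is complete when neither end carries a partial marker."""
    loc = feature.location
    return type(loc.start) is ExactPosition and type(loc.end) is ExactPosition


def _is_trans_spliced(feature) -> bool:
    parts = feature.location.parts
    strands = {p.strand for p in parts}
    return len(strands) > 1


def import_genbank(
    path,
    registry: LocusRegistry,
    tree: TaxonomyTree,
    allowed_taxa: Optional[set[int]] = None,
) -> ImportReport:
    """Extract locus-resolvable features from a GenBank flat file.

    Each gene/CDS/rRNA feature with a resolvable gene name becomes one
    :class:`SequenceRecord` carrying the feature's spliced DNA in coding
    orientation.  Gene features shadowed by a CDS/rRNA for the same gene in
    the same record are skipped (the CDS carries the precise extent).
    """
    report = ImportReport()
    with _open_maybe_gzip(path) as fh:
        for rec_index, record in enumerate(SeqIO.parse(fh, "genbank")):
            taxid = _source_taxid(record)
            features = [f for f in record.features if f.type in _FEATURE_TYPES]
            covered = {
                (f.qualifiers.get("gene") or [""])[0]
                for f in features if f.type in ("CDS", "rRNA")
            }
            for feat in features:
                gene = (feat.qualifiers.get("gene")
                        or feat.qualifiers.get("product") or [""])[0]
                if feat.type == "gene" and gene in covered:
                    continue
                acc = f"{record.id}:{gene or feat.type}"
                if not gene:
                    report.rejections.append(
                        Rejection(acc, "no gene name", f"record {rec_index}"))
                    continue
                locus = registry.resolve(gene)
                if locus is None:
                    report.rejections.append(
                        Rejection(acc, "unresolved gene name", gene))
                    continue
                if taxid is None:
                    report.rejections.append(
                        Rejection(acc, "no taxid", f"record {rec_index}"))
                    continue
                if not _taxon_allowed(taxid, tree, allowed_taxa):
                    report.rejections.append(
                        Rejection(acc, "taxon screen", f"taxid {taxid}"))
                    continue
                if _is_trans_spliced(feat):
                    report.rejections.append(
                        Rejection(acc, "trans-spliced join", gene))
                    continue
                dna = str(feat.extract(record.seq))
                complete = feat.type == "CDS" and _is_complete(feat)
                table = int((feat.qualifiers.get("transl_table") or ["1"])[0])
                report.records.append(SequenceRecord(
                    accession=acc,
                    taxid=taxid,
                    dna=dna,
                    locus=locus,
                    provenance=("genome" if _is_genome_derived(record.description)
                                else "annotated"),
                    full_length=complete,
                    description=record.description,
                    frame_known=feat.type == "CDS",
                    genetic_code_id=table,
                ))
    return report


_TAG = re.compile(r"(\w+)=(\S+)")


def import_fasta(
    path,
    registry: LocusRegistry,
    tree: TaxonomyTree,
    allowed_taxa: Optional[set[int]] = None,
) -> ImportReport:
    """Import FASTA sequences with ``locus=``/``taxid=`` header tags.

    Malformed headers (missing taxid, non-numeric taxid) are rejected with
    their line position; they never abort the import.
    """
    report = ImportReport()
    with _open_maybe_gzip(path) as fh:
        for i, record in enumerate(SeqIO.parse(fh, "fasta")):
            tags = dict(_TAG.findall(record.description))
            acc = record.id
            if "taxid" not in tags or not re.fullmatch(r"\d+", tags["taxid"]):
                report.rejections.append(
                    Rejection(acc, "no taxid", f"sequence {i + 1}"))
                continue
            taxid = int(tags["taxid"])
            if not _taxon_allowed(taxid, tree, allowed_taxa):
                report.rejections.append(
                    Rejection(acc, "taxon screen", f"taxid {taxid}"))
                continue
            if not record.seq:
                report.rejections.append(
                    Rejection(acc, "empty sequence", f"sequence {i + 1}"))
                continue
            locus = registry.resolve(tags["locus"]) if "locus" in tags else None
            try:
                rec = SequenceRecord(
                    accession=acc,
                    taxid=taxid,
                    dna=str(record.seq),
                    locus=locus,
                    provenance="annotated",
                    full_length=tags.get("full_length", "").lower() == "true",
                    description=record.description,
                    frame_known=tags.get("full_length", "").lower() == "true",
                )
            except ValueError as exc:
                report.rejections.append(
                    Rejection(acc, "bad sequence", str(exc)))
                continue
            if locus is None:
                rec.frame_known = False
                report.unassigned.append(rec)
            else:
                report.records.append(rec)
    return report
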