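"""The unit of imported data: one DNA sequence assigned to (locus, species)."""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

__all__ = ["SequenceRecord", "Rejection", "PROVENANCES"]

PROVENANCES = ("annotated", "similarity", "genome")

_DNA_OK = re.compile(r"^[ACGTRYSWKMBDHVN]+$", re.IGNORECASE)


@dataclass
class SequenceRecord:
    """One imported DNA sequence with provenance and assignment.

    ``provenance`` records how the locus identity was established:
    ``annotated`` (from source-record annotation), ``similarity`` (assigned
    by search against annotated sequences), or ``genome`` (annotated and
    derived from a fully sequenced genome — the highest-trust class).
    ``genome`` records also count as annotated for precedence purposes.
    """

    accession: str
    taxid: int
    dna: str
    locus: Optional[str] = None
    provenance: str = "annotated"
    full_length: bool = False
    description: str = ""
    frame_known: bool = False
    genetic_code_id: int = 1

    def __post_init__(self) -> None:
        self.dna = self.dna.upper()
        if not self.dna:
            raise ValueError(f"record {self.accession}: empty sequence")
        if not _DNA_OK.match(self.dna):
            bad = sorted(set(self.dna) - set("ACGTRYSWKMBDHVN"))
            raise ValueError(
                f"record {self.accession}: non-IUPAC DNA characters {bad}"
            )
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def is_annotated(self) -> bool:
        """Genome-derived records count as annotated for precedence."""
        return self.provenance in ("annotated", "genome")


@dataclass
class Rejection:
    """Why an input feature or sequence was not imported."""

    accession: str
    reason: str
    detail: str = ""
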