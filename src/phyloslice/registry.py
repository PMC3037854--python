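"""Curated locus lists and gene-name synonym resolution.

Multi-gene dataset assembly starts from a curated list of loci (genes),
each with a set of free-text synonyms as they appear in sequence-record
annotation.  Resolution of an annotated gene name to a canonical locus is
an exact lookup after normalization; there is no fuzzy matching — records
whose names do not resolve are handled downstream by similarity search.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = ["Locus", "LocusRegistry", "SynonymCollisionError", "normalize_name"]

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Normalize a gene name: strip, case-fold, collapse internal whitespace."""
    return _WS.sub(" ", name.strip()).casefold()


class SynonymCollisionError(ValueError):
    """A synonym is claimed by two distinct loci."""

    def __init__(self, synonym: str, locus_a: str, locus_b: str):
        self.synonym = synonym
        self.loci = (locus_a, locus_b)
        super().__init__(
            f"synonym {synonym!r} maps to both locus {locus_a!r} and locus {locus_b!r}"
        )


@dataclass
class Locus:
    """One curated locus: a canonical name plus its synonym set.

    ``coding`` distinguishes protein-coding genes (compared at the protein
    level during similarity search and aligned codon-wise) from RNA genes.
    """

    canonical_name: str
    synonyms: set[str] = field(default_factory=set)
    coding: bool = True
    genetic_code_id: int = 1

    def __post_init__(self) -> None:
        if not self.canonical_name or not self.canonical_name.strip():
            raise ValueError("canonical_name must be non-empty")
        # canonical name is always a member of its own synonym set
        self.synonyms = {normalize_name(s) for s in self.synonyms if s.strip()}
        self.synonyms.add(normalize_name(self.canonical_name))


class LocusRegistry:
    """Ordered collection of loci with unique, disjoint synonym sets."""

    def __init__(self, loci: Iterable[Locus] = ()):  # preserves insertion order
        self._loci: dict[str, Locus] = {}
        self._synonym_to_locus: dict[str, str] = {}
        for locus in loci:
            self.add(locus)

    def add(self, locus: Locus) -> None:
        if locus.canonical_name in self._loci:
            existing = locus.canonical_name
            raise SynonymCollisionError(locus.canonical_name, existing, existing)
        for syn in sorted(locus.synonyms):
            if syn in self._synonym_to_locus:
                raise SynonymCollisionError(
                    syn, self._synonym_to_locus[syn], locus.canonical_name
                )
        self._loci[locus.canonical_name] = locus
        for syn in locus.synonyms:
            self._synonym_to_locus[syn] = locus.canonical_name

    def add_locus(
        self,
        canonical_name: str,
        synonyms: Iterable[str] = (),
        coding: bool = True,
        genetic_code_id: int = 1,
    ) -> Locus:
        locus = Locus(canonical_name, set(synonyms), coding, genetic_code_id)
        self.add(locus)
        return locus

    def resolve(self, name: str) -> Optional[str]:
        """Resolve free text to a canonical locus name, or None on no-match."""
        return self._synonym_to_locus.get(normalize_name(name))

    def __len__(self) -> int:
        return len(self._loci)

    def __iter__(self) -> Iterator[Locus]:
        return iter(self._loci.values())

    def __contains__(self, canonical_name: str) -> bool:
        return canonical_name in self._loci

    def __getitem__(self, canonical_name: str) -> Locus:
        return self._loci[canonical_name]

    @property
    def locus_names(self) -> list[str]:
        return list(self._loci)

    def to_rows(self) -> list[list[str]]:
        """Serialize as CSV-ready rows (canonical name first, then synonyms)."""
        rows = []
        for locus in self:
            extra = sorted(locus.synonyms - {normalize_name(locus.canonical_name)})
            rows.append([locus.canonical_name, *extra])
        return rows

    def save_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            csv.writer(fh).writerows(self.to_rows())


def load_synonyms_csv(path) -> LocusRegistry:
    """Load a locus-synonym CSV: one locus per row, canonical name first.

    A header row whose first cell begins with "locus" (any case) is skipped.
    Duplicate synonyms within a row are deduplicated; a synonym appearing in
    two different rows raises :class:`SynonymCollisionError`.
    """
    registry = LocusRegistry()
    n_rows = 0
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            cells = [c.strip() for c in row if c.strip()]
            if not cells:
                continue
            if i == 0 and cells[0].casefold().startswith("locus"):
                continue
            registry.add_locus(cells[0], cells[1:])
            n_rows += 1
    if n_rows == 0:
        raise ValueError("no loci")
    return registry
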