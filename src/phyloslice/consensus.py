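"""Collapse per-(species, locus) record sets into single consensus sequences.

When several sequences exist for one locus in one species they are reduced
to one representative by precedence rules:

1. any genome-derived record wins outright (longest such if several) —
   genome annotation is the highest-trust source;
2. else a *single* annotated record takes precedence over any number of
   similarity-identified ones;
3. else a lone record stands as-is;
4. else all available records are assembled into contigs and the longest
   contig is the consensus (mis-annotated outliers end up in short
   secondary contigs and are thereby discarded).

The default assembler is a greedy overlap-layout merger: repeatedly join
the pair of contigs with the longest suffix-prefix overlap of at least
``min_overlap`` bases and at least 95% identity within the overlap.  An
external assembler (e.g. CAP3) can be substituted via the ``engine`` hook.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import pandas as pd

from .records import SequenceRecord
from .registry import LocusRegistry

__all__ = [
    "ConsensusSequence",
    "Dataset",
    "assemble",
    "build_consensus",
    "build_dataset",
    "occupancy",
]

DEFAULT_MIN_OVERLAP = 40
DEFAULT_MIN_IDENTITY = 0.95


@dataclass
class ConsensusSequence:
    taxid: int
    locus: str
    dna: str
    n_input: int
    method: str  # genome | single_annotated | single | assembled
    full_length: bool = False

    def __post_init__(self) -> None:
        if not self.dna:
            raise ValueError("consensus dna must be non-empty")
        if self.method == "assembled" and self.n_input < 2:
            raise ValueError("assembled consensus requires >=2 inputs")


# ---------------------------------------------------------------- assembly


def _max_mismatches(length: int, min_identity: float) -> int:
    return int((1.0 - min_identity) * length)


def _contained(small: str, big: str, min_identity: float) -> bool:
    """True if ``small`` occurs within ``big`` (allowing mismatches)."""
    n, m = len(small), len(big)
    if n > m:
        return False
    allowed = _max_mismatches(n, min_identity)
    if allowed == 0:
        return small in big
    for start in range(m - n + 1):
        mism = 0
        for a, b in zip(small, big[start:start + n]):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            return True
    return False


def _best_overlap(a: str, b: str, min_overlap: int, min_identity: float) -> int:
    """Longest suffix(a)/prefix(b) overlap >= min_overlap at >= min_identity."""
    for length in range(min(len(a), len(b)), min_overlap - 1, -1):
        allowed = _max_mismatches(length, min_identity)
        mism = 0
        for x, y in zip(a[-length:], b[:length]):
            if x != y:
                mism += 1
                if mism > allowed:
                    break
        else:
            return length
    return 0


def _merge(a: str, b: str, overlap: int) -> str:
    # at disagreements within the overlap, the longer contig's bases win
    chosen = a[-overlap:] if len(a) >= len(b) else b[:overlap]
    return a[:-overlap] + chosen + b[overlap:]


def assemble(
    fragments: Sequence[str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[str]:
    """Greedy overlap-layout assembly of DNA fragments into contigs.

    Fragments are canonicalised (length-descending, then lexicographic)
    before merging, so the result is invariant under input permutation.
    Returns contigs ordered by length descending, then lexicographically;
    every fragment is placed in exactly one contig (possibly a singleton).
    """
    contigs = sorted((f.upper() for f in fragments), key=lambda s: (-len(s), s))
    if not contigs:
        return []

    changed = True
    while changed and len(contigs) > 1:
        changed = False
        # absorb contained contigs first
        kept: list[str] = []
        for c in contigs:
            if any(c != k and _contained(c, k, min_identity) for k in kept):
                changed = True
            elif c in kept:  # exact duplicate
                changed = True
            else:
                kept.append(c)
        contigs = kept
        # then merge the pair with the longest overlap
        best: Optional[tuple[int, int, int]] = None  # (overlap, i, j)
        for i, a in enumerate(contigs):
            for j, b in enumerate(contigs):
                if i == j:
                    continue
                ov = _best_overlap(a, b, min_overlap, min_identity)
                if ov and (best is None or ov > best[0]):
                    best = (ov, i, j)
        if best is not None:
            ov, i, j = best
            merged = _merge(contigs[i], contigs[j], ov)
            contigs = [c for k, c in enumerate(contigs) if k not in (i, j)]
            contigs.append(merged)
            contigs.sort(key=lambda s: (-len(s), s))
            changed = True
    return sorted(contigs, key=lambda s: (-len(s), s))


# ------------------------------------------------------------- precedence


def build_consensus(
    records: Sequence[SequenceRecord],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    engine: Optional[Callable[[Sequence[str]], list[str]]] = None,
) -> ConsensusSequence:
    """Build the consensus for one (species, locus) cell.

    ``engine`` may replace the internal assembler; it must return contigs
    sorted longest-first.
    """
    if not records:
        raise ValueError("no records for consensus")
    taxids = {r.taxid for r in records}
    loci = {r.locus for r in records}
    if len(taxids) != 1 or len(loci) != 1 or None in loci:
        raise ValueError(
            f"records must share one taxid and one locus, got {taxids} x {loci}"
        )
    taxid, locus = records[0].taxid, records[0].locus
    assert locus is not None

    genome = [r for r in records if r.provenance == "genome"]
    if genome:
        chosen = max(genome, key=lambda r: (len(r.dna), r.accession))
        return ConsensusSequence(taxid, locus, chosen.dna, len(records),
                                 "genome", chosen.full_length)

    annotated = [r for r in records if r.is_annotated]
    if len(annotated) == 1:
        chosen = annotated[0]
        return ConsensusSequence(taxid, locus, chosen.dna, len(records),
                                 "single_annotated", chosen.full_length)

    if len(records) == 1:
        chosen = records[0]
        return ConsensusSequence(taxid, locus, chosen.dna, 1,
                                 "single", chosen.full_length)

    if engine is not None:
        contigs = engine([r.dna for r in records])
    else:
        contigs = assemble([r.dna for r in records], min_overlap, min_identity)
    longest = max(len(c) for c in contigs)
    # longest contig wins; ties go to the lexicographically smallest
    winner = min(c for c in contigs if len(c) == longest)
    return ConsensusSequence(taxid, locus, winner, len(records),
                             "assembled", False)


# ---------------------------------------------------------------- dataset


class Dataset:
    """The species x locus grid of consensus sequences."""

    def __init__(self, registry: LocusRegistry, taxonomy_label: str = "taxonomy"):
        self.registry = registry
        self.taxonomy_label = taxonomy_label
        self.grid: dict[tuple[int, str], ConsensusSequence] = {}

    def put(self, consensus: ConsensusSequence) -> None:
        self.grid[(consensus.taxid, consensus.locus)] = consensus

    def get(self, taxid: int, locus: str) -> Optional[ConsensusSequence]:
        return self.grid.get((taxid, locus))

    def taxa(self) -> list[int]:
        return sorted({t for t, _ in self.grid})

    def loci(self) -> list[str]:
        present = {l for _, l in self.grid}
        return [l for l in self.registry.locus_names if l in present]

    def cell_length(self, taxid: int, locus: str) -> int:
        cons = self.grid.get((taxid, locus))
        return len(cons.dna) if cons else 0

    def __len__(self) -> int:
        return len(self.grid)


def build_dataset(
    records: Sequence[SequenceRecord],
    registry: LocusRegistry,
    taxonomy_label: str = "taxonomy",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> Dataset:
    """Group assigned records by (species, locus) and build every consensus."""
    dataset = Dataset(registry, taxonomy_label)
    cells: dict[tuple[int, str], list[SequenceRecord]] = {}
    for rec in records:
        if rec.locus is None:
            raise ValueError(f"record {rec.accession} has no locus assignment")
        cells.setdefault((rec.taxid, rec.locus), []).append(rec)
    for key in sorted(cells):
        group = sorted(cells[key], key=lambda r: r.accession)
        dataset.put(build_consensus(group, min_overlap, min_identity))
    return dataset


def occupancy(dataset: Dataset, order_by_total: bool = True) -> pd.DataFrame:
    """Species x locus matrix of consensus lengths (0 = missing).

    Includes a ``total`` row and column; data rows/columns are ordered by
    total character count (descending) when ``order_by_total`` is set,
    otherwise by taxid / registry order.
    """
    taxa = dataset.taxa()
    loci = dataset.loci()
    mat = pd.DataFrame(
        [[dataset.cell_length(t, l) for l in loci] for t in taxa],
        index=pd.Index(taxa, name="taxid"),
        columns=loci,
        dtype=int,
    )
    if order_by_total and not mat.empty:
        mat = mat.loc[
            mat.sum(axis=1).sort_values(ascending=False, kind="stable").index,
            mat.sum(axis=0).sort_values(ascending=False, kind="stable").index,
        ]
    mat["total"] = mat.sum(axis=1)
    mat.loc["total"] = mat.sum(axis=0)
    return mat
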