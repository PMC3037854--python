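"""Export: concatenated partitioned NEXUS supermatrices and annotated trees.

The supermatrix concatenates one aligned block per locus, in slice order,
with absent (taxon, locus) cells filled with the missing symbol ``?``
(distinct from alignment gaps ``-``).  Character sets are declared per
locus and, for codon-partitioned loci, per codon position, in a
MrBayes-compatible SETS/mrbayes block so downstream inference can model
partitions separately.

Externally inferred trees, whose leaves are labelled with numeric taxon
ids, can be relabelled with scientific names and decorated with per-locus
character-count bar-chart and AT-content heat-map annotation files in the
iTOL dataset format.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Optional

import dendropy
from Bio import Phylo

from .consensus import Dataset
from .alignment import LocusAlignment
from .slicing import Slice, at_content
from .taxonomy import TaxonomyTree

__all__ = [
    "Supermatrix",
    "build_supermatrix",
    "write_nexus",
    "parse_nexus",
    "relabel_tree",
    "itol_annotations",
]

MISSING = "?"
GAP = "-"


@dataclass
class Supermatrix:
    name: str
    taxa: list[int]
    loci: list[str]
    spans: dict[str, tuple[int, int]]  # 1-based inclusive
    matrix: dict[int, str]
    codon_partitioned: set[str] = field(default_factory=set)

    @property
    def nchar(self) -> int:
        return max((end for _, end in self.spans.values()), default=0)

    def charsets(self) -> dict[str, str]:
        """Charset name -> NEXUS positions expression (locus + codon pos)."""
        out: dict[str, str] = {}
        for locus in self.loci:
            start, end = self.spans[locus]
            out[locus] = f"{start}-{end}"
            if locus in self.codon_partitioned:
                for pos in range(3):
                    out[f"{locus}_pos{pos + 1}"] = f"{start + pos}-{end}\\3"
        return out


def build_supermatrix(
    sl: Slice, alignments: dict[str, LocusAlignment], name: Optional[str] = None
) -> Supermatrix:
    """Concatenate per-locus alignments over the slice's taxa."""
    spans: dict[str, tuple[int, int]] = {}
    codon: set[str] = set()
    pos = 0
    for locus in sl.loci:
        aln = alignments[locus]
        extra = set(aln.rows) - set(sl.taxa)
        if extra:
            raise ValueError(
                f"alignment for {locus} contains taxa outside the slice: "
                f"{sorted(extra)}")
        spans[locus] = (pos + 1, pos + aln.length)
        pos += aln.length
        if aln.codon_partitioned:
            codon.add(locus)
    matrix: dict[int, str] = {}
    for taxid in sl.taxa:
        parts = []
        for locus in sl.loci:
            aln = alignments[locus]
            row = aln.rows.get(taxid)
            if row is None:
                parts.append(MISSING * aln.length)
            else:
                if len(row) != aln.length:
                    raise ValueError(
                        f"row for taxon {taxid} in {locus} has length "
                        f"{len(row)}, alignment length is {aln.length}")
                parts.append(row)
        matrix[taxid] = "".join(parts)
    return Supermatrix(name or sl.name, list(sl.taxa), list(sl.loci),
                       spans, matrix, codon)


def write_nexus(sm: Supermatrix, path) -> None:
    """Write a DATA + SETS + mrbayes NEXUS file, taxid row labels."""
    charsets = sm.charsets()
    with open(path, "w") as fh:
        fh.write("#NEXUS\n")
        fh.write(f"[ supermatrix: {sm.name} ]\n\n")
        fh.write("BEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(sm.taxa)} NCHAR={sm.nchar};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n")
        fh.write("  MATRIX\n")
        width = max(len(str(t)) for t in sm.taxa)
        for taxid in sm.taxa:
            fh.write(f"    {str(taxid).ljust(width)}  {sm.matrix[taxid]}\n")
        fh.write("  ;\nEND;\n\n")
        fh.write("BEGIN SETS;\n")
        for cname, expr in charsets.items():
            fh.write(f"  CHARSET {cname} = {expr};\n")
        fh.write("END;\n\n")
        fh.write("BEGIN mrbayes;\n")
        for cname, expr in charsets.items():
            fh.write(f"  charset {cname} = {expr};\n")
        locus_sets = ", ".join(sm.loci)
        fh.write(
            f"  partition by_locus = {len(sm.loci)}: {locus_sets};\n"
            "  set partition = by_locus;\n"
        )
        fh.write("END;\n")


_CHARSET_RE = re.compile(
    r"CHARSET\s+(\S+)\s*=\s*([^;]+);", re.IGNORECASE)


def parse_nexus(path) -> tuple[dict[int, str], dict[str, str]]:
    """Read back a supermatrix NEXUS file: (matrix, charsets)."""
    chars = dendropy.DnaCharacterMatrix.get(path=str(path), schema="nexus")
    matrix = {
        int(taxon.label): str(chars[taxon]).upper()
        for taxon in chars.taxon_namespace
    }
    text = open(path).read()
    sets_block = re.search(r"BEGIN\s+SETS;(.*?)END;", text,
                           re.IGNORECASE | re.DOTALL)
    charsets: dict[str, str] = {}
    if sets_block:
        for m in _CHARSET_RE.finditer(sets_block.group(1)):
            charsets[m.group(1)] = m.group(2).strip()
    return matrix, charsets


# ------------------------------------------------------------------ trees


def _safe_name(name: str) -> str:
    return name.replace(" ", "_")


def relabel_tree(tree_file, fmt: str, taxonomy: TaxonomyTree) -> str:
    """Relabel taxid leaves with scientific names; topology untouched.

    ``fmt`` is one of ``newick``, ``nexus``, ``phyloxml``.  Unknown or
    non-numeric leaf labels raise, listing every offender.
    """
    fmt = fmt.lower()
    if fmt in ("newick", "nexus"):
        tree = dendropy.Tree.get(path=str(tree_file), schema=fmt)
        bad = []
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else None
            if label is None or not re.fullmatch(r"\d+", label.strip()):
                bad.append(str(label))
            elif int(label) not in taxonomy:
                bad.append(label)
        if bad:
            raise ValueError(f"unknown leaf taxids: {', '.join(sorted(bad))}")
        for leaf in tree.leaf_node_iter():
            taxid = int(leaf.taxon.label)
            leaf.taxon.label = _safe_name(taxonomy.scientific_name(taxid))
        return tree.as_string(schema=fmt)
    if fmt == "phyloxml":
        tree = Phylo.read(str(tree_file), "phyloxml")
        leaves = tree.get_terminals()
        bad = [
            str(leaf.name) for leaf in leaves
            if leaf.name is None
            or not re.fullmatch(r"\d+", leaf.name.strip())
            or int(leaf.name) not in taxonomy
        ]
        if bad:
            raise ValueError(f"unknown leaf taxids: {', '.join(sorted(bad))}")
        for leaf in leaves:
            leaf.name = _safe_name(taxonomy.scientific_name(int(leaf.name)))
        buf = io.StringIO()
        Phylo.write(tree, buf, "phyloxml")
        return buf.getvalue()
    raise ValueError(f"unsupported tree format {fmt!r}")


# ------------------------------------------------------------ annotations


def itol_annotations(sl: Slice, dataset: Dataset) -> tuple[str, str]:
    """iTOL dataset files: per-locus character counts (stacked multibar)
    and per-locus AT content (heatmap), keyed by taxid.

    Missing cells contribute 0 to the bar chart and a blank heatmap field.
    """
    labels = ",".join(sl.loci)
    bar = [
        "DATASET_MULTIBAR",
        "SEPARATOR COMMA",
        f"DATASET_LABEL,characters per locus ({sl.name})",
        f"FIELD_LABELS,{labels}",
        "DATA",
    ]
    heat = [
        "DATASET_HEATMAP",
        "SEPARATOR COMMA",
        f"DATASET_LABEL,AT content per locus ({sl.name})",
        f"FIELD_LABELS,{labels}",
        "DATA",
    ]
    for taxid in sl.taxa:
        counts = [str(dataset.cell_length(taxid, locus)) for locus in sl.loci]
        bar.append(f"{taxid}," + ",".join(counts))
        ats = []
        for locus in sl.loci:
            cons = dataset.get(taxid, locus)
            at = at_content(cons.dna) if cons is not None else None
            ats.append("" if at is None else f"{at:.4f}")
        heat.append(f"{taxid}," + ",".join(ats))
    return "\n".join(bar) + "\n", "\n".join(heat) + "\n"
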