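"""Seeded synthetic datasets with known truth.

The generator emulates the raw material of multi-gene dataset assembly: a
small multi-level taxonomy (orders / families / species plus a divergent
outgroup), per-locus coding sequences evolved down that taxonomy by
per-branch substitution, per-lineage rate multipliers (planted "fast"
species), AT-composition pressure (planted "biased" species), patchy
locus-by-species occupancy, fragmentation of cells into overlapping
EST-like partial records, and annotation noise (synonym use or missing
gene names).  Everything is a deterministic function of the seed.

It emits exactly the file formats the ingest stage consumes — a locus
synonym CSV, a taxonomy CSV, a GenBank file holding genome-derived
full-length reference records for two reference species (one in-group,
one deeply divergent outgroup, for per-locus cutoff calibration), and a
tagged FASTA of everything else — plus truth tables (TSV) recording each
species' planted rate class and AT pressure and each cell's true sequence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from random import Random
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .consensus import Dataset
from .registry import LocusRegistry
from .taxonomy import TaxonomyTree

__all__ = ["SimulationSpec", "SimulationResult", "simulate", "truth_check",
           "dataset_from_truth"]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    Defaults model a desk-scale multigene assembly: a handful of orders
    with a few species each, three ribosomal-protein-sized coding loci
    (300 bp), a few percent divergence per branch, a 3x rate multiplier
    for planted fast lineages, and strong (0.9) AT pressure with an
    elevated substitution load for planted biased lineages — compositional
    outliers are long-branched too.
    """

    seed: int = 0
    n_orders: int = 4
    families_per_order: int = 2
    species_per_family: int = 3
    n_loci: int = 3
    locus_length: int = 300
    branch_rate: float = 0.02
    rate_multiplier: float = 3.0
    at_pressure: float = 0.9
    bias_rate_multiplier: float = 10.0
    outgroup_rate_multiplier: float = 10.0
    fast_per_order: int = 0
    biased_per_order: int = 0
    missing_prob: float = 0.15
    partial_prob: float = 0.3
    fragment_prob: float = 0.35
    fragments_per_cell: tuple[int, int] = (2, 3)
    fragment_length: tuple[int, int] = (150, 240)
    min_fragment_overlap: int = 60
    annotation_noise_prob: float = 0.1

    def validate(self) -> None:
        if self.locus_length % 3 != 0:
            raise ValueError("locus_length must be a multiple of 3")
        for name in ("at_pressure", "missing_prob", "partial_prob",
                     "fragment_prob", "annotation_noise_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.n_orders, self.families_per_order,
               self.species_per_family, self.n_loci) < 1:
            raise ValueError("taxonomy shape and n_loci must be >= 1")
        if self.families_per_order > 9 or self.species_per_family > 9:
            raise ValueError("at most 9 families/order and 9 species/family")
        if self.fast_per_order + self.biased_per_order > (
                self.families_per_order * self.species_per_family):
            raise ValueError("more planted species than species per order")


@dataclass
class SimulationResult:
    spec: SimulationSpec
    outdir: Path
    loci_csv: Path
    taxonomy_csv: Path
    genbank: Path
    fasta: Path
    truth_species_tsv: Path
    truth_cells_tsv: Path
    registry: LocusRegistry
    tree: TaxonomyTree
    ref_a: int  # in-group reference species (genome-derived records)
    ref_b: int  # outgroup reference species
    outgroup: int
    #: taxid -> {"fast": bool, "biased": bool, "order": order taxid}
    species_truth: dict[int, dict] = field(default_factory=dict)
    #: (taxid, locus) -> {"sequence", "n_subs", "emitted", "fragments"}
    cell_truth: dict[tuple[int, str], dict] = field(default_factory=dict)


def _random_coding_sequence(rng: Random, length: int) -> str:
    codons = []
    while len(codons) * 3 < length:
        codon = "".join(rng.choice(_BASES) for _ in range(3))
        if codon not in _STOPS:
            codons.append(codon)
    return "".join(codons)


def _mutate(rng: Random, seq: str, rate: float, at_pressure: float,
            coding: bool) -> tuple[str, int]:
    """Apply per-site substitutions; returns (sequence, substitution count)."""
    chars = list(seq)
    n_subs = 0
    for pos in range(len(chars)):
        if rng.random() >= rate:
            continue
        current = chars[pos]
        for _ in range(10):  # retry around stop codons
            if rng.random() < at_pressure:
                choices = [b for b in "AT" if b != current]
            else:
                choices = [b for b in _BASES if b != current]
            new = rng.choice(choices) if choices else current
            if new == current:
                continue
            if coding:
                codon_start = pos - pos % 3
                codon = chars[codon_start:codon_start + 3]
                codon[pos % 3] = new
                if "".join(codon) in _STOPS:
                    continue
            chars[pos] = new
            n_subs += 1
            break
    return "".join(chars), n_subs


def _fragment(rng: Random, seq: str, spec: SimulationSpec) -> list[str]:
    n = rng.randint(*spec.fragments_per_cell)
    length = len(seq)
    frags = []
    start = 0
    prev_end = 0
    for i in range(n):
        flen = rng.randint(*spec.fragment_length)
        if i == n - 1:
            # final fragment reaches the end but must overlap its predecessor
            start = max(0, min(length - flen,
                               prev_end - spec.min_fragment_overlap))
            frags.append(seq[start:])
            break
        end = min(start + flen, length)
        frags.append(seq[start:end])
        prev_end = end
        if end >= length:
            break
        overlap = rng.randint(spec.min_fragment_overlap,
                              spec.min_fragment_overlap + 40)
        start = max(0, end - overlap)
    return [f for f in frags if f]


def _genbank_record(acc: str, taxid: int, organism: str, locus_name: str,
                    dna: str, table: int = 1) -> SeqRecord:
    rec = SeqRecord(
        Seq(dna), id=acc, name=acc.replace(".", "_")[:16],
        description=f"{organism} {locus_name} gene, complete genome",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["organism"] = organism
    rec.features.append(SeqFeature(
        FeatureLocation(0, len(dna)), type="source",
        qualifiers={"organism": [organism], "db_xref": [f"taxon:{taxid}"]},
    ))
    rec.features.append(SeqFeature(
        FeatureLocation(0, len(dna)), type="CDS",
        qualifiers={"gene": [locus_name], "transl_table": [str(table)],
                    "codon_start": ["1"]},
    ))
    return rec


def simulate(spec: SimulationSpec, outdir) -> SimulationResult:
    """Generate one synthetic dataset under ``spec`` into ``outdir``."""
    spec.validate()
    rng = Random(spec.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- loci and registry -------------------------------------------
    locus_names = [f"loc{i + 1}" for i in range(spec.n_loci)]
    registry = LocusRegistry()
    synonym_of: dict[str, str] = {}
    for name in locus_names:
        syn = f"g{name[3:]}"
        registry.add_locus(name, [name.upper(), syn])
        synonym_of[name] = syn
    loci_csv = outdir / "loci.csv"
    registry.save_csv(loci_csv)

    # ---- taxonomy -----------------------------------------------------
    tree = TaxonomyTree("synthetic")
    tree.add_node(1, "Root", "no rank", None)
    outgroup_order = 90
    tree.add_node(outgroup_order, "Outgroupia", "order", 1)
    tree.add_node(91, "Outgroupidae", "family", outgroup_order)
    ref_b = 92
    tree.add_node(ref_b, "Outgroupus refexus", "species", 91)
    orders = []
    species: list[int] = []
    order_of: dict[int, int] = {ref_b: outgroup_order}
    for i in range(spec.n_orders):
        order = 100 * (i + 1)
        orders.append(order)
        tree.add_node(order, f"Order{i + 1}", "order", 1)
        for j in range(spec.families_per_order):
            family = order + 10 * (j + 1)
            tree.add_node(family, f"Family{i + 1}.{j + 1}", "family", order)
            for k in range(spec.species_per_family):
                sp = family + k + 1
                tree.add_node(sp, f"Species {i + 1}.{j + 1}.{k + 1}",
                              "species", family)
                species.append(sp)
                order_of[sp] = order
    tree.validate()
    taxonomy_csv = outdir / "taxonomy.csv"
    tree.save_csv(taxonomy_csv)
    ref_a = species[0]  # first in-group species: dense, genome-derived

    # ---- plant fast / biased species ---------------------------------
    species_truth: dict[int, dict] = {
        sp: {"fast": False, "biased": False, "order": order_of[sp]}
        for sp in species + [ref_b]
    }
    for order in orders:
        candidates = [sp for sp in species
                      if order_of[sp] == order and sp != ref_a]
        flagged = rng.sample(
            sorted(candidates), spec.fast_per_order + spec.biased_per_order)
        for sp in flagged[:spec.fast_per_order]:
            species_truth[sp]["fast"] = True
        for sp in flagged[spec.fast_per_order:]:
            species_truth[sp]["biased"] = True

    # ---- evolve sequences down the tree ------------------------------
    # per locus: taxid -> sequence at that node
    node_seq: dict[str, dict[int, str]] = {}
    cell_truth: dict[tuple[int, str], dict] = {}
    for locus in locus_names:
        root_seq = _random_coding_sequence(rng, spec.locus_length)
        seqs = {1: root_seq}
        # breadth-first over the fixed taxonomy
        queue = [1]
        while queue:
            parent = queue.pop(0)
            for child in tree.nodes[parent].children:
                node = tree.nodes[child]
                rate = spec.branch_rate
                pressure = 0.0
                if node.rank == "species":
                    truth = species_truth[child]
                    if child == ref_b:
                        rate *= spec.outgroup_rate_multiplier
                    elif truth["fast"]:
                        rate *= spec.rate_multiplier
                    elif truth["biased"]:
                        rate *= spec.bias_rate_multiplier
                        pressure = spec.at_pressure
                seqs[child], n_subs = _mutate(
                    rng, seqs[parent], rate, pressure, coding=True)
                if node.rank == "species":
                    cell_truth[(child, locus)] = {
                        "sequence": seqs[child],
                        "expected": seqs[child],
                        "n_subs": n_subs,
                        "emitted": True,
                        "partial": False,
                        "fragments": 1,
                    }
                queue.append(child)
        node_seq[locus] = seqs

    # ---- emit files ---------------------------------------------------
    genbank = outdir / "refs.gb"
    gb_records = []
    for ref, organism in ((ref_a, tree.scientific_name(ref_a)),
                          (ref_b, tree.scientific_name(ref_b))):
        for locus in locus_names:
            gb_records.append(_genbank_record(
                f"REF{ref}L{locus[3:]}", ref, organism, locus,
                cell_truth[(ref, locus)]["sequence"]))
    with open(genbank, "w") as fh:
        SeqIO.write(gb_records, fh, "genbank")

    fasta = outdir / "sequences.fsa"
    counter = 0
    with open(fasta, "w") as fh:
        for sp in species:
            if sp == ref_a:
                continue  # reference comes from the GenBank file
            # planted outliers model genome-backed taxa: always data-dense
            planted = (species_truth[sp]["fast"] or species_truth[sp]["biased"])
            for locus in locus_names:
                truth = cell_truth[(sp, locus)]
                seq = truth["sequence"]
                if planted:
                    pieces, full = [seq], True
                else:
                    if rng.random() < spec.missing_prob:
                        truth["emitted"] = False
                        continue
                    draw = rng.random()
                    if draw < spec.partial_prob:
                        # a genuinely partial cell: one incomplete fragment
                        flen = min(rng.randint(*spec.fragment_length),
                                   len(seq) - 1)
                        start = rng.randint(0, len(seq) - flen)
                        pieces = [seq[start:start + flen]]
                        full = False
                        truth["partial"] = True
                        truth["expected"] = pieces[0]
                    elif draw < spec.partial_prob + spec.fragment_prob:
                        pieces = _fragment(rng, seq, spec)
                        full = False
                    else:
                        pieces = [seq]
                        full = True
                truth["fragments"] = len(pieces)
                for piece in pieces:
                    counter += 1
                    tags = [f"taxid={sp}"]
                    if rng.random() < spec.annotation_noise_prob:
                        if rng.random() < 0.5:
                            pass  # gene name lost: similarity route
                        else:
                            tags.insert(0, f"locus={synonym_of[locus]}")
                    else:
                        tags.insert(0, f"locus={locus}")
                    if full:
                        tags.append("full_length=true")
                    fh.write(f">sim{counter:05d} {' '.join(tags)}\n{piece}\n")

    # ---- truth tables -------------------------------------------------
    truth_species_tsv = outdir / "truth_species.tsv"
    with open(truth_species_tsv, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["taxid", "order", "fast", "biased"])
        for sp in sorted(species_truth):
            t = species_truth[sp]
            w.writerow([sp, t["order"], int(t["fast"]), int(t["biased"])])
    truth_cells_tsv = outdir / "truth_cells.tsv"
    with open(truth_cells_tsv, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["taxid", "locus", "length", "n_subs", "emitted",
                    "partial", "fragments", "sequence", "expected"])
        for (sp, locus) in sorted(cell_truth):
            t = cell_truth[(sp, locus)]
            w.writerow([sp, locus, len(t["sequence"]), t["n_subs"],
                        int(t["emitted"]), int(t["partial"]), t["fragments"],
                        t["sequence"], t["expected"]])

    return SimulationResult(
        spec=spec, outdir=outdir, loci_csv=loci_csv,
        taxonomy_csv=taxonomy_csv, genbank=genbank, fasta=fasta,
        truth_species_tsv=truth_species_tsv, truth_cells_tsv=truth_cells_tsv,
        registry=registry, tree=tree, ref_a=ref_a, ref_b=ref_b,
        outgroup=outgroup_order, species_truth=species_truth,
        cell_truth=cell_truth,
    )


def dataset_from_truth(result: SimulationResult) -> Dataset:
    """Build the consensus grid directly from the generator's truth.

    Bypasses ingest and assembly: each emitted cell becomes one consensus
    holding its recoverable sequence (full, or the partial window).
    Convenient for studying the selection criteria in isolation.
    """
    from .consensus import ConsensusSequence

    dataset = Dataset(result.registry, result.tree.label)
    for (taxid, locus), truth in sorted(result.cell_truth.items()):
        if truth["emitted"]:
            dataset.put(ConsensusSequence(
                taxid=taxid, locus=locus, dna=truth["expected"],
                n_input=1, method="single",
                full_length=not truth["partial"],
            ))
    return dataset


@dataclass
class TruthReport:
    exact: int = 0
    mismatch: int = 0
    missing: int = 0
    unexpected: int = 0
    mismatched_cells: list[tuple[int, str]] = field(default_factory=list)

    @property
    def recovery_rate(self) -> float:
        total = self.exact + self.mismatch + self.missing
        return self.exact / total if total else 1.0


def truth_check(dataset: Dataset, result: SimulationResult) -> TruthReport:
    """Compare a pipeline-built dataset against the generator's truth.

    A cell counts as exact when the recovered consensus equals the
    recoverable truth (the full terminal sequence, or the emitted window
    for genuinely partial cells) character-for-character.  Cells the
    generator dropped must be absent from the dataset.
    """
    report = TruthReport()
    for (taxid, locus), truth in sorted(result.cell_truth.items()):
        cons = dataset.get(taxid, locus)
        if not truth["emitted"]:
            if cons is not None:
                report.unexpected += 1
            continue
        if cons is None:
            report.missing += 1
        elif cons.dna == truth["expected"]:
            report.exact += 1
        else:
            report.mismatch += 1
            report.mismatched_cells.append((taxid, locus))
    return report
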