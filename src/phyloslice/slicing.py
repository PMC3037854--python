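"""Slices: taxa x loci subsets, selected manually or by explicit criteria.

Large assembled datasets are mined for analysis subsets ("slices").
Besides manual picking, representative species can be selected per
taxonomic level under three criteria designed to counter systematic bias
in deep phylogenetic reconstruction:

``most_chars``
    rank candidates by total characters over the selected loci — data
    quantity, blind to how many loci contribute (a candidate with fewer
    loci but more characters outranks a rival with partial sequences).

``least_bias``
    rank by mean absolute deviation of per-locus AT content from the
    dataset-wide per-locus mean — compositional outliers score badly.
    Lower is better; only candidates with at least one sequence compete.

``slowest_rate``
    rank by mean similarity to other species: per locus, the candidate's
    aligned sequence is compared with ten randomly chosen species from
    outside its own level node; the similarity to one comparator is the
    fraction of the candidate's non-gap alignment columns where the
    comparator matches exactly.  Fast-evolving lineages (long branches)
    resemble everything less and are avoided.  Higher is better.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .alignment import LocusAlignment, align_locus
from .consensus import Dataset
from .taxonomy import TaxonomyTree

__all__ = [
    "Slice",
    "CriterionScore",
    "CRITERIA",
    "at_content",
    "global_at_means",
    "score_most_chars",
    "score_least_bias",
    "score_slowest_rate",
    "build_rate_alignments",
    "auto_select",
    "manual_select",
    "mean_pairwise_divergence",
]

CRITERIA = ("most_chars", "least_bias", "slowest_rate")
N_COMPARATORS = 10

_GAP = "-"


@dataclass
class CriterionScore:
    taxid: int
    criterion: str
    score: float
    higher_better: bool

    def rank_key(self) -> tuple:
        # sortable so that better scores come first, ties by taxid ascending
        primary = -self.score if self.higher_better else self.score
        return (primary, self.taxid)


@dataclass
class Slice:
    """A stored subset of taxa and loci, with how it was derived."""

    name: str
    taxa: list[int]
    loci: list[str]
    selection_spec: Optional[dict] = None

    def __post_init__(self) -> None:
        self.taxa = sorted(set(self.taxa))
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate loci in slice")

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name, "taxa": self.taxa, "loci": self.loci,
             "selection_spec": self.selection_spec},
            indent=2, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "Slice":
        d = json.loads(text)
        return cls(d["name"], d["taxa"], d["loci"], d.get("selection_spec"))


# ------------------------------------------------------------- criteria


def at_content(dna: str) -> Optional[float]:
    """Fraction of unambiguous bases that are A or T.

    Ambiguity codes and gaps are excluded from numerator and denominator.
    Returns None when no unambiguous base is present.
    """
    if not dna:
        raise ValueError("at_content of empty sequence")
    up = dna.upper()
    at = sum(up.count(c) for c in "AT")
    acgt = at + sum(up.count(c) for c in "CG")
    if acgt == 0:
        return None
    return at / acgt


def global_at_means(dataset: Dataset, loci: Sequence[str]) -> dict[str, float]:
    """Per-locus mean AT content across the dataset.

    Averaged per species (each species' consensus contributes one value,
    regardless of length) so deeply sequenced species do not dominate.
    """
    means: dict[str, float] = {}
    for locus in loci:
        values = []
        for taxid in dataset.taxa():
            cons = dataset.get(taxid, locus)
            if cons is not None:
                at = at_content(cons.dna)
                if at is not None:
                    values.append(at)
        if values:
            means[locus] = sum(values) / len(values)
    return means


def score_most_chars(
    dataset: Dataset, taxid: int, loci: Sequence[str]
) -> CriterionScore:
    total = sum(dataset.cell_length(taxid, locus) for locus in loci)
    return CriterionScore(taxid, "most_chars", float(total), higher_better=True)


def score_least_bias(
    dataset: Dataset,
    taxid: int,
    loci: Sequence[str],
    global_means: dict[str, float],
) -> Optional[CriterionScore]:
    """Mean |AT - global mean| over the loci the candidate possesses.

    Returns None (excluded) for candidates with no sequence at any
    selected locus — absence is not evidence of bias.
    """
    diffs = []
    for locus in loci:
        cons = dataset.get(taxid, locus)
        if cons is None or locus not in global_means:
            continue
        at = at_content(cons.dna)
        if at is not None:
            diffs.append(abs(at - global_means[locus]))
    if not diffs:
        return None
    return CriterionScore(taxid, "least_bias", sum(diffs) / len(diffs),
                          higher_better=False)


def build_rate_alignments(
    dataset: Dataset, loci: Sequence[str], quick: bool = True
) -> dict[str, LocusAlignment]:
    """One rapid all-species alignment per locus, for rate scoring."""
    alignments: dict[str, LocusAlignment] = {}
    for locus in loci:
        seqs = [dataset.get(t, locus) for t in dataset.taxa()]
        present = [s for s in seqs if s is not None]
        if present:
            info = dataset.registry[locus]
            alignments[locus] = align_locus(
                present, coding=info.coding,
                genetic_code_id=info.genetic_code_id, quick=quick,
            )
    return alignments


def _derive_seed(seed: int, taxid: int, locus: str) -> int:
    digest = hashlib.sha256(f"{seed}:{taxid}:{locus}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def row_similarity(candidate_row: str, comparator_row: str) -> Optional[float]:
    """Fraction of candidate non-gap columns where the comparator matches."""
    matches = 0
    sites = 0
    for a, b in zip(candidate_row, comparator_row):
        if a != _GAP:
            sites += 1
            if a == b:
                matches += 1
    if sites == 0:
        return None
    return matches / sites


def score_slowest_rate(
    dataset: Dataset,
    taxid: int,
    loci: Sequence[str],
    level_node: int,
    tree: TaxonomyTree,
    seed: int,
    alignments: dict[str, LocusAlignment],
) -> Optional[CriterionScore]:
    """Mean similarity to sampled out-group species, per locus then overall.

    Per locus, up to ``N_COMPARATORS`` species are drawn uniformly without
    replacement (seeded per candidate and locus) from the pool of species
    outside the candidate's level node that possess the locus.  Candidates
    with no scorable locus are excluded (None).
    """
    locus_scores = []
    for locus in loci:
        aln = alignments.get(locus)
        if aln is None or taxid not in aln.rows:
            continue
        pool = sorted(
            t for t in aln.rows
            if t != taxid and not tree.is_descendant(t, of=level_node)
        )
        if not pool:
            continue
        rng = random.Random(_derive_seed(seed, taxid, locus))
        if len(pool) > N_COMPARATORS:
            comparators = sorted(rng.sample(pool, N_COMPARATORS))
        else:
            comparators = pool
        sims = []
        for comp in comparators:
            sim = row_similarity(aln.rows[taxid], aln.rows[comp])
            if sim is not None:
                sims.append(sim)
        if sims:
            locus_scores.append(sum(sims) / len(sims))
    if not locus_scores:
        return None
    return CriterionScore(taxid, "slowest_rate",
                          sum(locus_scores) / len(locus_scores),
                          higher_better=True)


# ------------------------------------------------------------- selection


def auto_select(
    dataset: Dataset,
    tree: TaxonomyTree,
    selected_nodes: Iterable[int],
    level: str,
    n_per_group: int,
    loci: Sequence[str],
    criterion: str,
    seed: int = 0,
    name: str = "auto",
    extra_taxa: Iterable[int] = (),
) -> Slice:
    """Pick the ``n_per_group`` best candidates per level node.

    Traverses the taxonomy from the selected nodes down to every node of
    the requested rank, ranks each level node's candidate species under
    the criterion (ties by taxid ascending), and unions the winners.
    ``extra_taxa`` adds explicit species (e.g. an outgroup) untouched by
    ranking.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; expected one of "
                         f"{CRITERIA}")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    selected_nodes = list(selected_nodes)
    loci = list(loci)
    level_node_list = tree.level_nodes(selected_nodes, level)

    global_means: dict[str, float] = {}
    alignments: dict[str, LocusAlignment] = {}
    if criterion == "least_bias":
        global_means = global_at_means(dataset, loci)
    elif criterion == "slowest_rate":
        alignments = build_rate_alignments(dataset, loci, quick=True)

    chosen: set[int] = set()
    any_rankable = False
    for node in level_node_list:
        scores: list[CriterionScore] = []
        for cand in tree.candidate_species(node):
            if criterion == "most_chars":
                score: Optional[CriterionScore] = score_most_chars(
                    dataset, cand, loci)
            elif criterion == "least_bias":
                score = score_least_bias(dataset, cand, loci, global_means)
            else:
                score = score_slowest_rate(
                    dataset, cand, loci, node, tree, seed, alignments)
            if score is not None:
                scores.append(score)
        if scores:
            any_rankable = True
            scores.sort(key=lambda s: s.rank_key())
            chosen.update(s.taxid for s in scores[:n_per_group])
    if not any_rankable:
        raise ValueError("empty slice: no rankable candidates under "
                         f"criterion {criterion!r}")
    chosen.update(extra_taxa)
    return Slice(
        name=name,
        taxa=sorted(chosen),
        loci=loci,
        selection_spec={
            "selected_nodes": sorted(selected_nodes),
            "level": level,
            "n_per_group": n_per_group,
            "criterion": criterion,
            "seed": seed,
        },
    )


def manual_select(
    dataset: Dataset,
    tree: TaxonomyTree,
    chosen: Iterable[int],
    loci: Sequence[str],
    name: str = "manual",
) -> Slice:
    """Chosen species are included directly; chosen higher-level groups
    contribute all their descendant species."""
    taxa: set[int] = set()
    for taxid in chosen:
        node = tree.nodes.get(taxid)
        if node is None:
            raise KeyError(f"taxid {taxid} not found in taxonomy")
        if node.rank.casefold() == "species":
            taxa.add(taxid)
        else:
            taxa.update(tree.candidate_species(taxid))
    return Slice(name=name, taxa=sorted(taxa), loci=list(loci))


# ------------------------------------------------------------- analysis


def mean_pairwise_divergence(
    dataset: Dataset, sl: Slice, quick: bool = True
) -> float:
    """Mean pairwise p-distance among slice taxa, averaged over loci.

    A cheap proxy for total tree length: slices of slowly evolving,
    mutually similar species show lower divergence.
    """
    per_locus = []
    for locus in sl.loci:
        present = [dataset.get(t, locus) for t in sl.taxa]
        present = [c for c in present if c is not None]
        if len(present) < 2:
            continue
        info = dataset.registry[locus]
        aln = align_locus(present, coding=info.coding,
                          genetic_code_id=info.genetic_code_id, quick=quick)
        rows = [aln.rows[t] for t in sorted(aln.rows)]
        dists = []
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                shared = [
                    (a, b) for a, b in zip(rows[i], rows[j])
                    if a != _GAP and b != _GAP
                ]
                if shared:
                    dists.append(
                        sum(1 for a, b in shared if a != b) / len(shared))
        if dists:
            per_locus.append(sum(dists) / len(dists))
    if not per_locus:
        return 0.0
    return sum(per_locus) / len(per_locus)
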