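import hashlib
import random

import pytest

from conftest import make_random_dataset, make_random_tree, random_dna
from phyloslice.consensus import ConsensusSequence, Dataset
from phyloslice.registry import LocusRegistry
from phyloslice.slicing import (at_content, auto_select,
                                build_rate_alignments, global_at_means,
                                manual_select, score_least_bias,
                                score_most_chars, score_slowest_rate)

# ------------------------------------------------------------- oracles


def oracle_at(dna):
    counts = {b: dna.upper().count(b) for b in "ACGT"}
    denom = sum(counts.values())
    return None if denom == 0 else (counts["A"] + counts["T"]) / denom


def oracle_most_chars(ds, taxid, loci):
    return float(sum(len(ds.get(taxid, l).dna) if ds.get(taxid, l) else 0
                     for l in loci))


def oracle_global_means(ds, loci):
    means = {}
    for locus in loci:
        vals = [oracle_at(ds.get(t, locus).dna) for t in ds.taxa()
                if ds.get(t, locus)]
        vals = [v for v in vals if v is not None]
        if vals:
            means[locus] = sum(vals) / len(vals)
    return means


def oracle_least_bias(ds, taxid, loci, means):
    diffs = [abs(oracle_at(ds.get(taxid, l).dna) - means[l])
             for l in loci if ds.get(taxid, l) and l in means]
    return sum(diffs) / len(diffs) if diffs else None


def oracle_slowest_rate(ds, taxid, loci, level_node, tree, seed, alignments):
    """Independent recomputation using the documented seeding convention."""
    locus_scores = []
    for locus in loci:
        aln = alignments.get(locus)
        if aln is None or taxid not in aln.rows:
            continue
        pool = sorted(t for t in aln.rows
                      if t != taxid and not tree.is_descendant(t, level_node))
        if not pool:
            continue
        digest = hashlib.sha256(f"{seed}:{taxid}:{locus}".encode()).digest()
        rng = random.Random(int.from_bytes(digest[:4], "big"))
        comps = sorted(rng.sample(pool, 10)) if len(pool) > 10 else pool
        sims = []
        for comp in comps:
            cand, other = aln.rows[taxid], aln.rows[comp]
            sites = [(a, b) for a, b in zip(cand, other) if a != "-"]
            if sites:
                sims.append(sum(1 for a, b in sites if a == b) / len(sites))
        if sims:
            locus_scores.append(sum(sims) / len(sims))
    return (sum(locus_scores) / len(locus_scores)) if locus_scores else None


# ------------------------------------------------------------- at_content


class TestAtContent:
    @pytest.mark.parametrize("dna,expected", [
        ("ATAT", 1.0), ("ACGT", 0.5), ("NNAA", 1.0), ("GCGC", 0.0),
        ("acgt", 0.5),
    ])
    def test_known_values(self, dna, expected):
        assert at_content(dna) == pytest.approx(expected)

    def test_all_ambiguous_is_undefined(self):
        assert at_content("NNNN") is None

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            at_content("")


# ------------------------------------------------------------- criteria


def put(ds, taxid, locus, dna):
    ds.put(ConsensusSequence(taxid, locus, dna, 1, "single"))


def two_locus_dataset():
    reg = LocusRegistry()
    for locus in ("l1", "l2"):
        reg.add_locus(locus)
    return Dataset(reg)


class TestMostChars:
    def test_sums_lengths_over_selected_loci(self):
        ds = two_locus_dataset()
        put(ds, 1, "l1", "A" * 300)
        put(ds, 1, "l2", "A" * 450)
        assert score_most_chars(ds, 1, ["l1", "l2"]).score == 750

    def test_missing_everything_scores_zero(self):
        ds = two_locus_dataset()
        assert score_most_chars(ds, 1, ["l1", "l2"]).score == 0

    def test_fewer_loci_but_more_characters_outranks(self):
        ds = two_locus_dataset()
        put(ds, 1, "l1", "A" * 900)           # one locus, 900 chars
        put(ds, 2, "l1", "A" * 400)
        put(ds, 2, "l2", "A" * 400)           # two loci, 800 chars
        a = score_most_chars(ds, 1, ["l1", "l2"])
        b = score_most_chars(ds, 2, ["l1", "l2"])
        assert a.rank_key() < b.rank_key()


class TestLeastBias:
    def test_candidate_at_global_mean_scores_zero(self):
        ds = two_locus_dataset()
        put(ds, 1, "l1", "ATGC" * 30)  # AT 0.5
        put(ds, 2, "l1", "ATGC" * 30)
        means = global_at_means(ds, ["l1"])
        assert score_least_bias(ds, 1, ["l1"], means).score == 0.0

    def test_single_locus_deviation_is_absolute_difference(self):
        ds = two_locus_dataset()
        put(ds, 1, "l1", "AT" * 35 + "GC" * 15)   # AT 0.70
        put(ds, 2, "l1", "AT" * 15 + "GC" * 35)   # AT 0.30  -> mean 0.50
        means = global_at_means(ds, ["l1"])
        score = score_least_bias(ds, 1, ["l1"], means)
        assert score.score == pytest.approx(0.20)
        assert not score.higher_better

    def test_candidate_with_no_sequence_is_excluded(self):
        ds = two_locus_dataset()
        put(ds, 2, "l1", "ATGC")
        means = global_at_means(ds, ["l1"])
        assert score_least_bias(ds, 1, ["l1", "l2"], means) is None


class TestSlowestRate:
    def _dataset(self, rng, tree):
        ds = make_random_dataset(rng, tree, fill=1.0)
        return ds

    def test_identical_candidate_scores_one(self, ):
        tree = make_random_tree(random.Random(0), n_orders=2, n_families=1,
                                n_species=3)
        reg = LocusRegistry()
        reg.add_locus("l1")
        ds = Dataset(reg)
        for sp in tree.species():
            put(ds, sp, "l1", "ACGTAC" * 10)
        alns = build_rate_alignments(ds, ["l1"])
        score = score_slowest_rate(ds, tree.species()[0], ["l1"],
                                   tree.nodes[tree.species()[0]].parent,
                                   tree, seed=1, alignments=alns)
        assert score.score == pytest.approx(1.0)

    def test_totally_dissimilar_candidate_scores_zero(self):
        tree = make_random_tree(random.Random(0), n_orders=2, n_families=1,
                                n_species=2)
        reg = LocusRegistry()
        reg.add_locus("l1")
        ds = Dataset(reg)
        species = tree.species()
        for sp in species[:-1]:
            put(ds, sp, "l1", "A" * 30)
        put(ds, species[-1], "l1", "C" * 30)
        alns = build_rate_alignments(ds, ["l1"])
        level = tree.nodes[tree.nodes[species[-1]].parent].parent
        score = score_slowest_rate(ds, species[-1], ["l1"], level, tree,
                                   seed=1, alignments=alns)
        assert score.score == pytest.approx(0.0)

    def test_candidate_with_no_pool_is_excluded(self):
        tree = make_random_tree(random.Random(0), n_orders=1, n_families=1,
                                n_species=3)
        reg = LocusRegistry()
        reg.add_locus("l1")
        ds = Dataset(reg)
        for sp in tree.species():
            put(ds, sp, "l1", "ACGT" * 10)
        alns = build_rate_alignments(ds, ["l1"])
        # level node = the single order: nobody is outside it
        assert score_slowest_rate(ds, tree.species()[0], ["l1"], 100, tree,
                                  seed=1, alignments=alns) is None

    def test_matches_independent_recomputation_with_same_seed(self):
        rng = random.Random(12)
        tree = make_random_tree(rng, n_orders=2, n_families=2, n_species=2)
        ds = self._dataset(rng, tree)
        loci = ds.registry.locus_names
        alns = build_rate_alignments(ds, loci)
        for seed in (0, 7):
            for sp in tree.species():
                order = tree.nodes[tree.nodes[sp].parent].parent
                got = score_slowest_rate(ds, sp, loci, order, tree, seed,
                                         alns)
                want = oracle_slowest_rate(ds, sp, loci, order, tree, seed,
                                           alns)
                if want is None:
                    assert got is None
                else:
                    assert got.score == pytest.approx(want)


class TestOracleEquivalence:
    def test_rankings_match_brute_force_on_random_datasets(self):
        rng = random.Random(99)
        for _ in range(20):
            tree = make_random_tree(rng, n_orders=2, n_families=2,
                                    n_species=2)
            ds = make_random_dataset(rng, tree,
                                     loci=("a", "b", "c")[:rng.randint(2, 3)])
            loci = ds.registry.locus_names
            means = global_at_means(ds, loci)
            oracle_means = oracle_global_means(ds, loci)
            assert means == pytest.approx(oracle_means)
            for sp in tree.species():
                assert score_most_chars(ds, sp, loci).score == \
                    oracle_most_chars(ds, sp, loci)
                got = score_least_bias(ds, sp, loci, means)
                want = oracle_least_bias(ds, sp, loci, oracle_means)
                if want is None:
                    assert got is None
                else:
                    assert got.score == pytest.approx(want)


# ------------------------------------------------------------- selection


class TestAutoSelect:
    def _fixture(self):
        rng = random.Random(21)
        tree = make_random_tree(rng, n_orders=2, n_families=2, n_species=2)
        ds = make_random_dataset(rng, tree, fill=0.9)
        return tree, ds

    def test_most_chars_picks_the_max_character_species_per_order(self):
        tree, ds = self._fixture()
        loci = ds.registry.locus_names
        sl = auto_select(ds, tree, [1], "order", 1, loci, "most_chars")
        assert len(sl.taxa) == 2
        for order in (100, 200):
            cands = tree.candidate_species(order)
            best = max(cands,
                       key=lambda t: (oracle_most_chars(ds, t, loci), -t))
            winner = [t for t in sl.taxa if t in cands]
            assert winner == [best]

    def test_small_group_includes_everyone_without_error(self):
        tree, ds = self._fixture()
        sl = auto_select(ds, tree, [1], "order", 5,
                         ds.registry.locus_names, "most_chars")
        rankable = [t for t in tree.species()
                    if True]  # most_chars ranks everyone
        assert sl.taxa == sorted(rankable)

    def test_at_shifted_species_never_chosen_under_least_bias(self):
        rng = random.Random(31)
        tree = make_random_tree(rng, n_orders=2, n_families=1, n_species=3)
        reg = LocusRegistry()
        reg.add_locus("l1")
        ds = Dataset(reg)
        for sp in tree.species():
            shifted = sp in (111, 211)  # one planted outlier per order
            dna = ("AT" * 30) if shifted else ("ATGC" * 15)
            put(ds, sp, "l1", dna)
        sl = auto_select(ds, tree, [1], "order", 1, ["l1"], "least_bias")
        assert not set(sl.taxa) & {111, 211}

    def test_deterministic_and_seed_sensitivity(self):
        tree, ds = self._fixture()
        loci = ds.registry.locus_names
        for crit in ("most_chars", "least_bias"):
            a = auto_select(ds, tree, [1], "order", 1, loci, crit, seed=1)
            b = auto_select(ds, tree, [1], "order", 1, loci, crit, seed=2)
            assert a.taxa == b.taxa  # no randomness in these criteria
        a = auto_select(ds, tree, [1], "order", 1, loci, "slowest_rate",
                        seed=3)
        b = auto_select(ds, tree, [1], "order", 1, loci, "slowest_rate",
                        seed=3)
        assert a.taxa == b.taxa  # same seed, same slice

    def test_outgroup_added_verbatim(self):
        tree, ds = self._fixture()
        sl = auto_select(ds, tree, [100], "order", 1,
                         ds.registry.locus_names, "most_chars",
                         extra_taxa=[221])
        assert 221 in sl.taxa

    def test_empty_slice_is_an_error(self):
        tree, _ = self._fixture()
        reg = LocusRegistry()
        reg.add_locus("l1")
        empty = Dataset(reg)
        with pytest.raises(ValueError, match="empty slice"):
            auto_select(empty, tree, [1], "order", 1, ["l1"], "least_bias")

    def test_unknown_criterion_rejected(self):
        tree, ds = self._fixture()
        with pytest.raises(ValueError, match="criterion"):
            auto_select(ds, tree, [1], "order", 1,
                        ds.registry.locus_names, "fanciest")


class TestManualSelect:
    def test_higher_group_expands_to_descendant_species(self, toy_tree):
        reg = LocusRegistry()
        reg.add_locus("l1")
        ds = Dataset(reg)
        sl = manual_select(ds, toy_tree, [10], ["l1"])
        assert sl.taxa == [111, 112, 121]

    def test_single_species_is_a_singleton(self, toy_tree):
        reg = LocusRegistry()
        reg.add_locus("l1")
        sl = manual_select(Dataset(reg), toy_tree, [111], ["l1"])
        assert sl.taxa == [111]

    def test_overlapping_choices_union_without_duplicates(self, toy_tree):
        reg = LocusRegistry()
        reg.add_locus("l1")
        sl = manual_select(Dataset(reg), toy_tree, [10, 11, 111, 211],
                           ["l1"])
        assert sl.taxa == [111, 112, 121, 211]

    def test_unknown_taxid_is_not_found(self, toy_tree):
        reg = LocusRegistry()
        reg.add_locus("l1")
        with pytest.raises(KeyError):
            manual_select(Dataset(reg), toy_tree, [999], ["l1"])
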