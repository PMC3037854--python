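# Methods

This note documents the models, conventions and numerical choices behind
phyloslice, in the order of the workflow.

## Name resolution

Gene names are normalized by trimming surrounding whitespace, case
folding, and collapsing internal whitespace runs, then matched exactly
against the registry's synonym sets. Synonym sets of distinct loci must
be disjoint after normalization; a shared synonym is rejected at load
time naming both loci. There is deliberately no fuzzy matching: a record
whose annotation does not resolve is routed through similarity search
instead, which is the correct tool for genuinely unlabelled sequence.

## Taxonomy

The taxonomy is a rooted tree keyed by numeric taxid, loadable from
NCBI-dump style `nodes.dmp`/`names.dmp` tables or a one-file CSV. Edits
(create/rename/move) preserve connectivity and acyclicity, verified by
full traversal. User-created nodes receive negative taxids allocated
downward from −1 so they can never collide with public identifiers. Rank
labels compare case-insensitively and `no rank` nodes are never level
nodes. All orderings are taxid-ascending; reproducibility everywhere in
the package rests on total orders like this one.

A selected node whose own rank equals the requested level counts as a
level node of itself, and a species is its own candidate representative.
The alternative (strict descendants only) silently empties selections
rooted at the level of interest.

## Sequence import and similarity assignment

GenBank gene/CDS/rRNA features are spliced and reverse-complemented to
coding orientation via Biopython; `gene` features shadowed by a CDS/rRNA
for the same gene are skipped so one gene yields one record. A record is
*genome-derived* when its description matches (case-insensitively) one of
`complete genome`, `whole genome shotgun`, `chromosome`; it is
*full-length* when a CDS carries no partial-position markers.
Trans-spliced joins (mixed strands in one location) are rejected with a
per-feature report entry; every feature ends up either accepted or in the
rejection report.

Unannotated records are assigned by local alignment against the annotated
set (exact duplicates removed): protein-level with BLOSUM62 and affine
gaps (open −11, extend −1) for coding loci, using the best of six reading
frames when the query frame is unknown; nucleotide-level (+1/−2, open −5,
extend −2, both strands) for RNA loci. Because loci evolve at different
rates, the acceptance threshold is calibrated per locus as the score
between that locus's sequences in two reference species chosen to be more
divergent than any in-group pair — an in-group homolog then scores at
least as high. A locus missing either reference falls back to a
configurable default threshold with a warning. A record is assigned the
locus of its best hit iff that score reaches the locus threshold; ties
break by score then lowest subject accession. Consequence worth knowing:
a short fragment cannot always reach a threshold calibrated on
full-length references, so very short queries may be left over even when
genuinely homologous — mirroring the conservative behaviour wanted when
screening bulk archives. An external BLAST+ can replace the internal
scorer, in which case cutoffs must be recomputed with the same engine.

## Consensus precedence and assembly

For each (species, locus) cell, precedence is total and checked in
order: (1) any genome-derived record → longest such wins; (2) exactly one
annotated record → it wins over any number of similarity-identified ones;
(3) one record total → itself; (4) otherwise *all* available records
(including multiple annotated ones) are assembled and the longest contig
is the consensus, ties going to the lexicographically smallest. Falling
through to assembly when two or more annotated records exist is a
deliberate reading of the precedence rules: the single-annotated
exception is about trusting one curated record over noisy similarity
hits, not about avoiding assembly per se.

The internal assembler merges greedily by the longest approximate
suffix–prefix overlap: minimum overlap 40 bases (configurable), at least
95 % identity within the overlap (mismatch budget ⌊0.05·L⌋),
disagreements resolved from the longer contig, containments absorbed.
Fragments are canonicalised (length-descending, then lexicographic)
before merging, making the result invariant under input permutation.
Error-free tiled fragments of a gene reconstruct it exactly whenever
adjacent overlaps meet the minimum — the identity the generator's
fragmentation parameters are chosen to satisfy. An external assembler
(e.g. CAP3) can be plugged in via the `engine` hook where indel-tolerant
assembly is needed; the internal merger does not model indels.

## Selection criteria

AT content is (A+T)/(A+C+G+T), case-insensitive, ambiguity codes excluded
from both numerator and denominator; a sequence with no unambiguous base
has undefined AT content. The per-locus *global mean* AT is averaged per
species (one value per consensus, unweighted by length) so deeply
sequenced species cannot drag the mean.

`least_bias` and `slowest_rate` average over the loci a candidate
actually possesses. Penalizing absences would conflate these criteria
with `most_chars`, which already measures quantity. A candidate with no
scorable locus is excluded — skipped, with the next-ranked candidate
taking its place — rather than ranked worst.

For `slowest_rate`, one rapid alignment per locus is built across all
species possessing it (quick mode, see below). Per candidate and locus,
up to 10 comparator species are drawn uniformly without replacement from
the pool outside the candidate's level node; similarity to a comparator
is the fraction of the candidate's non-gap alignment columns the
comparator matches exactly (candidate gaps excluded from the
denominator, comparator gaps count as mismatch). Sampling is seeded per
(run seed, candidate taxid, locus) through SHA-256, so runs are exactly
reproducible cross-platform and recorded in the slice's `selection_spec`.
Changing the seed can change `slowest_rate` selections but never
`most_chars`/`least_bias`, which are deterministic.

## Alignment protocol

Per locus: full-length coding sequences with clean translations are
translated (terminal stop stripped; an internal stop demotes the record
to stage 2 with a warning), protein-aligned, and back-aligned so each
protein gap becomes a 3-base DNA gap. Remaining sequences are
profile-added one at a time; existing rows change only by insertion of
columns gapped in all of them, so stage-1 homology statements survive.
With no full-length sequences the locus is aligned at the DNA level
directly. Degapping any row reproduces that taxon's consensus exactly,
except that stage-1 rows drop the stripped terminal stop — the round-trip
contract is defined on the stop-stripped sequence.

The internal engine is a progressive profile–profile aligner: pairwise
similarities → greedy joining of the closest clusters → affine-gap Gotoh
alignment of column-frequency profiles under expected sum-of-pairs score
(BLOSUM62 for protein, +5/−4 with neutral N for DNA; gap open −10,
extend −0.5 protein / −1 DNA). `quick=True` estimates the guide order
from k-mer similarity (k=3 protein, k=5 DNA) instead of full pairwise
alignment scores; it is used for rate scoring where many alignments are
built per selection run. An external aligner (MUSCLE/MAFFT) can replace
the engine for production fidelity; the two-stage protocol is
engine-agnostic.

## Export

Locus alignments are concatenated in slice order; a taxon missing a
locus gets that span filled with `?` (missing), distinct from `-`
(alignment gap). Charsets use 1-based inclusive NEXUS coordinates with
`\3` codon stepping, and codon-position charsets are emitted only for
loci whose every row is frame-known coding sequence (any stage-2 partial
disables them — their frames are unknown). The matrix is labelled by
taxid, matching the leaf-naming convention used for tree annotation, and
a `mrbayes` block declares one partition per locus. Written files
round-trip through an independent NEXUS parser (dendropy) in the test
suite.

## Synthetic data generator

The generator is first-class, tested code; its defaults define the study
conditions used throughout the tests. A taxonomy of 4 orders × 2
families × 3 species plus a deeply divergent single-species outgroup;
3 coding loci of 300 bp (ribosomal-protein scale, matching the
three-gene analyses the criteria were designed for); 0.02 substitutions
per site per branch; per-cell drop probability 0.15; of the emitted
cells, 30 % are genuinely partial single fragments (150–240 bp), 35 %
are tiled overlapping fragments (overlap ≥ 60, reassemblable), the rest
full-length; 10 % of records lose or alias their gene name. Sequences
evolve by per-site substitution down the tree, rejecting in-frame stop
codons. Planted *fast* species multiply their terminal branch rate by 3;
planted *biased* species receive AT-directed substitution (target base
drawn from {A, T} with probability 0.9) under a 10× terminal load —
compositional outliers are long-branched too, which is both the
biological expectation and what makes a single planting provide bias and
rate heterogeneity at once. Planted species are emitted data-dense
(never missing, never fragmented), modelling genome-backed outlier taxa;
this is what lets quantity-greedy selection be drawn toward them. The
bias-recovery fixtures raise the planted load to 15× so the planted
condition (≥ 50 substitutions per locus) holds with margin over sampling
noise. Two reference species (the first in-group species and the
outgroup) are emitted as genome-derived GenBank records and anchor the
similarity cutoffs.

What the generator does not model: indels (so the assembler's exact
tiling assumption always holds on synthetic data), rate variation among
sites, codon usage, chimeric or contaminant sequences, and sequencing
error. Passing tests therefore demonstrate the correctness of the
bookkeeping and the discriminative logic of the criteria under planted
signal, not robustness to misassembly or alignment error on real data.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale by design: tens of
species, loci of hundreds of bases, 10–200 replicates per property.
Every stochastic step (generation, comparator sampling) flows from an
explicit integer seed; the full simulate→import→consensus→slice→align→
export chain is byte-deterministic given one seed, and the plain-file
project store writes sorted output so a reloaded store reproduces its
files exactly.

## Known limitations

Amino-acid input data is out of scope (DNA in, protein used internally
only). Orthology is assumed, not inferred — annotation or upstream
orthology tools must be trusted. The internal assembler and aligner
favour determinism and zero dependencies over sensitivity; plug in CAP3
or MUSCLE/MAFFT equivalents for production work on real, indel-bearing
data. The `least_bias` criterion ignores how variable each locus's
composition is dataset-wide (weighting low-variance loci more would
sharpen it), and missing-data handling within criteria remains a
composite-score opportunity rather than a solved problem.
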