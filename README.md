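# phyloslice

Supermatrix assembly and bias-aware taxon selection for multi-gene
phylogenetics.

Large multi-gene, multi-taxon DNA datasets resolve deep phylogenies, but
their accuracy is limited less by data volume than by *systematic bias*:
lineages with unusual base composition or accelerated evolutionary rates
actively mislead reconstruction (long-branch attraction, compositional
attraction), and support for wrong relationships grows with more data.
One defence is explicit taxon choice — assemble the dataset for *all*
available species, then pick, for each taxonomic group, the
representative least likely to distort the analysis.

phyloslice is a headless workbench for that workflow, aimed at molecular
systematists. It covers:

- **Locus registries** — curated gene lists with synonym sets; free-text
  annotation resolves to canonical loci (`load_synonyms_csv`, `resolve`).
- **Editable taxonomies** — NCBI-style trees keyed by numeric taxid, with
  create/rename/move edits and operational groups (negative taxids).
- **Sequence import** — GenBank flat files (plain or gzipped) and tagged
  FASTA (`>acc locus=<name> taxid=<int>`), screened against the taxa of
  interest. Unannotated sequences (ESTs) are assigned by local-alignment
  search against the annotated set, with a per-locus score cutoff
  calibrated from two reference species.
- **Consensus building** — per (species, locus) cell: genome-derived
  records take precedence, a single annotated record beats any number of
  similarity-identified ones, otherwise fragments are assembled by greedy
  overlap merging and the longest contig wins.
- **Slices** — subsets of taxa × loci, picked manually or automatically:
  one representative per level node (e.g. per order) ranked by

  | criterion | score | direction |
  |---|---|---|
  | `most_chars` | Σ consensus lengths over selected loci | higher better |
  | `least_bias` | mean over loci of \|AT<sub>sp,locus</sub> − AT̄<sub>locus</sub>\| | lower better |
  | `slowest_rate` | mean exact-match similarity to 10 random species outside the level node | higher better |

- **Two-stage alignment** — full-length coding sequences are translated,
  protein-aligned, and back-aligned to DNA (each protein gap becomes a
  3-base gap); partial sequences are then profile-added without
  disturbing the stage-1 columns.
- **Export** — concatenated NEXUS supermatrix with per-locus charsets and
  per-codon-position charsets where frames are known, a
  MrBayes-compatible partition block, iTOL bar-chart/heat-map annotation
  files, and taxid→scientific-name relabelling of Newick/NEXUS/PhyloXML
  trees.
- **Synthetic data** — a seeded generator that evolves coding loci down a
  toy taxonomy with planted AT-pressured and fast lineages, patchy
  occupancy, fragmentation and annotation noise, emitting the exact file
  formats the importer consumes plus truth tables.

## Worked example

```bash
python examples/pick_representatives.py
```

builds a 25-species × 3-locus dataset with one planted AT-biased,
long-branched species per order and selects one representative per order
under each criterion:

```
most_chars    taxa=[111, 212, 321, 421] planted-outliers-included=2
              mean per-locus AT SD=0.0525  mean pairwise divergence=0.2546
least_bias    taxa=[122, 221, 313, 411] planted-outliers-included=0
              mean per-locus AT SD=0.0054  mean pairwise divergence=0.0932
slowest_rate  taxa=[112, 222, 313, 412] planted-outliers-included=0
              mean per-locus AT SD=0.0190  mean pairwise divergence=0.0971
```

The quantity-greedy slice absorbs the data-rich outliers and shows the
highest AT spread and the longest implied tree; the composition- and
rate-aware slices avoid them — the trade-off the criteria exist to
manage. `examples/assemble_dataset.py` shows file-level assembly with
similarity cutoffs, and `examples/export_supermatrix.py` the alignment,
NEXUS export and tree annotation steps.

The same workflow is scriptable from a shell via the thin CLI:

```bash
phyloslice --project demo loci load loci.csv
phyloslice --project demo tax load taxonomy.csv
phyloslice --project demo import fasta sequences.fsa --refs 111,92
phyloslice --project demo consensus
phyloslice --project demo slice auto --name reps --level order --n 1 \
    --criterion least_bias --loci loc1,loc2,loc3 --seed 42
phyloslice --project demo export nexus reps
```

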