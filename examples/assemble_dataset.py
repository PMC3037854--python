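"""Assemble a multi-gene dataset from sequence files.

Generates a small synthetic study (25 species, 3 coding loci, patchy
EST-like coverage), imports the GenBank reference records and tagged
FASTA sequences, calibrates per-locus similarity cutoffs from the two
reference species, assigns unannotated records by similarity, and builds
the species x locus consensus grid.
"""

import warnings

from phyloslice import SimulationSpec, assemble_dataset, occupancy, simulate
from phyloslice.simulate import truth_check

result = simulate(SimulationSpec(seed=42, biased_per_order=1), "scratch/example_sim")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    asm = assemble_dataset(
        result.registry, result.tree,
        genbank_paths=[result.genbank],
        fasta_paths=[result.fasta],
        ref_taxa=(result.ref_a, result.ref_b),
    )

print(f"records gathered:      {asm.n_gathered}")
print(f"similarity leftovers:  {len(asm.leftovers)}")
print(f"consensus cells:       {len(asm.dataset)}")
if asm.cutoffs is not None:
    print("per-locus cutoff scores:",
          {k: round(v) for k, v in asm.cutoffs.thresholds.items()})
else:
    print("per-locus cutoffs: not needed (every record carried annotation)")

occ = occupancy(asm.dataset)
print("\noccupancy matrix (consensus lengths, ordered by total characters):")
print(occ.head(8).to_string())

report = truth_check(asm.dataset, result)
print(f"\ncells recovered exactly vs. simulation truth: "
      f"{report.exact}/{report.exact + report.mismatch + report.missing} "
      f"({100 * report.recovery_rate:.1f}%)")
print("(mismatches arise when annotation noise leaves a lone annotated "
      "fragment that outranks its similarity-routed siblings)")
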