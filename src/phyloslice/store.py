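"""Plain-file project persistence.

A project is one directory of text files — locus CSV, taxonomy CSV,
imported records and the consensus grid as tagged FASTA, slices as JSON —
so a dataset plus its slices can be shared as a portable archive and
scripted against directly.  All writers emit sorted, deterministic output:
reloading a store reproduces the identical dataset byte for byte.
"""

from __future__ import annotations

import re
from pathlib import Path

from .consensus import ConsensusSequence, Dataset
from .records import SequenceRecord
from .registry import LocusRegistry, load_synonyms_csv
from .slicing import Slice
from .taxonomy import TaxonomyTree, load_taxonomy_csv

__all__ = ["ProjectStore"]

_TAG = re.compile(r"(\w+)=(\S+)")


class ProjectStore:
    def __init__(self, root):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        (self.root / "slices").mkdir(exist_ok=True)

    # ---- registry ----------------------------------------------------

    @property
    def registry_path(self) -> Path:
        return self.root / "loci.csv"

    def save_registry(self, registry: LocusRegistry) -> None:
        registry.save_csv(self.registry_path)

    def load_registry(self) -> LocusRegistry:
        return load_synonyms_csv(self.registry_path)

    # ---- taxonomy ----------------------------------------------------

    @property
    def taxonomy_path(self) -> Path:
        return self.root / "taxonomy.csv"

    def save_taxonomy(self, tree: TaxonomyTree) -> None:
        tree.save_csv(self.taxonomy_path)

    def load_taxonomy(self) -> TaxonomyTree:
        return load_taxonomy_csv(self.taxonomy_path)

    # ---- records -----------------------------------------------------

    @property
    def records_path(self) -> Path:
        return self.root / "records.fsa"

    def save_records(self, records) -> None:
        with open(self.records_path, "w") as fh:
            for rec in sorted(records, key=lambda r: r.accession):
                tags = (
                    f"taxid={rec.taxid} locus={rec.locus or '.'} "
                    f"provenance={rec.provenance} "
                    f"full_length={str(rec.full_length).lower()} "
                    f"frame_known={str(rec.frame_known).lower()} "
                    f"genetic_code={rec.genetic_code_id}"
                )
                fh.write(f">{rec.accession} {tags}\n{rec.dna}\n")

    def load_records(self) -> list[SequenceRecord]:
        records = []
        with open(self.records_path) as fh:
            header = None
            seq_lines: list[str] = []
            for line in list(fh) + [">"]:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    if header is not None:
                        acc = header.split()[0]
                        tags = dict(_TAG.findall(header))
                        locus = tags.get("locus")
                        records.append(SequenceRecord(
                            accession=acc,
                            taxid=int(tags["taxid"]),
                            dna="".join(seq_lines),
                            locus=None if locus in (None, ".") else locus,
                            provenance=tags.get("provenance", "annotated"),
                            full_length=tags.get("full_length") == "true",
                            frame_known=tags.get("frame_known") == "true",
                            genetic_code_id=int(tags.get("genetic_code", 1)),
                        ))
                    header = line[1:]
                    seq_lines = []
                else:
                    seq_lines.append(line.strip())
        return records

    # ---- dataset -----------------------------------------------------

    @property
    def dataset_path(self) -> Path:
        return self.root / "consensus.fsa"

    def save_dataset(self, dataset: Dataset) -> None:
        with open(self.dataset_path, "w") as fh:
            for key in sorted(dataset.grid):
                cons = dataset.grid[key]
                fh.write(
                    f">{cons.taxid}|{cons.locus} method={cons.method} "
                    f"n_input={cons.n_input} "
                    f"full_length={str(cons.full_length).lower()}\n"
                    f"{cons.dna}\n"
                )

    def load_dataset(self, registry: LocusRegistry,
                     taxonomy_label: str = "taxonomy") -> Dataset:
        dataset = Dataset(registry, taxonomy_label)
        if not self.dataset_path.exists():
            return dataset
        with open(self.dataset_path) as fh:
            header = None
            seq_lines: list[str] = []
            for line in list(fh) + [">"]:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    if header is not None:
                        key = header.split()[0]
                        taxid_s, locus = key.split("|", 1)
                        tags = dict(_TAG.findall(header))
                        dataset.put(ConsensusSequence(
                            taxid=int(taxid_s),
                            locus=locus,
                            dna="".join(seq_lines),
                            n_input=int(tags.get("n_input", 1)),
                            method=tags.get("method", "single"),
                            full_length=tags.get("full_length") == "true",
                        ))
                    header = line[1:]
                    seq_lines = []
                else:
                    seq_lines.append(line.strip())
        return dataset

    # ---- slices ------------------------------------------------------

    def save_slice(self, sl: Slice) -> None:
        (self.root / "slices" / f"{sl.name}.json").write_text(sl.to_json())

    def load_slice(self, name: str) -> Slice:
        return Slice.from_json(
            (self.root / "slices" / f"{name}.json").read_text())

    def list_slices(self) -> list[str]:
        return sorted(p.stem for p in (self.root / "slices").glob("*.json"))
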