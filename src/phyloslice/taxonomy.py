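"""Editable rooted taxonomy keyed by numeric taxon id.

The dataset is organised around a taxonomy (by default NCBI-style), which
users may edit: creating operational groups ("parasites"), renaming, and
moving subtrees.  User-created nodes receive negative taxids allocated
downward from -1 so they can never collide with NCBI identifiers.

Two input formats are supported: NCBI taxonomy-dump style ``nodes.dmp`` /
``names.dmp`` tables, and a simple one-file CSV
(``taxid,parent_taxid,rank,name``) convenient for small trees.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = ["TaxonNode", "TaxonomyTree", "load_taxonomy", "load_taxonomy_csv"]


@dataclass
class TaxonNode:
    taxid: int
    name: str
    rank: str
    parent: Optional[int] = None
    children: list[int] = field(default_factory=list)


class TaxonomyTree:
    """Rooted tree of :class:`TaxonNode` with edit and traversal support."""

    def __init__(self, label: str = "taxonomy"):
        self.label = label
        self.nodes: dict[int, TaxonNode] = {}
        self.root: Optional[int] = None
        self._next_user_taxid = -1

    # -- construction -------------------------------------------------

    def add_node(
        self, taxid: int, name: str, rank: str, parent: Optional[int]
    ) -> TaxonNode:
        if taxid in self.nodes:
            raise ValueError(f"duplicate taxid {taxid}")
        node = TaxonNode(taxid, name, rank, parent)
        self.nodes[taxid] = node
        if parent is None:
            if self.root is not None:
                raise ValueError("tree already has a root")
            self.root = taxid
        else:
            if parent not in self.nodes:
                raise ValueError(f"orphan node {taxid}: parent {parent} unknown")
            self.nodes[parent].children.append(taxid)
        return node

    def validate(self) -> None:
        """Check connectivity and acyclicity by full traversal from the root."""
        if self.root is None:
            raise ValueError("tree has no root")
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            taxid = stack.pop()
            if taxid in seen:
                raise ValueError(f"cycle detected at taxid {taxid}")
            seen.add(taxid)
            stack.extend(self.nodes[taxid].children)
        orphans = set(self.nodes) - seen
        if orphans:
            raise ValueError(
                "orphan nodes not reachable from root: "
                + ", ".join(str(t) for t in sorted(orphans))
            )
        for taxid, node in self.nodes.items():
            for child in node.children:
                if self.nodes[child].parent != taxid:
                    raise ValueError(f"inconsistent parent link at {child}")

    # -- queries ------------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def _require(self, taxid: int) -> TaxonNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise KeyError(f"taxid {taxid} not found in taxonomy") from None

    def scientific_name(self, taxid: int) -> str:
        return self._require(taxid).name

    def name_to_taxid(self) -> dict[str, int]:
        return {node.name: node.taxid for node in self.nodes.values()}

    def descendants(self, taxid: int, include_self: bool = True) -> list[int]:
        """All descendant taxids (preorder), optionally including the node."""
        self._require(taxid)
        out: list[int] = []
        stack = [taxid]
        while stack:
            t = stack.pop()
            if t != taxid or include_self:
                out.append(t)
            stack.extend(reversed(self.nodes[t].children))
        return out

    def ancestors(self, taxid: int) -> list[int]:
        """Ancestor chain from the node's parent up to the root."""
        node = self._require(taxid)
        chain = []
        while node.parent is not None:
            chain.append(node.parent)
            node = self.nodes[node.parent]
        return chain

    def is_descendant(self, taxid: int, of: int) -> bool:
        """True if ``taxid`` equals ``of`` or lies in its subtree."""
        return taxid == of or of in self.ancestors(taxid)

    def species(self) -> list[int]:
        return sorted(
            t for t, n in self.nodes.items() if n.rank.casefold() == "species"
        )

    def level_nodes(self, selected: Iterable[int], level: str) -> list[int]:
        """Every node of rank ``level`` descended from (or equal to) any
        selected node, deduplicated, taxid-ascending.

        Rank labels compare case-insensitively; "no rank" nodes never match.
        """
        level_cf = level.casefold()
        if level_cf == "no rank":
            return []
        found: set[int] = set()
        for sel in selected:
            for t in self.descendants(sel, include_self=True):
                if self.nodes[t].rank.casefold() == level_cf:
                    found.add(t)
        return sorted(found)

    def candidate_species(self, level_node: int) -> list[int]:
        """All species descended from (or equal to) a level node."""
        return sorted(
            t
            for t in self.descendants(level_node, include_self=True)
            if self.nodes[t].rank.casefold() == "species"
        )

    # -- edits --------------------------------------------------------

    def create_node(
        self, name: str, parent: int, rank: str = "no rank"
    ) -> TaxonNode:
        """Create a user node under ``parent``; taxids run -1, -2, ..."""
        self._require(parent)
        while self._next_user_taxid in self.nodes:
            self._next_user_taxid -= 1
        node = self.add_node(self._next_user_taxid, name, rank, parent)
        self._next_user_taxid -= 1
        return node

    def rename_node(self, taxid: int, name: str) -> None:
        self._require(taxid).name = name

    def move_node(self, taxid: int, new_parent: int) -> None:
        """Reparent ``taxid`` (and its whole subtree) under ``new_parent``."""
        node = self._require(taxid)
        self._require(new_parent)
        if node.parent is None:
            raise ValueError("cannot move the root")
        if self.is_descendant(new_parent, of=taxid):
            raise ValueError(
                f"cannot move {taxid} under its own descendant {new_parent}"
            )
        self.nodes[node.parent].children.remove(taxid)
        node.parent = new_parent
        self.nodes[new_parent].children.append(taxid)

    # -- serialization ------------------------------------------------

    def to_csv_rows(self) -> list[list[str]]:
        rows = []
        for taxid in sorted(self.nodes):
            n = self.nodes[taxid]
            parent = "" if n.parent is None else str(n.parent)
            rows.append([str(taxid), parent, n.rank, n.name])
        return rows

    def save_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["taxid", "parent_taxid", "rank", "name"])
            w.writerows(self.to_csv_rows())


def _build(rows: list[tuple[int, Optional[int], str, str]], label: str) -> TaxonomyTree:
    """Assemble a tree from (taxid, parent, rank, name) rows in any order."""
    tree = TaxonomyTree(label)
    pending = {taxid: (parent, rank, name) for taxid, parent, rank, name in rows}
    if len(pending) != len(rows):
        raise ValueError("duplicate taxids in input")
    roots = [t for t, (p, _, _) in pending.items() if p is None or p == t]
    if len(roots) != 1:
        raise ValueError(f"expected exactly one root, found {len(roots)}")
    # NCBI dumps make the root its own parent; normalise to parent=None
    root = roots[0]
    order = [root]
    children: dict[int, list[int]] = {}
    for t, (p, _, _) in pending.items():
        if t != root:
            children.setdefault(p, []).append(t)  # type: ignore[arg-type]
    stack = [root]
    seen = {root}
    while stack:
        t = stack.pop()
        for c in sorted(children.get(t, ())):
            order.append(c)
            seen.add(c)
            stack.append(c)
    orphans = sorted(set(pending) - seen)
    if orphans:
        raise ValueError(
            "orphan nodes (parent id absent or unreachable): "
            + ", ".join(str(t) for t in orphans)
        )
    for t in order:
        p, rank, name = pending[t]
        tree.add_node(t, name, rank, None if t == root else p)
    tree.validate()
    return tree


def load_taxonomy_csv(path, label: str = "taxonomy") -> TaxonomyTree:
    """Load the simple CSV format: ``taxid,parent_taxid,rank,name``.

    An empty parent field marks the root.  A header row is skipped if the
    first cell is not numeric.
    """
    rows: list[tuple[int, Optional[int], str, str]] = []
    with open(path, newline="") as fh:
        for cells in csv.reader(fh):
            if not cells or not cells[0].strip():
                continue
            try:
                taxid = int(cells[0])
            except ValueError:
                continue  # header
            parent = int(cells[1]) if len(cells) > 1 and cells[1].strip() else None
            rank = cells[2].strip() if len(cells) > 2 else "no rank"
            name = cells[3].strip() if len(cells) > 3 else str(taxid)
            rows.append((taxid, parent, rank, name))
    return _build(rows, label)


def load_taxonomy(nodes_path, names_path=None, label: str = "taxonomy") -> TaxonomyTree:
    """Load an NCBI taxonomy-dump style pair of tables.

    ``nodes_path`` rows: ``taxid | parent taxid | rank | ...`` separated by
    ``\\t|\\t`` (standard dump) — the root points to itself.  ``names_path``
    rows: ``taxid | name | unique name | name class``; the "scientific name"
    class is used.  If ``names_path`` is omitted, names default to taxids.
    """
    names: dict[int, str] = {}
    if names_path is not None:
        with open(names_path) as fh:
            for line in fh:
                parts = [p.strip() for p in line.rstrip("\t|\n").split("|")]
                if len(parts) >= 4 and parts[3] == "scientific name":
                    names[int(parts[0])] = parts[1]
                elif len(parts) >= 2 and int(parts[0]) not in names:
                    names[int(parts[0])] = parts[1]
    rows: list[tuple[int, Optional[int], str, str]] = []
    with open(nodes_path) as fh:
        for line in fh:
            parts = [p.strip() for p in line.rstrip("\t|\n").split("|")]
            if len(parts) < 3 or not parts[0]:
                continue
            taxid = int(parts[0])
            parent: Optional[int] = int(parts[1])
            rank = parts[2]
            rows.append((taxid, parent, rank, names.get(taxid, str(taxid))))
    return _build(rows, label)
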