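"""NCBI-taxdump parsing and rank trace-back.

The classifier assigns reads at species level only; accuracy at genus,
family, order, class and phylum is obtained by tracing each species taxid up
the taxonomy to its ancestor at the requested rank. This module parses the
standard NCBI dump dialect (nodes.dmp / names.dmp / merged.dmp: fields
delimited by "\\t|\\t", records terminated by "\\t|") and provides those
ancestor lookups.

delnodes.dmp (taxa deleted from NCBI) is intentionally ignored: deleted taxa
simply fail lookup as absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

__all__ = [
    "TaxonomyError",
    "TaxdumpFormatError",
    "UnknownTaxidError",
    "RANKS",
    "TaxonomyTree",
    "load_taxdump",
]

#: The six named ranks used for trace-back evaluation, species-first.
RANKS = ("species", "genus", "family", "order", "class", "phylum")


class TaxonomyError(Exception):
    """Base class for taxonomy failures."""


class TaxdumpFormatError(TaxonomyError):
    """Malformed dump file: cycles, dangling parents, bad fields."""


class UnknownTaxidError(TaxonomyError, KeyError):
    """Taxid not present in the tree (distinguishes absent vs merged-away)."""


def _split_dmp(line: str) -> list[str]:
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


@dataclass
class TaxonomyTree:
    """Taxid-indexed tree: each node stores (parent taxid, rank, name).

    ``merged`` maps retired taxids onto their current replacements, as in
    NCBI's merged.dmp.
    """

    nodes: dict[int, tuple[int, str, str]] = field(default_factory=dict)
    merged: dict[int, int] = field(default_factory=dict)
    root_taxid: int = 1

    def resolve(self, taxid: int) -> int:
        """Follow merged-id redirections to a live taxid."""
        seen = set()
        while taxid not in self.nodes:
            if taxid in seen or taxid not in self.merged:
                raise UnknownTaxidError(
                    f"taxid {taxid} is absent from the taxonomy"
                    + (" (merged chain has no live target)" if taxid in seen else "")
                )
            seen.add(taxid)
            taxid = self.merged[taxid]
        return taxid

    def parent(self, taxid: int) -> int:
        return self.nodes[self.resolve(taxid)][0]

    def rank(self, taxid: int) -> str:
        return self.nodes[self.resolve(taxid)][1]

    def name(self, taxid: int) -> str:
        return self.nodes[self.resolve(taxid)][2]

    def ancestor_at_rank(self, taxid: int, rank: str) -> Optional[int]:
        """First node of the given rank on the path from ``taxid`` to the root.

        A node queried at its own rank returns itself. Returns None when the
        chain reaches the root without encountering the rank (rank-sparse
        lineages are common in NCBI).
        """
        node = self.resolve(taxid)
        while True:
            parent, node_rank, _ = self.nodes[node]
            if node_rank == rank:
                return node
            if node == self.root_taxid:
                return None
            node = parent

    def species_of(self, taxid: int) -> Optional[int]:
        """Species-rank ancestor (itself if already species; None if above)."""
        return self.ancestor_at_rank(taxid, "species")

    def lineage(self, taxid: int) -> list[int]:
        """Path of taxids from the node up to and including the root."""
        node = self.resolve(taxid)
        chain = [node]
        while node != self.root_taxid:
            node = self.nodes[node][0]
            chain.append(node)
        return chain

    def validate(self) -> None:
        """Check parent links: no dangling parents, every chain hits the root."""
        for taxid, (parent, _, _) in self.nodes.items():
            if parent not in self.nodes:
                raise TaxdumpFormatError(
                    f"taxid {taxid} has parent {parent} absent from nodes"
                )
        # walk each chain with memoised "reaches root" marks
        ok: set[int] = {self.root_taxid}
        for taxid in self.nodes:
            path = []
            node = taxid
            while node not in ok:
                if node in path:
                    raise TaxdumpFormatError(f"cycle detected at taxid {node}")
                path.append(node)
                parent = self.nodes[node][0]
                if parent == node and node != self.root_taxid:
                    raise TaxdumpFormatError(f"cycle detected at taxid {node}")
                node = parent
            ok.update(path)
        for old, new in self.merged.items():
            try:
                self.resolve(new)
            except UnknownTaxidError as exc:
                raise TaxdumpFormatError(
                    f"merged taxid {old} points at unresolvable {new}"
                ) from exc


def load_taxdump(
    nodes_path: str | Path,
    names_path: str | Path,
    merged_path: str | Path | None = None,
) -> TaxonomyTree:
    """Parse NCBI-format nodes.dmp / names.dmp (and optionally merged.dmp).

    Only names of class "scientific name" are retained. The returned tree is
    validated: a cycle or a parent referencing a missing taxid raises
    :class:`TaxdumpFormatError` naming the offending taxid.
    """
    names: dict[int, str] = {}
    for line in Path(names_path).read_text().splitlines():
        if not line.strip():
            continue
        fields = _split_dmp(line)
        if len(fields) < 4:
            raise TaxdumpFormatError(f"names.dmp: malformed record {line!r}")
        if fields[3] == "scientific name":
            names[int(fields[0])] = fields[1]

    tree = TaxonomyTree()
    root: Optional[int] = None
    for line in Path(nodes_path).read_text().splitlines():
        if not line.strip():
            continue
        fields = _split_dmp(line)
        if len(fields) < 3:
            raise TaxdumpFormatError(f"nodes.dmp: malformed record {line!r}")
        taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
        tree.nodes[taxid] = (parent, rank, names.get(taxid, str(taxid)))
        if taxid == parent:
            if root is not None and root != taxid:
                raise TaxdumpFormatError(
                    f"multiple self-parenting roots: {root} and {taxid}"
                )
            root = taxid
    if root is None:
        raise TaxdumpFormatError("nodes.dmp has no self-parenting root node")
    tree.root_taxid = root

    if merged_path is not None:
        for line in Path(merged_path).read_text().splitlines():
            if not line.strip():
                continue
            fields = _split_dmp(line)
            if len(fields) < 2:
                raise TaxdumpFormatError(f"merged.dmp: malformed record {line!r}")
            tree.merged[int(fields[0])] = int(fields[1])

    tree.validate()
    return tree
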