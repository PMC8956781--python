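"""Taxonomy tree with lineage, rank-projection and lowest-common-ancestor queries.

The tree is a simplified NCBI-style hierarchy: every node has a parent
(the root is its own parent) and a rank label from a closed set.  Nodes
with rank ``no_rank`` are transparent to rank projection — they are
traversed but never returned for a named-rank query.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

RANKS = frozenset(
    {"root", "domain", "phylum", "class", "order", "family", "genus", "species", "no_rank"}
)


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy table (cycle, orphan, duplicate)."""


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    parent_id: str
    rank: str
    name: str

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise TaxonomyError(f"unknown rank {self.rank!r} for taxon {self.taxon_id!r}")


class TaxonomyTree:
    """Rooted taxonomy over :class:`TaxonNode` records keyed by id.

    Construction validates the invariants: exactly one root (the node
    that is its own parent), every parent resolves, and the parent
    relation is acyclic.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[str, TaxonNode] = {}
        for node in nodes:
            if node.taxon_id in self.nodes:
                raise TaxonomyError(f"duplicate taxon_id {node.taxon_id!r}")
            self.nodes[node.taxon_id] = node
        roots = [n.taxon_id for n in self.nodes.values() if n.parent_id == n.taxon_id]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}: {roots}")
        self.root = roots[0]
        for node in self.nodes.values():
            if node.parent_id not in self.nodes:
                raise TaxonomyError(
                    f"taxon {node.taxon_id!r} has unknown parent {node.parent_id!r}"
                )
        self._check_acyclic()
        self._lineage_cache: dict[str, tuple[str, ...]] = {}

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done
        for start in self.nodes:
            if start in state:
                continue
            path = []
            cur = start
            while cur not in state and cur != self.root:
                state[cur] = 0
                path.append(cur)
                cur = self.nodes[cur].parent_id
                if state.get(cur) == 0:
                    raise TaxonomyError(f"cycle detected through taxon {cur!r}")
            for p in path:
                state[p] = 1
            state[self.root] = 1

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def _require(self, taxon_id: str) -> TaxonNode:
        try:
            return self.nodes[taxon_id]
        except KeyError:
            raise KeyError(f"unknown taxon_id {taxon_id!r}") from None

    def lineage(self, taxon_id: str) -> list[str]:
        """Root-to-node path of taxon ids (root first, ``taxon_id`` last)."""
        cached = self._lineage_cache.get(taxon_id)
        if cached is not None:
            return list(cached)
        self._require(taxon_id)
        path = []
        cur = taxon_id
        while cur != self.root:
            path.append(cur)
            cur = self.nodes[cur].parent_id
        path.append(self.root)
        path.reverse()
        self._lineage_cache[taxon_id] = tuple(path)
        return path

    def lca(self, taxa: Iterable[str]) -> str:
        """Deepest node lying on the root-path of every member of ``taxa``."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of an empty taxon set is undefined")
        paths = [self.lineage(t) for t in taxa]
        shortest = min(len(p) for p in paths)
        ancestor = self.root
        for depth in range(shortest):
            level = {p[depth] for p in paths}
            if len(level) != 1:
                break
            ancestor = level.pop()
        return ancestor

    def rank_ancestor(self, taxon_id: str, rank: str) -> str | None:
        """Ancestor-or-self of ``taxon_id`` carrying ``rank``, or ``None``.

        ``no_rank`` nodes are skipped; asking for rank ``no_rank`` is
        rejected because those nodes are by design unaddressable.
        """
        if rank not in RANKS or rank == "no_rank":
            raise ValueError(f"cannot project onto rank {rank!r}")
        self._require(taxon_id)
        for tid in reversed(self.lineage(taxon_id)):
            if self.nodes[tid].rank == rank:
                return tid
        return None

    def name(self, taxon_id: str) -> str:
        return self._require(taxon_id).name


def load_taxonomy(source: str | Path | io.TextIOBase) -> TaxonomyTree:
    """Read a 4-column taxonomy TSV (taxon_id, parent_id, rank, name).

    Lines beginning with ``#`` and blank lines are ignored.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            return load_taxonomy(fh)
    nodes = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise TaxonomyError(
                f"line {lineno}: expected 4 tab-separated columns, got {len(fields)}"
            )
        nodes.append(TaxonNode(*fields))
    return TaxonomyTree(nodes)


def write_taxonomy(tree_or_nodes: TaxonomyTree | Mapping[str, TaxonNode], path: str | Path) -> None:
    nodes = tree_or_nodes.nodes if isinstance(tree_or_nodes, TaxonomyTree) else tree_or_nodes
    with open(path, "wt", encoding="utf-8") as fh:
        for node in nodes.values():
            fh.write(f"{node.taxon_id}\t{node.parent_id}\t{node.rank}\t{node.name}\n")
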