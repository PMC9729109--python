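"""NCBI-dialect taxonomy handling and lowest-common-ancestor queries.

The taxonomy is a rooted tree of named, ranked nodes in the ``nodes.dmp`` /
``names.dmp`` dialect: pipe-delimited columns, the root being its own parent.
Taxonomic read assignment reduces every read's set of accepted alignment hits
to the deepest node ancestral to all of them (the LCA).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO


class TaxonomyFormatError(ValueError):
    """Raised when a taxonomy dump violates the tree invariants."""


@dataclass
class Taxonomy:
    """Rooted tree of taxonomic nodes.

    Attributes
    ----------
    parent : dict
        node id -> parent id; the root is its own parent.
    rank : dict
        node id -> rank label (e.g. ``species``, ``genus``, ``family``).
    name : dict
        node id -> scientific name.
    """

    parent: dict[int, int] = field(default_factory=dict)
    rank: dict[int, str] = field(default_factory=dict)
    name: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._depth_cache: dict[int, int] = {}

    def __contains__(self, node: int) -> bool:
        return node in self.parent

    def __len__(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        for n, p in self.parent.items():
            if n == p:
                return n
        raise TaxonomyFormatError("taxonomy has no root")

    def add_node(self, node: int, parent: int, rank: str, name: str) -> None:
        self.parent[node] = parent
        self.rank[node] = rank
        self.name[node] = name
        self._depth_cache.clear()

    def validate(self) -> None:
        """Check the tree invariants: one root, parents present, no cycles."""
        roots = [n for n, p in self.parent.items() if n == p]
        if len(roots) != 1:
            raise TaxonomyFormatError(
                f"expected exactly one root, found {len(roots)}: {roots[:5]}"
            )
        for n, p in self.parent.items():
            if p not in self.parent:
                raise TaxonomyFormatError(f"node {n} has dangling parent {p}")
        # cycle check by walking to the root from every node
        for n in self.parent:
            seen = set()
            cur = n
            while self.parent[cur] != cur:
                if cur in seen:
                    raise TaxonomyFormatError(f"cycle detected at node {cur}")
                seen.add(cur)
                cur = self.parent[cur]

    def depth(self, node: int) -> int:
        """Number of edges from *node* up to the root (root has depth 0)."""
        d = self._depth_cache.get(node)
        if d is not None:
            return d
        path = []
        cur = node
        while cur not in self._depth_cache and self.parent[cur] != cur:
            path.append(cur)
            cur = self.parent[cur]
        base = self._depth_cache.get(cur, 0)
        for i, n in enumerate(reversed(path), start=1):
            self._depth_cache[n] = base + i
        return self._depth_cache.get(node, 0)

    def lineage(self, node: int) -> list[int]:
        """Root-to-node path, inclusive."""
        if node not in self.parent:
            raise KeyError(f"unknown node {node}")
        path = [node]
        while self.parent[path[-1]] != path[-1]:
            path.append(self.parent[path[-1]])
        return path[::-1]

    def is_ancestor(self, anc: int, node: int) -> bool:
        """True if *anc* is an ancestor of *node* or the node itself."""
        cur = node
        while True:
            if cur == anc:
                return True
            if self.parent[cur] == cur:
                return False
            cur = self.parent[cur]

    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {n: [] for n in self.parent}
        for n, p in self.parent.items():
            if n != p:
                ch[p].append(n)
        return ch

    def postorder(self) -> list[int]:
        """Nodes ordered children-before-parents (for subtree aggregation)."""
        ch = self.children_map()
        order: list[int] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(ch[n])
        return order[::-1]


def lca_of_pair(taxonomy: Taxonomy, a: int, b: int) -> int:
    """LCA of two nodes by lifting the deeper node."""
    da, db = taxonomy.depth(a), taxonomy.depth(b)
    while da > db:
        a = taxonomy.parent[a]
        da -= 1
    while db > da:
        b = taxonomy.parent[b]
        db -= 1
    while a != b:
        a = taxonomy.parent[a]
        b = taxonomy.parent[b]
    return a


def lca_of_set(taxonomy: Taxonomy, nodes: Iterable[int]) -> int:
    """Deepest node that is an ancestor-or-self of every node in the set.

    Parameters
    ----------
    nodes : iterable of node ids
        Must be nonempty and all present in the taxonomy.
    """
    it = iter(set(nodes))
    try:
        acc = next(it)
    except StopIteration:
        raise ValueError("lca_of_set requires a nonempty node set") from None
    if acc not in taxonomy:
        raise KeyError(f"unknown node {acc}")
    for n in it:
        if n not in taxonomy:
            raise KeyError(f"unknown node {n}")
        acc = lca_of_pair(taxonomy, acc, n)
    return acc


def load_taxonomy(nodes_stream: TextIO | str, names_stream: TextIO | str) -> Taxonomy:
    """Parse nodes.dmp / names.dmp dialect streams into a :class:`Taxonomy`.

    Lines are pipe-delimited with whitespace padding:
    ``tax_id | parent tax_id | rank |`` for nodes and
    ``tax_id | name | unique name | name class |`` for names (only the
    ``scientific name`` class is used). Nodes without a scientific name get
    the placeholder ``node_<id>``.

    Raises
    ------
    TaxonomyFormatError
        On a dangling parent or a cycle, naming the offending node.
    """
    if isinstance(nodes_stream, str):
        nodes_stream = io.StringIO(nodes_stream)
    if isinstance(names_stream, str):
        names_stream = io.StringIO(names_stream)

    tax = Taxonomy()
    for line in nodes_stream:
        line = line.strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split("|")]
        if len(parts) < 3:
            raise TaxonomyFormatError(f"malformed nodes line: {line!r}")
        node, parent, rank = int(parts[0]), int(parts[1]), parts[2]
        tax.parent[node] = parent
        tax.rank[node] = rank

    for line in names_stream:
        line = line.strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split("|")]
        if len(parts) < 4:
            raise TaxonomyFormatError(f"malformed names line: {line!r}")
        node, name, _, name_class = int(parts[0]), parts[1], parts[2], parts[3]
        if name_class == "scientific name" and node in tax.parent:
            tax.name[node] = name

    for node in tax.parent:
        tax.name.setdefault(node, f"node_{node}")
        tax.rank.setdefault(node, "no rank")
    tax.validate()
    return tax


def write_taxonomy(taxonomy: Taxonomy, nodes_stream: TextIO, names_stream: TextIO) -> None:
    """Emit the taxonomy back in the dump dialect (round-trips with load)."""
    for node in sorted(taxonomy.parent):
        nodes_stream.write(
            f"{node}\t|\t{taxonomy.parent[node]}\t|\t{taxonomy.rank[node]}\t|\n"
        )
        names_stream.write(
            f"{node}\t|\t{taxonomy.name[node]}\t|\t\t|\tscientific name\t|\n"
        )
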