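"""The eight rooted-tree encodings of a decomposed secondary structure.

All eight trees contain the loop-stem relation: one vertex per loop, one edge
per stem, rooted at the opening region.  The remaining three structural
features are switched on per type:

====  =========  =========  ==========
type  loop size  stem size  loop group
====  =========  =========  ==========
1
2     x                     x
3                x
4     x          x          x
5     x
6     x          x
7                           x
8                x          x
====  =========  =========  ==========

Loop size is recorded as one unpaired-nucleotide leaf per unpaired position
(types 2, 4, 5, 6).  Stem size is recorded by expanding the edge of a stem of
s base pairs into a path of s-1 stem-region vertices (types 3, 4, 6, 8; a
lonely pair adds none).  Loop group is recorded with artificial group
vertices: internal in types 2 and 4 (one per loop group, holding that group's
unpaired leaves) and leaves in types 7 and 8 (one per loop group, sizes
dropped).  Type 1 is the classical loop-stem tree and type 6 the arc tree.

Children are unordered throughout: polynomials and canonical forms treat them
as multisets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .structures import RegionDecomposition

__all__ = ["RootedTree", "build_tree", "canonical_form", "TREE_TYPES"]

TREE_TYPES = (1, 2, 3, 4, 5, 6, 7, 8)

LOOP = "loop"
STEM_REGION = "stem_region"
UNPAIRED_LEAF = "unpaired_leaf"
ARTIFICIAL_GROUP = "artificial_group"

_LOOP_SIZE_TYPES = {2, 4, 5, 6}
_STEM_SIZE_TYPES = {3, 4, 6, 8}
_GROUP_INTERNAL_TYPES = {2, 4}
_GROUP_LEAF_TYPES = {7, 8}


@dataclass
class RootedTree:
    """A vertex-class-labelled rooted tree with unordered children.

    ``classes[v]`` is the vertex class of vertex ``v``; ``children[v]`` its
    child indices; vertex 0 is the root (the opening region).
    """

    classes: list[str] = field(default_factory=lambda: [LOOP])
    children: list[list[int]] = field(default_factory=lambda: [[]])
    tree_type: int = 1

    @property
    def root(self) -> int:
        return 0

    @property
    def n_vertices(self) -> int:
        return len(self.classes)

    @property
    def n_edges(self) -> int:
        return self.n_vertices - 1

    def add_vertex(self, parent: int, klass: str) -> int:
        v = len(self.classes)
        self.classes.append(klass)
        self.children.append([])
        self.children[parent].append(v)
        return v

    def leaves(self) -> list[int]:
        return [v for v in range(self.n_vertices) if not self.children[v]]

    def postorder(self) -> list[int]:
        """Vertices with every child before its parent (iterative; deep-safe)."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def contract(self, klass: str) -> "RootedTree":
        """Remove all vertices of one class, splicing children to grandparents.

        Internal vertices of ``klass`` are contracted onto their parent edge;
        leaf vertices of ``klass`` are deleted.  Relates the tree types:
        contracting unpaired leaves and artificial groups recovers type 1/3
        from type 2/4, etc.
        """
        keep_children: dict[int, list[int]] = {}

        def resolve(v: int) -> list[int]:
            out: list[int] = []
            for c in self.children[v]:
                if self.classes[c] == klass:
                    out.extend(resolve(c))
                else:
                    out.append(c)
            return out

        order = self.postorder()
        for v in order:
            keep_children[v] = resolve(v)
        kept = [v for v in range(self.n_vertices) if self.classes[v] != klass or v == self.root]
        remap = {v: i for i, v in enumerate(kept)}
        out = RootedTree(classes=[], children=[], tree_type=self.tree_type)
        out.classes = [self.classes[v] for v in kept]
        out.children = [[remap[c] for c in keep_children[v]] for v in kept]
        return out

    # -- exports ------------------------------------------------------------

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            label = f"{self.classes[v]}_{v}"
            if not self.children[v]:
                return label
            return "(" + ",".join(rec(c) for c in self.children[v]) + ")" + label

        return rec(self.root) + ";"

    def to_edge_tsv(self) -> str:
        lines = ["parent\tchild\tparent_class\tchild_class"]
        for v in range(self.n_vertices):
            for c in self.children[v]:
                lines.append(f"{v}\t{c}\t{self.classes[v]}\t{self.classes[c]}")
        return "\n".join(lines) + "\n"

    def to_dot(self) -> str:
        shape = {
            LOOP: "circle",
            STEM_REGION: "circle",
            UNPAIRED_LEAF: "point",
            ARTIFICIAL_GROUP: "square",
        }
        lines = ["digraph tree {"]
        for v in range(self.n_vertices):
            lines.append(f'  v{v} [label="" shape={shape[self.classes[v]]}];')
        for v in range(self.n_vertices):
            for c in self.children[v]:
                lines.append(f"  v{v} -> v{c};")
        lines.append("}")
        return "\n".join(lines) + "\n"


def build_tree(decomp: RegionDecomposition, tree_type: int) -> RootedTree:
    """Build the type ``tree_type`` rooted tree of a decomposition.

    The loop-stem skeleton is shared by all types; per-type decorations are
    applied on top.  Raises ``ValueError`` for an unknown type.
    """
    if tree_type not in TREE_TYPES:
        raise ValueError(f"unknown tree type {tree_type}; expected 1..8")

    t = RootedTree(classes=[], children=[], tree_type=tree_type)
    t.classes.append(LOOP)
    t.children.append([])
    loop_vertex = {0: 0}  # decomposition loop index -> tree vertex

    # Loop-stem skeleton, with optional stem-region path expansion.
    order = [0]
    seen = {0}
    queue = [0]
    while queue:
        lp = queue.pop(0)
        for s_idx in decomp.loops[lp].bounding_stems:
            stem = decomp.stems[s_idx]
            if stem.child_loop in seen or stem.parent_loop != lp:
                continue
            attach = loop_vertex[lp]
            if tree_type in _STEM_SIZE_TYPES:
                for _ in range(stem.n_stem_regions):
                    attach = t.add_vertex(attach, STEM_REGION)
            v = t.add_vertex(attach, LOOP)
            loop_vertex[stem.child_loop] = v
            seen.add(stem.child_loop)
            queue.append(stem.child_loop)
            order.append(stem.child_loop)

    for lp_idx, v in loop_vertex.items():
        lp = decomp.loops[lp_idx]
        if tree_type in _GROUP_INTERNAL_TYPES:
            for group in lp.groups:
                g = t.add_vertex(v, ARTIFICIAL_GROUP)
                for _ in group:
                    t.add_vertex(g, UNPAIRED_LEAF)
        elif tree_type in _GROUP_LEAF_TYPES:
            for _ in lp.groups:
                t.add_vertex(v, ARTIFICIAL_GROUP)
        elif tree_type in _LOOP_SIZE_TYPES:
            for _ in lp.unpaired_positions:
                t.add_vertex(v, UNPAIRED_LEAF)
    return t


def canonical_form(t: RootedTree) -> str:
    """AHU-style canonical encoding incorporating vertex classes.

    Two trees get equal strings iff they are isomorphic as rooted trees with
    matching vertex classes and unordered children.
    """
    enc: dict[int, str] = {}
    for v in t.postorder():
        kids = sorted(enc[c] for c in t.children[v])
        enc[v] = "(" + t.classes[v] + "|" + "".join(kids) + ")"
    return enc[t.root]
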