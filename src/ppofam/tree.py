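"""Phylogenetic tree container with Newick round-trip I/O.

The container is deliberately small: nodes with children, branch lengths and
internal-node labels (bootstrap supports are stored as label strings so that
integer labels round-trip byte-identically through Newick).
"""

from __future__ import annotations

from typing import Callable, Iterator


class NewickError(ValueError):
    """Newick syntax error; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class Node:
    __slots__ = ("name", "length", "label", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None,
                 label: str | None = None):
        self.name = name          # leaf name
        self.length = length      # branch length to parent
        self.label = label        # internal-node label (e.g. bootstrap %)
        self.children: list[Node] = []
        self.parent: Node | None = None

    # -- structure ----------------------------------------------------
    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def find_leaf(self, name: str) -> "Node | None":
        for n in self.postorder():
            if n.is_leaf() and n.name == name:
                return n
        return None

    def copy(self) -> "Node":
        dup = Node(self.name, self.length, self.label)
        for c in self.children:
            dup.add(c.copy())
        return dup

    @property
    def support(self) -> float | None:
        if self.label is None:
            return None
        try:
            return float(self.label)
        except ValueError:
            return None

    # -- splits -------------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized to the side *excluding*
        the lexicographically smallest leaf name."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self.postorder():
            if node is self or node.is_leaf():
                continue
            side = frozenset(node.leaf_names())
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(side)
        return splits

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({to_newick(self)!r})"


# ---------------------------------------------------------------------------
# Newick I/O


def _format_length(x: float) -> str:
    x = float(x)
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def to_newick(root: Node) -> str:
    def render(node: Node) -> str:
        if node.is_leaf():
            s = node.name or ""
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.label is not None:
                s += node.label
            elif node.name:
                s += node.name
        if node.length is not None:
            s += ":" + _format_length(node.length)
        return s

    return render(root) + ";"


def from_newick(text: str) -> Node:
    s = text.strip()
    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(msg, pos)

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add(parse_node())
                if pos >= len(s):
                    raise error("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {s[pos]!r}")
            label = parse_token()
            if label:
                node.label = label
        else:
            name = parse_token()
            node.name = name or None
        if pos < len(s) and s[pos] == ":":
            pos += 1
            tok = parse_token()
            try:
                node.length = float(tok)
            except ValueError:
                raise error(f"bad branch length {tok!r}") from None
        return node

    def parse_token() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos]

    root = parse_node()
    if pos >= len(s) or s[pos] != ";":
        raise error("expected ';'" if pos >= len(s) else f"unexpected {s[pos]!r}")
    return root


# ---------------------------------------------------------------------------
# rooting


def reroot_above(node: Node) -> Node:
    """Return a new root placed at the midpoint of ``node``'s pendant edge.

    The subtree below ``node`` keeps its orientation; the rest of the tree is
    re-hung on the other side. Branch lengths are preserved (the split edge's
    halves sum to the original length).
    """
    if node.parent is None:
        raise ValueError("cannot reroot above the root")
    half = (node.length / 2.0) if node.length is not None else None

    new_root = Node()
    old_parent = node.parent
    old_parent.children = [c for c in old_parent.children if c is not node]
    node.parent = None
    node.length = half
    new_root.add(node)
    new_root.add(_invert(old_parent, half))
    _splice_degree_two(new_root)
    return new_root


def _invert(node: Node, length_to_new_parent: float | None) -> Node:
    """Reverse parent links from ``node`` upward; returns ``node`` re-hung."""
    parent = node.parent
    node.parent = None
    old_length = node.length
    node.length = length_to_new_parent
    if parent is not None:
        parent.children = [c for c in parent.children if c is not node]
        node.add(_invert(parent, old_length))
    return node


def _splice_degree_two(root: Node) -> None:
    """Remove internal degree-2 nodes (e.g. a former root after rerooting)."""
    for node in list(root.postorder()):
        if node is root:
            continue
        if len(node.children) == 1:
            only = node.children[0]
            only.length = (only.length or 0.0) + (node.length or 0.0)
            parent = node.parent
            idx = parent.children.index(node)
            only.parent = parent
            parent.children[idx] = only


def map_leaf_values(root: Node, values: dict[str, int],
                    missing: Callable[[str], int] | None = None) -> dict[Node, int]:
    out = {}
    for leaf in root.leaves():
        if leaf.name in values:
            out[leaf] = values[leaf.name]
        elif missing is not None:
            out[leaf] = missing(leaf.name)
        else:
            raise KeyError(f"no value for leaf {leaf.name!r}")
    return out
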