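"""Reading, writing and annotating phylogenetic trees.

This module provides a stack-safe Newick parser/writer (megatrees routinely
exceed Python's recursion limit, so every traversal here is iterative), a
tabular metadata join keyed on tip labels, deterministic polytomy resolution
into zero-length binary chains, and node annotation with cached tip counts
and ages-before-present.

Conventions
-----------
* Quoted Newick labels are preserved verbatim; no underscore-to-space
  conversion is applied anywhere.
* ``Node.date`` is the age of the node itself (time before present), anchored
  so that the deepest tip sits at age 0.  Non-ultrametric trees are allowed
  and simply yield positive tip dates.  The age of the origin of the root
  stem is ``root.date + root.length``.
* Trees without branch lengths are treated as cladograms; features that need
  dates refuse to run rather than inventing lengths.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "Node",
    "Tree",
    "MetadataTable",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "attach_metadata",
    "resolve_polytomies",
    "annotate",
]

#: characters that force quoting of a Newick label
_RESERVED = set("()[]':;,")


class NewickParseError(ValueError):
    """Malformed Newick input; ``offset`` is the 0-based character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class Node:
    """A single node of a phylogeny.

    ``length`` is the duration of the branch *above* the node (``None`` for
    cladograms), ``tip_count`` and ``date`` are caches filled by
    :func:`annotate`, and ``polytomy_flag`` records the resolution mode
    (``"break"`` or ``"highlight"``) on zero-length branches introduced by
    :func:`resolve_polytomies`.
    """

    __slots__ = ("label", "length", "children", "metadata",
                 "tip_count", "date", "polytomy_flag", "id")

    def __init__(self, label: str = "", length: Optional[float] = None,
                 children: Optional[list["Node"]] = None):
        self.label = label
        self.length = length
        self.children: list[Node] = children if children is not None else []
        self.metadata: dict[str, str] = {}
        self.tip_count: Optional[int] = None
        self.date: Optional[float] = None
        self.polytomy_flag: Optional[str] = None
        self.id: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.id} {kind} label={self.label!r} length={self.length}>"


class Tree:
    """A rooted phylogeny.

    Nodes are indexed in preorder: ``tree.nodes[i].id == i`` and a parent's id
    is always smaller than its children's, which lets bottom-up passes run as
    simple reversed loops over ``tree.nodes``.
    """

    def __init__(self, root: Node):
        self.root = root
        self.nodes: list[Node] = []
        self.parents: list[Optional[Node]] = []
        self.n_tips: int = 0
        self.has_lengths: bool = False
        self._reindex()

    # -- structure maintenance ------------------------------------------------

    def _reindex(self) -> None:
        nodes: list[Node] = []
        parents: list[Optional[Node]] = []
        seen: set[int] = set()
        stack: list[tuple[Node, Optional[Node]]] = [(self.root, None)]
        while stack:
            nd, par = stack.pop()
            if id(nd) in seen:
                raise ValueError("tree contains a cycle or a shared subtree")
            seen.add(id(nd))
            nd.id = len(nodes)
            nodes.append(nd)
            parents.append(par)
            for child in reversed(nd.children):
                stack.append((child, nd))
        self.nodes = nodes
        self.parents = parents
        self.n_tips = sum(1 for nd in nodes if nd.is_leaf)
        for nd in nodes:
            if nd.length is not None and (not math.isfinite(nd.length) or nd.length < 0):
                raise ValueError(f"branch length of node {nd.label!r} must be finite and >= 0")
        if len(nodes) == 1:
            self.has_lengths = nodes[0].length is not None
        else:
            self.has_lengths = all(nd.length is not None for nd in nodes[1:])

    # -- traversal ------------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        return iter(self.nodes)

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            nd, done = stack.pop()
            if done:
                yield nd
            else:
                stack.append((nd, True))
                for child in reversed(nd.children):
                    stack.append((child, False))

    def leaves(self) -> Iterator[Node]:
        return (nd for nd in self.nodes if nd.is_leaf)

    def copy(self) -> "Tree":
        """Deep structural copy (iterative; safe on 100k-deep caterpillars)."""
        clones: dict[int, Node] = {}
        for nd in self.nodes:
            c = Node(nd.label, nd.length)
            c.metadata = dict(nd.metadata)
            c.tip_count = nd.tip_count
            c.date = nd.date
            c.polytomy_flag = nd.polytomy_flag
            clones[nd.id] = c
        for nd in self.nodes:
            clones[nd.id].children = [clones[ch.id] for ch in nd.children]
        return Tree(clones[self.root.id])


# ---------------------------------------------------------------------------
# Newick parsing
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> Tree:
    """Parse a single Newick statement into a :class:`Tree`.

    Accepts unquoted and single-quoted labels (with ``''`` escapes), internal
    node labels, multifurcations, absent branch lengths and bracketed
    comments.  Parsing is iterative, so trees of any depth are safe.
    """
    n = len(text)

    def skip(i: int) -> int:
        # whitespace and (possibly nested) [...] comments
        while i < n:
            c = text[i]
            if c.isspace():
                i += 1
            elif c == "[":
                depth, j = 1, i + 1
                while j < n and depth:
                    if text[j] == "[":
                        depth += 1
                    elif text[j] == "]":
                        depth -= 1
                    j += 1
                if depth:
                    raise NewickParseError("unterminated comment", i)
                i = j
            else:
                break
        return i

    root = Node()
    cur = root
    stack: list[Node] = []
    seen_terminator = False
    i = skip(0)
    if i >= n:
        raise NewickParseError("empty Newick input", 0)
    while i < n:
        i = skip(i)
        if i >= n:
            break
        c = text[i]
        if c == "(":
            child = Node()
            cur.children.append(child)
            stack.append(cur)
            cur = child
            i += 1
        elif c == ",":
            if not stack:
                raise NewickParseError("comma outside parentheses", i)
            cur = Node()
            stack[-1].children.append(cur)
            i += 1
        elif c == ")":
            if not stack:
                raise NewickParseError("unbalanced parentheses", i)
            cur = stack.pop()
            i += 1
        elif c == ";":
            if stack:
                raise NewickParseError("unbalanced parentheses: missing ')'", i)
            seen_terminator = True
            i += 1
            break
        elif c == ":":
            j = skip(i + 1)
            k = j
            while k < n and text[k] not in "(),;:[" and not text[k].isspace():
                k += 1
            token = text[j:k]
            try:
                value = float(token)
            except ValueError:
                raise NewickParseError(f"invalid branch length {token!r}", j) from None
            if value < 0:
                raise NewickParseError("negative branch length", j)
            if not math.isfinite(value):
                raise NewickParseError("non-finite branch length", j)
            cur.length = value
            i = k
        elif c == "'":
            j = i + 1
            buf: list[str] = []
            while True:
                if j >= n:
                    raise NewickParseError("unterminated quoted label", i)
                if text[j] == "'":
                    if j + 1 < n and text[j + 1] == "'":
                        buf.append("'")
                        j += 2
                    else:
                        j += 1
                        break
                else:
                    buf.append(text[j])
                    j += 1
            if cur.label:
                raise NewickParseError("unexpected second label", i)
            cur.label = "".join(buf)
            i = j
        else:
            j = i
            while j < n and text[j] not in "(),;:[" and not text[j].isspace():
                j += 1
            if cur.label:
                raise NewickParseError("unexpected second label", i)
            cur.label = text[i:j]
            i = j
    if not seen_terminator:
        raise NewickParseError("missing ';' terminator", min(i, n))
    if text[i:].strip():
        raise NewickParseError("trailing content after ';'", i)
    return Tree(root)


def _format_label(label: str) -> str:
    if not label:
        return ""
    if any(ch in _RESERVED or ch.isspace() for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(length: Optional[float]) -> str:
    if length is None:
        return ""
    return f":{float(length)!r}"


def write_newick(tree: Tree) -> str:
    """Serialize a tree back to Newick (exact round-trip of lengths).

    Labels containing reserved characters are single-quoted, never dropped.
    Emission is token-streamed with an explicit stack, so deep caterpillars
    serialize in linear time without recursion.
    """
    tokens: list[str] = []
    stack: list[tuple[str, Node]] = [("node", tree.root)]
    while stack:
        kind, nd = stack.pop()
        if kind == "node":
            if nd.children:
                tokens.append("(")
                stack.append(("tail", nd))
                for idx in range(len(nd.children) - 1, -1, -1):
                    stack.append(("node", nd.children[idx]))
                    if idx:
                        stack.append(("comma", nd))
            else:
                tokens.append(_format_label(nd.label))
                tokens.append(_format_length(nd.length))
        elif kind == "tail":
            tokens.append(")")
            tokens.append(_format_label(nd.label))
            tokens.append(_format_length(nd.length))
        else:  # comma
            tokens.append(",")
    tokens.append(";")
    return "".join(tokens)


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

@dataclass
class MetadataTable:
    """Per-tip attributes keyed by tip label.

    ``records`` maps tip label -> {attribute name -> value}.  Keys must be
    unique and attribute names non-empty.
    """

    key_column: str
    records: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        for key, attrs in self.records.items():
            for name in attrs:
                if not name:
                    raise ValueError(f"empty attribute name for key {key!r}")

    @classmethod
    def from_csv(cls, source, delimiter: Optional[str] = None,
                 key_column: Optional[str] = None) -> "MetadataTable":
        """Read a delimited table with a header row; first column is the key
        unless ``key_column`` names another one.  ``source`` may be a path or
        an open text file.  Duplicate keys raise with the offending labels.
        """
        if hasattr(source, "read"):
            text = source.read()
        else:
            with open(source, "r", encoding="utf-8", newline="") as fh:
                text = fh.read()
        if delimiter is None:
            header = text.splitlines()[0] if text else ""
            delimiter = "\t" if "\t" in header else ","
        reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
        if not reader.fieldnames:
            raise ValueError("metadata table has no header row")
        key = key_column or reader.fieldnames[0]
        if key not in reader.fieldnames:
            raise ValueError(f"key column {key!r} not in header {reader.fieldnames}")
        records: dict[str, dict[str, str]] = {}
        duplicates: list[str] = []
        for row in reader:
            label = row[key]
            if label in records:
                duplicates.append(label)
                continue
            records[label] = {name: value for name, value in row.items()
                              if name != key and name is not None}
        if duplicates:
            raise ValueError(f"duplicate metadata keys: {sorted(set(duplicates))}")
        return cls(key_column=key, records=records)

    def to_csv(self, path, delimiter: str = ",") -> None:
        names: list[str] = []
        for attrs in self.records.values():
            for name in attrs:
                if name not in names:
                    names.append(name)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter)
            writer.writerow([self.key_column] + names)
            for key in self.records:
                row = [key] + [self.records[key].get(nm, "") for nm in names]
                writer.writerow(row)


def attach_metadata(tree: Tree, table: MetadataTable) -> tuple[Tree, list[str]]:
    """Join a metadata table onto the tree's tips by label.

    Returns ``(tree, orphans)`` where ``orphans`` lists table keys that match
    no tip (reported, not fatal).  Tips without a table row keep empty
    metadata.  Tips sharing a label all receive the row.
    """
    by_label: dict[str, list[Node]] = {}
    for tip in tree.leaves():
        by_label.setdefault(tip.label, []).append(tip)
    orphans: list[str] = []
    for key, attrs in table.records.items():
        tips = by_label.get(key)
        if not tips:
            orphans.append(key)
            continue
        for tip in tips:
            tip.metadata.update(attrs)
    return tree, orphans


# ---------------------------------------------------------------------------
# Polytomy resolution and annotation
# ---------------------------------------------------------------------------

def resolve_polytomies(tree: Tree, mode: str = "break") -> Tree:
    """Make the tree strictly binary, in place.

    Every node with k > 2 children is replaced by a left-leaning chain of
    k−1 binary nodes: the first two children are merged first, then the chain
    folds leftward, introducing k−2 zero-length internal branches flagged
    with ``mode``.  The renderer either suppresses flagged branches
    (``"break"``, drawing the polytomy as a physical break) or styles them
    distinctly (``"highlight"``).  The tip set and every root-to-tip path
    length are unchanged; binary input is returned as-is.
    """
    if mode not in ("break", "highlight"):
        raise ValueError(f"mode must be 'break' or 'highlight', got {mode!r}")
    changed = False
    for node in list(tree.nodes):
        k = len(node.children)
        if k <= 2:
            continue
        changed = True
        children = node.children
        left = children[0]
        for nxt in children[1:-1]:
            wrap = Node(label="", length=0.0 if tree.has_lengths else None,
                        children=[left, nxt])
            wrap.polytomy_flag = mode
            left = wrap
        node.children = [left, children[-1]]
    if changed:
        tree._reindex()
    return tree


def annotate(tree: Tree) -> Tree:
    """Fill cached ``tip_count`` for every node and, when branch lengths are
    present, ``date`` (age before present, deepest tip anchored at 0).
    """
    for nd in tree.postorder():
        nd.tip_count = 1 if nd.is_leaf else sum(c.tip_count for c in nd.children)
    if tree.has_lengths:
        dist = [0.0] * len(tree.nodes)
        for nd in tree.nodes:
            if tree.parents[nd.id] is not None:
                dist[nd.id] = dist[tree.parents[nd.id].id] + (nd.length or 0.0)
        deepest = max(dist)
        for nd in tree.nodes:
            nd.date = deepest - dist[nd.id]
    return tree
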