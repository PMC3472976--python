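"""Tip matching and clade ranking for search-and-fly navigation.

In a tree too large to scan by eye, search must surface *clades*, not just
tips: a query like "whale" should rank the smallest clade containing all
whales above the root (which also contains every hit, diluted).  Clades are
therefore ordered by total hit count first and by the proportion of their
tips that are hits second — the biggest relevant clade wins, the tightest
clade wins ties.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from typing import Iterable, Sequence

from .layout import SceneGraph
from .tree_io import Node, Tree

__all__ = ["SearchResult", "match_tips", "rank_clades", "highlight_set"]


def _fold(s: str) -> str:
    """Diacritic-stripped, case-folded form used for matching."""
    decomposed = unicodedata.normalize("NFKD", s)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch)).casefold()


def match_tips(tree: Tree, query: str, fields: Sequence[str] = ()) -> set[Node]:
    """Case-insensitive substring match of ``query`` against each tip's label
    and the named metadata fields; a tip matches if any field matches."""
    q = _fold(query.strip())
    if not q:
        raise ValueError("query is empty")
    meta_fields = [f for f in fields if f != "label"]
    hits: set[Node] = set()
    for tip in tree.leaves():
        if q in _fold(tip.label):
            hits.add(tip)
            continue
        for f in meta_fields:
            value = tip.metadata.get(f)
            if value is not None and q in _fold(str(value)):
                hits.add(tip)
                break
    return hits


@dataclass
class SearchResult:
    node: Node
    hit_count: int
    tip_fraction: float
    rank: int = 0


def rank_clades(tree: Tree, hits: Iterable[Node],
                method: str = "lexicographic") -> list[SearchResult]:
    """Rank every clade containing at least one hit.

    Hit counts are accumulated in one bottom-up pass.  ``lexicographic``
    (default) orders by hit count desc, then tip fraction desc, then clade
    size asc, then stable tree order — a total, deterministic order.
    ``product`` scores clades by hit_count × tip_fraction instead.
    """
    if method not in ("lexicographic", "product"):
        raise ValueError(f"unknown ranking method {method!r}")
    hit_ids = {nd.id for nd in hits}
    if not hit_ids:
        return []
    n = len(tree.nodes)
    if any(nd.tip_count is None for nd in tree.nodes):
        for nd in tree.postorder():
            nd.tip_count = 1 if nd.is_leaf else sum(c.tip_count for c in nd.children)
    hc = [0] * n
    # reversed preorder is a valid bottom-up order
    for nd in reversed(tree.nodes):
        if nd.is_leaf:
            hc[nd.id] = 1 if nd.id in hit_ids else 0
        else:
            hc[nd.id] = sum(hc[c.id] for c in nd.children)
    results = [SearchResult(nd, hc[nd.id], hc[nd.id] / nd.tip_count)
               for nd in tree.nodes if hc[nd.id] > 0]
    if method == "lexicographic":
        results.sort(key=lambda r: (-r.hit_count, -r.tip_fraction,
                                    r.node.tip_count, r.node.id))
    else:
        results.sort(key=lambda r: (-r.hit_count * r.tip_fraction,
                                    -r.hit_count, r.node.tip_count, r.node.id))
    for pos, r in enumerate(results, start=1):
        r.rank = pos
    return results


def highlight_set(scene: SceneGraph, results: Sequence[SearchResult],
                  top_k: int = 10) -> set[int]:
    """Scene element indices to style for the top-k results: each clade's
    whole subtree plus the path of elements from the root to it."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    out: set[int] = set()
    for result in results[:top_k]:
        idx = scene.node_index[result.node.id]
        stack = [idx]
        while stack:
            i = stack.pop()
            if i in out:
                continue
            out.add(i)
            stack.extend(scene.children[i])
        j = scene.parents[idx]
        while j is not None:
            out.add(j)
            j = scene.parents[j]
    return out
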