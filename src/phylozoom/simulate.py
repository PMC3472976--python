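"""Random trees, random metadata and tiny hand-checkable fixtures.

Everything here exists so the rest of the package is testable at any scale
without downloading data.  Trees come from a Yule (pure-birth) process —
sufficient to exercise layout, culling and search on anything from a cherry
to a 100,000-tip megatree — with an optional balance bias that produces
pathologically unbalanced topologies for stress tests.  All randomness goes
through numpy's PCG64 generator, so a seed reproduces the same tree on any
platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tree_io import MetadataTable, Node, Tree, annotate, parse_newick

__all__ = ["SimParams", "simulate_yule", "simulate_metadata", "fixture",
           "FIXTURE_NAMES"]


@dataclass(frozen=True)
class SimParams:
    """Yule simulation settings.

    balance_bias weights the choice of splitting lineage by depth:
    0.5 is the standard uniform choice; values toward 1 prefer deep lineages
    (caterpillar-like trees), toward 0 shallow ones (balanced trees).  The
    biased path recomputes weights each split and is meant for small stress
    trees; the uniform path is vectorised and handles 100k tips in seconds.
    """

    n_tips: int
    birth_rate: float = 1.0
    balance_bias: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 1:
            raise ValueError("n_tips must be >= 1")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if not (0.0 <= self.balance_bias <= 1.0):
            raise ValueError("balance_bias must lie in [0, 1]")


def simulate_yule(params: SimParams) -> Tree:
    """Grow a Yule tree to ``n_tips`` lineages.

    Waiting time to the next split with k lineages is Exponential(k·λ); the
    splitting lineage is chosen uniformly (balance_bias 0.5) or biased by
    depth.  Branch lengths are elapsed times; the process stops at the last
    split, so the tree is ultrametric with the deepest tips at age 0 and the
    root stem origin at age Σ_{k=1..n−1} Exp(k·λ).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_tips
    root = Node()
    if n == 1:
        root.label = "t1"
        tree = Tree(root)
        return annotate(tree)
    gamma = 6.0 * (2.0 * params.balance_bias - 1.0)
    active: list[Node] = [root]
    birth = [0.0]
    depth = [0]
    t = 0.0
    if gamma == 0.0:
        waits = rng.exponential(1.0, size=n - 1) / (
            params.birth_rate * np.arange(1, n))
        picks = (rng.random(n - 1) * np.arange(1, n)).astype(np.int64)
        for step in range(n - 1):
            t += waits[step]
            i = int(picks[step])
            _split(active, birth, depth, i, t)
    else:
        for _ in range(n - 1):
            k = len(active)
            t += rng.exponential(1.0 / (params.birth_rate * k))
            w = (1.0 + np.asarray(depth, dtype=float)) ** gamma
            i = int(rng.choice(k, p=w / w.sum()))
            _split(active, birth, depth, i, t)
    for idx, tip in enumerate(active):
        tip.length = t - birth[idx]
        tip.label = f"t{idx + 1}"
    tree = Tree(root)
    return annotate(tree)


def _split(active: list[Node], birth: list[float], depth: list[int],
           i: int, t: float) -> None:
    node = active[i]
    node.length = t - birth[i]
    left, right = Node(), Node()
    node.children = [left, right]
    active[i] = left
    birth[i] = t
    active.append(right)
    birth.append(t)
    depth.append(depth[i] + 1)
    depth[i] += 1


def simulate_metadata(tree: Tree, categories: dict[str, float], seed: int = 0,
                      attribute: str = "category") -> MetadataTable:
    """Assign each tip an independent draw from a categorical distribution.

    ``categories`` maps value -> probability; probabilities must sum to 1
    within 1e-9.  Deterministic given ``seed``.
    """
    values = list(categories)
    probs = np.array([categories[v] for v in values], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"category probabilities must be >= 0 and sum to 1, "
                         f"got sum {probs.sum()!r}")
    rng = np.random.default_rng(seed)
    tips = [tip for tip in tree.leaves()]
    draws = rng.choice(len(values), size=len(tips), p=probs)
    records = {tip.label: {attribute: values[int(d)]}
               for tip, d in zip(tips, draws)}
    return MetadataTable(key_column="label", records=records)


# ---------------------------------------------------------------------------
# Hand-checkable fixtures
# ---------------------------------------------------------------------------

_FIXTURES: dict[str, str] = {
    "cherry": "(A:1,B:1):1;",
    "caterpillar-8": "(((((((t1:1,t2:1):1,t3:2):1,t4:3):1,t5:4):1,t6:5):1,t7:6):1,t8:7);",
    "balanced-16": "((((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1):1,"
                   "(((i:1,j:1):1,(k:1,l:1):1):1,((m:1,n:1):1,(o:1,p:1):1):1):1);",
    "polytomy-5": "(A,B,C,D,E);",
    "dated-4": "((A:1,B:2):1,(C:3,D:1):2):1;",
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture(name: str):
    """Return ``(tree, expected)`` for a named golden fixture.

    ``expected`` holds hand-computed values (bearings, flag counts, dates)
    that tests assert against the default presets.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {list(FIXTURE_NAMES)}")
    tree = parse_newick(_FIXTURES[name])
    expected: dict = {}
    if name == "cherry":
        expected = {
            "spiral_child_bearings": (math.pi / 6, -math.pi / 6),
            "spiral_child_length": 0.8,
            "n_tips": 2,
        }
    elif name == "caterpillar-8":
        expected = {"n_tips": 8, "max_depth": 7}
    elif name == "balanced-16":
        expected = {"n_tips": 16, "root_children_tips": (8, 8)}
    elif name == "polytomy-5":
        expected = {"n_tips": 5, "flagged_branches": 3}
    elif name == "dated-4":
        # distances from root: A 2, B 3, C 5, D 3; deepest tip C anchors age 0
        expected = {
            "n_tips": 4,
            "dates": {"A": 3.0, "B": 2.0, "C": 0.0, "D": 2.0},
            "root_date": 5.0,
            "stem_origin_age": 6.0,
        }
    return tree, expected
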