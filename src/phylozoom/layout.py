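"""Fractal 2-D layout of a whole phylogeny as a scene graph.

The entire tree is laid out on "one page": the root stem sits at the origin
growing up the +y axis, and every other branch is produced by one recursion
step that scales the parent's length and width by fixed ratios and rotates
its bearing by a fixed angle (self-similar forms), or allocates width and
angle from the species richness of the two subtrees (the natural form).
Because the ratios are below one, clades subtending few splits stay large —
evolutionarily distinct tips render big, bushy clades shrink.

World coordinates are y-up; bearing 0 points along +y and increases
counterclockwise, so a branch with start ``(x, y)``, bearing θ and length L
ends at ``(x − L·sinθ, y + L·cosθ)``.

The scene graph mirrors the tree: one branch element per node (2N−1 for a
binary N-tip tree) plus one leaf disc per tip.  Every element carries its own
axis-aligned bounding box and the box of its whole subtree, which is what
makes viewport culling of megatrees cheap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Optional

from .tree_io import Node, Tree

__all__ = [
    "LayoutParams",
    "BranchGeometry",
    "LeafGeometry",
    "SceneGraph",
    "LayoutError",
    "compute_layout",
    "child_geometry",
    "natural_allocation",
    "scene_bounds",
    "scene_to_json",
    "scene_from_json",
    "bbox_union",
    "bbox_intersects",
    "PRESETS",
]

BBox = tuple[float, float, float, float]  # xmin, ymin, xmax, ymax


class LayoutError(ValueError):
    pass


def bbox_union(a: BBox, b: BBox) -> BBox:
    return (min(a[0], b[0]), min(a[1], b[1]), max(a[2], b[2]), max(a[3], b[3]))


def bbox_intersects(a: BBox, b: BBox) -> bool:
    return a[0] <= b[2] and b[0] <= a[2] and a[1] <= b[3] and b[1] <= a[3]


def bbox_contains(outer: BBox, inner: BBox, eps: float = 1e-9) -> bool:
    return (outer[0] - eps <= inner[0] and outer[1] - eps <= inner[1]
            and outer[2] + eps >= inner[2] and outer[3] + eps >= inner[3])


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayoutParams:
    """Fractal growth rules for one layout form.

    angle_pair
        (inner, outer) child bearings relative to the parent bearing, radians.
    length_ratio_pair / width_ratio_pair
        child/parent scale factors in (0, 1], indexed (inner, outer).
    natural_exponent
        β in the natural form's richness allocation tips^β / Σ tips^β;
        β = 0.5 makes branch *area* roughly proportional to richness.
    """

    form: str = "spiral"
    angle_pair: tuple[float, float] = (math.pi / 6, -math.pi / 6)
    length_ratio_pair: tuple[float, float] = (0.8, 0.8)
    width_ratio_pair: tuple[float, float] = (0.75, 0.75)
    root_length: float = 1.0
    root_width: float = 0.15
    natural_exponent: float = 0.5
    leaf_radius_fraction: float = 0.5  # leaf disc radius / terminal branch width

    def __post_init__(self):
        if self.form not in ("spiral", "feather", "natural"):
            raise LayoutError(f"unknown form {self.form!r}")
        for r in (*self.length_ratio_pair, *self.width_ratio_pair):
            if not (0.0 < r <= 1.0):
                raise LayoutError(f"ratios must lie in (0, 1], got {r}")
        for a in self.angle_pair:
            if not (-math.pi < a < math.pi):
                raise LayoutError(f"angles must lie in (-pi, pi), got {a}")
        if self.root_length <= 0 or self.root_width <= 0:
            raise LayoutError("root_length and root_width must be > 0")
        if self.natural_exponent <= 0:
            raise LayoutError("natural_exponent must be > 0")

    @classmethod
    def preset(cls, name: str, **overrides) -> "LayoutParams":
        key = name.replace("-like", "")
        if key not in PRESETS:
            raise LayoutError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return replace(PRESETS[key], **overrides) if overrides else PRESETS[key]


PRESETS: dict[str, LayoutParams] = {
    # tight equal ratios, symmetric fan-out
    "spiral": LayoutParams(form="spiral",
                           angle_pair=(math.pi / 6, -math.pi / 6),
                           length_ratio_pair=(0.8, 0.8),
                           width_ratio_pair=(0.75, 0.75)),
    # asymmetric ratios: a dominant stem with short alternating side shoots
    "feather": LayoutParams(form="feather",
                            angle_pair=(1.1, -0.22),
                            length_ratio_pair=(0.45, 0.88),
                            width_ratio_pair=(0.55, 0.9),
                            root_width=0.12),
    # widths and angles follow subtree richness; balance is visible at a glance
    "natural": LayoutParams(form="natural",
                            angle_pair=(math.pi / 3, -math.pi / 3),
                            length_ratio_pair=(0.82, 0.82),
                            width_ratio_pair=(0.72, 0.72),
                            root_width=0.2),
}


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

class BranchGeometry:
    """A branch drawn as a constant-width rectangle.

    ``info`` carries small display facts resolved at layout time (subtree tip
    count, children tip counts, node date, tip metadata) so a serialized
    scene is self-contained for rendering.
    """

    __slots__ = ("node_id", "label", "x", "y", "bearing", "length", "width",
                 "style_class", "info")

    def __init__(self, node_id: int, label: str, x: float, y: float,
                 bearing: float, length: float, width: float,
                 style_class: str = "normal", info: Optional[dict] = None):
        self.node_id = node_id
        self.label = label
        self.x = x
        self.y = y
        self.bearing = bearing
        self.length = length
        self.width = width
        self.style_class = style_class
        self.info = info or {}

    @property
    def kind(self) -> str:
        return "branch"

    @property
    def start(self) -> tuple[float, float]:
        return (self.x, self.y)

    @property
    def end(self) -> tuple[float, float]:
        return (self.x - self.length * math.sin(self.bearing),
                self.y + self.length * math.cos(self.bearing))

    def corners(self) -> list[tuple[float, float]]:
        """The four rectangle corners in world coordinates."""
        px, py = math.cos(self.bearing), math.sin(self.bearing)
        hw = 0.5 * self.width
        ex, ey = self.end
        return [(self.x + px * hw, self.y + py * hw),
                (self.x - px * hw, self.y - py * hw),
                (ex - px * hw, ey - py * hw),
                (ex + px * hw, ey + py * hw)]

    def bbox(self) -> BBox:
        pts = self.corners()
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        return (min(xs), min(ys), max(xs), max(ys))


class LeafGeometry:
    """A tip rendered as a disc tangent to the end of its terminal branch."""

    __slots__ = ("node_id", "label", "cx", "cy", "radius", "info")

    def __init__(self, node_id: int, label: str, cx: float, cy: float,
                 radius: float, info: Optional[dict] = None):
        self.node_id = node_id
        self.label = label
        self.cx = cx
        self.cy = cy
        self.radius = radius
        self.info = info or {}

    @property
    def kind(self) -> str:
        return "leaf"

    @property
    def center(self) -> tuple[float, float]:
        return (self.cx, self.cy)

    def bbox(self) -> BBox:
        r = self.radius
        return (self.cx - r, self.cy - r, self.cx + r, self.cy + r)


class SceneGraph:
    """Flat preorder store of scene elements with parent/child links.

    ``node_index`` maps a tree node id to its branch element, ``leaf_index``
    to a tip's disc.  ``subtree_bboxes[i]`` covers element i and everything
    below it.  ``fills`` holds optional per-element colour overrides set by
    the styling functions.
    """

    __slots__ = ("entries", "bboxes", "subtree_bboxes", "parents", "children",
                 "node_index", "leaf_index", "fills", "params")

    def __init__(self, params: Optional[LayoutParams] = None):
        self.entries: list = []
        self.bboxes: list[BBox] = []
        self.subtree_bboxes: list[BBox] = []
        self.parents: list[Optional[int]] = []
        self.children: list[list[int]] = []
        self.node_index: dict[int, int] = {}
        self.leaf_index: dict[int, int] = {}
        self.fills: dict[int, str] = {}
        self.params = params

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, geom, parent: Optional[int]) -> int:
        idx = len(self.entries)
        self.entries.append(geom)
        self.bboxes.append(geom.bbox())
        self.parents.append(parent)
        self.children.append([])
        if parent is not None:
            self.children[parent].append(idx)
        if geom.kind == "branch":
            self.node_index[geom.node_id] = idx
        else:
            self.leaf_index[geom.node_id] = idx
        return idx

    def finalize(self) -> None:
        # preorder guarantees children come after parents, so one reversed
        # sweep computes every subtree box
        self.subtree_bboxes = list(self.bboxes)
        for i in range(len(self.entries) - 1, 0, -1):
            p = self.parents[i]
            self.subtree_bboxes[p] = bbox_union(self.subtree_bboxes[p],
                                                self.subtree_bboxes[i])


# ---------------------------------------------------------------------------
# Layout recursion
# ---------------------------------------------------------------------------

def natural_allocation(tips_a: int, tips_b: int, params: LayoutParams
                       ) -> tuple[float, float, float, float]:
    """Richness-based width and angle split for the natural form.

    Returns ``(width_fraction_a, width_fraction_b, angle_a, angle_b)`` where
    ``width_fraction_i = tips_i^β / (tips_a^β + tips_b^β)`` and the angles
    are unsigned bearing deviations proportional to the *other* child's
    fraction, scaled into the preset's angle range — the richer child
    continues closer to the parent's bearing.  Swapping the inputs swaps the
    outputs exactly.
    """
    if tips_a < 1 or tips_b < 1:
        raise LayoutError("tip counts must be >= 1")
    beta = params.natural_exponent
    wa = tips_a ** beta
    wb = tips_b ** beta
    fa = wa / (wa + wb)
    fb = wb / (wa + wb)
    amp = max(abs(params.angle_pair[0]), abs(params.angle_pair[1]))
    return fa, fb, amp * fb, amp * fa


def child_geometry(parent: BranchGeometry, child_slot: str, child_node: Node,
                   sibling_node: Node, params: LayoutParams) -> BranchGeometry:
    """One recursion step: geometry of a child branch from its parent's.

    ``child_slot`` is ``"inner"`` (first child in Newick order) or
    ``"outer"``.  Fixed-ratio forms scale length/width by the slot's ratios
    and rotate by the slot's angle; the natural form replaces width and angle
    with :func:`natural_allocation` outputs (slot only supplies the turn
    direction).  Zero-length branches introduced by polytomy resolution in
    ``break`` mode become degenerate zero-length geometry the renderer skips.
    """
    if child_slot not in ("inner", "outer"):
        raise LayoutError(f"child_slot must be 'inner' or 'outer', got {child_slot!r}")
    slot = 0 if child_slot == "inner" else 1
    if params.form == "natural":
        fa, _fb, ang_a, _ang_b = natural_allocation(child_node.tip_count,
                                                    sibling_node.tip_count, params)
        width = parent.width * fa
        angle = math.copysign(ang_a, params.angle_pair[slot]) if ang_a else 0.0
        length = parent.length * params.length_ratio_pair[slot]
    else:
        length = parent.length * params.length_ratio_pair[slot]
        width = parent.width * params.width_ratio_pair[slot]
        angle = params.angle_pair[slot]
    if child_node.polytomy_flag == "break":
        length = 0.0
        style = "polytomy"
    elif child_node.polytomy_flag:
        style = "polytomy"
    elif child_node.is_leaf:
        style = "leaf-stem"
    else:
        style = "normal"
    ex, ey = parent.end
    return BranchGeometry(child_node.id, child_node.label, ex, ey,
                          parent.bearing + angle, length, width, style)


def _ensure_tip_counts(tree: Tree) -> None:
    if tree.root.tip_count is None or any(
            nd.tip_count is None for nd in tree.nodes):
        for nd in tree.postorder():
            nd.tip_count = 1 if nd.is_leaf else sum(c.tip_count for c in nd.children)


def _branch_info(node: Node) -> dict:
    info: dict = {"tips": node.tip_count}
    if node.children:
        info["children_tips"] = [c.tip_count for c in node.children]
    if node.date is not None:
        info["date"] = node.date
    return info


def compute_layout(tree: Tree, params: LayoutParams) -> SceneGraph:
    """Lay out the whole tree as a scene graph (the "one page").

    The tree must be strictly binary (run
    :func:`~phylozoom.tree_io.resolve_polytomies` first).  The root stem is
    placed at the origin with bearing 0; traversal is iterative and the
    function is pure — identical inputs give bit-identical scenes, and no
    element is pruned.
    """
    for nd in tree.nodes:
        if len(nd.children) not in (0, 2):
            raise LayoutError(
                f"node {nd.label or nd.id!r} has {len(nd.children)} children; "
                "run resolve_polytomies first")
    _ensure_tip_counts(tree)
    scene = SceneGraph(params)
    root = tree.root
    root_style = "leaf-stem" if root.is_leaf else "normal"
    root_geom = BranchGeometry(root.id, root.label, 0.0, 0.0, 0.0,
                               params.root_length, params.root_width,
                               root_style, _branch_info(root))
    stack: list[tuple[Node, BranchGeometry, Optional[int]]] = [(root, root_geom, None)]
    while stack:
        node, geom, parent_idx = stack.pop()
        idx = scene.add(geom, parent_idx)
        if node.is_leaf:
            ex, ey = geom.end
            radius = params.leaf_radius_fraction * geom.width
            dx = -math.sin(geom.bearing)
            dy = math.cos(geom.bearing)
            leaf = LeafGeometry(node.id, node.label,
                                ex + dx * radius, ey + dy * radius, radius,
                                dict(node.metadata))
            scene.add(leaf, idx)
        else:
            a, b = node.children
            geom_a = child_geometry(geom, "inner", a, b, params)
            geom_a.info = _branch_info(a)
            geom_b = child_geometry(geom, "outer", b, a, params)
            geom_b.info = _branch_info(b)
            stack.append((b, geom_b, idx))
            stack.append((a, geom_a, idx))
    scene.finalize()
    return scene


def scene_bounds(scene: SceneGraph) -> BBox:
    """Tight axis-aligned box around every element (the home "one page" view)."""
    if not scene.entries:
        raise LayoutError("empty scene")
    return scene.subtree_bboxes[0]


# ---------------------------------------------------------------------------
# Scene JSON schema
# ---------------------------------------------------------------------------

SCENE_SCHEMA = "phylozoom-scene-1"


def _r9(x: float) -> float:
    return round(float(x), 9)


def _r9s(seq) -> list[float]:
    return [_r9(v) for v in seq]


def scene_to_dict(scene: SceneGraph) -> dict:
    elements = []
    for i, geom in enumerate(scene.entries):
        if geom.kind == "branch":
            el = {"type": "branch", "node": geom.node_id, "label": geom.label,
                  "start": _r9s(geom.start), "bearing": _r9(geom.bearing),
                  "length": _r9(geom.length), "width": _r9(geom.width),
                  "style": geom.style_class}
        else:
            el = {"type": "leaf", "node": geom.node_id, "label": geom.label,
                  "center": _r9s(geom.center), "radius": _r9(geom.radius)}
        el["bbox"] = _r9s(scene.bboxes[i])
        el["subtree_bbox"] = _r9s(scene.subtree_bboxes[i])
        el["parent"] = scene.parents[i]
        if geom.info:
            el["info"] = geom.info
        if i in scene.fills:
            el["fill"] = scene.fills[i]
        elements.append(el)
    return {"schema": SCENE_SCHEMA, "elements": elements}


def scene_to_json(scene: SceneGraph, indent: Optional[int] = None) -> str:
    """Serialize a scene to the documented JSON schema (1e-9 precision)."""
    return json.dumps(scene_to_dict(scene), indent=indent, separators=(",", ":")
                      if indent is None else None)


def scene_from_json(text: str) -> SceneGraph:
    data = json.loads(text)
    if data.get("schema") != SCENE_SCHEMA:
        raise ValueError(f"not a {SCENE_SCHEMA} document")
    scene = SceneGraph()
    for el in data["elements"]:
        if el["type"] == "branch":
            geom = BranchGeometry(el["node"], el.get("label", ""),
                                  el["start"][0], el["start"][1], el["bearing"],
                                  el["length"], el["width"],
                                  el.get("style", "normal"), el.get("info"))
        else:
            geom = LeafGeometry(el["node"], el.get("label", ""),
                                el["center"][0], el["center"][1], el["radius"],
                                el.get("info"))
        idx = scene.add(geom, el["parent"])
        scene.bboxes[idx] = tuple(el["bbox"])
        if "fill" in el:
            scene.fills[idx] = el["fill"]
    scene.subtree_bboxes = [tuple(el["subtree_bbox"]) for el in data["elements"]]
    return scene
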