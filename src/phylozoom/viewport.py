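"""Viewport transforms, level-of-detail culling, zoom targeting and flights.

This is the math that makes a megatree explorable: the scene graph holds
every element of the "one page", and :func:`visible_elements` walks it,
pruning whole subtrees whose bounding box misses the viewport or whose
projected size falls below the one-pixel shape threshold.  Because an
element's box is contained in its subtree box and ratios shrink descendants,
the pruned traversal provably returns the same draw list as testing every
element independently — only faster, with work bounded by on-screen content
rather than tree size.

Screen coordinates follow the raster convention (y-down, origin top-left);
the flip lives only in :func:`world_to_screen`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Union

from .layout import BBox, SceneGraph, bbox_intersects
from .tree_io import Node, Tree

__all__ = [
    "Viewport",
    "DrawEntry",
    "DrawList",
    "FlightPath",
    "GrowthEntry",
    "DEFAULT_THRESHOLDS",
    "DETAIL_LEVELS",
    "world_to_screen",
    "screen_to_world",
    "world_rect",
    "visible_elements",
    "zoom_to_node",
    "flight_path",
    "growth_frame",
]

#: detail levels ordered from poorest to richest
DETAIL_LEVELS = ("shape", "shape+label", "shape+label+metadata")

#: minimum on-screen size (max bbox dimension, px) to earn each level
DEFAULT_THRESHOLDS: dict[str, float] = {
    "shape": 1.0,
    "shape+label": 40.0,
    "shape+label+metadata": 150.0,
}


@dataclass(frozen=True)
class Viewport:
    """World-to-screen transform state: world ``center``, ``scale`` in pixels
    per scene unit, and ``screen`` size ``(width_px, height_px)``."""

    center: tuple[float, float]
    scale: float
    screen: tuple[float, float]

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.screen[0] <= 0 or self.screen[1] <= 0:
            raise ValueError("screen dimensions must be > 0")


def world_to_screen(vp: Viewport, p: tuple[float, float]) -> tuple[float, float]:
    return ((p[0] - vp.center[0]) * vp.scale + vp.screen[0] / 2.0,
            vp.screen[1] / 2.0 - (p[1] - vp.center[1]) * vp.scale)


def screen_to_world(vp: Viewport, s: tuple[float, float]) -> tuple[float, float]:
    return ((s[0] - vp.screen[0] / 2.0) / vp.scale + vp.center[0],
            vp.center[1] - (s[1] - vp.screen[1] / 2.0) / vp.scale)


def world_rect(vp: Viewport) -> BBox:
    """The world-space rectangle the viewport shows."""
    hw = vp.screen[0] / (2.0 * vp.scale)
    hh = vp.screen[1] / (2.0 * vp.scale)
    return (vp.center[0] - hw, vp.center[1] - hh,
            vp.center[0] + hw, vp.center[1] + hh)


# ---------------------------------------------------------------------------
# Culling
# ---------------------------------------------------------------------------

@dataclass
class DrawEntry:
    index: int                      # element index into the scene
    geometry: dict                  # screen-space geometry
    detail: str                     # one of DETAIL_LEVELS


class DrawList:
    """Elements a renderer must paint for one viewport, in tree order."""

    def __init__(self, entries: list[DrawEntry]):
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_json(self, indent: Optional[int] = None) -> str:
        payload = [{"index": e.index, "detail": e.detail, **e.geometry}
                   for e in self.entries]
        return json.dumps(payload, indent=indent)


def _check_thresholds(thresholds: dict[str, float]) -> tuple[float, float, float]:
    t = tuple(thresholds[name] for name in DETAIL_LEVELS)
    if not (0 < t[0] < t[1] < t[2]):
        raise ValueError("thresholds must be strictly increasing with detail richness")
    return t


def _detail_for(size_px: float, t: tuple[float, float, float]) -> Optional[str]:
    if size_px >= t[2]:
        return DETAIL_LEVELS[2]
    if size_px >= t[1]:
        return DETAIL_LEVELS[1]
    if size_px >= t[0]:
        return DETAIL_LEVELS[0]
    return None


def _screen_geometry(geom, vp: Viewport) -> dict:
    if geom.kind == "branch":
        return {"type": "branch", "label": geom.label,
                "start": world_to_screen(vp, geom.start),
                "end": world_to_screen(vp, geom.end),
                "width_px": geom.width * vp.scale,
                "length_px": geom.length * vp.scale,
                "bearing": geom.bearing,
                "style": geom.style_class}
    return {"type": "leaf", "label": geom.label,
            "center": world_to_screen(vp, geom.center),
            "radius_px": geom.radius * vp.scale}


def visible_elements(scene: SceneGraph, vp: Viewport,
                     thresholds: Optional[dict[str, float]] = None) -> DrawList:
    """Cull the scene against a viewport.

    Returns exactly the elements whose own bbox intersects the view rectangle
    and whose projected size (max bbox dimension × scale) meets the shape
    threshold, each tagged with the richest detail level its size earns.
    Whole subtrees are pruned through the subtree bboxes; pruning never
    changes the result.
    """
    t = _check_thresholds(thresholds or DEFAULT_THRESHOLDS)
    rect = world_rect(vp)
    scale = vp.scale
    out: list[DrawEntry] = []
    if not scene.entries:
        return DrawList(out)
    stack = [0]
    bboxes = scene.bboxes
    subtree = scene.subtree_bboxes
    children = scene.children
    while stack:
        i = stack.pop()
        sb = subtree[i]
        if not bbox_intersects(sb, rect):
            continue
        if max(sb[2] - sb[0], sb[3] - sb[1]) * scale < t[0]:
            continue
        bb = bboxes[i]
        if bbox_intersects(bb, rect):
            size = max(bb[2] - bb[0], bb[3] - bb[1]) * scale
            level = _detail_for(size, t)
            if level is not None:
                out.append(DrawEntry(i, _screen_geometry(scene.entries[i], vp), level))
        for c in reversed(children[i]):
            stack.append(c)
    return DrawList(out)


# ---------------------------------------------------------------------------
# Zoom targeting and flights
# ---------------------------------------------------------------------------

def _node_entry(scene: SceneGraph, node: Union[Node, int]) -> int:
    node_id = node.id if isinstance(node, Node) else int(node)
    try:
        return scene.node_index[node_id]
    except KeyError:
        raise KeyError(f"node {node_id} is not in this scene") from None


def zoom_to_node(scene: SceneGraph, node: Union[Node, int],
                 screen: tuple[float, float], fill: float = 0.9) -> Viewport:
    """Viewport centred on a node's subtree box, scaled so the box occupies
    ``fill`` of the limiting screen dimension."""
    if not (0 < fill <= 1):
        raise ValueError("fill must lie in (0, 1]")
    idx = _node_entry(scene, node)
    bb = scene.subtree_bboxes[idx]
    bw = max(bb[2] - bb[0], 1e-12)
    bh = max(bb[3] - bb[1], 1e-12)
    scale = fill * min(screen[0] / bw, screen[1] / bh)
    center = ((bb[0] + bb[2]) / 2.0, (bb[1] + bb[3]) / 2.0)
    return Viewport(center=center, scale=scale, screen=tuple(screen))


class FlightPath:
    """Keyframes of a camera flight; first frame is the departure viewport,
    the last frames the target exactly."""

    def __init__(self, frames: list[Viewport], duration_hint: float):
        self.frames = frames
        self.duration_hint = duration_hint

    def __len__(self) -> int:
        return len(self.frames)

    def to_json(self, indent: Optional[int] = None) -> str:
        payload = {
            "duration_hint_s": self.duration_hint,
            "frames": [{"center": list(f.center), "scale": f.scale,
                        "screen": list(f.screen)} for f in self.frames],
        }
        return json.dumps(payload, indent=indent)


def flight_path(scene: SceneGraph, from_vp: Viewport, target_node: Union[Node, int],
                frames_per_doubling: int = 6, fill: float = 0.9,
                fps: float = 30.0) -> FlightPath:
    """Fly-to-target keyframes with constant perceived zoom speed.

    Scale interpolates geometrically; the centre drifts linearly against
    log-scale progress.  Frame count is
    ``ceil(|log2(scale_end / scale_start)| × frames_per_doubling)`` with a
    minimum of 2; endpoints are exact.
    """
    if frames_per_doubling < 1:
        raise ValueError("frames_per_doubling must be >= 1")
    end = zoom_to_node(scene, target_node, from_vp.screen, fill)
    doublings = abs(math.log2(end.scale / from_vp.scale))
    n_frames = max(2, math.ceil(doublings * frames_per_doubling))
    frames: list[Viewport] = []
    for i in range(n_frames):
        if i == 0:
            frames.append(from_vp)
            continue
        if i == n_frames - 1:
            frames.append(end)
            continue
        t = i / (n_frames - 1)
        scale = from_vp.scale * (end.scale / from_vp.scale) ** t
        cx = from_vp.center[0] + (end.center[0] - from_vp.center[0]) * t
        cy = from_vp.center[1] + (end.center[1] - from_vp.center[1]) * t
        frames.append(Viewport(center=(cx, cy), scale=scale, screen=from_vp.screen))
    return FlightPath(frames, duration_hint=(n_frames - 1) / fps)


# ---------------------------------------------------------------------------
# Growth animation
# ---------------------------------------------------------------------------

@dataclass
class GrowthEntry:
    index: int        # scene element index
    partial: bool     # branch straddles t and is still growing
    fraction: float   # surviving fraction of the branch, 1.0 when complete


def growth_frame(scene: SceneGraph, tree: Tree, t: float) -> list[GrowthEntry]:
    """Elements alive at age-before-present ``t`` for a growth animation.

    A branch is included once its origin (its parent node's date) is older
    than ``t``; a branch straddling ``t`` is flagged partial with surviving
    fraction ``(origin − t) / length``.  ``t <= 0`` returns the whole scene.
    Requires a dated tree (:func:`~phylozoom.tree_io.annotate` after parsing
    a tree with branch lengths).
    """
    if not tree.has_lengths or tree.root.date is None:
        raise ValueError("growth frames need a dated tree: parse a tree with "
                         "branch lengths and call annotate() first")
    out: list[GrowthEntry] = []
    nodes = tree.nodes
    for i, geom in enumerate(scene.entries):
        nd = nodes[geom.node_id]
        if geom.kind == "leaf":
            if t <= 0 or nd.date >= t:
                out.append(GrowthEntry(i, False, 1.0))
            continue
        origin = nd.date + (nd.length or 0.0)
        if t <= 0:
            out.append(GrowthEntry(i, False, 1.0))
        elif origin > t:
            if nd.date < t and nd.length:
                out.append(GrowthEntry(i, True, (origin - t) / nd.length))
            else:
                out.append(GrowthEntry(i, False, 1.0))
    return out
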