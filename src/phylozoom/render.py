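"""Styling, SVG rendering and the self-contained interactive HTML export.

Branch timescales are expressed by colour (a linear sRGB gradient over node
ages), categorical metadata by a palette keyed on a tip attribute, and the
raw balance numbers of every split by metadata panels inscribed inside the
branch shapes.  ``render_svg`` paints exactly what the culler returns,
ancestors first so wide stems never occlude twigs, and its byte output is
deterministic.  ``export_interactive_html`` writes one offline file holding
the tree, the precomputed scene and a fixed script with the same culling and
search rules.
"""

from __future__ import annotations

import math
import re
import string
from dataclasses import dataclass, field
from typing import Optional

from . import _template
from .layout import (BBox, LayoutParams, SceneGraph, compute_layout,
                     scene_to_dict)
from .tree_io import (MetadataTable, Node, Tree, annotate, attach_metadata,
                      resolve_polytomies, write_newick)
from .viewport import (DEFAULT_THRESHOLDS, DETAIL_LEVELS, Viewport,
                       visible_elements, world_to_screen)

__all__ = [
    "StyleConfig",
    "MetadataPanel",
    "IUCN_PALETTE",
    "style_by_date",
    "style_by_category",
    "build_metadata_panel",
    "render_svg",
    "export_interactive_html",
]

_HEX_RE = re.compile(r"^#[0-9a-fA-F]{6}$")

#: conventional Red List colours (configurable, not a contract)
IUCN_PALETTE: dict[str, str] = {
    "LC": "#006666", "NT": "#99cc00", "VU": "#cc9900",
    "EN": "#cc6633", "CR": "#cc3333", "EW": "#542344", "EX": "#000000",
}


def _check_hex(color: str, what: str) -> str:
    if not _HEX_RE.match(color):
        raise ValueError(f"{what} must be a 6-digit hex colour, got {color!r}")
    return color


@dataclass
class StyleConfig:
    """Colours and polytomy treatment for rendering."""

    palette: dict[str, str] = field(default_factory=dict)
    date_gradient: tuple[str, str] = ("#46321e", "#8fce5a")  # (old, young)
    polytomy_style: str = "dashed"  # suppress | dashed | accent-color
    highlight_color: str = "#ffcc00"
    background: str = "#fdfdf8"
    branch_color: str = "#8b6b4a"
    leaf_color: str = "#4a8b5c"
    text_color: str = "#222222"

    def __post_init__(self):
        for key, color in self.palette.items():
            if not key:
                raise ValueError("palette keys must be non-empty")
            _check_hex(color, f"palette[{key!r}]")
        if len(set(self.palette)) != len(self.palette):  # dicts dedupe anyway
            raise ValueError("palette keys must be unique")
        for c in (*self.date_gradient, self.highlight_color, self.background,
                  self.branch_color, self.leaf_color, self.text_color):
            _check_hex(c, "colour")
        if self.polytomy_style not in ("suppress", "dashed", "accent-color"):
            raise ValueError(f"unknown polytomy_style {self.polytomy_style!r}")


def _hex_to_rgb(c: str) -> tuple[int, int, int]:
    return (int(c[1:3], 16), int(c[3:5], 16), int(c[5:7], 16))


def _rgb_to_hex(rgb: tuple[int, int, int]) -> str:
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def _lerp_hex(young: str, old: str, u: float) -> str:
    """Channel-wise linear interpolation in sRGB; u=0 -> young, u=1 -> old."""
    a = _hex_to_rgb(young)
    b = _hex_to_rgb(old)
    return _rgb_to_hex(tuple(round(a[k] + u * (b[k] - a[k])) for k in range(3)))


# ---------------------------------------------------------------------------
# Styling
# ---------------------------------------------------------------------------

def style_by_date(scene: SceneGraph, tree: Tree,
                  gradient: Optional[tuple[str, str]] = None) -> SceneGraph:
    """Colour each branch by the age of its origin (its parent node's date),
    linearly between ``color_old`` (root age) and ``color_young`` (present).

    Leaf discs take their tip's own date.  Requires an annotated, dated tree.
    """
    if not tree.has_lengths or tree.root.date is None:
        raise ValueError("style_by_date needs a dated tree: call annotate() "
                         "on a tree with branch lengths first")
    old, young = gradient or StyleConfig().date_gradient
    _check_hex(old, "color_old")
    _check_hex(young, "color_young")
    root_age = tree.root.date
    nodes = tree.nodes
    for i, geom in enumerate(scene.entries):
        nd = nodes[geom.node_id]
        if geom.kind == "leaf":
            age = nd.date
        else:
            age = nd.date + (nd.length or 0.0)
        u = 1.0 if root_age <= 0 else min(max(age / root_age, 0.0), 1.0)
        scene.fills[i] = _lerp_hex(young, old, u)
    return scene


def style_by_category(scene: SceneGraph, tree: Tree, attribute: str,
                      palette: dict[str, str], default: Optional[str] = None,
                      branch_mode: str = "none") -> SceneGraph:
    """Colour leaf discs by a tip metadata attribute.

    ``branch_mode="majority"`` additionally colours internal branches by the
    most frequent value among descendant tips (ties broken by the smaller
    value, so the result is deterministic).  A value absent from the palette
    uses ``default``, or raises listing the uncovered values.
    """
    if branch_mode not in ("none", "majority"):
        raise ValueError(f"unknown branch_mode {branch_mode!r}")
    for color in palette.values():
        _check_hex(color, "palette colour")
    values: dict[int, Optional[str]] = {}
    uncovered: set[str] = set()
    for tip in tree.leaves():
        v = tip.metadata.get(attribute)
        values[tip.id] = v
        if v is not None and v not in palette:
            uncovered.add(v)
    if uncovered and default is None:
        raise ValueError(f"palette does not cover values {sorted(uncovered)} "
                         f"of attribute {attribute!r} and no default is set")
    if default is not None:
        _check_hex(default, "default colour")

    def color_of(v: Optional[str]) -> Optional[str]:
        if v is None:
            return default
        return palette.get(v, default)

    counts: dict[int, dict[str, int]] = {}
    if branch_mode == "majority":
        for nd in reversed(tree.nodes):  # bottom-up
            if nd.is_leaf:
                v = values[nd.id]
                counts[nd.id] = {v: 1} if v is not None else {}
            else:
                merged: dict[str, int] = {}
                for c in nd.children:
                    for v, k in counts[c.id].items():
                        merged[v] = merged.get(v, 0) + k
                counts[nd.id] = merged
    for i, geom in enumerate(scene.entries):
        nd = tree.nodes[geom.node_id]
        if geom.kind == "leaf":
            c = color_of(values[nd.id])
            if c is not None:
                scene.fills[i] = c
        elif branch_mode == "majority":
            tally = counts.get(nd.id) or {}
            if tally:
                best = max(sorted(tally), key=lambda v: tally[v])
                c = color_of(best)
                if c is not None:
                    scene.fills[i] = c
    return scene


# ---------------------------------------------------------------------------
# Metadata panels
# ---------------------------------------------------------------------------

@dataclass
class MetadataPanel:
    """Text block inscribed in a branch rectangle or leaf disc.

    Geometry is in world units: a ``width`` × ``height`` rectangle centred at
    ``(cx, cy)``, rotated to ``bearing``; ``bbox`` is its world-space AABB,
    guaranteed to sit inside the element's own bbox.
    """

    node_id: int
    lines: list[str]
    image_ref: Optional[str]
    cx: float
    cy: float
    width: float
    height: float
    bearing: float
    font_size: float
    bbox: BBox


_PANEL_MARGIN = 0.8          # inscribed fraction of the branch rectangle
_CHAR_ASPECT = 0.62          # crude width/em for sizing text


def build_metadata_panel(scene: SceneGraph, node: Node | int,
                         detail_level: str = DETAIL_LEVELS[2]) -> MetadataPanel:
    """Panel content and inscribed geometry for one node.

    Internal nodes show the raw balance numbers (each child's tip count) and
    the node's age when dated; tips show their label and attached metadata.
    Only the full-detail level carries panels.
    """
    if detail_level != DETAIL_LEVELS[2]:
        raise ValueError(f"metadata panels exist only at {DETAIL_LEVELS[2]!r}")
    node_id = node.id if isinstance(node, Node) else int(node)
    idx = scene.node_index[node_id]
    geom = scene.entries[idx]
    info = geom.info or {}
    lines: list[str] = []
    image_ref = None
    if "children_tips" in info:
        lines.append(" | ".join(str(k) for k in info["children_tips"]))
        if "date" in info:
            lines.append(f"age {info['date']:.6g}")
    else:
        lines.append(geom.label or "(unnamed tip)")
        leaf_idx = scene.leaf_index.get(node_id)
        meta = scene.entries[leaf_idx].info if leaf_idx is not None else {}
        for key, value in (meta or {}).items():
            if key == "image":
                image_ref = str(value)
            else:
                lines.append(f"{key}: {value}")
    if geom.length > 0:
        width = _PANEL_MARGIN * geom.width
        height = _PANEL_MARGIN * geom.length
        ex, ey = geom.end
        cx = (geom.x + ex) / 2.0
        cy = (geom.y + ey) / 2.0
        bearing = geom.bearing
    else:
        # degenerate branch: pin a square panel at its start point
        side = _PANEL_MARGIN * geom.width
        width = height = side
        cx, cy = geom.x, geom.y
        bearing = geom.bearing
    longest = max(len(line) for line in lines)
    font = min(height / max(len(lines), 1),
               width / max(longest * _CHAR_ASPECT, 1e-9)) * 0.9
    # AABB of the rotated panel rectangle
    c, s = abs(math.cos(bearing)), abs(math.sin(bearing))
    hx = (width * c + height * s) / 2.0
    hy = (width * s + height * c) / 2.0
    bbox = (cx - hx, cy - hy, cx + hx, cy + hy)
    return MetadataPanel(node_id, lines, image_ref, cx, cy, width, height,
                         bearing, font, bbox)


# ---------------------------------------------------------------------------
# SVG rendering
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _svg_text(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;"))


def render_svg(scene: SceneGraph, vp: Viewport,
               style: Optional[StyleConfig] = None,
               thresholds: Optional[dict[str, float]] = None,
               highlight: Optional[set[int]] = None) -> str:
    """Render one viewport of a scene to an SVG document string.

    Draws exactly the culler's draw list in tree order (ancestors under
    descendants); output is byte-identical for identical inputs.  Polytomy
    branches follow ``style.polytomy_style`` (``suppress`` omits them — the
    "physical break" treatment).
    """
    style = style or StyleConfig()
    draw = visible_elements(scene, vp, thresholds)
    w, h = vp.screen
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(w)}" '
        f'height="{_fmt(h)}" viewBox="0 0 {_fmt(w)} {_fmt(h)}">',
        f'<rect class="background" x="0" y="0" width="{_fmt(w)}" '
        f'height="{_fmt(h)}" fill="{style.background}"/>',
        '<g id="scene">',
    ]
    for entry in draw:
        geom = scene.entries[entry.index]
        fill = scene.fills.get(entry.index)
        extra = ""
        if geom.kind == "branch" and geom.style_class == "polytomy":
            if style.polytomy_style == "suppress":
                continue
            if style.polytomy_style == "dashed":
                extra = (f' stroke="{style.highlight_color}"'
                         f' stroke-dasharray="4 3" stroke-width="1"')
            else:  # accent-color
                fill = fill or style.highlight_color
        if highlight and entry.index in highlight:
            extra += f' stroke="{style.highlight_color}" stroke-width="2"'
        group = [f'<g class="el {geom.kind}" data-index="{entry.index}">']
        if geom.kind == "branch":
            fill = fill or style.branch_color
            pts = " ".join(f"{_fmt(px)},{_fmt(py)}"
                           for px, py in (world_to_screen(vp, p)
                                          for p in geom.corners()))
            group.append(f'<polygon points="{pts}" fill="{fill}"{extra}/>')
            if entry.detail in DETAIL_LEVELS[1:] and geom.label:
                group.append(_label_text(geom, vp, style))
            if entry.detail == DETAIL_LEVELS[2]:
                group.extend(_panel_texts(scene, entry.index, vp, style))
        else:
            fill = fill or style.leaf_color
            cx, cy = world_to_screen(vp, geom.center)
            r = geom.radius * vp.scale
            group.append(f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" '
                         f'r="{_fmt(r)}" fill="{fill}"{extra}/>')
            if entry.detail in DETAIL_LEVELS[1:] and geom.label:
                fs = max(6.0, r * 0.3)
                group.append(f'<text x="{_fmt(cx)}" y="{_fmt(cy)}" '
                             f'text-anchor="middle" font-size="{_fmt(fs)}" '
                             f'fill="{style.text_color}">'
                             f'{_svg_text(geom.label)}</text>')
        group.append("</g>")
        parts.append("".join(group))
    parts.append("</g></svg>")
    return "\n".join(parts)


def _label_text(geom, vp: Viewport, style: StyleConfig) -> str:
    sx, sy = world_to_screen(vp, geom.start)
    ex, ey = world_to_screen(vp, geom.end)
    cx, cy = (sx + ex) / 2.0, (sy + ey) / 2.0
    deg = math.degrees(math.atan2(ey - sy, ex - sx))
    if deg > 90:
        deg -= 180
    elif deg < -90:
        deg += 180
    fs = max(6.0, geom.width * vp.scale * 0.3)
    return (f'<text x="{_fmt(cx)}" y="{_fmt(cy)}" text-anchor="middle" '
            f'font-size="{_fmt(fs)}" fill="{style.text_color}" '
            f'transform="rotate({_fmt(deg)} {_fmt(cx)} {_fmt(cy)})">'
            f'{_svg_text(geom.label)}</text>')


def _panel_texts(scene: SceneGraph, index: int, vp: Viewport,
                 style: StyleConfig) -> list[str]:
    geom = scene.entries[index]
    if geom.kind != "branch":
        return []
    panel = build_metadata_panel(scene, geom.node_id)
    cx, cy = world_to_screen(vp, (panel.cx, panel.cy))
    fs = max(4.0, panel.font_size * vp.scale)
    out = []
    n = len(panel.lines)
    for k, line in enumerate(panel.lines):
        dy = (k - (n - 1) / 2.0) * fs * 1.2
        out.append(f'<text class="panel" x="{_fmt(cx)}" y="{_fmt(cy + dy)}" '
                   f'text-anchor="middle" font-size="{_fmt(fs)}" '
                   f'fill="{style.text_color}">{_svg_text(line)}</text>')
    return out


# ---------------------------------------------------------------------------
# Interactive single-file HTML export
# ---------------------------------------------------------------------------

def export_interactive_html(tree: Tree, params: Optional[LayoutParams] = None,
                            style: Optional[StyleConfig] = None,
                            out: Optional[str] = None,
                            metadata: Optional[MetadataTable] = None,
                            polytomy_mode: str = "highlight",
                            title: str = "phylozoom explorer") -> str:
    """Build one self-contained interactive HTML explorer for a tree.

    The file embeds the Newick text, the precomputed scene JSON and a fixed
    script (no network references anywhere); opening it offline reproduces
    pan/zoom exploration and clade-ranked search of the same tree.  Returns
    the HTML text; writes it to ``out`` when given.
    """
    params = params or LayoutParams.preset("natural")
    style = style or StyleConfig()
    work = tree.copy()
    if metadata is not None:
        attach_metadata(work, metadata)
    resolve_polytomies(work, polytomy_mode)
    annotate(work)
    scene = compute_layout(work, params)
    payload = {
        "scene": scene_to_dict(scene),
        "thresholds": {"shape": DEFAULT_THRESHOLDS["shape"],
                       "label": DEFAULT_THRESHOLDS["shape+label"],
                       "metadata": DEFAULT_THRESHOLDS["shape+label+metadata"]},
        "style": {"background": style.background,
                  "branch_color": style.branch_color,
                  "leaf_color": style.leaf_color,
                  "text_color": style.text_color,
                  "highlight_color": style.highlight_color,
                  "polytomy_color": style.highlight_color,
                  "polytomy_style": style.polytomy_style},
        "meta": {"n_tips": work.n_tips},
    }
    import json as _json
    payload_json = _json.dumps(payload, separators=(",", ":")).replace("</", "<\\/")
    newick = write_newick(work).replace("</", "<\\/")
    html = string.Template(_template.HTML_TEMPLATE).substitute(
        title=_svg_text(title), newick=newick, payload=payload_json)
    if out is not None:
        try:
            with open(out, "w", encoding="utf-8") as fh:
                fh.write(html)
        except OSError as exc:
            raise OSError(f"cannot write HTML export to {out!r}: {exc}") from exc
    return html
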