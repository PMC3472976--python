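# phylozoom

Fractal, zoomable 2-D layouts for arbitrarily large phylogenies.

Phylogenies with 10⁵–10⁶ tips cannot be drawn legibly at any fixed page
size: printed flat, a megatree needs more paper than exists.  `phylozoom`
takes the zooming-interface approach instead.  The whole tree is laid out
*once* on a single unbounded plane as a self-similar arrangement of filled
branch shapes — every branch is a rectangle wide enough to carry labels and
metadata inside it — and a viewport with level-of-detail culling reveals
structure progressively as you zoom, the way a map application reveals
towns and streets.  Because the layout is fractal, the cost of drawing any
one view depends on what is on screen, not on how many tips the tree has.

The package provides, as a library and a `phylozoom` CLI:

* **Newick I/O** — a stack-safe parser/writer (100,000-tip caterpillars are
  fine), CSV/TSV metadata joins keyed on tip labels, deterministic polytomy
  resolution into flagged zero-length chains, and node annotation with tip
  counts and ages.
* **Fractal layout** — three presets (`spiral`, `feather`, `natural`).  In
  fixed-ratio forms a child branch's length and width are the parent's times
  ratios r, w ∈ (0,1], and its bearing turns by a fixed angle, so a branch at
  depth d has length `root_length · Π rᵢ`.  The *natural* form instead
  allocates widths by subtree richness, `wᵢ = nᵢᵝ / (n₁ᵝ + n₂ᵝ)` (β = 0.5 by
  default), and turns the richer child less — clade balance is visible at a
  glance, and the raw counts appear inside the branch when you zoom in.
* **Viewport & LOD** — exact culling via per-subtree bounding boxes: an
  element is drawn when its box intersects the view and its on-screen size
  exceeds 1 px; labels appear at 40 px, in-branch metadata panels at 150 px.
  Pruned traversal is provably identical to testing every element.
* **Search** — substring match over labels and metadata; clades ranked by
  total hit count, then by the fraction of their tips that are hits; flight
  keyframes with geometric (constant perceived speed) zoom interpolation.
* **Export** — deterministic SVG snapshots, and a single self-contained
  interactive HTML file (embedded tree + scene + script, zero external
  references) that works offline in any browser.
* **Simulation** — a seeded Yule generator (with a balance-bias knob for
  pathological topologies) and random categorical metadata, so everything is
  testable at any scale with no downloads.

## Worked example

```
$ phylozoom simulate --tips 64 --seed 1 --out tree.nwk --metadata meta.csv
wrote 64-tip tree to tree.nwk
wrote metadata for 64 tips to meta.csv
$ phylozoom layout --in tree.nwk --form natural --out scene.json
laid out 64 tips as 191 elements in 0.01s -> scene.json
$ phylozoom render --scene scene.json --fit --size 1000x800 --out home.svg
rendered 136 elements -> home.svg
$ phylozoom search --in tree.nwk --query t1 --top 2
[
  {
    "rank": 1,
    "label": "",
    "node": 0,
    "hits": 11,
    "tip_fraction": 0.171875,
    "clade_tips": 64
  },
  {
    "rank": 2,
    "label": "",
    "node": 3,
    "hits": 6,
    "tip_fraction": 0.333333333,
    "clade_tips": 18
  }
]
$ phylozoom fly --scene scene.json --target t17 --out flight.json
29 keyframes -> flight.json
$ phylozoom export-html --in tree.nwk --metadata meta.csv --out explorer.html
exported 64-tip explorer -> explorer.html
```

Reading the numbers: a binary 64-tip tree yields 2·64−1 = 127 branch shapes
plus 64 leaf discs = 191 scene elements; the home view draws the 136 of them
that are at least one pixel on a 1000×800 screen.  The query `t1` hits 11
tip labels (`t1`, `t10`–`t19`); the root necessarily contains all 11 hits
(fraction 11/64 ≈ 0.17) and ranks first, while an 18-tip clade holding 6
hits at fraction 1/3 is the tightest runner-up.  The flight from the home
view to tip `t17` doubles the scale about five times at six keyframes per
doubling, giving 29 frames.  `explorer.html` is a complete offline explorer
of the same tree — open it in a browser, drag to pan, scroll to zoom, and
type in the search box to fly to the best-ranked clade.

The same pipeline in Python:

```python
from phylozoom import (SimParams, simulate_yule, annotate, LayoutParams,
                       compute_layout, zoom_to_node, visible_elements)

tree = annotate(simulate_yule(SimParams(n_tips=10_000, seed=1)))
scene = compute_layout(tree, LayoutParams.preset("natural"))
home = zoom_to_node(scene, tree.root.id, screen=(1280, 800), fill=0.95)
print(len(visible_elements(scene, home)), "elements on screen")
```

## Scope

`phylozoom` is a layout/visualization engine: it does not infer, root,
rearrange or date trees, and the fractal forms tolerate self-overlap at
extreme parameter choices rather than guaranteeing planarity.  See
`docs/methods.md` for the model, parameter defaults and limitations.
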