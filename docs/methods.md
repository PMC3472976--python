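# Methods

This note documents the models, geometric conventions, parameter defaults
and deliberate design choices behind `phylozoom`, and what the test suite
does and does not demonstrate.

## The layout model

A phylogeny is drawn as an arrangement of filled shapes on an unbounded
plane ("one page"): one constant-width rectangle per branch and one disc per
tip, with metadata rendered *inside* shapes once they are large enough on
screen.  World coordinates are y-up; a branch is described by its start
point, bearing θ (0 = +y, counterclockwise positive), length L and width W,
ending at `start + L·(−sin θ, cos θ)`.  The root stem is placed at the
origin with bearing 0, length `root_length` (default 1) and width
`root_width`.

Layout requires a strictly binary tree; polytomies are first resolved into
left-leaning chains of zero-length flagged branches (first two children
merged, then folded leftward — deterministic and order-preserving).  A node
with k children contributes k−2 flagged branches; tip sets and root-to-tip
path lengths are unchanged exactly.  In `break` mode flagged branches get
degenerate zero-length geometry and are omitted by renderers, so the
polytomy reads as a physical break; in `highlight` mode they keep normal
fractal geometry and a distinct style class.

### Fixed-ratio (self-similar) forms

One recursion step produces a child from its parent:

    L_child = L_parent · r(slot)      W_child = W_parent · w(slot)
    θ_child = θ_parent + α(slot)      start_child = end_parent

with `slot ∈ {inner, outer}` assigned by Newick child order (first child =
inner).  Presets:

| preset    | α (inner, outer) | r            | w            |
|-----------|------------------|--------------|--------------|
| `spiral`  | (+π/6, −π/6)     | (0.80, 0.80) | (0.75, 0.75) |
| `feather` | (+1.10, −0.22)   | (0.45, 0.88) | (0.55, 0.90) |

Geometry deliberately ignores the tree's branch *lengths*: time is expressed
through colour, text and growth animation instead, so the shape can encode
topology and balance.  Because all ratios are < 1, a branch at depth d has
length `root_length · Π path ratios` exactly (asserted to 1e-9 against the
closed form), and leaf disc radius decreases strictly with the number of
ancestral splits — evolutionarily distinct tips render large.

### The natural form

Widths and angles are reallocated at every split from subtree richness.
With child tip counts (n₁, n₂) and exponent β (default 0.5):

    fᵢ = nᵢᵝ / (n₁ᵝ + n₂ᵝ)          W_child_i = W_parent · fᵢ
    |Δθ_i| = A · f_other,  A = max |α|

so fractions sum to 1, swapping children swaps the outputs exactly, and the
richer child both stays wider and deviates less from the parent's bearing —
balance is readable at a glance.  β = 0.5 makes branch cross-section area
roughly proportional to richness, which keeps megatree stems legible; it is
exposed as `natural_exponent` because nothing forces this choice.  Lengths
in the natural form still follow the fixed length ratios (0.82) so depth
remains the length cue.  `natural_allocation` returns angle *magnitudes*;
the turn sign comes from the slot at the recursion step — this is what makes
the swap symmetry exact rather than approximate.

Leaf discs have radius 0.5 × terminal branch width, tangent to the branch
end.  Branches are rectangles; the curved, tapered strokes of polished
viewers are a rendering style deliberately kept out of the geometry model.

## Scene graph and culling

The scene stores elements flat in preorder with parent/child indices; every
element carries its own AABB and the AABB of its whole subtree, computed in
one reversed (bottom-up) sweep.  Culling of viewport V (center, scale in
px/unit, screen size) draws element e iff

    bbox(e) ∩ rect(V) ≠ ∅   and   max-dimension(bbox(e)) · scale ≥ 1 px,

with richer detail at 40 px (labels) and 150 px (in-branch metadata
panels).  Traversal prunes a whole subtree when its subtree box misses the
view rectangle or projects below 1 px; since every element's box is
contained in its subtree box, pruning cannot change the result — the suite
and the acceptance script assert equality against an independently written
per-element oracle on thousands of scene × viewport pairs.

Deep-zoom draw lists (viewports framing a single tip) stay bounded by
on-screen content — a few hundred elements for a 100,000-tip tree, asserted
against a configured cap of 5,000 — which is the operational sense in which
draw cost is independent of tree size.  Wide views of a large tree can
legitimately contain tens of thousands of ≥ 1 px elements; the bound is a
statement about content-equivalent viewports, not about the home view.

All traversals in the package (parse, write, annotate, resolve, layout,
bbox, culling, ranking) are iterative; 100k-deep caterpillars must not
overflow the interpreter stack, and this is part of the tested contract.

## Dates, growth and colour

`annotate` anchors ages so the deepest tip sits at 0 and
`date(child) = date(parent) − length(child)`; the root *stem origin* has age
`root.date + root.length`.  Non-ultrametric trees simply get positive tip
dates; trees without lengths are cladograms, and every date-dependent
feature (date gradients, growth frames) refuses them with a clear error
rather than inventing lengths.

A growth frame at age t includes a branch once its origin (parent date) is
strictly older than t; a straddling branch is flagged partial with surviving
fraction `(origin − t)/length`, so a renderer can draw branches growing.
`t ≤ 0` returns the whole scene.  Date colouring interpolates a two-colour
gradient channel-wise linearly in sRGB over [0, root age] (endpoints exact,
stated so tests can assert); categorical colouring maps a tip attribute
through a palette, with optional majority-vote colouring of internal
branches (ties to the lexicographically smaller value, for determinism).

## Search

Matching is case-insensitive substring over the tip label and named
metadata fields, with diacritics folded to ASCII first.  Ranking collects
every clade with ≥ 1 hit (one bottom-up pass) and orders lexicographically:
hit count desc, tip fraction desc, clade size asc, tree order — a total
order.  How the two published signals (hits, fraction) combine is not fixed
anywhere authoritative; lexicographic is the default because it is
explainable ("biggest relevant clade first, tightest on ties"), and a
`product` score (hits × fraction) is exposed as the alternative.  Neither is
claimed to replicate any particular viewer's formula.

## Flights

Scale interpolates geometrically and the centre linearly against log-scale
progress, giving constant perceived zoom speed; the frame count is
`ceil(|log₂(s_end/s_start)| · frames_per_doubling)` with a minimum of 2 and
exact endpoints.  No geodesic zoom-out-then-in path is attempted.

## Synthetic data

The Yule (pure-birth) generator is the package's test substrate: with k
lineages the wait to the next split is Exponential(k·λ), the splitting
lineage is chosen uniformly, and the process stops at the n-th lineage
birth, making the tree ultrametric with stem-origin age Σ_{k=1..n−1}
Exp(k·λ) — mean Σ 1/k ≈ 2.593 at n = 8, λ = 1, which the suite and the
acceptance script verify by Monte Carlo (2,000 replicates, 4-SE band).  A
`balance_bias` b weights lineage choice by `(1+depth)^γ`, γ = 6(2b−1):
b = 0.5 is the exact uniform process, b → 1 produces caterpillar-like
stress topologies, b → 0 balanced ones.  The biased path is O(n) per split
and intended for small trees.  All randomness uses numpy's PCG64, so seeds
reproduce across platforms.

What the generator does *not* emulate: extinction, rate variation,
calibrated timescales, realistic taxon names or patchy metadata.  Passing
tests therefore demonstrate geometric and algorithmic correctness and
scalability on Yule-shaped trees, not fidelity to any empirical phylogeny;
real trees enter through the Newick reader, which the suite cross-checks
against an independent parser (dendropy) on path-length sums.

## Numerical and policy choices

* Scene JSON serializes numbers rounded to 1e-9; Newick lengths round-trip
  via shortest-repr floats (exact).
* Metadata panels are inscribed at 0.8 of the branch rectangle with a crude
  0.62 em/char width model — guaranteed inside the element's own bbox, which
  is the tested invariant; typographic beauty is not.
* Degenerate subtree boxes (zero extent) are padded by 1e-12 in zoom
  targeting to avoid division by zero.
* The problem sizes exercised by the default suite and acceptance run
  (20 × 100 culling pairs at 64–1,024 tips, one 100,000-tip layout, 2,000
  Yule replicates) were chosen as the smallest scales at which the scaling
  claims are non-trivially exercised; the full run completes in well under a
  minute on one CPU.

## Known limitations

* Fractal forms can self-overlap at extreme angle/ratio combinations; no
  planarity guarantee is attempted.
* The interactive HTML reimplements culling/search in embedded JS from the
  same constants; its rendering is canvas-based and approximates the SVG
  styling (no metadata panels beyond balance numbers and ages).
* `search` is substring-only by design; no fuzzy or phonetic matching.
* SVG output is a static snapshot of one viewport; it is not the zooming
  deliverable, the HTML export is.
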