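import math
import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from phylozoom import (LayoutParams, SimParams, Viewport, annotate,
                       compute_layout, parse_newick, resolve_polytomies,
                       scene_bounds, simulate_yule, zoom_to_node)


@pytest.fixture
def cherry_tree():
    return annotate(parse_newick("(A:1,B:1):1;"))


@pytest.fixture
def spiral_params():
    return LayoutParams.preset("spiral")


def make_yule(n, seed=0, bias=0.5):
    tree = simulate_yule(SimParams(n_tips=n, seed=seed, balance_bias=bias))
    resolve_polytomies(tree)
    annotate(tree)
    return tree


def make_caterpillar(n):
    """Maximally unbalanced dated tree, built iteratively (depth n-1)."""
    from phylozoom.tree_io import Node, Tree

    cur = Node(children=[Node("t1", 1.0), Node("t2", 1.0)])
    for i in range(3, n + 1):
        cur.length = 1.0
        cur = Node(children=[cur, Node(f"t{i}", 1.0)])
    return annotate(Tree(cur))


def make_scene(n, seed=0, form="spiral"):
    tree = make_yule(n, seed)
    return tree, compute_layout(tree, LayoutParams.preset(form))


def random_viewports(scene, count, seed, screen=(800.0, 600.0)):
    """Random viewports spanning home-scale to deep zoom, for culling tests."""
    rng = random.Random(seed)
    b = scene_bounds(scene)
    bw = max(b[2] - b[0], 1e-9)
    bh = max(b[3] - b[1], 1e-9)
    home_scale = min(screen[0] / bw, screen[1] / bh)
    out = []
    for _ in range(count):
        cx = rng.uniform(b[0], b[2])
        cy = rng.uniform(b[1], b[3])
        scale = home_scale * 10 ** rng.uniform(-0.7, 4.0)
        out.append(Viewport(center=(cx, cy), scale=scale, screen=screen))
    return out


def brute_force_visible(scene, vp, thresholds=None):
    """Independent per-element culling oracle: no pruning, no shared code path."""
    from phylozoom.viewport import DEFAULT_THRESHOLDS
    t = thresholds or DEFAULT_THRESHOLDS
    hw = vp.screen[0] / (2.0 * vp.scale)
    hh = vp.screen[1] / (2.0 * vp.scale)
    rect = (vp.center[0] - hw, vp.center[1] - hh,
            vp.center[0] + hw, vp.center[1] + hh)
    out = []
    for i, bb in enumerate(scene.bboxes):
        if bb[0] > rect[2] or rect[0] > bb[2] or bb[1] > rect[3] or rect[1] > bb[3]:
            continue
        size = max(bb[2] - bb[0], bb[3] - bb[1]) * vp.scale
        if size >= t["shape+label+metadata"]:
            level = "shape+label+metadata"
        elif size >= t["shape+label"]:
            level = "shape+label"
        elif size >= t["shape"]:
            level = "shape"
        else:
            continue
        out.append((i, level))
    return out
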