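"""Static single-file HTML explorer template.

The exported file embeds the Newick text, the precomputed scene JSON and a
fixed vanilla-JS script implementing the same culling, search-ranking and
flight rules as the library (same thresholds, same bbox tests), rendering to
a canvas.  It references nothing outside itself, so the file works offline.

Substituted placeholders: ``$title``, ``$newick``, ``$payload``.
Only ``string.Template`` placeholders are used, so the JS below must avoid
bare ``$`` characters.
"""

HTML_TEMPLATE = r"""<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>$title</title>
<style>
 html, body { margin: 0; height: 100%; overflow: hidden;
              font-family: sans-serif; background: #fdfdf8; }
 #bar { position: absolute; top: 8px; left: 8px; z-index: 2; }
 #q { padding: 4px 8px; font-size: 14px; width: 220px; }
 #info { position: absolute; bottom: 8px; left: 8px; z-index: 2;
         font-size: 12px; color: #555; }
 canvas { display: block; }
</style>
</head>
<body>
<div id="bar"><input id="q" placeholder="search tips, Enter to fly"></div>
<div id="info"></div>
<canvas id="view"></canvas>
<script type="text/x-newick" id="tree-data">$newick</script>
<script type="application/json" id="scene-data">$payload</script>
<script>
"use strict";
(function () {
  var payload = JSON.parse(document.getElementById("scene-data").textContent);
  var els = payload.scene.elements;
  var style = payload.style;
  var TH = payload.thresholds;
  var canvas = document.getElementById("view");
  var ctx = canvas.getContext("2d");
  var info = document.getElementById("info");

  /* viewport state: world center, pixels per world unit */
  var vp = { cx: 0, cy: 0, scale: 1 };
  var highlightSet = null;

  function sceneBounds() { return els[0].subtree_bbox; }

  function fitHome() {
    var b = sceneBounds();
    var bw = Math.max(b[2] - b[0], 1e-12), bh = Math.max(b[3] - b[1], 1e-12);
    vp.scale = 0.95 * Math.min(canvas.width / bw, canvas.height / bh);
    vp.cx = (b[0] + b[2]) / 2; vp.cy = (b[1] + b[3]) / 2;
  }

  function resize() {
    canvas.width = window.innerWidth; canvas.height = window.innerHeight;
    draw();
  }

  function wx(x) { return (x - vp.cx) * vp.scale + canvas.width / 2; }
  function wy(y) { return canvas.height / 2 - (y - vp.cy) * vp.scale; }

  function viewRect() {
    var hw = canvas.width / (2 * vp.scale), hh = canvas.height / (2 * vp.scale);
    return [vp.cx - hw, vp.cy - hh, vp.cx + hw, vp.cy + hh];
  }

  function intersects(a, b) {
    return a[0] <= b[2] && b[0] <= a[2] && a[1] <= b[3] && b[1] <= a[3];
  }

  function drawBranch(el, size) {
    var sx = wx(el.start[0]), sy = wy(el.start[1]);
    var len = el.length * vp.scale, wid = el.width * vp.scale;
    if (el.style === "polytomy" && style.polytomy_style === "suppress") { return; }
    ctx.save();
    ctx.translate(sx, sy);
    ctx.rotate(-el.bearing);
    var fill = el.fill || (highlightSet && highlightSet.has(el.idx)
               ? style.highlight_color
               : (el.style === "polytomy" ? style.polytomy_color : style.branch_color));
    ctx.fillStyle = fill;
    ctx.fillRect(-wid / 2, -len, wid, len);
    if (size >= TH.label && el.label) {
      ctx.fillStyle = style.text_color;
      ctx.font = Math.max(9, wid * 0.35) + "px sans-serif";
      ctx.textAlign = "center";
      ctx.fillText(el.label, 0, -len / 2, wid * 3);
    }
    if (size >= TH.metadata && el.info) {
      var lines = [];
      if (el.info.children_tips) { lines.push(el.info.children_tips.join(" | ")); }
      if (el.info.date !== undefined) { lines.push("age " + el.info.date.toFixed(3)); }
      ctx.fillStyle = style.text_color;
      ctx.font = Math.max(10, wid * 0.25) + "px sans-serif";
      ctx.textAlign = "center";
      for (var k = 0; k < lines.length; k++) {
        ctx.fillText(lines[k], 0, -len * 0.25 + 14 * k, wid * 3);
      }
    }
    ctx.restore();
  }

  function drawLeaf(el, size) {
    var cx = wx(el.center[0]), cy = wy(el.center[1]);
    var r = el.radius * vp.scale;
    ctx.beginPath();
    ctx.arc(cx, cy, r, 0, 2 * Math.PI);
    ctx.fillStyle = el.fill || (highlightSet && highlightSet.has(el.idx)
                    ? style.highlight_color : style.leaf_color);
    ctx.fill();
    if (size >= TH.label && el.label) {
      ctx.fillStyle = style.text_color;
      ctx.font = Math.max(9, r * 0.3) + "px sans-serif";
      ctx.textAlign = "center";
      ctx.fillText(el.label, cx, cy, 2 * r);
    }
    if (size >= TH.metadata && el.info) {
      ctx.fillStyle = style.text_color;
      ctx.font = Math.max(9, r * 0.18) + "px sans-serif";
      var j = 1;
      for (var key in el.info) {
        ctx.fillText(key + ": " + el.info[key], cx, cy + j * r * 0.25, 2 * r);
        j++;
      }
    }
  }

  /* child index lists precomputed once */
  var kids = [];
  (function () {
    for (var i = 0; i < els.length; i++) { kids.push([]); }
    for (var i = 1; i < els.length; i++) { kids[els[i].parent].push(i); }
  })();

  /* culled draw: prune subtrees by subtree bbox, exactly as the library */
  function draw() {
    ctx.fillStyle = style.background;
    ctx.fillRect(0, 0, canvas.width, canvas.height);
    var rect = viewRect();
    var stack = [0];
    var drawn = 0;
    while (stack.length) {
      var i = stack.pop();
      var el = els[i];
      var sb = el.subtree_bbox;
      if (!intersects(sb, rect)) { continue; }
      if (Math.max(sb[2] - sb[0], sb[3] - sb[1]) * vp.scale < TH.shape) { continue; }
      var bb = el.bbox;
      if (intersects(bb, rect)) {
        var size = Math.max(bb[2] - bb[0], bb[3] - bb[1]) * vp.scale;
        if (size >= TH.shape) {
          el.idx = i;
          if (el.type === "branch") { drawBranch(el, size); }
          else { drawLeaf(el, size); }
          drawn++;
        }
      }
      var ks = kids[i];
      for (var c = ks.length - 1; c >= 0; c--) { stack.push(ks[c]); }
    }
    info.textContent = payload.meta.n_tips + " tips, " + drawn +
      " elements drawn, scale " + vp.scale.toExponential(2);
  }

  /* pan and zoom */
  var dragging = false, lastX = 0, lastY = 0;
  canvas.addEventListener("mousedown", function (e) {
    dragging = true; lastX = e.clientX; lastY = e.clientY;
  });
  window.addEventListener("mouseup", function () { dragging = false; });
  window.addEventListener("mousemove", function (e) {
    if (!dragging) { return; }
    vp.cx -= (e.clientX - lastX) / vp.scale;
    vp.cy += (e.clientY - lastY) / vp.scale;
    lastX = e.clientX; lastY = e.clientY;
    draw();
  });
  canvas.addEventListener("wheel", function (e) {
    e.preventDefault();
    var f = Math.pow(1.0015, -e.deltaY);
    var mx = e.clientX - canvas.width / 2, my = e.clientY - canvas.height / 2;
    var wx0 = vp.cx + mx / vp.scale, wy0 = vp.cy - my / vp.scale;
    vp.scale *= f;
    vp.cx = wx0 - mx / vp.scale;
    vp.cy = wy0 + my / vp.scale;
    draw();
  }, { passive: false });

  /* search: substring match on tip labels + metadata, rank clades by
     (hits desc, tip fraction desc, clade size asc), fly to the winner */
  function fold(s) { return s.toLowerCase(); }
  function searchAndFly(q) {
    q = fold(q.trim());
    if (!q) { return; }
    var hc = new Array(els.length).fill(0);
    for (var i = 0; i < els.length; i++) {
      var el = els[i];
      if (el.type !== "leaf") { continue; }
      var hit = fold(el.label || "").indexOf(q) >= 0;
      if (!hit && el.info) {
        for (var key in el.info) {
          if (fold(String(el.info[key])).indexOf(q) >= 0) { hit = true; break; }
        }
      }
      if (hit) {
        var j = el.parent;
        hc[i] = 1;
        while (j !== null) { hc[j]++; j = els[j].parent; }
      }
    }
    var best = -1, bh = 0, bf = 0, bt = Infinity;
    for (var i = 0; i < els.length; i++) {
      if (els[i].type !== "branch" || hc[i] === 0) { continue; }
      var tips = (els[i].info && els[i].info.tips) || 1;
      var f = hc[i] / tips;
      if (hc[i] > bh || (hc[i] === bh && (f > bf || (f === bf && tips < bt)))) {
        best = i; bh = hc[i]; bf = f; bt = tips;
      }
    }
    highlightSet = new Set();
    for (var i = 0; i < els.length; i++) { if (hc[i] > 0) { highlightSet.add(i); } }
    if (best >= 0) { flyTo(best); } else { draw(); }
  }

  function flyTo(i) {
    var b = els[i].subtree_bbox;
    var bw = Math.max(b[2] - b[0], 1e-12), bh2 = Math.max(b[3] - b[1], 1e-12);
    var endScale = 0.9 * Math.min(canvas.width / bw, canvas.height / bh2);
    var endCx = (b[0] + b[2]) / 2, endCy = (b[1] + b[3]) / 2;
    var s0 = vp.scale, c0x = vp.cx, c0y = vp.cy;
    var doublings = Math.abs(Math.log(endScale / s0) / Math.LN2);
    var n = Math.max(2, Math.ceil(doublings * 6));
    var frame = 0;
    function step() {
      frame++;
      var t = frame / (n - 1);
      if (t >= 1) {
        vp.scale = endScale; vp.cx = endCx; vp.cy = endCy; draw(); return;
      }
      vp.scale = s0 * Math.pow(endScale / s0, t);
      vp.cx = c0x + (endCx - c0x) * t;
      vp.cy = c0y + (endCy - c0y) * t;
      draw();
      window.requestAnimationFrame(step);
    }
    step();
  }

  document.getElementById("q").addEventListener("keydown", function (e) {
    if (e.key === "Enter") { searchAndFly(e.target.value); }
  });
  window.addEventListener("resize", resize);
  canvas.width = window.innerWidth; canvas.height = window.innerHeight;
  fitHome();
  draw();
})();
</script>
</body>
</html>
"""
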