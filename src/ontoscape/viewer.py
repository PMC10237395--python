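"""Standalone interactive HTML export.

Emits one self-contained HTML file with the scene embedded as a JSON data
block and a small hand-written canvas renderer: orbit (drag), zoom (wheel),
pan (shift-drag), click-to-highlight in red with a context panel, and label /
wireframe toggles.  The viewer performs no layout — positions, colors, sizes
and thicknesses come verbatim from the scene — and the camera orbits about
the scene's vertical axis so "up" always stays up.  No network resources are
referenced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .scene import Scene, _scene_to_dict

__all__ = ["ViewerOptions", "render_html"]


@dataclass
class ViewerOptions:
    show_labels: bool = True
    label_backdrop: bool = True
    wireframe: bool = False
    #: optional distance beyond which labels are culled; None = never
    label_distance_cutoff: float | None = None


_TEMPLATE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>ontoscape scene</title>
<style>
 body {{ margin:0; background:#101018; color:#ddd; font:13px sans-serif; overflow:hidden; }}
 #panel {{ position:absolute; top:8px; left:8px; background:rgba(20,20,32,.85);
          padding:8px 12px; border-radius:6px; max-width:340px; }}
 #legend {{ position:absolute; top:8px; right:8px; background:rgba(20,20,32,.85);
           padding:8px 12px; border-radius:6px; }}
 .sw {{ display:inline-block; width:10px; height:10px; margin-right:6px; }}
 canvas {{ display:block; }}
 label {{ margin-right:10px; }}
</style>
</head>
<body>
<canvas id="c"></canvas>
<div id="panel">
 <div>
  <label><input type="checkbox" id="labels" {labels_checked}> labels</label>
  <label><input type="checkbox" id="wire" {wire_checked}> wireframe</label>
 </div>
 <div id="info">drag = orbit, wheel = zoom, shift-drag = pan, click = select</div>
</div>
<div id="legend">{legend_html}</div>
<script id="scene-data" type="application/json">
{scene_json}
</script>
<script>
"use strict";
var SCENE = JSON.parse(document.getElementById("scene-data").textContent);
var OPTS = {options_json};
var canvas = document.getElementById("c"), ctx = canvas.getContext("2d");
var yaw = 0.6, pitch = 0.35, dist = 1600, panX = 0, panY = 0;
var selected = null;
var HIGHLIGHT = "rgb(255,0,0)";  /* clicked node highlight: red */
var center = [0, 0, 0];
(function () {{
  var n = SCENE.nodes.length;
  if (!n) return;
  var s = [0, 0, 0];
  SCENE.nodes.forEach(function (nd) {{
    s[0] += nd.position[0]; s[1] += nd.position[1]; s[2] += nd.position[2];
  }});
  center = [s[0] / n, s[1] / n, s[2] / n];
}})();
function project(p) {{
  var x = p[0] - center[0], y = p[1] - center[1], z = p[2] - center[2];
  var cx = Math.cos(yaw), sx = Math.sin(yaw);
  var X = cx * x + sx * z, Z = -sx * x + cx * z;
  var cp = Math.cos(pitch), sp = Math.sin(pitch);
  var Y = cp * y - sp * Z, Zc = sp * y + cp * Z + dist;
  if (Zc < 1) Zc = 1;
  var f = 900 / Zc;
  return [canvas.width / 2 + (X * f) + panX,
          canvas.height / 2 - (Y * f) + panY, f];
}}
var pos2d = [];
function draw() {{
  canvas.width = window.innerWidth; canvas.height = window.innerHeight;
  ctx.clearRect(0, 0, canvas.width, canvas.height);
  var byIri = {{}};
  pos2d = [];
  SCENE.nodes.forEach(function (nd) {{
    var pr = project(nd.position);
    byIri[nd.iri] = pr;
    pos2d.push([pr[0], pr[1], nd]);
  }});
  var wire = document.getElementById("wire").checked;
  SCENE.edges.forEach(function (e) {{
    var a = byIri[e.child_iri], b = byIri[e.parent_iri];
    if (!a || !b) return;
    ctx.strokeStyle = "rgba(" + e.color.join(",") + ",0.55)";
    var t = e.thickness;
    var scaffold = t > 1 && SCENE.nodes.some(function (nd) {{
      return nd.iri === e.child_iri && nd.pinned;
    }});
    ctx.lineWidth = wire && !scaffold ? 1 : t * Math.max(a[2], 0.2);
    ctx.beginPath(); ctx.moveTo(a[0], a[1]); ctx.lineTo(b[0], b[1]); ctx.stroke();
  }});
  var showLabels = document.getElementById("labels").checked;
  SCENE.nodes.forEach(function (nd) {{
    var pr = byIri[nd.iri];
    var r = nd.size * pr[2];
    ctx.fillStyle = nd.iri === selected ? HIGHLIGHT : "rgb(" + nd.color.join(",") + ")";
    ctx.beginPath(); ctx.arc(pr[0], pr[1], Math.max(r, 1.2), 0, 6.2832); ctx.fill();
    if (showLabels && nd.label && (pr[2] > 0.45 || nd.iri === selected)) {{
      if (OPTS.label_backdrop && !wire) {{
        ctx.fillStyle = "rgba(0,0,0,0.5)";
        var w = ctx.measureText(nd.label).width;
        ctx.fillRect(pr[0] + r + 2, pr[1] - 9, w + 4, 13);
      }}
      ctx.fillStyle = "#eee";
      ctx.fillText(nd.label, pr[0] + r + 4, pr[1] + 2);
    }}
  }});
}}
canvas.addEventListener("mousedown", function (ev) {{
  var sx = ev.clientX, sy = ev.clientY, moved = false;
  function mm(e) {{
    moved = true;
    if (e.shiftKey) {{ panX += e.clientX - sx; panY += e.clientY - sy; }}
    else {{ yaw += (e.clientX - sx) * 0.008; pitch += (e.clientY - sy) * 0.008;
            pitch = Math.max(-1.4, Math.min(1.4, pitch)); }}
    sx = e.clientX; sy = e.clientY; draw();
  }}
  function mu(e) {{
    window.removeEventListener("mousemove", mm);
    window.removeEventListener("mouseup", mu);
    if (!moved) pick(e.clientX, e.clientY);
  }}
  window.addEventListener("mousemove", mm);
  window.addEventListener("mouseup", mu);
}});
canvas.addEventListener("wheel", function (e) {{
  dist *= e.deltaY > 0 ? 1.1 : 0.9; dist = Math.max(50, dist); draw(); e.preventDefault();
}});
function pick(x, y) {{
  var best = null, bestD = 144;
  pos2d.forEach(function (p) {{
    var d = (p[0] - x) * (p[0] - x) + (p[1] - y) * (p[1] - y);
    if (d < bestD) {{ bestD = d; best = p[2]; }}
  }});
  selected = best ? best.iri : null;
  var info = document.getElementById("info");
  if (best) {{
    var kids = SCENE.edges.filter(function (e) {{ return e.parent_iri === best.iri; }}).length;
    var par = SCENE.edges.filter(function (e) {{ return e.child_iri === best.iri; }})
      .map(function (e) {{ return e.parent_iri; }});
    info.innerHTML = "<b>" + (best.label || best.iri) + "</b><br>" +
      best.prefix + " &middot; depth " + best.depth +
      (best.deprecated ? " &middot; deprecated" : "") +
      "<br>children: " + kids + (par.length ? "<br>parent: " + par[0] : "");
  }} else {{
    info.textContent = "drag = orbit, wheel = zoom, shift-drag = pan, click = select";
  }}
  draw();
}}
document.getElementById("labels").addEventListener("change", draw);
document.getElementById("wire").addEventListener("change", draw);
window.addEventListener("resize", draw);
draw();
</script>
</body>
</html>
"""


def _legend_html(scene: Scene) -> str:
    rows = []
    for e in scene.legend:
        rows.append(
            f'<div><span class="sw" style="background:rgb({e.color[0]},'
            f'{e.color[1]},{e.color[2]})"></span>{e.prefix}: {e.term_count}</div>'
        )
    return "\n".join(rows)


def render_html(
    scene: Scene, options: ViewerOptions | None = None, path: str | Path = "scene.html"
) -> Path:
    """Write a single self-contained HTML viewer for a scene.

    The embedded data block is byte-identical for byte-identical scenes;
    the viewer never recomputes positions or styling.
    """
    options = options or ViewerOptions()
    try:
        scene_json = json.dumps(_scene_to_dict(scene), indent=0, allow_nan=False)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"scene is not serializable: {exc}") from exc
    html = _TEMPLATE.format(
        scene_json=scene_json,
        options_json=json.dumps(
            {
                "label_backdrop": options.label_backdrop,
                "label_distance_cutoff": options.label_distance_cutoff,
            }
        ),
        labels_checked="checked" if options.show_labels else "",
        wire_checked="checked" if options.wireframe else "",
        legend_html=_legend_html(scene),
    )
    path = Path(path)
    path.write_text(html)
    return path
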