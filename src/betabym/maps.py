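"""Choropleth reporting: static figures and a self-contained interactive HTML map.

Values are binned into ordered color classes (quantile breaks by default,
explicit cut points for cross-run comparability) on a light-to-red palette:
red marks the highest-burden areas. The interactive document embeds the
polygon payload (GeoJSON with per-area tooltip fields and precomputed fill
colors) directly in the HTML and renders it with a small inline script, so
it opens offline and its content can be verified by parsing the file.
"""

from __future__ import annotations

import html
import json
import logging
from dataclasses import dataclass

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.collections import PatchCollection
from matplotlib.patches import Patch
from matplotlib.path import Path as MplPath
from matplotlib.patches import PathPatch

from .data_io import IntegrityError, PolygonSet
from .postprocess import FitResult

logger = logging.getLogger("betabym")

__all__ = ["MapLayer", "quantile_breaks", "render_static_map", "render_interactive_map"]

# light -> red, 5 classes (ColorBrewer 'Reds' style)
DEFAULT_PALETTE = ("#fee5d9", "#fcae91", "#fb6a4a", "#de2d26", "#a50f15")


def quantile_breaks(values: np.ndarray, n_classes: int = 5) -> np.ndarray:
    """Strictly increasing interior quantile cut points (may yield fewer classes)."""
    qs = np.linspace(0, 1, n_classes + 1)[1:-1]
    return np.unique(np.quantile(np.asarray(values, float), qs))


@dataclass
class MapLayer:
    polygons: PolygonSet
    values: np.ndarray
    legend_title: str
    palette: tuple[str, ...] = DEFAULT_PALETTE
    class_breaks: np.ndarray | int = 5  # quantile count or explicit interior cuts

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.polygons):
            raise IntegrityError("values not aligned with polygons")
        if isinstance(self.class_breaks, int):
            self.class_breaks = quantile_breaks(self.values, self.class_breaks)
        else:
            self.class_breaks = np.asarray(self.class_breaks, dtype=float)
            if np.any(np.diff(self.class_breaks) <= 0):
                raise ValueError("class breaks must be strictly increasing")

    def classes(self) -> np.ndarray:
        """Class index per area; monotone in the mapped value."""
        return np.searchsorted(self.class_breaks, self.values, side="right")

    def colors(self) -> list[str]:
        n_classes = len(self.class_breaks) + 1
        pal = list(self.palette)
        if n_classes > len(pal):
            raise ValueError("palette has fewer colors than classes")
        # spread the palette across however many classes survive deduplication
        take = np.linspace(0, len(pal) - 1, n_classes).round().astype(int)
        pal = [pal[i] for i in take]
        return [pal[c] for c in self.classes()]

    def legend_labels(self) -> list[str]:
        edges = [-np.inf, *self.class_breaks, np.inf]
        labels = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            if np.isinf(lo):
                labels.append(f"< {hi:.3g}" if not np.isinf(hi) else "all values")
            elif np.isinf(hi):
                labels.append(f">= {lo:.3g}")
            else:
                labels.append(f"{lo:.3g} - {hi:.3g}")
        return labels


def _geom_to_path(geom) -> MplPath:
    polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    vertices, codes = [], []
    for poly in polys:
        for ring in [poly.exterior, *poly.interiors]:
            pts = np.asarray(ring.coords)
            vertices.extend(pts)
            codes.extend([MplPath.MOVETO] + [MplPath.LINETO] * (len(pts) - 2) + [MplPath.CLOSEPOLY])
    return MplPath(vertices, codes)


def render_static_map(layer: MapLayer, path) -> None:
    """Write a PNG or SVG choropleth with legend; SVG output is deterministic."""
    plt.rcParams["svg.hashsalt"] = "betabym"
    fig, ax = plt.subplots(figsize=(7, 6))
    colors = layer.colors()
    patches = [PathPatch(_geom_to_path(g)) for g in layer.polygons.geometry]
    coll = PatchCollection(patches, facecolor=colors, edgecolor="#555555", linewidth=0.5)
    ax.add_collection(coll)
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_axis_off()
    # legend: one patch per class in palette order
    n_classes = len(layer.class_breaks) + 1
    take = np.linspace(0, len(layer.palette) - 1, n_classes).round().astype(int)
    handles = [
        Patch(facecolor=layer.palette[i], edgecolor="#555555", label=lbl)
        for i, lbl in zip(take, layer.legend_labels())
    ]
    ax.legend(handles=handles, title=layer.legend_title, loc="lower left", fontsize=8)
    fmt = str(path).rsplit(".", 1)[-1].lower()
    meta = {"Date": None} if fmt == "svg" else {}
    fig.savefig(path, metadata=meta, dpi=150)
    plt.close(fig)
    logger.info("wrote static map to %s", path)


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
 body {{ font-family: sans-serif; margin: 0; }}
 #map {{ width: 100vw; height: 90vh; }}
 #tooltip {{ position: fixed; display: none; background: #fff; border: 1px solid #888;
            padding: 6px 8px; font-size: 12px; pointer-events: none; white-space: pre; }}
 .legend {{ position: fixed; bottom: 8px; left: 8px; background: #fff;
           border: 1px solid #888; padding: 6px 8px; font-size: 12px; }}
 .legend span.swatch {{ display: inline-block; width: 14px; height: 11px;
                       margin-right: 4px; border: 1px solid #555; }}
 path.area {{ stroke: #555; stroke-width: 0.003; }}
 path.area:hover {{ stroke-width: 0.01; }}
</style></head>
<body>
<h3 style="margin:6px">{title}</h3>
<svg id="map" viewBox="{viewbox}" preserveAspectRatio="xMidYMid meet"></svg>
<div id="tooltip"></div>
<div class="legend"><b>{legend_title}</b><br>{legend_html}</div>
<script id="payload" type="application/json">{payload}</script>
<script>
var data = JSON.parse(document.getElementById("payload").textContent);
var svg = document.getElementById("map");
var tip = document.getElementById("tooltip");
data.features.forEach(function (f) {{
  var p = document.createElementNS("http://www.w3.org/2000/svg", "path");
  p.setAttribute("d", f.properties.svg_path);
  p.setAttribute("fill", f.properties.fill);
  p.setAttribute("class", "area");
  p.addEventListener("mousemove", function (ev) {{
    tip.style.display = "block";
    tip.style.left = (ev.clientX + 12) + "px";
    tip.style.top = (ev.clientY + 12) + "px";
    tip.textContent = f.properties.tooltip;
  }});
  p.addEventListener("mouseleave", function () {{ tip.style.display = "none"; }});
  svg.appendChild(p);
}});
</script>
</body></html>
"""


def _svg_path(geom, ymax: float) -> str:
    polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    parts = []
    for poly in polys:
        for ring in [poly.exterior, *poly.interiors]:
            pts = [f"{x:.6g},{ymax - y:.6g}" for x, y in ring.coords]
            parts.append("M" + "L".join(pts) + "Z")
    return "".join(parts)


def _tooltip_text(row, covariates) -> str:
    lines = [
        str(row["area_name"]),
        f"observed: {100 * row['observed']:.1f}%",
        f"predicted: {100 * row['predicted']:.1f}%",
        f"95% CrI: {100 * row['q2.5']:.1f}% - {100 * row['q97.5']:.1f}%",
    ]
    for name, value in covariates:
        lines.append(f"{name}: {value:.1f}")
    return "\n".join(lines)


def render_interactive_map(
    fit: FitResult,
    polygons: PolygonSet,
    path,
    layer_choice: str = "predicted",
    palette: tuple[str, ...] = DEFAULT_PALETTE,
    class_breaks=5,
    covariate_values: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a self-contained interactive choropleth HTML document.

    ``layer_choice`` is 'predicted', 'sd', or 'exceed_<t>' for an exceedance
    layer (e.g. 'exceed_0.7'). Hovering an area shows its county name,
    observed and predicted prevalence, the 95% CrI bounds, and the values of
    any significant risk factors (or those passed in covariate_values).
    """
    areas = fit.areas
    aligned = polygons.aligned_to(list(areas.index))
    if layer_choice not in areas.columns:
        raise ValueError(f"unknown layer '{layer_choice}'; have {list(areas.columns)}")
    values = areas[layer_choice].to_numpy(dtype=float)
    layer = MapLayer(aligned, values, layer_choice, palette, class_breaks)
    colors = layer.colors()
    classes = layer.classes()

    if covariate_values is None:
        covariate_values = {}

    bounds = np.array([g.bounds for g in aligned.geometry])
    xmin, ymin = bounds[:, 0].min(), bounds[:, 1].min()
    xmax, ymax = bounds[:, 2].max(), bounds[:, 3].max()

    features = []
    for i, aid in enumerate(areas.index):
        row = areas.loc[aid]
        covs = [(name, float(vals[i])) for name, vals in covariate_values.items()]
        props = {
            "area_id": str(aid),
            "area_name": str(row["area_name"]),
            "observed_pct": round(100 * float(row["observed"]), 1),
            "predicted_pct": round(100 * float(row["predicted"]), 1),
            "cri_lower_pct": round(100 * float(row["q2.5"]), 1),
            "cri_upper_pct": round(100 * float(row["q97.5"]), 1),
            "value": float(values[i]),
            "color_class": int(classes[i]),
            "fill": colors[i],
            "tooltip": _tooltip_text(row, covs),
            "svg_path": _svg_path(aligned.geometry[i], ymax + ymin),
        }
        for name, val in covs:
            props[name] = round(val, 1)
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": json.loads(json.dumps(shapely_mapping(aligned.geometry[i]))),
            }
        )

    payload = {"type": "FeatureCollection", "layer": layer_choice, "features": features}
    n_classes = len(layer.class_breaks) + 1
    take = np.linspace(0, len(palette) - 1, n_classes).round().astype(int)
    legend_html = "<br>".join(
        f'<span class="swatch" style="background:{palette[i]}"></span>{html.escape(lbl)}'
        for i, lbl in zip(take, layer.legend_labels())
    )
    doc = _HTML_TEMPLATE.format(
        title=f"betabym choropleth: {html.escape(layer_choice)}",
        legend_title=html.escape(layer_choice),
        legend_html=legend_html,
        viewbox=f"{xmin:.6g} {ymin:.6g} {xmax - xmin:.6g} {ymax - ymin:.6g}",
        payload=json.dumps(payload),
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(doc)
    logger.info("wrote interactive map to %s", path)


def shapely_mapping(geom):
    import shapely.geometry

    return shapely.geometry.mapping(geom)
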