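"""Poincaré-disk projection, HSV color coding and cluster-map rendering.

The lattice is projected onto the open unit disk (Poincaré model), a
hue-saturation disk assigns each node a color — hue from its angle (plus a
user rotation), saturation from its radius, value fixed at 1 — and every
pixel of a segmentation map is painted with the color of its assigned
node. Because nearby lattice nodes carry similar molecular profiles, the
color code is topology preserving: similar profiles get similar colors.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .h2som import ClusterAssignment, H2SOMModel, HyperbolicLattice
from .io import MSIDataset

__all__ = [
    "ColorMap",
    "SegmentationMap",
    "poincare_positions",
    "colorize",
    "render_cluster_map",
    "export_cluster_profiles",
    "export_json",
]


@dataclass
class ColorMap:
    """Node id -> (hue, saturation, value) with the rotation that made it."""

    hsv: dict[int, tuple[float, float, float]]
    rotation: float

    def rgba(self, node_id: int) -> tuple[int, int, int, int]:
        h, s, v = self.hsv[node_id]
        r, g, b = colorsys.hsv_to_rgb(h, s, v)
        return (int(round(r * 255)), int(round(g * 255)),
                int(round(b * 255)), 255)


@dataclass
class SegmentationMap:
    """RGBA raster of one dataset at one hierarchy level, plus a legend."""

    raster: np.ndarray            # (ny, nx, 4) uint8
    legend: dict[int, tuple[int, int, int, int]]
    time_point: int
    level: int

    def save_png(self, path) -> None:
        from PIL import Image

        Image.fromarray(self.raster, mode="RGBA").save(path)


def poincare_positions(
        lattice: HyperbolicLattice) -> dict[int, tuple[float, float]]:
    """Project lattice nodes into the open unit disk.

    A node at hyperbolic radius rho maps to Euclidean radius tanh(rho / 2)
    at its own angle, so the root lands at the origin, every node stays
    strictly inside the disk, and deeper rings sit at larger radii.
    """
    out = {}
    for node in lattice.nodes:
        r = float(np.tanh(node.rho / 2.0))
        out[node.id] = (r * float(np.cos(node.angle)),
                        r * float(np.sin(node.angle)))
    return out


def colorize(positions: dict[int, tuple[float, float]],
             rotation: float = 0.0) -> ColorMap:
    """Color nodes from the hue-saturation disk underneath them.

    hue = (angle + rotation) / 2π mod 1; saturation = |z| scaled so the
    outermost ring reaches 1; value = 1. The root is achromatic. Rotating
    by 2π reproduces the identical map.
    """
    radii = {nid: float(np.hypot(x, y)) for nid, (x, y) in positions.items()}
    rmax = max(radii.values()) if radii else 1.0
    hsv = {}
    for nid, (x, y) in positions.items():
        r = radii[nid]
        angle = float(np.arctan2(y, x))
        hue = ((angle + rotation) / (2.0 * np.pi)) % 1.0
        sat = r / rmax if rmax > 0 else 0.0
        hsv[nid] = (hue, sat, 1.0)
    return ColorMap(hsv=hsv, rotation=float(rotation))


def render_cluster_map(assignment: ClusterAssignment, colormap: ColorMap,
                       dataset: MSIDataset, level: int,
                       underlay: np.ndarray | None = None
                       ) -> SegmentationMap:
    """Paint each assigned pixel with its level-ancestor's color.

    Pixels without an assigned profile stay fully transparent (or show the
    optional RGBA ``underlay``, over which assigned colors are composited).
    """
    nx, ny = dataset.grid_shape
    if underlay is not None:
        underlay = np.asarray(underlay, dtype=np.uint8)
        if underlay.shape[:2] != (ny, nx):
            raise ValueError(
                f"underlay shape {underlay.shape[:2]} != grid {(ny, nx)}")
        raster = underlay.copy()
    else:
        raster = np.zeros((ny, nx, 4), dtype=np.uint8)

    ids = assignment.at_level(level)
    sel = assignment.index["t"].to_numpy() == dataset.time_point
    xs = assignment.index["x"].to_numpy()[sel]
    ys = assignment.index["y"].to_numpy()[sel]
    if xs.size and (xs.max() >= nx or ys.max() >= ny):
        raise ValueError("assignment coordinates outside the dataset grid")
    legend: dict[int, tuple[int, int, int, int]] = {}
    for nid in np.unique(ids[sel]):
        legend[int(nid)] = colormap.rgba(int(nid))
    colors = np.array([colormap.rgba(int(n)) for n in ids[sel]],
                      dtype=np.uint8).reshape(-1, 4)
    raster[ys, xs] = colors
    return SegmentationMap(raster=raster, legend=legend,
                           time_point=dataset.time_point, level=level)


def export_cluster_profiles(model: H2SOMModel,
                            assignment: ClusterAssignment,
                            level: int) -> pd.DataFrame:
    """One row per occupied cluster: prototype intensities + member count.

    Empty clusters are omitted; member counts sum to the number of
    profiles.
    """
    ids = assignment.at_level(level)
    mz = model.feature_mz
    cols = ([f"mz_{v:.2f}" for v in mz] if mz is not None else
            [f"feature_{i}" for i in
             range(model.prototypes.shape[1])])
    rows = []
    for nid in np.unique(ids):
        count = int((ids == nid).sum())
        rows.append([int(nid), count] + list(model.prototypes[int(nid)]))
    return pd.DataFrame(rows, columns=["cluster_id", "member_count"] + cols)


def export_json(path, model: H2SOMModel, colormap: ColorMap,
                assignments: ClusterAssignment) -> None:
    """Static export (nodes, positions, colors, prototypes, assignments)
    that an external viewer could consume in place of the interactive tool.
    """
    positions = poincare_positions(model.lattice)
    nodes = []
    for node in model.lattice.nodes:
        x, y = positions[node.id]
        h, s, v = colormap.hsv[node.id]
        nodes.append({
            "id": node.id, "level": node.level, "parent": node.parent,
            "x": x, "y": y, "hue": h, "saturation": s, "value": v,
            "prototype": [float(f) for f in model.prototypes[node.id]],
        })
    payload = {
        "rotation": colormap.rotation,
        "ring_sizes": list(model.lattice.ring_sizes),
        "feature_mz": ([float(v) for v in model.feature_mz]
                       if model.feature_mz is not None else None),
        "nodes": nodes,
        "assignments": assignments.to_frame().to_dict(orient="list"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh,
                  default=lambda o: o.item() if hasattr(o, "item") else str(o))
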