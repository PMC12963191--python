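"""Graded axisymmetric meshes of the layered tissue domain.

The domain is the (r, z) half-section of a disc: r in [0, R] with R the
domain radius, z = 0 at the skin surface increasing with depth through the
layer stack.  Meshes are structured, graded radially (fine under and around
the indenter patch, geometrically coarsening toward the far boundary) and
subdivided into 6-node quadratic triangles.  Element "volume" is the
physical volume of the ring swept by the triangle, area * 2*pi*r_centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np

from .anatomy import AnatomyModel, SOFT_LAYERS

__all__ = ["Mesh", "MeshError", "build_mesh", "tag_roi", "element_volumes", "RESOLUTIONS"]


class MeshError(ValueError):
    pass


#: Resolution presets: radial subdivisions of the loaded patch [0, a],
#: radial geometric growth factor beyond the patch, and through-thickness
#: element counts per named layer.  Counts grow strictly with resolution so
#: the levels nest in node budget.
RESOLUTIONS: Dict[str, dict] = {
    "coarse": {
        "n_patch": 5,
        "growth": 1.5,
        "layer_divisions": {"epidermis": 3, "dermis": 3, "adipose": 4, "muscle": 4, "bone": 3},
    },
    "medium": {
        "n_patch": 8,
        "growth": 1.35,
        "layer_divisions": {"epidermis": 3, "dermis": 5, "adipose": 7, "muscle": 7, "bone": 3},
    },
    "fine": {
        "n_patch": 12,
        "growth": 1.25,
        "layer_divisions": {"epidermis": 4, "dermis": 7, "adipose": 10, "muscle": 10, "bone": 4},
    },
}


@dataclass
class Mesh:
    """Axisymmetric quadratic-triangle mesh with layer and ROI tagging.

    nodes : (nn, 2) float array of (r, z) coordinates in mm.
    elements : (ne, 6) int connectivity; local order is the three corners
        counter-clockwise followed by the midside nodes of edges (0,1),
        (1,2), (2,0).
    layer_tag : (ne,) array of layer names.
    roi_mask : (ne,) bool, True for soft-tissue elements whose centroid lies
        within the region-of-interest radius.
    element_volume : (ne,) physical ring volumes in mm^3.
    """

    nodes: np.ndarray
    elements: np.ndarray
    layer_tag: np.ndarray
    roi_mask: np.ndarray
    element_volume: np.ndarray
    indenter_radius: float
    roi_radius: float
    domain_radius: float
    depth: float
    resolution: str = "custom"

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements[:, :3]].mean(axis=1)

    def corner_coords(self) -> np.ndarray:
        return self.nodes[self.elements[:, :3]]


def _radial_line(a: float, R: float, n_patch: int, growth: float, snap: Sequence[float] = ()) -> np.ndarray:
    """Node radii: uniform spacing h = a/n_patch on [0, a], then geometric
    growth to R, rescaled so the last node lands exactly on R.  Radii in
    ``snap`` (e.g. the ROI radius) are imposed exactly by moving the
    nearest tail node, so region boundaries align with element edges."""
    if R < a:
        raise MeshError("domain radius smaller than indenter radius")
    r = list(np.linspace(0.0, a, n_patch + 1))
    if R == a:
        return np.asarray(r)
    h = a / n_patch
    tail = []
    pos = a
    while pos < R - 1e-12:
        h *= growth
        pos += h
        tail.append(pos)
    if len(tail) < 2:
        tail = [a + (R - a) / 2.0, R]
    # affine rescale of the tail onto (a, R]
    tail = np.asarray(tail)
    tail = a + (tail - a) * (R - a) / (tail[-1] - a)
    for s in snap:
        if a + 1e-9 < s < R - 1e-9:
            tail[np.argmin(np.abs(tail[:-1] - s))] = s
    if np.any(np.diff(tail) <= 0):
        raise MeshError("radial snap produced a non-monotone grid")
    return np.concatenate([r, tail])


def _layer_z_lines(model: AnatomyModel, divisions: Mapping[str, int], default_dz: float) -> Tuple[np.ndarray, list]:
    """z node lines through the stack and per-interval layer names."""
    z = [0.0]
    interval_layers: list = []
    for ly in model.layers:
        n = divisions.get(ly.name)
        if n is None:
            # unnamed/benchmark layer: geometric coarsening with depth
            n = 1
            edges = [0.0]
            h, pos = default_dz, 0.0
            while pos < ly.thickness - 1e-12:
                pos += h
                edges.append(pos)
                h *= 1.3
            edges = np.asarray(edges) * ly.thickness / edges[-1]
            sub = edges[1:]
            n = len(sub)
        else:
            if n < 3:
                raise MeshError(
                    f"layer {ly.name!r}: {n} element layers through the thickness is "
                    "below the minimum of 3; choose a finer resolution"
                )
            sub = np.linspace(0.0, ly.thickness, n + 1)[1:]
        z0 = z[-1]
        z.extend(z0 + s for s in sub)
        interval_layers.extend([ly.name] * len(sub))
    return np.asarray(z), interval_layers


def build_mesh(
    model: AnatomyModel,
    resolution: str = "medium",
    layer_divisions: Mapping[str, int] | None = None,
) -> Mesh:
    """Build the graded axisymmetric quadratic-triangle mesh for a model.

    ``layer_divisions`` overrides the preset through-thickness counts (used
    by benchmark problems with non-standard layer names).
    """
    if resolution not in RESOLUTIONS:
        raise MeshError(f"unknown resolution {resolution!r}; expected one of {list(RESOLUTIONS)}")
    preset = RESOLUTIONS[resolution]
    divisions = dict(preset["layer_divisions"])
    if layer_divisions:
        divisions.update(layer_divisions)

    a = model.indenter_radius
    rline = _radial_line(
        a, model.domain_half_width, preset["n_patch"], preset["growth"], snap=(model.roi_radius,)
    )
    zline, interval_layers = _layer_z_lines(model, divisions, default_dz=a / preset["n_patch"] * 2.0)

    nr, nz = len(rline) - 1, len(zline) - 1
    # corner grid
    corner_id = np.arange((nr + 1) * (nz + 1)).reshape(nr + 1, nz + 1)
    corners = np.empty(((nr + 1) * (nz + 1), 2))
    for i, r in enumerate(rline):
        for j, z in enumerate(zline):
            corners[corner_id[i, j]] = (r, z)

    tris = []
    tags = []
    for i in range(nr):
        for j in range(nz):
            n00, n10 = corner_id[i, j], corner_id[i + 1, j]
            n01, n11 = corner_id[i, j + 1], corner_id[i + 1, j + 1]
            # split along the (n00, n11) diagonal; CCW in (r, z-down) plane
            tris.append((n00, n11, n01))
            tris.append((n00, n10, n11))
            tags.extend([interval_layers[j]] * 2)
    tris = np.asarray(tris, dtype=np.int64)

    # quadratic midside nodes via shared-edge dictionary
    nodes = [tuple(xy) for xy in corners]
    node_arr = list(corners)
    edge_mid: Dict[Tuple[int, int], int] = {}

    def midnode(na: int, nb: int) -> int:
        key = (na, nb) if na < nb else (nb, na)
        idx = edge_mid.get(key)
        if idx is None:
            idx = len(node_arr)
            node_arr.append(0.5 * (corners[na] + corners[nb]))
            edge_mid[key] = idx
        return idx

    elements = np.empty((len(tris), 6), dtype=np.int64)
    for e, (c0, c1, c2) in enumerate(tris):
        elements[e] = (c0, c1, c2, midnode(c0, c1), midnode(c1, c2), midnode(c2, c0))

    nodes = np.asarray(node_arr)
    layer_tag = np.asarray(tags, dtype=object)

    mesh = Mesh(
        nodes=nodes,
        elements=elements,
        layer_tag=layer_tag,
        roi_mask=np.zeros(len(elements), dtype=bool),
        element_volume=np.zeros(len(elements)),
        indenter_radius=a,
        roi_radius=model.roi_radius,
        domain_radius=model.domain_half_width,
        depth=float(zline[-1]),
        resolution=resolution,
    )
    mesh.element_volume = element_volumes(mesh)
    soft_present = {ly.name for ly in model.soft_layers}
    if soft_present:
        mesh.roi_mask = tag_roi(mesh, model.roi_radius, include_layers=soft_present)
    return mesh


def element_volumes(mesh: Mesh) -> np.ndarray:
    """Physical ring volume of each element: triangle area * 2*pi*r_centroid.

    Exact for straight-sided triangles, since the centroid rule integrates
    the linear weight r over a triangle exactly.
    """
    xy = mesh.corner_coords()
    r0, z0 = xy[:, 0, 0], xy[:, 0, 1]
    r1, z1 = xy[:, 1, 0], xy[:, 1, 1]
    r2, z2 = xy[:, 2, 0], xy[:, 2, 1]
    area2 = (r1 - r0) * (z2 - z0) - (r2 - r0) * (z1 - z0)
    if np.any(area2 <= 0):
        raise MeshError("degenerate or inverted element (non-positive area)")
    rc = (r0 + r1 + r2) / 3.0
    return 0.5 * np.abs(area2) * 2.0 * np.pi * rc


def tag_roi(mesh: Mesh, roi_radius: float, include_layers: Iterable[str] = SOFT_LAYERS) -> np.ndarray:
    """Mask of elements with centroid r <= roi_radius in the included layers."""
    if roi_radius > mesh.domain_radius + 1e-9:
        raise MeshError("ROI radius exceeds the domain radius")
    include = set(include_layers)
    rc = mesh.centroids()[:, 0]
    mask = (rc <= roi_radius) & np.isin(mesh.layer_tag.astype(str), list(include))
    if not mask.any():
        raise MeshError("empty ROI: no element centroid inside the ROI radius")
    return mask
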