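"""Simulation geometry and mesh generation.

The simulated scene is a 2D cross-section through a cylindrical tumor:
a tumor disk of radius ``R_t`` centered in an ``L_t x W_t`` rectangle of
healthy tissue, ringed by a thin capillary annulus of thickness ``d_c``
fed by two straight vessels of width ``d_a`` that reach the lateral
tissue edges (inlet left, outlet right).  A permanent magnet sits above
the tissue on the vertical symmetry axis, and everything is embedded in
a large air box for the magnetostatic far field.

Boundary tag convention (tissue rectangle):

* ``"1"`` bottom edge  — roller, no interstitial flow
* ``"2"`` vessel inlet (left end of the feeder)
* ``"3"`` vessel outlet (right end)
* ``"4"`` top edge (magnet side) — roller, boundary load, P_i = 0
* ``"5"`` lateral edges — roller, P_i = 0
* ``"wall"``/``"wall_inner"`` vessel walls (flow mesh), ``"far"`` air box

Three per-physics meshes are generated instead of one global mesh:
``tissue`` (poroelasticity), ``flow`` (vessel network) and ``magnetic``
(air + magnet + tissue); they are coupled by field interpolation.  The
tissue and magnetics meshes are built by triangulating the half-plane
``x >= 0`` point cloud and mirroring it, so the triangulation is exactly
symmetric about the vertical axis whenever the geometry is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from shapely import contains_xy
from shapely.geometry import Point, box

from .fem import Mesh, boundary_edges, orient_ccw
from .params import ParamSet

SHAPE_IDS = ("HR", "VR", "SC", "BC")

_RECT_DIMS = {"HR": (0.02, 0.01), "VR": (0.01, 0.02)}  # width, height (m)
_CIRC_RADII = {"SC": 0.005, "BC": 0.01}


class GeometryError(ValueError):
    pass


# ----------------------------------------------------------------------
# magnet placement
# ----------------------------------------------------------------------

@dataclass
class MagnetSpec:
    """Permanent-magnet geometry, placement and remanence."""

    shape: str                       # "rect" | "circle"
    center: tuple
    B_rem_magnitude: float = 1.5     # remanent flux density (T)
    magnetization_axis: tuple = (0.0, -1.0)
    width: float = 0.0               # rect only (m)
    height: float = 0.0
    radius: float = 0.0              # circle only (m)

    def __post_init__(self):
        ax = np.asarray(self.magnetization_axis, float)
        nrm = np.hypot(*ax)
        if nrm == 0:
            raise GeometryError("magnetization axis must be a nonzero vector")
        self.magnetization_axis = tuple(ax / nrm)
        if self.shape not in ("rect", "circle"):
            raise GeometryError(f"unknown magnet shape {self.shape!r}")
        if self.shape == "rect" and (self.width <= 0 or self.height <= 0):
            raise GeometryError("rect magnet needs positive width and height")
        if self.shape == "circle" and self.radius <= 0:
            raise GeometryError("circular magnet needs a positive radius")

    def polygon(self, n_arc: int = 256):
        cx, cy = self.center
        if self.shape == "rect":
            return box(cx - self.width / 2, cy - self.height / 2,
                       cx + self.width / 2, cy + self.height / 2)
        return Point(cx, cy).buffer(self.radius, quad_segs=n_arc // 4)

    @property
    def max_dim(self) -> float:
        if self.shape == "rect":
            return max(self.width, self.height)
        return 2.0 * self.radius

    @property
    def B_rem_vector(self) -> np.ndarray:
        return self.B_rem_magnitude * np.asarray(self.magnetization_axis)


def tangential_distance(shape_id: str, p: ParamSet) -> float:
    """Center-to-center distance at which the magnet touches the tissue."""
    if shape_id in _RECT_DIMS:
        return p.W_t / 2 + _RECT_DIMS[shape_id][1] / 2
    if shape_id in _CIRC_RADII:
        return p.W_t / 2 + _CIRC_RADII[shape_id]
    raise GeometryError(f"unknown magnet shape id {shape_id!r}")


def place_magnet(shape_id: str, center_distance: float | None = None,
                 p: ParamSet | None = None,
                 B_rem: float = 1.5) -> MagnetSpec:
    """Place one of the four study magnets above the tissue.

    ``HR``/``VR`` are the 10 mm x 20 mm rectangle laid horizontally or
    vertically; ``SC``/``BC`` are circles of radius 5 mm and 10 mm.  The
    magnet is centered on the vertical axis through the tumor at the
    requested center-to-center distance from the tissue center (default:
    tangential contact).  The magnetization axis points at the tissue.
    """
    p = p if p is not None else ParamSet()
    d_tan = tangential_distance(shape_id, p)
    if center_distance is None:
        center_distance = d_tan
    if center_distance < d_tan - 1e-12:
        raise GeometryError(
            f"center distance {center_distance} m would overlap the tissue "
            f"({shape_id} tangential distance is {d_tan} m)"
        )
    center = (0.0, center_distance)
    if shape_id in _RECT_DIMS:
        w, h = _RECT_DIMS[shape_id]
        return MagnetSpec("rect", center, B_rem, (0.0, -1.0),
                          width=w, height=h)
    return MagnetSpec("circle", center, B_rem, (0.0, -1.0),
                      radius=_CIRC_RADII[shape_id])


# ----------------------------------------------------------------------
# domain geometry (tagged shapely regions)
# ----------------------------------------------------------------------

@dataclass
class DomainGeometry:
    """Tagged closed regions of the full scene (tissue frame, meters)."""

    params: ParamSet
    magnet: MagnetSpec
    air_halfsize: float
    regions: dict = field(default_factory=dict)

    def region_area(self, tag: str) -> float:
        return self.regions[tag].area


def build_domain(p: ParamSet, magnet: MagnetSpec,
                 air_padding: float = 0.15) -> DomainGeometry:
    """Assemble the tagged region map and verify the scene is consistent."""
    if air_padding < 3.0 * magnet.max_dim:
        raise GeometryError(
            f"air padding {air_padding} m must be at least 3x the largest "
            f"magnet dimension ({magnet.max_dim} m)"
        )
    tissue_rect = box(-p.L_t / 2, -p.W_t / 2, p.L_t / 2, p.W_t / 2)
    tumor = Point(0, 0).buffer(p.R_t, quad_segs=128)
    ring = Point(0, 0).buffer(p.R_t + p.d_c, quad_segs=128).difference(tumor)
    strip = box(-p.L_t / 2, -p.d_a / 2, p.L_t / 2, p.d_a / 2)
    outer_disk = Point(0, 0).buffer(p.R_t + p.d_c, quad_segs=128)
    feed_in = strip.difference(outer_disk).intersection(
        box(-p.L_t / 2, -p.d_a / 2, 0, p.d_a / 2))
    feed_out = strip.difference(outer_disk).intersection(
        box(0, -p.d_a / 2, p.L_t / 2, p.d_a / 2))
    healthy = tissue_rect.difference(outer_disk).difference(
        feed_in).difference(feed_out)
    mag_poly = magnet.polygon()
    if mag_poly.intersection(tissue_rect).area > 1e-12 * mag_poly.area:
        raise GeometryError("magnet overlaps the tissue rectangle")
    extent = max(
        p.L_t / 2, p.W_t / 2,
        abs(magnet.center[0]) + magnet.max_dim / 2,
        abs(magnet.center[1]) + magnet.max_dim / 2,
    )
    half = extent + air_padding
    air = box(-half, -half, half, half).difference(tissue_rect).difference(
        mag_poly)
    regions = {
        "tumor": tumor,
        "vessel_ring": ring,
        "vessel_feed_in": feed_in,
        "vessel_feed_out": feed_out,
        "healthy": healthy,
        "magnet": mag_poly,
        "air": air,
    }
    for tag, shape in regions.items():
        if shape.area <= 0:
            raise GeometryError(f"region {tag!r} has non-positive area")
    return DomainGeometry(params=p, magnet=magnet, air_halfsize=half,
                          regions=regions)


# ----------------------------------------------------------------------
# point-cloud helpers
# ----------------------------------------------------------------------

def _ring_n(r: float, h: float) -> int:
    """Points on a circle of radius r at arc spacing ~h, multiple of 4."""
    return max(8, int(math.ceil(2 * math.pi * r / h / 4.0)) * 4)


def _circle_pts(r, n, center=(0.0, 0.0)):
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + r * np.cos(th),
                            center[1] + r * np.sin(th)])


def _odd_linspace(a, b, h):
    """linspace from a to b at spacing <= h with an odd point count."""
    n = int(math.ceil((b - a) / h / 2.0)) * 2 + 1
    return np.linspace(a, b, n)


def _rect_boundary_pts(x0, y0, x1, y1, h):
    xs = _odd_linspace(x0, x1, h)
    ys = _odd_linspace(y0, y1, h)
    out = [
        np.column_stack([xs, np.full_like(xs, y0)]),
        np.column_stack([xs, np.full_like(xs, y1)]),
        np.column_stack([np.full_like(ys[1:-1], x0), ys[1:-1]]),
        np.column_stack([np.full_like(ys[1:-1], x1), ys[1:-1]]),
    ]
    return np.vstack(out)


def _dedupe_points(points, tol):
    """Drop points closer than ``tol`` to an earlier point."""
    pts = np.asarray(points, float)
    kd = cKDTree(pts)
    pairs = kd.query_pairs(tol, output_type="ndarray")
    drop = np.zeros(len(pts), bool)
    for a, b in pairs:
        hi = max(a, b)
        lo = min(a, b)
        if not drop[lo]:
            drop[hi] = True
    return pts[~drop]


def _weld(points, tol):
    """Merge near-coincident points; return (unique_points, index_map)."""
    pts = np.asarray(points, float)
    kd = cKDTree(pts)
    pairs = kd.query_pairs(tol, output_type="ndarray")
    parent = np.arange(len(pts))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(len(pts))])
    uniq, inv = np.unique(roots, return_inverse=True)
    return pts[uniq], inv


def _drop_degenerate(points, tris, rel_tol=1e-12):
    p = points
    t = tris
    det = ((p[t[:, 1], 0] - p[t[:, 0], 0]) * (p[t[:, 2], 1] - p[t[:, 0], 1])
           - (p[t[:, 2], 0] - p[t[:, 0], 0]) * (p[t[:, 1], 1] - p[t[:, 0], 1]))
    edge = np.max(np.abs(p[t] - p[t][:, [1, 2, 0]]), axis=(1, 2))
    keep = np.abs(det) > rel_tol * np.maximum(edge, 1e-300) ** 2 * 1e3
    return t[keep]


def _triangulate(points, symmetric, axis_tol=1e-12, mirror_tol=1e-9):
    """Delaunay triangulation, optionally exactly mirror-symmetric in x.

    The symmetric path snaps |x| < axis_tol to zero, unions the cloud
    with its mirror image (deduplicated at ``mirror_tol``), triangulates
    the half cloud x >= 0 and mirrors it.  A symmetric scene therefore
    yields a bitwise mirror-symmetric mesh, and mirrored scenes yield
    identical meshes.
    """
    pts = np.array(points, float)
    pts[np.abs(pts[:, 0]) < axis_tol, 0] = 0.0
    if not symmetric:
        d = Delaunay(pts)
        tris = _drop_degenerate(pts, d.simplices)
        return pts, orient_ccw(pts, tris)
    pts = _dedupe_points(np.vstack([pts, pts * np.array([-1.0, 1.0])]),
                         mirror_tol)
    pts[np.abs(pts[:, 0]) < axis_tol, 0] = 0.0
    right = pts[pts[:, 0] >= 0.0]
    d = Delaunay(right)
    tris = _drop_degenerate(right, d.simplices)
    off_axis = right[:, 0] > 0.0
    n = len(right)
    mirror_map = np.arange(n)
    mirror_map[off_axis] = n + np.arange(int(off_axis.sum()))
    mirrored = right[off_axis] * np.array([-1.0, 1.0])
    all_pts = np.vstack([right, mirrored])
    all_tris = np.vstack([tris, mirror_map[tris]])
    all_tris = _drop_degenerate(all_pts, all_tris)
    return all_pts, orient_ccw(all_pts, all_tris)


# ----------------------------------------------------------------------
# tissue mesh
# ----------------------------------------------------------------------

def _disk_ring_points(p: ParamSet, h_in: float, h_out: float,
                      r_stop: float):
    """Spiderweb rings: tumor interior, the two capillary circles, and
    graded rings growing outward to radius ``r_stop``."""
    Rt, dc = p.R_t, p.d_c
    pts = [np.zeros((1, 2))]
    nr = max(3, int(round(Rt / h_in)))
    for r in np.linspace(0.0, Rt, nr + 1)[1:-1]:
        pts.append(_circle_pts(r, _ring_n(r, h_in)))
    n_c = _ring_n(Rt, min(h_in, 4 * dc))
    pts.append(_circle_pts(Rt, n_c))
    pts.append(_circle_pts(Rt + dc, n_c))
    r = Rt + dc
    dr = max(dc, 0.5 * h_in)
    while True:
        dr = min(dr * 1.35, h_out)
        if r + dr > r_stop:
            break
        r = r + dr
        pts.append(_circle_pts(r, _ring_n(r, dr)))
    return np.vstack(pts), r


def _classify_disk(points, tris, Rt, dc, eps=1e-9):
    """Tag triangles tumor / vessel_ring / healthy by vertex radii."""
    rv = np.hypot(points[tris][:, :, 0], points[tris][:, :, 1])
    rc = np.hypot(*points[tris].mean(axis=1).T)
    tags = np.empty(len(tris), dtype=object)
    inner = (rv < Rt - eps).any(axis=1)
    outer = (rv > Rt + dc + eps).any(axis=1)
    on_in = np.abs(rv - Rt) <= eps
    on_out = np.abs(rv - (Rt + dc)) <= eps
    tags[:] = "healthy"
    tags[inner] = "tumor"
    band = ~inner & ~outer
    both = band & on_in.any(axis=1) & on_out.any(axis=1)
    tags[both] = "vessel_ring"
    all_in = band & on_in.all(axis=1)
    tags[all_in & (rc < Rt)] = "tumor"
    tags[all_in & (rc >= Rt)] = "vessel_ring"
    all_out = band & on_out.all(axis=1) & ~on_in.any(axis=1)
    tags[all_out & (rc < Rt + dc)] = "vessel_ring"
    tags[all_out & (rc >= Rt + dc)] = "healthy"
    return tags


def mesh_tissue(p: ParamSet, h_tumor: float = 2.5e-4, h_far: float = 1.0e-3,
                symmetric: bool = True) -> Mesh:
    """Triangulate the tissue rectangle with tumor/ring/healthy tags."""
    if h_tumor <= 0 or h_far <= 0:
        raise GeometryError("mesh target edge lengths must be positive")
    r_stop = min(p.L_t, p.W_t) / 2 - 1.6 * h_far
    disk_pts, r_last = _disk_ring_points(p, h_tumor, h_far, r_stop)
    bpts = _rect_boundary_pts(-p.L_t / 2, -p.W_t / 2,
                              p.L_t / 2, p.W_t / 2, h_far)
    xs = _odd_linspace(-p.L_t / 2 + 0.7 * h_far, p.L_t / 2 - 0.7 * h_far,
                       h_far)
    ys = _odd_linspace(-p.W_t / 2 + 0.7 * h_far, p.W_t / 2 - 0.7 * h_far,
                       h_far)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    grid = grid[np.hypot(grid[:, 0], grid[:, 1]) > r_last + 0.55 * h_far]
    points = np.vstack([disk_pts, bpts, grid])
    tol = 0.25 * min(h_tumor, p.d_c)
    points = _dedupe_points(points, tol)
    points, tris = _triangulate(points, symmetric, mirror_tol=tol)
    region = _classify_disk(points, tris, p.R_t, p.d_c)
    edges = boundary_edges(tris)
    mids = points[edges].mean(axis=1)
    tags = np.empty(len(edges), dtype=object)
    tol = 1e-9
    tags[:] = "5"
    tags[np.abs(mids[:, 1] + p.W_t / 2) < tol] = "1"
    tags[np.abs(mids[:, 1] - p.W_t / 2) < tol] = "4"
    return Mesh(points=points, triangles=tris, region=region,
                edges=edges, edge_tag=tags)


# ----------------------------------------------------------------------
# vessel-network (flow) mesh — structured and conforming
# ----------------------------------------------------------------------

def mesh_flow(p: ParamSet, n_layers: int = 5, h_arc: float = 1.5e-4,
              h_axial: float = 2.5e-4, n_across: int = 9) -> Mesh:
    """Structured conforming mesh of the capillary ring plus feeders.

    The annulus is meshed on a polar grid whose outer-circle nodes
    coincide exactly with the feeder end columns inside the junction
    spans, so ring and feeders share nodes.  The right half is built
    explicitly and mirrored, making the triangulation exactly symmetric
    about the vertical axis (the inlet/outlet *tags* remain left/right).
    """
    if n_layers < 3:
        raise GeometryError("need >= 3 radial node layers (>= 2 elements) "
                            "across the capillary ring")
    if n_across < 3 or n_across % 2 == 0:
        raise GeometryError("n_across must be an odd integer >= 3")
    Ri, Ro = p.R_t, p.R_t + p.d_c
    if p.d_a / 2 >= Ro:
        raise GeometryError("feeder width exceeds ring diameter")

    y_rows = np.linspace(-p.d_a / 2, p.d_a / 2, n_across)
    a_jun = np.arcsin(y_rows / Ro)              # right-junction angles
    a_max = a_jun[-1]

    # right-half angular grid: junction angles + uniform fill to +-pi/2,
    # odd fill count so the +-pi/2 columns are present exactly
    arc = (np.pi / 2 - a_max) * Ro
    m = int(math.ceil(arc / h_arc)) + 1
    fill_up = np.linspace(a_max, np.pi / 2, m)[1:]
    theta = np.unique(np.concatenate([a_jun, fill_up, -fill_up]))

    radii = np.linspace(Ri, Ro, n_layers)
    nth = len(theta)
    ann_nodes = np.empty((nth, n_layers, 2))
    ann_nodes[:, :, 0] = np.cos(theta)[:, None] * radii[None, :]
    ann_nodes[:, :, 1] = np.sin(theta)[:, None] * radii[None, :]

    pts = [ann_nodes.reshape(-1, 2)]
    tris = []
    tags = []

    def nid(j, i):
        return j * n_layers + i

    for j in range(nth - 1):
        for i in range(n_layers - 1):
            a, b = nid(j, i), nid(j + 1, i)
            c, d = nid(j + 1, i + 1), nid(j, i + 1)
            tris += [[a, b, c], [a, c, d]]
            tags += ["vessel_ring", "vessel_ring"]

    # right feeder: mapped grid from the outer circle to the outlet edge
    offset = ann_nodes.reshape(-1, 2).shape[0]
    x_end = p.L_t / 2
    x_start = np.sqrt(Ro ** 2 - y_rows ** 2)
    n_x = max(3, int(math.ceil((x_end - x_start.min()) / h_axial)) + 1)
    feed_nodes = np.empty((n_across, n_x, 2))
    for k, y in enumerate(y_rows):
        feed_nodes[k, :, 0] = np.linspace(x_start[k], x_end, n_x)
        feed_nodes[k, :, 1] = y
    pts.append(feed_nodes.reshape(-1, 2))

    def fid(k, j):
        return offset + k * n_x + j

    for k in range(n_across - 1):
        for j in range(n_x - 1):
            a, b = fid(k, j), fid(k, j + 1)
            c, d = fid(k + 1, j + 1), fid(k + 1, j)
            tris += [[a, b, c], [a, c, d]]
            tags += ["vessel_feed_out", "vessel_feed_out"]

    points = np.vstack(pts)
    tris = np.asarray(tris, dtype=np.int64)
    points[np.abs(points[:, 0]) < 1e-12, 0] = 0.0

    # mirror the right half to the left
    off_axis = points[:, 0] > 0.0
    n = len(points)
    mmap = np.arange(n)
    mmap[off_axis] = n + np.arange(int(off_axis.sum()))
    points = np.vstack([points, points[off_axis] * np.array([-1.0, 1.0])])
    tris = np.vstack([tris, mmap[tris]])
    tags = np.array(
        tags + [t.replace("feed_out", "feed_in") for t in tags],
        dtype=object)

    points, imap = _weld(points, 1e-10)
    tris = imap[tris]
    areas = _signed_areas(points, tris)
    keep_mask = np.abs(areas) > 1e-20
    tris = tris[keep_mask]
    tags = tags[keep_mask]
    tris = orient_ccw(points, tris)

    edges = boundary_edges(tris)
    mids = points[edges].mean(axis=1)
    r_nodes = np.hypot(points[edges][:, :, 0], points[edges][:, :, 1])
    etags = np.empty(len(edges), dtype=object)
    etags[:] = "wall"
    etags[np.all(np.abs(r_nodes - Ri) < 1e-9, axis=1)] = "wall_inner"
    etags[np.abs(mids[:, 0] + p.L_t / 2) < 1e-9] = "2"
    etags[np.abs(mids[:, 0] - p.L_t / 2) < 1e-9] = "3"
    return Mesh(points=points, triangles=tris, region=tags,
                edges=edges, edge_tag=etags)


def _signed_areas(points, tris):
    p = points
    t = tris
    return 0.5 * ((p[t[:, 1], 0] - p[t[:, 0], 0])
                  * (p[t[:, 2], 1] - p[t[:, 0], 1])
                  - (p[t[:, 2], 0] - p[t[:, 0], 0])
                  * (p[t[:, 1], 1] - p[t[:, 0], 1]))


# ----------------------------------------------------------------------
# magnetics mesh (air box + magnet + tissue)
# ----------------------------------------------------------------------

def _magnet_points(magnet: MagnetSpec, h: float):
    pts = []
    if magnet.shape == "rect":
        cx, cy = magnet.center
        x0, x1 = cx - magnet.width / 2, cx + magnet.width / 2
        y0, y1 = cy - magnet.height / 2, cy + magnet.height / 2
        pts.append(_rect_boundary_pts(x0, y0, x1, y1, h))
        xs = _odd_linspace(x0 + 0.7 * h, x1 - 0.7 * h, h)
        ys = _odd_linspace(y0 + 0.7 * h, y1 - 0.7 * h, h)
        gx, gy = np.meshgrid(xs, ys)
        pts.append(np.column_stack([gx.ravel(), gy.ravel()]))
    else:
        R = magnet.radius
        pts.append(_circle_pts(R, _ring_n(R, h), magnet.center))
        nr = max(2, int(round(R / h)))
        for r in np.linspace(0.0, R, nr + 1)[1:-1]:
            pts.append(_circle_pts(r, _ring_n(r, h), magnet.center))
        pts.append(np.asarray([magnet.center]))
    return np.vstack(pts)


def mesh_magnetics(p: ParamSet, magnet: MagnetSpec,
                   box_halfsize: float | None = None,
                   h_fine: float = 6.0e-4, h_mid: float = 1.4e-3,
                   growth: float = 1.45,
                   symmetric: bool = True) -> Mesh:
    """Mesh air box + magnet + tissue for the scalar-potential solve.

    Fine resolution in the tissue and magnet, a uniform near-field band
    around them, and geometrically graded shells out to the far (psi=0)
    boundary.  ``symmetric=True`` symmetrizes the point cloud about the
    vertical axis before triangulating, so an on-axis (or mirrored)
    magnet yields an exactly mirror-symmetric mesh.
    """
    mag_poly = magnet.polygon()
    if box_halfsize is None:
        extent = max(p.L_t / 2, abs(magnet.center[1]) + magnet.max_dim / 2
                     + abs(magnet.center[0]))
        # generous far-field: truncation at the psi=0 box otherwise
        # biases the interior field at the percent level
        box_halfsize = max(0.18, extent + 3 * magnet.max_dim)
    A = box_halfsize

    r_stop = min(p.L_t, p.W_t) / 2 - 1.6 * h_fine
    disk_pts, r_last = _disk_ring_points(p, h_fine, h_fine, r_stop)
    tissue_b = _rect_boundary_pts(-p.L_t / 2, -p.W_t / 2,
                                  p.L_t / 2, p.W_t / 2, h_fine)
    xs = _odd_linspace(-p.L_t / 2 + 0.7 * h_fine, p.L_t / 2 - 0.7 * h_fine,
                       h_fine)
    ys = _odd_linspace(-p.W_t / 2 + 0.7 * h_fine, p.W_t / 2 - 0.7 * h_fine,
                       h_fine)
    gx, gy = np.meshgrid(xs, ys)
    tgrid = np.column_stack([gx.ravel(), gy.ravel()])
    tgrid = tgrid[np.hypot(tgrid[:, 0], tgrid[:, 1]) > r_last + 0.55 * h_fine]

    mag_pts = _magnet_points(magnet, 0.8 * h_fine)

    # near-field uniform band around tissue + magnet
    bx0, by0, bx1, by1 = mag_poly.union(
        box(-p.L_t / 2, -p.W_t / 2, p.L_t / 2, p.W_t / 2)).bounds
    pad = 6.0e-3
    if symmetric:
        # keep the near-field band mirror-symmetric even for an
        # off-axis magnet, so mirrored placements share one mesh
        bx1 = max(abs(bx0), abs(bx1))
        bx0 = -bx1
    nb = (bx0 - pad, by0 - pad, bx1 + pad, by1 + pad)
    xs = _odd_linspace(nb[0], nb[2], h_mid)
    ys = _odd_linspace(nb[1], nb[3], h_mid)
    gx, gy = np.meshgrid(xs, ys)
    near = np.column_stack([gx.ravel(), gy.ravel()])
    keep = ~contains_xy(mag_poly.buffer(0.7 * h_mid), near[:, 0], near[:, 1])
    keep &= ~contains_xy(
        box(-p.L_t / 2 - 0.7 * h_mid, -p.W_t / 2 - 0.7 * h_mid,
            p.L_t / 2 + 0.7 * h_mid, p.W_t / 2 + 0.7 * h_mid),
        near[:, 0], near[:, 1])
    near = near[keep]

    # graded rectangular shells out to the air box
    shells = []
    d = 1.6 * h_mid
    cum = 0.0
    while True:
        cum += d
        x0, y0, x1, y1 = nb[0] - cum, nb[1] - cum, nb[2] + cum, nb[3] + cum
        if x0 <= -A or y0 <= -A or x1 >= A or y1 >= A:
            break
        shells.append(_rect_boundary_pts(x0, y0, x1, y1, 0.9 * d))
        d *= growth
    shells.append(_rect_boundary_pts(-A, -A, A, A, 0.9 * d))
    points = np.vstack([disk_pts, tissue_b, tgrid, mag_pts, near] + shells)
    tol = min(1.0e-4, 0.3 * h_fine)
    points = _dedupe_points(points, tol)

    points, tris = _triangulate(points, symmetric, mirror_tol=tol)
    region = _classify_magnetics(points, tris, p, mag_poly)
    edges = boundary_edges(tris)
    etags = np.full(len(edges), "far", dtype=object)
    return Mesh(points=points, triangles=tris, region=region,
                edges=edges, edge_tag=etags)


def _classify_magnetics(points, tris, p, mag_poly):
    cent = points[tris].mean(axis=1)
    region = _classify_disk(points, tris, p.R_t, p.d_c)
    in_tissue = ((np.abs(cent[:, 0]) < p.L_t / 2)
                 & (np.abs(cent[:, 1]) < p.W_t / 2))
    region[~in_tissue] = "air"
    in_mag = contains_xy(mag_poly, cent[:, 0], cent[:, 1])
    region[in_mag] = "magnet"
    return region


def retag_magnet(mesh: Mesh, p: ParamSet, magnet: MagnetSpec) -> Mesh:
    """Re-classify a magnetics mesh for a different magnet placement.

    The triangulation is reused; only region tags change.  Useful for
    comparing mirrored placements on one (symmetric) mesh, where the
    resolved zones cover both positions."""
    region = _classify_magnetics(mesh.points, mesh.triangles, p,
                                 magnet.polygon())
    return Mesh(points=mesh.points, triangles=mesh.triangles,
                region=region, edges=mesh.edges, edge_tag=mesh.edge_tag)


# ----------------------------------------------------------------------
# mesh bundle
# ----------------------------------------------------------------------

@dataclass
class MeshSet:
    """The three per-physics meshes of one simulation case."""

    tissue: Mesh
    flow: Mesh
    magnetic: Mesh


def mesh_domain(g: DomainGeometry, h_tissue: float = 2.5e-4,
                h_vessel: float = 1.5e-4, h_air: float = 6.0e-4,
                symmetric: bool = True) -> MeshSet:
    """Mesh all three physics domains of a built scene."""
    p = g.params
    if h_vessel > p.d_c / 2:
        raise GeometryError(
            f"h_vessel={h_vessel} must be <= d_c/2 so the capillary ring "
            "is at least two elements thick")
    n_layers = max(3, int(round(p.d_c / h_vessel)) + 1)
    tissue = mesh_tissue(p, h_tumor=h_tissue, h_far=4 * h_tissue,
                         symmetric=symmetric)
    flow = mesh_flow(p, n_layers=n_layers, h_arc=2.5 * h_vessel,
                     h_axial=4 * h_vessel)
    magnetic = mesh_magnetics(p, g.magnet, box_halfsize=g.air_halfsize,
                              h_fine=h_air, symmetric=symmetric)
    return MeshSet(tissue=tissue, flow=flow, magnetic=magnetic)
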