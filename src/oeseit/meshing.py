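"""Structured tetrahedral meshing of layered cylindrical phantoms.

The phantoms used throughout this package are unions of coaxial, full-height
cylinders (boundary, lungs, blood target, optional axial channel), so the
mesh is built as an extrusion: a graded two-dimensional triangulation of the
cross-section is swept through a graded stack of z-layers and every
triangular prism is cut into three tetrahedra.  Diagonals on the prism quad
faces are chosen from global vertex indices, which makes the cut identical
on the two sides of every shared face and hence the mesh conforming.

The cross-section triangulation is a Delaunay triangulation
(``scipy.spatial.Delaunay``) of a structured point cloud:

* a boundary ring whose angular spacing is refined inside the electrode
  bands so electrode patches are resolved by several facets,
* explicit node rings on every material interface circle (lungs, target,
  channel) so region boundaries are captured as polygonal chords,
* a jittered hexagonal background lattice filling the remainder.

All randomness (lattice jitter, ring phase) flows through a seed, so a given
specification always produces the identical mesh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "Circle2D",
    "CrossSection",
    "graded_ring_angles",
    "graded_layers",
    "build_cross_section",
    "extrude_to_tets",
    "tet_volumes",
    "triangle_areas",
    "boundary_triangles",
]


@dataclass(frozen=True)
class Circle2D:
    """A circle in the cross-section plane (model units)."""

    cx: float
    cy: float
    r: float

    def contains(self, xy: np.ndarray) -> np.ndarray:
        d = np.hypot(xy[..., 0] - self.cx, xy[..., 1] - self.cy)
        return d < self.r

    def signed_distance(self, xy: np.ndarray) -> np.ndarray:
        return np.hypot(xy[..., 0] - self.cx, xy[..., 1] - self.cy) - self.r


def _segment(a: float, b: float, h: float, endpoint: bool = True) -> np.ndarray:
    """Uniform subdivision of [a, b] with spacing <= h, endpoints included."""
    n = max(1, int(np.ceil((b - a) / h - 1e-9)))
    pts = np.linspace(a, b, n + 1)
    return pts if endpoint else pts[1:-1]


def graded_ring_angles(
    centers: np.ndarray,
    half_arc: float,
    h_fine: float,
    h_coarse: float,
) -> np.ndarray:
    """Angles on the outer boundary ring, refined around electrode centers.

    Each electrode band [c - half_arc, c + half_arc] is subdivided at
    ``h_fine`` with nodes placed exactly on the band edges (so the patch
    outline coincides with mesh edges); the gaps between bands are filled at
    ``h_coarse``.  Angles are radians; bands must not overlap.
    """
    centers = np.sort(np.asarray(centers, dtype=float) % (2 * np.pi))
    pad = h_fine
    angles = []
    for i, c in enumerate(centers):
        band = np.concatenate(
            [
                [c - half_arc - pad],
                _segment(c - half_arc, c + half_arc, h_fine),
                [c + half_arc + pad],
            ]
        )
        angles.append(band)
        nxt = centers[(i + 1) % len(centers)] + (2 * np.pi if i + 1 == len(centers) else 0.0)
        lo, hi = c + half_arc + pad, nxt - half_arc - pad
        if hi - lo < min(h_coarse, 2 * h_fine):
            continue
        angles.append(_segment(lo, hi, h_coarse, endpoint=False))
    out = np.concatenate(angles) % (2 * np.pi)
    out = np.unique(np.round(out, 12))
    # merge near-duplicates produced by the modular wrap
    keep = np.ones(len(out), dtype=bool)
    keep[1:] = np.diff(out) > 1e-9
    return out[keep]


def graded_layers(
    height: float,
    fine_lo: float,
    fine_hi: float,
    hz_fine: float,
    hz_coarse: float,
    extra_breaks: tuple[float, ...] = (),
) -> np.ndarray:
    """z-layer heights: fine spacing inside [fine_lo, fine_hi], coarse outside.

    ``extra_breaks`` (e.g. the edges of a ring electrode band) are inserted
    exactly so that facet selections along z are not quantised.
    """
    breaks = sorted({0.0, fine_lo, fine_hi, height} | {float(b) for b in extra_breaks})
    z = [0.0]
    for a, b in zip(breaks[:-1], breaks[1:]):
        h = hz_fine if (a >= fine_lo - 1e-12 and b <= fine_hi + 1e-12) else hz_coarse
        z.extend(_segment(a, b, h)[1:])
    return np.asarray(z)


@dataclass
class CrossSection:
    """A 2-D triangulation of the phantom cross-section."""

    points: np.ndarray  # (n, 2)
    triangles: np.ndarray  # (m, 3), CCW
    boundary_radius: float


def _hex_lattice(radius: float, h: float, rng: np.random.Generator) -> np.ndarray:
    dy = h * np.sqrt(3.0) / 2.0
    ny = int(np.ceil(2 * radius / dy)) + 2
    nx = int(np.ceil(2 * radius / h)) + 2
    ys = (np.arange(ny) - ny / 2) * dy
    pts = []
    for j, y in enumerate(ys):
        xs = (np.arange(nx) - nx / 2 + 0.5 * (j % 2)) * h
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    pts = np.concatenate(pts)
    pts = pts + rng.uniform(-0.12 * h, 0.12 * h, size=pts.shape)
    return pts


def build_cross_section(
    radius: float,
    h: float,
    boundary_angles: np.ndarray,
    interface_circles: list[Circle2D],
    hole: Circle2D | None,
    hole_nodes: int,
    seed: int,
) -> CrossSection:
    """Triangulate a disc (optionally with a central hole) with imprinted circles.

    ``interface_circles`` receive explicit node rings so the material
    interfaces are resolved as polygons; circles with radius below the local
    spacing additionally get a centre node.  ``hole`` is meshed out entirely
    (triangles whose centroid falls inside it are discarded), with
    ``hole_nodes`` nodes on its wall.
    """
    rng = np.random.default_rng(seed)
    structured = [
        np.column_stack([radius * np.sin(boundary_angles), radius * np.cos(boundary_angles)])
    ]
    ring_spacings = []
    for c in interface_circles:
        n = max(16, int(np.ceil(2 * np.pi * c.r / h)))
        th = 2 * np.pi * (np.arange(n) + rng.uniform(0, 1)) / n
        structured.append(np.column_stack([c.cx + c.r * np.sin(th), c.cy + c.r * np.cos(th)]))
        ring_spacings.append(2 * np.pi * c.r / n)
        if c.r < 1.2 * h:
            structured.append(np.array([[c.cx, c.cy]]))
    if hole is not None:
        th = 2 * np.pi * np.arange(hole_nodes) / hole_nodes
        structured.append(
            np.column_stack([hole.cx + hole.r * np.sin(th), hole.cy + hole.r * np.cos(th)])
        )
    structured = np.concatenate(structured)

    lattice = _hex_lattice(radius, h, rng)
    keep = np.hypot(lattice[:, 0], lattice[:, 1]) < radius - 0.55 * h
    for c, s in zip(interface_circles, ring_spacings):
        band = max(0.55 * h, 0.8 * s)
        keep &= np.abs(c.signed_distance(lattice)) > band
        if c.r < 1.2 * h:  # centre node present
            keep &= np.hypot(lattice[:, 0] - c.cx, lattice[:, 1] - c.cy) > 0.55 * h
    if hole is not None:
        keep &= hole.signed_distance(lattice) > 0.55 * h
    lattice = lattice[keep]
    # drop lattice points crowding any structured node
    if len(lattice):
        d, _ = cKDTree(structured).query(lattice, k=1)
        lattice = lattice[d > 0.45 * h]

    points = np.concatenate([structured, lattice])
    tri = Delaunay(points)
    t = tri.simplices
    # orient CCW and drop degenerate slivers
    p = points[t]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    flip = area2 < 0
    t[flip] = t[flip][:, [0, 2, 1]]
    t = t[np.abs(area2) > 1e-12]
    if hole is not None:
        cent = points[t].mean(axis=1)
        t = t[hole.signed_distance(cent) > -1e-9]
    # deterministic element order
    order = np.lexsort(t.T[::-1])
    return CrossSection(points=points, triangles=t[order], boundary_radius=radius)


def extrude_to_tets(cs: CrossSection, z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extrude a cross-section through layer heights ``z``.

    Returns ``(vertices, tets, column)`` where ``column[k]`` is the index of
    the 2-D parent triangle of tetrahedron ``k`` (used to propagate region
    labels, which are constant along z for full-height cylinders).

    Each prism is split into three tetrahedra; the diagonal of every vertical
    quad face runs from its lowest-index bottom vertex, a rule that depends
    only on the shared face and therefore matches across neighbouring prisms.
    """
    pts2, tris = cs.points, cs.triangles
    n2, L = len(pts2), len(z)
    verts = np.column_stack(
        [np.tile(pts2, (L, 1)), np.repeat(np.asarray(z, dtype=float), n2)]
    )

    # rotate each triangle so its smallest 2-D index comes first (orientation kept)
    t = tris.copy()
    roll = np.argmin(t, axis=1)
    for r in (1, 2):
        m = roll == r
        t[m] = np.roll(t[m], -r, axis=1)
    a, b, c = t[:, 0], t[:, 1], t[:, 2]
    case_a = b < c  # diagonal of the (b, c) quad face starts at the smaller of b, c

    tets_per_layer = []
    for k in range(L - 1):
        lo, hi = k * n2, (k + 1) * n2
        A, B, C = a + lo, b + lo, c + lo
        A1, B1, C1 = a + hi, b + hi, c + hi
        T = np.empty((len(t), 3, 4), dtype=np.int64)
        # case A: diagonal b -> c'; case B: diagonal c -> b'
        T[case_a, 0] = np.stack([A, B, C, C1], axis=1)[case_a]
        T[case_a, 1] = np.stack([A, B, C1, B1], axis=1)[case_a]
        T[~case_a, 0] = np.stack([A, B, C, B1], axis=1)[~case_a]
        T[~case_a, 1] = np.stack([A, C, C1, B1], axis=1)[~case_a]
        T[:, 2] = np.stack([A, B1, C1, A1], axis=1)
        tets_per_layer.append(T.reshape(-1, 4))
    tets = np.concatenate(tets_per_layer)
    column = np.tile(np.repeat(np.arange(len(t)), 3), L - 1)

    vol = tet_volumes(verts, tets)
    neg = vol < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    return verts, tets, column


def tet_volumes(verts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = verts[tets]
    d = p[:, 1:] - p[:, :1]
    return np.einsum("ki,ki->k", d[:, 0], np.cross(d[:, 1], d[:, 2])) / 6.0


def triangle_areas(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    p = verts[faces]
    return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


def boundary_triangles(tets: np.ndarray, n_verts: int) -> np.ndarray:
    """Faces that belong to exactly one tetrahedron (sorted vertex triples)."""
    faces = tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
    faces = np.sort(faces, axis=1)
    code = (faces[:, 0].astype(np.int64) * n_verts + faces[:, 1]) * n_verts + faces[:, 2]
    _, first, counts = np.unique(code, return_index=True, return_counts=True)
    return faces[first[counts == 1]]


def face_multiplicities(tets: np.ndarray, n_verts: int) -> np.ndarray:
    """Multiplicity of every distinct face; a conforming mesh has only 1s and 2s."""
    faces = np.sort(tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3), axis=1)
    code = (faces[:, 0].astype(np.int64) * n_verts + faces[:, 1]) * n_verts + faces[:, 2]
    _, counts = np.unique(code, return_counts=True)
    return counts
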