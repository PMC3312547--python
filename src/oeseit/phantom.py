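"""Cylindrical thorax phantoms with an external ring or an internal electrode.

The phantom is the in-silico stand-in for a saline-tank thorax: a cylinder
of diameter 2 and height 0.8 model units carrying 16 circular electrodes
(diameter 0.1, centred at z = 0.4).  Two full-height cylinders of inflated
lung tissue (diameter 0.8, 0.13 S/m) flank a full-height blood target
cylinder (0.7 S/m) in a background of 0.48 S/m, the tabulated tissue values
at 50 kHz.  In the *external* arrangement all 16 electrodes sit on the outer
wall; in the *internal* arrangement electrode 16 moves onto the wall of an
axial channel (diameter 0.1) representing the oesophagus, modelled as a
meshed-out void.

Conventions
-----------
Electrode ``l`` (1-based) is centred at angle ``theta = 2*pi*(l-1)/16``
measured from the +y axis, i.e. position ``(R sin(theta), R cos(theta))``;
electrode 9 therefore sits at -y and the blood target is moved along the -y
axis toward it.  The lungs sit at (+/-0.55, 0) so the target corridor never
touches them.  The internal electrode is a ring band around the channel wall
with the same surface area as the external discs, the shape of a catheter
ring electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import meshing
from .meshing import Circle2D

__all__ = [
    "PhantomGeometryError",
    "PhantomSpec",
    "Mesh",
    "Electrode",
    "ElectrodeSet",
    "ConductivityField",
    "build_phantom",
    "assign_conductivity",
    "sweep_positions",
    "refine_phantom",
]

REGION_BACKGROUND = 0
REGION_LUNG = 1
REGION_TARGET = 2
REGION_NAMES = {REGION_BACKGROUND: "background", REGION_LUNG: "lung", REGION_TARGET: "target"}

# baseline mesh-size parameters at scale factor 1 (model units)
_H0 = 0.085  # background in-plane spacing
_ANG_FINE0 = 0.030  # boundary-ring spacing inside electrode bands (radians)
_ANG_COARSE0 = 0.085  # boundary-ring spacing between bands (radians)
_HZ_FINE0 = 0.0333  # layer spacing across the electrode band in z
_HZ_COARSE0 = 0.095  # layer spacing elsewhere

# scale factors of the two evaluation-grade discretizations; chosen so the
# fine (forward) mesh lands in the mid 30-thousands of elements and the
# coarse (inverse) one near 28 thousand, and deliberately incommensurate so
# the two meshes share no element structure
_FORWARD_SCALE = 1.00
_INVERSE_SCALE = 1.12
_SALT = {"forward": 101, "inverse": 202, "custom": 303}
_N_REF = 40000  # approximate element count at scale 1, for custom densities


class PhantomGeometryError(ValueError):
    """Raised when interior cylinders collide or leave the boundary."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and conductivities of one phantom configuration."""

    boundary_diameter: float = 2.0
    boundary_height: float = 0.8
    electrode_diameter: float = 0.1
    electrode_center_z: float = 0.4
    n_electrodes: int = 16
    arrangement: str = "external"  # or "internal"
    internal_channel_diameter: float = 0.1
    lung_diameter: float = 0.8
    lung_center_offset: float = 0.55
    include_lungs: bool = True
    target_diameter: float = 0.1
    target_offset: float = 0.5
    target_direction_electrode: int = 9  # 1-based electrode number
    conductivities: dict = field(
        default_factory=lambda: {"background": 0.48, "lung": 0.13, "blood": 0.7}
    )
    contact_impedance: float = 1e-3  # Ohm * m^2, same on every electrode

    # -- derived geometry -------------------------------------------------
    @property
    def radius(self) -> float:
        return self.boundary_diameter / 2.0

    @property
    def channel_radius(self) -> float:
        return self.internal_channel_diameter / 2.0

    def electrode_angle(self, number: int) -> float:
        """Angle (radians from +y) of a 1-based electrode number."""
        return 2.0 * np.pi * (number - 1) / self.n_electrodes

    @property
    def target_center(self) -> np.ndarray:
        th = self.electrode_angle(self.target_direction_electrode)
        return self.target_offset * np.array([np.sin(th), np.cos(th)])

    def lung_circles(self) -> list[Circle2D]:
        if not self.include_lungs:
            return []
        r = self.lung_diameter / 2.0
        return [
            Circle2D(+self.lung_center_offset, 0.0, r),
            Circle2D(-self.lung_center_offset, 0.0, r),
        ]

    def target_circle(self, offset: float | None = None) -> Circle2D | None:
        if self.target_diameter <= 0:
            return None
        off = self.target_offset if offset is None else offset
        th = self.electrode_angle(self.target_direction_electrode)
        return Circle2D(off * np.sin(th), off * np.cos(th), self.target_diameter / 2.0)

    def validate(self) -> None:
        if self.arrangement not in ("external", "internal"):
            raise PhantomGeometryError(f"unknown arrangement {self.arrangement!r}")
        if self.n_electrodes < 4:
            raise PhantomGeometryError("need at least 4 electrodes")
        if self.contact_impedance <= 0:
            raise PhantomGeometryError("contact impedance must be positive")
        margin = 0.02
        interior: list[tuple[str, Circle2D]] = []
        if self.arrangement == "internal":
            interior.append(("channel", Circle2D(0.0, 0.0, self.channel_radius)))
        interior += [("lung", c) for c in self.lung_circles()]
        tc = self.target_circle()
        if tc is not None:
            if self.target_offset < 0:
                raise PhantomGeometryError("target offset must be non-negative")
            interior.append(("target", tc))
        for name, c in interior:
            if np.hypot(c.cx, c.cy) + c.r > self.radius - margin:
                raise PhantomGeometryError(f"{name} cylinder reaches the boundary wall")
        for i, (na, ca) in enumerate(interior):
            for nb, cb in interior[i + 1 :]:
                if {na, nb} == {"lung"}:
                    continue  # the two lungs are allowed to touch each other only
                d = np.hypot(ca.cx - cb.cx, ca.cy - cb.cy)
                if d < ca.r + cb.r + margin:
                    raise PhantomGeometryError(f"{na} and {nb} cylinders collide")
        ez = self.electrode_center_z
        if not (self.electrode_diameter / 2 < ez < self.boundary_height - self.electrode_diameter / 2):
            raise PhantomGeometryError("electrode band leaves the cylinder wall")

    @property
    def internal_band_height(self) -> float:
        """Height of the internal ring electrode with disc-equivalent area."""
        disc = np.pi * (self.electrode_diameter / 2.0) ** 2
        return disc / (2.0 * np.pi * self.channel_radius)


@dataclass
class Mesh:
    """Conforming tetrahedral mesh of one phantom with labelled facets."""

    vertices: np.ndarray  # (n, 3)
    elements: np.ndarray  # (m, 4)
    element_region: np.ndarray  # (m,) codes from REGION_NAMES
    facets: dict  # surface label -> (k, 3) vertex triples
    info: dict

    _volumes: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def volumes(self) -> np.ndarray:
        if self._volumes is None:
            self._volumes = meshing.tet_volumes(self.vertices, self.elements)
        return self._volumes

    def centroids(self) -> np.ndarray:
        return self.vertices[self.elements].mean(axis=1)

    def total_volume(self) -> float:
        return float(self.volumes().sum())

    def region_volume(self, code: int) -> float:
        return float(self.volumes()[self.element_region == code].sum())

    def facet_areas(self, faces: np.ndarray) -> np.ndarray:
        return meshing.triangle_areas(self.vertices, faces)


@dataclass
class Electrode:
    number: int  # 1-based
    facets: np.ndarray  # (k, 3)
    center: np.ndarray  # (3,)
    z_contact: float

    def area(self, mesh: Mesh) -> float:
        return float(mesh.facet_areas(self.facets).sum())


@dataclass
class ElectrodeSet:
    electrodes: list

    @property
    def n(self) -> int:
        return len(self.electrodes)

    def __iter__(self):
        return iter(self.electrodes)

    def __getitem__(self, i):
        return self.electrodes[i]


def _density_scale(density) -> tuple[float, int]:
    if density == "forward":
        return _FORWARD_SCALE, _SALT["forward"]
    if density == "inverse":
        return _INVERSE_SCALE, _SALT["inverse"]
    n = int(density)
    if n < 200:
        raise ValueError("target element count too small to mesh the phantom")
    return (_N_REF / n) ** (1.0 / 3.0), _SALT["custom"]


def build_phantom(spec: PhantomSpec, density="forward", seed: int = 0):
    """Mesh one phantom and locate its electrodes.

    ``density`` is ``"forward"`` (fine evaluation mesh), ``"inverse"``
    (coarser evaluation mesh, a distinct discretization for reconstruction)
    or an integer target element count for reduced-size experiments.
    Deterministic for a given (spec, density, seed).

    Returns ``(Mesh, ElectrodeSet)``.
    """
    spec.validate()
    f, salt = _density_scale(density)
    mesh_seed = int(np.random.SeedSequence([int(seed), salt]).generate_state(1)[0])

    R, H = spec.radius, spec.boundary_height
    internal = spec.arrangement == "internal"
    n_wall = spec.n_electrodes - 1 if internal else spec.n_electrodes
    wall_numbers = list(range(1, n_wall + 1))
    centers = np.array([spec.electrode_angle(l) for l in wall_numbers])
    half_arc = (spec.electrode_diameter / 2.0) / R

    angles = meshing.graded_ring_angles(
        centers, half_arc, min(_ANG_FINE0 * f, 0.060), _ANG_COARSE0 * f
    )
    circles = list(spec.lung_circles())
    tc = spec.target_circle()
    if tc is not None:
        circles.append(tc)
    hole = Circle2D(0.0, 0.0, spec.channel_radius) if internal else None
    cs = meshing.build_cross_section(
        R, _H0 * f, angles, circles, hole, hole_nodes=16, seed=mesh_seed
    )

    ez, er = spec.electrode_center_z, spec.electrode_diameter / 2.0
    extra = (ez,)
    if internal:
        hb = spec.internal_band_height / 2.0
        extra = (ez, ez - hb, ez + hb)
    z = meshing.graded_layers(
        H, ez - er, ez + er, min(_HZ_FINE0 * f, 0.055), _HZ_COARSE0 * f, extra
    )

    verts, tets, column = meshing.extrude_to_tets(cs, z)

    # region labels: constant per extruded column, classified by the parent
    # triangle centroid against the full-height feature cylinders
    tri_cent = cs.points[cs.triangles].mean(axis=1)
    tri_region = np.full(len(cs.triangles), REGION_BACKGROUND, dtype=np.int8)
    for c in spec.lung_circles():
        tri_region[c.contains(tri_cent)] = REGION_LUNG
    if tc is not None:
        tri_region[tc.contains(tri_cent)] = REGION_TARGET
    element_region = tri_region[column]

    facets = _classify_boundary(verts, tets, R, spec.channel_radius if internal else None, H)
    electrodes = _locate_electrodes(spec, verts, facets, wall_numbers)

    mesh = Mesh(
        vertices=verts,
        elements=tets,
        element_region=element_region,
        facets=facets,
        info={
            "arrangement": spec.arrangement,
            "target_offset": spec.target_offset,
            "target_diameter": spec.target_diameter,
            "density": density,
            "seed": int(seed),
            "radius": R,
            "height": H,
            "electrode_plane_z": spec.electrode_center_z,
            "channel_radius": spec.channel_radius if internal else None,
        },
    )
    return mesh, electrodes


def _classify_boundary(verts, tets, R, channel_radius, H):
    faces = meshing.boundary_triangles(tets, len(verts))
    vr = np.hypot(verts[:, 0], verts[:, 1])
    fz = verts[faces][:, :, 2]
    fr = vr[faces]
    tol = 1e-7
    bottom = np.all(fz < tol, axis=1)
    top = np.all(fz > H - tol, axis=1)
    wall = np.all(np.abs(fr - R) < tol, axis=1) & ~bottom & ~top
    out = {"bottom": faces[bottom], "top": faces[top], "wall": faces[wall]}
    used = bottom | top | wall
    if channel_radius is not None:
        chan = np.all(np.abs(fr - channel_radius) < tol, axis=1) & ~used
        out["channel"] = faces[chan]
        used |= chan
    if not np.all(used):
        raise RuntimeError(f"{np.sum(~used)} boundary facets left unclassified")
    return out


def _locate_electrodes(spec: PhantomSpec, verts, facets, wall_numbers):
    R, ez, er = spec.radius, spec.electrode_center_z, spec.electrode_diameter / 2.0
    wall = facets["wall"]
    cent = verts[wall].mean(axis=1)
    th = np.arctan2(cent[:, 0], cent[:, 1])  # angle from +y, matching electrode layout
    electrodes = []
    for num in wall_numbers:
        th_e = spec.electrode_angle(num)
        dth = (th - th_e + np.pi) % (2 * np.pi) - np.pi
        d2 = (R * dth) ** 2 + (cent[:, 2] - ez) ** 2
        sel = wall[d2 <= er**2]
        if len(sel) == 0:
            raise RuntimeError(f"electrode {num}: mesh too coarse, empty facet patch")
        center = np.array([R * np.sin(th_e), R * np.cos(th_e), ez])
        electrodes.append(Electrode(num, sel, center, spec.contact_impedance))
    if spec.arrangement == "internal":
        chan = facets["channel"]
        cz = verts[chan][:, :, 2].mean(axis=1)
        hb = spec.internal_band_height / 2.0
        sel = chan[np.abs(cz - ez) <= hb + 1e-12]
        if len(sel) == 0:
            raise RuntimeError("internal electrode: empty facet band")
        electrodes.append(
            Electrode(
                spec.n_electrodes, sel, np.array([0.0, spec.channel_radius, ez]),
                spec.contact_impedance,
            )
        )
    return ElectrodeSet(electrodes)


@dataclass
class ConductivityField:
    """Per-element real conductivity (S/m) on a mesh."""

    sigma: np.ndarray
    mesh: Mesh

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (self.mesh.n_elements,):
            raise ValueError("one conductivity value per element required")
        if np.any(self.sigma <= 0):
            raise ValueError("conductivity must be positive")


def assign_conductivity(
    mesh: Mesh,
    spec: PhantomSpec,
    target_offset: float | None = None,
    include_target: bool = True,
) -> ConductivityField:
    """Paint tissue conductivities onto a mesh by element-centroid tests.

    Every element centroid is tested against the full-height feature
    cylinders: inside the blood target -> 0.7 S/m (unless ``include_target``
    is off, which yields the reference state for difference imaging), inside
    a lung -> 0.13 S/m, otherwise background 0.48 S/m.
    """
    cent = mesh.centroids()[:, :2]
    sig = np.full(mesh.n_elements, spec.conductivities["background"])
    for c in spec.lung_circles():
        sig[c.contains(cent)] = spec.conductivities["lung"]
    if include_target:
        tc = spec.target_circle(target_offset)
        if tc is not None:
            sig[tc.contains(cent)] = spec.conductivities["blood"]
    return ConductivityField(sig, mesh)


def sweep_positions(spec: PhantomSpec | None = None) -> np.ndarray:
    """Radial target offsets of the position sweep: 0.2 to 0.8 in 0.1 steps."""
    return np.round(np.linspace(0.2, 0.8, 7), 10)


def refine_phantom(mesh: Mesh, electrodes: ElectrodeSet) -> tuple[Mesh, ElectrodeSet]:
    """Uniform (red) refinement: every tetrahedron splits into eight children.

    Edge midpoints become new vertices; each boundary and electrode triangle
    splits into its four nested children, so the refined phantom is the same
    geometry observed on a strictly finer discretization — the oracle used
    for convergence checks.
    """
    verts, tets = mesh.vertices, mesh.elements
    edges = np.concatenate(
        [tets[:, [a, b]] for a, b in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))]
    )
    edges = np.sort(edges, axis=1)
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    mid_index = {tuple(e): len(verts) + i for i, e in enumerate(uniq)}
    new_verts = np.vstack([verts, verts[uniq].mean(axis=1)])

    def mid(a, b):
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        return np.array([mid_index[(x, y)] for x, y in zip(lo, hi)])

    v0, v1, v2, v3 = tets.T
    m01, m02, m03 = mid(v0, v1), mid(v0, v2), mid(v0, v3)
    m12, m13, m23 = mid(v1, v2), mid(v1, v3), mid(v2, v3)
    children = [
        (v0, m01, m02, m03),
        (v1, m01, m12, m13),
        (v2, m02, m12, m23),
        (v3, m03, m13, m23),
        (m01, m23, m02, m03),
        (m01, m23, m03, m13),
        (m01, m23, m13, m12),
        (m01, m23, m12, m02),
    ]
    new_tets = np.concatenate([np.column_stack(c) for c in children])
    new_region = np.tile(mesh.element_region, 8)
    vol = meshing.tet_volumes(new_verts, new_tets)
    neg = vol < 0
    new_tets[neg] = new_tets[neg][:, [0, 1, 3, 2]]

    def split_tris(tris):
        if len(tris) == 0:
            return tris.reshape(0, 3)
        a, b, c = tris.T
        mab, mac, mbc = mid(a, b), mid(a, c), mid(b, c)
        return np.concatenate(
            [
                np.column_stack(t)
                for t in ((a, mab, mac), (b, mab, mbc), (c, mac, mbc), (mab, mbc, mac))
            ]
        )

    facets = {k: split_tris(v) for k, v in mesh.facets.items()}
    new_mesh = Mesh(new_verts, new_tets, new_region, facets, dict(mesh.info))
    new_els = ElectrodeSet(
        [Electrode(e.number, split_tris(e.facets), e.center, e.z_contact) for e in electrodes]
    )
    return new_mesh, new_els
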