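"""GREIT-style figures of merit on a mid-plane raster of a reconstruction.

A 3-D reconstruction is resampled onto a square pixel grid (default 64x64)
across the electrode plane z = 0.4, masked to the boundary circle.  The
image is thresholded at one quarter of its peak amplitude (in the sign
direction of the peak, the GREIT convention) and compared with the known
target footprint:

* AR   -- amplitude response: summed image amplitude over the quarter set
          divided by the summed true contrast over the true target pixels;
          1 for perfect recovery.
* PE   -- position error: distance between the amplitude-weighted centre of
          gravity of the quarter set and the true target centre (model units).
* RES  -- resolution: quarter-set pixel count as a fraction of all
          in-boundary pixels.
* SD   -- shape deformation: quarter-set area falling outside the true
          target, normalised by the true target area.
* RNG  -- ringing: opposite-sign amplitude in an annulus around the quarter
          set (outer radius twice the set's equivalent radius), relative to
          the in-set amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .inverse import LCurveResult, Reconstruction
from .phantom import Mesh

__all__ = [
    "PlanarImage",
    "TargetTruth",
    "MeritReport",
    "rasterize",
    "quarter_amplitude_set",
    "merit_report",
]


@dataclass
class PlanarImage:
    """Pixel raster of a reconstruction at the electrode plane."""

    values: np.ndarray  # (g, g), 0 outside mask
    mask: np.ndarray  # (g, g) bool, True inside the boundary circle and mesh
    xs: np.ndarray  # pixel-centre coordinates along each axis
    pixel_size: float

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.xs, self.xs, indexing="ij")


@dataclass
class TargetTruth:
    """Ground-truth target footprint on the raster."""

    center: np.ndarray  # (2,) model units
    radius: float
    pixels: np.ndarray  # (g, g) bool, subset of the image mask
    contrast: float  # true conductivity change (S/m)


@dataclass
class MeritReport:
    AR: float
    PE: float
    RES: float
    SD: float
    RNG: float
    lambda_corner: float
    valid: bool = True
    note: str = ""


def rasterize(reconstruction: Reconstruction, grid_size: int = 64, z: float | None = None,
              mesh: Mesh | None = None) -> PlanarImage:
    """Point-sample a per-element image onto a pixel grid at the electrode plane.

    Each pixel takes the value of the element containing its centre; pixel
    centres outside the mesh (outside the boundary circle, or inside the
    internal-electrode channel) are masked, never extrapolated.
    """
    mesh = mesh if mesh is not None else reconstruction.mesh
    if mesh is None:
        raise ValueError("rasterize needs the inverse mesh")
    R = mesh.info.get("radius", 1.0)
    if z is None:
        z = 0.5 * mesh.info.get("height", 0.8)
        # prefer the electrode plane when recorded
        z = mesh.info.get("electrode_plane_z", z)
    px = 2.0 * R / grid_size
    xs = -R + px * (np.arange(grid_size) + 0.5)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    inside = np.hypot(X, Y) < R
    pts = np.column_stack([X[inside], Y[inside], np.full(inside.sum(), z)])
    elem = _locate(mesh, pts)
    values = np.zeros((grid_size, grid_size))
    mask = np.zeros((grid_size, grid_size), dtype=bool)
    found = elem >= 0
    idx = np.flatnonzero(inside.ravel())[found]
    mask.ravel()[idx] = True
    values.ravel()[idx] = reconstruction.delta_sigma[elem[found]]
    return PlanarImage(values, mask, xs, px)


def _locate(mesh: Mesh, pts: np.ndarray, k: int = 60) -> np.ndarray:
    """Index of the element containing each point, -1 when outside the mesh."""
    cent = mesh.centroids()
    tree = cKDTree(cent)
    k = min(k, mesh.n_elements)
    _, cand = tree.query(pts, k=k)
    cand = np.atleast_2d(cand)
    verts = mesh.vertices
    elems = mesh.elements
    out = np.full(len(pts), -1, dtype=np.int64)
    todo = np.ones(len(pts), dtype=bool)
    for j in range(k):
        if not todo.any():
            break
        rows = np.flatnonzero(todo)
        e = cand[rows, j]
        p0 = verts[elems[e, 0]]
        T = np.stack([verts[elems[e, i]] - p0 for i in (1, 2, 3)], axis=2)
        rhs = (pts[rows] - p0)[..., None]
        try:
            lam = np.linalg.solve(T, rhs)[..., 0]
        except np.linalg.LinAlgError:  # rare singular tet batches
            lam = np.einsum("nij,njk->nik", np.linalg.pinv(T), rhs)[..., 0]
        ok = (lam.min(axis=1) >= -1e-9) & (lam.sum(axis=1) <= 1 + 1e-9)
        hit = rows[ok]
        out[hit] = e[ok]
        todo[hit] = False
    return out


def target_truth(image: PlanarImage, center, radius: float, contrast: float) -> TargetTruth:
    """Footprint of a cylindrical target on an image raster."""
    X, Y = image.pixel_centers()
    center = np.asarray(center, dtype=float)
    pix = (np.hypot(X - center[0], Y - center[1]) < radius) & image.mask
    return TargetTruth(center, radius, pix, contrast)


def quarter_amplitude_set(image: PlanarImage) -> np.ndarray:
    """Boolean pixel set at or above one quarter of the peak amplitude.

    The peak's sign defines the target direction; an all-zero image yields
    an empty set.
    """
    v = np.where(image.mask, image.values, 0.0)
    peak = np.abs(v).max()
    if peak == 0:
        return np.zeros_like(image.mask)
    sign = np.sign(v.ravel()[np.argmax(np.abs(v))])
    return (sign * v >= 0.25 * peak) & image.mask


def merit_report(
    image: PlanarImage,
    truth: TargetTruth,
    lcurve: LCurveResult | None = None,
) -> MeritReport:
    """All five figures of merit for one image against its ground truth."""
    lam = lcurve.lambda_corner_normalized if lcurve is not None else np.nan
    q = quarter_amplitude_set(image)
    if not q.any():
        return MeritReport(np.nan, np.nan, np.nan, np.nan, np.nan, lam, False, "empty quarter set")
    if not truth.pixels.any():
        return MeritReport(np.nan, np.nan, np.nan, np.nan, np.nan, lam, False, "empty true target")
    v = np.where(image.mask, image.values, 0.0)
    sign = np.sign(v.ravel()[np.argmax(np.abs(v))])
    amp = sign * v  # amplitudes in the target's sign direction

    ar = float(amp[q].sum() / (truth.contrast * truth.pixels.sum()))

    X, Y = image.pixel_centers()
    w = amp[q]
    cog = np.array([np.sum(X[q] * w), np.sum(Y[q] * w)]) / w.sum()
    pe = float(np.hypot(*(cog - truth.center)))

    res = float(q.sum() / image.mask.sum())
    sd = float(np.logical_and(q, ~truth.pixels).sum() / truth.pixels.sum())

    r_eq = np.sqrt(q.sum() / np.pi) * image.pixel_size
    ring = (np.hypot(X - cog[0], Y - cog[1]) <= 2.0 * r_eq) & image.mask & ~q
    opposite = np.minimum(amp[ring], 0.0)
    rng = float(-opposite.sum() / w.sum())

    return MeritReport(ar, pe, res, sd, rng, lam)
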