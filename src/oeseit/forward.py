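"""Complete-electrode-model (CEM) forward solver and measurement simulation.

The forward problem is the quasi-static conduction equation
``div(sigma grad u) = 0`` with electrode boundary conditions that include a
surface contact impedance ``z_c``: under electrode ``l`` the potential
satisfies ``u + z_c sigma du/dn = U_l`` and the current through the patch
integrates to the injected ``I_l``; elsewhere the normal current vanishes.
Discretised with first-order tetrahedral elements this yields the standard
symmetric augmented system in the vertex potentials and the ``N_el``
electrode voltages.  The system is singular up to an additive constant;
uniqueness comes from charge conservation (``sum I_l = 0``, guaranteed by
pair drive) plus a gauge: either ``sum U_l = 0`` (default) or pinning the
potential at a ground node at the bottom centre of the tank.

Measurements follow the adjacent (neighbouring-pair) protocol: current is
driven through each pair ``(l, l+1)`` in turn and voltages are read from
every adjacent pair not touching a drive electrode, ``N_el * (N_el - 3)``
values per frame (208 for 16 electrodes).  Gaussian measurement noise with
standard deviation equal to a fixed fraction of the largest voltage in the
reference frame models instrument noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .phantom import ConductivityField, ElectrodeSet, Mesh

__all__ = [
    "StimulationProtocol",
    "adjacent_protocol",
    "CEMSystem",
    "assemble_cem",
    "solve_forward",
    "ForwardSolution",
    "MeasurementFrame",
    "NoiseModel",
    "apply_noise",
    "difference_frame",
]


@dataclass(frozen=True)
class StimulationProtocol:
    """Drive pairs and measurement pairs of one frame (0-based electrode indices)."""

    n_el: int
    amplitude: float  # drive current, amperes
    injections: np.ndarray  # (n_inj, 2) drive+ / drive-
    measurements: np.ndarray  # (n_meas, 3) injection index, m+, m-

    @property
    def n_measurements(self) -> int:
        return len(self.measurements)

    def compatible(self, other: "StimulationProtocol") -> bool:
        return (
            self.n_el == other.n_el
            and np.array_equal(self.injections, other.injections)
            and np.array_equal(self.measurements, other.measurements)
        )


def adjacent_protocol(n_el: int, amplitude: float = 1e-3) -> StimulationProtocol:
    """Adjacent drive / adjacent measure protocol.

    Drive pairs are ``(l, l+1 mod n)``; for each drive, measurement pairs are
    the adjacent pairs ``(m, m+1 mod n)`` with neither electrode driven,
    taken in ring order starting just past the drive pair.  This yields
    ``n_el * (n_el - 3)`` measurements per frame.
    """
    if n_el < 4:
        raise ValueError("adjacent protocol needs at least 4 electrodes")
    injections = np.array([(l, (l + 1) % n_el) for l in range(n_el)])
    rows = []
    for i, (a, b) in enumerate(injections):
        for k in range(n_el - 3):
            m = (b + 1 + k) % n_el
            rows.append((i, m, (m + 1) % n_el))
    return StimulationProtocol(
        n_el=n_el,
        amplitude=float(amplitude),
        injections=injections,
        measurements=np.array(rows),
    )


def p1_gradients(mesh: Mesh) -> np.ndarray:
    """Constant shape-function gradients per element, shape (m, 4, 3)."""
    p = mesh.vertices[mesh.elements]
    edges = p[:, 1:] - p[:, :1]  # rows: p1-p0, p2-p0, p3-p0
    inv = np.linalg.inv(edges)  # columns of inv are gradients of lambda_1..3
    G = np.empty((mesh.n_elements, 4, 3))
    G[:, 1:] = np.transpose(inv, (0, 2, 1))
    G[:, 0] = -G[:, 1:].sum(axis=1)
    return G


class CEMSystem:
    """Assembled and factorised CEM operator for one conductivity state."""

    def __init__(self, mesh, electrodes, matrix, gauge, gradients, ndof):
        self.mesh = mesh
        self.electrodes = electrodes
        self.matrix = matrix
        self.gauge = gauge
        self.gradients = gradients
        self.ndof = ndof
        self._lu = None

    @property
    def n_el(self) -> int:
        return self.electrodes.n

    def _factor(self):
        if self._lu is None:
            try:
                self._lu = spla.splu(self.matrix.tocsc())
            except RuntimeError as err:
                raise RuntimeError(
                    "CEM system is singular -- no gauge was applied"
                ) from err
        return self._lu

    def solve_currents(self, currents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Solve for one or more electrode current patterns.

        ``currents`` has shape (n_patterns, n_el), each row summing to zero.
        Returns ``(potentials, voltages)`` of shapes (n_patterns, n_nodes)
        and (n_patterns, n_el).
        """
        if self.gauge == "none":
            # the pair-drive rhs is consistent, so an LU factor can return one
            # of the infinitely many solutions silently; refuse instead
            raise RuntimeError("CEM system is singular: no gauge was applied")
        currents = np.atleast_2d(np.asarray(currents, dtype=float))
        if not np.allclose(currents.sum(axis=1), 0.0, atol=1e-15):
            raise ValueError("injected currents must conserve charge (sum to zero)")
        n = self.mesh.n_vertices
        rhs = np.zeros((self.ndof, len(currents)))
        rhs[n : n + self.n_el] = currents.T
        x = self._factor().solve(rhs)
        if not np.all(np.isfinite(x)):
            raise RuntimeError("CEM solve produced non-finite values (singular system?)")
        resid = np.linalg.norm(self.matrix @ x - rhs)
        if resid > 1e-6 * max(np.linalg.norm(rhs), 1e-300):
            raise RuntimeError(
                "CEM solve did not converge (singular system -- no gauge applied?)"
            )
        return x[:n].T, x[n : n + self.n_el].T


def assemble_cem(
    mesh: Mesh,
    sigma: ConductivityField,
    electrodes: ElectrodeSet,
    gauge: str = "sum",
) -> CEMSystem:
    """Assemble the symmetric CEM system for one conductivity field.

    ``gauge`` is ``"sum"`` (enforce ``sum U_l = 0`` by a rank-one
    augmentation that leaves the physical solution untouched), ``"node"``
    (pin the potential at the vertex nearest the bottom centre, the tank's
    ground-electrode position) or ``"none"`` (leave the singular operator;
    solving then fails loudly).
    """
    if sigma.mesh is not mesh:
        raise ValueError("conductivity field was built on a different mesh")
    n = mesh.n_vertices
    L = electrodes.n
    ndof = n + L
    G = p1_gradients(mesh)
    vol = mesh.volumes()

    # volume stiffness: sum_e vol_e sigma_e g_i . g_j
    K = np.einsum("e,eik,ejk->eij", vol * sigma.sigma, G, G)
    conn = mesh.elements
    rows = np.repeat(conn, 4, axis=1).ravel()
    cols = np.tile(conn, (1, 4)).ravel()
    data = [K.ravel()]
    rr = [rows]
    cc = [cols]

    tri_mass = (np.ones((3, 3)) + np.eye(3)) / 12.0
    for k, el in enumerate(electrodes):
        areas = mesh.facet_areas(el.facets)
        total = areas.sum()
        if total <= 0 or len(el.facets) == 0:
            raise ValueError(f"electrode {el.number} has zero contact area")
        zc = el.z_contact
        if zc <= 0:
            raise ValueError("contact impedance must be positive")
        # node-node surface mass
        m_local = np.einsum("f,ij->fij", areas / zc, tri_mass)
        fr = np.repeat(el.facets, 3, axis=1).ravel()
        fc = np.tile(el.facets, (1, 3)).ravel()
        rr.append(fr)
        cc.append(fc)
        data.append(m_local.ravel())
        # node-voltage coupling
        w = np.repeat(areas / (3.0 * zc), 3)
        fn = el.facets.ravel()
        ecol = np.full(len(fn), n + k)
        rr += [fn, ecol]
        cc += [ecol, fn]
        data += [-w, -w]
        # voltage-voltage diagonal
        rr.append([n + k])
        cc.append([n + k])
        data.append([total / zc])

    A = sp.coo_matrix(
        (np.concatenate([np.asarray(d, dtype=float).ravel() for d in data]),
         (np.concatenate([np.asarray(r).ravel() for r in rr]),
          np.concatenate([np.asarray(c).ravel() for c in cc]))),
        shape=(ndof, ndof),
    ).tocsr()

    if gauge == "sum":
        # rank-one augmentation on the electrode-voltage block: makes the
        # operator definite and pins sum U_l = 0 without touching the physics
        scale = A.diagonal()[:n].mean()
        ed = np.arange(n, ndof)
        rows1 = np.repeat(ed, L)
        cols1 = np.tile(ed, L)
        aug = sp.coo_matrix(
            (np.full(L * L, scale), (rows1, cols1)), shape=(ndof, ndof)
        )
        A = (A + aug).tocsr()
    elif gauge == "node":
        bottom = mesh.vertices[:, 2] < mesh.vertices[:, 2].min() + 1e-9
        idx = np.where(bottom)[0]
        ground = idx[np.argmin(np.hypot(*mesh.vertices[idx, :2].T))]
        A = A.tolil()
        A[ground, :] = 0.0
        A[:, ground] = 0.0
        A[ground, ground] = 1.0
        A = A.tocsr()
    elif gauge != "none":
        raise ValueError(f"unknown gauge {gauge!r}")

    return CEMSystem(mesh, electrodes, A, gauge, G, ndof)


@dataclass
class ForwardSolution:
    """Interior potentials and electrode voltages for every injection."""

    potentials: np.ndarray  # (n_inj, n_nodes), volts
    voltages: np.ndarray  # (n_inj, n_el), volts
    protocol: StimulationProtocol


@dataclass
class MeasurementFrame:
    """One frame of electrode-pair voltages (volts)."""

    values: np.ndarray
    protocol: StimulationProtocol
    noise_level: float | None = None
    noise_seed: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.protocol.n_measurements:
            raise ValueError("frame length does not match the protocol")


def solve_forward(
    system: CEMSystem, protocol: StimulationProtocol
) -> tuple[ForwardSolution, MeasurementFrame]:
    """Simulate every injection of a protocol and extract the noise-free frame."""
    if protocol.n_el != system.n_el:
        raise ValueError("protocol electrode count does not match the phantom")
    currents = np.zeros((len(protocol.injections), protocol.n_el))
    rows = np.arange(len(protocol.injections))
    currents[rows, protocol.injections[:, 0]] = protocol.amplitude
    currents[rows, protocol.injections[:, 1]] = -protocol.amplitude
    potentials, voltages = system.solve_currents(currents)
    inj, mp, mm = protocol.measurements.T
    values = voltages[inj, mp] - voltages[inj, mm]
    sol = ForwardSolution(potentials, voltages, protocol)
    return sol, MeasurementFrame(values, protocol)


@dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian measurement noise.

    The standard deviation is ``relative_level`` times the root-mean-square
    voltage of the reference frame, identical on every channel.  This reads
    a noise level quoted as a percentage "of the signal" against the typical
    measured voltage while keeping the noise white (``C_n`` proportional to
    the identity), so the unweighted residual norm is the correctly whitened
    one.
    """

    relative_level: float = 5e-4
    seed: int = 0

    def __post_init__(self):
        if self.relative_level < 0:
            raise ValueError("noise level must be non-negative")


def apply_noise(
    frame: MeasurementFrame,
    model: NoiseModel,
    reference: MeasurementFrame | None = None,
) -> MeasurementFrame:
    """Add seed-reproducible Gaussian noise to a frame.

    ``reference`` supplies the amplitude scale (defaults to the frame
    itself); pass the homogeneous/reference frame so both states of a
    difference pair receive identically scaled noise.
    """
    if model.relative_level == 0:
        return replace(frame, noise_level=0.0, noise_seed=model.seed)
    ref = frame if reference is None else reference
    std = model.relative_level * float(
        np.linalg.norm(ref.values) / np.sqrt(len(ref.values))
    )
    rng = np.random.default_rng(model.seed)
    noisy = frame.values + rng.normal(0.0, std, size=len(frame.values))
    return MeasurementFrame(noisy, frame.protocol, model.relative_level, model.seed)


def difference_frame(
    frame_with_target: MeasurementFrame, frame_reference: MeasurementFrame
) -> MeasurementFrame:
    """Element-wise voltage difference ``V_target - V_ref`` for difference imaging."""
    if not frame_with_target.protocol.compatible(frame_reference.protocol):
        raise ValueError("frames were measured under different protocols")
    return MeasurementFrame(
        frame_with_target.values - frame_reference.values,
        frame_with_target.protocol,
        frame_with_target.noise_level,
        frame_with_target.noise_seed,
    )
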