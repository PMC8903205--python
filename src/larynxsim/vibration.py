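"""Flow-induced self-sustained oscillation of the layered vocal folds.

Each of 15 coronal slices carries a 2-D plane-strain finite-element mesh of
10 x 6 cells (two linear triangles per cell, 77 nodes per slice) of
incompressible, transversally isotropic gel (shear modulus mu, viscosity
eta, penalty bulk term).  Anterior-posterior fibers couple corresponding
nodes of adjacent slices as tensioned strings whose tension comes from the
layer fiber stress; this is where the equivalent shear modulus mu' acts.
Boundaries are fixed on the anterior, posterior and lateral surfaces and
pressure-loaded on the inferior, medial and superior surfaces.  Midline
collision is handled by a one-sided penalty spring with extra damping
during contact.

Time integration is symplectic (semi-implicit) Euler at the acoustic
sampling rate, with the gel damping term handled implicitly through a
prefactorized constant operator so that tissue and waveguide stay
synchronous at 44.1 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import SimConfig, DEFAULT_CONFIG, KPA_TO_CGS
from .posture import (ActivationState, PosturalGeometry, MedialSurfaceField,
                      medial_surface, posture_from_activation, compute_strain,
                      compute_adduction, apply_posture_rules)
from .tissue import (TissueState, load_layer_params, tissue_state_for_posture,
                     FOLD_LAYERS)
from .aeroacoustics import Waveguide, glottal_flow, surface_pressures

__all__ = [
    "FoldMesh",
    "SystemOperators",
    "VibrationState",
    "VibroAcousticRecord",
    "build_mesh",
    "assemble_system",
    "step",
    "simulate",
    "static_deflection",
    "mechanical_energy",
]

LAYER_OF_INDEX = {0: "SLLP", 1: "LIG", 2: "TA"}


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class FoldMesh:
    """Finite-element mesh of one vocal fold (15 slices x 77 nodes)."""

    geom: PosturalGeometry
    y: np.ndarray            # (n_slices,) slice positions, cm
    z: np.ndarray            # (n_rows+1,) node row heights, cm
    X: np.ndarray            # (n_slices, n_rows+1, n_cols+1) lateral coords, cm
    xi0: np.ndarray          # (n_slices, n_rows+1) rest medial half-widths, cm
    tri: np.ndarray          # (n_elements, 3) local node ids within a slice
    tri_layer: np.ndarray    # (n_elements,) 0 SLLP / 1 LIG / 2 muscle
    node_layer: np.ndarray   # (n_nodes_per_slice,) layer index per node
    fixed: np.ndarray        # (n_slices, n_rows+1, n_cols+1) bool
    side: str = "right"
    n_cols: int = 10
    n_rows: int = 6

    @property
    def n_slices(self) -> int:
        return len(self.y)

    @property
    def nodes_per_slice(self) -> int:
        return (self.n_rows + 1) * (self.n_cols + 1)

    @property
    def elements_per_slice(self) -> int:
        return len(self.tri)

    @property
    def n_dof(self) -> int:
        return 2 * self.n_slices * self.nodes_per_slice

    def local_id(self, j: int, i: int) -> int:
        return j * (self.n_cols + 1) + i

    def dof(self, s: int, j: int, i: int, comp: int) -> int:
        return 2 * (s * self.nodes_per_slice + self.local_id(j, i)) + comp

    @property
    def sign(self) -> float:
        return 1.0 if self.side == "right" else -1.0

    def to_json(self, path) -> None:
        """Export the mesh description (counts, coordinates, layers, BCs)."""
        import json
        from pathlib import Path
        doc = {
            "side": self.side,
            "n_slices": self.n_slices,
            "nodes_per_slice": self.nodes_per_slice,
            "elements_per_slice": self.elements_per_slice,
            "y_cm": self.y.tolist(),
            "z_cm": self.z.tolist(),
            "x_cm": self.X.tolist(),
            "triangles": self.tri.tolist(),
            "triangle_layer": self.tri_layer.tolist(),
            "fixed": self.fixed.astype(int).tolist(),
            "geometry": {"L": self.geom.L, "T": self.geom.T,
                         "xi01": self.geom.xi01, "xi02": self.geom.xi02,
                         "xib": self.geom.xib, "epsilon": self.geom.epsilon},
        }
        Path(path).write_text(json.dumps(doc))


def _depth_profile(z: np.ndarray, T: float, depth: float) -> np.ndarray:
    """Lateral depth of the fold body vs height (curved lateral boundary)."""
    return depth * (0.5 + 0.5 * np.sin(np.pi * z / T))


def build_mesh(geom: PosturalGeometry, cfg: SimConfig = DEFAULT_CONFIG,
               side: str = "right") -> FoldMesh:
    """Mesh the posture: medial column on xi0(y, z), curved lateral boundary."""
    if geom.T <= 0.0 or geom.L <= 0.0:
        raise DegenerateGeometryError(f"degenerate posture L={geom.L}, T={geom.T}")
    nc, nr, ns = cfg.n_cols, cfg.n_rows, cfg.n_slices
    y = np.linspace(0.0, geom.L, ns)
    z = np.linspace(0.0, geom.T, nr + 1)
    surf = medial_surface(geom, y, z)
    depth = _depth_profile(z, geom.T, cfg.depth_cm)
    frac = np.arange(nc + 1) / nc
    sign = 1.0 if side == "right" else -1.0
    # X[s, j, i] = xi0(y_s, z_j) + frac_i * depth(z_j), mirrored for the left fold
    X = sign * (surf.xi0[:, :, None] + frac[None, None, :] * depth[None, :, None])

    tri = []
    tri_layer = []
    n_sllp, n_lig, n_mus = cfg.layer_cols
    assert n_sllp + n_lig + n_mus == nc
    for j in range(nr):
        for i in range(nc):
            n00 = j * (nc + 1) + i
            n10 = n00 + 1
            n01 = n00 + (nc + 1)
            n11 = n01 + 1
            layer = 0 if i < n_sllp else (1 if i < n_sllp + n_lig else 2)
            tri.append((n00, n10, n11))
            tri_layer.append(layer)
            tri.append((n00, n11, n01))
            tri_layer.append(layer)
    node_layer = np.array([0 if min(i, nc - 1) < n_sllp
                           else (1 if min(i, nc - 1) < n_sllp + n_lig else 2)
                           for j in range(nr + 1) for i in range(nc + 1)])

    fixed = np.zeros((ns, nr + 1, nc + 1), dtype=bool)
    fixed[:, :, nc] = True       # lateral surface
    fixed[0, :, :] = True        # anterior boundary
    fixed[ns - 1, :, :] = True   # posterior boundary
    return FoldMesh(geom=geom, y=y, z=z, X=X, xi0=surf.xi0,
                    tri=np.array(tri), tri_layer=np.array(tri_layer),
                    node_layer=node_layer, fixed=fixed, side=side,
                    n_cols=nc, n_rows=nr)


@dataclass
class SystemOperators:
    """Assembled linear operators of the fold (full-DOF, fixed rows zeroed)."""

    mesh: FoldMesh
    K: sp.csr_matrix          # total stiffness (gel + strings + penalty)
    K_gel: sp.csr_matrix      # in-plane gel part (damping is proportional to it)
    C: sp.csr_matrix          # viscous damping
    M: np.ndarray             # lumped masses, (n_dof,)
    free: np.ndarray          # (n_dof,) bool
    node_area: np.ndarray     # (n_slices, nodes_per_slice) coronal area share
    dy: float                 # slice spacing
    medial_dof_x: np.ndarray  # (n_slices, n_rows+1) x-DOF of medial nodes
    k_contact: np.ndarray     # (n_slices, n_rows+1) collision spring
    c_contact: np.ndarray     # (n_slices, n_rows+1) collision damping
    # precomputed surface-load index/weight arrays (interior slices)
    med_dofs: np.ndarray = None   # (n_int, n_rows+1) medial x-DOFs
    med_w: np.ndarray = None      # (n_rows+1,) medial edge weights dz*dy
    inf_dofs: np.ndarray = None   # flat z-DOFs of inferior surface nodes
    inf_w: np.ndarray = None      # matching dx*dy weights
    sup_dofs: np.ndarray = None
    sup_w: np.ndarray = None
    _solve: object = None     # prefactorized (M + dt C)

    def factorize(self, dt: float) -> None:
        n = len(self.M)
        A = sp.diags(self.M) + dt * self.C
        self._solve = spla.factorized(A.tocsc())


def _triangle_stiffness(xy: np.ndarray, D: np.ndarray, t: float):
    """CST stiffness (6x6), area and lumped mass share for one triangle."""
    x, zc = xy[:, 0], xy[:, 1]
    b = np.array([zc[1] - zc[2], zc[2] - zc[0], zc[0] - zc[1]])
    c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]])
    area2 = x[0] * b[0] + x[1] * b[1] + x[2] * b[2]
    area = 0.5 * abs(area2)
    if area <= 0:
        raise DegenerateGeometryError("zero-area element")
    B = np.zeros((3, 6))
    B[0, 0::2] = b
    B[1, 1::2] = c
    B[2, 0::2] = c
    B[2, 1::2] = b
    B /= area2
    Ke = area * t * B.T @ D @ B
    return Ke, area


def assemble_system(mesh: FoldMesh, tissue: TissueState,
                    cfg: SimConfig = DEFAULT_CONFIG) -> SystemOperators:
    """Assemble stiffness, damping and mass operators for the fold.

    Gel: plane-strain linear triangles with shear modulus mu and a penalty
    bulk modulus (incompressibility).  Fibers: strings between matching
    nodes of adjacent slices, tension sigma_fiber(layer) times the node's
    coronal area share, contributing stiffness T/dy on both in-plane
    components.  Damping is stiffness-proportional with time constant
    eta/mu (gel part only).  Masses are lumped from the tissue density.
    """
    mu, eta, rho = tissue.mu, tissue.eta, cfg.density
    lam = cfg.penalty_factor * mu
    D = np.array([[lam + 2 * mu, lam, 0.0],
                  [lam, lam + 2 * mu, 0.0],
                  [0.0, 0.0, mu]])
    # deviatoric (shear-only) operator: viscosity acts on shear strain rate,
    # not on the numerical incompressibility penalty
    D_shear = np.array([[2 * mu, 0.0, 0.0],
                        [0.0, 2 * mu, 0.0],
                        [0.0, 0.0, mu]])
    ns, nps = mesh.n_slices, mesh.nodes_per_slice
    ndof = mesh.n_dof
    dy = mesh.geom.L / (ns - 1)

    rows, cols, vals, vals_shear = [], [], [], []
    M = np.zeros(ndof)
    node_area = np.zeros((ns, nps))
    for s in range(ns):
        coords = np.stack([mesh.X[s].ravel(), np.tile(mesh.z, (mesh.n_cols + 1, 1)).T.ravel()],
                          axis=1)
        base = 2 * s * nps
        for e, (tri, lay) in enumerate(zip(mesh.tri, mesh.tri_layer)):
            xy = coords[tri]
            Ke, area = _triangle_stiffness(xy, D, dy)
            Ke_sh, _ = _triangle_stiffness(xy, D_shear, dy)
            dofs = np.empty(6, dtype=int)
            dofs[0::2] = base + 2 * tri
            dofs[1::2] = base + 2 * tri + 1
            rows.append(np.repeat(dofs, 6))
            cols.append(np.tile(dofs, 6))
            vals.append(Ke.ravel())
            vals_shear.append(Ke_sh.ravel())
            m_share = rho * area * dy / 3.0
            for n in tri:
                M[base + 2 * n] += m_share
                M[base + 2 * n + 1] += m_share
                node_area[s, n] += area / 3.0

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    K_gel = sp.csr_matrix((np.concatenate(vals), (rows, cols)),
                          shape=(ndof, ndof))
    K_shear = sp.csr_matrix((np.concatenate(vals_shear), (rows, cols)),
                            shape=(ndof, ndof))

    # inter-slice fiber strings
    sigma = np.array([max(0.0, tissue.sigma_fiber[LAYER_OF_INDEX[k]])
                      for k in range(3)])
    srows, scols, svals = [], [], []
    for s in range(ns - 1):
        tension = sigma[mesh.node_layer] * 0.5 * (node_area[s] + node_area[s + 1])
        k_str = tension / dy
        for n in range(nps):
            if k_str[n] == 0.0:
                continue
            for comp in (0, 1):
                d1 = 2 * (s * nps + n) + comp
                d2 = 2 * ((s + 1) * nps + n) + comp
                srows.extend([d1, d1, d2, d2])
                scols.extend([d1, d2, d1, d2])
                svals.extend([k_str[n], -k_str[n], -k_str[n], k_str[n]])
    K_str = sp.csr_matrix((svals, (srows, scols)), shape=(ndof, ndof))

    free_nodes = ~mesh.fixed.reshape(ns, nps)
    free = np.repeat(free_nodes.ravel(), 2)
    P = sp.diags(free.astype(float))
    K_gel = (P @ K_gel @ P).tocsr()
    K_shear = (P @ K_shear @ P).tocsr()
    K_str = (P @ K_str @ P).tocsr()
    K = (K_gel + K_str).tocsr()
    C = ((eta / mu) * K_shear).tocsr()
    M[~free] = rho * 1e-6  # inert placeholder; fixed DOFs never move

    medial_dof_x = np.array([[mesh.dof(s, j, 0, 0) for j in range(mesh.n_rows + 1)]
                             for s in range(ns)])
    kdiag = np.asarray(K.diagonal())
    k_contact = cfg.collision_factor * kdiag[medial_dof_x]
    k_contact[k_contact <= 0] = cfg.collision_factor * np.median(kdiag[kdiag > 0])
    c_contact = np.sqrt(k_contact * M[medial_dof_x])

    # surface-load bookkeeping (interior slices; end slices are fixed)
    sign = mesh.sign
    dz = np.gradient(mesh.z)
    med_dofs = medial_dof_x[1:ns - 1]
    med_w = dz * dy
    inf_dofs, inf_w, sup_dofs, sup_w = [], [], [], []
    for s in range(1, ns - 1):
        for row, dofs, wlist in ((0, inf_dofs, inf_w),
                                 (mesh.n_rows, sup_dofs, sup_w)):
            xrow = sign * mesh.X[s, row, :]
            dx = np.gradient(xrow)
            for i in range(mesh.n_cols):  # lateral column is fixed
                dofs.append(mesh.dof(s, row, i, 1))
                wlist.append(dx[i] * dy)

    return SystemOperators(mesh=mesh, K=K, K_gel=K_gel, C=C, M=M, free=free,
                           node_area=node_area, dy=dy,
                           medial_dof_x=medial_dof_x,
                           k_contact=k_contact, c_contact=c_contact,
                           med_dofs=med_dofs, med_w=med_w,
                           inf_dofs=np.array(inf_dofs), inf_w=np.array(inf_w),
                           sup_dofs=np.array(sup_dofs), sup_w=np.array(sup_w))


@dataclass
class VibrationState:
    """Nodal displacement/velocity state of the fold during time stepping."""

    u: np.ndarray
    v: np.ndarray
    t: float = 0.0
    contact: np.ndarray | None = None
    xi_m: float = 0.0


def mechanical_energy(ops: SystemOperators, state: VibrationState) -> float:
    """Kinetic + elastic strain energy of the current state."""
    u, v = state.u, state.v
    return float(0.5 * v @ (ops.M * v) + 0.5 * u @ (ops.K @ u))


def step(ops: SystemOperators, state: VibrationState, forces: np.ndarray,
         cfg: SimConfig = DEFAULT_CONFIG) -> VibrationState:
    """One symplectic Euler step with implicit gel damping.

    ``forces`` is the full-DOF external force vector (aerodynamic +
    collision spring).  Collision damping is applied as a local implicit
    velocity relaxation on contacting medial nodes (split step), which
    keeps the update unconditionally stable in the damping terms.
    """
    dt = cfg.dt
    if ops._solve is None:
        ops.factorize(dt)
    rhs = ops.M * state.v + dt * (forces - ops.K @ state.u)
    v = ops._solve(rhs)
    v[~ops.free] = 0.0
    if state.contact is not None and state.contact.any():
        dof = ops.medial_dof_x[state.contact]
        v[dof] /= 1.0 + dt * ops.c_contact[state.contact] / ops.M[dof]
    u = state.u + dt * v
    u[~ops.free] = 0.0
    return VibrationState(u=u, v=v, t=state.t + dt, contact=state.contact,
                          xi_m=state.xi_m)


def static_deflection(ops: SystemOperators, forces: np.ndarray) -> np.ndarray:
    """Direct static solve K u = F on the free DOFs (quasi-static oracle)."""
    idx = np.where(ops.free)[0]
    Kff = ops.K[np.ix_(idx, idx)]
    u = np.zeros(ops.mesh.n_dof)
    u[idx] = spla.spsolve(Kff.tocsc(), forces[idx])
    return u


@dataclass
class VibroAcousticRecord:
    """Time series of one simulated phonation at the acoustic rate."""

    fs: float
    po: np.ndarray             # radiated oral pressure, dyn/cm^2
    ug: np.ndarray             # glottal flow, cm^3/s
    Ag: np.ndarray             # minimum glottal area, cm^2
    L: np.ndarray              # vocal fold length (constant posture), cm
    sigma: dict[str, np.ndarray]  # per-layer fiber stress, dyn/cm^2
    aborted: bool = False
    geom: PosturalGeometry | None = None
    tissue: TissueState | None = None

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.po)) / self.fs

    def area_amplitude(self, t0: float, t1: float) -> float:
        """Peak-to-peak glottal-area amplitude within [t0, t1] seconds."""
        i0, i1 = int(t0 * self.fs), int(t1 * self.fs)
        seg = self.Ag[i0:i1]
        if len(seg) == 0:
            return 0.0
        return float(seg.max() - seg.min())


def _aero_forces(ops: SystemOperators, p_rows: np.ndarray, p_sub: float,
                 p_supra: float, half_widths: np.ndarray):
    """Aerodynamic surface loads + collision penalty on the full DOF vector."""
    mesh = ops.mesh
    F = np.zeros(mesh.n_dof)
    sign = mesh.sign
    # medial surface: intraglottal pressure pushes the fold laterally;
    # inferior/superior surfaces see the sub-/supraglottal pressures
    F[ops.med_dofs] = sign * p_rows[None, :] * ops.med_w[None, :]
    F[ops.inf_dofs] += p_sub * ops.inf_w
    F[ops.sup_dofs] -= p_supra * ops.sup_w

    # midline collision: one-sided penalty spring
    contact = half_widths < 0.0
    if contact.any():
        F[ops.medial_dof_x[contact]] += sign * (
            ops.k_contact[contact] * (-half_widths[contact]))
    return F, contact


def simulate(act: ActivationState, cfg: SimConfig = DEFAULT_CONFIG,
             layers: dict | None = None, duration: float | None = None,
             side: str = "right") -> VibroAcousticRecord:
    """Run the coupled posture -> tissue -> vibration + acoustics pipeline.

    Returns the vibro-acoustic record at 44.1 kHz.  The lung pressure ramps
    up over ``cfg.pressure_ramp_s`` and a tiny seeded initial nodal velocity
    breaks the symmetric equilibrium so that oscillation can start.
    """
    if layers is None:
        layers = load_layer_params()
    duration = cfg.duration_s if duration is None else duration

    eps = compute_strain(act, layers, cfg)
    xi02 = compute_adduction(act, cfg)
    geom = apply_posture_rules(eps, act.aTA, xi02, cfg)
    tissue = tissue_state_for_posture(eps, act.aTA, layers, cfg)
    mesh = build_mesh(geom, cfg, side=side)
    ops = assemble_system(mesh, tissue, cfg)
    ops.factorize(cfg.dt)
    wg = Waveguide(cfg=cfg)

    n = int(round(duration * cfg.fs))
    rng = np.random.default_rng(cfg.seed)
    u = np.zeros(mesh.n_dof)
    v = np.zeros(mesh.n_dof)
    v[ops.free] = cfg.perturb_velocity * rng.standard_normal(int(ops.free.sum()))
    state = VibrationState(u=u, v=v)

    po = np.zeros(n)
    ug_arr = np.zeros(n)
    ag_arr = np.zeros(n)
    rho = cfg.rho_air
    PL = act.PL
    sign = mesh.sign
    ug = 0.0
    aborted = False
    check_every = 200
    for k in range(n):
        ramp = min(1.0, state.t / cfg.pressure_ramp_s) if cfg.pressure_ramp_s > 0 else 1.0
        wg.set_lung_pressure(PL * ramp)

        half_w = sign * mesh.X[:, :, 0] + sign * state.u[ops.medial_dof_x]
        a_z = 2.0 * np.trapezoid(np.clip(half_w, 0.0, None), mesh.y, axis=0)
        Ag = float(max(a_z.min(), 0.0))
        ug = glottal_flow(Ag, wg.f_sub[-1], wg.b_sup[0], wg.Zs, wg.Ze, rho)
        p_sub, p_supra = wg.glottal_pressures(ug)
        p_rows = surface_pressures(a_z, ug, p_sub, p_supra, rho)

        F, contact = _aero_forces(ops, p_rows, p_sub, p_supra, half_w)
        state.contact = contact
        state = step(ops, state, F, cfg)

        po[k] = wg.step(ug)
        ug_arr[k] = ug
        ag_arr[k] = Ag

        if k % check_every == 0:
            umax = np.abs(state.u).max()
            if not np.isfinite(umax) or umax > cfg.abort_displacement_cm:
                aborted = True
                po, ug_arr, ag_arr = po[:k], ug_arr[:k], ag_arr[:k]
                break

    L_arr = np.full(len(po), geom.L)
    sigma = {"SLLP": np.full(len(po), tissue.sigma_y["SLLP"]),
             "LIG": np.full(len(po), tissue.sigma_y["LIG"]),
             "MUS": np.full(len(po), tissue.sigma_fiber["TA"])}
    return VibroAcousticRecord(fs=cfg.fs, po=po, ug=ug_arr, Ag=ag_arr,
                               L=L_arr, sigma=sigma, aborted=aborted,
                               geom=geom, tissue=tissue)
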