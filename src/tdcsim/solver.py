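"""Quasi-static finite-volume solver for the potential in a voxel conductor.

The stimulation potential obeys the current-conservation equation
``div(sigma grad(phi)) = 0`` inside the body, with the electrode pads held at
fixed potentials and every outer boundary insulated.  The discretisation is a
7-point box-integration scheme on the voxel grid: each face between two
voxels carries a conductance equal to the harmonic mean of the two voxel
conductivities times face area over spacing.  A zero-conductivity neighbour
(air, internal air) yields zero face conductance, which is exactly the
no-flux condition — this realises both the insulated bounding box and the
skin-air interface at once, so no boundary rows are needed.

Current is injected by holding the active pad(s) at +1 V and the reference
pad at 0 V, then rescaling the linear solution so the net current through the
active pad surface equals the requested total (1 mA by default); this is
valid because the problem is linear in the boundary data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import LinearOperator, cg, spsolve

from .conductivity import ConductivityTable, assign_conductivity
from .montage import PlacedMontage
from .volumes import Grid, ScalarVolume, VectorVolume

__all__ = [
    "SolverConfig",
    "LinearSystem",
    "SolveInfo",
    "SolvedCase",
    "face_conductances",
    "assemble_system",
    "solve_potential",
    "compute_fields",
    "measure_current",
    "normalize_to_current",
    "divergence_residual",
    "solve_montage",
]

_SIX = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class SolverConfig:
    """Linear-solver options.

    ``solver_kind='auto'`` uses a sparse direct factorisation for small
    systems and Jacobi-preconditioned conjugate gradients otherwise.
    """

    relative_residual_tolerance: float = 1e-8
    max_iterations: int = 100_000
    solver_kind: str = "auto"  # "auto" | "cg" | "direct"
    direct_threshold: int = 40_000

    def __post_init__(self):
        if self.relative_residual_tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.solver_kind not in ("auto", "cg", "direct"):
            raise ValueError(f"unknown solver_kind {self.solver_kind!r}")


def face_conductances(sigma: np.ndarray, spacing_mm) -> list[np.ndarray]:
    """Per-axis face conductances in siemens (harmonic mean * area / spacing)."""
    s = np.asarray(spacing_mm, dtype=float) * 1e-3  # m
    geo = [s[1] * s[2] / s[0], s[0] * s[2] / s[1], s[0] * s[1] / s[2]]
    out = []
    for a in range(3):
        s1 = sigma[tuple(slice(None, -1) if i == a else slice(None) for i in range(3))]
        s2 = sigma[tuple(slice(1, None) if i == a else slice(None) for i in range(3))]
        tot = s1 + s2
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(tot > 0, 2.0 * s1 * s2 / np.where(tot > 0, tot, 1.0), 0.0)
        out.append(h * geo[a])
    return out


@dataclass
class LinearSystem:
    """Assembled reduced system A x = b over the free conductive voxels."""

    A: csr_matrix
    b: np.ndarray
    unknown_index: np.ndarray   # flat voxel -> row index, -1 elsewhere
    conductive: np.ndarray      # boolean grid mask
    dirichlet_phi: np.ndarray   # grid array, NaN off the pads
    grid: Grid
    sigma: np.ndarray
    active: np.ndarray
    reference: np.ndarray


def assemble_system(sigma_vol: ScalarVolume, placed: PlacedMontage,
                    active_potential: float = 1.0) -> LinearSystem:
    """Build the finite-volume system with Dirichlet pad nodes.

    Active pads are tied to one common potential (+1 V provisional), the
    reference pad to 0 V.  Raises if either node set is empty or if the two
    are not connected through conductive voxels.
    """
    grid = sigma_vol.grid
    sigma = sigma_vol.values
    active, reference = placed.active_nodes, placed.reference_nodes
    if not active.any() or not reference.any():
        raise ValueError("empty electrode node set")
    conductive = sigma > 0
    comp, _ = ndimage.label(conductive, _SIX)
    if not (set(np.unique(comp[active])) & set(np.unique(comp[reference]))) - {0}:
        raise ValueError("active and reference pads are not connected through conductive voxels")

    dirichlet = active | reference
    phi_d = np.full(grid.shape, np.nan)
    phi_d[active] = active_potential
    phi_d[reference] = 0.0

    unknown = conductive & ~dirichlet
    nvox = int(np.prod(grid.shape))
    uidx = np.full(nvox, -1, dtype=np.int64)
    uflat = unknown.ravel()
    uidx[uflat] = np.arange(int(uflat.sum()))

    lin = np.arange(nvox).reshape(grid.shape)
    dflat = dirichlet.ravel()
    phid_flat = phi_d.ravel()
    diag = np.zeros(nvox)
    bfull = np.zeros(nvox)
    rows, cols, vals = [], [], []
    for a, g in enumerate(face_conductances(sigma, grid.spacing)):
        L = lin[tuple(slice(None, -1) if i == a else slice(None) for i in range(3))].ravel()
        R = lin[tuple(slice(1, None) if i == a else slice(None) for i in range(3))].ravel()
        gv = g.ravel()
        nz = gv > 0
        L, R, gv = L[nz], R[nz], gv[nz]
        np.add.at(diag, L, gv)
        np.add.at(diag, R, gv)
        both = uflat[L] & uflat[R]
        rows.extend([uidx[L[both]], uidx[R[both]]])
        cols.extend([uidx[R[both]], uidx[L[both]]])
        vals.extend([-gv[both], -gv[both]])
        for s1, s2 in ((L, R), (R, L)):
            m = uflat[s1] & dflat[s2]
            np.add.at(bfull, s1[m], gv[m] * phid_flat[s2[m]])

    diag_u = diag[uflat]
    diag_u[diag_u == 0] = 1.0  # isolated conductive voxels: pin phi to 0
    n = int(uflat.sum())
    r = np.concatenate(rows + [np.arange(n)])
    c = np.concatenate(cols + [np.arange(n)])
    v = np.concatenate(vals + [diag_u])
    A = coo_matrix((v, (r, c)), shape=(n, n)).tocsr()
    return LinearSystem(A, bfull[uflat], uidx, conductive, phi_d, grid, sigma, active, reference)


@dataclass
class SolveInfo:
    method: str
    iterations: int
    relative_residual: float


def solve_potential(system: LinearSystem, config: SolverConfig | None = None
                    ) -> tuple[ScalarVolume, SolveInfo]:
    """Solve the assembled system; returns the potential (V) on the full grid.

    Air voxels carry phi = 0 by convention and are excluded from all physics.
    """
    if config is None:
        config = SolverConfig()
    A, b = system.A, system.b
    n = A.shape[0]
    direct = config.solver_kind == "direct" or (config.solver_kind == "auto" and n <= config.direct_threshold)
    if direct:
        x = spsolve(A.tocsc(), b)
        res = float(np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300))
        info = SolveInfo("direct", 1, res)
    else:
        d = A.diagonal()
        Minv = LinearOperator((n, n), matvec=lambda r: r / d)
        count = {"it": 0}

        def cb(_):
            count["it"] += 1

        x, flag = cg(A, b, rtol=config.relative_residual_tolerance, atol=0.0,
                     maxiter=config.max_iterations, M=Minv, callback=cb)
        res = float(np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300))
        if flag != 0:
            raise RuntimeError(
                f"conjugate gradients did not converge in {config.max_iterations} iterations "
                f"(relative residual {res:.3e})"
            )
        info = SolveInfo("cg+jacobi", count["it"], res)
    phi = np.zeros(system.grid.shape)
    phi.ravel()[system.unknown_index >= 0] = x[system.unknown_index[system.unknown_index >= 0]]
    dir_mask = np.isfinite(system.dirichlet_phi)
    phi[dir_mask] = system.dirichlet_phi[dir_mask]
    return ScalarVolume(system.grid, phi, units="V"), info


def compute_fields(phi_vol: ScalarVolume, sigma_vol: ScalarVolume
                   ) -> tuple[VectorVolume, VectorVolume]:
    """Electric field E = -grad(phi) (V/m) and current density J = sigma E (A/m^2).

    Gradients are central differences on conductive voxels, one-sided where a
    neighbour is air, and zero where both neighbours along an axis are air.
    Air voxels carry zero field by definition.
    """
    grid = phi_vol.grid
    phi = phi_vol.values
    sigma = sigma_vol.values
    cond = sigma > 0
    E = np.zeros((3, *grid.shape))
    for a in range(3):
        h = grid.spacing[a] * 1e-3  # m
        cp = np.zeros_like(cond)
        cm = np.zeros_like(cond)
        pp = np.zeros_like(phi)
        pm = np.zeros_like(phi)
        src = tuple(slice(1, None) if i == a else slice(None) for i in range(3))
        dst = tuple(slice(None, -1) if i == a else slice(None) for i in range(3))
        cp[dst] = cond[src]
        pp[dst] = phi[src]
        cm[src] = cond[dst]
        pm[src] = phi[dst]
        grad = np.zeros_like(phi)
        both = cp & cm
        grad[both] = (pp[both] - pm[both]) / (2 * h)
        only_p = cp & ~cm
        grad[only_p] = (pp[only_p] - phi[only_p]) / h
        only_m = cm & ~cp
        grad[only_m] = (phi[only_m] - pm[only_m]) / h
        E[a] = np.where(cond, -grad, 0.0)
    J = sigma[None, ...] * E
    return VectorVolume(grid, E, units="V/m"), VectorVolume(grid, J, units="A/m^2")


def measure_current(phi_vol: ScalarVolume, sigma_vol: ScalarVolume, node_mask: np.ndarray) -> float:
    """Net current (A) leaving a voxel set through its closed face surface."""
    phi = phi_vol.values
    sigma = sigma_vol.values
    cond = sigma > 0
    total = 0.0
    for a, g in enumerate(face_conductances(sigma, phi_vol.grid.spacing)):
        sl1 = tuple(slice(None, -1) if i == a else slice(None) for i in range(3))
        sl2 = tuple(slice(1, None) if i == a else slice(None) for i in range(3))
        inL = node_mask[sl1] & cond[sl2] & ~node_mask[sl2]
        inR = node_mask[sl2] & cond[sl1] & ~node_mask[sl1]
        total += float(np.sum(g[inL] * (phi[sl1][inL] - phi[sl2][inL])))
        total += float(np.sum(g[inR] * (phi[sl2][inR] - phi[sl1][inR])))
    return total


def plane_current(phi_vol: ScalarVolume, sigma_vol: ScalarVolume, axis: int, index: int) -> float:
    """Current (A) crossing the grid plane between slices index and index+1."""
    mask = np.zeros(phi_vol.grid.shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[axis] = slice(None, index + 1)
    mask[tuple(sl)] = True
    return measure_current(phi_vol, sigma_vol, mask)


def normalize_to_current(phi: ScalarVolume, E: VectorVolume, J: VectorVolume,
                         sigma_vol: ScalarVolume, placed: PlacedMontage,
                         target_mA: float | None = None):
    """Scale phi, E, J so the net active-pad current equals the target.

    Returns ``(phi, E, J, achieved_mA)`` with the achieved current re-measured
    after scaling.  Raises if the provisional current is essentially zero
    (open circuit).
    """
    if target_mA is None:
        target_mA = placed.spec.injected_current_mA
    I = measure_current(phi, sigma_vol, placed.active_nodes)
    if abs(I) < 1e-15:
        raise RuntimeError("provisional injected current is ~0 A: open circuit between pads")
    k = (target_mA * 1e-3) / I
    phi2 = ScalarVolume(phi.grid, phi.values * k, units="V")
    E2 = VectorVolume(E.grid, E.values * k, units=E.units)
    J2 = VectorVolume(J.grid, J.values * k, units=J.units)
    achieved = measure_current(phi2, sigma_vol, placed.active_nodes) * 1e3
    return phi2, E2, J2, achieved


def divergence_residual(phi_vol: ScalarVolume, sigma_vol: ScalarVolume) -> np.ndarray:
    """Discrete net current (A) out of each voxel: should vanish off-electrode."""
    phi = phi_vol.values
    out = np.zeros_like(phi)
    for a, g in enumerate(face_conductances(sigma_vol.values, phi_vol.grid.spacing)):
        sl1 = tuple(slice(None, -1) if i == a else slice(None) for i in range(3))
        sl2 = tuple(slice(1, None) if i == a else slice(None) for i in range(3))
        f = g * (phi[sl1] - phi[sl2])   # current from voxel 1 to voxel 2
        out[sl1] += f
        out[sl2] -= f
    return out


@dataclass
class SolvedCase:
    """One montage solved on one phantom, normalised to the injected current."""

    placed: PlacedMontage
    sigma: ScalarVolume
    phi: ScalarVolume
    E: VectorVolume
    J: VectorVolume
    achieved_mA: float
    info: SolveInfo


def solve_montage(placed: PlacedMontage, table: ConductivityTable | None = None,
                  config: SolverConfig | None = None,
                  target_mA: float | None = None) -> SolvedCase:
    """Assign conductivities, solve, derive fields and normalise the current."""
    sigma = assign_conductivity(placed.volume, table)
    system = assemble_system(sigma, placed)
    phi, info = solve_potential(system, config)
    E, J = compute_fields(phi, sigma)
    phi, E, J, achieved = normalize_to_current(phi, E, J, sigma, placed, target_mA)
    return SolvedCase(placed, sigma, phi, E, J, achieved, info)
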