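"""Analytic series potential for concentric-sphere volume conductors.

Verification standard for the voxel solver: for a homogeneous or multilayer
sphere with a point current source and sink on its outer surface (insulated
elsewhere), the potential separates into a Legendre series

    phi(r, gamma) = sum_n R_n(r) [ P_n(cos gamma_src) - P_n(cos gamma_snk) ]

with per-shell radial parts ``A r^n + B r^-(n+1)`` chained across interfaces
by continuity of phi and of the radial current density.  The recursion uses
radially scaled basis functions so no term overflows at high order.  The
degree-0 term cancels between source and sink, so the series starts at n = 1.

This is an exact solution of the same boundary-value problem the
finite-volume solver discretises, in the spherical limit; the comparison
(:func:`oracle_compare`) excludes a small band around the electrodes where
the point-source potential is singular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ShellModel", "analytic_potential", "oracle_compare", "solve_shell_fd"]


@dataclass
class ShellModel:
    """Concentric shells (radii ascending, mm), surface electrodes, current."""

    radii_mm: tuple[float, ...]
    sigmas_S_per_m: tuple[float, ...]
    source: tuple[float, float, float]   # unit vector, current +I enters here
    sink: tuple[float, float, float]     # unit vector, current -I
    current_mA: float = 1.0
    truncation_order: int = 200

    def __post_init__(self):
        r = np.asarray(self.radii_mm, dtype=float)
        if len(r) != len(self.sigmas_S_per_m):
            raise ValueError("need one conductivity per shell")
        if np.any(np.diff(r) <= 0) or r[0] <= 0:
            raise ValueError("shell radii must be positive and strictly increasing")
        if any(s <= 0 for s in self.sigmas_S_per_m):
            raise ValueError("shell conductivities must be positive")
        if self.truncation_order < 1:
            raise ValueError("truncation order must be >= 1")
        for name in ("source", "sink"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, tuple(v / np.linalg.norm(v)))

    # ------------------------------------------------------------------ I/O
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "radii_mm": list(self.radii_mm),
            "sigmas_S_per_m": list(self.sigmas_S_per_m),
            "source": list(self.source), "sink": list(self.sink),
            "current_mA": self.current_mA, "truncation_order": self.truncation_order,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ShellModel":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["radii_mm"]), tuple(d["sigmas_S_per_m"]),
                   tuple(d["source"]), tuple(d["sink"]),
                   d.get("current_mA", 1.0), d.get("truncation_order", 200))


def _radial_coefficients(model: ShellModel) -> tuple[np.ndarray, np.ndarray]:
    """Scaled coefficients (A, B), shape (L, nshell).

    Within shell j (outer radius b_j) the radial part is
    ``A[n,j] (r/b_j)^n + B[n,j] (b_j/r)^(n+1)``; B of the innermost shell is
    zero (regularity at the origin).
    """
    radii = np.asarray(model.radii_mm, dtype=float) * 1e-3  # m
    sig = np.asarray(model.sigmas_S_per_m, dtype=float)
    L = model.truncation_order
    ns = np.arange(1, L + 1, dtype=float)
    nshell = len(radii)
    A = np.zeros((L, nshell))
    B = np.zeros((L, nshell))
    A[:, 0] = 1.0
    for j in range(nshell - 1):
        bj, bj1 = radii[j], radii[j + 1]
        t = (bj / bj1) ** ns            # <= 1
        s = (bj1 / bj) ** (ns + 1)      # >= 1
        u = A[:, j] + B[:, j]
        v = (sig[j] / sig[j + 1]) * (ns * A[:, j] - (ns + 1) * B[:, j])
        A[:, j + 1] = ((ns + 1) * u + v) / ((2 * ns + 1) * t)
        B[:, j + 1] = (ns * u - v) / ((2 * ns + 1) * s)
    # outer boundary: sigma dphi/dr at R equals the point-source surface density
    R = radii[-1]
    I = model.current_mA * 1e-3
    flux = sig[-1] * (ns * A[:, -1] - (ns + 1) * B[:, -1]) / R
    c = I * (2 * ns + 1) / (4 * np.pi * R**2) / flux
    return A * c[:, None], B * c[:, None]


def _legendre_table(x: np.ndarray, L: int) -> np.ndarray:
    """P_n(x) for n = 1..L, shape (L, len(x)), by the three-term recurrence."""
    out = np.empty((L, len(x)))
    pm1 = np.ones_like(x)
    p = x.copy()
    out[0] = p
    for n in range(1, L):
        pm1, p = p, ((2 * n + 1) * x * p - n * pm1) / (n + 1)
        out[n] = p
    return out


def analytic_potential(model: ShellModel, points_mm: np.ndarray,
                       tail_tol: float | None = None) -> tuple[np.ndarray, float]:
    """Series potential (V) at interior points; returns ``(phi, tail_estimate)``.

    ``tail_estimate`` is the largest magnitude of the final series term
    relative to the evaluated potential scale; if ``tail_tol`` is given and
    exceeded, raises with a suggestion to increase the truncation order.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    radii = np.asarray(model.radii_mm, dtype=float)
    r = np.linalg.norm(pts, axis=1)
    if np.any(r >= radii[-1]):
        raise ValueError("all evaluation points must lie strictly inside the outer radius")
    L = model.truncation_order
    A, B = _radial_coefficients(model)
    shell = np.searchsorted(radii, r, side="left")  # first shell with b >= r
    src = np.asarray(model.source)
    snk = np.asarray(model.sink)
    with np.errstate(invalid="ignore"):
        unit = pts / np.where(r[:, None] > 0, r[:, None], 1.0)
    cs = np.clip(unit @ src, -1, 1)
    ck = np.clip(unit @ snk, -1, 1)
    cs[r == 0] = 0.0
    ck[r == 0] = 0.0
    Ps = _legendre_table(cs, L)
    Pk = _legendre_table(ck, L)
    ang = Ps - Pk  # (L, npts)

    phi = np.zeros(len(pts))
    last = np.zeros(len(pts))
    ns = np.arange(1, L + 1, dtype=float)
    rm = r * 1e-3
    for j in np.unique(shell):
        m = shell == j
        bj = radii[j] * 1e-3
        ratio = rm[m] / bj
        rad = A[:, j, None] * ratio[None, :] ** ns[:, None]
        if B[:, j].any():
            # only outer shells carry B; there ratio is bounded away from 0
            rad = rad + B[:, j, None] * ratio[None, :] ** -(ns[:, None] + 1)
        terms = rad * ang[:, m]
        phi[m] = terms.sum(axis=0)
        last[m] = np.abs(terms[-1])
    scale = max(float(np.max(np.abs(phi))), 1e-300)
    tail = float(np.max(last) / scale)
    if tail_tol is not None and tail > tail_tol:
        raise RuntimeError(
            f"series tail estimate {tail:.2e} exceeds {tail_tol:.2e}; "
            f"increase truncation_order (currently {L})"
        )
    return phi, tail


def oracle_compare(fd_phi, sigma_vol, model: ShellModel, exclude_voxels: float = 2.0,
                   electrode_radius_mm: float = 0.0) -> dict:
    """Compare a finite-volume solution of a voxelised shell model to the series.

    Both potentials are reduced to zero mean over the compared voxels (the
    two solutions fix their additive constants differently).  Voxels within a
    band of ``exclude_voxels`` voxel widths around each electrode are
    excluded (the point-source potential is singular there); when the FD
    solve used finite patches, pass their radius as ``electrode_radius_mm``
    so the band is measured from the patch rim.  Non-conductive voxels and
    voxels outside the outer shell are excluded too.  Returns relative L2 and
    max errors plus a per-shell breakdown.
    """
    grid = fd_phi.grid
    if sigma_vol.grid != grid:
        raise ValueError("potential and conductivity grids differ")
    cond = sigma_vol.values > 0
    idx = np.argwhere(cond)
    pts = grid.world(idx)
    r = np.linalg.norm(pts, axis=1)
    radii = np.asarray(model.radii_mm, dtype=float)
    vox = float(max(grid.spacing))
    keep = r < radii[-1] - 0.5 * vox
    for epos in (model.source, model.sink):
        ep = np.asarray(epos) * radii[-1]
        keep &= np.linalg.norm(pts - ep, axis=1) > electrode_radius_mm + exclude_voxels * vox
    idx, pts, r = idx[keep], pts[keep], r[keep]
    if len(pts) == 0:
        raise ValueError("no voxels left to compare: grid/model mismatch")
    ana, _tail = analytic_potential(model, pts)
    fd = fd_phi.values[tuple(idx.T)]
    ana = ana - ana.mean()
    fd = fd - fd.mean()
    diff = fd - ana
    norm = float(np.linalg.norm(ana))
    report = {
        "relative_l2": float(np.linalg.norm(diff) / norm),
        "max_abs_V": float(np.max(np.abs(diff))),
        "n_voxels": int(len(pts)),
        "per_shell": {},
    }
    shell = np.searchsorted(radii, r, side="left")
    for j in range(len(radii)):
        m = shell == j
        if m.any():
            report["per_shell"][j] = float(
                np.linalg.norm(diff[m]) / max(np.linalg.norm(ana[m]), 1e-300))
    return report


def solve_shell_fd(model: ShellModel, voxel_mm: float, config=None,
                   patch_radius_mm: float = 5.0):
    """Finite-volume solve of the voxelised shell model, scaled to its current.

    Each point electrode becomes a small Dirichlet patch of fixed physical
    radius on the outer surface (so grid refinement converges toward one
    continuum problem rather than a resolution-dependent electrode); the
    solution is rescaled so the net source current equals
    ``model.current_mA``.  Returns ``(phi, sigma_vol)`` on the voxel grid,
    for use with :func:`oracle_compare`.
    """
    # imported here to keep the oracle importable on its own
    from .solver import (SolverConfig, assemble_system, measure_current,
                         solve_potential)
    from .volumes import Grid, ScalarVolume

    radii = np.asarray(model.radii_mm, dtype=float)
    R = radii[-1]
    nhalf = int(np.ceil((R + 2 * voxel_mm) / voxel_mm))
    n = 2 * nhalf + 1
    o = -nhalf * voxel_mm
    grid = Grid((n, n, n), (voxel_mm,) * 3, (o,) * 3)
    x, y, z = grid.meshgrid()
    r = np.sqrt(x**2 + y**2 + z**2)
    sigma = np.zeros(grid.shape)
    for j in range(len(radii) - 1, -1, -1):  # outside in
        sigma[r <= radii[j]] = model.sigmas_S_per_m[j]
    sigma_vol = ScalarVolume(grid, sigma, units="S/m")

    cond = sigma > 0

    def electrode_mask(direction):
        # surface shell of conductive voxels within the patch radius of the
        # electrode point; falls back to the nearest conductive voxel when the
        # grid is coarser than the patch
        p = np.asarray(direction) * R
        d2 = (x - p[0]) ** 2 + (y - p[1]) ** 2 + (z - p[2]) ** 2
        shell = cond & (r > R - 1.25 * voxel_mm)
        m = shell & (d2 <= patch_radius_mm**2)
        if not m.any():
            idx = np.unravel_index(np.argmin(np.where(cond, d2, np.inf)), grid.shape)
            m = np.zeros(grid.shape, dtype=bool)
            m[idx] = True
        return m

    class _Placed:  # minimal stand-in carrying the node sets
        active_nodes = electrode_mask(model.source)
        reference_nodes = electrode_mask(model.sink)

    system = assemble_system(sigma_vol, _Placed)
    phi, _info = solve_potential(system, config or SolverConfig())
    I = measure_current(phi, sigma_vol, _Placed.active_nodes)
    phi = ScalarVolume(grid, phi.values * (model.current_mA * 1e-3) / I, units="V")
    return phi, sigma_vol
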