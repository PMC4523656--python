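"""Clinical tDCS electrode montages: 10-20 scalp positions and pad placement.

Electrodes are the classic clinical construction: a highly conductive
rectangular pad (5 x 7 cm) on top of a saline sponge (7 x 8 cm) that contacts
the skin.  Four standard montages are provided:

* ``A`` - F3 (active) and F4 (reference), both on the scalp;
* ``B`` - T3 active, reference on the right arm (extracephalic);
* ``C`` - C3 and C4 active (wired in parallel), reference on the right arm;
* ``D`` - Fz active, reference on the right tibia.

Scalp positions are realised as fixed (inclination, azimuth) angles of the
10-20 EEG system on the best-fit scalp sphere; F3/F4 are the spherical
midpoints of Fz-F7 and Fz-F8 as in the standard construction.  Sponge and pad
voxels occupy signed-distance bands above the nominal anatomical surface so
pads follow the local curvature; a pad therefore never touches skin directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume

__all__ = [
    "ElectrodeSpec",
    "MontageSpec",
    "PlacedMontage",
    "standard_montage",
    "locate_1020",
    "place_montage",
    "TEN_TWENTY_POSITIONS",
    "EXTRACEPHALIC_POSITIONS",
]

_SIX = ndimage.generate_binary_structure(3, 1)
_SPONGE_ID = 20
_PAD_ID = 21


def _sph(incl_deg: float, az_deg: float) -> np.ndarray:
    """Unit vector from inclination (from vertex +z) and azimuth (from +x toward +y)."""
    th, ph = np.deg2rad(incl_deg), np.deg2rad(az_deg)
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    w = np.arccos(np.clip(a @ b, -1, 1))
    v = (np.sin((1 - t) * w) * a + np.sin(t * w) * b) / np.sin(w)
    return v / np.linalg.norm(v)


def _ten_twenty_table() -> dict[str, np.ndarray]:
    # 10-20 angles on the unit sphere: midline chain in 20% steps of the
    # nasion-inion half-circle (36 deg), ear-to-ear chain likewise, outer ring
    # at 72 deg inclination with electrodes every 36 deg of azimuth.
    t = {
        "Cz": _sph(0, 0),
        "Fz": _sph(36, 0), "Pz": _sph(36, 180),
        "C3": _sph(36, 90), "C4": _sph(36, -90),
        "T3": _sph(72, 90), "T4": _sph(72, -90),
        "F7": _sph(72, 54), "F8": _sph(72, -54),
        "Fpz": _sph(72, 0), "Oz": _sph(72, 180),
    }
    t["F3"] = _slerp(t["Fz"], t["F7"], 0.5)
    t["F4"] = _slerp(t["Fz"], t["F8"], 0.5)
    return t


TEN_TWENTY_POSITIONS: dict[str, np.ndarray] = _ten_twenty_table()
EXTRACEPHALIC_POSITIONS = ("right_arm", "right_tibia")


@dataclass(frozen=True)
class ElectrodeSpec:
    """One pad+sponge electrode at a named position."""

    position: str
    role: str  # "active" | "reference"
    pad_size: tuple[float, float] = (70.0, 50.0)      # mm, (long axis, short axis)
    sponge_size: tuple[float, float] = (80.0, 70.0)   # mm
    pad_thickness: float = 1.0                        # mm
    sponge_thickness: float = 5.0                     # mm

    def __post_init__(self):
        if self.role not in ("active", "reference"):
            raise ValueError(f"role must be active/reference, got {self.role!r}")
        if self.pad_size[0] > self.sponge_size[0] or self.pad_size[1] > self.sponge_size[1]:
            raise ValueError("pad footprint must fit inside the sponge footprint")


@dataclass(frozen=True)
class MontageSpec:
    """A named set of electrodes and the total injected current."""

    name: str
    electrodes: tuple[ElectrodeSpec, ...]
    injected_current_mA: float = 1.0

    def __post_init__(self):
        roles = [e.role for e in self.electrodes]
        if roles.count("active") < 1 or roles.count("reference") != 1:
            raise ValueError("a montage needs >= 1 active and exactly 1 reference electrode")
        if self.injected_current_mA <= 0:
            raise ValueError("injected current must be positive")

    @property
    def extracephalic(self) -> bool:
        return any(e.position in EXTRACEPHALIC_POSITIONS for e in self.electrodes)


_STANDARD = {
    "A": (("F3", "active"), ("F4", "reference")),
    "B": (("T3", "active"), ("right_arm", "reference")),
    "C": (("C3", "active"), ("C4", "active"), ("right_arm", "reference")),
    "D": (("Fz", "active"), ("right_tibia", "reference")),
}


def standard_montage(name: str, injected_current_mA: float = 1.0,
                     electrode_scale: float = 1.0) -> MontageSpec:
    """One of the four standard clinical montages A-D (1 mA by default).

    ``electrode_scale`` shrinks the pad/sponge footprints proportionally, for
    reduced-size phantoms on which full-size clinical pads would not fit.
    """
    if name not in _STANDARD:
        raise KeyError(f"unknown montage {name!r}; choose one of {sorted(_STANDARD)}")
    k = electrode_scale
    return MontageSpec(
        name=name,
        electrodes=tuple(
            ElectrodeSpec(p, r, pad_size=(70.0 * k, 50.0 * k), sponge_size=(80.0 * k, 70.0 * k))
            for p, r in _STANDARD[name]
        ),
        injected_current_mA=injected_current_mA,
    )


# ------------------------------------------------------------------ placement

def _fit_scalp_sphere(vol: LabelVolume) -> tuple[np.ndarray, float]:
    """Head centre and scalp radius; from metadata or an algebraic sphere fit."""
    if "head_center" in vol.meta and "scalp_outer_radius" in vol.meta:
        return np.asarray(vol.meta["head_center"], dtype=float), float(vol.meta["scalp_outer_radius"])
    skin = vol.mask("skin")
    surf = skin & ndimage.binary_dilation(vol.labels == 0, _SIX)
    pts = vol.grid.world(np.argwhere(surf))
    if len(pts) < 10:
        raise ValueError("cannot fit a scalp sphere: too few skin-surface voxels")
    # Kasa algebraic fit: |p|^2 = 2 c.p + (r^2 - |c|^2)
    A = np.c_[2 * pts, np.ones(len(pts))]
    b = np.sum(pts**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c = sol[:3]
    return c, float(np.sqrt(sol[3] + c @ c))


def locate_1020(vol: LabelVolume, position: str):
    """Scalp point and tangent frame for a 10-20 electrode position.

    Returns ``(point, normal, long_axis, short_axis)`` in world mm; the long
    axis is the anterior-posterior tangent at the point.
    """
    if position not in TEN_TWENTY_POSITIONS:
        raise KeyError(f"unsupported 10-20 position {position!r}; "
                       f"supported: {sorted(TEN_TWENTY_POSITIONS)}")
    center, radius = _fit_scalp_sphere(vol)
    n = TEN_TWENTY_POSITIONS[position]
    point = center + radius * n
    ap = np.array([1.0, 0.0, 0.0])
    t1 = ap - (ap @ n) * n
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    surface = {"type": "sphere", "center": center.tolist(), "radius": radius}
    return point, n.copy(), t1, t2, surface


def _locate_site(vol: LabelVolume, position: str):
    if position in TEN_TWENTY_POSITIONS:
        return locate_1020(vol, position)
    sites = vol.meta.get("sites", {})
    if position not in sites:
        raise ValueError(
            f"position {position!r} requires a body phantom with a recorded site "
            f"(available: {sorted(sites) or 'none — head-only phantom'})"
        )
    s = sites[position]
    p = np.asarray(s["point"], dtype=float)
    n = np.asarray(s["normal"], dtype=float)
    n /= np.linalg.norm(n)
    t1 = np.asarray(s["long_axis"], dtype=float)
    t1 = t1 - (t1 @ n) * n
    t1 /= np.linalg.norm(t1)
    return p, n, t1, np.cross(n, t1), s["surface"]


@dataclass
class PlacedMontage:
    """Phantom with sponge/pad voxels added plus the electrode node sets."""

    volume: LabelVolume
    spec: MontageSpec
    active_nodes: np.ndarray      # boolean mask over the grid
    reference_nodes: np.ndarray
    sites: dict[str, dict] = field(default_factory=dict)


def _place_electrode(labels: np.ndarray, vol: LabelVolume, e: ElectrodeSpec, where,
                     other_centers: list[np.ndarray]) -> np.ndarray:
    """Voxelise one electrode as signed-distance shells of the nominal surface.

    The sponge occupies the band between the nominal anatomical surface
    (scalp sphere or limb cylinder, recorded with the site) and one sponge
    thickness above it, restricted to the footprint rectangle in tangent
    coordinates; the pad occupies the band above the sponge.  Because every
    tissue voxel centre lies inside the nominal surface, the sponge is
    face-adjacent to the skin staircase and the pad can only reach skin
    through the sponge.  Band thicknesses are rounded up to one voxel.

    Where two electrodes' sponge footprints would collide (large clinical
    sponges on a small head), each footprint is clipped at the
    inter-electrode bisector leaving an air gap of about one voxel, so
    distinct electrodes never merge electrically.  Returns the boolean
    pad-voxel mask.
    """
    grid = vol.grid
    p, n, t1, t2, surface = where
    vox = float(min(grid.spacing))
    t_sp = max(1, round(e.sponge_thickness / vox)) * vox
    t_pad = max(1, round(e.pad_thickness / vox)) * vox
    half = 0.5 * max(e.sponge_size) + t_sp + t_pad + 2 * vox

    # subbox around the electrode
    lo = np.maximum(0, np.floor((p - half - grid.origin) / grid.spacing).astype(int))
    hi = np.minimum(grid.shape, np.ceil((p + half - grid.origin) / grid.spacing).astype(int) + 1)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    sub = labels[sl]
    xs = grid.axis_coords(0)[sl[0]][:, None, None]
    ys = grid.axis_coords(1)[sl[1]][None, :, None]
    zs = grid.axis_coords(2)[sl[2]][None, None, :]
    dx, dy, dz = xs - p[0], ys - p[1], zs - p[2]
    u = dx * t1[0] + dy * t1[1] + dz * t1[2]
    v = dx * t2[0] + dy * t2[1] + dz * t2[2]
    shape = np.broadcast_shapes(u.shape, (len(xs), ys.shape[1], zs.shape[2]))
    near = np.ones(shape, dtype=bool)
    d_own = np.sqrt(dx**2 + dy**2 + dz**2)
    for q in other_centers:
        d_other = np.sqrt((xs - q[0]) ** 2 + (ys - q[1]) ** 2 + (zs - q[2]) ** 2)
        near &= d_own < d_other - 1.0 * vox

    if surface["type"] == "sphere":
        c = np.asarray(surface["center"], dtype=float)
        hloc = np.sqrt((xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2) - surface["radius"]
    elif surface["type"] == "cylinder_z":
        cx, cy = surface["center_xy"]
        hloc = np.sqrt((xs - cx) ** 2 + (ys - cy) ** 2) - surface["radius"]
    else:
        raise ValueError(f"unknown surface type {surface['type']!r}")
    hloc = np.broadcast_to(hloc, shape)

    sponge_fp = (np.abs(u) <= 0.5 * e.sponge_size[0]) & (np.abs(v) <= 0.5 * e.sponge_size[1]) & near
    pad_fp = (np.abs(u) <= 0.5 * e.pad_size[0]) & (np.abs(v) <= 0.5 * e.pad_size[1]) & near
    free = sub == 0
    sponge_sel = free & sponge_fp & (hloc > 0) & (hloc <= t_sp)
    sub[sponge_sel] = _SPONGE_ID
    pad_mask_sub = free & pad_fp & (hloc > t_sp) & (hloc <= t_sp + t_pad)
    sub[pad_mask_sub] = _PAD_ID

    if not pad_mask_sub.any():
        raise ValueError(f"electrode at {e.position!r} produced no pad voxels "
                         "(footprint off the surface?)")
    pad_mask = np.zeros(grid.shape, dtype=bool)
    pad_mask[sl] = pad_mask_sub
    return pad_mask


def place_montage(phantom: LabelVolume, spec: MontageSpec) -> PlacedMontage:
    """Voxelise every electrode of a montage onto a copy of the phantom.

    Deterministic; raises if an extracephalic position is requested on a
    head-only phantom or if two electrodes overlap.
    """
    if spec.extracephalic and "sites" not in phantom.meta:
        raise ValueError(
            f"montage {spec.name!r} has an extracephalic reference; a body phantom is required"
        )
    vol = phantom.copy()
    for eid, name in ((20, "sponge"), (21, "electrode_pad")):
        vol.names.setdefault(eid, name)
    frames = [_locate_site(vol, e.position) for e in spec.electrodes]
    centers = [f[0] for f in frames]
    for i, ei in enumerate(spec.electrodes):
        for j in range(i + 1, len(spec.electrodes)):
            ej = spec.electrodes[j]
            limit = 0.5 * (min(ei.pad_size) + min(ej.pad_size))
            if np.linalg.norm(centers[i] - centers[j]) < limit:
                raise ValueError(
                    f"pads at {ei.position!r} and {ej.position!r} overlap "
                    f"(centre distance below {limit:g} mm)"
                )
    sites: dict[str, dict] = {}
    active = np.zeros(vol.grid.shape, dtype=bool)
    reference = np.zeros(vol.grid.shape, dtype=bool)
    for i, e in enumerate(spec.electrodes):
        others = [c for j, c in enumerate(centers) if j != i]
        pad_mask = _place_electrode(vol.labels, vol, e, frames[i], others)
        sites[e.position] = {"point": frames[i][0].tolist(), "normal": frames[i][1].tolist()}
        if e.role == "active":
            active |= pad_mask
        else:
            reference |= pad_mask
    if (active & reference).any():
        raise ValueError("active and reference pads overlap")
    vol.meta["montage"] = spec.name
    return PlacedMontage(vol, spec, active, reference, sites)
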