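"""Parametric voxel phantoms: layered-sphere heads and simplified whole bodies.

The study needs a small family of human volume conductors differing in size
(an adult female, an adult male and an adolescent).  Real MRI-derived
anatomies are replaced by deterministic parametric phantoms:

* a head made of concentric spheres (scalp skin / skull / CSF / grey matter /
  white matter), with the deep brain structures that the dosimetry reports on
  (cerebellum, medulla oblongata, pons, midbrain, thalamus) carved out of the
  inner sphere at fixed fractional coordinates;
* a whole body assembled from primitives (head sphere, neck cylinder, trunk
  ellipsoid, arm and leg cylinders) with skin / subcutaneous-fat shells,
  muscle bulk and bone cores, so that extracephalic reference electrodes on
  the right arm or right tibia can be placed.

The family is generated by isotropic scaling of one reference adult geometry
by standing height, so the adolescent member is smaller in every linear
dimension — the property the variability analysis probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .volumes import Grid, LabelVolume

__all__ = [
    "AnthropometryParams",
    "PhantomFamily",
    "build_layered_sphere_head",
    "build_body_phantom",
    "make_phantom_family",
    "default_profiles",
    "TISSUE_IDS",
]

# Fixed label vocabulary shared by every phantom.  Names resolve in the
# conductivity table (directly or through an alias).
TISSUE_IDS: dict[int, str] = {
    0: "air",
    1: "skin",
    2: "bone",
    3: "cerebrospinal_fluid",
    4: "brain_grey_matter",
    5: "brain_white_matter",
    6: "cerebellum",
    7: "medulla_oblongata",
    8: "pons",
    9: "midbrain",
    10: "thalamus",
    11: "fat_sat",
    12: "muscle",
    20: "sponge",
    21: "electrode_pad",
}
_ID = {v: k for k, v in TISSUE_IDS.items()}

#: Reference adult (1.77 m standing height); all lengths in mm.
_REFERENCE = {
    "height": 1.77,
    "head_outer_radius": 92.0,
    "scalp": 6.0,
    "skull": 7.0,
    "csf": 3.0,
    "grey": 10.0,
    "neck_radius": 55.0,
    "neck_length": 70.0,
    "trunk_height": 560.0,
    "trunk_halfwidth": 170.0,
    "trunk_halfdepth": 100.0,
    "shoulder_radius": 40.0,
    "arm_radius": 42.0,
    "arm_length": 600.0,
    "leg_radius": 60.0,
}

_SIX = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class AnthropometryParams:
    """Dimensions of one phantom (mm except ``height`` in m)."""

    name: str
    height: float
    head_outer_radius: float
    layer_thicknesses: dict[str, float]  # scalp, skull, csf, grey; white fills the rest
    voxel_size: float = 2.0
    neck_radius: float = 55.0
    neck_length: float = 70.0
    trunk_height: float = 560.0
    trunk_halfwidth: float = 170.0
    trunk_halfdepth: float = 100.0
    shoulder_radius: float = 40.0
    arm_radius: float = 42.0
    arm_length: float = 600.0
    leg_radius: float = 60.0

    def __post_init__(self):
        dims = [self.height, self.head_outer_radius, self.voxel_size, self.neck_radius,
                self.neck_length, self.trunk_height, self.trunk_halfwidth, self.trunk_halfdepth,
                self.shoulder_radius, self.arm_radius, self.arm_length, self.leg_radius,
                *self.layer_thicknesses.values()]
        if any(d <= 0 for d in dims):
            raise ValueError(f"all dimensions of {self.name!r} must be positive")
        for key in ("scalp", "skull", "csf", "grey"):
            if key not in self.layer_thicknesses:
                raise ValueError(f"missing layer thickness {key!r}")
        if sum(self.layer_thicknesses.values()) >= self.head_outer_radius:
            raise ValueError(
                f"head layers of {self.name!r} "
                f"(sum {sum(self.layer_thicknesses.values()):g} mm) exceed the outer radius "
                f"{self.head_outer_radius:g} mm"
            )

    @classmethod
    def scaled_reference(cls, name: str, height_m: float, voxel_size: float = 2.0,
                         **overrides) -> "AnthropometryParams":
        """Isotropically scale the 1.77 m reference adult to a target height."""
        k = height_m / _REFERENCE["height"]
        p = cls(
            name=name,
            height=height_m,
            head_outer_radius=_REFERENCE["head_outer_radius"] * k,
            layer_thicknesses={t: _REFERENCE[t] * k for t in ("scalp", "skull", "csf", "grey")},
            voxel_size=voxel_size,
            **{f: _REFERENCE[f] * k for f in (
                "neck_radius", "neck_length", "trunk_height", "trunk_halfwidth",
                "trunk_halfdepth", "shoulder_radius", "arm_radius", "arm_length", "leg_radius")},
        )
        for key, val in overrides.items():
            setattr(p, key, val)
        return p


def default_profiles(voxel_size: float = 2.0) -> list[AnthropometryParams]:
    """Adult-female, adult-male and adolescent analogues (heights 1.63/1.77/1.47 m)."""
    return [
        AnthropometryParams.scaled_reference("ella_like", 1.63, voxel_size),
        AnthropometryParams.scaled_reference("duke_like", 1.77, voxel_size),
        AnthropometryParams.scaled_reference("billie_like", 1.47, voxel_size),
    ]


# --------------------------------------------------------------------- helpers

def _symmetric_axis(half_extent_mm: float, vox: float) -> tuple[int, float]:
    """Odd voxel count and origin so that world 0 is a voxel-centre plane."""
    nhalf = int(np.ceil(half_extent_mm / vox))
    n = 2 * nhalf + 1
    return n, -nhalf * vox


def _head_radii(params: AnthropometryParams, voxel: float | None = None) -> dict[str, float]:
    # Each layer is at least one voxel thick, so the skin/skull/CSF conduction
    # topology survives coarse grids where a thin layer would otherwise alias
    # away (a 6-connected walk inward from air always enters through scalp).
    floor = voxel if voxel is not None else 0.0
    t = {k: max(v, floor) for k, v in params.layer_thicknesses.items()}
    R = params.head_outer_radius
    r = {"scalp_outer": R}
    r["skull_outer"] = R - t["scalp"]
    r["csf_outer"] = r["skull_outer"] - t["skull"]
    r["grey_outer"] = r["csf_outer"] - t["csf"]
    r["white_outer"] = r["grey_outer"] - t["grey"]
    if r["white_outer"] <= 0:
        raise ValueError("head layers leave no room for white matter at this voxel size")
    return r


def _paint_head_sphere(labels: np.ndarray, grid: Grid, center: np.ndarray,
                       params: AnthropometryParams) -> None:
    """Assign concentric head layers plus deep sub-regions inside a sphere."""
    radii = _head_radii(params, voxel=float(min(grid.spacing)))
    x, y, z = grid.meshgrid()
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    r = np.sqrt(d2)
    inside = r <= radii["scalp_outer"]
    labels[inside] = _ID["skin"]
    labels[r <= radii["skull_outer"]] = _ID["bone"]
    labels[r <= radii["csf_outer"]] = _ID["cerebrospinal_fluid"]
    labels[r <= radii["grey_outer"]] = _ID["brain_grey_matter"]
    white = r <= radii["white_outer"]
    labels[white] = _ID["brain_white_matter"]

    # Deep structures at fixed fractional coordinates of the inner sphere.
    rw = radii["white_outer"]
    cx, cy, cz = center

    def carve(mask, tid):
        labels[mask & white] = tid

    th2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - (cz + 0.25 * rw)) ** 2
    carve(th2 <= (0.18 * rw) ** 2, _ID["thalamus"])
    cb2 = (x - (cx - 0.52 * rw)) ** 2 + (y - cy) ** 2 + (z - (cz - 0.52 * rw)) ** 2
    carve(cb2 <= (0.33 * rw) ** 2, _ID["cerebellum"])
    def stem_part(zc, sr, sz, tid):
        m = ((x - (cx - 0.12 * rw)) ** 2 + (y - cy) ** 2) / (sr * rw) ** 2 \
            + ((z - (cz + zc * rw)) / (sz * rw)) ** 2 <= 1.0
        carve(m, tid)

    stem_part(-0.33, 0.16, 0.12, _ID["midbrain"])
    stem_part(-0.55, 0.20, 0.14, _ID["pons"])
    stem_part(-0.76, 0.14, 0.12, _ID["medulla_oblongata"])


def build_layered_sphere_head(params: AnthropometryParams, padding_mm: float = 16.0) -> LabelVolume:
    """Concentric-sphere head phantom centred at the world origin.

    ``padding_mm`` of air surrounds the scalp so electrodes (sponge + pad)
    fit inside the grid.  Deterministic: identical params give bit-identical
    volumes.
    """
    vox = params.voxel_size
    half = params.head_outer_radius + padding_mm
    n, o = _symmetric_axis(half, vox)
    grid = Grid((n, n, n), (vox, vox, vox), (o, o, o))
    labels = np.zeros(grid.shape, dtype=np.int16)
    _paint_head_sphere(labels, grid, np.zeros(3), params)
    meta = {
        "kind": "layered_sphere_head",
        "head_center": [0.0, 0.0, 0.0],
        "scalp_outer_radius": params.head_outer_radius,
        "frame": "+x anterior (nose), +y subject-left, +z up; mm",
        "params": asdict(params),
    }
    return LabelVolume(grid, labels, dict(TISSUE_IDS), meta)


def _cylinder_z(x, y, center, radius):
    return (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius ** 2


def build_body_phantom(params: AnthropometryParams, padding_mm: float = 16.0) -> LabelVolume:
    """Whole-body phantom: head + neck + trunk + arms + legs, feet at z = 0.

    The outermost shell of every body part is skin, the next shell
    subcutaneous fat; the bulk is muscle with bone cores along the spine and
    limb axes.  The head keeps its concentric layers.  Right-arm and
    right-tibia electrode sites are recorded in the metadata.
    """
    vox = params.voxel_size
    H = params.height * 1000.0
    R = params.head_outer_radius
    head_c = np.array([0.0, 0.0, H - R])
    neck_top = H - 2 * R + 0.3 * R          # embedded into the head sphere
    neck_bot = H - 2 * R - params.neck_length
    trunk_top = neck_bot
    trunk_bot = trunk_top - params.trunk_height
    if trunk_bot <= 4 * vox:
        raise ValueError(f"body primitives of {params.name!r} do not fit below the head: "
                         "trunk reaches the ground, leaving no room for legs")
    arm_y = params.trunk_halfwidth + 0.6 * params.arm_radius
    arm_top = trunk_top - 0.25 * params.shoulder_radius
    arm_bot = arm_top - params.arm_length
    hip_y = 0.5 * params.trunk_halfwidth
    legs_top = trunk_bot + 0.07 * params.trunk_height
    trunk_c = np.array([0.0, 0.0, 0.5 * (trunk_top + trunk_bot)])

    xhalf = max(params.trunk_halfdepth, R, params.leg_radius) + padding_mm
    yhalf = arm_y + params.arm_radius + padding_mm
    nx, ox = _symmetric_axis(xhalf, vox)
    ny, oy = _symmetric_axis(yhalf, vox)
    nz = int(np.ceil((H + 2 * padding_mm) / vox)) + 1
    oz = -padding_mm
    grid = Grid((nx, ny, nz), (vox, vox, vox), (ox, oy, oz))
    labels = np.zeros(grid.shape, dtype=np.int16)
    x, y, z = grid.meshgrid()

    muscle = _ID["muscle"]
    # Trunk ellipsoid
    tr = ((x / params.trunk_halfdepth) ** 2 + (y / params.trunk_halfwidth) ** 2
          + ((z - trunk_c[2]) / (0.5 * params.trunk_height)) ** 2) <= 1.0
    labels[tr] = muscle
    # Neck
    labels[_cylinder_z(x, y, (0, 0), params.neck_radius) & (z >= neck_bot) & (z <= neck_top)] = muscle
    # Shoulders (horizontal connectors) and arms
    zsh = arm_top - 0.5 * params.shoulder_radius
    sh = ((x ** 2 + (z - zsh) ** 2) <= params.shoulder_radius ** 2) & (np.abs(y) <= arm_y)
    labels[sh] = muscle
    for sy in (+arm_y, -arm_y):
        labels[_cylinder_z(x, y, (0, sy), params.arm_radius) & (z >= arm_bot) & (z <= arm_top)] = muscle
    # Legs
    for sy in (+hip_y, -hip_y):
        labels[_cylinder_z(x, y, (0, sy), params.leg_radius) & (z >= 0) & (z <= legs_top)] = muscle

    # Bone cores: spine + limb bones
    bone = _ID["bone"]
    spine = _cylinder_z(x, y, (-0.25 * params.trunk_halfdepth, 0), 0.18 * params.trunk_halfdepth)
    labels[spine & (z >= trunk_bot + 0.05 * params.trunk_height) & (z <= neck_top) & (labels == muscle)] = bone
    for sy in (+arm_y, -arm_y):
        m = _cylinder_z(x, y, (0, sy), 0.32 * params.arm_radius) & (z >= arm_bot + vox) & (z <= arm_top)
        labels[m & (labels == muscle)] = bone
    for sy in (+hip_y, -hip_y):
        m = _cylinder_z(x, y, (0, sy), 0.3 * params.leg_radius) & (z >= vox) & (z <= legs_top)
        labels[m & (labels == muscle)] = bone

    # Skin and subcutaneous-fat shells on the body (head keeps its own layers)
    body = labels > 0
    air = ~body
    skin_shell = body & ndimage.binary_dilation(air, _SIX)
    fat_shell = body & ~skin_shell & ndimage.binary_dilation(skin_shell, _SIX)
    labels[fat_shell] = _ID["fat_sat"]
    labels[skin_shell] = _ID["skin"]

    # Head sphere painted last so its layered structure overrides neck overlap
    _paint_head_sphere(labels, grid, head_c, params)

    z_tibia = 0.25 * legs_top
    n_arm = np.array([0.0, -1.0, 0.0])
    n_tib = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)  # anteromedial on the right leg
    meta = {
        "kind": "body_phantom",
        "head_center": head_c.tolist(),
        "scalp_outer_radius": R,
        "frame": "+x anterior (nose), +y subject-left, +z up; mm",
        "params": asdict(params),
        "sites": {
            "right_arm": {
                "point": [0.0, -(arm_y + params.arm_radius), 0.5 * (arm_top + arm_bot)],
                "normal": n_arm.tolist(),
                "long_axis": [0.0, 0.0, 1.0],
                "surface": {"type": "cylinder_z", "center_xy": [0.0, -arm_y],
                            "radius": params.arm_radius},
            },
            "right_tibia": {
                "point": (np.array([0.0, -hip_y, z_tibia]) + params.leg_radius * n_tib).tolist(),
                "normal": n_tib.tolist(),
                "long_axis": [0.0, 0.0, 1.0],
                "surface": {"type": "cylinder_z", "center_xy": [0.0, -hip_y],
                            "radius": params.leg_radius},
            },
        },
    }
    return LabelVolume(grid, labels, dict(TISSUE_IDS), meta)


@dataclass
class PhantomFamily:
    """Ordered collection of phantom profiles sharing one tissue vocabulary."""

    profiles: list[AnthropometryParams] = field(default_factory=default_profiles)

    def __post_init__(self):
        if len(self.profiles) < 2:
            raise ValueError("a phantom family needs at least 2 profiles")
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate phantom names: {names}")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.profiles]

    def __iter__(self):
        return iter(self.profiles)

    def __len__(self):
        return len(self.profiles)

    def profile(self, name: str) -> AnthropometryParams:
        for p in self.profiles:
            if p.name == name:
                return p
        raise KeyError(f"no phantom named {name!r}")

    def build_head(self, name: str, voxel_size: float | None = None) -> LabelVolume:
        p = self.profile(name)
        if voxel_size is not None:
            p = AnthropometryParams(**{**asdict(p), "voxel_size": voxel_size})
        return build_layered_sphere_head(p)

    def build_body(self, name: str, voxel_size: float | None = None) -> LabelVolume:
        p = self.profile(name)
        if voxel_size is not None:
            p = AnthropometryParams(**{**asdict(p), "voxel_size": voxel_size})
        return build_body_phantom(p)


def make_phantom_family(profiles: list[AnthropometryParams] | None = None) -> PhantomFamily:
    """Family of phantoms; defaults to the three height-scaled analogues."""
    return PhantomFamily(profiles if profiles is not None else default_profiles())
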