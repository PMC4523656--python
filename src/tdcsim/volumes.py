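"""Voxel containers shared by every stage of the pipeline.

All volumes live on a uniform rectilinear :class:`Grid`.  World coordinates
are millimetres in a right-handed frame with +x toward the nose (anterior),
+y toward the subject's left and +z up; voxel values are cell-centred and the
``origin`` is the world coordinate of the centre of voxel (0, 0, 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Grid",
    "LabelVolume",
    "ScalarVolume",
    "VectorVolume",
    "write_vtk_image",
]


@dataclass(frozen=True)
class Grid:
    """Geometry of a uniform voxel grid (spacing and origin in mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def meshgrid(self):
        """Open (broadcastable) coordinate arrays (x[:,None,None], ...)."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates of voxel indices (N, 3) -> (N, 3) mm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def affine(self) -> np.ndarray:
        a = np.diag([*self.spacing, 1.0])
        a[:3, 3] = self.origin
        return a

    def scaled(self, k: float) -> "Grid":
        """Same voxel lattice with every linear dimension multiplied by k."""
        return Grid(self.shape, tuple(s * k for s in self.spacing), tuple(o * k for o in self.origin))


@dataclass
class LabelVolume:
    """Dense tissue-label volume: one small integer id per voxel, id 0 = air."""

    grid: Grid
    labels: np.ndarray  # int16, shape == grid.shape
    names: dict[int, str]  # id -> canonical tissue name
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int16)
        if self.labels.shape != tuple(self.grid.shape):
            raise ValueError("labels shape does not match grid")
        self.names = {int(k): v for k, v in self.names.items()}
        if 0 not in self.names:
            self.names[0] = "air"

    def id_of(self, name: str) -> int:
        for i, n in self.names.items():
            if n == name:
                return i
        raise KeyError(f"no tissue named {name!r} in this volume")

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.id_of(name)

    def present_ids(self) -> np.ndarray:
        return np.unique(self.labels)

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.grid, self.labels.copy(), dict(self.names), json.loads(json.dumps(self.meta)))

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path: str | Path) -> None:
        """Write labels as int16 NIfTI plus a JSON sidecar (names + meta)."""
        path = Path(path)
        img = nib.Nifti1Image(self.labels.astype(np.int16), self.grid.affine())
        img.header.set_zooms(self.grid.spacing)
        nib.save(img, str(path))
        sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
        sidecar.write_text(
            json.dumps({"names": {str(k): v for k, v in self.names.items()}, "meta": self.meta}, indent=1, sort_keys=True)
        )

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LabelVolume":
        path = Path(path)
        img = nib.load(str(path))
        labels = np.asarray(img.dataobj, dtype=np.int16)
        aff = img.affine
        grid = Grid(labels.shape, tuple(float(aff[i, i]) for i in range(3)), tuple(float(aff[i, 3]) for i in range(3)))
        sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
        names, meta = {0: "air"}, {}
        if sidecar.exists():
            d = json.loads(sidecar.read_text())
            names = {int(k): v for k, v in d.get("names", {}).items()}
            meta = d.get("meta", {})
        return cls(grid, labels, names, meta)


@dataclass
class ScalarVolume:
    """Per-voxel scalar field (conductivity in S/m, potential in V, |E| ...)."""

    grid: Grid
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("values shape does not match grid")

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.grid.affine())
        img.header.set_zooms(self.grid.spacing)
        nib.save(img, str(path))


@dataclass
class VectorVolume:
    """Per-voxel 3-vector field, components first: shape (3, nx, ny, nz)."""

    grid: Grid
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.values.shape != (3, *self.grid.shape):
            raise ValueError("values shape must be (3, nx, ny, nz)")

    def amplitude(self) -> np.ndarray:
        """Euclidean norm per voxel."""
        return np.sqrt(np.sum(self.values**2, axis=0))

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.moveaxis(self.values, 0, -1).astype(np.float32), self.grid.affine())
        nib.save(img, str(path))


def write_vtk_image(path: str | Path, grid: Grid, scalars: dict[str, np.ndarray]) -> None:
    """Write point-data arrays as a legacy-ASCII VTK STRUCTURED_POINTS file."""
    nx, ny, nz = grid.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntdcsim volume\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN {} {} {}\n".format(*grid.origin))
        fh.write("SPACING {} {} {}\n".format(*grid.spacing))
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in scalars.items():
            if arr.shape != tuple(grid.shape):
                raise ValueError(f"array {name!r} shape does not match grid")
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # VTK expects x fastest -> Fortran order
            np.savetxt(fh, arr.ravel(order="F"), fmt="%.6g")
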