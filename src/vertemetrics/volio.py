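"""Volume and mesh I/O with explicit world-coordinate geometry.

All raster data is carried as a :class:`VoxelVolume`: a 3D array whose axes
map to the anatomical axes right-left (array axis 0, +x toward subject
right), posterior-anterior (axis 1, +y anterior) and inferior-superior
(axis 2, +z superior).  Voxel centers sit at world coordinate
``origin + spacing * index`` (mm).  NIfTI files whose affine is an axis
permutation/flip of this convention are reoriented on load; oblique
affines are rejected — resampling is deliberately out of scope.

The bone/background boundary of a binary volume is taken at iso-level
0.5, matching the marching-cubes convention used by the surface module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh

AXIS_NAMES = ("RL", "AP", "SI")

__all__ = [
    "AXIS_NAMES",
    "VoxelVolume",
    "LabelVolume",
    "SurfaceMesh",
    "ObliqueAffineError",
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
]


class ObliqueAffineError(ValueError):
    """Raised for NIfTI affines that are not axis-aligned up to permutation/flip."""


@dataclass(eq=False)
class VoxelVolume:
    """A 3D scalar grid in world mm coordinates.

    ``data[i, j, k]`` is the sample whose voxel center lies at
    ``origin + spacing * (i, j, k)``; array axes follow :data:`AXIS_NAMES`.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_names: tuple[str, str, str] = AXIS_NAMES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World mm coordinates of (possibly fractional) voxel indices, (..., 3)."""
        return np.asarray(self.origin) + np.asarray(idx) * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def world_bounds(self) -> np.ndarray:
        """(2, 3) min/max world coordinates of the outermost voxel centers."""
        hi = self.index_to_world(np.asarray(self.shape) - 1)
        return np.vstack([np.asarray(self.origin), hi])

    def with_data(self, data: np.ndarray) -> "VoxelVolume":
        if data.shape != self.data.shape:
            raise ValueError("replacement data must keep the grid shape")
        return VoxelVolume(data, self.spacing, self.origin)

    def same_grid(self, other: "VoxelVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass(eq=False)
class LabelVolume(VoxelVolume):
    """Integer-labeled volume; 0 is background, nonzero labels are named."""

    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelVolume data must be an integer array")
        self.labels = {int(k): str(v) for k, v in self.labels.items()}
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.labels)
        if missing:
            raise ValueError(f"labels present in data but not in the label table: {sorted(missing)}")

    def id_of(self, name: str) -> int:
        for k, v in self.labels.items():
            if v == name:
                return k
        raise KeyError(f"no label named {name!r}")

    def mask_of(self, name: str) -> VoxelVolume:
        """Binary volume of one named label."""
        return VoxelVolume(
            (self.data == self.id_of(name)).astype(np.uint8), self.spacing, self.origin
        )


@dataclass(eq=False)
class SurfaceMesh:
    """Triangulated surface; vertices in world mm, faces as index triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_empty(self) -> bool:
        return len(self.faces) == 0

    def area(self) -> float:
        return float(self.to_trimesh().area)

    def triangles(self) -> np.ndarray:
        """(n_faces, 3, 3) vertex coordinates per triangle."""
        return self.vertices[self.faces]


# ---------------------------------------------------------------------------
# NIfTI volumes

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".labels.json")
    return path.with_name(name + ".labels.json")


def _check_axis_aligned(mat: np.ndarray) -> None:
    # Each row/column of the rotation-scale block must have exactly one
    # significant entry, i.e. the affine is a permutation * flip * scale.
    for axis in range(3):
        for vec in (mat[axis, :], mat[:, axis]):
            mags = np.abs(vec)
            if np.sum(mags > 1e-4 * mags.max()) != 1:
                raise ObliqueAffineError(
                    "oblique affine: volume axes are not aligned with world axes; "
                    "resample the image before loading (resampling is out of scope)"
                )


def read_volume(path: str | Path) -> VoxelVolume | LabelVolume:
    """Load a NIfTI volume, reorienting to the canonical RL/AP/SI axis order.

    If a ``<stem>.labels.json`` sidecar exists the result is a
    :class:`LabelVolume` carrying its label table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    aff = np.asarray(img.affine, dtype=float)
    _check_axis_aligned(aff[:3, :3])
    ornt = nib.orientations.io_orientation(aff)
    data = np.asarray(img.get_fdata())
    data = nib.orientations.apply_orientation(data, ornt)
    aff = aff @ nib.orientations.inv_ornt_aff(ornt, img.shape)
    spacing = tuple(np.diag(aff)[:3])
    origin = tuple(aff[:3, 3])

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        table = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        return LabelVolume(np.rint(data).astype(np.int32), spacing, origin, labels=table)
    if np.issubdtype(img.get_data_dtype(), np.integer):
        data = np.rint(data).astype(np.int32)
    return VoxelVolume(data, spacing, origin)


def write_volume(vol: VoxelVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; label tables go to a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = vol.data
    if isinstance(vol, LabelVolume):
        data = data.astype(np.int32)
    elif vol.is_binary():
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, vol.affine)
    nib.save(img, str(path))
    if isinstance(vol, LabelVolume):
        _sidecar_path(path).write_text(
            json.dumps({str(k): v for k, v in vol.labels.items()}, indent=1)
        )
    return path


# ---------------------------------------------------------------------------
# Meshes

def read_mesh(path: str | Path) -> SurfaceMesh:
    """Load an STL or PLY mesh (vertices in mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    tm = trimesh.load_mesh(str(path))
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"no triangles found in {path}")
    return SurfaceMesh.from_trimesh(tm)


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> Path:
    """Write a mesh as binary STL or ascii PLY, chosen by the file suffix."""
    if mesh.is_empty():
        raise ValueError("refusing to write an empty mesh")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tm = mesh.to_trimesh()
    suffix = path.suffix.lower()
    if suffix == ".stl":
        tm.export(str(path), file_type="stl")
    elif suffix == ".ply":
        tm.export(str(path), file_type="ply", encoding="ascii")
    else:
        raise ValueError(f"unsupported mesh format {suffix!r}; use .stl or .ply")
    return path
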