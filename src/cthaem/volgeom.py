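"""Volume data model, NIfTI/DICOM I/O, resampling and thin-slab MIP.

Conventions used throughout the package:

* world coordinates are millimetres in an LPS-style frame;
* ``Volume.values`` is indexed ``[i, j, k]`` along the (x, y, z) world axes,
  so an *axial* slice is ``values[:, :, k]`` and a *coronal* slice is
  ``values[:, j, :]``;
* voxel indices are 0-based and ``world = origin + axes @ (spacing * index)``;
* slabs and ROIs are closed intervals / regions on voxel *centers*.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "Mask",
    "MIPSlab",
    "GeometryError",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "resample_to_reference",
    "mip_slab",
]

#: HU value used for voxels that fall outside the source field of view.
OUT_OF_FIELD_HU = -1000.0

_PLANES = ("axial", "coronal", "sagittal")
#: array axis along which each named plane stacks its slices
_PLANE_AXIS = {"axial": 2, "coronal": 1, "sagittal": 0}


class GeometryError(ValueError):
    """Raised when volume geometry metadata is inconsistent or invalid."""


def _as_direction(axes) -> np.ndarray:
    axes = np.asarray(axes, dtype=float)
    if axes.shape != (3, 3):
        raise GeometryError(f"direction matrix must be 3x3, got {axes.shape}")
    if not np.all(np.isfinite(axes)):
        raise GeometryError("direction matrix contains non-finite entries")
    if abs(abs(np.linalg.det(axes)) - 1.0) > 1e-6:
        raise GeometryError("direction matrix is not orthonormal (|det| != 1)")
    if not np.allclose(axes.T @ axes, np.eye(3), atol=1e-6):
        raise GeometryError("direction matrix is not orthonormal")
    return axes


@dataclass
class Volume:
    """A 3D scalar grid of CT attenuation in Hounsfield units.

    Parameters
    ----------
    values : (nx, ny, nz) ndarray
        Attenuation in HU, indexed along the (x, y, z) world axes.
    spacing : 3-sequence of float
        Per-axis voxel size in mm; strictly positive.
    origin : 3-sequence of float
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    axes : (3, 3) ndarray
        Orthonormal direction matrix mapping index axes to world axes.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise GeometryError("values must be a 3D array with all dims >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 strictly positive floats, got {self.spacing}")
        if len(self.origin) != 3 or any(not np.isfinite(o) for o in self.origin):
            raise GeometryError(f"origin must be 3 finite floats, got {self.origin}")
        self.axes = _as_direction(self.axes)

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine."""
        aff = np.eye(4)
        aff[:3, :3] = self.axes @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) fractional voxel indices to world mm."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing) @ self.axes.T + np.asarray(self.origin)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map (..., 3) world-mm points to fractional voxel indices."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) @ self.axes / np.asarray(self.spacing)

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinate of voxel centers along one index axis (axis-aligned grids)."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n) * self.axes[axis, axis]

    def same_grid(self, other: "Volume | Mask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.axes, other.axes, atol=atol)
        )

    def with_values(self, values: np.ndarray) -> "Volume":
        return replace(self, values=values)


@dataclass
class Mask:
    """Binary labelling of a :class:`Volume` grid (tumor / liver / vessel / residual)."""

    values: np.ndarray
    label: Literal["tumor", "liver", "vessel", "residual"] = "tumor"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise GeometryError("mask values must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.axes = _as_direction(self.axes)

    @classmethod
    def like(cls, vol: Volume, values: np.ndarray, label: str = "tumor") -> "Mask":
        if values.shape != vol.shape:
            raise GeometryError("mask shape does not match parent volume")
        return cls(values=values, label=label, spacing=vol.spacing, origin=vol.origin, axes=vol.axes)

    # share the geometry helpers
    shape = Volume.shape
    affine = Volume.affine
    index_to_world = Volume.index_to_world
    world_to_index = Volume.world_to_index
    axis_coords = Volume.axis_coords
    same_grid = Volume.same_grid

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class MIPSlab:
    """Thin-slab maximum intensity projection (per-pixel max over a slab of slices)."""

    values: np.ndarray
    plane: Literal["axial", "coronal", "sagittal"]
    slab_center_mm: float
    slab_thickness_mm: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _from_nifti(path: str) -> Volume:
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    aff = img.affine
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise GeometryError(f"non-positive spacing in NIfTI affine of {path}")
    axes = lin / spacing
    return Volume(values=data, spacing=tuple(spacing), origin=tuple(aff[:3, 3]), axes=axes)


def _from_dicom_series(path: str) -> Volume:
    import pydicom

    files = sorted(
        os.path.join(path, f) for f in os.listdir(path) if not f.startswith(".")
    )
    if not files:
        raise FileNotFoundError(f"no files in DICOM series directory {path}")
    slices = [pydicom.dcmread(f) for f in files]
    normal = None
    positions = []
    for ds in slices:
        iop = np.array(ds.ImageOrientationPatient, dtype=float)
        n = np.cross(iop[:3], iop[3:])
        if normal is None:
            normal = n
        positions.append(float(np.dot(np.array(ds.ImagePositionPatient, float), normal)))
    order = np.argsort(positions)
    slices = [slices[i] for i in order]
    files = [files[i] for i in order]
    positions = sorted(positions)
    steps = np.diff(positions)
    if len(steps) > 0:
        ref = np.median(steps)
        bad = np.where(np.abs(steps - ref) > 0.01 * max(abs(ref), 1e-6))[0]
        if ref <= 0 or bad.size:
            offenders = ", ".join(os.path.basename(files[i + 1]) for i in bad[:5])
            raise GeometryError(
                f"inconsistent slice spacing in DICOM series {path}: "
                f"expected step {ref:.4f} mm, offending slices: {offenders}"
            )
    first = slices[0]
    rows, cols = int(first.Rows), int(first.Columns)
    stack = np.empty((cols, rows, len(slices)), dtype=np.float64)
    for k, ds in enumerate(slices):
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        # DICOM pixel_array is (row, col); our layout is (x=col, y=row, z)
        stack[:, :, k] = (slope * arr + intercept).T
    iop = np.array(first.ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    slice_dir = np.cross(row_dir, col_dir)
    ps = [float(v) for v in first.PixelSpacing]  # (row spacing, col spacing)
    dz = float(np.median(steps)) if len(steps) else float(getattr(first, "SliceThickness", 1.0))
    axes = np.stack([row_dir, col_dir, slice_dir], axis=1)
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    return Volume(values=stack, spacing=(ps[1], ps[0], dz), origin=origin, axes=axes)


def read_volume(path: str, format: Literal["nifti", "dicom_series"] | None = None) -> Volume:
    """Read a CT volume (HU) from a NIfTI file or a DICOM series directory.

    DICOM rescale slope/intercept are applied so values are in HU. A DICOM
    series with inconsistent slice spacing raises :class:`GeometryError`
    naming the offending slices.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "dicom_series" if os.path.isdir(path) else "nifti"
    if format == "nifti":
        return _from_nifti(path)
    if format == "dicom_series":
        return _from_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def write_volume(vol: Volume, path: str) -> None:
    """Write a volume as NIfTI-1; integer dtypes round-trip bit-exactly."""
    import nibabel as nib

    img = nib.Nifti1Image(vol.values, vol.affine)
    nib.save(img, path)


def write_mask(mask: Mask, path: str) -> None:
    """Masks are stored as unsigned 8-bit NIfTI with 0/1 values."""
    import nibabel as nib

    aff = np.eye(4)
    aff[:3, :3] = mask.axes @ np.diag(mask.spacing)
    aff[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), aff), path)


def read_mask(path: str, label: str = "tumor") -> Mask:
    vol = read_volume(path, "nifti")
    return Mask(values=vol.values > 0, label=label, spacing=vol.spacing,
                origin=vol.origin, axes=vol.axes)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_reference(
    moving: Volume | Mask,
    reference: Volume | Mask,
    interpolation: Literal["linear", "nearest"] | None = None,
    fill_value: float | None = None,
):
    """Resample ``moving`` onto the grid of ``reference``.

    Masks default to nearest-neighbour interpolation (and stay binary);
    volumes default to linear. Out-of-field voxels take ``fill_value``
    (default −1000 HU for volumes, 0 for masks).
    """
    is_mask = isinstance(moving, Mask)
    if interpolation is None:
        interpolation = "nearest" if is_mask else "linear"
    order = 0 if interpolation == "nearest" else 1
    if fill_value is None:
        fill_value = 0.0 if is_mask else OUT_OF_FIELD_HU

    nx, ny, nz = reference.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = reference.index_to_world(idx)
    midx = moving.world_to_index(world).reshape(nx, ny, nz, 3)
    coords = [midx[..., a] for a in range(3)]
    src = moving.values.astype(float) if is_mask else moving.values
    out = ndimage.map_coordinates(
        src, coords, order=order, mode="constant", cval=fill_value
    )
    if is_mask:
        return Mask(values=out > 0.5, label=moving.label, spacing=reference.spacing,
                    origin=reference.origin, axes=np.array(reference.axes))
    return Volume(values=out, spacing=reference.spacing, origin=reference.origin,
                  axes=np.array(reference.axes))


# ---------------------------------------------------------------------------
# Thin-slab MIP
# ---------------------------------------------------------------------------

def mip_slab(
    volume: Volume,
    plane: Literal["axial", "coronal", "sagittal"],
    center_mm: float,
    thickness_mm: float = 7.0,
) -> MIPSlab:
    """Thin-slab maximum intensity projection.

    Each output pixel is the maximum HU over voxels whose centers fall within
    the closed slab ``[center - t/2, center + t/2]`` along the projection
    axis. The default 7 mm thickness sits in the middle of the 5–10 mm range
    conventionally used to read feeding arteries.
    """
    if plane not in _PLANES:
        raise ValueError(f"plane must be one of {_PLANES}")
    if thickness_mm <= 0:
        raise ValueError("slab thickness must be positive")
    axis = _PLANE_AXIS[plane]
    coords = volume.axis_coords(axis)
    lo, hi = center_mm - thickness_mm / 2.0, center_mm + thickness_mm / 2.0
    sel = (coords >= lo) & (coords <= hi)
    if not sel.any():
        # degenerate slab thinner than one spacing: take the nearest slice
        nearest = int(np.argmin(np.abs(coords - center_mm)))
        if abs(coords[nearest] - center_mm) > thickness_mm / 2.0 + volume.spacing[axis]:
            raise ValueError("slab does not intersect the volume")
        sel = np.zeros_like(sel)
        sel[nearest] = True
    sub = np.take(volume.values, np.where(sel)[0], axis=axis)
    with np.errstate(invalid="ignore"):
        proj = np.nanmax(sub, axis=axis)
    return MIPSlab(values=proj, plane=plane, slab_center_mm=float(center_mm),
                   slab_thickness_mm=float(thickness_mm))
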