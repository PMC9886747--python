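"""Deformable (native↔arterial) and rigid (pre↔post) registration.

The deformable stage is a 3-level multiresolution symmetric-forces demons
registration, appropriate for same-modality CT pairs. Intensities are clipped
to [−100, 200] HU before the metric so vessels present only in the arterial
phase do not bias the match. The rigid stage (used to co-register the pre- and
post-treatment enhancement maps) is a mean-squares Euler3D registration.

Displacement-field convention: fields live on the *fixed*-image grid and map
fixed-grid world points into moving-image space, ``p_moving = p_fixed + u(p)``,
with components in world mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volgeom import Mask, Volume, GeometryError

__all__ = [
    "DeformationField",
    "RegistrationReport",
    "RigidTransform",
    "register_deformable",
    "register_rigid",
    "warp",
    "registration_error",
]


@dataclass
class DeformationField:
    """Dense per-voxel displacement (mm) on the fixed-image grid."""

    displacements: np.ndarray  # (nx, ny, nz, 3)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 4 or self.displacements.shape[-1] != 3:
            raise GeometryError("displacements must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.displacements)):
            raise GeometryError("displacement field contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.axes = np.asarray(self.axes, dtype=float)

    @classmethod
    def identity(cls, like: Volume) -> "DeformationField":
        return cls(
            displacements=np.zeros(like.shape + (3,)),
            spacing=like.spacing,
            origin=like.origin,
            axes=np.array(like.axes),
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.displacements, axis=-1)

    def jacobian_determinant(self) -> np.ndarray:
        """det(I + du/dx) evaluated with central differences."""
        grads = np.empty(self.shape + (3, 3))
        for c in range(3):
            for a in range(3):
                grads[..., c, a] = np.gradient(
                    self.displacements[..., c], self.spacing[a], axis=a
                )
        grads += np.eye(3)
        return np.linalg.det(grads)


@dataclass
class RegistrationReport:
    """Similarity trace and convergence flags of one registration run."""

    metric_trace: list[list[float]]
    levels: list[int]
    converged: bool
    mean_error_mm: float | None = None
    std_error_mm: float | None = None


@dataclass
class RigidTransform:
    """Rigid transform mapping fixed-image world points to moving-image space."""

    matrix: np.ndarray  # 3x3 rotation
    translation: np.ndarray  # 3-vector mm

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.matrix.T
        return RigidTransform(rinv, -rinv @ self.translation)

    @property
    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.matrix
        m[:3, 3] = self.translation
        return m

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.matrix) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# SimpleITK interop
# ---------------------------------------------------------------------------

def _to_sitk(vol: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.T.astype(np.float64)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    img.SetDirection(tuple(np.asarray(vol.axes).flatten()))
    return img


def _field_from_sitk(img: sitk.Image) -> DeformationField:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3)
    disp = np.ascontiguousarray(np.transpose(arr, (2, 1, 0, 3)))
    return DeformationField(
        displacements=disp,
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        axes=np.asarray(img.GetDirection()).reshape(3, 3),
    )


def _field_to_sitk(fld: DeformationField) -> sitk.Image:
    arr = np.ascontiguousarray(np.transpose(fld.displacements, (2, 1, 0, 3)))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(fld.spacing)
    img.SetOrigin(fld.origin)
    img.SetDirection(tuple(np.asarray(fld.axes).flatten()))
    return img


def _check_overlap(a: Volume, b: Volume) -> None:
    for axis in range(3):
        alo = a.origin[axis]
        ahi = alo + a.spacing[axis] * (a.shape[axis] - 1)
        blo = b.origin[axis]
        bhi = blo + b.spacing[axis] * (b.shape[axis] - 1)
        if min(ahi, bhi) < max(alo, blo):
            raise GeometryError("volumes do not overlap in world space")


# ---------------------------------------------------------------------------
# Deformable registration
# ---------------------------------------------------------------------------

@dataclass
class DeformableParams:
    """Settings of the demons registration.

    ``smooth_sigma_vox`` regularises both the update field and the running
    displacement field (Gaussian, in voxels of the current level).
    ``histogram_match`` maps the moving (native) intensities onto the fixed
    (arterial) distribution before the metric; the demons force assumes
    intensity constancy and arterial enhancement otherwise leaves a
    systematic DC offset over the parenchyma that drags the match along
    texture gradients.
    """

    levels: Sequence[int] = (4, 2, 1)
    iterations: Sequence[int] = (150, 80, 20)
    smooth_sigma_vox: float = 2.0
    clip_hu: tuple[float, float] = (-100.0, 200.0)
    histogram_match: bool = True
    histogram_levels: int = 256
    histogram_match_points: int = 15
    convergence_rtol: float = 1e-4


def _shrink(img: sitk.Image, factor: int) -> sitk.Image:
    if factor == 1:
        return img
    sigma = [factor * s / 2.0 for s in img.GetSpacing()]
    sm = sitk.SmoothingRecursiveGaussian(img, sigma)
    return sitk.Shrink(sm, [factor] * 3)


def register_deformable(
    fixed: Volume,
    moving: Volume,
    params: DeformableParams | None = None,
) -> tuple[DeformationField, RegistrationReport]:
    """Deformable registration of ``moving`` onto ``fixed`` (same-modality CT).

    Returns a displacement field on the fixed grid such that
    ``warp(moving, field)`` approximates ``fixed``, together with a
    :class:`RegistrationReport` carrying the per-level metric trace.
    """
    params = params or DeformableParams()
    _check_overlap(fixed, moving)

    lo, hi = params.clip_hu
    f_img = _to_sitk(fixed.with_values(np.clip(fixed.values, lo, hi)))
    m_img = _to_sitk(moving.with_values(np.clip(moving.values, lo, hi)))
    if params.histogram_match:
        m_img = sitk.HistogramMatching(
            m_img, f_img,
            numberOfHistogramLevels=params.histogram_levels,
            numberOfMatchPoints=params.histogram_match_points,
        )

    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    # ITK demons smoothing standard deviations are in voxel units
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(params.smooth_sigma_vox)
    demons.SetSmoothUpdateField(True)
    demons.SetUpdateFieldStandardDeviations(params.smooth_sigma_vox)

    traces: list[list[float]] = []
    disp: sitk.Image | None = None
    for shrink, iters in zip(params.levels, params.iterations):
        f_l = _shrink(f_img, shrink)
        m_l = _shrink(m_img, shrink)
        if disp is None:
            disp = sitk.Image(f_l.GetSize(), sitk.sitkVectorFloat64, 3)
            disp.CopyInformation(f_l)
        else:
            disp = sitk.Resample(disp, f_l, sitk.Transform(), sitk.sitkLinear)
            disp = sitk.Cast(disp, sitk.sitkVectorFloat64)
        trace: list[float] = []
        demons.SetNumberOfIterations(int(iters))
        demons.RemoveAllCommands()
        demons.AddCommand(
            sitk.sitkIterationEvent, lambda: trace.append(demons.GetMetric())
        )
        disp = demons.Execute(f_l, m_l, disp)
        traces.append(trace)

    fld = _field_from_sitk(disp)
    converged = all(
        (len(t) < 2) or (t[-1] <= t[0] * (1.0 + params.convergence_rtol)) for t in traces
    )
    report = RegistrationReport(
        metric_trace=traces, levels=list(params.levels), converged=converged
    )
    return fld, report


# ---------------------------------------------------------------------------
# Warping
# ---------------------------------------------------------------------------

def warp(
    volume_or_mask: Volume | Mask,
    fld: DeformationField,
    interpolation: Literal["linear", "nearest"] | None = None,
    fill_value: float | None = None,
):
    """Pull ``volume_or_mask`` back through a displacement field.

    The output lives on the field's (fixed) grid: voxel at world point ``p``
    takes the moving image's value at ``p + u(p)``. Masks are warped with
    nearest-neighbour interpolation and stay binary. Out-of-field samples take
    ``fill_value`` (NaN for volumes by default, so downstream ROI statistics
    can exclude them; 0 for masks).
    """
    is_mask = isinstance(volume_or_mask, Mask)
    if interpolation is None:
        interpolation = "nearest" if is_mask else "linear"
    order = 0 if interpolation == "nearest" else 1
    if fill_value is None:
        fill_value = 0.0 if is_mask else np.nan

    # exact shortcut: a zero field on the source grid is the identity map
    same_grid = (
        volume_or_mask.shape == fld.shape
        and np.allclose(volume_or_mask.spacing, fld.spacing, atol=1e-9)
        and np.allclose(volume_or_mask.origin, fld.origin, atol=1e-9)
        and np.allclose(volume_or_mask.axes, fld.axes, atol=1e-9)
    )
    if same_grid and not fld.displacements.any():
        if is_mask:
            return Mask(values=volume_or_mask.values.copy(), label=volume_or_mask.label,
                        spacing=fld.spacing, origin=fld.origin, axes=np.array(fld.axes))
        return Volume(values=volume_or_mask.values.copy(), spacing=fld.spacing,
                      origin=fld.origin, axes=np.array(fld.axes))

    nx, ny, nz = fld.shape
    idx = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
        axis=-1,
    ).astype(float)
    world = idx * np.asarray(fld.spacing) @ np.asarray(fld.axes).T + np.asarray(fld.origin)
    mapped = world + fld.displacements
    midx = volume_or_mask.world_to_index(mapped.reshape(-1, 3)).reshape(nx, ny, nz, 3)
    coords = [midx[..., a] for a in range(3)]
    src = volume_or_mask.values.astype(float)
    out = ndimage.map_coordinates(src, coords, order=order, mode="constant", cval=fill_value)
    if is_mask:
        return Mask(values=out > 0.5, label=volume_or_mask.label, spacing=fld.spacing,
                    origin=fld.origin, axes=np.array(fld.axes))
    return Volume(values=out, spacing=fld.spacing, origin=fld.origin, axes=np.array(fld.axes))


# ---------------------------------------------------------------------------
# Rigid registration
# ---------------------------------------------------------------------------

def register_rigid(fixed: Volume, moving: Volume) -> RigidTransform:
    """Rigid (rotation + translation) mean-squares registration.

    Used to co-register the pre- and post-treatment sessions; rigid by design
    so that genuine enhancement differences are not deformed away.
    """
    _check_overlap(fixed, moving)
    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)

    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(0.25, 12345)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=200,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(initial, inPlace=False)
    final = reg.Execute(f_img, m_img)

    try:
        euler = sitk.Euler3DTransform(final)
    except Exception:
        euler = sitk.Euler3DTransform(
            sitk.CompositeTransform(final).GetNthTransform(0)
        )
    mat = np.asarray(euler.GetMatrix()).reshape(3, 3)
    center = np.asarray(euler.GetCenter())
    trans = np.asarray(euler.GetTranslation())
    # sitk applies p' = R (p - c) + c + t ; fold the center into the offset
    offset = center + trans - mat @ center
    return RigidTransform(matrix=mat, translation=offset)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_field(fld: DeformationField, path: str) -> None:
    """Write a displacement field as 3-component (vector) NIfTI, mm units."""
    import nibabel as nib

    aff = np.eye(4)
    aff[:3, :3] = np.asarray(fld.axes) @ np.diag(fld.spacing)
    aff[:3, 3] = fld.origin
    nib.save(nib.Nifti1Image(fld.displacements.astype(np.float32), aff), path)


def load_field(path: str) -> DeformationField:
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector convention
        data = data[:, :, :, 0, :]
    lin = img.affine[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    return DeformationField(
        displacements=data.astype(float),
        spacing=tuple(spacing),
        origin=tuple(img.affine[:3, 3]),
        axes=lin / spacing,
    )


def save_rigid(tf: RigidTransform, path: str) -> None:
    """Write a rigid transform as JSON (4x4 matrix, mm)."""
    import json

    with open(path, "w") as fh:
        json.dump({"matrix_4x4_mm": tf.as_matrix.tolist()}, fh, indent=1)


def load_rigid(path: str) -> RigidTransform:
    import json

    with open(path) as fh:
        m = np.asarray(json.load(fh)["matrix_4x4_mm"])
    return RigidTransform(matrix=m[:3, :3], translation=m[:3, 3])


# ---------------------------------------------------------------------------
# Accuracy assessment
# ---------------------------------------------------------------------------

def registration_error(
    estimated: DeformationField,
    truth: DeformationField,
    roi: Mask,
) -> tuple[float, float]:
    """Mean and std (mm) of per-voxel displacement-difference magnitudes in an ROI."""
    if estimated.shape != truth.shape:
        raise GeometryError("deformation fields are on different grids")
    if roi.values.shape != estimated.shape:
        raise GeometryError("ROI is not on the field grid")
    sel = roi.values
    if not sel.any():
        raise ValueError("empty ROI")
    diff = estimated.displacements[sel] - truth.displacements[sel]
    mags = np.linalg.norm(diff, axis=-1)
    return float(mags.mean()), float(mags.std())
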