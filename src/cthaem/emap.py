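"""Enhancement maps: arterial minus registered native phase.

The arterial phase is the fixed image of the deformable registration, so the
map lives on the arterial geometry — the quantity being measured (arterial
enhancement) is never interpolated twice. No smoothing or clipping is ever
applied to map values: negative values (subtraction voids from contrast
stasis) are diagnostic and are retained. Voxels whose native-phase sample
fell outside the field of view carry NaN and are excluded from all ROI
statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Literal

import numpy as np

from .register import DeformationField, RigidTransform, register_rigid, warp
from .volgeom import GeometryError, MIPSlab, Volume

__all__ = ["EnhancementMap", "compute_em", "align_em_pair", "render_em"]


@dataclass
class EnhancementMap:
    """Signed ΔHU volume on the arterial-phase grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    axes: np.ndarray = dfield(default_factory=lambda: np.eye(3))
    phase_pair: Literal["pre", "post"] = "pre"
    registration_id: str = ""
    smoothing_applied: bool = False

    def __post_init__(self) -> None:
        if self.smoothing_applied:
            raise ValueError("enhancement maps are never smoothed")
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.axes = np.asarray(self.axes, dtype=float)

    # reuse the Volume geometry helpers
    shape = Volume.shape
    affine = Volume.affine
    index_to_world = Volume.index_to_world
    world_to_index = Volume.world_to_index
    axis_coords = Volume.axis_coords
    same_grid = Volume.same_grid

    def as_volume(self, fill: float = 0.0) -> Volume:
        vals = np.where(np.isfinite(self.values), self.values, fill)
        return Volume(vals, spacing=self.spacing, origin=self.origin, axes=np.array(self.axes))


def compute_em(
    native: Volume,
    arterial: Volume,
    field: DeformationField,
    phase_pair: Literal["pre", "post"] = "pre",
    registration_id: str = "",
) -> EnhancementMap:
    """Subtract the registered native phase from the arterial phase.

    ``field`` must live on the arterial grid and map it into native space.
    Values are ``arterial − warp(native)``, unsmoothed and unclipped;
    out-of-field voxels are NaN.
    """
    if field.shape != arterial.shape or not (
        np.allclose(field.spacing, arterial.spacing, atol=1e-6)
        and np.allclose(field.origin, arterial.origin, atol=1e-6)
    ):
        raise GeometryError("deformation field is not on the arterial grid")
    warped = warp(native, field, interpolation="linear", fill_value=np.nan)
    return EnhancementMap(
        values=arterial.values - warped.values,
        spacing=arterial.spacing,
        origin=arterial.origin,
        axes=np.array(arterial.axes),
        phase_pair=phase_pair,
        registration_id=registration_id,
    )


def align_em_pair(
    pre_em: EnhancementMap,
    post_em: EnhancementMap,
    pre_anchor: Volume | None = None,
    post_anchor: Volume | None = None,
) -> tuple[EnhancementMap, RigidTransform]:
    """Co-register the post-treatment map onto the pre-treatment grid.

    The rigid transform is estimated from anchor volumes (by default the
    underlying native volumes supplied by the caller; if absent, the maps
    themselves with NaN treated as 0) and the post map is resampled onto the
    pre grid through it. Returns the resampled map and the transform
    (pre-grid world point → post-grid world point).
    """
    if pre_anchor is None:
        pre_anchor = pre_em.as_volume()
    if post_anchor is None:
        post_anchor = post_em.as_volume()
    identical = (
        pre_em.same_grid(post_em)
        and np.allclose(pre_anchor.values, post_anchor.values, atol=1e-9)
    )
    if identical:
        transform = RigidTransform.identity()
    else:
        transform = register_rigid(pre_anchor, post_anchor)

    if transform_is_identity(transform) and pre_em.same_grid(post_em):
        resampled = post_em.values.copy()
    else:
        from scipy import ndimage

        nx, ny, nz = pre_em.shape
        idx = np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        world = pre_em.index_to_world(idx)
        mapped = transform.apply_points(world)
        midx = post_em.world_to_index(mapped).reshape(nx, ny, nz, 3)
        resampled = ndimage.map_coordinates(
            post_em.values, [midx[..., a] for a in range(3)],
            order=1, mode="constant", cval=np.nan,
        )
    out = EnhancementMap(
        values=resampled,
        spacing=pre_em.spacing,
        origin=pre_em.origin,
        axes=np.array(pre_em.axes),
        phase_pair="post",
        registration_id=post_em.registration_id,
    )
    return out, transform


def save_em(em: EnhancementMap, path: str) -> None:
    """Write a map as float32 NIfTI plus a JSON sidecar (provenance + checksum)."""
    import hashlib
    import json

    import nibabel as nib

    data = em.values.astype(np.float32)
    nib.save(nib.Nifti1Image(data, em.affine), path)
    sidecar = {
        "phase_pair": em.phase_pair,
        "registration_id": em.registration_id,
        "smoothing_applied": em.smoothing_applied,
        "sha256": hashlib.sha256(np.ascontiguousarray(data).tobytes()).hexdigest(),
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def load_em(path: str) -> EnhancementMap:
    """Read a map written by :func:`save_em`, verifying the sidecar checksum."""
    import hashlib
    import json

    from .volgeom import read_volume

    vol = read_volume(path, "nifti")
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    digest = hashlib.sha256(
        np.ascontiguousarray(vol.values.astype(np.float32)).tobytes()
    ).hexdigest()
    if digest != sidecar["sha256"]:
        raise ValueError(f"checksum mismatch for {path}")
    return EnhancementMap(
        values=vol.values,
        spacing=vol.spacing,
        origin=vol.origin,
        axes=np.array(vol.axes),
        phase_pair=sidecar["phase_pair"],
        registration_id=sidecar["registration_id"],
    )


def transform_is_identity(t: RigidTransform, atol: float = 1e-12) -> bool:
    return bool(
        np.allclose(t.matrix, np.eye(3), atol=atol)
        and np.allclose(t.translation, 0.0, atol=atol)
    )


def render_em(
    em: EnhancementMap | MIPSlab,
    window: tuple[float, float],
    inverted: bool = False,
    slice_index: int | None = None,
    plane: Literal["axial", "coronal", "sagittal"] = "axial",
) -> np.ndarray:
    """Linear windowing of a map slice (or MIP slab) to [0, 1] for display.

    ``inverted=True`` renders low ΔHU white and high ΔHU black (inverted gray
    scale). Values clamp to the window. Visualization only — never feeds
    quantitation.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must satisfy lo < hi")
    if isinstance(em, MIPSlab):
        img = em.values
    else:
        from .volgeom import _PLANE_AXIS

        axis = _PLANE_AXIS[plane]
        if slice_index is None:
            slice_index = em.shape[axis] // 2
        img = np.take(em.values, slice_index, axis=axis)
    out = (np.clip(img, lo, hi) - lo) / (hi - lo)
    out = np.where(np.isfinite(out), out, 0.0)
    return 1.0 - out if inverted else out
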