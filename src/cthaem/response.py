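"""ROI definition/transfer, relative enhancement, and the response call.

The method's core statistic: mean enhancement-map value over the tumor ROI
divided by the mean over a normal-parenchyma ROI in the contralateral lobe,

    T_RE = mean(EM | ROI_tumor) / mean(EM | ROI_normal),

computed on the pre-treatment map (T_pre_RE) and, after transferring the
ROIs, on the post-treatment map (T_post_RE). Residual disease is called when
T_post_RE > 1. For post-treatment maps the tumor mean may be restricted to
voxels above a ΔHU cutoff τ (default 0): contrast stasis subtracts to ~0 and
would otherwise bias the normalisation toward zero ("higher-attenuation
voxel" correction).

ROIs are planar: the tumor ROI is the tumor cross-section on the axial or
coronal slice of maximal in-plane area (ties go to axial); the normal ROI is
a circle of fixed area placed on vessel-free contralateral parenchyma.
Planar ROI operations require axis-aligned volume geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage
from skimage import measure

from .emap import EnhancementMap
from .register import RigidTransform
from .volgeom import Mask

__all__ = [
    "PlanarROI",
    "RelativeEnhancement",
    "PhaseEnhancement",
    "ResponseCall",
    "define_tumor_roi",
    "define_normal_roi",
    "transfer_roi",
    "relative_enhancement",
    "classify_response",
]

# in-plane world axes of each plane type (indices into (x, y, z))
_PLANE_AXES = {"axial": (0, 1), "coronal": (0, 2)}
_PLANE_NORMAL = {"axial": 2, "coronal": 1}


@dataclass
class PlanarROI:
    """A closed polygon on one axial or coronal slice, in world mm."""

    plane: Literal["axial", "coronal"]
    slice_world_mm: float
    vertices: np.ndarray  # (n, 2) in-plane world coordinates
    role: Literal["tumor", "normal"] = "tumor"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if self.vertices.shape[0] < 3:
            raise ValueError("ROI polygon needs at least 3 vertices")
        if self.area_mm2 <= 0:
            raise ValueError("ROI area must be positive")

    @property
    def area_mm2(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    def to_dict(self) -> dict:
        return {
            "plane": self.plane,
            "slice_world_mm": self.slice_world_mm,
            "vertices_mm": self.vertices.tolist(),
            "role": self.role,
        }


@dataclass
class PhaseEnhancement:
    """ROI statistics of one phase's enhancement map."""

    T: float
    mean_tumor: float
    mean_normal: float
    n_voxels_tumor_used: int
    high_attenuation_mode: bool
    high_attenuation_applicable: bool
    tau_hu: float


@dataclass
class RelativeEnhancement:
    """Pre/post relative-enhancement values and the ROI statistics behind them."""

    T_pre_RE: float
    T_post_RE: float
    mean_tumor_pre: float
    mean_tumor_post: float
    mean_normal_pre: float
    mean_normal_post: float
    n_voxels_tumor_used: int
    high_attenuation_mode: bool
    tau_hu: float


@dataclass
class ResponseCall:
    """Residual vs non-residual: residual iff T_post_RE strictly > 1."""

    call: Literal["residual", "non_residual"]
    T_post_RE: float


class NormalizationError(ValueError):
    """Normal-parenchyma ROI mean is not positive; the ratio is undefined."""


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _require_axis_aligned(obj) -> None:
    if not np.allclose(np.abs(obj.axes), np.eye(3), atol=1e-6):
        raise ValueError("planar ROI operations require axis-aligned geometry")


def _plane_grid(em, plane: str):
    """In-plane world coordinate vectors and the slice-axis coordinates."""
    ax_u, ax_v = _PLANE_AXES[plane]
    ax_n = _PLANE_NORMAL[plane]
    return em.axis_coords(ax_u), em.axis_coords(ax_v), em.axis_coords(ax_n), ax_u, ax_v, ax_n


def _extract_slice(values: np.ndarray, plane: str, index: int) -> np.ndarray:
    return np.take(values, index, axis=_PLANE_NORMAL[plane])


def _mask_to_polygon(mask2d: np.ndarray, u_coords: np.ndarray, v_coords: np.ndarray) -> np.ndarray:
    """Outline of the largest connected blob of a 2D mask, in world mm.

    Contours run at the 0.5 level midway between pixel centers, so
    point-in-polygon tests at pixel centers reproduce the mask exactly.
    """
    contours = measure.find_contours(mask2d.astype(float), 0.5)
    if not contours:
        raise ValueError("empty in-plane region")
    contour = max(contours, key=lambda c: c.shape[0])
    du = u_coords[1] - u_coords[0] if len(u_coords) > 1 else 1.0
    dv = v_coords[1] - v_coords[0] if len(v_coords) > 1 else 1.0
    world = np.empty_like(contour)
    world[:, 0] = u_coords[0] + contour[:, 0] * du
    world[:, 1] = v_coords[0] + contour[:, 1] * dv
    return world


def rasterize_roi(roi: PlanarROI, em) -> tuple[np.ndarray, int]:
    """Pixels of ``em``'s nearest slice whose centers fall inside the ROI.

    Returns the in-plane boolean mask and the slice index.
    """
    _require_axis_aligned(em)
    u, v, n, ax_u, ax_v, ax_n = _plane_grid(em, roi.plane)
    k = int(np.argmin(np.abs(n - roi.slice_world_mm)))
    uu, vv = np.meshgrid(u, v, indexing="ij")
    pts = np.column_stack([uu.ravel(), vv.ravel()])
    inside = MplPath(roi.vertices).contains_points(pts).reshape(uu.shape)
    return inside, k


def roi_values(roi: PlanarROI, em: EnhancementMap) -> np.ndarray:
    """Finite map values inside the ROI on its slice."""
    inside, k = rasterize_roi(roi, em)
    sl = _extract_slice(em.values, roi.plane, k)
    vals = sl[inside]
    return vals[np.isfinite(vals)]


# ---------------------------------------------------------------------------
# ROI definition
# ---------------------------------------------------------------------------

def define_tumor_roi(pre_em: EnhancementMap, tumor_mask: Mask) -> PlanarROI:
    """Tumor cross-section on the axial or coronal slice of maximal area.

    Scans all axial and all coronal slices of the tumor mask and selects the
    slice with the largest in-plane tumor area (mm²); ties are broken toward
    axial. The ROI polygon is the outline of that cross-section.
    """
    _require_axis_aligned(tumor_mask)
    if not tumor_mask.values.any():
        raise ValueError("tumor mask is empty")
    best = None  # (area_mm2, plane_order, plane, index)
    for order, plane in enumerate(("axial", "coronal")):
        ax_n = _PLANE_NORMAL[plane]
        ax_u, ax_v = _PLANE_AXES[plane]
        pix_area = tumor_mask.spacing[ax_u] * tumor_mask.spacing[ax_v]
        counts = tumor_mask.values.sum(axis=tuple(a for a in range(3) if a != ax_n))
        areas = counts * pix_area
        k = int(np.argmax(areas))
        area = float(areas[k])
        if area > 0 and (best is None or area > best[0] + 1e-12):
            best = (area, order, plane, k)
    if best is None:
        raise ValueError("tumor mask has no in-plane extent")
    _, _, plane, k = best
    u, v, n, *_ = _plane_grid(tumor_mask, plane)
    mask2d = _extract_slice(tumor_mask.values, plane, k)
    poly = _mask_to_polygon(mask2d, u, v)
    return PlanarROI(plane=plane, slice_world_mm=float(n[k]), vertices=poly, role="tumor")


def define_normal_roi(
    pre_em: EnhancementMap,
    liver_mask: Mask,
    tumor_lobe: Literal["left", "right"],
    vessel_mask: Mask | None = None,
    area_mm2: float = 300.0,
    lobe_split_x_mm: float | None = None,
    plane: Literal["axial", "coronal"] = "axial",
    n_vertices: int = 128,
) -> PlanarROI:
    """Circular ROI on vessel-free contralateral parenchyma.

    Searches every slice of the requested plane type for the point of the
    contralateral hepatic lobe that maximises the in-plane distance to
    vessels and to the liver boundary, and centers a circle of ``area_mm2``
    (default 300 mm²) there. Raises if no slice offers enough vessel-free
    parenchyma, advising a smaller area.
    """
    _require_axis_aligned(liver_mask)
    if lobe_split_x_mm is None:
        xs = liver_mask.axis_coords(0)
        occ = liver_mask.values.any(axis=(1, 2))
        lobe_split_x_mm = float(np.mean(xs[occ])) if occ.any() else float(np.mean(xs))
    xs = liver_mask.axis_coords(0)
    contralateral = xs < lobe_split_x_mm if tumor_lobe == "left" else xs > lobe_split_x_mm

    eligible = liver_mask.values.copy()
    eligible &= contralateral[:, None, None]
    if vessel_mask is not None:
        eligible &= ~vessel_mask.values
    if not eligible.any():
        raise ValueError("contralateral lobe contains no eligible parenchyma")

    u, v, n, ax_u, ax_v, ax_n = _plane_grid(liver_mask, plane)
    sampling = (liver_mask.spacing[ax_u], liver_mask.spacing[ax_v])
    # the whole circle must stay inside vessel-free contralateral parenchyma:
    # treat non-liver, vessels and the ipsilateral side as blocked
    blocked = ~liver_mask.values
    blocked |= ~contralateral[:, None, None]
    if vessel_mask is not None:
        blocked |= vessel_mask.values

    best = None  # (distance, slice_index, center_uv)
    for k in range(liver_mask.shape[ax_n]):
        elig2d = _extract_slice(eligible, plane, k)
        if not elig2d.any():
            continue
        free2d = ~_extract_slice(blocked, plane, k)
        dist = ndimage.distance_transform_edt(free2d, sampling=sampling)
        dist[~elig2d] = 0.0
        idx = np.unravel_index(np.argmax(dist), dist.shape)
        if best is None or dist[idx] > best[0]:
            best = (float(dist[idx]), k, (u[idx[0]], v[idx[1]]))
    if best is None:
        raise ValueError("no qualifying vessel-free region; try a smaller area_mm2")

    # regular polygon whose shoelace area equals area_mm2
    radius = float(np.sqrt(2.0 * area_mm2 / (n_vertices * np.sin(2.0 * np.pi / n_vertices))))
    if best[0] < radius:
        raise ValueError(
            f"largest vessel-free disk (r={best[0]:.1f} mm) cannot hold the requested "
            f"ROI (r={radius:.1f} mm); try a smaller area_mm2"
        )
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    cu, cv = best[2]
    verts = np.column_stack([cu + radius * np.cos(theta), cv + radius * np.sin(theta)])
    return PlanarROI(plane=plane, slice_world_mm=float(n[best[1]]), vertices=verts, role="normal")


def transfer_roi(roi: PlanarROI, transform: RigidTransform, target: EnhancementMap | None = None) -> PlanarROI:
    """Map ROI vertices through a rigid transform and re-snap to a slice.

    The polygon's 3D vertices (in-plane coordinates + slice position) are
    pushed through the transform; the new slice position is the mean of the
    transformed normal coordinates, re-snapped to the nearest slice of
    ``target`` when given. In-plane rotations out of the plane family are not
    supported (the pre/post co-registration is near-axial by construction).
    """
    ax_u, ax_v = _PLANE_AXES[roi.plane]
    ax_n = _PLANE_NORMAL[roi.plane]
    pts3 = np.zeros((roi.vertices.shape[0], 3))
    pts3[:, ax_u] = roi.vertices[:, 0]
    pts3[:, ax_v] = roi.vertices[:, 1]
    pts3[:, ax_n] = roi.slice_world_mm
    mapped = transform.apply_points(pts3)
    slice_mm = float(np.mean(mapped[:, ax_n]))
    if target is not None:
        coords = target.axis_coords(ax_n)
        k = int(np.argmin(np.abs(coords - slice_mm)))
        if not (coords.min() - target.spacing[ax_n] <= slice_mm <= coords.max() + target.spacing[ax_n]):
            raise ValueError("transferred ROI falls outside the target volume")
        slice_mm = float(coords[k])
    verts = np.column_stack([mapped[:, ax_u], mapped[:, ax_v]])
    return PlanarROI(plane=roi.plane, slice_world_mm=slice_mm, vertices=verts, role=roi.role)


# ---------------------------------------------------------------------------
# The statistic
# ---------------------------------------------------------------------------

def relative_enhancement(
    em: EnhancementMap,
    roi_tumor: PlanarROI,
    roi_normal: PlanarROI,
    high_attenuation_mode: bool = False,
    tau_hu: float = 0.0,
) -> PhaseEnhancement:
    """T = mean(EM | tumor ROI) / mean(EM | normal ROI) for one phase.

    In ``high_attenuation_mode`` the tumor mean uses only voxels with
    EM > ``tau_hu`` (default 0 ΔHU, which exactly excludes stasis
    subtraction voids). If no tumor voxel exceeds τ, the mean falls back to
    all tumor voxels and the mode is flagged inapplicable.
    """
    tumor_vals = roi_values(roi_tumor, em)
    normal_vals = roi_values(roi_normal, em)
    if tumor_vals.size == 0 or normal_vals.size == 0:
        raise ValueError("ROI contains no finite map values")
    mean_normal = float(normal_vals.mean())
    if mean_normal <= 0:
        raise NormalizationError(
            f"normal-parenchyma mean is {mean_normal:.2f} ΔHU (must be > 0); "
            "parenchymal enhancement failed or the ROI is misplaced"
        )
    applicable = False
    used = tumor_vals
    if high_attenuation_mode:
        subset = tumor_vals[tumor_vals > tau_hu]
        if subset.size:
            used = subset
            applicable = True
    mean_tumor = float(used.mean())
    return PhaseEnhancement(
        T=mean_tumor / mean_normal,
        mean_tumor=mean_tumor,
        mean_normal=mean_normal,
        n_voxels_tumor_used=int(used.size),
        high_attenuation_mode=bool(high_attenuation_mode),
        high_attenuation_applicable=applicable,
        tau_hu=float(tau_hu),
    )


def classify_response(T_post_RE: float) -> ResponseCall:
    """Residual iff T_post_RE is strictly greater than 1 (1.0 → non-residual)."""
    if not np.isfinite(T_post_RE):
        raise ValueError("T_post_RE must be finite")
    call = "residual" if T_post_RE > 1.0 else "non_residual"
    return ResponseCall(call=call, T_post_RE=float(T_post_RE))
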