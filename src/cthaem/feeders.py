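"""Feeding-artery identification for residual-enhancement regions.

The study read 5–10 mm thin-slab MIPs by eye to find the artery "leading to"
each residual-enhancement area. This module substitutes an explicit,
parameter-reporting surrogate: a multiscale Hessian vesselness filter
followed by a minimal-cost (shortest-path) trace from the hepatic-artery
root to the region, run in 3D on the full map (MIP slabs are for QC
renders only — 3D paths avoid projection ambiguities). A traced artery is
classified *persistent feeder* if at least half of its path runs inside the
(dilated) pre-treatment vessel mask, otherwise *new collateral*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import frangi
from skimage.graph import MCP_Geometric

from .emap import EnhancementMap
from .volgeom import GeometryError, Mask, Volume

__all__ = [
    "ResidualRegion",
    "ArteryTrace",
    "FeederCall",
    "detect_residual_regions",
    "vesselness",
    "trace_feeder",
    "classify_feeder",
]

#: path search is aborted (→ no artery) when the best path's minimum
#: normalised vesselness falls below this
MIN_PATH_VESSELNESS = 0.1
#: cost regulariser: cost = 1 / (vesselness + EPS)
EPS = 1e-3

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ResidualRegion:
    """A 26-connected component of supra-threshold tumor voxels on the post map."""

    mask: Mask
    centroid_mm: np.ndarray
    mean_delta_hu: float
    n_voxels: int
    threshold_hu: float


@dataclass
class ArteryTrace:
    """Minimal-cost path from the artery root to a residual region."""

    path_mm: np.ndarray  # (n, 3) ordered world points
    mean_intensity: float
    vesselness_min: float
    path_length_mm: float


@dataclass
class FeederCall:
    """Persistent feeder vs new collateral, by pre-treatment vessel overlap."""

    status: Literal["persistent_feeder", "new_collateral"]
    overlap_fraction: float
    dilation_mm: float
    overlap_threshold: float


def detect_residual_regions(
    post_em: EnhancementMap,
    tumor_mask: Mask,
    threshold_hu: float = 20.0,
    min_voxels: int = 5,
) -> list[ResidualRegion]:
    """Connected residual-enhancement components within the tumor.

    Voxels of the tumor mask whose post-treatment map value exceeds
    ``threshold_hu`` (default 20 ΔHU ≈ the parenchymal uplift) are grouped
    into 26-connected components; components smaller than ``min_voxels`` are
    discarded as noise. Regions are returned sorted by volume, descending.
    An empty list is a valid result (no residual enhancement).
    """
    if post_em.shape != tumor_mask.shape:
        raise GeometryError("post map and tumor mask are on different grids")
    with np.errstate(invalid="ignore"):
        hot = tumor_mask.values & (post_em.values > threshold_hu)
    labels, n = ndimage.label(hot, structure=_CONN26)
    regions: list[ResidualRegion] = []
    for lab in range(1, n + 1):
        sel = labels == lab
        nv = int(sel.sum())
        if nv < min_voxels:
            continue
        idx = np.argwhere(sel)
        centroid = tumor_mask.index_to_world(idx.mean(axis=0))
        regions.append(
            ResidualRegion(
                mask=Mask(values=sel, label="residual", spacing=tumor_mask.spacing,
                          origin=tumor_mask.origin, axes=np.array(tumor_mask.axes)),
                centroid_mm=np.asarray(centroid, float),
                mean_delta_hu=float(np.nanmean(post_em.values[sel])),
                n_voxels=nv,
                threshold_hu=float(threshold_hu),
            )
        )
    regions.sort(key=lambda r: r.n_voxels, reverse=True)
    return regions


def vesselness(
    map_or_volume: Volume | EnhancementMap,
    scales_mm: Sequence[float] = (0.9, 1.5, 2.4),
) -> Volume:
    """Multiscale tubular-structure score in [0, 1] (Hessian eigenvalues).

    Bright tubes score high, plates and blobs are suppressed. The maximum
    over scales is normalised by the global maximum, so a uniform volume
    returns all zeros.
    """
    if len(scales_mm) == 0 or any(s <= 0 for s in scales_mm):
        raise ValueError("scales_mm must be positive")
    vals = np.where(np.isfinite(map_or_volume.values), map_or_volume.values, 0.0)
    mean_spacing = float(np.mean(map_or_volume.spacing))
    sigmas = [s / mean_spacing for s in scales_mm]
    resp = frangi(vals, sigmas=sigmas, black_ridges=False)
    peak = float(resp.max())
    if peak > 0:
        resp = resp / peak
    return Volume(values=resp, spacing=map_or_volume.spacing,
                  origin=map_or_volume.origin, axes=np.array(map_or_volume.axes))


def trace_feeder(
    post_em: EnhancementMap,
    region: ResidualRegion,
    root_mm: Sequence[float],
    vesselness_map: Volume,
) -> ArteryTrace | None:
    """Minimal-cost path from the artery root to the region boundary.

    The cost of a step is its geometric length times ``1/(v + ε)`` where
    ``v`` is the vesselness normalised by its own maximum (so the path is
    invariant to uniform rescaling of the map). Returns ``None`` when the
    best path's minimum vesselness is below 0.1 — no artery leads to the
    region.
    """
    if vesselness_map.shape != post_em.shape:
        raise GeometryError("vesselness map is not on the map grid")
    root_idx = np.round(vesselness_map.world_to_index(np.asarray(root_mm, float))).astype(int)
    if np.any(root_idx < 0) or np.any(root_idx >= np.asarray(vesselness_map.shape)):
        raise ValueError("root point lies outside the volume")
    v = vesselness_map.values
    peak = float(v.max())
    if peak <= 0:
        return None
    v = v / peak
    costs = 1.0 / (v + EPS)
    ends = np.argwhere(region.mask.values)
    if ends.size == 0:
        raise ValueError("residual region is empty")
    mcp = MCP_Geometric(costs, fully_connected=True, sampling=vesselness_map.spacing)
    cum, _ = mcp.find_costs([tuple(root_idx)], ends=[tuple(e) for e in ends])
    end_costs = cum[tuple(ends.T)]
    best = int(np.argmin(end_costs))
    if not np.isfinite(end_costs[best]):
        return None
    path_idx = np.asarray(mcp.traceback(tuple(ends[best])), dtype=float)
    v_along = v[tuple(path_idx.astype(int).T)]
    if float(v_along.min()) < MIN_PATH_VESSELNESS:
        return None
    path_mm = vesselness_map.index_to_world(path_idx)
    steps = np.linalg.norm(np.diff(path_mm, axis=0), axis=1)
    with np.errstate(invalid="ignore"):
        intensity = np.nanmean(post_em.values[tuple(path_idx.astype(int).T)])
    return ArteryTrace(
        path_mm=path_mm,
        mean_intensity=float(intensity),
        vesselness_min=float(v_along.min()),
        path_length_mm=float(steps.sum()),
    )


def classify_feeder(
    trace: ArteryTrace,
    pre_vessel_mask: Mask,
    dilation_mm: float = 1.2,
    overlap_threshold: float = 0.5,
) -> FeederCall:
    """Persistent feeder vs newly developed collateral.

    The overlap fraction is the fraction of path points lying within
    ``dilation_mm`` of the pre-treatment vessel mask; the call is
    *persistent_feeder* iff overlap ≥ ``overlap_threshold`` (≥ rule, default
    0.5). The trace must already live in the pre-treatment frame.
    """
    if trace is None or trace.path_mm.shape[0] == 0:
        raise ValueError("empty trace")
    if not pre_vessel_mask.values.any():
        dist_at = np.full(trace.path_mm.shape[0], np.inf)
    else:
        dist = ndimage.distance_transform_edt(
            ~pre_vessel_mask.values, sampling=pre_vessel_mask.spacing
        )
        idx = pre_vessel_mask.world_to_index(trace.path_mm)
        dist_at = ndimage.map_coordinates(dist, idx.T, order=1, mode="nearest")
    overlap = float(np.mean(dist_at <= dilation_mm))
    status = "persistent_feeder" if overlap >= overlap_threshold else "new_collateral"
    return FeederCall(
        status=status,
        overlap_fraction=overlap,
        dilation_mm=float(dilation_mm),
        overlap_threshold=float(overlap_threshold),
    )
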