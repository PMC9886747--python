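"""Synthetic dual-phase CT hepatic arteriography case generator.

Each case emulates the four acquisitions of an intraprocedural DEB-TACE
session — pre-treatment native + arterial and post-treatment native +
arterial — for a liver (ellipsoid) containing one hypervascular tumor
(sphere), with

* parenchymal arterial uplift of the liver and a stronger tumor uplift
  pre-treatment,
* a configurable residual-enhancement fraction ``f`` post-treatment: a
  spherical cap at the tumor margin keeps the full tumor uplift, the rest of
  the tumor is "treated",
* contrast stasis in the treated subregion, added equally to the
  post-treatment native AND arterial phases so it cancels under subtraction
  (the physical effect the enhancement-mapping method exploits),
* feeding arteries rendered as curved tubes with Gaussian cross-section
  (arterial phases only), flagged pre-only / post-only / both,
* a smooth random deformation between the native and arterial acquisition of
  each session, with everywhere-positive Jacobian,
* smooth liver parenchymal texture (identical across phases — anatomy, not
  noise) and independent additive Gaussian noise per acquisition.

All scene ingredients are analytic functions of world coordinates, so the
deformed native phases are rendered exactly and the ground-truth deformation
fields, masks and expected relative-enhancement values are known.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .register import DeformationField
from .volgeom import Mask, Volume

__all__ = [
    "VesselSpec",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomCase",
    "generate_case",
    "simulate_deformation",
    "generate_cohort",
]


@dataclass
class VesselSpec:
    """A tubular artery: polyline of world points with a Gaussian profile."""

    points: np.ndarray  # (n, 3) world mm
    radius_mm: float = 1.2
    peak_hu: float = 250.0
    presence: Literal["pre_only", "post_only", "both"] = "both"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)


def _vessel_zoff(tumor_radius: float) -> float:
    """Axial offset keeping vessels clear of the tumor's equatorial slice."""
    return min(4.0, 0.55 * tumor_radius)


def _default_vessels(
    liver_center: np.ndarray,
    liver_semi_axes: np.ndarray,
    tumor_center: np.ndarray,
    tumor_radius: float,
) -> list[VesselSpec]:
    cx, cy, cz = liver_center
    ax, ay, az = liver_semi_axes
    tx, ty, tz = tumor_center
    r = tumor_radius
    zoff = _vessel_zoff(r)
    feeder = VesselSpec(
        points=np.array(
            [
                [cx + ax, cy - 0.4 * ay, cz + zoff],
                [tx + 1.4 * r, cy - 0.15 * ay, cz + zoff],
                [tx + 0.7 * r, ty, tz + zoff],
            ]
        ),
        presence="both",
    )
    return [feeder]


def default_collateral(spec: "PhantomSpec") -> VesselSpec:
    """A post-only collateral artery approaching the residual cap from +y.

    Mirror image of the default feeder on the other side of the tumor; its
    proximal end (``points[0]``) is the tracing root for the collateral.
    """
    cx, cy, cz = np.asarray(spec.liver_center_mm, float)
    ax, ay, az = np.asarray(spec.liver_semi_axes_mm, float)
    tx, ty, tz = spec.tumor_center_mm
    r = spec.tumor_radius_mm
    zoff = _vessel_zoff(r)
    return VesselSpec(
        points=np.array(
            [
                [cx + ax, cy + 0.4 * ay, cz + zoff],
                [tx + 1.4 * r, cy + 0.15 * ay, cz + zoff],
                [tx + 0.7 * r, ty + 1.0, tz + zoff],
            ]
        ),
        presence="post_only",
    )


@dataclass
class PhantomSpec:
    """Parameters of one synthetic dual-phase CTHA case.

    Defaults give a 96³ grid at 0.6 mm isotropic spacing (quasi-isotropic
    high-resolution CT), liver HU 55 / tumor HU 45 on the native phase,
    parenchymal arterial uplift 20 HU and pre-treatment tumor uplift 60 HU
    (so the analytic pre-treatment relative enhancement is 3.0), stasis
    150 HU, noise sigma 8 HU.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 0.6
    liver_center_mm: tuple[float, float, float] | None = None  # default: grid center
    liver_semi_axes_mm: tuple[float, float, float] = (26.0, 20.0, 18.0)
    tumor_offset_mm: tuple[float, float, float] = (12.0, 0.0, 0.0)
    tumor_radius_mm: float = 7.0
    hu_background: float = 0.0
    hu_liver_native: float = 55.0
    hu_tumor_native: float = 45.0
    parenchymal_enhancement: float = 20.0
    tumor_enhancement: float = 60.0
    residual_fraction: float = 0.5
    stasis_delta: float = 150.0
    vessel_tree: list[VesselSpec] | None = None
    deformation_amplitude_mm: float = 3.0
    session_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sigma_hu: float = 8.0
    texture_sigma_hu: float = 10.0
    texture_scale_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.residual_fraction <= 1.0):
            raise ValueError("residual_fraction must be in [0, 1]")
        if self.deformation_amplitude_mm < 0:
            raise ValueError("deformation_amplitude_mm must be >= 0")
        if self.noise_sigma_hu < 0:
            raise ValueError("noise_sigma_hu must be >= 0")
        grid_extent = np.asarray(self.grid_shape) * self.spacing_mm
        if self.liver_center_mm is None:
            self.liver_center_mm = tuple(grid_extent / 2.0)
        # tumor sphere must be contained in the liver ellipsoid
        c = np.asarray(self.tumor_offset_mm, float)
        a = np.asarray(self.liver_semi_axes_mm, float)
        r = self.tumor_radius_mm
        # conservative containment check: inflate the normalized radius
        if np.sqrt(np.sum((np.abs(c) + r) ** 2 / a**2)) > 1.0:
            raise ValueError("tumor sphere is not contained in the liver ellipsoid")
        if self.vessel_tree is None:
            self.vessel_tree = _default_vessels(
                np.asarray(self.liver_center_mm),
                np.asarray(self.liver_semi_axes_mm),
                self.tumor_center_mm,
                self.tumor_radius_mm,
            )

    @property
    def tumor_center_mm(self) -> np.ndarray:
        return np.asarray(self.liver_center_mm) + np.asarray(self.tumor_offset_mm)

    @property
    def expected_T_pre(self) -> float:
        return self.tumor_enhancement / self.parenchymal_enhancement

    @property
    def expected_T_post(self) -> float:
        """Analytic post-treatment relative enhancement (high-attenuation subset).

        With ``f > 0`` the enhancing subset of the tumor carries the full
        tumor uplift, so the ratio equals the pre-treatment value; with
        ``f = 0`` no tumor voxel enhances and the ratio is 0.
        """
        if self.residual_fraction > 0:
            return self.tumor_enhancement / self.parenchymal_enhancement
        return 0.0

    @property
    def lobe_split_x_mm(self) -> float:
        return float(self.liver_center_mm[0])

    @property
    def feeder_root_mm(self) -> np.ndarray | None:
        """Seed point for feeder tracing: proximal end of the first vessel."""
        if not self.vessel_tree:
            return None
        return np.asarray(self.vessel_tree[0].points[0], float)


@dataclass
class PhantomTruth:
    """Complete ground truth emitted with every case."""

    tumor_mask: Mask
    residual_mask: Mask
    liver_mask: Mask
    vessel_mask_pre: Mask
    vessel_mask_post: Mask
    vessel_centerlines: list[VesselSpec]
    new_collateral_present: bool
    deformation_pre: DeformationField
    deformation_post: DeformationField
    expected_T_pre: float
    expected_T_post: float
    residual_fraction: float
    lobe_split_x_mm: float
    feeder_root_mm: np.ndarray


@dataclass
class PhantomCase:
    case_id: str
    spec: PhantomSpec
    pre_native: Volume
    pre_arterial: Volume
    post_native: Volume | None
    post_arterial: Volume | None
    truth: PhantomTruth


# ---------------------------------------------------------------------------
# Deformation simulation
# ---------------------------------------------------------------------------

class _GaussianBumpField:
    """Smooth displacement: superposition of vector Gaussian bumps (analytic)."""

    def __init__(self, centers, sigmas, vectors):
        self.centers = np.asarray(centers, float)
        self.sigmas = np.asarray(sigmas, float)
        self.vectors = np.asarray(vectors, float)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, float)
        out = np.zeros_like(pts)
        for c, s, v in zip(self.centers, self.sigmas, self.vectors):
            d2 = np.sum((pts - c) ** 2, axis=-1)
            out += np.exp(-0.5 * d2 / s**2)[..., None] * v
        return out


def _grid_points(grid: Volume | Mask) -> np.ndarray:
    nx, ny, nz = grid.shape
    idx = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
        axis=-1,
    ).astype(float)
    return idx * np.asarray(grid.spacing) + np.asarray(grid.origin)


def simulate_deformation(
    grid: Volume | Mask,
    amplitude_mm: float,
    seed: int,
    n_bumps: int = 6,
    bandwidth_mm: tuple[float, float] = (20.0, 30.0),
) -> DeformationField:
    """Smooth random displacement field with max |u| == amplitude (grid-sampled)."""
    fld, _ = _simulate_deformation_analytic(grid, amplitude_mm, seed, n_bumps, bandwidth_mm)
    return fld


def _simulate_deformation_analytic(
    grid: Volume | Mask,
    amplitude_mm: float,
    seed: int,
    n_bumps: int = 6,
    bandwidth_mm: tuple[float, float] = (20.0, 30.0),
) -> tuple[DeformationField, "_GaussianBumpField"]:
    """Smooth random displacement field with max |u| == amplitude.

    The field is a superposition of wide Gaussian bumps (bandwidth >= 20 mm),
    rescaled so the maximum displacement magnitude on the grid equals
    ``amplitude_mm``. Raises if the resulting map would fold (non-positive
    Jacobian determinant anywhere, checked numerically).

    Returns the sampled :class:`DeformationField` together with the analytic
    bump function (used by the generator for exact scene rendering).
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    extent = np.asarray(grid.shape) * np.asarray(grid.spacing)
    rng = np.random.default_rng(seed)
    centers = np.asarray(grid.origin) + rng.uniform(0.15, 0.85, (n_bumps, 3)) * extent
    sigmas = rng.uniform(*bandwidth_mm, n_bumps)
    vectors = rng.normal(size=(n_bumps, 3))
    fn = _GaussianBumpField(centers, sigmas, vectors)

    pts = _grid_points(grid)
    disp = fn(pts)
    maxmag = float(np.linalg.norm(disp, axis=-1).max())
    if amplitude_mm == 0 or maxmag == 0:
        fn = _GaussianBumpField(centers, sigmas, np.zeros_like(vectors))
        fld = DeformationField(
            np.zeros(grid.shape + (3,)), grid.spacing, grid.origin, np.array(grid.axes)
        )
        return fld, fn
    scale = amplitude_mm / maxmag
    fn = _GaussianBumpField(centers, sigmas, vectors * scale)
    fld = DeformationField(disp * scale, grid.spacing, grid.origin, np.array(grid.axes))
    if float(fld.jacobian_determinant().min()) <= 0.0:
        raise ValueError(
            f"deformation amplitude {amplitude_mm} mm folds the grid "
            "(non-positive Jacobian); reduce the amplitude"
        )
    return fld, fn


def _invert_displacement(fn: "_GaussianBumpField", pts: np.ndarray,
                         tol: float = 1e-4, max_iter: int = 50) -> np.ndarray:
    """Fixed-point inversion v(y) = -u(y + v(y)) of an analytic field."""
    v = np.zeros_like(pts)
    for _ in range(max_iter):
        v_new = -fn(pts + v)
        if float(np.abs(v_new - v).max()) < tol:
            v = v_new
            break
        v = v_new
    return v


# ---------------------------------------------------------------------------
# Analytic scene
# ---------------------------------------------------------------------------

def _polyline_distance(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min distance from each point to a polyline (vectorised per segment)."""
    d = np.full(pts.shape[0], np.inf)
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            dist = np.linalg.norm(pts - a, axis=1)
        else:
            t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            dist = np.linalg.norm(pts - proj, axis=1)
        d = np.minimum(d, dist)
    return d


class _Scene:
    """Evaluates phantom tissue values at arbitrary world points."""

    def __init__(self, spec: PhantomSpec, rng: np.random.Generator):
        self.spec = spec
        self.liver_c = np.asarray(spec.liver_center_mm, float)
        self.liver_a = np.asarray(spec.liver_semi_axes_mm, float)
        self.tumor_c = spec.tumor_center_mm
        # residual cap threshold: minimise |voxel fraction - f| over column cuts
        self.cap_x0 = self._cap_threshold()
        # coarse smooth texture grid (same in every phase: anatomy)
        step = spec.texture_scale_mm
        extent = np.asarray(spec.grid_shape) * spec.spacing_mm
        tex_shape = np.maximum((extent / step).astype(int) + 3, 4)
        self.tex_values = rng.normal(0.0, spec.texture_sigma_hu, tuple(tex_shape))
        self.tex_step = step

    def _cap_threshold(self) -> float:
        """x-threshold of the marginal residual cap ({x >= x0} of the tumor)."""
        spec = self.spec
        f = spec.residual_fraction
        r, cx = spec.tumor_radius_mm, self.tumor_c[0]
        if f <= 0.0:
            return cx + r + 1.0
        if f >= 1.0:
            return cx - r - 1.0
        h = spec.spacing_mm
        # candidate thresholds: midpoints between voxel-center columns
        cols = np.arange(np.floor((cx - r) / h), np.ceil((cx + r) / h) + 1) * h + h / 2.0
        # voxel-count fraction of the sphere mask with center x >= x0
        pts = self._tumor_voxel_centers()
        x = pts[:, 0]
        best_x0, best_err = cols[0], np.inf
        for x0 in (cols[:-1] + cols[1:]) / 2.0:
            frac = float(np.mean(x >= x0))
            if abs(frac - f) < best_err:
                best_err, best_x0 = abs(frac - f), x0
        return float(best_x0)

    def _tumor_voxel_centers(self) -> np.ndarray:
        spec = self.spec
        h = spec.spacing_mm
        r, c = spec.tumor_radius_mm, self.tumor_c
        lo = np.floor((c - r) / h).astype(int)
        hi = np.ceil((c + r) / h).astype(int) + 1
        ax = [np.arange(lo[a], hi[a]) * h + h / 2.0 for a in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
        inside = np.sum((pts - c) ** 2, axis=1) <= r**2
        return pts[inside]

    # -- membership ------------------------------------------------------
    def in_liver(self, pts: np.ndarray) -> np.ndarray:
        return np.sum(((pts - self.liver_c) / self.liver_a) ** 2, axis=-1) <= 1.0

    def in_tumor(self, pts: np.ndarray) -> np.ndarray:
        return np.sum((pts - self.tumor_c) ** 2, axis=-1) <= self.spec.tumor_radius_mm**2

    def in_residual(self, pts: np.ndarray) -> np.ndarray:
        return self.in_tumor(pts) & (pts[..., 0] >= self.cap_x0)

    def texture(self, pts: np.ndarray) -> np.ndarray:
        coords = [(pts[..., a] - self.spec.liver_center_mm[a]) / self.tex_step
                  + self.tex_values.shape[a] / 2.0 for a in range(3)]
        return ndimage.map_coordinates(self.tex_values, coords, order=1, mode="nearest")

    # -- tissue values -----------------------------------------------------
    def base(self, pts: np.ndarray, post: bool) -> np.ndarray:
        """Native-phase value: background / liver (+texture) / tumor (+stasis post)."""
        spec = self.spec
        liver = self.in_liver(pts)
        tumor = self.in_tumor(pts)
        out = np.full(pts.shape[:-1], spec.hu_background, dtype=np.float64)
        tex = self.texture(pts)
        out[liver] = spec.hu_liver_native + tex[liver]
        out[tumor] = spec.hu_tumor_native
        if post:
            treated = tumor & ~self.in_residual(pts)
            out[treated] += spec.stasis_delta
        return out

    def uplift(self, pts: np.ndarray, post: bool) -> np.ndarray:
        """Arterial-phase enhancement added on top of :meth:`base`."""
        spec = self.spec
        liver = self.in_liver(pts)
        tumor = self.in_tumor(pts)
        out = np.zeros(pts.shape[:-1], dtype=np.float64)
        out[liver & ~tumor] = spec.parenchymal_enhancement
        if post:
            out[self.in_residual(pts)] = spec.tumor_enhancement
        else:
            out[tumor] = spec.tumor_enhancement
        flat = pts.reshape(-1, 3)
        vout = out.reshape(-1)
        # post-treatment, the embolized tumor bed carries no arterial signal
        if post:
            treated = (self.in_tumor(flat) & ~self.in_residual(flat))
        for v in self.spec.vessel_tree:
            if v.presence == "both" or v.presence == ("post_only" if post else "pre_only"):
                d = _polyline_distance(flat, v.points)
                # compact support at 3 radii keeps the profile strictly local
                near = d < 3.0 * v.radius_mm
                if post:
                    near &= ~treated
                prof = v.peak_hu * np.exp(-0.5 * (d[near] / v.radius_mm) ** 2)
                vout[near] = np.maximum(vout[near], prof)
        return out

    def acquisition(self, pts: np.ndarray, phase: str, post: bool) -> np.ndarray:
        vals = self.base(pts, post)
        if phase == "arterial":
            vals = vals + self.uplift(pts, post)
        return vals


# ---------------------------------------------------------------------------
# Case generation
# ---------------------------------------------------------------------------

def _seed_stream(seed: int, *salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *salt]))


def generate_case(
    spec: PhantomSpec,
    case_id: str = "case",
    sessions: tuple[str, ...] = ("pre", "post"),
) -> PhantomCase:
    """Render the four acquisitions plus complete ground truth.

    ``sessions=("pre",)`` renders only the pre-treatment pair (used by the
    registration-accuracy suite, which needs no post-treatment volumes).

    The arterial phase of each session is the reference pose; the native
    phase of each session is acquired under a smooth random deformation of
    amplitude ``spec.deformation_amplitude_mm``. The stored truth deformation
    fields follow the package convention (arterial grid → native space), i.e.
    they are exactly what a perfect registration of the pair would recover.
    Identical seeds give bit-identical outputs.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = (spec.spacing_mm,) * 3
    ref = Volume(np.zeros(shape), spacing=spacing, origin=(spec.spacing_mm / 2.0,) * 3)
    pts = _grid_points(ref)

    scene = _Scene(spec, rng=_seed_stream(spec.seed, 0))

    # truth deformation fields (analytic, sampled on the arterial grid)
    fld_pre, fn_pre = _simulate_deformation_analytic(
        ref, spec.deformation_amplitude_mm,
        seed=int(_seed_stream(spec.seed, 1).integers(2**31)))
    fld_post, fn_post = _simulate_deformation_analytic(
        ref, spec.deformation_amplitude_mm,
        seed=int(_seed_stream(spec.seed, 2).integers(2**31)))

    shift = np.asarray(spec.session_shift_mm, float)

    want_post = "post" in sessions

    # native phases sample the scene at y + v(y) where v inverts the truth field
    if spec.deformation_amplitude_mm > 0:
        v_pre = _invert_displacement(fn_pre, pts)
        v_post = _invert_displacement(fn_post, pts + shift) if want_post else None
    else:
        v_pre = np.zeros_like(pts)
        v_post = np.zeros_like(pts) if want_post else None

    pre_arterial_vals = scene.acquisition(pts, "arterial", post=False)
    pre_native_vals = scene.acquisition(pts + v_pre, "native", post=False)
    post_arterial_vals = post_native_vals = None
    if want_post:
        post_arterial_vals = scene.acquisition(pts + shift, "arterial", post=True)
        post_native_vals = scene.acquisition(pts + shift + v_post, "native", post=True)

    if spec.noise_sigma_hu > 0:
        noise_rng = _seed_stream(spec.seed, 3)
        phases = [pre_native_vals, pre_arterial_vals]
        if want_post:
            phases += [post_native_vals, post_arterial_vals]
        for arr in phases:
            arr += noise_rng.normal(0.0, spec.noise_sigma_hu, arr.shape)

    def vol(vals):
        return Volume(vals, spacing=spacing, origin=ref.origin)

    # truth masks on the reference (pre-arterial) grid
    liver_m = Mask.like(ref, scene.in_liver(pts), "liver")
    tumor_m = Mask.like(ref, scene.in_tumor(pts), "tumor")
    residual_m = Mask.like(ref, scene.in_residual(pts), "residual")
    pre_vessels = np.zeros(shape, bool)
    post_vessels = np.zeros(shape, bool)
    flat = pts.reshape(-1, 3)
    for v in spec.vessel_tree:
        inside = (_polyline_distance(flat, v.points) <= v.radius_mm).reshape(shape)
        if v.presence in ("both", "pre_only"):
            pre_vessels |= inside
        if v.presence in ("both", "post_only"):
            post_vessels |= inside
    truth = PhantomTruth(
        tumor_mask=tumor_m,
        residual_mask=residual_m,
        liver_mask=liver_m,
        vessel_mask_pre=Mask.like(ref, pre_vessels, "vessel"),
        vessel_mask_post=Mask.like(ref, post_vessels, "vessel"),
        vessel_centerlines=list(spec.vessel_tree),
        new_collateral_present=any(v.presence == "post_only" for v in spec.vessel_tree),
        deformation_pre=fld_pre,
        deformation_post=fld_post,
        expected_T_pre=spec.expected_T_pre,
        expected_T_post=spec.expected_T_post,
        residual_fraction=spec.residual_fraction,
        lobe_split_x_mm=spec.lobe_split_x_mm,
        feeder_root_mm=spec.feeder_root_mm,
    )
    return PhantomCase(
        case_id=case_id,
        spec=spec,
        pre_native=vol(pre_native_vals),
        pre_arterial=vol(pre_arterial_vals),
        post_native=vol(post_native_vals) if want_post else None,
        post_arterial=vol(post_arterial_vals) if want_post else None,
        truth=truth,
    )


def cohort_specs(
    n_cases: int,
    residual_prevalence: float,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    residual_fraction_range: tuple[float, float] = (0.2, 0.8),
) -> list[tuple[str, PhantomSpec]]:
    """Deterministic per-case (case_id, spec) pairs for a labelled cohort.

    round(n * prevalence) cases get a residual fraction drawn uniformly from
    ``residual_fraction_range``; the rest get f = 0. Per-case seeds derive
    from the cohort seed. Generating cases one spec at a time keeps a cohort
    run's memory footprint to a single case.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not (0.0 <= residual_prevalence <= 1.0):
        raise ValueError("residual_prevalence must be in [0, 1]")
    base_spec = base_spec or PhantomSpec()
    n_res = int(np.floor(n_cases * residual_prevalence + 0.5))
    rng = _seed_stream(seed, 100)
    fractions = np.concatenate([
        rng.uniform(*residual_fraction_range, n_res),
        np.zeros(n_cases - n_res),
    ])
    # deterministic interleaving of residual / non-residual cases
    order = rng.permutation(n_cases)
    fractions = fractions[order]
    out = []
    for i in range(n_cases):
        case_seed = int(_seed_stream(seed, 200 + i).integers(2**31))
        spec = replace(base_spec, residual_fraction=float(fractions[i]), seed=case_seed)
        out.append((f"case_{i:03d}", spec))
    return out


def generate_cohort(
    n_cases: int,
    residual_prevalence: float,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    residual_fraction_range: tuple[float, float] = (0.2, 0.8),
) -> list[PhantomCase]:
    """A labelled cohort: round(n * prevalence) residual cases, the rest f = 0.

    Same seed, same truth labels and volumes. For large cohorts prefer
    iterating :func:`cohort_specs` and generating one case at a time.
    """
    return [
        generate_case(spec, case_id=case_id)
        for case_id, spec in cohort_specs(
            n_cases, residual_prevalence, base_spec, seed, residual_fraction_range
        )
    ]
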