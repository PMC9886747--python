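"""Shared reduced-size phantom configurations for fast unit tests.

The full-size (96³) defaults are exercised by the acceptance suite; unit
tests that only need *a* liver with *a* tumor use these smaller grids. The
normal-ROI area must shrink with the liver so the circle still fits in the
contralateral lobe.
"""

from __future__ import annotations

from cthaem.emap import compute_em
from cthaem.phantom import PhantomSpec, default_collateral
from cthaem.register import DeformationField

#: 64³ grid (38.4 mm field of view)
FAST = dict(
    grid_shape=(64, 64, 64),
    liver_semi_axes_mm=(16.0, 12.0, 11.0),
    tumor_offset_mm=(7.0, 0.0, 0.0),
    tumor_radius_mm=4.5,
)
FAST_ROI_AREA = 90.0

#: 48³ grid (28.8 mm field of view)
TINY = dict(
    grid_shape=(48, 48, 48),
    liver_semi_axes_mm=(12.0, 9.5, 8.5),
    tumor_offset_mm=(5.5, 0.0, 0.0),
    tumor_radius_mm=3.5,
)
TINY_ROI_AREA = 50.0


def fast_spec(**kw) -> PhantomSpec:
    return PhantomSpec(**{**FAST, **kw})


def tiny_spec(**kw) -> PhantomSpec:
    return PhantomSpec(**{**TINY, **kw})


def two_vessel_spec(base=None, **kw) -> PhantomSpec:
    """A case with the default feeder plus a post-only collateral."""
    spec = fast_spec(**kw) if base is None else base
    spec.vessel_tree = spec.vessel_tree + [default_collateral(spec)]
    return spec


def identity_maps(case):
    """Pre/post enhancement maps through the identity field (no registration)."""
    fld = DeformationField.identity(case.pre_arterial)
    em_pre = compute_em(case.pre_native, case.pre_arterial, fld, phase_pair="pre")
    em_post = None
    if case.post_arterial is not None:
        em_post = compute_em(case.post_native, case.post_arterial, fld, phase_pair="post")
    return em_pre, em_post
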