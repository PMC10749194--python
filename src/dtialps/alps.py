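"""ALPS-index computation: ROI placement, diffusivity extraction, the index.

The diffusivity-along-perivascular-space (ALPS) index is

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

where Dxx/Dyy/Dzz are the *diagonal tensor elements in image axes* (not
eigenvalues), averaged over a 5 mm disk ROI in the projection-fiber and
association-fiber tracts on a single axial slice at the level of the
lateral ventricle body. The x-axis is the perivascular direction,
perpendicular to both tracts, so the numerator tracks water mobility along
the perivascular space while the denominator normalises by the diffusivity
perpendicular to both fibers and to the perivascular space.

Clinically the ROIs are drawn by hand on a color FA map; against the
phantom's known geometry they are placed automatically at the tract
centroids, which removes rater variability from the recovery experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .containers import DWIVolume, TensorField
from .errors import DTIALPSError, ExtractionError, PlacementError
from .gradients import GradientTable

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import PhantomSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROISpec:
    """A disk ROI on a single axial slice.

    ``center`` is the in-plane voxel coordinate (i, j) of the disk center,
    ``slice_index`` the axial slice (z voxel index), ``diameter`` in mm.
    """

    fiber_class: str            # "projection" | "association"
    center: tuple[int, int]
    slice_index: int
    diameter: float = 5.0
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        if self.fiber_class not in ("projection", "association"):
            raise PlacementError(f"unknown fiber class {self.fiber_class!r}")
        if self.diameter <= 0:
            raise PlacementError("ROI diameter must be > 0")


@dataclass(frozen=True)
class ALPSMeasurement:
    """The four ROI-mean diffusivities (mm^2/s) and the resulting index."""

    dxx_proj: float
    dyy_proj: float
    dxx_assoc: float
    dzz_assoc: float
    n_voxels_proj: int
    n_voxels_assoc: int
    alps: float


def compute_alps(
    dxx_proj: float, dyy_proj: float, dxx_assoc: float, dzz_assoc: float
) -> float:
    """ALPS index from the four ROI diffusivities.

    Scale-invariant: multiplying all four inputs by the same positive
    constant leaves the index unchanged. Requires positive inputs.
    """
    for v, name in ((dxx_proj, "dxx_proj"), (dyy_proj, "dyy_proj"),
                    (dxx_assoc, "dxx_assoc"), (dzz_assoc, "dzz_assoc")):
        if v <= 0:
            raise DTIALPSError(f"ALPS input {name} must be > 0, got {v}")
    return (dxx_proj + dxx_assoc) / (dyy_proj + dzz_assoc)


def roi_mask(
    roi: ROISpec,
    voxel_size: tuple[float, float, float],
    grid_shape: tuple[int, int, int],
) -> np.ndarray:
    """Digital disk mask for an ROI: boolean (X, Y, Z) array.

    A voxel on the ROI's slice is included iff its in-plane center lies
    within ``diameter / 2`` (mm, inclusive) of the ROI center — half-in
    voxels are excluded. The center voxel is always included, so the mask
    is never empty.
    """
    mask = np.zeros(grid_shape, dtype=bool)
    radius = roi.diameter / 2.0
    ci, cj = roi.center
    # voxel centers on a regular grid: in-plane distance in mm
    ni = int(np.ceil(radius / voxel_size[0]))
    nj = int(np.ceil(radius / voxel_size[1]))
    for di in range(-ni, ni + 1):
        for dj in range(-nj, nj + 1):
            if np.hypot(di * voxel_size[0], dj * voxel_size[1]) <= radius:
                i, j = ci + di, cj + dj
                if 0 <= i < grid_shape[0] and 0 <= j < grid_shape[1]:
                    mask[i, j, roi.slice_index] = True
    mask[ci, cj, roi.slice_index] = True  # guaranteed nonempty
    return mask


def place_rois_auto(
    phantom_spec: "PhantomSpec", diameter: float = 5.0
) -> tuple[ROISpec, ROISpec]:
    """Place the projection and association ROIs at the tract centroids.

    The axial slice is the tract centroid slice (the phantom analog of the
    lateral-ventricle-body level). Deterministic. Raises
    :class:`PlacementError` if the disk does not fit inside the tract
    in-plane.
    """
    rois = []
    for region in (phantom_spec.projection, phantom_spec.association):
        ci, cj, ck = region.centroid()
        roi = ROISpec(region.name, (ci, cj), ck, diameter)
        mask = roi_mask(roi, phantom_spec.voxel_size, phantom_spec.grid_shape)
        for voxel in np.argwhere(mask):
            if not region.contains(tuple(voxel)):
                raise PlacementError(
                    f"{diameter} mm ROI does not fit inside the "
                    f"{region.name} tract [{region.lo}, {region.hi})"
                )
        rois.append(roi)
    return rois[0], rois[1]


def extract_axis_diffusivities(
    field: TensorField, mask: np.ndarray
) -> tuple[float, float, float]:
    """ROI-mean diffusivities along the image axes: (Dxx, Dyy, Dzz) means
    of the diagonal tensor components over the masked voxels."""
    if not np.any(mask):
        raise ExtractionError("empty ROI mask")
    vals = field.data[mask]
    return (
        float(vals[:, 0].mean()),
        float(vals[:, 1].mean()),
        float(vals[:, 2].mean()),
    )


def measure_alps(
    field: TensorField,
    roi_proj: ROISpec,
    roi_assoc: ROISpec,
) -> ALPSMeasurement:
    """Extract the four diffusivities from a fitted field and form the index."""
    mask_p = roi_mask(roi_proj, field.voxel_size, field.grid_shape)
    mask_a = roi_mask(roi_assoc, field.voxel_size, field.grid_shape)
    dxx_p, dyy_p, _ = extract_axis_diffusivities(field, mask_p)
    dxx_a, _, dzz_a = extract_axis_diffusivities(field, mask_a)
    alps = compute_alps(dxx_p, dyy_p, dxx_a, dzz_a)
    m = ALPSMeasurement(
        dxx_proj=dxx_p, dyy_proj=dyy_p, dxx_assoc=dxx_a, dzz_assoc=dzz_a,
        n_voxels_proj=int(mask_p.sum()), n_voxels_assoc=int(mask_a.sum()),
        alps=alps,
    )
    logger.info(
        "ALPS %.4f (Dxxproj=%.3e Dyyproj=%.3e Dxxassoc=%.3e Dzzassoc=%.3e; "
        "%d/%d voxels)",
        m.alps, m.dxx_proj, m.dyy_proj, m.dxx_assoc, m.dzz_assoc,
        m.n_voxels_proj, m.n_voxels_assoc,
    )
    return m


def run_subject_pipeline(
    dwi: DWIVolume,
    gtab: GradientTable | None = None,
    phantom_spec: "PhantomSpec | None" = None,
    rois: tuple[ROISpec, ROISpec] | None = None,
    diameter: float = 5.0,
) -> ALPSMeasurement:
    """End-to-end single-subject measurement: fit -> ROIs -> index.

    ROIs come either from the known phantom geometry (``phantom_spec``) or
    are given explicitly (``rois``, manual mode for non-phantom data).
    Stage failures propagate with the stage named in the message.
    """
    from .tensor import fit_tensor  # local import keeps module layering acyclic

    if (phantom_spec is None) == (rois is None):
        raise DTIALPSError("provide exactly one of phantom_spec or rois")
    try:
        field = fit_tensor(dwi, gtab)
    except DTIALPSError as exc:
        raise type(exc)(f"tensor-fit stage: {exc}") from exc
    try:
        if rois is None:
            rois = place_rois_auto(phantom_spec, diameter)
    except DTIALPSError as exc:
        raise type(exc)(f"ROI-placement stage: {exc}") from exc
    try:
        return measure_alps(field, rois[0], rois[1])
    except DTIALPSError as exc:
        raise type(exc)(f"extraction stage: {exc}") from exc
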