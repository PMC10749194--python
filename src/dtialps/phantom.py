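"""Three-fiber-tract DWI phantom with an exact, analytically-known ALPS index.

The phantom mimics the white-matter geometry at the level of the lateral
ventricle body where the ALPS index is measured: three disjoint cuboid
tracts whose fibers run along the image axes —

* projection fibers along z (inferior-superior),
* association fibers along y (anterior-posterior),
* subcortical fibers along x (right-left),

embedded in an isotropic background. The perivascular space runs along x,
perpendicular to both the projection and association tracts, so perivascular
water mobility is encoded as the x-axis diffusivity (Dxx) of those two
tracts. Given a target ALPS index, that Dxx is solved for analytically, so
the ground-truth index of every phantom is exact by construction.

Signals follow the mono-exponential Stejskal-Tanner model
``S_i = S0 * exp(-b_i * g_i^T D g_i)`` with optional Rician noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .alps import compute_alps
from .containers import DWIVolume, TensorField
from .errors import PhantomError
from .gradients import GradientTable

_AXIS_NAMES = ("x", "y", "z")


@dataclass(frozen=True)
class Region:
    """Axis-aligned cuboid tract: ``lo`` inclusive, ``hi`` exclusive, in
    voxel coordinates; ``fiber_axis`` is the image axis (0=x, 1=y, 2=z) the
    fibers run along."""

    name: str
    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    fiber_axis: int

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def contains(self, voxel: tuple[int, int, int]) -> bool:
        return all(l <= v < h for v, l, h in zip(voxel, self.lo, self.hi))

    def centroid(self) -> tuple[int, int, int]:
        return tuple((l + h - 1) // 2 for l, h in zip(self.lo, self.hi))

    def overlaps(self, other: "Region") -> bool:
        return all(l < oh and ol < h for l, h, ol, oh in
                   zip(self.lo, self.hi, other.lo, other.hi))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and diffusivities of the three-tract phantom.

    Diffusivities are mm^2/s. ``d_parallel`` applies along each tract's
    fiber axis, ``d_perp`` across it (except the perivascular x-axis of the
    projection and association tracts, which is set per-phantom from the
    target ALPS index); the background is isotropic at ``d_background``.
    Defaults are typical deep white / gray matter magnitudes.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 24)
    voxel_size: tuple[float, float, float] = (1.72, 1.72, 3.0)
    projection: Region = field(
        default=Region("projection", (6, 10, 4), (16, 38, 20), fiber_axis=2))
    association: Region = field(
        default=Region("association", (20, 10, 4), (30, 38, 20), fiber_axis=1))
    subcortical: Region = field(
        default=Region("subcortical", (34, 10, 4), (44, 38, 20), fiber_axis=0))
    d_parallel: float = 1.4e-3
    d_perp: float = 0.4e-3
    d_background: float = 0.8e-3

    def __post_init__(self) -> None:
        for d, name in ((self.d_parallel, "d_parallel"), (self.d_perp, "d_perp"),
                        (self.d_background, "d_background")):
            if d <= 0:
                raise PhantomError(f"{name} must be > 0, got {d}")
        expected_axes = {"projection": 2, "association": 1, "subcortical": 0}
        for region in self.regions:
            if region.fiber_axis != expected_axes[region.name]:
                raise PhantomError(
                    f"{region.name} fibers must run along "
                    f"{_AXIS_NAMES[expected_axes[region.name]]}"
                )
            for l, h, n in zip(region.lo, region.hi, self.grid_shape):
                if not (0 <= l < h <= n):
                    raise PhantomError(
                        f"region {region.name} [{region.lo}, {region.hi}) "
                        f"does not fit inside grid {self.grid_shape}"
                    )
        regions = self.regions
        for i, a in enumerate(regions):
            for b in regions[i + 1:]:
                if a.overlaps(b):
                    raise PhantomError(f"regions {a.name} and {b.name} overlap")

    @property
    def regions(self) -> tuple[Region, Region, Region]:
        return (self.projection, self.association, self.subcortical)


def solve_perivascular_dxx(
    target_alps: float, dyy_proj: float, dzz_assoc: float
) -> float:
    """Invert the ALPS formula for the perivascular x-axis diffusivity.

    With the perivascular diffusivity shared by both tracts
    (Dxx_proj = Dxx_assoc = d), the index
    mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc) reduces to
    ``d / mean(dyy_proj, dzz_assoc)``, so
    ``d = target_alps * (dyy_proj + dzz_assoc) / 2``.
    """
    for v, name in ((target_alps, "target_alps"), (dyy_proj, "dyy_proj"),
                    (dzz_assoc, "dzz_assoc")):
        if v <= 0:
            raise PhantomError(f"{name} must be > 0, got {v}")
    return target_alps * 0.5 * (dyy_proj + dzz_assoc)


def make_phantom(spec: PhantomSpec, alps_true: float) -> TensorField:
    """Build the ground-truth tensor field for a subject with index ``alps_true``.

    All tensors are diagonal in image axes. The projection tract's largest
    eigenvalue lies on z and the association tract's on y; the x-axis
    diffusivity of both is solved from ``alps_true`` so the region-mean
    ground-truth ALPS index equals the target exactly.

    Raises
    ------
    PhantomError
        If the required perivascular diffusivity reaches ``d_parallel``:
        the principal axis would no longer be the fiber axis (also emitted
        as a warning before rejection).
    """
    if alps_true <= 0:
        raise PhantomError(f"alps_true must be > 0, got {alps_true}")
    d_pv = solve_perivascular_dxx(alps_true, spec.d_perp, spec.d_perp)
    if d_pv >= spec.d_parallel:
        msg = (
            f"target ALPS {alps_true} needs perivascular Dxx {d_pv:.3e} >= "
            f"d_parallel {spec.d_parallel:.3e}: principal axis would no "
            "longer be the fiber axis"
        )
        warnings.warn(msg)
        raise PhantomError(msg)
    data = np.zeros(spec.grid_shape + (6,))
    data[..., :3] = spec.d_background  # isotropic background
    diag = {
        # (Dxx, Dyy, Dzz) per tract; fiber axis carries d_parallel
        "projection": (d_pv, spec.d_perp, spec.d_parallel),
        "association": (d_pv, spec.d_parallel, spec.d_perp),
        "subcortical": (spec.d_parallel, spec.d_perp, spec.d_perp),
    }
    for region in spec.regions:
        sl = region.slices()
        for c in range(3):
            data[sl + (c,)] = diag[region.name][c]
        data[sl + (slice(3, 6),)] = 0.0
    return TensorField(data, spec.voxel_size)


def analytic_alps(field: TensorField, spec: PhantomSpec) -> float:
    """Ground-truth ALPS index from the region means of a phantom field."""
    proj = field.data[spec.projection.slices()]
    assoc = field.data[spec.association.slices()]
    return compute_alps(
        dxx_proj=float(proj[..., 0].mean()),
        dyy_proj=float(proj[..., 1].mean()),
        dxx_assoc=float(assoc[..., 0].mean()),
        dzz_assoc=float(assoc[..., 2].mean()),
    )


def simulate_dwi(
    field: TensorField,
    gtab: GradientTable,
    s0: float = 1000.0,
    snr: float | None = 30.0,
    seed: int = 0,
) -> DWIVolume:
    """Forward-simulate the DWI signal of a tensor field.

    Noiseless (``snr=None``) signals are the exact Stejskal-Tanner values.
    Otherwise Rician noise is applied: the magnitude of the complex signal
    with i.i.d. Gaussian noise of sigma = s0 / snr on both channels, as in
    magnitude MRI. Reproducible for a given seed.
    """
    if s0 <= 0:
        raise PhantomError(f"s0 must be > 0, got {s0}")
    if snr is not None and snr <= 0:
        raise PhantomError(f"snr must be > 0 or None, got {snr}")
    g = gtab.bvecs
    # g^T D g from the 6 stored components, vectorised over voxels and dirs
    quad = (
        np.einsum("...c,nc->...n", field.data[..., :3], g * g)
        + 2.0 * np.einsum("...,n->...n", field.data[..., 3], g[:, 0] * g[:, 1])
        + 2.0 * np.einsum("...,n->...n", field.data[..., 4], g[:, 0] * g[:, 2])
        + 2.0 * np.einsum("...,n->...n", field.data[..., 5], g[:, 1] * g[:, 2])
    )
    signal = s0 * np.exp(-gtab.bvals * quad)
    if snr is not None:
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        real = signal + rng.normal(0.0, sigma, signal.shape)
        imag = rng.normal(0.0, sigma, signal.shape)
        signal = np.hypot(real, imag)
    return DWIVolume(signal, gtab, field.voxel_size, field.affine)
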