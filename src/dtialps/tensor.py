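"""Voxelwise diffusion-tensor estimation and derived maps.

The fit is ordinary log-linear least squares on the Stejskal-Tanner model:
for each voxel, ``ln(S_i / S0) = -b_i * g_i^T D g_i`` is linear in the six
tensor components, with the design row
``b_i * (gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz)``. The estimator is
exact on noiseless positive signals, which is what makes full-pipeline
parameter-recovery validation possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import DWIVolume, TensorField
from .errors import FitError
from .gradients import GradientTable

logger = logging.getLogger(__name__)

#: signals are clamped to SIGNAL_FLOOR * S0 before the log, so that
#: noise-driven nonpositive magnitudes cannot produce NaNs
SIGNAL_FLOOR = 1e-6


def design_matrix(gtab: GradientTable) -> np.ndarray:
    """(n_dwi, 6) log-linear design over the b > 0 entries of ``gtab``."""
    g = gtab.bvecs[gtab.dwi_mask]
    b = gtab.bvals[gtab.dwi_mask]
    return b[:, None] * np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])


def fit_tensor(
    dwi: DWIVolume,
    gtab: GradientTable | None = None,
    mask: np.ndarray | None = None,
) -> TensorField:
    """Fit a diffusion tensor per voxel by log-linear least squares.

    Parameters
    ----------
    dwi : the 4-D signal.
    gtab : gradient table; defaults to ``dwi.gtab``.
    mask : optional boolean (X, Y, Z) mask; voxels outside are left zero.

    Raises
    ------
    FitError
        If the scheme has no b = 0 entry, fewer than 6 weighted directions,
        or a rank-deficient design (e.g. coplanar directions).
    """
    gtab = dwi.gtab if gtab is None else gtab
    if not np.any(gtab.b0_mask):
        raise FitError("scheme has no b = 0 entry to estimate S0")
    n_dwi = int(gtab.dwi_mask.sum())
    if n_dwi < 6:
        raise FitError(f"only {n_dwi} weighted directions; need >= 6")
    a = design_matrix(gtab)
    rank = np.linalg.matrix_rank(a)
    if rank < 6:
        raise FitError(
            f"gradient design is rank-deficient (rank {rank} < 6): "
            "directions are degenerate (e.g. coplanar)"
        )
    shape = dwi.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    s0 = dwi.data[..., gtab.b0_mask].mean(axis=-1)[mask]        # (nvox,)
    s = dwi.data[..., gtab.dwi_mask][mask]                      # (nvox, n_dwi)
    if np.any(s0 <= 0):
        raise FitError("nonpositive S0 inside mask")
    s = np.maximum(s, SIGNAL_FLOOR * s0[:, None])
    y = -np.log(s / s0[:, None])                                # (nvox, n_dwi)
    coeffs, *_ = np.linalg.lstsq(a, y.T, rcond=None)            # (6, nvox)
    data = np.zeros(shape + (6,))
    data[mask] = coeffs.T
    return TensorField(data, dwi.voxel_size, dwi.affine)


@dataclass
class EigenSystem:
    """Per-voxel eigendecomposition, eigenvalues sorted descending.

    ``eigenvectors[..., :, i]`` is the unit eigenvector of
    ``eigenvalues[..., i]``; column 0 is the principal direction.
    """

    eigenvalues: np.ndarray   # (X, Y, Z, 3), lambda1 >= lambda2 >= lambda3
    eigenvectors: np.ndarray  # (X, Y, Z, 3, 3), columns are eigenvectors

    @property
    def principal(self) -> np.ndarray:
        """(X, Y, Z, 3) principal diffusion direction per voxel."""
        return self.eigenvectors[..., :, 0]


def eigensystem(field: TensorField) -> EigenSystem:
    """Eigendecompose every tensor; negative eigenvalues are clamped to 0.

    Clamping (rather than rejecting) mirrors common DTI tools and keeps the
    downstream index computable on noisy fits; the number of clamped values
    is reported through the module logger.
    """
    vals, vecs = np.linalg.eigh(field.to_matrices())  # ascending
    vals = vals[..., ::-1]
    vecs = vecs[..., ::-1]
    n_neg = int((vals < 0).sum())
    if n_neg:
        logger.info("clamped %d negative eigenvalues to 0", n_neg)
        vals = np.clip(vals, 0.0, None)
    return EigenSystem(vals, vecs)


def fractional_anisotropy(eigs: EigenSystem) -> np.ndarray:
    """FA map: ``sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||``.

    Zero tensors (0/0) are assigned FA = 0. Values lie in [0, 1]: 0 for an
    isotropic tensor, 1 in the single-stick limit.
    """
    lam = eigs.eigenvalues
    dev = lam - lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(1.5) * np.linalg.norm(dev, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    fa = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return np.clip(fa, 0.0, 1.0)


def color_fa(eigs: EigenSystem, fa: np.ndarray) -> np.ndarray:
    """Directionally-encoded color map, shape (X, Y, Z, 3) in [0, 1].

    Channel c is FA-weighted |e1 . axis_c| with the standard convention
    red = x, green = y, blue = z: in the phantom the subcortical tract
    renders red, the association tract green, the projection tract blue.
    """
    rgb = fa[..., None] * np.abs(eigs.principal)
    return np.clip(rgb, 0.0, 1.0)
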