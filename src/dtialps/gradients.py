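"""Diffusion gradient schemes.

A :class:`GradientTable` pairs b-values (s/mm^2) with unit gradient
directions, mirroring the FSL ``bval``/``bvec`` convention: b = 0 entries
carry a zero vector, all other vectors have unit norm.

Directions are generated by a deterministic Fibonacci spiral on the upper
half-sphere (antipodal directions are equivalent in diffusion MRI), then
rotated by a seeded uniform random rotation so that different seeds give
different — but individually reproducible — schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSchemeError

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class GradientTable:
    """Acquisition scheme: b-values and unit gradient directions.

    Parameters
    ----------
    bvals : (n,) array of b-values in s/mm^2.
    bvecs : (n, 3) array of gradient directions; zero vectors are permitted
        only where the b-value is zero, all others must be unit norm.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).reshape(-1)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise InvalidSchemeError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise InvalidSchemeError(
                f"{bvals.shape[0]} b-values but {bvecs.shape[0]} directions"
            )
        if np.any(bvals < 0):
            raise InvalidSchemeError("negative b-value")
        norms = np.linalg.norm(bvecs, axis=1)
        b0 = bvals == 0
        if np.any(np.abs(norms[~b0] - 1.0) > _UNIT_TOL):
            raise InvalidSchemeError(
                "non-b0 gradient vectors must be unit norm (within 1e-6)"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        """Boolean mask selecting the b = 0 entries."""
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        """Boolean mask selecting the diffusion-weighted (b > 0) entries."""
        return self.bvals > 0


def _fibonacci_half_sphere(n: int) -> np.ndarray:
    """n points approximately uniform on the z >= 0 half-sphere."""
    i = np.arange(n)
    z = (i + 0.5) / n                      # in (0, 1): strictly upper half
    r = np.sqrt(1.0 - z * z)
    golden = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    phi = golden * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def build_gradient_table(
    n_directions: int = 30,
    b: float = 1000.0,
    n_b0: int = 1,
    seed: int = 0,
) -> GradientTable:
    """Build a single-shell scheme: ``n_b0`` b = 0 entries followed by
    ``n_directions`` unit vectors at b-value ``b``.

    The default (30 directions at b = 1000 s/mm^2, one b = 0) matches a
    standard clinical single-shot EPI DTI protocol. Deterministic for a
    given seed.

    Raises
    ------
    InvalidSchemeError
        If fewer than 6 directions are requested (the symmetric tensor has
        6 free parameters).
    """
    if n_directions < 6:
        raise InvalidSchemeError(
            f"{n_directions} directions cannot determine a 6-parameter tensor; "
            "need at least 6"
        )
    if n_b0 < 0:
        raise InvalidSchemeError("n_b0 must be >= 0")
    if b <= 0:
        raise InvalidSchemeError("b must be > 0 for the weighted shell")
    dirs = _fibonacci_half_sphere(n_directions)
    rot = _random_rotation(np.random.default_rng(seed))
    dirs = dirs @ rot.T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals, bvecs)
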