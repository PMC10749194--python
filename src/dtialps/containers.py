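"""Voxel-grid containers shared across the simulation and fitting stages.

Tensor components are stored in the 6-vector order
(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz), units mm^2/s, with the image axes
x = right-left, y = anterior-posterior, z = inferior-superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientTable

#: component order of the last axis of TensorField.data
TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")

# index pairs of each component in the 3x3 matrix
_COMP_IJ = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


def _default_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    """RAS-positive scaling affine for an image with the given voxel size."""
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


@dataclass
class TensorField:
    """Grid of symmetric diffusion tensors.

    Attributes
    ----------
    data : (X, Y, Z, 6) array in :data:`TENSOR_COMPONENTS` order, mm^2/s.
    voxel_size : (3,) voxel edge lengths in mm.
    affine : 4x4 voxel-to-world matrix (RAS); defaults to a pure scaling.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 6:
            raise ValueError(f"tensor data must be (X, Y, Z, 6), got {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def to_matrices(self) -> np.ndarray:
        """Expand to full symmetric matrices, shape (X, Y, Z, 3, 3)."""
        m = np.zeros(self.data.shape[:3] + (3, 3))
        for c, (i, j) in enumerate(_COMP_IJ):
            m[..., i, j] = self.data[..., c]
            m[..., j, i] = self.data[..., c]
        return m

    @classmethod
    def from_matrices(
        cls,
        matrices: np.ndarray,
        voxel_size: tuple[float, float, float],
        affine: np.ndarray | None = None,
    ) -> "TensorField":
        """Pack symmetric (X, Y, Z, 3, 3) matrices into 6-component storage."""
        matrices = np.asarray(matrices, dtype=float)
        data = np.stack([matrices[..., i, j] for i, j in _COMP_IJ], axis=-1)
        return cls(data, voxel_size, affine)


@dataclass
class DWIVolume:
    """4-D diffusion-weighted signal: one 3-D volume per gradient entry.

    ``data[..., i]`` is the signal for ``gtab.bvals[i]`` / ``gtab.bvecs[i]``.
    """

    data: np.ndarray
    gtab: GradientTable
    voxel_size: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"DWI data must be 4-D, got shape {self.data.shape}")
        if self.data.shape[-1] != len(self.gtab):
            raise ValueError(
                f"{self.data.shape[-1]} volumes but {len(self.gtab)} gradient entries"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]
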