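"""The shared spatial frame of all maps: mask, world coordinates and
hemisphere labels.

Hemisphere membership follows the RAS convention of the NIfTI affine:
world x < 0 is the left hemisphere, x > 0 the right, and voxels lying
exactly on the mid-sagittal plane (x = 0, within a small numerical
tolerance to absorb affine round-off) are labelled midline.  Midline
voxels belong to neither hemisphere, so a connection touching one is
never contralateral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import InputError

#: Integer hemisphere codes used throughout the package.
LEFT, MIDLINE, RIGHT = -1, 0, 1

#: |world x| below this (mm) counts as the mid-sagittal plane.
MIDLINE_TOL_MM = 1e-6


@dataclass
class VoxelGrid:
    """Gray-matter mask plus the left/right geometry of the grid.

    Parameters
    ----------
    mask
        3D boolean array marking gray-matter voxels.
    affine
        4x4 voxel-index -> world-mm mapping (RAS orientation assumed for
        the x axis).

    Attributes
    ----------
    world_x
        Per-voxel world x coordinate in mm (3D float array).
    hemisphere
        Per-voxel code: -1 left, 0 midline, +1 right (3D int8 array).
    """

    mask: np.ndarray
    affine: np.ndarray
    world_x: np.ndarray = field(init=False)
    hemisphere: np.ndarray = field(init=False)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask.ndim != 3:
            raise InputError(f"mask must be 3D, got shape {self.mask.shape}")
        if self.affine.shape != (4, 4):
            raise InputError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise InputError("affine is singular")
        ii = np.arange(self.mask.shape[0], dtype=float)
        # world x depends only on the voxel index through the affine rows;
        # evaluate on the full index grid once.
        i, j, k = np.meshgrid(
            ii,
            np.arange(self.mask.shape[1], dtype=float),
            np.arange(self.mask.shape[2], dtype=float),
            indexing="ij",
        )
        a = self.affine
        self.world_x = a[0, 0] * i + a[0, 1] * j + a[0, 2] * k + a[0, 3]
        hemi = np.sign(self.world_x).astype(np.int8)
        hemi[np.abs(self.world_x) < MIDLINE_TOL_MM] = MIDLINE
        self.hemisphere = hemi

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        """Number of gray-matter voxels (the N of the degree formulas)."""
        return int(self.mask.sum())

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        """Per-axis voxel edge length in mm, from the affine column norms."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def masked_hemisphere(self) -> np.ndarray:
        """Hemisphere codes of the masked voxels, in C-order of the mask."""
        return self.hemisphere[self.mask]

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to world mm coordinates."""
        ijk = np.atleast_2d(ijk)
        homog = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ homog.T).T[:, :3]

    def hemisphere_counts(self) -> dict[str, int]:
        h = self.masked_hemisphere()
        return {
            "L": int((h == LEFT).sum()),
            "M": int((h == MIDLINE).sum()),
            "R": int((h == RIGHT).sum()),
        }

    # ------------------------------------------------------------------ I/O

    def save(self, mask_path, hemisphere_path=None) -> None:
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), self.affine), str(mask_path))
        if hemisphere_path is not None:
            nib.save(
                nib.Nifti1Image(self.hemisphere.astype(np.int8), self.affine),
                str(hemisphere_path),
            )

    @classmethod
    def load(cls, mask_path) -> "VoxelGrid":
        img = nib.load(str(mask_path))
        return cls(mask=np.asarray(img.dataobj) > 0, affine=img.affine)
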