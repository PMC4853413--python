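"""In-memory containers for one subject's data and results, with NIfTI/TSV I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InputError


@dataclass
class TimeSeriesVolume:
    """One subject's 4D BOLD data.

    ``data`` is (x, y, z, t); ``tr_s`` is the repetition time in seconds;
    ``affine`` maps voxel indices to world mm.
    """

    data: np.ndarray
    tr_s: float
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise InputError(f"expected 4D data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise InputError("time dimension must be >= 2")
        if not self.tr_s > 0:
            raise InputError("tr_s must be positive")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise InputError("affine must be an invertible 4x4 matrix")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def masked_series(self, mask: np.ndarray) -> np.ndarray:
        """Return the (timepoints, n_masked) matrix of voxel series.

        Columns follow the C-order of the mask's True voxels, matching
        ``np.flatnonzero(mask)``.
        """
        return self.data[mask].T.copy()

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], self.tr_s))
        nib.save(img, str(path))

    @classmethod
    def load(cls, path, tr_s: float | None = None) -> "TimeSeriesVolume":
        img = nib.load(str(path))
        if tr_s is None:
            zooms = img.header.get_zooms()
            if len(zooms) < 4 or zooms[3] <= 0:
                raise InputError(
                    f"{path}: repetition time not stored in header; pass tr_s"
                )
            tr_s = float(zooms[3])
        return cls(np.asarray(img.dataobj, dtype=float), tr_s, img.affine)


@dataclass
class NuisanceSet:
    """Nuisance regressors for one subject: a (timepoints, k) table.

    Typical columns are head-motion parameters and the white-matter,
    cerebrospinal-fluid and global mean signals.
    """

    table: pd.DataFrame

    def __post_init__(self):
        if not isinstance(self.table, pd.DataFrame):
            self.table = pd.DataFrame(np.asarray(self.table, dtype=float))
            self.table.columns = [f"reg_{i}" for i in range(self.table.shape[1])]
        flat = (self.table == 0).all(axis=0)
        if flat.any():
            raise InputError(
                "constant-zero nuisance regressor(s): "
                + ", ".join(map(str, self.table.columns[flat]))
            )

    @property
    def values(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)

    @property
    def names(self) -> list[str]:
        return list(map(str, self.table.columns))

    def __len__(self) -> int:
        return len(self.table)

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "NuisanceSet":
        return cls(pd.read_csv(path, sep="\t"))


#: map short measure names to FCDMaps attributes
MEASURE_ATTRS = {
    "gfcd": ("g_raw", "g_norm"),
    "cfcd": ("c_raw", "c_norm"),
    "ifcd": ("i_raw", "i_norm"),
}


@dataclass
class FCDMaps:
    """Raw and normalized degree maps for one subject.

    Raw maps count connected voxels (integers); normalized maps are the
    raw maps divided by the subject's mask-mean global count ``mean_g``,
    so the mask mean of ``g_norm`` is one.
    """

    g_raw: np.ndarray
    c_raw: np.ndarray
    i_raw: np.ndarray
    g_norm: np.ndarray
    c_norm: np.ndarray
    i_norm: np.ndarray
    mean_g: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def get(self, measure: str, kind: str = "norm") -> np.ndarray:
        """Return one map; ``measure`` in {gfcd, cfcd, ifcd}, ``kind`` raw|norm."""
        try:
            raw_attr, norm_attr = MEASURE_ATTRS[measure.lower()]
        except KeyError:
            raise KeyError(f"unknown measure {measure!r}; expected gfcd|cfcd|ifcd")
        return getattr(self, raw_attr if kind == "raw" else norm_attr)

    def save(self, prefix) -> list[str]:
        """Write the six maps as ``<prefix><measure>_<kind>.nii.gz``."""
        written = []
        for measure, (raw_attr, norm_attr) in MEASURE_ATTRS.items():
            for kind, attr in (("raw", raw_attr), ("norm", norm_attr)):
                path = f"{prefix}{measure}_{kind}.nii.gz"
                arr = getattr(self, attr).astype(np.float32)
                nib.save(nib.Nifti1Image(arr, self.affine), path)
                written.append(path)
        return written
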