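"""Functional connectivity density (FCD) mapping.

For each gray-matter voxel i, count the other voxels j whose time-series
Pearson correlation exceeds a threshold (0.6 by default, strict ">"):

    global  FCD_i = #{ j != i : r_ij > threshold }            (degree)
    contra  FCD_i = the subset with j in the opposite hemisphere
    ipsi    FCD_i = global FCD_i - contra FCD_i

The three raw counts are then normalized by the subject's mask-mean
global count, so the mask mean of normalized gFCD is one and subjects
with different overall connectivity levels become comparable.

A pair is *contralateral* only when the two voxels carry strictly
opposite hemisphere labels {L, R}; midline voxels (world x = 0)
contribute ipsilaterally only.  Negative correlations never connect
(the threshold condition is one-sided).

The pairwise pass is computed blockwise over the (upper-triangular)
block decomposition of the correlation matrix, so the full N x N matrix
is never materialized, but the counts are identical to an exhaustive
double loop over all pairs and invariant to the block size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import FCDMaps, TimeSeriesVolume
from .errors import (
    ConfigurationError,
    InputError,
    InternalConsistencyError,
    ZeroVarianceError,
)
from .grids import VoxelGrid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationThresholdRule:
    """Binarization rule: voxels i, j are connected iff r_ij > threshold."""

    threshold: float = 0.6

    def __post_init__(self):
        if not 0 < self.threshold < 1:
            raise ConfigurationError("threshold must lie strictly in (0, 1)")


def correlation_degree(
    data: np.ndarray,
    hemisphere: np.ndarray,
    rule: CorrelationThresholdRule = CorrelationThresholdRule(),
    block_size: int = 1024,
) -> tuple[np.ndarray, np.ndarray]:
    """Global and contralateral degree of every column of ``data``.

    Parameters
    ----------
    data
        (timepoints, N) matrix of masked voxel series; every column must
        have nonzero variance.
    hemisphere
        length-N codes: -1 left, 0 midline, +1 right.

    Returns
    -------
    (g_raw, c_raw)
        Integer arrays of length N: the number of other voxels whose
        correlation with this one exceeds the threshold, and the subset
        in the opposite hemisphere.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise InputError("data must be (timepoints, N) with N >= 2")
    hemisphere = np.asarray(hemisphere)
    if hemisphere.shape != (data.shape[1],):
        raise InputError("hemisphere labels must match the number of columns")

    centered = data - data.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    flat = np.flatnonzero(norms == 0)
    if flat.size:
        raise ZeroVarianceError(flat)
    z = centered / norms  # r_ij is now the plain dot product z_i . z_j

    n = data.shape[1]
    g_raw = np.zeros(n, dtype=np.int64)
    c_raw = np.zeros(n, dtype=np.int64)
    starts = range(0, n, block_size)
    for a in starts:
        ia = slice(a, min(a + block_size, n))
        ha = hemisphere[ia]
        for b in range(a, n, block_size):
            jb = slice(b, min(b + block_size, n))
            corr = z[:, ia].T @ z[:, jb]
            adj = corr > rule.threshold
            if a == b:
                np.fill_diagonal(adj, False)
            # strictly opposite labels <=> product of codes is -1
            contra = adj & (ha[:, None] * hemisphere[jb][None, :] == -1)
            g_raw[ia] += adj.sum(axis=1)
            c_raw[ia] += contra.sum(axis=1)
            if b > a:  # mirror contribution of the off-diagonal block
                g_raw[jb] += adj.sum(axis=0)
                c_raw[jb] += contra.sum(axis=0)
    return g_raw, c_raw


def decompose(g_raw: np.ndarray, c_raw: np.ndarray) -> np.ndarray:
    """Ipsilateral degree: global minus contralateral, elementwise."""
    g_raw = np.asarray(g_raw)
    c_raw = np.asarray(c_raw)
    if (c_raw > g_raw).any():
        raise InternalConsistencyError(
            "contralateral count exceeds global count at "
            f"{int((c_raw > g_raw).sum())} voxel(s)"
        )
    return g_raw - c_raw


def normalize_fcd(
    g_raw: np.ndarray, c_raw: np.ndarray, i_raw: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Divide the three raw maps by the mask mean of the global map.

    Returns (g_norm, c_norm, i_norm, mean_g).  After normalization the
    mask mean of g_norm is exactly one.
    """
    mask = np.asarray(mask, dtype=bool)
    mean_g = float(np.asarray(g_raw, dtype=float)[mask].mean())
    if mean_g == 0:
        raise InputError(
            "mean global FCD is zero — no connections anywhere; check the "
            "threshold and the data"
        )
    out = tuple(np.asarray(m, dtype=float) / mean_g for m in (g_raw, c_raw, i_raw))
    return (*out, mean_g)


def fcd_maps_for_subject(
    vol: TimeSeriesVolume,
    grid: VoxelGrid,
    rule: CorrelationThresholdRule = CorrelationThresholdRule(),
    block_size: int = 1024,
) -> FCDMaps:
    """Compute all six FCD maps (raw and normalized g/c/i) for one subject.

    Zero-variance voxels are dropped from the working mask with a logged
    warning rather than raising; voxels outside the (working) mask get 0
    in every map.
    """
    if vol.shape3d != grid.shape:
        raise InputError(f"volume grid {vol.shape3d} != mask grid {grid.shape}")
    mask = grid.mask.copy()
    series = vol.masked_series(mask)
    variable = series.std(axis=0) > 0
    if not variable.all():
        n_drop = int((~variable).sum())
        logger.warning(
            "dropping %d zero-variance voxel(s) from the working mask", n_drop
        )
        flat_idx = np.flatnonzero(mask)[~variable]
        mask.flat[flat_idx] = False
        series = series[:, variable]
    if series.shape[1] < 2:
        raise InputError("fewer than 2 usable voxels in the mask")

    g, c = correlation_degree(series, grid.hemisphere[mask], rule, block_size)
    i = decompose(g, c)

    def to_volume(values, dtype):
        out = np.zeros(grid.shape, dtype=dtype)
        out[mask] = values
        return out

    g_raw = to_volume(g, np.int32)
    c_raw = to_volume(c, np.int32)
    i_raw = to_volume(i, np.int32)
    g_norm, c_norm, i_norm, mean_g = normalize_fcd(g_raw, c_raw, i_raw, mask)
    return FCDMaps(g_raw, c_raw, i_raw, g_norm, c_norm, i_norm, mean_g, grid.affine)
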