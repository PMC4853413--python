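"""Temporal cleaning of BOLD series before connectivity mapping.

Stages, applied in this order to every gray-matter voxel:

1. linear detrending (removes the slow scanner drift and the mean),
2. nuisance regression (head motion, white matter, CSF, global signal),
3. band-pass filtering to the resting-state band, 0.01-0.08 Hz.

Optional spatial Gaussian smoothing (default 8 mm FWHM when enabled) runs
before the temporal stages.  Detrending and nuisance regression are OLS
projections; the band-pass is an ideal (rectangular) filter in the
discrete Fourier domain with inclusive band edges, which makes it exactly
idempotent.  All three temporal stages are linear and non-expansive: they
can only remove energy from a series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import NuisanceSet, TimeSeriesVolume
from .errors import ConfigurationError, InputError, RankDeficiencyError

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _as_matrix(ts: np.ndarray) -> tuple[np.ndarray, bool]:
    """Promote a 1D series to an (T, 1) column; remember to squeeze back."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim == 1:
        return ts[:, None], True
    if ts.ndim != 2:
        raise InputError(f"expected 1D or (timepoints, n) series, got {ts.shape}")
    return ts, False


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residual of each column of y on the design matrix."""
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def detrend_linear(ts: np.ndarray) -> np.ndarray:
    """Remove the best-fitting intercept + linear ramp from each series.

    The residual is zero-mean and orthogonal to the ramp.  Accepts a 1D
    series or a (timepoints, n) matrix.
    """
    y, squeeze = _as_matrix(ts)
    T = y.shape[0]
    if T < 3:
        raise InputError("detrending needs at least 3 timepoints")
    design = np.column_stack([np.ones(T), np.arange(T, dtype=float)])
    out = _residualize(y, design)
    return out[:, 0] if squeeze else out


def regress_nuisance(ts: np.ndarray, nuisance: NuisanceSet) -> np.ndarray:
    """OLS residual of each series on {intercept} ∪ nuisance regressors."""
    y, squeeze = _as_matrix(ts)
    X = nuisance.values
    if X.shape[0] != y.shape[0]:
        raise InputError(
            f"nuisance rows ({X.shape[0]}) != series length ({y.shape[0]})"
        )
    design = np.column_stack([np.ones(y.shape[0]), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns explainable by the others to name the culprits
        bad = []
        for col, name in enumerate(nuisance.names, start=1):
            others = np.delete(design, col, axis=1)
            resid = design[:, col] - others @ np.linalg.lstsq(others, design[:, col], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(design[:, col]), 1.0):
                bad.append(name)
        raise RankDeficiencyError(bad or nuisance.names)
    out = _residualize(y, design)
    return out[:, 0] if squeeze else out


def bandpass(
    ts: np.ndarray, tr_s: float, f_lo: float = 0.01, f_hi: float = 0.08
) -> np.ndarray:
    """Ideal band-pass filter in the DFT domain.

    Frequency components with f_lo <= f <= f_hi (inclusive, so a bin
    exactly on an edge is kept) are retained; all others, including DC,
    are zeroed.  Applied along axis 0.
    """
    y, squeeze = _as_matrix(ts)
    if not 0 <= f_lo < f_hi:
        raise ConfigurationError("need 0 <= f_lo < f_hi")
    nyquist = 1.0 / (2.0 * tr_s)
    if f_hi >= nyquist:
        raise ConfigurationError(
            f"f_hi = {f_hi} Hz is at or above Nyquist = {nyquist} Hz for TR {tr_s} s"
        )
    T = y.shape[0]
    freqs = np.fft.rfftfreq(T, d=tr_s)
    keep = (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)
    spec = np.fft.rfft(y, axis=0)
    spec[~keep] = 0.0
    out = np.fft.irfft(spec, n=T, axis=0)
    return out[:, 0] if squeeze else out


def smooth_gaussian(vol: TimeSeriesVolume, fwhm_mm: float = 8.0) -> TimeSeriesVolume:
    """Per-timepoint 3D Gaussian smoothing with the given FWHM in mm.

    The kernel width is converted from mm to voxels per axis using the
    affine's column norms; boundaries are handled by reflection.  FWHM 0
    is the identity.
    """
    if fwhm_mm < 0:
        raise ConfigurationError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return vol
    voxel_sizes = np.sqrt((vol.affine[:3, :3] ** 2).sum(axis=0))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_sizes
    out = ndimage.gaussian_filter(
        vol.data, sigma=(*sigma_vox, 0.0), mode="reflect"
    )
    return TimeSeriesVolume(out, vol.tr_s, vol.affine)


@dataclass
class PreprocessOptions:
    """Which stages to run.  Defaults reproduce the standard pipeline:
    no smoothing (phantoms are unsmoothed by construction), detrend,
    nuisance regression, band-pass 0.01-0.08 Hz."""

    fwhm_mm: float | None = None  # None disables smoothing
    detrend: bool = True
    regress: bool = True
    bandpass: bool = True
    f_lo: float = 0.01
    f_hi: float = 0.08


def preprocess_subject(
    vol: TimeSeriesVolume,
    nuisance: NuisanceSet | None,
    mask: np.ndarray,
    options: PreprocessOptions | None = None,
) -> TimeSeriesVolume:
    """Run the enabled stages on every masked voxel's series.

    Smoothing (if enabled) is applied to the whole volume first; the
    temporal stages then run on masked voxels only, in the fixed order
    detrend -> nuisance regression -> band-pass.  Voxels outside the mask
    pass through untouched (apart from smoothing).
    """
    options = options or PreprocessOptions()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape3d:
        raise InputError(f"mask shape {mask.shape} != volume grid {vol.shape3d}")
    if options.regress and nuisance is not None and len(nuisance) != vol.n_timepoints:
        raise InputError("nuisance table length != number of timepoints")

    if options.fwhm_mm is not None:
        vol = smooth_gaussian(vol, options.fwhm_mm)

    series = vol.masked_series(mask)  # (T, n_masked)
    if options.detrend:
        series = detrend_linear(series)
    if options.regress and nuisance is not None:
        series = regress_nuisance(series, nuisance)
    if options.bandpass:
        series = bandpass(series, vol.tr_s, options.f_lo, options.f_hi)

    data = vol.data.copy()
    data[mask] = series.T
    return TimeSeriesVolume(data, vol.tr_s, vol.affine)
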