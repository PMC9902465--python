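"""Voxel-wise activity measures: ALFF, fALFF, ReHo, and their surround steps.

ALFF is the mean amplitude (square root of periodogram power) over the
0.01-0.1 Hz band; fALFF divides the in-band amplitude sum by the amplitude
sum over all positive frequencies up to Nyquist; ReHo is Kendall's
coefficient of concordance (KCC) of a voxel's time series with its in-mask
neighbors (27-voxel cube by default).  Band-pass filtering is an ideal
frequency-domain mask, smoothing a mask-aware Gaussian kernel, and nuisance
regression ordinary least squares with intercept and linear trend always
included.

The study protocol orders these as: nuisance regression, then spatial
smoothing (skipped for ReHo), then band-pass (skipped for fALFF, which needs
the full spectrum), then the measure; ``voxel_measure_pipeline`` enforces
that ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class VoxelSeries:
    """4D voxel data (X x Y x Z x T) with a binary brain mask."""

    data: np.ndarray
    tr_seconds: float
    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("voxel data must be 4D (X, Y, Z, T)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must equal the spatial shape")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("masked voxels must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_seconds


@dataclass
class VoxelMap:
    """3D map of one measure on a mask."""

    values: np.ndarray
    mask: np.ndarray
    measure_tag: str
    units: str = "arbitrary"
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("map must be finite within the mask")


def _band_bins(n_t: int, tr: float, low: float, high: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_t, d=tr)
    return (freqs >= low) & (freqs <= high)


def bandpass(series, low_hz: float, high_hz: float):
    """Ideal frequency-domain band-pass; removes the mean (DC bin).

    Accepts a :class:`VoxelSeries` (filters along the last axis) or a
    :class:`~brainfc.connectivity.RoiTimeSeries` (filters along time, axis 0).
    """
    from brainfc.connectivity import RoiTimeSeries

    if isinstance(series, VoxelSeries):
        nyq = series.nyquist_hz
        tr = series.tr_seconds
        axis = -1
        x = series.data
    elif isinstance(series, RoiTimeSeries):
        nyq = 0.5 / series.tr_seconds
        tr = series.tr_seconds
        axis = 0
        x = series.data
    else:
        raise TypeError("bandpass expects VoxelSeries or RoiTimeSeries")
    if not (0 <= low_hz < high_hz <= nyq + 1e-12):
        raise ValueError(
            f"band must satisfy 0 <= low < high <= Nyquist ({nyq:.4g} Hz at "
            f"TR={tr} s)"
        )
    n_t = x.shape[axis]
    spec = np.fft.rfft(x, axis=axis)
    keep = _band_bins(n_t, tr, low_hz, high_hz)
    keep[0] = False  # always remove DC (demean)
    shape = [1] * x.ndim
    shape[axis] = keep.size
    out = np.fft.irfft(spec * keep.reshape(shape), n=n_t, axis=axis)
    if isinstance(series, VoxelSeries):
        return VoxelSeries(out, series.tr_seconds, series.mask, series.voxel_size_mm)
    return RoiTimeSeries(out, list(series.roi_labels), series.tr_seconds, series.subject_id)


def _amplitude_spectrum(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Single-taper amplitude spectrum: sqrt of the periodogram per bin."""
    n_t = x.shape[axis]
    xd = x - x.mean(axis=axis, keepdims=True)
    spec = np.fft.rfft(xd, axis=axis)
    # periodogram power |F|^2 / T; amplitude = sqrt(power)
    return np.abs(spec) / np.sqrt(n_t)


def alff(series: VoxelSeries, band: tuple[float, float] = (0.01, 0.1)) -> VoxelMap:
    """Mean low-frequency amplitude per voxel over the given band."""
    if series.n_timepoints < 8:
        raise ValueError("ALFF needs at least 8 timepoints")
    keep = _band_bins(series.n_timepoints, series.tr_seconds, *band)
    keep[0] = False
    if not keep.any():
        raise ValueError("frequency band is empty after discretization")
    amp = _amplitude_spectrum(series.data)
    vals = amp[..., keep].mean(axis=-1)
    vals[~series.mask] = 0.0
    return VoxelMap(vals, series.mask, "ALFF", units="amplitude")


def falff(series: VoxelSeries, band: tuple[float, float] = (0.01, 0.1)) -> VoxelMap:
    """Fractional ALFF: in-band amplitude sum over full-range amplitude sum.

    Computed on unfiltered data (the band-pass step is skipped for this
    measure) so the denominator covers all positive frequencies up to
    Nyquist, DC excluded.  Flat voxels get 0 with a warning flag.
    """
    if series.n_timepoints < 8:
        raise ValueError("fALFF needs at least 8 timepoints")
    keep = _band_bins(series.n_timepoints, series.tr_seconds, *band)
    keep[0] = False
    if not keep.any():
        raise ValueError("frequency band is empty after discretization")
    amp = _amplitude_spectrum(series.data)
    num = amp[..., keep].sum(axis=-1)
    den = amp[..., 1:].sum(axis=-1)
    flat = den == 0
    flags = {}
    if (flat & series.mask).any():
        warnings.warn("flat voxel(s) inside mask: fALFF set to 0", stacklevel=2)
        flags["flat_voxels"] = int((flat & series.mask).sum())
    vals = np.where(flat, 0.0, num / np.where(flat, 1.0, den))
    vals[~series.mask] = 0.0
    return VoxelMap(vals, series.mask, "fALFF", units="fraction", flags=flags)


def kendall_w(series_stack: np.ndarray) -> float:
    """Kendall's coefficient of concordance for an n x T stack of series.

    Ranks each series over time (average ranks on ties) and measures the
    agreement of the n rankings; 1 = identical orderings, 0 = no agreement.
    """
    n, t = series_stack.shape
    ranks = np.vstack([rankdata(row) for row in series_stack])
    r_sum = ranks.sum(axis=0)
    s = ((r_sum - r_sum.mean()) ** 2).sum()
    denom = n**2 * (t**3 - t) / 12.0
    if denom == 0:
        return 0.0
    return float(min(s / denom, 1.0))


_NEIGHBORHOOD_OFFSETS = {
    7: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) <= 1],
    19: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if abs(dx) + abs(dy) + abs(dz) <= 2],
    27: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)],
}


def reho(series: VoxelSeries, neighborhood: int = 27) -> VoxelMap:
    """Regional homogeneity: KCC of each voxel with its in-mask neighbors.

    Boundary voxels use whatever neighbors fall inside the mask; a voxel with
    fewer than 2 in-mask series gets 0 and is counted in ``flags``.
    Input should be band-passed but *not* smoothed.
    """
    if neighborhood not in _NEIGHBORHOOD_OFFSETS:
        raise ValueError("neighborhood must be one of 7, 19, 27")
    offsets = _NEIGHBORHOOD_OFFSETS[neighborhood]
    shape = series.data.shape[:3]
    vals = np.zeros(shape)
    isolated = 0
    for idx in np.argwhere(series.mask):
        x, y, z = idx
        stack = []
        for dx, dy, dz in offsets:
            xx, yy, zz = x + dx, y + dy, z + dz
            if 0 <= xx < shape[0] and 0 <= yy < shape[1] and 0 <= zz < shape[2] \
                    and series.mask[xx, yy, zz]:
                stack.append(series.data[xx, yy, zz])
        if len(stack) < 2:
            isolated += 1
            continue
        vals[x, y, z] = kendall_w(np.asarray(stack))
    flags = {"isolated_voxels": isolated} if isolated else {}
    return VoxelMap(vals, series.mask, "ReHo", units="concordance", flags=flags)


def smooth(obj, fwhm_mm: float):
    """Mask-aware Gaussian smoothing with the given FWHM in millimetres.

    Convolves data and mask separately and divides, so edge voxels are
    renormalized rather than diluted by out-of-mask zeros.  Works on a
    :class:`VoxelMap` or (frame-wise) a :class:`VoxelSeries`.
    """
    if fwhm_mm == 0:
        return obj
    if isinstance(obj, VoxelMap):
        vox = (3.0, 3.0, 3.0)
        data = obj.values[..., None]
        mask = obj.mask
    elif isinstance(obj, VoxelSeries):
        vox = obj.voxel_size_mm
        data = obj.data
        mask = obj.mask
    else:
        raise TypeError("smooth expects VoxelMap or VoxelSeries")
    sigma_vox = [fwhm_mm * _FWHM_TO_SIGMA / v for v in vox]
    m = mask.astype(float)
    norm = ndimage.gaussian_filter(m, sigma_vox)
    out = np.empty_like(data)
    for t in range(data.shape[3]):
        frame = data[..., t] * m
        sm = ndimage.gaussian_filter(frame, sigma_vox)
        out[..., t] = np.where(mask, sm / np.where(norm == 0, 1.0, norm), 0.0)
    if isinstance(obj, VoxelMap):
        return VoxelMap(out[..., 0], obj.mask, obj.measure_tag, obj.units, dict(obj.flags))
    return VoxelSeries(out, obj.tr_seconds, obj.mask, obj.voxel_size_mm)


def nuisance_regress(series, regressors: np.ndarray):
    """OLS residuals on [intercept, linear trend, regressors] per voxel/ROI.

    Rank-deficient regressor sets have their dependent columns dropped with a
    warning.  Residuals are orthogonal to every retained column.
    """
    from brainfc.connectivity import RoiTimeSeries

    if isinstance(series, VoxelSeries):
        t = series.n_timepoints
        y = series.data[series.mask].T  # T x V
    elif isinstance(series, RoiTimeSeries):
        t = series.n_timepoints
        y = series.data
    else:
        raise TypeError("nuisance_regress expects VoxelSeries or RoiTimeSeries")
    regressors = np.asarray(regressors, dtype=float)
    if regressors.ndim == 1:
        regressors = regressors[:, None]
    if regressors.size and regressors.shape[0] != t:
        raise ValueError("regressor matrix must have T rows")
    trend = np.linspace(-1, 1, t)
    design = np.column_stack([np.ones(t), trend] + (
        [regressors] if regressors.size else []))
    if design.shape[1] >= t:
        raise ValueError("more regressors than timepoints")
    q, r = np.linalg.qr(design)
    keep = np.abs(np.diag(r)) > 1e-10 * np.abs(r[0, 0])
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} linearly dependent regressor column(s)",
            stacklevel=2,
        )
        design = design[:, keep]
        q, _ = np.linalg.qr(design)
    resid = y - q @ (q.T @ y)
    if isinstance(series, VoxelSeries):
        out = np.zeros_like(series.data)
        out[series.mask] = resid.T
        return VoxelSeries(out, series.tr_seconds, series.mask, series.voxel_size_mm)
    return RoiTimeSeries(resid, list(series.roi_labels), series.tr_seconds, series.subject_id)


def voxel_measure_pipeline(
    series: VoxelSeries,
    measure: str,
    regressors: np.ndarray | None = None,
    fwhm_mm: float = 4.0,
    band: tuple[float, float] = (0.01, 0.1),
    neighborhood: int = 27,
) -> VoxelMap:
    """Nuisance regression -> smoothing (except ReHo) -> band-pass (except
    fALFF) -> measure, matching the study's preprocessing order."""
    if measure not in {"ALFF", "fALFF", "ReHo"}:
        raise ValueError("measure must be ALFF, fALFF or ReHo")
    s = series
    if regressors is not None:
        s = nuisance_regress(s, regressors)
    if measure != "ReHo":
        s = smooth(s, fwhm_mm)
    if measure != "fALFF":
        s = bandpass(s, *band)
    if measure == "ALFF":
        return alff(s, band)
    if measure == "fALFF":
        return falff(s, band)
    return reho(s, neighborhood)
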