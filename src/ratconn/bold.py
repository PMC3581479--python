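"""Resting-state BOLD preprocessing and functional connectivity.

Pipeline stages follow the conventional seed-based analysis: spatial
smoothing + linear-drift removal, nuisance regression (global mean, six
motion parameters, linear trend), band-pass filtering to the
low-frequency band (0.01-0.1 Hz), ROI time-series extraction, Fisher-z
correlation matrices and voxelwise seed maps, and averaging of homologous
left/right seed pairs into inter- and intra-hemispheric values.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import RoiAtlas

ATANH_CLIP = 1.0 - 1e-7


@dataclass
class BoldSeries:
    """Voxel- or ROI-organized BOLD signal with timing and nuisance set.

    ``data`` is (x, y, z, t) for voxel series or (n_roi, t) for ROI
    series. ``frame_times`` must be strictly increasing and uniformly
    spaced; nuisance regressors (columns of a DataFrame) share the time
    axis.
    """

    data: np.ndarray
    tr: float
    frame_times: np.ndarray | None = None
    nuisance: pd.DataFrame | None = None
    voxel_size: np.ndarray | None = None
    roi_ids: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n_t = self.data.shape[-1]
        if self.frame_times is None:
            self.frame_times = np.arange(n_t) * self.tr
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        dt = np.diff(self.frame_times)
        if dt.size and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("frame_times must be strictly increasing and uniform")
        if self.nuisance is not None and len(self.nuisance) != n_t:
            raise ValueError("nuisance regressors must match the time axis")
        if self.voxel_size is not None:
            self.voxel_size = np.broadcast_to(
                np.asarray(self.voxel_size, dtype=float), (3,)
            ).copy()

    @property
    def is_voxel(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]


@dataclass
class FCMatrix:
    """Symmetric ROI x ROI Fisher-z functional connectivity.

    The diagonal is NaN by convention (self-connectivity is not defined);
    rows/columns of constant series are NaN as well.
    """

    z: np.ndarray
    roi_ids: np.ndarray
    n_frames_used: int

    @property
    def r(self) -> np.ndarray:
        return np.tanh(self.z)

    def to_frame(self, names=None) -> pd.DataFrame:
        idx = names if names is not None else self.roi_ids
        return pd.DataFrame(self.z, index=idx, columns=idx)


def _detrend(data):
    """Remove per-series linear trend (least squares) along the last axis."""
    n = data.shape[-1]
    t = np.arange(n) - (n - 1) / 2
    t_norm = t / np.sqrt((t**2).sum())
    mean = data.mean(axis=-1, keepdims=True)
    slope = (data - mean) @ t_norm
    return data - mean - slope[..., None] * t_norm


def preprocess(series: BoldSeries, fwhm: float = 1.0) -> BoldSeries:
    """Gaussian spatial smoothing at the stated FWHM plus linear detrend.

    Smoothing applies only to voxel-organized series (ROI series are just
    detrended); ``fwhm`` is in mm, converted with sigma = FWHM / 2.3548.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    data = series.data
    if series.is_voxel and fwhm > 0:
        if series.voxel_size is None:
            raise ValueError("voxel smoothing requires voxel_size")
        sigma = (fwhm / 2.3548) / series.voxel_size
        data = ndimage.gaussian_filter(data, sigma=(*sigma, 0.0))
    return replace(series, data=_detrend(data))


def regress_nuisance(series: BoldSeries, include=None) -> BoldSeries:
    """OLS residuals after projecting out the nuisance regressors.

    The design holds an intercept plus the nuisance set (global mean, six
    motion traces, linear trend — 8 regressors by default). Collinear
    columns are dropped with a warning. ``include`` optionally restricts
    to a subset of nuisance columns (e.g. to toggle global-signal
    regression off).
    """
    if series.nuisance is None:
        raise ValueError("series has no nuisance regressor set")
    nui = series.nuisance if include is None else series.nuisance[list(include)]
    X = np.column_stack([np.ones(series.n_frames), nui.to_numpy()])
    # drop collinear columns by rank-revealing QR (pivoted via SVD threshold)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("nuisance matrix rank-deficient; dropping collinear columns")
        keep = []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
        X = X[:, keep]
    flat = series.data.reshape(-1, series.n_frames)
    beta, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
    resid = flat.T - X @ beta
    return replace(series, data=resid.T.reshape(series.data.shape))


def bandpass_data(data: np.ndarray, tr: float, low: float = 0.01,
                  high: float = 0.1) -> np.ndarray:
    """Zero-phase spectral band-pass along the last axis.

    Implemented by masking the real FFT outside [low, high] Hz (the
    convention of standard resting-state band-pass tools): exactly unit
    passband gain, complete stopband rejection, no phase shift. The DC
    bin is always removed.
    """
    fs = 1.0 / tr
    nyq = fs / 2
    if not (0 <= low < high):
        raise ValueError("need 0 <= low < high")
    if high > nyq + 1e-12:
        raise ValueError(f"high cutoff {high} Hz exceeds Nyquist {nyq} Hz")
    n = data.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= low) & (freqs <= high) & (freqs > 0)
    spec = np.fft.rfft(data, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def bandpass(series: BoldSeries, low: float = 0.01, high: float = 0.1) -> BoldSeries:
    """Band-pass every series to the low-frequency band (default 0.01-0.1 Hz)."""
    return replace(series, data=bandpass_data(series.data, series.tr, low, high))


def roi_timeseries(
    series: BoldSeries, atlas: RoiAtlas, min_voxels: int = 2, gray_only: bool = True
):
    """Mean time series per atlas ROI with small-ROI exclusion flags.

    ROIs spanning fewer than ``min_voxels`` voxels are flagged excluded
    (mirroring the exclusion of regions too small to identify reliably at
    the acquisition resolution).

    Returns
    -------
    (BoldSeries, pandas.DataFrame)
        ROI-organized series (rows ordered as the atlas table) and a
        table with ``label_id, name, n_voxels, included``.
    """
    if not series.is_voxel:
        raise ValueError("roi_timeseries needs a voxel-organized series")
    table = atlas.gray_table if gray_only else atlas.roi_table
    labels = atlas.label_volume
    sig = np.zeros((len(table), series.n_frames))
    rows = []
    for i, rec in enumerate(table.itertuples(index=False)):
        mask = labels == int(rec.label_id)
        n_vox = int(mask.sum())
        included = n_vox >= min_voxels
        if n_vox == 0:
            warnings.warn(f"ROI {rec.name!r} ({rec.label_id}) is empty; excluded")
        elif not included:
            warnings.warn(f"ROI {rec.name!r} spans {n_vox} voxel(s); excluded")
        if n_vox:
            sig[i] = series.data[mask].mean(axis=0)
        rows.append((rec.label_id, rec.name, n_vox, included))
    flags = pd.DataFrame(rows, columns=["label_id", "name", "n_voxels", "included"])
    out = BoldSeries(
        data=sig, tr=series.tr, frame_times=series.frame_times,
        nuisance=series.nuisance, roi_ids=table["label_id"].to_numpy(),
    )
    return out, flags


def _fisher_z(r):
    return np.arctanh(np.clip(r, -ATANH_CLIP, ATANH_CLIP))


def fc_matrix(roi_ts) -> FCMatrix:
    """Fisher-z Pearson correlation matrix among ROI time series.

    Accepts a ROI-organized :class:`BoldSeries` or a plain (n_roi, t)
    array. Constant series yield NaN rows/columns; |r| is clipped at
    1 - 1e-7 before atanh so degenerate inputs never produce infinities.
    The diagonal is NaN.
    """
    if isinstance(roi_ts, BoldSeries):
        data, roi_ids = roi_ts.data, roi_ts.roi_ids
    else:
        data, roi_ids = np.asarray(roi_ts, dtype=float), None
    if data.ndim != 2:
        raise ValueError("roi_ts must be 2-D (n_roi, n_frames)")
    n_roi, n_t = data.shape
    if n_t < 3:
        raise ValueError("need at least 3 frames")
    sd = data.std(axis=1)
    const = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    z = _fisher_z(r)
    z[const, :] = np.nan
    z[:, const] = np.nan
    np.fill_diagonal(z, np.nan)
    if roi_ids is None:
        roi_ids = np.arange(n_roi)
    return FCMatrix(z=z, roi_ids=np.asarray(roi_ids), n_frames_used=n_t)


def seed_map(series: BoldSeries, seed_signal) -> np.ndarray:
    """Voxelwise Fisher-z correlation map against a seed time series.

    Constant voxels map to NaN.
    """
    seed_sig = np.asarray(seed_signal, dtype=float)
    if seed_sig.shape[-1] != series.n_frames:
        raise ValueError("seed signal must share the series' time axis")
    flat = series.data.reshape(-1, series.n_frames)
    s = seed_sig - seed_sig.mean()
    x = flat - flat.mean(axis=1, keepdims=True)
    num = x @ s
    den = np.linalg.norm(x, axis=1) * np.linalg.norm(s)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    z = _fisher_z(r)
    z[den == 0] = np.nan
    return z.reshape(series.data.shape[:-1])


def average_homologous(fc: FCMatrix, atlas: RoiAtlas):
    """Average homologous left/right seeds into per-pair FC values.

    For ROI names A, B with left/right labels A_L, A_R, B_L, B_R:

    * intra-hemispheric value(A, B) = mean{ z(A_L, B_L), z(A_R, B_R) }
    * inter-hemispheric value(A, B) = mean{ z(A_L, B_R), z(A_R, B_L) }
    * inter-hemispheric homotopic value(A, A) = z(A_L, A_R)

    Missing (NaN) hemispheres make the corresponding averaged value NaN.

    Returns
    -------
    (pandas.DataFrame, pandas.DataFrame)
        intra- and inter-hemispheric matrices indexed by ROI name.
    """
    table = atlas.gray_table
    id_index = {int(lab): k for k, lab in enumerate(fc.roi_ids)}
    names = list(dict.fromkeys(table["name"]))
    left = {r.name: int(r.label_id) for r in table.itertuples(index=False)
            if r.hemisphere == "left"}
    right = {r.name: int(r.label_id) for r in table.itertuples(index=False)
             if r.hemisphere == "right"}
    n = len(names)
    intra = np.full((n, n), np.nan)
    inter = np.full((n, n), np.nan)

    def zval(li, lj):
        i, j = id_index.get(li), id_index.get(lj)
        if i is None or j is None:
            return np.nan
        return fc.z[i, j]

    for i, a in enumerate(names):
        inter[i, i] = zval(left[a], right[a])
        for j, b in enumerate(names):
            if i == j:
                continue
            intra[i, j] = np.mean([zval(left[a], left[b]), zval(right[a], right[b])])
            inter[i, j] = np.mean([zval(left[a], right[b]), zval(right[a], left[b])])
    return (pd.DataFrame(intra, index=names, columns=names),
            pd.DataFrame(inter, index=names, columns=names))
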