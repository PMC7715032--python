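"""Three-dimensional space-time correlation maps of spike rasters.

The pairwise statistic is the overlap-normalized cross-correlation of
1 ms binary spike trains,

    (x*y)[n] = 1/(sigma_x sigma_y) * 1/L(n) * sum_m (x[m]-mu_x)(y[m+n]-mu_y)

with mu and sigma computed over the full trains and L(n) = N - |n| the
overlap length at shift n (this is the only reading under which the
autocorrelation equals 1 at zero lag).  Pair correlations are averaged
into a 3D array indexed by the pair's longitudinal lag, transverse lag
(0.1 mm bins) and time lag (1 ms bins).  The global map averages every
pair; local maps admit only pairs with at least one member inside one
of the nine CA3 sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .geometry import SectionGrid
from .sources import BinnedSpikeMatrix, SpikeRaster, bin_spikes

__all__ = [
    "XcorrResult", "CorrelationMap", "DegenerateTrainError", "EmptyMapError",
    "normalized_xcorr", "accumulate_map", "local_map", "cross_section",
    "peak_correlation", "spatial_profile", "estimate_cluster_sd",
    "population_pattern_lag",
]


class DegenerateTrainError(ValueError):
    pass


class EmptyMapError(RuntimeError):
    pass


@dataclass
class XcorrResult:
    """Normalized cross-correlation over lags -max_lag..max_lag (bins)."""

    lags: np.ndarray      # bin lags (multiply by bin_ms for ms)
    values: np.ndarray    # nan where overlap < 2
    overlap: np.ndarray   # L(n) = N - |n|


def _xcorr_raw(xc: np.ndarray, yc: np.ndarray, max_lag: int) -> np.ndarray:
    """c[n] = sum_m xc[m] yc[m+n] for n in -max_lag..max_lag (FFT)."""
    n = len(xc)
    nfft = 1
    while nfft < n + max_lag + 1:
        nfft *= 2
    X = np.fft.rfft(xc, nfft)
    Y = np.fft.rfft(yc, nfft)
    c = np.fft.irfft(np.conj(X) * Y, nfft)
    # c[k] = sum_m xc[m] yc[m+k] with negative k wrapped
    return np.concatenate([c[nfft - max_lag:], c[: max_lag + 1]])


def normalized_xcorr(x: np.ndarray, y: np.ndarray, max_lag: int) -> XcorrResult:
    """Overlap-normalized cross-correlation of two binned spike trains.

    Positive lag n means y is shifted later: the sum runs over
    (x[m]-mu_x)(y[m+n]-mu_y).  Raises DegenerateTrainError if either
    train is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("trains must have equal length")
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the train length")
    mx, my = x.mean(), y.mean()
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise DegenerateTrainError("constant train has zero variance")
    lags = np.arange(-max_lag, max_lag + 1)
    overlap = n - np.abs(lags)
    raw = _xcorr_raw(x - mx, y - my, max_lag)
    values = np.where(overlap >= 2, raw / (sx * sy * np.maximum(overlap, 1)), np.nan)
    return XcorrResult(lags=lags, values=values, overlap=overlap)


@dataclass
class CorrelationMap:
    """3D (longitudinal lag, transverse lag, time lag) correlation map."""

    values: np.ndarray        # (nb_long, nb_trans, nlags); nan where no pair
    counts: np.ndarray        # (nb_long, nb_trans) pair contributions per spatial bin
                              # (every time lag of a spatial bin shares its count)
    spatial_res_mm: float
    bin_ms: float
    max_lag: int              # in time bins
    long_offset: int          # bin index of displacement 0
    trans_offset: int
    scope: str = "global"
    n_pairs: int = 0
    n_silent: int = 0

    @property
    def lags_ms(self) -> np.ndarray:
        return np.arange(-self.max_lag, self.max_lag + 1) * self.bin_ms

    def long_lags_mm(self) -> np.ndarray:
        nb = self.values.shape[0]
        return (np.arange(nb) - self.long_offset) * self.spatial_res_mm

    def trans_lags_mm(self) -> np.ndarray:
        nb = self.values.shape[1]
        return (np.arange(nb) - self.trans_offset) * self.spatial_res_mm

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path, values=self.values, counts=self.counts,
            meta=np.array([self.spatial_res_mm, self.bin_ms, self.max_lag,
                           self.long_offset, self.trans_offset,
                           self.n_pairs, self.n_silent]),
            scope=np.asarray(self.scope))

    @classmethod
    def load_npz(cls, path) -> "CorrelationMap":
        with np.load(path) as d:
            m = d["meta"]
            return cls(d["values"], d["counts"], float(m[0]), float(m[1]),
                       int(m[2]), int(m[3]), int(m[4]), str(d["scope"]),
                       int(m[5]), int(m[6]))


def _prepare(raster_or_binned, bin_ms: float):
    if isinstance(raster_or_binned, SpikeRaster):
        return bin_spikes(raster_or_binned, bin_ms)
    return raster_or_binned


def accumulate_map(raster, positions: np.ndarray,
                   spatial_res_mm: float = 0.1, bin_ms: float = 1.0,
                   max_lag_ms: float = 500.0,
                   member_mask: Optional[np.ndarray] = None,
                   max_pairs: Optional[int] = None, seed: int = 0,
                   scope: str = "global", min_count: int = 1,
                   chunk: int = 2048) -> CorrelationMap:
    """Average pairwise normalized cross-correlations into a 3D map.

    Every unordered pair of distinct active neurons contributes in both
    orders, with the signed displacement (second minus first neuron)
    floor-binned at the spatial resolution; this enforces the point
    symmetry map[d, t] = map[-d, -t] at the continuous-displacement
    level.  Silent (zero-variance) neurons are dropped with a logged
    count.  ``member_mask`` restricts to pairs with at least one member
    in the mask (local maps); ``max_pairs`` enables seeded uniform pair
    subsampling for large populations.  ``min_count`` masks spatial bins
    averaging fewer pair contributions (the bin mean of very few pairs
    is an unreliable extreme-value candidate on small populations).
    """
    binned = _prepare(raster, bin_ms)
    x = binned.x.astype(float)
    n_all, N = x.shape
    if positions.shape[0] != n_all:
        raise ValueError("positions and raster sizes differ")
    max_lag = int(round(max_lag_ms / bin_ms))
    if max_lag >= N:
        raise ValueError("max_lag must be smaller than the number of bins")

    active = binned.sigma > 0
    n_silent = int((~active).sum())
    idx_active = np.nonzero(active)[0]
    na = len(idx_active)
    if na < 2:
        raise EmptyMapError("fewer than two active neurons")

    # unordered pairs among active neurons (optionally filtered / subsampled)
    ii, jj = np.triu_indices(na, k=1)
    gi, gj = idx_active[ii], idx_active[jj]
    if member_mask is not None:
        keep = member_mask[gi] | member_mask[gj]
        gi, gj = gi[keep], gj[keep]
    if len(gi) == 0:
        raise EmptyMapError("no admissible pair")
    if max_pairs is not None and len(gi) > max_pairs:
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(gi), size=max_pairs, replace=False)
        gi, gj = gi[sel], gj[sel]

    # spatial geometry: one fixed bin range covering all displacements
    off_long = int(np.floor(positions[:, 0].max() / spatial_res_mm)) + 1
    off_trans = int(np.floor(positions[:, 1].max() / spatial_res_mm)) + 1
    nb_long = 2 * off_long + 1
    nb_trans = 2 * off_trans + 1
    nlags = 2 * max_lag + 1

    sums = np.zeros((nb_long * nb_trans, nlags))
    counts = np.zeros(nb_long * nb_trans, dtype=np.int64)

    mu = binned.mu
    sigma = binned.sigma
    xc = x - mu[:, None]
    nfft = 1
    while nfft < N + max_lag + 1:
        nfft *= 2
    Z = np.fft.rfft(xc, nfft, axis=1)

    def flat_bin(di, dj):
        bl = np.floor(di / spatial_res_mm).astype(np.int64) + off_long
        bt = np.floor(dj / spatial_res_mm).astype(np.int64) + off_trans
        return bl * nb_trans + bt

    d = positions[gj] - positions[gi]
    bins_fwd = flat_bin(d[:, 0], d[:, 1])
    bins_rev = flat_bin(-d[:, 0], -d[:, 1])

    for start in range(0, len(gi), chunk):
        sl = slice(start, start + chunk)
        a, b = gi[sl], gj[sl]
        C = np.fft.irfft(np.conj(Z[a]) * Z[b], nfft, axis=1)
        c = np.concatenate([C[:, nfft - max_lag:], C[:, : max_lag + 1]], axis=1)
        overlap = N - np.abs(np.arange(-max_lag, max_lag + 1))
        vals = c / (sigma[a] * sigma[b])[:, None] / overlap[None, :]
        np.add.at(sums, bins_fwd[sl], vals)
        np.add.at(sums, bins_rev[sl], vals[:, ::-1])
        np.add.at(counts, bins_fwd[sl], 1)
        np.add.at(counts, bins_rev[sl], 1)

    values = np.full_like(sums, np.nan)
    nz = counts >= max(min_count, 1)
    values[nz] = sums[nz] / counts[nz, None]
    return CorrelationMap(
        values=values.reshape(nb_long, nb_trans, nlags),
        counts=counts.reshape(nb_long, nb_trans),
        spatial_res_mm=spatial_res_mm, bin_ms=bin_ms, max_lag=max_lag,
        long_offset=off_long, trans_offset=off_trans, scope=scope,
        n_pairs=2 * len(gi), n_silent=n_silent)


def local_map(raster, positions: np.ndarray, grid: SectionGrid,
              row: str, col: str, **kwargs) -> CorrelationMap:
    """Correlation map restricted to pairs with >= 1 member in one section."""
    from .geometry import LONGITUDINAL_ROWS, TRANSVERSE_COLUMNS

    if row not in LONGITUDINAL_ROWS or col not in TRANSVERSE_COLUMNS:
        raise ValueError(f"unknown section ({row}, {col})")
    r = LONGITUDINAL_ROWS.index(row)
    c = TRANSVERSE_COLUMNS.index(col)
    in_rows = grid.row_mask_array(positions[:, 0])[:, r]
    in_col = grid.column_index_array(positions[:, 1]) == c
    mask = in_rows & in_col
    return accumulate_map(raster, positions, member_mask=mask,
                          scope=f"local({row},{col})", **kwargs)


def cross_section(cmap: CorrelationMap, mode: str = "longitudinal-temporal",
                  at: float = 0.0, threshold: Optional[float] = None,
                  ) -> Tuple[np.ndarray, dict]:
    """2D slice of the map.

    mode 'longitudinal-temporal': slice at a fixed transverse lag (mm);
    mode 'longitudinal-transverse': slice at a fixed time lag (ms).
    ``threshold`` (e.g. 0.30) zeroes bins with |value| below that
    fraction of the maximum absolute value.
    """
    if mode == "longitudinal-temporal":
        bt = int(np.floor(at / cmap.spatial_res_mm)) + cmap.trans_offset
        if not 0 <= bt < cmap.values.shape[1]:
            raise IndexError("transverse lag out of range")
        sl = cmap.values[:, bt, :].copy()
        meta = {"rows_mm": cmap.long_lags_mm(), "cols_ms": cmap.lags_ms}
    elif mode == "longitudinal-transverse":
        tl = int(round(at / cmap.bin_ms)) + cmap.max_lag
        if not 0 <= tl < cmap.values.shape[2]:
            raise IndexError("time lag out of range")
        sl = cmap.values[:, :, tl].copy()
        meta = {"rows_mm": cmap.long_lags_mm(), "cols_mm": cmap.trans_lags_mm()}
    else:
        raise ValueError(f"unknown cross-section mode {mode!r}")
    if threshold is not None:
        m = np.nanmax(np.abs(sl))
        sl[np.abs(sl) < threshold * m] = 0.0
    return sl, meta


def peak_correlation(cmap: CorrelationMap) -> float:
    """Maximum of the value array over all populated bins."""
    if not np.isfinite(cmap.values).any():
        raise EmptyMapError("fully masked map")
    return float(np.nanmax(cmap.values))


# --------------------------------------------------------------------------
# analysis helpers

def spatial_profile(cmap: CorrelationMap, time_lag_ms: float = 0.0) -> Tuple[np.ndarray, np.ndarray]:
    """Correlation vs longitudinal lag at transverse lag 0 and a fixed time lag."""
    sl, meta = cross_section(cmap, "longitudinal-temporal", at=0.0)
    tl = int(round(time_lag_ms / cmap.bin_ms)) + cmap.max_lag
    return meta["rows_mm"], sl[:, tl]


def estimate_cluster_sd(cmap: CorrelationMap, time_lag_ms: float = 0.0,
                        trans_window_mm: float = 0.25) -> float:
    """Spatial sd of planted Gaussian co-activation, from the map's half-width.

    For events recruiting neurons with Gaussian participation of sd s,
    the pairwise correlation falls off as exp(-d^2 / (4 s^2)); the
    half-width at half maximum of the longitudinal correlation profile
    is 2 s sqrt(ln 2), inverted here by linear interpolation.

    The profile is the map at the requested time lag averaged over
    transverse lags within ``trans_window_mm`` (more pairs per bin than
    the single zero-lag column) and lightly smoothed; the baseline is
    the median of the far field (|d| > 2 mm).
    """
    tl = int(round(time_lag_ms / cmap.bin_ms)) + cmap.max_lag
    nb = int(round(trans_window_mm / cmap.spatial_res_mm))
    sl = cmap.values[:, cmap.trans_offset - nb: cmap.trans_offset + nb + 1, tl]
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        c = np.nanmean(sl, axis=1)
    d = cmap.long_lags_mm()
    finite = np.isfinite(c)
    d, c = d[finite], c[finite]
    if len(c) < 5:
        raise EmptyMapError("too few populated longitudinal bins")
    c = np.convolve(c, np.ones(3) / 3.0, mode="same")
    far = np.abs(d) > 2.0
    baseline = float(np.median(c[far])) if far.any() else 0.0
    # center the peak search on zero displacement
    i0 = int(np.argmin(np.abs(d)))
    lo = max(0, i0 - 5)
    i_pk = lo + int(np.argmax(c[lo: i0 + 6]))
    peak = c[i_pk]
    if peak <= baseline:
        raise EmptyMapError("no positive central peak")
    half = baseline + (peak - baseline) / 2.0
    right = left = None
    for i in range(i_pk, len(c) - 1):
        if c[i] >= half > c[i + 1]:
            frac = (c[i] - half) / (c[i] - c[i + 1])
            right = d[i] + frac * (d[i + 1] - d[i])
            break
    for i in range(i_pk, 0, -1):
        if c[i] >= half > c[i - 1]:
            frac = (c[i] - half) / (c[i] - c[i - 1])
            left = d[i] + frac * (d[i - 1] - d[i])
            break
    if right is None or left is None:
        raise EmptyMapError("half crossing not found")
    hwhm = 0.5 * (right - left)
    return float(hwhm / (2.0 * np.sqrt(np.log(2.0))))


def population_pattern_lag(raster_src: SpikeRaster, pos_src: np.ndarray,
                           raster_dst: SpikeRaster, pos_dst: np.ndarray,
                           space_bin_mm: float = 0.5, bin_ms: float = 1.0,
                           max_lag_ms: float = 50.0) -> float:
    """Lag (ms) at which the destination's space-time pattern best matches
    the source's, at matched longitudinal positions.

    Both rasters are reduced to (longitudinal bin x time) occupancy
    matrices; mean-subtracted time series at matched longitudinal bins
    are cross-correlated and summed.  Positive lag means the
    destination follows the source.
    """
    def occupancy(raster, pos):
        nb = int(np.ceil(pos[:, 0].max() / space_bin_mm)) + 1
        N = int(np.ceil(raster.duration_ms / bin_ms))
        M = np.zeros((nb, N))
        for i, train in enumerate(raster.trains):
            if len(train):
                b = int(pos[i, 0] / space_bin_mm)
                t = np.floor_divide(train, bin_ms).astype(int)
                np.add.at(M[b], t, 1.0)
        return M

    A = occupancy(raster_src, pos_src)
    B = occupancy(raster_dst, pos_dst)
    nb = min(A.shape[0], B.shape[0])
    A, B = A[:nb], B[:nb]
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    max_lag = int(round(max_lag_ms / bin_ms))
    N = A.shape[1]
    nfft = 1
    while nfft < N + max_lag + 1:
        nfft *= 2
    FA = np.fft.rfft(A, nfft, axis=1)
    FB = np.fft.rfft(B, nfft, axis=1)
    C = np.fft.irfft(np.conj(FA) * FB, nfft, axis=1).sum(axis=0)
    c = np.concatenate([C[nfft - max_lag:], C[: max_lag + 1]])
    lags = np.arange(-max_lag, max_lag + 1) * bin_ms
    return float(lags[int(np.argmax(c))])
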