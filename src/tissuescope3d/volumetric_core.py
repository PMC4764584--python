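"""Volume image model, TIFF I/O, Poisson noise calibration and BFBD de-noising.

Confocal stacks are photon-limited: intensity I relates to photon count N as
I = alpha*N + beta, so the variance at intensity I is V(I) = alpha*(I - beta).
In thick samples the gain is increased with depth, making alpha a function of z.
The BFBD (Bayesian foreground/background discrimination) de-noiser exploits the
axial elongation of the confocal PSF: along each x-y pixel the background varies
slowly in z and is estimated by an outlier-tolerant straight line; residuals
above a threshold (in units of the local noise sigma) are kept as foreground,
background and foreground are smoothed independently and summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy import ndimage


class CalibrationError(RuntimeError):
    """Raised when the noise model cannot be calibrated (e.g. constant image)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VolumeImage:
    """A single-channel 3D image.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Intensities in arbitrary units; raw images are non-negative.
    spacing : tuple of float
        Voxel size ``(sx, sy, sz)`` in micrometres.
    channel : str
        Stain label (e.g. ``"DAPI"``, ``"CD13"``, ``"Flk1"``, ``"phalloidin"``).
    z_origin : float
        Depth of the first plane in micrometres (used for depth-dependent noise).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel: str = ""
    z_origin: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VolumeImage.data must be 3D (z, y, x)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing components must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def z_depth(self, iz: np.ndarray | int) -> np.ndarray | float:
        """Depth (µm) of plane index ``iz``."""
        return self.z_origin + np.asarray(iz, dtype=float) * self.spacing[2]

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        return replace(self, data=data)


@dataclass
class NoiseModel:
    """Depth-dependent Poisson noise model V(I) = alpha(z) * (I - beta).

    ``alpha`` is stored per calibration slab (piecewise linear in depth,
    clamped beyond the end slabs); ``beta`` is the global digitization offset.
    """

    alpha: np.ndarray              # per-slab conversion coefficient, a.u./photon
    slab_centers: np.ndarray       # z indices of slab centres (voxels)
    beta: float
    slab_height: int

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.slab_centers = np.atleast_1d(np.asarray(self.slab_centers, dtype=float))
        if np.any(self.alpha <= 0):
            raise CalibrationError("alpha values must be > 0")

    def alpha_at(self, z: np.ndarray | float) -> np.ndarray:
        """Interpolate alpha at z (voxel index); clamps to the end slabs."""
        return np.interp(np.asarray(z, dtype=float), self.slab_centers, self.alpha)

    def variance(self, intensity: np.ndarray, z: np.ndarray | float) -> np.ndarray:
        """Predicted noise variance at the given intensity and depth (>= 0)."""
        a = self.alpha_at(z)
        return np.maximum(a * (np.asarray(intensity, dtype=float) - self.beta), 0.0)


@dataclass
class ImageMetrics:
    """Mean squared error and correlation coefficient over a region Omega."""

    mse: float
    coc: float
    region: str = "global"

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise ValueError("MSE must be >= 0")
        if not -1.0 - 1e-9 <= self.coc <= 1.0 + 1e-9:
            raise ValueError("CoC must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def read_tiff(path, channel: str = "", z_origin: float = 0.0) -> VolumeImage:
    """Read a multi-page TIFF as a VolumeImage, recovering voxel spacing.

    Spacing is taken from ImageJ metadata / TIFF resolution tags when present,
    otherwise defaults to 1 µm isotropic.
    """
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        sx = sy = sz = 1.0
        page = tf.pages[0]
        try:
            xres = page.tags["XResolution"].value
            sx = xres[1] / xres[0]
            yres = page.tags["YResolution"].value
            sy = yres[1] / yres[0]
        except (KeyError, ZeroDivisionError):
            pass
        ij = tf.imagej_metadata
        if ij and "spacing" in ij:
            sz = float(ij["spacing"])
    if data.ndim == 2:
        data = data[None]
    return VolumeImage(data, (float(sx), float(sy), float(sz)), channel, z_origin)


def write_tiff(path, img: VolumeImage) -> None:
    """Write a VolumeImage to a multi-page TIFF with ImageJ spacing metadata."""
    sx, sy, sz = img.spacing
    data = img.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )


# ---------------------------------------------------------------------------
# Outlier-tolerant straight-line fit
# ---------------------------------------------------------------------------

def _irls_lines(x: np.ndarray, y: np.ndarray, base_w: np.ndarray | None = None,
                tol: float = 1e-6, max_iter: int = 100):
    """Vectorized IRLS line fit with a Cauchy-like loss.

    ``x`` has shape (n,), ``y`` shape (n, ...); fits one line per trailing
    element. Returns (slope, intercept, residuals) with shapes y.shape[1:].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    w = np.ones_like(y) if base_w is None else np.broadcast_to(base_w, y.shape).copy()
    xb = x.reshape((n,) + (1,) * (y.ndim - 1))
    slope = np.zeros(y.shape[1:])
    intercept = y.mean(axis=0)
    for _ in range(max_iter):
        sw = w.sum(axis=0)
        swx = (w * xb).sum(axis=0)
        swy = (w * y).sum(axis=0)
        swxx = (w * xb * xb).sum(axis=0)
        swxy = (w * xb * y).sum(axis=0)
        det = sw * swxx - swx * swx
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        new_slope = (sw * swxy - swx * swy) / det
        new_intercept = (swxx * swy - swx * swxy) / det
        resid = y - (new_slope * xb + new_intercept)
        # robust scale per profile from the median absolute residual
        scale = 1.4826 * np.median(np.abs(resid), axis=0) + 1e-9
        w_new = 1.0 / (1.0 + (resid / (2.385 * scale)) ** 2)
        if base_w is not None:
            w_new = w_new * base_w
        delta = np.maximum(np.max(np.abs(new_slope - slope)),
                           np.max(np.abs(new_intercept - intercept)))
        slope, intercept, w = new_slope, new_intercept, w_new
        if delta < tol:
            break
    resid = y - (slope * xb + intercept)
    return slope, intercept, resid


def fit_line_outlier_tolerant(profile, variances=None):
    """Fit a straight line robust to a minority of large positive outliers.

    The line prediction is the background estimate at each point; points whose
    residual exceeds 2.5 robust standard deviations are flagged as outliers.

    Parameters
    ----------
    profile : sequence of float
        Ordered intensities (e.g. along z).
    variances : sequence of float, optional
        Per-point noise variances used as inverse base weights.

    Returns
    -------
    slope, intercept : float
    inlier_flags : ndarray of bool
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("profile must be 1D with length >= 3")
    x = np.arange(y.size, dtype=float)
    base_w = None
    if variances is not None:
        v = np.asarray(variances, dtype=float)
        base_w = 1.0 / np.maximum(v, 1e-12)
        base_w = base_w / base_w.max()
    slope, intercept, resid = _irls_lines(x, y, base_w)
    scale = 1.4826 * np.median(np.abs(resid)) + 1e-9
    inliers = np.abs(resid) <= 2.5 * scale
    if np.all(np.abs(resid) < 1e-9):        # exact line: everything inlier
        inliers = np.ones_like(inliers)
    return float(slope), float(intercept), inliers


# ---------------------------------------------------------------------------
# Noise-model estimation
# ---------------------------------------------------------------------------

def estimate_noise_model(img: VolumeImage, n_bins: int = 32,
                         slab_height: int = 16, min_bin_pixels: int = 50) -> NoiseModel:
    """Calibrate the Poisson noise model V(I) = alpha(z)*(I - beta) from a stack.

    Per depth slab, the half squared difference of sequential z-planes (an
    unbiased local variance estimate for slowly varying signal) is binned by
    the pair-mean intensity; the binned mean variance vs intensity is fitted by
    a straight line using the outlier-tolerant estimator.  A global beta is the
    median over slabs, after which alpha is re-fitted per slab through (beta, 0).
    """
    data = np.asarray(img.data, dtype=float)
    nz = data.shape[0]
    if nz < 3:
        raise ValueError("need >= 3 z-planes for calibration")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    slab_height = int(min(max(slab_height, 2), nz))

    diffs = np.diff(data, axis=0)                  # (nz-1, ny, nx)
    means = 0.5 * (data[1:] + data[:-1])
    halfvar = 0.5 * diffs ** 2

    lo, hi = float(means.min()), float(means.max())
    if hi - lo < 1e-12 or float(halfvar.max()) < 1e-12:
        raise CalibrationError("constant image: all bin variances are zero")
    edges = np.linspace(lo, hi, n_bins + 1)

    slab_starts = list(range(0, max(nz - 1, 1), slab_height))
    centers, alphas, betas = [], [], []
    fits = []
    for s in slab_starts:
        e = min(s + slab_height, nz - 1)
        if e - s < 1:
            continue
        m = means[s:e].ravel()
        v = halfvar[s:e].ravel()
        idx = np.clip(np.digitize(m, edges) - 1, 0, n_bins - 1)
        cnt = np.bincount(idx, minlength=n_bins)
        sum_v = np.bincount(idx, weights=v, minlength=n_bins)
        sum_m = np.bincount(idx, weights=m, minlength=n_bins)
        good = cnt >= min_bin_pixels
        if good.sum() < 3:
            continue
        bin_i = sum_m[good] / cnt[good]
        bin_v = sum_v[good] / cnt[good]
        # fit bin_v = a*(bin_i - b): robust line in (bin_i, bin_v)
        a, c, _res = _irls_lines(bin_i, bin_v[:, None])
        a, c = float(a[0]), float(c[0])
        if a <= 0:
            continue
        centers.append(0.5 * (s + e))
        fits.append((bin_i, bin_v))
        alphas.append(a)
        betas.append(-c / a)
    if not alphas:
        raise CalibrationError("no slab produced a valid variance-intensity fit")
    beta = float(np.median(betas))
    # re-fit alpha per slab with beta fixed (regression through the origin)
    alphas2 = []
    for (bin_i, bin_v) in fits:
        xs = bin_i - beta
        keep = xs > 1e-9
        if keep.sum() >= 2:
            alphas2.append(float(np.sum(xs[keep] * bin_v[keep]) / np.sum(xs[keep] ** 2)))
        else:
            alphas2.append(alphas[len(alphas2)])
    return NoiseModel(np.array(alphas2), np.array(centers), beta, slab_height)


# ---------------------------------------------------------------------------
# BFBD de-noising
# ---------------------------------------------------------------------------

def bfbd_denoise(img: VolumeImage, model: NoiseModel, window: int = 5,
                 threshold: float = 1.25, smooth_sigma: float = 0.5) -> VolumeImage:
    """Bayesian foreground/background discrimination de-noising.

    For every x-y pixel the z-profile background is estimated by the
    outlier-tolerant straight line over a sliding window of ``window`` planes;
    the residual above ``threshold``*sqrt(V(I)) is retained as foreground.
    Background and foreground are independently smoothed (Gaussian,
    ``smooth_sigma`` voxels) and summed; the output is non-negative.
    """
    if not isinstance(model, NoiseModel):
        raise TypeError("bfbd_denoise requires a calibrated NoiseModel")
    data = np.asarray(img.data, dtype=float)
    nz, ny, nx = data.shape
    window = int(max(3, min(window, nz)))
    half = window // 2

    background = np.empty_like(data)
    for z0 in range(nz):
        lo = max(0, min(z0 - half, nz - window))
        planes = data[lo:lo + window].reshape(window, -1)
        x = np.arange(lo, lo + window, dtype=float)
        slope, intercept, _ = _irls_lines(x, planes)
        background[z0] = (slope * z0 + intercept).reshape(ny, nx)

    zz = np.arange(nz, dtype=float)[:, None, None]
    sigma = np.sqrt(np.maximum(model.variance(data, np.broadcast_to(zz, data.shape)),
                               1e-12))
    resid = data - background
    foreground = np.where(resid > threshold * sigma, resid, 0.0)

    bg_s = ndimage.gaussian_filter(background, smooth_sigma)
    fg_s = ndimage.gaussian_filter(foreground, smooth_sigma)
    out = np.maximum(bg_s + fg_s, 0.0)
    return img.with_data(out)


# ---------------------------------------------------------------------------
# Image comparison metrics and vicinity masks
# ---------------------------------------------------------------------------

def image_metrics(a: VolumeImage | np.ndarray, b: VolumeImage | np.ndarray,
                  mask: np.ndarray | None = None) -> ImageMetrics:
    """MSE and correlation coefficient of two images over Omega = mask or all."""
    da = a.data if isinstance(a, VolumeImage) else np.asarray(a)
    db = b.data if isinstance(b, VolumeImage) else np.asarray(b)
    if da.shape != db.shape:
        raise ValueError("images must have the same shape")
    region = "global"
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("mask is empty")
        da, db = da[mask], db[mask]
        region = "vicinity"
    da = da.astype(float).ravel()
    db = db.astype(float).ravel()
    mse = float(np.mean((da - db) ** 2))
    ca, cb = da - da.mean(), db - db.mean()
    denom = np.sqrt((ca ** 2).sum() * (cb ** 2).sum())
    if denom < 1e-30:
        raise ValueError("CoC undefined: zero-variance input")
    coc = float(np.clip((ca * cb).sum() / denom, -1.0, 1.0))
    return ImageMetrics(mse, coc, region)


def ball_structuring_element(radius: int) -> np.ndarray:
    """Isotropic 3D ball of the given voxel radius (Euclidean)."""
    r = int(radius)
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (zz ** 2 + yy ** 2 + xx ** 2) <= r ** 2 + 1e-9


def vicinity_mask(labels: np.ndarray, inflate: int) -> np.ndarray:
    """Morphological dilation of a binary mask by an isotropic ball.

    ``inflate=0`` returns the mask unchanged; used to restrict de-noising
    metrics to the neighbourhood of the objects of interest.
    """
    labels = np.asarray(labels).astype(bool)
    if inflate < 0:
        raise ValueError("inflate must be >= 0")
    if inflate == 0:
        return labels.copy()
    return ndimage.binary_dilation(labels, structure=ball_structuring_element(inflate))
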