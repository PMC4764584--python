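"""Section-surface detection, unbending, and local maximum-entropy segmentation.

Physical sectioning of cleared tissue bends the slice and leaves uneven top and
bottom surfaces; unstained vessel lumina touching a surface are easily mistaken
for out-of-field space.  The surfaces are first measured per x-y column with a
Kapur maximum-entropy threshold and then refined by minimizing a Bayesian
energy: Cauchy data terms (tolerant to vessel-induced outliers), a Gaussian
coupling of the section thickness to its typical value, and a Laplace
smoothness prior on the top surface.  Minimization uses iterated conditional
modes (ICM).  The refined surfaces drive a quadratic B-spline unbending, and
large vessels are segmented with local maximum-entropy (LME) threshold fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline, RegularGridInterpolator

from .volumetric_core import VolumeImage

# 8-connected neighbourhood offsets used by the smoothness prior
_NEIGH8 = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SurfacePair:
    """Measured (ym1/ym2) and refined (y1/y2) top/bottom height fields.

    Heights are z indices (voxels) per x-y column; ``missing`` marks columns
    where no tissue was detected and heights were inpainted from neighbours.
    """

    ym1: np.ndarray
    ym2: np.ndarray
    y1: np.ndarray | None = None
    y2: np.ndarray | None = None
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ym1 = np.asarray(self.ym1, dtype=float)
        self.ym2 = np.asarray(self.ym2, dtype=float)
        if self.ym1.shape != self.ym2.shape:
            raise ValueError("ym1/ym2 shapes differ")
        if self.y1 is not None and self.y2 is not None:
            if np.any(np.asarray(self.y1) > np.asarray(self.y2)):
                raise ValueError("refined surfaces must satisfy y1 <= y2")

    @property
    def refined(self) -> bool:
        return self.y1 is not None and self.y2 is not None

    def best(self) -> tuple[np.ndarray, np.ndarray]:
        """Refined surfaces if available, else the measured ones."""
        if self.refined:
            return self.y1, self.y2
        return self.ym1, self.ym2


@dataclass
class SurfacePrior:
    """Parameters of the surface posterior.

    s : Cauchy scale of the measurement likelihood (voxels)
    sigma : Gaussian scale of the thickness variability (voxels)
    lam : rate of the Laplace smoothness prior (1/voxel)
    t_mad : median absolute deviation of the measured thickness (voxels)
    t0 : typical (median) thickness the Gaussian coupling is centred on
    """

    s: float
    sigma: float
    lam: float
    t_mad: float
    t0: float
    floored: bool = False

    def __post_init__(self) -> None:
        if min(self.s, self.sigma, self.lam) <= 0:
            raise ValueError("s, sigma and lam must be > 0")


@dataclass
class ThresholdField:
    """Per-cube Kapur thresholds, tri-linearly interpolated per voxel."""

    thresholds: np.ndarray                 # (nzc, nyc, nxc) grid of thresholds
    centers: tuple[np.ndarray, np.ndarray, np.ndarray]   # cube centres per axis
    cube: int
    _interp: RegularGridInterpolator | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        axes = []
        for c, n in zip(self.centers, self.thresholds.shape):
            c = np.asarray(c, dtype=float)
            if c.size != n:
                raise ValueError("centre axes do not match threshold grid")
            axes.append(c)
        self.centers = tuple(axes)

    def at(self, points: np.ndarray) -> np.ndarray:
        """Interpolated threshold at (z, y, x) voxel coordinates (clamped)."""
        if self._interp is None:
            self._interp = RegularGridInterpolator(
                self.centers, self.thresholds, method="linear",
                bounds_error=False, fill_value=None)
        pts = np.asarray(points, dtype=float)
        clipped = np.stack([np.clip(pts[..., i], self.centers[i][0],
                                    self.centers[i][-1]) for i in range(3)], axis=-1)
        return self._interp(clipped)

    def volume(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Dense per-voxel threshold volume of the given shape."""
        zz, yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                                 np.arange(shape[2]), indexing="ij")
        pts = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
        return self.at(pts).reshape(shape)


# ---------------------------------------------------------------------------
# Kapur maximum-entropy threshold
# ---------------------------------------------------------------------------

def max_entropy_threshold(hist: np.ndarray, bin_centers: np.ndarray | None = None) -> float:
    """Kapur maximum-entropy threshold of an intensity histogram.

    Maximizes the sum of foreground and background Shannon entropies over all
    split points; ties break to the lowest bin.  Returns the bin-centre value
    (or the bin index when no centres are given); foreground is ``> threshold``.
    """
    counts = np.asarray(hist, dtype=float)
    if counts.ndim != 1:
        raise ValueError("histogram must be 1D")
    if np.count_nonzero(counts) < 2:
        raise ValueError("need >= 2 occupied bins")
    p = counts / counts.sum()
    cdf = np.cumsum(p)
    # entropy accumulators: H(t) = -sum_{i<=t} p_i ln p_i
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cum_plogp = np.cumsum(plogp)
    total_plogp = cum_plogp[-1]
    t = np.arange(counts.size - 1)          # split after bin t
    pb = cdf[t]
    pf = 1.0 - pb
    valid = (pb > 0) & (pf > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        hb = np.log(pb) - cum_plogp[t] / pb
        hf = np.log(pf) - (total_plogp - cum_plogp[t]) / pf
    score = np.where(valid, hb + hf, -np.inf)
    best = int(np.argmax(score))            # argmax returns the first (lowest) tie
    if bin_centers is not None:
        bin_centers = np.asarray(bin_centers, dtype=float)
        return float(0.5 * (bin_centers[best] + bin_centers[best + 1]))
    return float(best)


def kapur_threshold(values: np.ndarray, n_bins: int = 256,
                    value_range: tuple[float, float] | None = None,
                    log_domain: bool = False,
                    tail_clip: float | None = None) -> float:
    """Kapur threshold of raw intensity values (histogram built internally).

    ``log_domain`` histograms log intensity (fluorescence staining is
    multiplicative, so the foreground mode becomes symmetric);
    ``tail_clip`` merges all values above that quantile into the top bin so a
    heavy staining tail cannot dominate the entropy criterion.  The returned
    threshold is always on the original intensity scale.
    """
    values = np.asarray(values, dtype=float).ravel()
    if log_domain:
        values = np.log(np.maximum(values, 1e-12))
    if value_range is None:
        hi = float(np.quantile(values, tail_clip)) if tail_clip else float(values.max())
        value_range = (float(values.min()), hi)
    lo, hi = value_range
    if hi - lo < 1e-12:
        raise ValueError("degenerate intensity range")
    counts, edges = np.histogram(np.clip(values, lo, hi), bins=n_bins,
                                 range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    thr = max_entropy_threshold(counts, centers)
    return float(np.exp(thr)) if log_domain else float(thr)


# ---------------------------------------------------------------------------
# Surface measurement and prior estimation
# ---------------------------------------------------------------------------

def measure_surfaces(img: VolumeImage, smooth_sigma: float = 1.0,
                     n_bins: int = 256) -> SurfacePair:
    """Measure top/bottom surfaces as the first/last above-threshold z per column.

    The stack is lightly smoothed along z before applying the global Kapur
    threshold.  Columns with no above-threshold voxel are marked missing and
    inpainted from the nearest valid column.
    """
    data = np.asarray(img.data, dtype=float)
    nz = data.shape[0]
    smoothed = ndimage.gaussian_filter1d(data, smooth_sigma, axis=0)
    thr = kapur_threshold(smoothed, n_bins=n_bins)
    above = smoothed > thr
    any_above = above.any(axis=0)
    zz = np.arange(nz)[:, None, None]
    ym1 = np.where(any_above, np.where(above, zz, nz).min(axis=0), 0).astype(float)
    ym2 = np.where(any_above, np.where(above, zz, -1).max(axis=0), 0).astype(float)
    missing = ~any_above
    if missing.any():
        if missing.all():
            raise ValueError("no tissue detected in any column")
        _, (iy, ix) = ndimage.distance_transform_edt(missing, return_indices=True)
        ym1 = ym1[iy, ix]
        ym2 = ym2[iy, ix]
    return SurfacePair(ym1, ym2, missing=missing)


def estimate_prior(sp: SurfacePair) -> SurfacePrior:
    """Estimate the surface-posterior parameters from the measured surfaces.

    t_MAD is the median absolute deviation of the section thickness
    |ym2 - ym1|; the Cauchy and Gaussian scales are both (pi/2) * t_MAD, and
    the Laplace smoothness rate is the maximum-likelihood estimate
    1 / mean|Delta y| on neighbour height differences of the measured surfaces.
    """
    thickness = np.abs(sp.ym2 - sp.ym1)
    t0 = float(np.median(thickness))
    t_mad = float(np.median(np.abs(thickness - t0)))
    floored = False
    if t_mad < 1.0:
        t_mad, floored = 1.0, True
    s = sigma = (np.pi / 2.0) * t_mad
    diffs = []
    for surf in (sp.ym1, sp.ym2):
        diffs.append(np.abs(np.diff(surf, axis=0)).ravel())
        diffs.append(np.abs(np.diff(surf, axis=1)).ravel())
    mean_abs = float(np.mean(np.concatenate(diffs)))
    lam = 1.0 / max(mean_abs, 1e-3)
    return SurfacePrior(s=s, sigma=sigma, lam=lam, t_mad=t_mad, t0=t0,
                        floored=floored)


# ---------------------------------------------------------------------------
# Surface energy and ICM refinement
# ---------------------------------------------------------------------------

def _data_term(y: np.ndarray, ym: np.ndarray, s: float) -> np.ndarray:
    """Negative log Cauchy likelihood per column (including constants)."""
    return np.log(np.pi * s) + np.log1p(((y - ym) / s) ** 2)


def surface_energy(sp: SurfacePair, prior: SurfacePrior) -> float:
    """Negative log posterior of the refined surfaces (up to the evidence).

    Sum over columns of the two Cauchy data terms and the Gaussian thickness
    term, plus Laplace smoothness terms over ordered 8-neighbour pairs of each
    surface (both cut surfaces are physically smooth; a one-sided prior lets
    ICM relieve the thickness coupling by dragging the unregularized surface).
    """
    y1, y2 = sp.best()
    e = _data_term(y1, sp.ym1, prior.s).sum()
    e += _data_term(y2, sp.ym2, prior.s).sum()
    e += (0.5 * ((y2 - y1 - prior.t0) / prior.sigma) ** 2
          + np.log(np.sqrt(2 * np.pi) * prior.sigma)).sum()
    ny, nx = y1.shape
    for surf in (y1, y2):
        for dy, dx in _NEIGH8:
            ys0, ys1 = max(-dy, 0), ny - max(dy, 0)
            xs0, xs1 = max(-dx, 0), nx - max(dx, 0)
            a = surf[ys0:ys1, xs0:xs1]
            b = surf[ys0 + dy: ys1 + dy, xs0 + dx: xs1 + dx]
            e += (prior.lam * np.abs(a - b) - np.log(prior.lam)).sum()
    return float(e)


def _neighbour_sum_abs(y1: np.ndarray, cand: np.ndarray) -> np.ndarray:
    """Sum over in-grid 8-neighbours of |cand - y1[neighbour]| per column.

    ``cand`` has shape (k, ny, nx); out-of-grid neighbours are skipped, exactly
    matching the border handling of :func:`surface_energy`.
    """
    ny, nx = y1.shape
    total = np.zeros_like(cand)
    for dy, dx in _NEIGH8:
        ys0, ys1 = max(-dy, 0), ny - max(dy, 0)
        xs0, xs1 = max(-dx, 0), nx - max(dx, 0)
        nb = y1[ys0 + dy: ys1 + dy, xs0 + dx: xs1 + dx]
        total[:, ys0:ys1, xs0:xs1] += np.abs(cand[:, ys0:ys1, xs0:xs1] - nb)
    return total


def refine_surfaces_icm(sp: SurfacePair, prior: SurfacePrior,
                        max_sweeps: int = 300) -> SurfacePair:
    """Refine measured surfaces by ICM on the surface posterior.

    Columns are updated coordinate-wise on a 2x2 four-colouring (no two
    columns of the same colour are 8-neighbours, so each quarter-sweep
    vectorizes while all neighbours stay fixed); candidate heights are
    integers within +-3*t_MAD of the current value.  Energy never increases;
    iteration stops when no column changes.
    """
    y1 = sp.ym1.copy()
    y2 = sp.ym2.copy()
    ny, nx = y1.shape
    rad = max(3, int(np.ceil(3 * prior.t_mad)))
    offs = np.arange(-rad, rad + 1, dtype=float)
    # stable tie-break: prefer the smallest move (offset 0 first)
    offsets = offs[np.argsort(np.abs(offs), kind="stable")][:, None, None]
    cgrid = (np.arange(ny)[:, None] % 2) * 2 + (np.arange(nx)[None, :] % 2)
    colors = [cgrid == c for c in range(4)]

    converged = False
    for _ in range(max_sweeps):
        changed = 0
        for par in colors:
            # --- update y1 on this colour ---
            cand = y1[None] + offsets
            cand = np.minimum(cand, y2[None])
            e = _data_term(cand, sp.ym1[None], prior.s)
            e += 0.5 * ((y2[None] - cand - prior.t0) / prior.sigma) ** 2
            # each undirected pair appears twice in the product -> factor 2
            e += 2.0 * prior.lam * _neighbour_sum_abs(y1, cand)
            pick = np.argmin(e, axis=0)
            # accept only clear improvements over staying put (offset 0 is
            # first in the candidate order), so float ties cannot oscillate
            better = np.take_along_axis(e, pick[None], axis=0)[0] < e[0] - 1e-9
            new = np.where(better, np.take_along_axis(cand, pick[None], axis=0)[0], y1)
            changed += int(np.count_nonzero((new != y1) & par))
            y1 = np.where(par, new, y1)
            # --- update y2 on this colour ---
            cand2 = y2[None] + offsets
            cand2 = np.maximum(cand2, y1[None])
            e2 = _data_term(cand2, sp.ym2[None], prior.s)
            e2 += 0.5 * ((cand2 - y1[None] - prior.t0) / prior.sigma) ** 2
            e2 += 2.0 * prior.lam * _neighbour_sum_abs(y2, cand2)
            pick2 = np.argmin(e2, axis=0)
            better2 = np.take_along_axis(e2, pick2[None], axis=0)[0] < e2[0] - 1e-9
            new2 = np.where(better2, np.take_along_axis(cand2, pick2[None], axis=0)[0], y2)
            changed += int(np.count_nonzero((new2 != y2) & par))
            y2 = np.where(par, new2, y2)
        if changed == 0:
            converged = True
            break
    if not converged:
        warnings.warn("ICM did not fully converge; returning best-so-far surfaces")
    return SurfacePair(sp.ym1, sp.ym2, y1=y1, y2=y2, missing=sp.missing)


# ---------------------------------------------------------------------------
# Section flattening (quadratic B-spline unbending)
# ---------------------------------------------------------------------------

def _spline_surface(h: np.ndarray, smooth: float | None = None) -> np.ndarray:
    ny, nx = h.shape
    if ny < 4 or nx < 4:
        return h.astype(float)
    s = smooth if smooth is not None else float(ny * nx)
    spl = RectBivariateSpline(np.arange(ny), np.arange(nx), h, kx=2, ky=2, s=s)
    return spl(np.arange(ny), np.arange(nx))


def flatten_section(img: VolumeImage, sp: SurfacePair,
                    inverse: bool = False) -> VolumeImage:
    """Unbend a section so both surfaces become planes (quadratic B-splines).

    A quadratic B-spline is fitted to each refined surface; each x-y column is
    linearly re-sampled in z so that the top surface maps to plane 0 and the
    bottom to the median thickness.  ``inverse=True`` applies the inverse
    remap (flattened -> bent), enabling round-trip checks.
    """
    if not sp.refined:
        raise ValueError("flatten_section requires refined surfaces")
    h1 = _spline_surface(sp.y1)
    h2 = _spline_surface(sp.y2)
    if np.any(h2 <= h1):
        raise ValueError("surfaces cross after spline fitting")
    data = np.asarray(img.data, dtype=float)
    nz, ny, nx = data.shape
    t_target = max(2, int(round(float(np.median(h2 - h1)))))
    scale = (h2 - h1) / t_target
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    if not inverse:
        out_nz = t_target + 1
        zp = np.arange(out_nz)[:, None, None]
        src_z = h1[None] + zp * scale[None]
    else:
        out_nz = nz
        zp = np.arange(out_nz)[:, None, None]
        src_z = (zp - h1[None]) / scale[None]
    coords = np.stack([np.broadcast_to(src_z, (out_nz, ny, nx)).ravel(),
                       np.broadcast_to(yy[None], (out_nz, ny, nx)).ravel(),
                       np.broadcast_to(xx[None], (out_nz, ny, nx)).ravel()])
    out = ndimage.map_coordinates(data, coords, order=1, mode="nearest")
    return img.with_data(out.reshape(out_nz, ny, nx))


# ---------------------------------------------------------------------------
# Local maximum entropy threshold field
# ---------------------------------------------------------------------------

def _cube_threshold(block: np.ndarray, n_bins: int = 128, floor_k: float = 6.0,
                    min_fg: float = 0.002, max_fg: float = 0.5,
                    try_mirror: bool = False) -> float | None:
    """Floor-constrained iterated Kapur threshold of one cube (None = invalid).

    The floor anchors to the background *class* — the voxels below the first
    Kapur split.  The descent assumes a bright minority; when that fails and
    ``try_mirror`` is set, the same procedure runs on the negated intensities
    (a dark minority, e.g. vessel lumina in stained tissue, is the mirrored
    problem) and the threshold maps back.
    """
    x = np.asarray(block, dtype=float).ravel()
    thr = _cube_threshold_oneside(x, n_bins, floor_k, min_fg, max_fg)
    if thr is None and try_mirror:
        thr_m = _cube_threshold_oneside(-x, n_bins, floor_k, min_fg, max_fg)
        if thr_m is not None:
            thr = -thr_m
    return thr


def _cube_threshold_oneside(x: np.ndarray, n_bins: int, floor_k: float,
                            min_fg: float, max_fg: float) -> float | None:
    try:
        thr = kapur_threshold(x, n_bins=n_bins)
    except ValueError:
        return None
    low = x[x <= thr]
    if low.size < 10:
        low = x
    med = float(np.median(low))
    mad = 1.4826 * float(np.median(np.abs(low - med)))
    floor = med + floor_k * max(mad, 1e-9)
    for _ in range(8):
        lower = x[x <= thr]
        if lower.size < 50:
            break
        try:
            nxt = kapur_threshold(lower, n_bins=n_bins)
        except ValueError:
            break
        if nxt < floor or nxt >= thr:
            break
        thr = nxt
    thr = max(thr, floor)
    fg = float((x > thr).mean())
    # validity: a bright-minority split whose threshold clears the cube's
    # majority (background) band; anything else is a split inside a
    # unimodal distribution (or the mirrored problem, handled by the caller)
    med_g = float(np.median(x))
    mad_g = 1.4826 * float(np.median(np.abs(x - med_g)))
    if fg < min_fg or fg > max_fg or thr <= med_g + 4.0 * max(mad_g, 1e-9):
        return None
    return float(thr)


def lme_threshold_field(img: VolumeImage, cube: int = 32, overlap: float = 0.5,
                        n_bins: int = 128, floor_k: float = 6.0,
                        min_fg_fraction: float = 0.002,
                        max_fg_fraction: float = 0.5,
                        mirror: bool = False) -> ThresholdField:
    """Per-cube Kapur thresholds on an overlapping grid, trilinearly interpolated.

    Cubes are ``cube`` voxels per side with the given fractional overlap;
    each cube is binned over its own intensity range (this is what lets the
    local threshold resolve a dim foreground mode sitting close to the
    background).  On histograms with a heavy staining tail and a PSF halo
    continuum, a single entropy split lands deep inside the tail; the cube
    threshold is therefore found by iterated descent — Kapur is re-applied to
    the below-threshold class while the next split stays above the local
    background band (median + ``floor_k`` robust SDs), and the result is
    clamped to that floor.  A cube is valid only when its foreground fraction
    lies in [``min_fg_fraction``, ``max_fg_fraction``]; invalid cubes (e.g.
    containing no structure) inherit the nearest valid cube's threshold.
    With no valid cube anywhere the global Kapur threshold is used.
    """
    if cube < 16:
        raise ValueError("cube must be >= 16 voxels per side")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    data = np.asarray(img.data, dtype=float)
    step = max(1, int(round(cube * (1.0 - overlap))))
    centers, starts = [], []
    for n in data.shape:
        s = np.arange(0, max(n - cube, 0) + 1, step)
        if s.size == 0 or s[-1] != max(n - cube, 0):
            s = np.append(s, max(n - cube, 0))
        s = np.unique(s)
        starts.append(s)
        centers.append(s + min(cube, n) / 2.0 - 0.5)
    grid = np.full([len(s) for s in starts], np.nan)
    for i, z0 in enumerate(starts[0]):
        for j, y0 in enumerate(starts[1]):
            for k, x0 in enumerate(starts[2]):
                block = data[z0:z0 + cube, y0:y0 + cube, x0:x0 + cube]
                thr = _cube_threshold(block, n_bins, floor_k,
                                      min_fg_fraction, max_fg_fraction,
                                      try_mirror=mirror)
                if thr is not None:
                    grid[i, j, k] = thr
    if np.isnan(grid).all():
        # no cube separates a foreground class (e.g. structures span whole
        # cubes): fall back to the global threshold with a permissive
        # foreground cap; if even globally nothing separates, the image has
        # no detectable structures and the field sits above every intensity
        thr = _cube_threshold(data, n_bins, floor_k, min_fg_fraction,
                              max_fg=0.95, try_mirror=mirror)
        grid[:] = thr if thr is not None else float(data.max()) + 1.0
    if np.isnan(grid).any():
        idx = ndimage.distance_transform_edt(np.isnan(grid), return_indices=True)[1]
        grid = grid[tuple(idx)]
    return ThresholdField(grid, tuple(centers), cube)


def segment_vessels(section: VolumeImage, sp: SurfacePair, fld: ThresholdField,
                    min_volume_um3: float = 500.0) -> np.ndarray:
    """Segment large unstained vessels inside the tissue slab.

    Vessels appear as empty (below-threshold) volume; the mask is restricted to
    columns between the refined surfaces (out-of-field space excluded) and
    size-filtered at ``min_volume_um3`` (default 500 voxels at 1 µm spacing).
    Build the threshold field with ``mirror=True`` — vessels are a dark
    minority inside bright tissue, the mirrored thresholding problem.
    """
    data = np.asarray(section.data, dtype=float)
    nz = data.shape[0]
    y1, y2 = sp.best()
    zz = np.arange(nz)[:, None, None]
    slab = (zz >= y1[None]) & (zz <= y2[None])
    below = data < fld.volume(data.shape)
    mask = below & slab
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask)
    min_vox = max(1, int(round(min_volume_um3 / section.voxel_volume)))
    sizes = np.bincount(labels.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes[1:] >= min_vox
    return keep[labels]


# ---------------------------------------------------------------------------
# Inter-section vessel gap interpolation
# ---------------------------------------------------------------------------

def _soft_indicator(mask2d: np.ndarray, softness: float = 2.0) -> np.ndarray:
    """Logistic of the signed Euclidean distance to the mask boundary."""
    mask2d = mask2d.astype(bool)
    if mask2d.any() and not mask2d.all():
        sdf = (ndimage.distance_transform_edt(mask2d)
               - ndimage.distance_transform_edt(~mask2d))
    else:
        sdf = np.where(mask2d, 1.0, -1.0) * 1e3
    return 1.0 / (1.0 + np.exp(-sdf / softness))


def interpolate_vessel_gap(maskA: np.ndarray, maskB: np.ndarray, gap: float,
                           spacing_z: float = 1.0, bridge_search: int = 10) -> np.ndarray:
    """Bridge the sectioning gap between vessel masks of adjacent sections.

    The last plane of ``maskA`` and the first plane of ``maskB`` are turned
    into smoothed (signed-distance logistic) indicator fields, linearly
    interpolated across the gap and thresholded at 0.5.  If the dilated end
    faces do not overlap, the vessels are left unbridged with a warning.

    Returns the (gap_planes, ny, nx) boolean gap volume.
    """
    maskA = np.asarray(maskA).astype(bool)
    maskB = np.asarray(maskB).astype(bool)
    faceA = maskA[-1] if maskA.ndim == 3 else maskA
    faceB = maskB[0] if maskB.ndim == 3 else maskB
    if faceA.shape != faceB.shape:
        raise ValueError("end faces must have the same shape")
    n_planes = max(1, int(round(gap / spacing_z)))
    out = np.zeros((n_planes,) + faceA.shape, dtype=bool)
    if not (faceA.any() and faceB.any()):
        warnings.warn("one end face is empty; gap left unbridged")
        return out
    dilA = ndimage.binary_dilation(faceA, iterations=bridge_search)
    if not (dilA & faceB).any():
        warnings.warn("end faces too far apart; gap left unbridged")
        return out
    fA = _soft_indicator(faceA)
    fB = _soft_indicator(faceB)
    for i in range(n_planes):
        t = (i + 1) / (n_planes + 1)
        out[i] = ((1 - t) * fA + t * fB) > 0.5
    return out
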