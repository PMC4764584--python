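"""Mosaic assembly of tile grids and multi-resolution rigid registration.

Each physical section is imaged as an N x M grid of partially overlapping
(~10%) 3D tiles.  Pairwise normalized cross-correlation (NCC) of neighbour
overlaps gives a local alignment metric; tile positions are chosen to
maximize the global metric G, the sum of neighbour correlations, by greedy
block-coordinate ascent from the nominal offsets.  Aligned tiles are fused
with multi-band (Laplacian-pyramid) blending so seams vanish without
blurring detail away from the overlaps.  High-resolution stacks are placed
into the low-resolution reconstruction by rigid registration (z-rotation +
translation) on a three-level scale pyramid: an exhaustive coarse rotation
search (the ±15° basin required for convergence) followed by alternating
shift-by-NCC and rotation-by-polar-NCC refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import match_template
from skimage.transform import warp_polar

from .volumetric_core import VolumeImage


@dataclass
class TileGrid:
    """N x M grid of overlapping tiles with recovered integer shifts."""

    tiles: list                         # nested list [row][col] of VolumeImage
    nominal_overlap: float = 0.10
    shifts: np.ndarray | None = None    # (N, M, 3) voxel positions (z, y, x)

    @property
    def n_rows(self) -> int:
        return len(self.tiles)

    @property
    def n_cols(self) -> int:
        return len(self.tiles[0])


@dataclass
class RigidTransform:
    """Rigid pose: rotation about z (degrees) + translation (z, y, x) voxels."""

    rotation_deg: float
    translation: tuple[float, float, float]
    score: float

    def __post_init__(self) -> None:
        if abs(self.score) > 1.0 + 1e-9:
            raise ValueError("|score| must be <= 1")


# ---------------------------------------------------------------------------
# Pairwise NCC shift
# ---------------------------------------------------------------------------

def ncc_shift(a: VolumeImage | np.ndarray, b: VolumeImage | np.ndarray,
              search: int = 8):
    """Shift of ``b`` relative to ``a`` maximizing overlap NCC.

    The normalized cross-correlation map is computed in one pass
    (frequency-domain products with local-sum normalization); only shifts
    within ±``search`` voxels of zero are considered.  Returns
    ``(shift, peak, ncc_map)`` with shift = (dz, dy, dx) such that
    translating ``b`` by it aligns it onto ``a``.
    """
    da = np.asarray(a.data if isinstance(a, VolumeImage) else a, dtype=float)
    db = np.asarray(b.data if isinstance(b, VolumeImage) else b, dtype=float)
    if da.shape != db.shape:
        raise ValueError("tiles must have equal shape")
    if min(da.shape) - 2 * search < 2 or np.prod(
            np.array(da.shape) - 2 * search) < 8 ** 3:
        raise ValueError("overlap smaller than 8^3 voxels over the search window")
    # correlate the central core of b against a: peak displacement = shift
    core = tuple(slice(search, s - search) for s in db.shape)
    template = db[core]
    ncc = match_template(da, template)
    # ncc[d] corresponds to shifting b by (d - search)
    center = np.array([search] * 3)
    window = ncc[:2 * search + 1, :2 * search + 1, :2 * search + 1]
    peak_idx = np.unravel_index(np.argmax(window), window.shape)
    shift = tuple(int(p - c) for p, c in zip(peak_idx, center))
    peak = float(window[peak_idx])
    return shift, peak, window


# ---------------------------------------------------------------------------
# Global-metric shift optimization
# ---------------------------------------------------------------------------

def _pair_ncc_map(a: np.ndarray, b: np.ndarray, nominal: np.ndarray,
                  search: int):
    """NCC of the overlap of tiles a, b for b at nominal+delta, delta in the
    search cube.  Returns a (2s+1)^3 map (NaN where the overlap is tiny)."""
    size = 2 * search + 1
    out = np.full((size, size, size), np.nan)
    shape = np.array(a.shape)
    for iz in range(size):
        for iy in range(size):
            for ix in range(size):
                off = nominal + np.array([iz, iy, ix]) - search
                lo_a = np.maximum(off, 0)
                hi_a = np.minimum(shape, off + shape)
                if np.any(hi_a - lo_a < 4):
                    continue
                sl_a = tuple(slice(l, h) for l, h in zip(lo_a, hi_a))
                sl_b = tuple(slice(l - o, h - o)
                             for l, h, o in zip(lo_a, hi_a, off))
                va = a[sl_a].ravel()
                vb = b[sl_b].ravel()
                va = va - va.mean()
                vb = vb - vb.mean()
                denom = np.sqrt((va ** 2).sum() * (vb ** 2).sum())
                if denom < 1e-12:
                    continue
                out[iz, iy, ix] = float((va * vb).sum() / denom)
    return out


def optimize_tile_shifts(grid: TileGrid, search: int = 6,
                         max_sweeps: int = 20) -> TileGrid:
    """Recover tile positions maximizing the summed neighbour correlations G.

    Pairwise overlap-NCC maps are precomputed on a ±``search`` cube around
    the nominal offsets; greedy block-coordinate ascent then moves one tile
    at a time to the position maximizing its summed correlation to all
    neighbours, until no move improves G.  The first tile is anchored at the
    origin.  A tile with no valid neighbour correlation raises an error
    naming it.
    """
    nr, nc = grid.n_rows, grid.n_cols
    tiles = [[np.asarray(grid.tiles[r][c].data, dtype=float)
              for c in range(nc)] for r in range(nr)]
    shape = np.array(tiles[0][0].shape)
    ov = grid.nominal_overlap
    nominal_step = np.array([
        0, int(round(shape[1] * (1 - ov))), int(round(shape[2] * (1 - ov)))])

    # neighbour pairs and their NCC maps
    maps = {}
    for r in range(nr):
        for c in range(nc):
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 >= nr or c2 >= nc:
                    continue
                nominal = np.array([0, dr * int(round(shape[1] * (1 - ov))),
                                    dc * int(round(shape[2] * (1 - ov)))])
                maps[((r, c), (r2, c2))] = (
                    _pair_ncc_map(tiles[r][c], tiles[r2][c2], nominal, search),
                    nominal)
    if nr * nc > 1:
        for r in range(nr):
            for c in range(nc):
                has = any(np.isfinite(m[0]).any() for k, m in maps.items()
                          if (r, c) in k)
                if not has:
                    raise ValueError(f"tile ({r},{c}) has no valid neighbour correlation")

    # positions initialized at nominal
    pos = np.zeros((nr, nc, 3), dtype=int)
    for r in range(nr):
        for c in range(nc):
            pos[r, c] = [0, r * int(round(shape[1] * (1 - ov))),
                         c * int(round(shape[2] * (1 - ov)))]

    def pair_score(key, p_a, p_b):
        m, nominal = maps[key]
        delta = (p_b - p_a) - nominal + search
        if np.any(delta < 0) or np.any(delta >= 2 * search + 1):
            return -np.inf
        v = m[tuple(delta)]
        return v if np.isfinite(v) else -np.inf

    def tile_score(r, c, p):
        s = 0.0
        for key in maps:
            if key[0] == (r, c):
                v = pair_score(key, p, pos[key[1]])
            elif key[1] == (r, c):
                v = pair_score(key, pos[key[0]], p)
            else:
                continue
            if np.isfinite(v):
                s += v
        return s

    # block-coordinate ascent: each tile moves to the best position in its
    # whole admissible cube given the current neighbours (single-step moves
    # stall in local optima when several tiles are misplaced jointly)
    nominal_pos = pos.copy()
    deltas = [np.array(d) - search for d in
              np.ndindex(2 * search + 1, 2 * search + 1, 2 * search + 1)]
    for _ in range(max_sweeps):
        moved = False
        for r in range(nr):
            for c in range(nc):
                if (r, c) == (0, 0):
                    continue                        # anchor
                best_p, best_s = pos[r, c].copy(), tile_score(r, c, pos[r, c])
                for d in deltas:
                    p = nominal_pos[r, c] + d
                    s = tile_score(r, c, p)
                    if s > best_s + 1e-12:
                        best_p, best_s = p, s
                if not np.array_equal(best_p, pos[r, c]):
                    pos[r, c] = best_p
                    moved = True
        if not moved:
            break
    return TileGrid(grid.tiles, grid.nominal_overlap, pos)


def global_metric(grid: TileGrid, search: int = 6) -> float:
    """G = sum of neighbour-overlap NCCs at the grid's current shifts."""
    if grid.shifts is None:
        raise ValueError("grid has no shifts")
    nr, nc = grid.n_rows, grid.n_cols
    total = 0.0
    for r in range(nr):
        for c in range(nc):
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 >= nr or c2 >= nc:
                    continue
                a = np.asarray(grid.tiles[r][c].data, dtype=float)
                b = np.asarray(grid.tiles[r2][c2].data, dtype=float)
                off = grid.shifts[r2, c2] - grid.shifts[r, c]
                shape = np.array(a.shape)
                lo_a = np.maximum(off, 0)
                hi_a = np.minimum(shape, off + shape)
                if np.any(hi_a - lo_a < 2):
                    continue
                sl_a = tuple(slice(l, h) for l, h in zip(lo_a, hi_a))
                sl_b = tuple(slice(l - o, h - o)
                             for l, h, o in zip(lo_a, hi_a, off))
                va = a[sl_a].ravel() - a[sl_a].mean()
                vb = b[sl_b].ravel() - b[sl_b].mean()
                denom = np.sqrt((va ** 2).sum() * (vb ** 2).sum())
                if denom > 1e-12:
                    total += float((va * vb).sum() / denom)
    return total


# ---------------------------------------------------------------------------
# Multi-band blending
# ---------------------------------------------------------------------------

def _tile_weight(shape) -> np.ndarray:
    """Separable tent weight: 1 at the tile centre, -> 0 at its faces."""
    ws = []
    for n in shape:
        x = np.arange(n, dtype=float)
        w = np.minimum(x + 1, n - x) / ((n + 1) / 2.0)
        ws.append(np.minimum(w, 1.0))
    return ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]


def blend_mosaic(grid: TileGrid, bands: int = 4) -> VolumeImage:
    """Fuse aligned tiles into one mosaic with multi-band blending.

    Each tile's Laplacian pyramid is combined with the Gaussian pyramid of
    its tent weight; low-frequency bands blend over wide regions and
    high-frequency bands over narrow ones, which removes seams without
    ghosting.  Voxels covered by exactly one tile are copied exactly.
    """
    if grid.shifts is None:
        raise ValueError("grid has no shifts; run optimize_tile_shifts first")
    nr, nc = grid.n_rows, grid.n_cols
    pos = grid.shifts.reshape(-1, 3)
    tiles = [np.asarray(grid.tiles[r][c].data, dtype=float)
             for r in range(nr) for c in range(nc)]
    shape = np.array(tiles[0].shape)
    lo = pos.min(axis=0)
    hi = (pos + shape).max(axis=0)
    canvas_shape = tuple(int(x) for x in (hi - lo))

    num = [np.zeros(canvas_shape) for _ in range(bands)]
    den = [np.zeros(canvas_shape) for _ in range(bands)]
    sigma = 2.0
    coverage = np.zeros(canvas_shape, dtype=np.int16)
    exact = np.zeros(canvas_shape)
    for t, p in zip(tiles, pos):
        sl = tuple(slice(int(a), int(a + s)) for a, s in zip(p - lo, shape))
        w = _tile_weight(shape)
        coverage[sl] += 1
        exact[sl] = t
        # Laplacian bands of the tile, Gaussian bands of the weight
        levels = []
        cur = t
        wcur = w
        for b in range(bands):
            if b < bands - 1:
                low = ndimage.gaussian_filter(cur, sigma * (2 ** b))
                levels.append((cur - low, wcur))
                cur = low
            else:
                levels.append((cur, wcur))
            wcur = ndimage.gaussian_filter(wcur, sigma * (2 ** b))
        for b, (lap, wb) in enumerate(levels):
            num[b][sl] += lap * wb
            den[b][sl] += wb
    out = np.zeros(canvas_shape)
    for b in range(bands):
        with np.errstate(invalid="ignore", divide="ignore"):
            out += np.where(den[b] > 1e-12, num[b] / np.maximum(den[b], 1e-12), 0)
    out[coverage == 1] = exact[coverage == 1]
    ref = grid.tiles[0][0]
    return VolumeImage(out, ref.spacing, ref.channel, ref.z_origin)


# ---------------------------------------------------------------------------
# Rigid registration on a scale pyramid with polar rotation refinement
# ---------------------------------------------------------------------------

def _rotate_z(vol: np.ndarray, angle_deg: float) -> np.ndarray:
    return ndimage.rotate(vol, angle_deg, axes=(1, 2), reshape=False,
                          order=1, mode="constant", cval=float(vol.mean()))


def _best_shift(moving: np.ndarray, fixed: np.ndarray):
    """Translation of moving inside fixed by NCC peak (match_template)."""
    pad = [(s // 4, s // 4) for s in moving.shape]
    ncc = match_template(np.pad(fixed, pad, mode="edge"), moving)
    peak = np.unravel_index(np.argmax(ncc), ncc.shape)
    score = float(ncc[peak])
    shift = np.array(peak) - np.array([p[0] for p in pad])
    return shift, score


def register_rigid_polar(moving: VolumeImage, fixed: VolumeImage,
                         coarse_range_deg: float = 15.0,
                         coarse_step_deg: float = 3.0,
                         min_score: float = 0.2,
                         iterations: int = 3) -> RigidTransform:
    """Rigid z-rotation + translation registration on a 3-level pyramid.

    The coarsest level (0.25x) finds the initial rotation by exhaustive
    search within ±``coarse_range_deg`` (the convergence basin of the polar
    refinement); each level then alternates translation-by-NCC-peak with
    rotation refinement from the angular NCC of polar-transformed mean
    projections, 2-3 iterations per level.  A final correlation below
    ``min_score`` raises a no-match error.
    """
    mv = np.asarray(moving.data, dtype=float)
    fx = np.asarray(fixed.data, dtype=float)
    factors = (0.25, 0.5, 1.0)
    pyramids = [(ndimage.zoom(mv, f, order=1), ndimage.zoom(fx, f, order=1))
                for f in factors]

    # coarse rotation search at the coarsest level
    m0, f0 = pyramids[0]
    best = (0.0, -np.inf)
    for ang in np.arange(-coarse_range_deg, coarse_range_deg + 1e-6,
                         coarse_step_deg):
        _, score = _best_shift(_rotate_z(m0, ang), f0)
        if score > best[1]:
            best = (float(ang), score)
    angle = best[0]

    shift_full = np.zeros(3)
    score = -np.inf
    for level, (ml, fl) in enumerate(pyramids):
        f = factors[level]
        for _ in range(iterations):
            rotated = _rotate_z(ml, angle)
            shift, score = _best_shift(rotated, fl)
            # polar rotation refinement on overlap mean-projections
            proj_m = rotated.mean(axis=0)
            lo = np.maximum(shift[1:], 0)
            hi = np.minimum(np.array(fl.shape[1:]),
                            shift[1:] + np.array(ml.shape[1:]))
            if np.any(hi - lo < 8):
                continue
            proj_f = fl.mean(axis=0)[lo[0]:hi[0], lo[1]:hi[1]]
            proj_m_c = proj_m[lo[0] - shift[1]:hi[0] - shift[1],
                              lo[1] - shift[2]:hi[1] - shift[2]]
            radius = min(proj_f.shape) / 2.0
            pol_f = warp_polar(proj_f, radius=radius)
            pol_m = warp_polar(proj_m_c, radius=radius)
            pf = pol_f - pol_f.mean()
            pm = pol_m - pol_m.mean()
            cc = np.fft.irfft(np.fft.rfft(pf, axis=0).conj()
                              * np.fft.rfft(pm, axis=0), axis=0).sum(axis=1)
            k = int(np.argmax(cc))
            dtheta = k if k <= len(cc) // 2 else k - len(cc)
            angle += float(dtheta) * (360.0 / pol_f.shape[0])
            angle = float(np.clip(angle, -coarse_range_deg - 10,
                                  coarse_range_deg + 10))
        shift_full = np.array(shift, dtype=float) / f
    if score < min_score:
        raise ValueError(f"no match: peak correlation {score:.3f} < {min_score}")
    return RigidTransform(rotation_deg=float(angle),
                          translation=tuple(shift_full),
                          score=float(np.clip(score, -1, 1)))
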