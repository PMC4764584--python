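"""Splitting of optically merged nuclei and per-nucleus DAPI quantification.

Closely packed nuclei are not resolved by confocal optics and segment as one
object.  Each segmented object is approximated by a single minimum-volume
enclosing ellipsoid (MVE) and by two overlapping MVEs; the natural log of the
better model's mesh misfit (MSE) across all objects is bimodal — a
two-Gaussian mixture separates mono/double structures from genuinely
multi-nuclear clusters.  Doubles are split along their two-ellipsoid model;
multis are re-seeded from the Laplacian-of-Gaussian scale-space maximum
projection (LoGMP; blob radius r = sqrt(2)*sigma) and regrown by active-mesh
expansion.  DNA content is quantified as the integral DAPI intensity inside
each nucleus mesh, with histogram stretching to a reference sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from .volumetric_core import VolumeImage
from .mesh_segmentation import (TriangleMesh, mesh_from_mask, mesh_to_mask,
                                expand_active_mesh)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Ellipsoid:
    """Ellipsoid { p : (p - c)^T E (p - c) <= 1 } with c in µm, E in µm^-2."""

    c: np.ndarray
    E: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        ev = np.linalg.eigvalsh(self.E)
        if np.any(ev <= 0):
            raise ValueError("E must be positive definite")

    @property
    def semi_axes(self) -> np.ndarray:
        """Semi-axis lengths (µm), descending."""
        ev = np.linalg.eigvalsh(self.E)
        return np.sort(1.0 / np.sqrt(ev))[::-1]

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return float(4.0 / 3.0 * np.pi * a * b * c)

    def quadratic_form(self, points: np.ndarray) -> np.ndarray:
        d = np.asarray(points, dtype=float) - self.c
        return np.einsum("...i,ij,...j->...", d, self.E, d)


@dataclass
class NucleusObject:
    """A segmented nuclear structure and its splitting metadata."""

    mesh: TriangleMesh
    multiplicity: str = "mono"            # mono | double | multi
    dapi_integral: float = 0.0
    seed: np.ndarray | None = None
    models: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dapi_integral < 0:
            raise ValueError("dapi_integral must be >= 0")


# ---------------------------------------------------------------------------
# Minimum-volume enclosing ellipsoid (Khachiyan's algorithm)
# ---------------------------------------------------------------------------

def fit_min_volume_ellipsoid(points: np.ndarray, tol: float = 1e-3,
                             max_iter: int = 1000) -> Ellipsoid:
    """Minimum-volume enclosing ellipsoid of a 3D point cloud.

    Khachiyan's barycentric coordinate-ascent scheme; the enclosure constraint
    max_p (p-c)^T E (p-c) <= 1 holds within ``tol``.  Requires >= 10
    non-coplanar points.
    """
    P0 = np.asarray(points, dtype=float)
    if P0.ndim != 2 or P0.shape[1] != 3 or P0.shape[0] < 10:
        raise ValueError("need >= 10 points in 3D")
    if np.linalg.matrix_rank(P0 - P0.mean(axis=0)) < 3:
        raise ValueError("points are degenerate (coplanar)")
    # the MVE depends only on the convex hull; fitting on hull vertices makes
    # the iteration cost independent of mesh density
    P = P0
    if len(P0) > 60:
        try:
            from scipy.spatial import ConvexHull
            P = P0[np.unique(ConvexHull(P0).vertices)]
        except Exception:
            P = P0
    n, d = P.shape
    Q = np.column_stack([P, np.ones(n)]).T           # (4, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = (Q * u) @ Q.T
        M = np.einsum("ji,jk,ki->i", Q, np.linalg.inv(X), Q)
        j = int(np.argmax(M))
        maximum = M[j]
        step = (maximum - d - 1.0) / ((d + 1.0) * (maximum - 1.0))
        if step < tol / (d + 1.0):
            break
        u = (1.0 - step) * u
        u[j] += step
    c = P.T @ u
    S = ((P.T * u) @ P) - np.outer(c, c)
    E = np.linalg.inv(S) / d
    # tighten so the enclosure holds exactly at the support points
    ell = Ellipsoid(c, E)
    qmax = float(ell.quadratic_form(P0).max())
    if qmax > 1.0:
        E = E / qmax
    return Ellipsoid(c, E)


def ellipsoid_fit_mse(mesh: TriangleMesh,
                      model: Ellipsoid | tuple[Ellipsoid, Ellipsoid]) -> float:
    """Mesh-to-model misfit MSE = sum_i ((p_i-c)^T E (p_i-c) - 1)^2 / (n - 9).

    For a two-ellipsoid model each vertex is scored against the nearer
    ellipsoid (smaller quadratic form).  The 9 in the normalization is the
    parameter count of one ellipsoid.
    """
    pts = mesh.vertices
    n = len(pts)
    if n <= 9:
        raise ValueError("need more than 9 vertices")
    if isinstance(model, Ellipsoid):
        q = model.quadratic_form(pts)
    else:
        q = np.minimum(model[0].quadratic_form(pts), model[1].quadratic_form(pts))
    return float(np.sum((q - 1.0) ** 2) / (n - 9))


def fit_double_ellipsoid(mesh: TriangleMesh, reassign_iters: int = 2
                         ) -> tuple[Ellipsoid, Ellipsoid]:
    """Two overlapping MVEs: split by the plane normal to the principal axis
    through the centroid, fit each half, then re-assign vertices to the
    nearer ellipsoid and re-fit (``reassign_iters`` rounds)."""
    pts = mesh.vertices
    ctr = pts.mean(axis=0)
    centred = pts - ctr
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    side = centred @ vt[0] >= 0
    halves = [pts[side], pts[~side]]
    ells = []
    for h in halves:
        if len(h) < 10:
            h = pts
        ells.append(fit_min_volume_ellipsoid(h))
    for _ in range(reassign_iters):
        q0 = ells[0].quadratic_form(pts)
        q1 = ells[1].quadratic_form(pts)
        side = q0 <= q1
        if side.sum() < 10 or (~side).sum() < 10:
            break
        ells = [fit_min_volume_ellipsoid(pts[side]),
                fit_min_volume_ellipsoid(pts[~side])]
    return ells[0], ells[1]


# ---------------------------------------------------------------------------
# Multiplicity classification from the ln(MSE) mixture
# ---------------------------------------------------------------------------

def classify_multiplicity(ln_mse: np.ndarray, best_model: list[str] | None = None,
                          random_state: int = 0):
    """Split mono/double from multi-nuclear objects via a 2-Gaussian mixture.

    ``ln_mse`` holds ln(MSE of the better ellipsoid model) per object.  The
    threshold is the upper limit of the 95% confidence interval of the
    lower-mean component (mu + 1.96 sigma); objects below keep their
    best-model label (``best_model``: "mono"/"double"), objects above are
    "multi".  A degenerate mixture falls back to a single Gaussian + 95%
    quantile rule (flagged).

    Returns (threshold, labels, fallback_flag).
    """
    x = np.asarray(ln_mse, dtype=float).reshape(-1, 1)
    if len(x) < 30:
        raise ValueError("need >= 30 objects for a stable mixture fit")
    fallback = False
    if np.ptp(x) < 1e-12:
        fallback = True
        thr = float(x[0, 0])
    else:
        gm = GaussianMixture(n_components=2, random_state=random_state,
                             n_init=5).fit(x)
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        weights = gm.weights_.ravel()
        lo = int(np.argmin(means))
        if weights.min() < 0.02 or abs(means[0] - means[1]) < 1e-6:
            fallback = True
            mu, sd = float(x.mean()), float(x.std())
            thr = mu + 1.96 * sd
        else:
            thr = float(means[lo] + 1.96 * sds[lo])
    labels = []
    for i, v in enumerate(x.ravel()):
        if v > thr:
            labels.append("multi")
        else:
            labels.append(best_model[i] if best_model is not None else "mono")
    return float(thr), labels, fallback


# ---------------------------------------------------------------------------
# LoG scale-space maximum projection seeding
# ---------------------------------------------------------------------------

def logmp_seeds(img: VolumeImage, sigma_min: float, sigma_max: float,
                n_scales: int = 6, rel_threshold: float = 0.10,
                mask: np.ndarray | None = None) -> np.ndarray:
    """Nuclei seeds from the LoG scale-space maximum projection.

    LoGMP(x) = max over sigma in [sigma_min, sigma_max] of the
    scale-normalized negated Laplacian-of-Gaussian response (bright blobs
    give positive peaks; blob radius relates to scale as r = sqrt(2)*sigma).
    Local maxima above ``rel_threshold`` x the global maximum are returned as
    (z, y, x) voxel coordinates.
    """
    if not sigma_min < sigma_max:
        raise ValueError("require sigma_min < sigma_max")
    data = np.asarray(img.data, dtype=float)
    sx, sy, sz = img.spacing
    sigmas = np.geomspace(sigma_min, sigma_max, n_scales)
    logmp = None
    for s in sigmas:
        sv = (s / sz, s / sy, s / sx)                # µm -> voxels per axis
        resp = -(s ** 2) * ndimage.gaussian_laplace(data, sv)
        logmp = resp if logmp is None else np.maximum(logmp, resp)
    if mask is not None:
        logmp = np.where(np.asarray(mask, dtype=bool), logmp, -np.inf)
    peak = float(logmp.max())
    if not np.isfinite(peak) or peak <= 0:
        return np.empty((0, 3), dtype=int)
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = (logmp == ndimage.maximum_filter(logmp, footprint=footprint))
    seeds = np.argwhere(local_max & (logmp >= rel_threshold * peak))
    # collapse plateau runs of adjacent maxima to single seeds
    if len(seeds) > 1:
        lbl, n = ndimage.label(local_max & (logmp >= rel_threshold * peak))
        seeds = np.array(ndimage.center_of_mass(np.ones_like(lbl), lbl,
                                                range(1, n + 1)))
        seeds = np.round(seeds).astype(int)
    return seeds


# ---------------------------------------------------------------------------
# Nucleus splitting
# ---------------------------------------------------------------------------

def analyse_nucleus_objects(meshes: list[TriangleMesh]) -> list[NucleusObject]:
    """Fit single and double ellipsoid models to every object; pick the better."""
    objs = []
    for m in meshes:
        single = fit_min_volume_ellipsoid(m.vertices)
        mse1 = ellipsoid_fit_mse(m, single)
        double = fit_double_ellipsoid(m)
        mse2 = ellipsoid_fit_mse(m, double)
        best = "mono" if mse1 <= mse2 else "double"
        objs.append(NucleusObject(
            mesh=m, multiplicity=best,
            models={"single": single, "double": double,
                    "mse_single": mse1, "mse_double": mse2,
                    "ln_mse_best": float(np.log(max(min(mse1, mse2), 1e-300)))}))
    return objs


def split_multinucleus(obj: NucleusObject, dapi: VolumeImage,
                       sigma_min: float = 2.5, sigma_max: float = 4.5,
                       ) -> list[NucleusObject]:
    """Split a double or multi-nuclear object into individual nuclei.

    Doubles are split by their two-ellipsoid model (each voxel of the object
    goes to the nearer ellipsoid).  Multis are re-seeded by LoGMP inside the
    object and regrown by active-mesh expansion from small seed spheres,
    constrained to the object; if fewer seeds than expected are found the
    best split is returned flagged.  Mono objects come back unchanged.
    """
    if obj.multiplicity == "mono":
        return [obj]
    spacing = dapi.spacing
    sx, sy, sz = spacing
    full_mask = mesh_to_mask(obj.mesh, dapi.shape, spacing)
    if not full_mask.any():
        return [obj]
    # work in the object's bounding box (plus margin): LoGMP and regrowth
    # then scale with the object, not with the full stack
    idx_all = np.argwhere(full_mask)
    lo = np.maximum(idx_all.min(axis=0) - 6, 0)
    hi = np.minimum(idx_all.max(axis=0) + 7, dapi.shape)
    crop = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
    offset_um = lo * np.array([sz, sy, sx])
    dapi = VolumeImage(np.asarray(dapi.data, dtype=float)[crop], spacing,
                       dapi.channel)
    parent_mask = full_mask[crop]
    shape = dapi.shape

    def _globalize(nuc: NucleusObject) -> NucleusObject:
        nuc.mesh.vertices = nuc.mesh.vertices + offset_um
        nuc.mesh._tm = None
        if nuc.seed is not None:
            nuc.seed = np.asarray(nuc.seed, dtype=float) + offset_um
        return nuc

    seeds = logmp_seeds(dapi, sigma_min, sigma_max, mask=parent_mask)
    # a "double" whose LoGMP shows three or more blobs is treated as multi
    if obj.multiplicity == "double" and len(seeds) < 3:
        e0, e1 = obj.models["double"]
        idx = np.argwhere(parent_mask)
        pts = (idx + lo) * np.array([sz, sy, sx])
        nearer = e0.quadratic_form(pts) <= e1.quadratic_form(pts)
        out = []
        for sel, ell in ((nearer, e0), (~nearer, e1)):
            m = np.zeros(shape, dtype=bool)
            m[tuple(idx[sel].T)] = True
            m = ndimage.binary_closing(m)
            meshes = mesh_from_mask(m, spacing)
            if meshes:
                big = max(meshes, key=lambda x: x.volume)
                out.append(_globalize(
                    NucleusObject(big, "mono", seed=ell.c - offset_um)))
        if len(out) < 2:
            obj.models["split_flag"] = "degenerate double split"
            return [obj]
        return out
    if len(seeds) < 2:
        obj.models["split_flag"] = "fewer seeds than expected"
        return [obj]
    zz, yy, xx = np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]]
    occupancy = np.zeros(shape, dtype=np.int32)
    barriers = ~parent_mask
    nuclei: list[NucleusObject] = []
    meshes = []
    for i, s in enumerate(seeds, start=1):
        r2 = ((zz - s[0]) * sz) ** 2 + ((yy - s[1]) * sy) ** 2 + ((xx - s[2]) * sx) ** 2
        seed_mask = (r2 <= 1.5 ** 2) & parent_mask
        if not seed_mask.any():
            continue
        sm = mesh_from_mask(seed_mask, spacing, min_voxels=1)
        if not sm:
            continue
        grown = expand_active_mesh(sm[0], dapi, pressure=1.0, rigidity=0.4,
                                   barriers=barriers, occupancy=occupancy,
                                   label=i, wall_threshold=np.inf)
        occupancy[mesh_to_mask(grown, shape, spacing)] = i
        meshes.append((grown, s))
    # resolve the partition: voxels of the parent go to the nearest seed mesh
    claim = np.zeros(shape, dtype=np.int32)
    for i, (m, _) in enumerate(meshes, start=1):
        mm = mesh_to_mask(m, shape, spacing) & parent_mask
        claim[mm & (claim == 0)] = i
    un = parent_mask & (claim == 0)
    if un.any():
        pos = np.argwhere(un)
        cen = np.array([s for _, s in meshes], dtype=float)
        d2 = ((pos[:, None] - cen[None]) ** 2).sum(axis=2)
        claim[tuple(pos.T)] = np.argmin(d2, axis=1) + 1
    for i, (_, s) in enumerate(meshes, start=1):
        m = claim == i
        if m.sum() < 8:
            continue
        ms = mesh_from_mask(ndimage.binary_closing(m), spacing,
                            split_components=False)
        if ms:
            nuclei.append(_globalize(NucleusObject(
                ms[0], "mono", seed=s * np.array([sz, sy, sx]))))
    if len(nuclei) < 2:
        obj.models["split_flag"] = "regrowth degenerate"
        return [obj]
    return nuclei


# ---------------------------------------------------------------------------
# DAPI integral intensity and inter-sample normalization
# ---------------------------------------------------------------------------

def dapi_integral(mesh: TriangleMesh, dapi: VolumeImage) -> float:
    """Integral DAPI intensity: sum of voxels whose centres lie in the mesh."""
    tm = mesh.as_trimesh()
    if not tm.is_watertight:
        raise ValueError("dapi_integral requires a closed mesh")
    mask = mesh_to_mask(mesh, dapi.shape, dapi.spacing)
    return float(np.asarray(dapi.data, dtype=float)[mask].sum())


def normalize_dapi(reference_hist: tuple[np.ndarray, np.ndarray],
                   sample_hist: tuple[np.ndarray, np.ndarray],
                   search: tuple[float, float] = (0.5, 2.0),
                   coarse: int = 151) -> float:
    """Scale factor s aligning a sample DAPI histogram to the reference.

    Minimizes d(s) = sum_i f0(x_i)^2 - sum_i f0(x_i) f_j(s x_i) / sum_i
    f_j(s x_i)^2 over s by grid search plus golden-section refinement; f_j is
    evaluated at stretched abscissae by linear interpolation.  Histograms are
    (counts, bin_centers) pairs.
    """
    f0, x0 = (np.asarray(a, dtype=float) for a in reference_hist)
    fj, xj = (np.asarray(a, dtype=float) for a in sample_hist)
    if f0.sum() <= 0 or fj.sum() <= 0:
        raise ValueError("histograms must be non-empty")
    f0 = f0 / np.trapezoid(f0, x0)
    fj = fj / np.trapezoid(fj, xj)

    def objective(s: float) -> float:
        fjs = np.interp(s * x0, xj, fj, left=0.0, right=0.0)
        denom = float((fjs ** 2).sum())
        if denom < 1e-30:
            return np.inf
        return float((f0 ** 2).sum() - (f0 * fjs).sum() ** 2 / denom)

    ss = np.linspace(search[0], search[1], coarse)
    vals = np.array([objective(s) for s in ss])
    if not np.isfinite(vals).any():
        raise ValueError("histogram supports do not overlap in the search range")
    k = int(np.argmin(vals))
    lo = ss[max(k - 1, 0)]
    hi = ss[min(k + 1, len(ss) - 1)]
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded")
    return float(res.x)
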