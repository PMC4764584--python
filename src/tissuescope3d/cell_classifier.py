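"""Marker-less cell-type classification from nuclear morphology.

Liver cell types (hepatocyte, sinusoidal endothelial cell, Kupffer cell,
stellate cell) can be told apart from the shape and texture of their nuclei
plus the staining context around them, without type-specific markers.  Each
nucleus yields a 74-parameter profile: geometry of the mesh and its
minimum-volume ellipsoid, DAPI/Flk1 intensity statistics, 13 Haralick
co-occurrence texture features, two intensity fractal dimensions, gliding-box
lacunarity moments, the DAPI surface gradient, and mean phalloidin/Flk1
intensity in 0-10 voxel shells around the nucleus.  Two supervised
classifiers are provided: a three-step cascade of binary linear discriminants
on Fisher-ranked features, and a Bayesian-network classifier whose structure
is learned by the K2 algorithm on equal-population discretized features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import gammaln
from scipy.stats import kurtosis, skew

from .volumetric_core import VolumeImage
from .mesh_segmentation import TriangleMesh, mesh_to_mask
from .nuclei_tools import NucleusObject, fit_min_volume_ellipsoid

CLASSES = ("hepatocyte", "SEC", "Kupffer", "stellate")

# the 74 nuclear parameters, grouped as extracted
FEATURE_NAMES: list[str] = (
    ["Volume", "Surface area", "a/b", "a/c", "b/c", "Sphericity",
     "Mean radius", "Radius variance", "Shape index", "CVM"]
    + ["DAPI mean", "DAPI Sd", "DAPI SKEW", "DAPI KURT"]
    + ["FLK1 mean", "FLK1 Sd", "FLK1 SKEW", "FLK1 KURT"]
    + [f"HF{i}" for i in range(1, 14)]
    + ["BC Frac Dim", "MB Frac Dim"]
    + [f"Lacunarity {i}" for i in range(1, 6)]
    + [f"Norm lac {i}" for i in range(2, 6)]
    + [f"Log lac {i}" for i in range(1, 6)]
    + [f"Log norm lac {i}" for i in range(2, 6)]
    + ["DAPI gradient surface"]
    + [f"Phallo surface intensity {i} vx" for i in range(11)]
    + [f"FLK1 surface intensity {i} vx" for i in range(11)]
)
assert len(FEATURE_NAMES) == 74


@dataclass
class TrainingSet:
    """Feature matrix plus class labels for supervised training."""

    X: np.ndarray                       # (n, 74)
    y: np.ndarray                       # (n,) class labels (strings)
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    provenance: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if len(np.unique(self.y)) < 2:
            raise ValueError("training set needs >= 2 classes")


# ---------------------------------------------------------------------------
# Channel normalization
# ---------------------------------------------------------------------------

def equalize_channel(img: VolumeImage, levels: int = 256) -> VolumeImage:
    """Histogram equalization over the whole stack (flat 0..levels-1 output)."""
    data = np.asarray(img.data, dtype=float)
    flat = data.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(flat.size)
    # average rank for ties so equal inputs map to equal outputs
    uniq, inv, cnt = np.unique(flat, return_inverse=True, return_counts=True)
    cum = np.cumsum(cnt) - cnt / 2.0
    eq = (cum[inv] / flat.size * levels).clip(0, levels - 1)
    return img.with_data(eq.reshape(data.shape))


# ---------------------------------------------------------------------------
# Haralick texture features (3D GLCM)
# ---------------------------------------------------------------------------

# the 13 unique 3D direction classes
_DIRECTIONS_3D = [(0, 0, 1), (0, 1, 0), (1, 0, 0), (0, 1, 1), (0, 1, -1),
                  (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0), (1, 1, 1),
                  (1, 1, -1), (1, -1, 1), (1, -1, -1)]


def averaged_glcm(intensities: np.ndarray, mask: np.ndarray, levels: int = 256,
                  distances: tuple[int, ...] = (1, 2, 3, 4, 5)) -> np.ndarray:
    """Normalized grey-level co-occurrence matrix averaged over the 65
    direction/distance combinations (13 directions x 5 distances), symmetric.

    Only voxel pairs with both ends inside ``mask`` are counted; intensities
    are quantized to ``levels`` grey levels over the masked range.
    """
    vals = np.asarray(intensities, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    inside = vals[mask]
    lo, hi = float(inside.min()), float(inside.max())
    if hi - lo < 1e-12:
        q = np.zeros_like(vals, dtype=np.int64)
    else:
        q = np.clip(((vals - lo) / (hi - lo) * levels).astype(np.int64),
                    0, levels - 1)
    acc = np.zeros((levels, levels), dtype=np.float64)
    nz, ny, nx = vals.shape
    for (dz, dy, dx) in _DIRECTIONS_3D:
        for dist in distances:
            oz, oy, ox = dz * dist, dy * dist, dx * dist
            z0, z1 = max(-oz, 0), nz - max(oz, 0)
            y0, y1 = max(-oy, 0), ny - max(oy, 0)
            x0, x1 = max(-ox, 0), nx - max(ox, 0)
            if z1 <= z0 or y1 <= y0 or x1 <= x0:
                continue
            a = q[z0:z1, y0:y1, x0:x1]
            b = q[z0 + oz:z1 + oz, y0 + oy:y1 + oy, x0 + ox:x1 + ox]
            mm = mask[z0:z1, y0:y1, x0:x1] & mask[z0 + oz:z1 + oz,
                                                  y0 + oy:y1 + oy,
                                                  x0 + ox:x1 + ox]
            if not mm.any():
                continue
            pairs = a[mm] * levels + b[mm]
            cnt = np.bincount(pairs, minlength=levels * levels).reshape(
                levels, levels)
            acc += cnt + cnt.T                      # symmetric GLCM
    s = acc.sum()
    return acc / s if s > 0 else acc


def haralick_features(p: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of a normalized symmetric GLCM."""
    levels = p.shape[0]
    i = np.arange(levels, dtype=float)
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    eps = 1e-12
    # p_{x+y} (k = 0..2L-2) and p_{x-y} (k = 0..L-1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    psum = np.bincount((ii + jj).astype(int).ravel(), weights=p.ravel(),
                       minlength=2 * levels - 1)
    pdiff = np.bincount(np.abs(ii - jj).astype(int).ravel(), weights=p.ravel(),
                        minlength=levels)
    k_sum = np.arange(2 * levels - 1, dtype=float)
    k_diff = np.arange(levels, dtype=float)
    f1 = float((p ** 2).sum())                                         # ASM
    f2 = float((k_diff ** 2 * pdiff).sum())                            # contrast
    f3 = float(((ii - mu) * (jj - mu) * p).sum() / max(sigma2, eps))   # correlation
    f4 = float(((ii - mu) ** 2 * p).sum())                             # variance
    f5 = float((p / (1.0 + (ii - jj) ** 2)).sum())                     # IDM
    f6 = float((k_sum * psum).sum())                                   # sum average
    f8 = float(-(psum * np.log(psum + eps)).sum())                     # sum entropy
    f7 = float(((k_sum - f6) ** 2 * psum).sum())                       # sum variance
    f9 = float(-(p * np.log(p + eps)).sum())                           # entropy
    mu_diff = float((k_diff * pdiff).sum())
    f10 = float(((k_diff - mu_diff) ** 2 * pdiff).sum())               # diff variance
    f11 = float(-(pdiff * np.log(pdiff + eps)).sum())                  # diff entropy
    pxy = np.outer(px, px)
    hxy = f9
    hxy1 = float(-(p * np.log(pxy + eps)).sum())
    hxy2 = float(-(pxy * np.log(pxy + eps)).sum())
    hx = float(-(px * np.log(px + eps)).sum())
    f12 = (hxy - hxy1) / max(hx, eps)                                  # IMC1
    f13 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))  # IMC2
    return np.array([f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13])


# ---------------------------------------------------------------------------
# Fractal dimensions and lacunarity
# ---------------------------------------------------------------------------

def box_counting_dimension(intensities: np.ndarray, mask: np.ndarray,
                           box_sizes: tuple[int, ...] = (1, 2, 3, 4, 5)
                           ) -> float:
    """Differential (gliding-box) box-counting fractal dimension of an
    intensity landscape; slope of log N(b) vs log(1/b)."""
    vals = np.where(mask, np.asarray(intensities, dtype=float), 0.0)
    inside = vals[mask]
    rng_i = float(inside.max() - inside.min())
    h0 = max(rng_i, 1e-9)
    # partition grid aligned to the mask bounding box
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    v_b = np.where(mask, vals, np.nan)[box]
    m_b = mask[box]
    ns = []
    for b in box_sizes:
        if b == 1:
            n = float(np.count_nonzero(m_b))
        else:
            pad = [(0, (-s) % b) for s in v_b.shape]
            vp = np.pad(v_b, pad, constant_values=np.nan)
            mp = np.pad(m_b, pad)
            blocks = vp.reshape(vp.shape[0] // b, b, vp.shape[1] // b, b,
                                vp.shape[2] // b, b)
            mblocks = mp.reshape(*blocks.shape)
            import warnings as _warnings
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                mx = np.nanmax(blocks, axis=(1, 3, 5))
                mn = np.nanmin(blocks, axis=(1, 3, 5))
            valid = mblocks.any(axis=(1, 3, 5))
            h = h0 * b / max(box_sizes)
            cols = np.ceil((mx - mn) / h) + 1
            n = float(cols[valid].sum()) if valid.any() else 1.0
        ns.append(max(n, 1.0))
    x = np.log(1.0 / np.asarray(box_sizes, dtype=float))
    y = np.log(ns)
    return float(np.polyfit(x, y, 1)[0])


def minkowski_bouligand_dimension(intensities: np.ndarray, mask: np.ndarray,
                                  radii: tuple[int, ...] = (1, 2, 3, 4, 5)
                                  ) -> float:
    """Minkowski-Bouligand dimension of the intensity surface by the blanket
    (morphological dilation/erosion) method: D = 3 - slope of log A(r)."""
    vals = np.where(mask, np.asarray(intensities, dtype=float), 0.0)
    areas = []
    for r in radii:
        size = 2 * r + 1
        up = ndimage.grey_dilation(vals, size=(size,) * 3)
        dn = ndimage.grey_erosion(vals, size=(size,) * 3)
        vol = float((up - dn)[mask].sum())
        areas.append(max(vol / (2.0 * r), 1e-9))
    x = np.log(radii)
    y = np.log(areas)
    slope = float(np.polyfit(x, y, 1)[0])
    return 3.0 - slope


def gliding_box_lacunarity(intensities: np.ndarray, mask: np.ndarray,
                           box_sizes: tuple[int, ...] = (1, 2, 3, 4, 5)
                           ) -> np.ndarray:
    """Mean-weighted gliding-box lacunarity Lambda(b) = <m^2>/<m>^2 of the
    intensity mass in b-voxel boxes whose centres lie inside the mask."""
    vals = np.where(mask, np.asarray(intensities, dtype=float), 0.0)
    out = []
    for b in box_sizes:
        m = ndimage.uniform_filter(vals, size=b) * b ** 3
        # gliding boxes fully inside the mask, so the statistic measures
        # intra-nuclear texture rather than the boundary step
        valid = ndimage.minimum_filter(mask.astype(np.uint8), size=b) > 0
        mm = m[valid] if valid.any() else m[mask]
        mean = float(mm.mean())
        out.append(float((mm ** 2).mean()) / max(mean ** 2, 1e-12))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def _discrete_curvatures(verts: np.ndarray, faces: np.ndarray,
                         normals: np.ndarray):
    """Per-vertex principal curvatures (k1 >= k2) of a triangle mesh.

    Gaussian curvature from the angle defect, mean curvature from the
    cotangent Laplacian (signed by the vertex normal), both normalized by
    the barycentric vertex area.
    """
    n = len(verts)
    area = np.zeros(n)
    angle_sum = np.zeros(n)
    lap = np.zeros((n, 3))
    tri = verts[faces]                                  # (F, 3, 3)
    for c in range(3):
        p0 = tri[:, c]
        p1 = tri[:, (c + 1) % 3]
        p2 = tri[:, (c + 2) % 3]
        e1, e2 = p1 - p0, p2 - p0
        cross = np.cross(e1, e2)
        cn = np.linalg.norm(cross, axis=1)
        dot = (e1 * e2).sum(axis=1)
        ang = np.arctan2(cn, dot)
        np.add.at(angle_sum, faces[:, c], ang)
        np.add.at(area, faces[:, c], 0.5 * cn / 3.0)
        # cotangent at this corner weights the OPPOSITE edge (p1, p2)
        cot = dot / np.maximum(cn, 1e-12)
        np.add.at(lap, faces[:, (c + 1) % 3], 0.5 * cot[:, None] * (p2 - p1))
        np.add.at(lap, faces[:, (c + 2) % 3], 0.5 * cot[:, None] * (p1 - p2))
    area = np.maximum(area, 1e-12)
    K = (2.0 * np.pi - angle_sum) / area
    h_vec = lap / (2.0 * area[:, None])
    H = np.linalg.norm(h_vec, axis=1)
    # sign: positive where the Laplacian points against the outward normal
    H *= np.sign((h_vec * -normals).sum(axis=1) + 1e-300)
    disc = np.maximum(H ** 2 - K, 0.0)
    return H + np.sqrt(disc), H - np.sqrt(disc), area


def _mesh_curvature_features(mesh: TriangleMesh) -> tuple[float, float]:
    """Area-weighted shape index and curvature variation measure (CVM).

    Shape index = (2/pi) atan((k2+k1)/(k2-k1)) per vertex (+1 for a convex
    cap, -1 for a cup); CVM = area-weighted coefficient of variation of the
    curvedness sqrt((k1^2+k2^2)/2).
    """
    # measure on a smoothed copy: raw marching-cubes surfaces are voxel
    # staircases whose per-vertex curvature is dominated by the steps
    import trimesh
    tm = trimesh.Trimesh(vertices=mesh.vertices.copy(),
                         faces=mesh.triangles.copy(), process=False)
    try:
        trimesh.smoothing.filter_taubin(tm, lamb=0.5, nu=-0.53, iterations=20)
    except Exception:
        pass
    k1, k2, w = _discrete_curvatures(np.asarray(tm.vertices),
                                     np.asarray(tm.faces),
                                     np.asarray(tm.vertex_normals))
    w = w / max(w.sum(), 1e-12)
    denom = k1 - k2
    si = (2.0 / np.pi) * np.arctan2(k2 + k1, np.where(np.abs(denom) < 1e-9,
                                                      1e-9, denom))
    shape_index = float((w * si).sum())
    curvedness = np.sqrt((k1 ** 2 + k2 ** 2) / 2.0)
    cmean = float((w * curvedness).sum())
    cvar = float((w * (curvedness - cmean) ** 2).sum())
    cvm = float(np.sqrt(cvar) / max(cmean, 1e-12))
    return shape_index, cvm


def _stats(vals: np.ndarray) -> list[float]:
    if vals.size < 2:
        return [float(vals.mean()) if vals.size else 0.0, 0.0, 0.0, 0.0]
    return [float(vals.mean()), float(vals.std(ddof=0)),
            float(skew(vals)), float(kurtosis(vals))]


def extract_features(nucleus: NucleusObject, dapi: VolumeImage,
                     flk1: VolumeImage, phalloidin: VolumeImage,
                     equalized: bool = False, levels: int = 256
                     ) -> np.ndarray:
    """The 74-parameter profile of one nucleus (order = ``FEATURE_NAMES``).

    Channels are histogram-equalized over the whole stack first (pass
    ``equalized=True`` if already done).  A nucleus whose mesh touches the
    image border is still measured but flagged ``unreliable`` on the object.
    """
    if not equalized:
        dapi = equalize_channel(dapi, levels)
        flk1 = equalize_channel(flk1, levels)
        phalloidin = equalize_channel(phalloidin, levels)
    mesh = nucleus.mesh
    spacing = dapi.spacing
    shape = dapi.shape
    mask = mesh_to_mask(mesh, shape, spacing)
    if not mask.any():
        raise ValueError("nucleus mesh rasterized to an empty mask")
    sx, sy, sz = spacing

    # border reliability flag
    idx = np.argwhere(mask)
    if (idx.min() <= 0 or idx[:, 0].max() >= shape[0] - 1
            or idx[:, 1].max() >= shape[1] - 1 or idx[:, 2].max() >= shape[2] - 1):
        nucleus.models["unreliable"] = True

    # tight bbox with margin for texture operators
    lo = np.maximum(idx.min(axis=0) - 2, 0)
    hi = np.minimum(idx.max(axis=0) + 3, shape)
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    m_b = mask[sl]
    dapi_b = np.asarray(dapi.data, dtype=float)[sl]

    feats: list[float] = []
    # --- geometry ---
    V = mesh.volume
    A = mesh.area
    ell = fit_min_volume_ellipsoid(mesh.vertices)
    a, b, c = ell.semi_axes
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * V) ** (2.0 / 3.0) / max(A, 1e-12)
    radii = np.linalg.norm(mesh.vertices - mesh.centroid, axis=1)
    shape_index, cvm = _mesh_curvature_features(mesh)
    feats += [V, A, a / b, a / c, b / c, sphericity,
              float(radii.mean()), float(radii.var()), shape_index, cvm]
    # --- DAPI / Flk1 intensity stats inside the nucleus ---
    dvals = np.asarray(dapi.data, dtype=float)[mask]
    fvals = np.asarray(flk1.data, dtype=float)[mask]
    feats += _stats(dvals)
    feats += _stats(fvals)
    # --- Haralick (averaged GLCM of DAPI inside the nucleus) ---
    glcm = averaged_glcm(dapi_b, m_b, levels=levels)
    feats += list(haralick_features(glcm))
    # --- fractal dimensions ---
    feats.append(box_counting_dimension(dapi_b, m_b))
    feats.append(minkowski_bouligand_dimension(dapi_b, m_b))
    # --- lacunarity moments ---
    lac = gliding_box_lacunarity(dapi_b, m_b)
    feats += list(lac)
    feats += list(lac[1:] / max(lac[0], 1e-12))
    feats += list(np.log(np.maximum(lac, 1e-12)))
    feats += list(np.log(np.maximum(lac[1:] / max(lac[0], 1e-12), 1e-12)))
    # --- DAPI surface gradient (area-weighted at triangle centres) ---
    gz, gy, gx = np.gradient(np.asarray(dapi.data, dtype=float), sz, sy, sx)
    gmag = np.sqrt(gz ** 2 + gy ** 2 + gx ** 2)
    tm = mesh.as_trimesh()
    centres = tm.triangles_center
    coords = np.stack([centres[:, 0] / sz, centres[:, 1] / sy,
                       centres[:, 2] / sx])
    gvals = ndimage.map_coordinates(gmag, coords, order=1, mode="nearest")
    areas = tm.area_faces
    feats.append(float((gvals * areas).sum() / max(areas.sum(), 1e-12)))
    # --- shell intensities at 0..10 voxels from the surface ---
    dist_out = ndimage.distance_transform_edt(~mask)
    for channel in (phalloidin, flk1):
        cd = np.asarray(channel.data, dtype=float)
        for k in range(11):
            ring = (dist_out > k) & (dist_out <= k + 1) if k > 0 else \
                (dist_out > 0) & (dist_out <= 1)
            feats.append(float(cd[ring].mean()) if ring.any() else 0.0)
    out = np.asarray(feats, dtype=float)
    if not np.all(np.isfinite(out)):
        out = np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)
    return out


# ---------------------------------------------------------------------------
# Fisher scores and the LDA cascade
# ---------------------------------------------------------------------------

def fisher_scores(ts: TrainingSet) -> np.ndarray:
    """Per-feature Fisher score F_i = sum_k n_k (u_ki - u_i)^2 / sum_k n_k s_ki^2.

    Zero within-class variance with non-zero between-class spread scores
    infinite (ranked first).
    """
    X, y = ts.X, ts.y
    classes = np.unique(y)
    if any((y == k).sum() < 2 for k in classes):
        raise ValueError("each class needs >= 2 members")
    overall = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for k in classes:
        sel = y == k
        nk = sel.sum()
        num += nk * (X[sel].mean(axis=0) - overall) ** 2
        den += nk * X[sel].std(axis=0, ddof=0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1), np.inf)
    out[(num == 0) & (den == 0)] = 0.0
    return out


class LDACascade:
    """Three-step cascade of binary linear discriminants.

    Step 1 separates hepatocytes from the rest, step 2 SECs from the
    remainder, step 3 Kupffer from stellate cells; each step uses the same
    Fisher-ranked prefix of k features.  Deterministic given the training
    set.
    """

    def __init__(self, k: int | None = None):
        self.k = k
        self.steps: list = []
        self.feature_idx: np.ndarray | None = None

    def fit(self, ts: TrainingSet) -> "LDACascade":
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        classes = np.unique(ts.y)
        order = [c for c in CLASSES if c in classes] or list(classes)
        scores = fisher_scores(ts)
        rank = np.argsort(-scores, kind="stable")
        k = self.k if self.k is not None else ts.X.shape[1]
        self.feature_idx = rank[:k]
        X = ts.X[:, self.feature_idx]
        y = ts.y.copy()
        self.steps = []
        remaining = np.ones(len(y), dtype=bool)
        self._order = order
        for target in order[:-1]:
            sel = remaining.copy()
            yy = np.where(y[sel] == target, target, "rest")
            if len(np.unique(yy)) < 2:
                self.steps.append((target, None))
                continue
            lda = LinearDiscriminantAnalysis()
            lda.fit(X[sel], yy)
            self.steps.append((target, lda))
            remaining &= ~(y == target)
        self._last = order[-1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))[:, self.feature_idx]
        out = np.array([self._last] * len(X), dtype=object)
        undecided = np.ones(len(X), dtype=bool)
        for target, lda in self.steps:
            if lda is None or not undecided.any():
                continue
            pred = lda.predict(X[undecided])
            hit = pred == target
            idxs = np.flatnonzero(undecided)
            out[idxs[hit]] = target
            undecided[idxs[hit]] = False
        return out.astype(str)


def lda_cascade(ts: TrainingSet, k: int) -> LDACascade:
    """Fit the three-step LDA cascade on the top-k Fisher-ranked features."""
    if k > ts.X.shape[1]:
        raise ValueError("k exceeds the number of features")
    return LDACascade(k=k).fit(ts)


def select_k_by_loocv(ts: TrainingSet, k_values=None) -> tuple[int, float]:
    """Choose the Fisher-prefix length maximizing LOOCV accuracy."""
    if k_values is None:
        k_values = range(1, ts.X.shape[1] + 1)
    best = (1, -1.0)
    for k in k_values:
        acc, _ = loocv(lambda t: lda_cascade(t, k),
                       lambda m, x: m.predict(x), ts)
        if acc > best[1]:
            best = (k, acc)
    return best


# ---------------------------------------------------------------------------
# Discretization and mutual information
# ---------------------------------------------------------------------------

def discretize_equal_population(x: np.ndarray, r: int = 5) -> np.ndarray:
    """Equal-population binning; tied values never split across bins.

    Each distinct value goes to the bin indicated by the cumulative count of
    strictly smaller values, so populations differ only by what ties force.
    Invariant under monotone transforms (a rank statistic).
    """
    x = np.asarray(x)
    n = len(x)
    if n < r:
        raise ValueError("need at least r values")
    uniq, inv, cnt = np.unique(x, return_inverse=True, return_counts=True)
    c_before = np.concatenate([[0], np.cumsum(cnt)[:-1]])
    ubin = np.minimum((c_before * r) // n, r - 1)
    return ubin[inv].astype(int)


def mutual_information(xb: np.ndarray, yb: np.ndarray) -> float:
    """MI (nats) of two binned variables with add-one smoothed probabilities
    P(x) = (n_x + 1) / (sum_x n_x + r)."""
    xb = np.asarray(xb, dtype=int)
    yb = np.asarray(yb, dtype=int)
    if xb.shape != yb.shape:
        raise ValueError("inputs must have the same length")
    rx = int(xb.max()) + 1
    ry = int(yb.max()) + 1
    n = len(xb)
    nx = np.bincount(xb, minlength=rx).astype(float)
    ny = np.bincount(yb, minlength=ry).astype(float)
    nxy = np.bincount(xb * ry + yb, minlength=rx * ry).astype(float).reshape(rx, ry)
    px = (nx + 1) / (n + rx)
    py = (ny + 1) / (n + ry)
    pxy = (nxy + 1) / (n + rx * ry)
    return float((pxy * np.log(pxy / np.outer(px, py))).sum())


# ---------------------------------------------------------------------------
# K2 Bayesian-network classifier
# ---------------------------------------------------------------------------

@dataclass
class BayesNet:
    """Discrete Bayesian network: node order, parent sets and smoothed CPTs."""

    nodes: list                          # node names; nodes[0] is the class
    cardinality: dict                    # node -> number of states
    parents: dict                        # node -> list of parent nodes
    cpt: dict                            # node -> ndarray (parent configs, states)

    def __post_init__(self) -> None:
        for node, table in self.cpt.items():
            if not np.allclose(table.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows of {node} must sum to 1")


def _k2_family_score(child: np.ndarray, parent_cols: list[np.ndarray],
                     r_child: int) -> float:
    """Log K2 (Cooper-Herskovits) score of one family."""
    if parent_cols:
        mix = np.zeros(len(child), dtype=np.int64)
        mult = 1
        for col in parent_cols:
            mix += col * mult
            mult *= int(col.max()) + 1
        configs, cfg_idx = np.unique(mix, return_inverse=True)
        q = len(configs)
    else:
        cfg_idx = np.zeros(len(child), dtype=np.int64)
        q = 1
    counts = np.zeros((q, r_child))
    np.add.at(counts, (cfg_idx, child), 1.0)
    nij = counts.sum(axis=1)
    score = (gammaln(r_child) - gammaln(nij + r_child)
             + gammaln(counts + 1).sum(axis=1)).sum()
    return float(score)


def k2_learn(data: np.ndarray, node_names: list, max_parents: int = 3) -> BayesNet:
    """K2 structure learning with a fixed node ordering.

    ``data`` holds one discretized column per node in ``node_names`` order
    (class first, features sorted by mutual information to the class).  For
    each node, parents are added greedily from its predecessors while the
    Cooper-Herskovits score improves, up to ``max_parents``.  CPTs use
    add-one smoothing.
    """
    data = np.asarray(data, dtype=int)
    n_nodes = data.shape[1]
    card = {node: int(data[:, i].max()) + 1 for i, node in enumerate(node_names)}
    parents: dict = {node_names[0]: []}
    for i in range(1, n_nodes):
        node = node_names[i]
        child = data[:, i]
        chosen: list[int] = []
        best = _k2_family_score(child, [], card[node])
        improved = True
        while improved and len(chosen) < max_parents:
            improved = False
            best_j = None
            for j in range(i):
                if j in chosen:
                    continue
                s = _k2_family_score(child, [data[:, jj] for jj in chosen + [j]],
                                     card[node])
                if s > best + 1e-9:
                    best, best_j, improved = s, j, True
            if best_j is not None:
                chosen.append(best_j)
        parents[node] = [node_names[j] for j in chosen]
    # CPTs with add-one smoothing
    name_to_col = {n: i for i, n in enumerate(node_names)}
    cpt = {}
    for node in node_names:
        pi = [name_to_col[p] for p in parents[node]]
        r = card[node]
        q = int(np.prod([card[p] for p in parents[node]])) if pi else 1
        counts = np.zeros((q, r))
        if pi:
            mult = np.ones(len(pi), dtype=int)
            for k in range(1, len(pi)):
                mult[k] = mult[k - 1] * card[parents[node][k - 1]]
            cfg = sum(data[:, c] * m for c, m in zip(pi, mult))
        else:
            cfg = np.zeros(len(data), dtype=int)
        np.add.at(counts, (cfg, data[:, name_to_col[node]]), 1.0)
        cpt[node] = (counts + 1.0) / (counts.sum(axis=1, keepdims=True) + r)
    return BayesNet(list(node_names), card, parents, cpt)


def bnc_predict(net: BayesNet, row: dict) -> dict:
    """Class posteriors for one discretized feature row (dict node -> state).

    The class node is ``net.nodes[0]``; posteriors sum to 1.
    """
    class_node = net.nodes[0]
    r_class = net.cardinality[class_node]
    log_post = np.zeros(r_class)
    for cval in range(r_class):
        assign = dict(row)
        assign[class_node] = cval
        lp = 0.0
        for node in net.nodes:
            pars = net.parents[node]
            if pars:
                mult = 1
                cfg = 0
                for p in pars:
                    cfg += assign[p] * mult
                    mult *= net.cardinality[p]
            else:
                cfg = 0
            lp += np.log(net.cpt[node][cfg, assign[node]] + 1e-300)
        log_post[cval] = lp
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    return {c: float(p) for c, p in enumerate(post)}


class BayesNetClassifier:
    """K2-learned Bayesian-network classifier on discretized features."""

    def __init__(self, n_bins: int = 5, max_parents: int = 3):
        self.n_bins = n_bins
        self.max_parents = max_parents

    def fit(self, ts: TrainingSet) -> "BayesNetClassifier":
        self.classes_, y_idx = np.unique(ts.y, return_inverse=True)
        n_feat = ts.X.shape[1]
        self._edges = []
        cols = []
        for i in range(n_feat):
            cols.append(discretize_equal_population(ts.X[:, i], self.n_bins))
        mi = np.array([mutual_information(c, y_idx) for c in cols])
        order = np.argsort(-mi, kind="stable")
        self.feature_order_ = order
        node_names = ["class"] + [f"f{i}" for i in order]
        data = np.column_stack([y_idx] + [cols[i] for i in order])
        self.net_ = k2_learn(data, node_names, self.max_parents)
        # remember bin boundaries for prediction-time discretization
        self._bin_edges = []
        for i in range(n_feat):
            qs = np.quantile(ts.X[:, i], np.linspace(0, 1, self.n_bins + 1)[1:-1])
            self._bin_edges.append(qs)
        self._train_cols = cols
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.zeros((len(X), len(self.classes_)))
        for n, x in enumerate(X):
            row = {}
            for rank, i in enumerate(self.feature_order_):
                b = int(np.searchsorted(self._bin_edges[i], x[i], side="right"))
                row[f"f{i}"] = min(b, self.n_bins - 1)
            post = bnc_predict(self.net_, row)
            out[n] = [post[c] for c in range(len(self.classes_))]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------

def loocv(fit_fn, predict_fn, ts: TrainingSet):
    """Leave-one-out accuracy and confusion matrix (rows = actual).

    ``fit_fn(ts_subset) -> model``; ``predict_fn(model, X_row) -> label``.
    """
    n = len(ts.y)
    if n < 2:
        raise ValueError("need >= 2 samples")
    classes = list(np.unique(ts.y))
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    correct = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        sub = TrainingSet(ts.X[keep], ts.y[keep], ts.feature_names)
        model = fit_fn(sub)
        pred = np.atleast_1d(predict_fn(model, ts.X[i:i + 1]))[0]
        ai = classes.index(ts.y[i])
        pi = classes.index(pred) if pred in classes else ai
        cm[ai, pi] += 1
        if pred == ts.y[i]:
            correct += 1
    return correct / n, cm
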