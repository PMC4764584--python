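"""Network and cell morphometrics, lobule zonation, and ploidy analysis.

Quantities extracted from reconstructed tissue: tubular-network statistics
(volume fraction, length density, radii, branch angles, node cardinality),
the cylinder-consistency check V_c = pi * r_s^2 * L_s relating independently
measured network descriptors, the CV-PV lobule coordinate chi parameterizing
zonation, relative-density zonation profiles, hierarchical ploidy clustering
on (volume, DAPI integral), and log-normal mixture fits of cell-size and
DNA-content distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .mesh_segmentation import NetworkGraph


@dataclass
class NetworkStats:
    """Morphometric summary of a tubular network.

    Units follow the tissue-morphometry convention: volume fraction
    dimensionless, length density mm/mm^3, radius mm, node density mm^-3.
    """

    volume_fraction: float
    length_density: float
    mean_radius: float
    branch_angles_deg: np.ndarray
    cardinality: dict
    node_density: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise ValueError("volume fraction must be in [0, 1]")


@dataclass
class LobuleCoordinate:
    """Position of a point along the CV-PV axis (0 = CV surface, 100 = PV)."""

    chi: float
    d_cv: float
    d_pv: float
    D: float


# ---------------------------------------------------------------------------
# Network statistics
# ---------------------------------------------------------------------------

def _edge_tangent(polyline: np.ndarray, from_start: bool, window_um: float = 5.0
                  ) -> np.ndarray | None:
    """Unit tangent of an edge at one end, averaged over the first window."""
    pts = polyline if from_start else polyline[::-1]
    if len(pts) < 2:
        return None
    deltas = np.diff(pts, axis=0)
    seglen = np.linalg.norm(deltas, axis=1)
    keep = np.cumsum(seglen) <= window_um
    if not keep.any():
        keep = np.zeros(len(deltas), dtype=bool)
        keep[0] = True
    t = deltas[keep].sum(axis=0)
    n = np.linalg.norm(t)
    return t / n if n > 1e-12 else None


def branch_angles(net: NetworkGraph, window_um: float = 5.0) -> np.ndarray:
    """Pairwise inter-branch angles (degrees) at every junction node.

    Tangents are averaged over the first ``window_um`` of each arm leaving
    the node, which suppresses voxel-scale zig-zag of the centreline.
    """
    g = net.graph
    angles = []
    for n in g.nodes:
        if g.degree(n) < 3:
            continue
        pos = g.nodes[n]["position"]
        tangents = []
        for u, v, d in g.edges(n, data=True):
            poly = d["polyline"]
            from_start = np.allclose(poly[0], pos, atol=1.0)
            t = _edge_tangent(poly, from_start, window_um)
            if t is not None:
                tangents.append(t)
        for i in range(len(tangents)):
            for j in range(i + 1, len(tangents)):
                c = float(np.clip(np.dot(tangents[i], tangents[j]), -1, 1))
                angles.append(np.degrees(np.arccos(c)))
    return np.asarray(angles)


def network_stats(net: NetworkGraph, tissue_volume_mm3: float,
                  network_volume_mm3: float | None = None,
                  mask: np.ndarray | None = None,
                  voxel_volume_mm3: float | None = None) -> NetworkStats:
    """Summarize a skeletonized network normalized by tissue volume.

    The network's own volume can be given directly (mm³) or via a binary
    ``mask`` plus ``voxel_volume_mm3``.  Edge lengths/radii are stored on the
    graph in µm and converted here.
    """
    if tissue_volume_mm3 <= 0:
        raise ValueError("tissue volume must be > 0")
    g = net.graph
    if g.number_of_edges() == 0:
        return NetworkStats(0.0, 0.0, 0.0, np.array([]), {}, 0.0)
    um_to_mm = 1e-3
    total_len_mm = net.total_length() * um_to_mm
    num = den = 0.0
    for *_, d in g.edges(data=True):
        num += d["mean_radius"] * d["length"]
        den += d["length"]
    mean_radius_mm = (num / den) * um_to_mm if den else 0.0
    vol = 0.0
    if network_volume_mm3 is not None:
        vol = network_volume_mm3
    elif mask is not None and voxel_volume_mm3 is not None:
        vol = float(np.count_nonzero(mask)) * voxel_volume_mm3
    card: dict[int, int] = {}
    n_junctions = 0
    for n in g.nodes:
        deg = g.degree(n)
        card[deg] = card.get(deg, 0) + 1
        if deg >= 3:
            n_junctions += 1
    return NetworkStats(
        volume_fraction=vol / tissue_volume_mm3,
        length_density=total_len_mm / tissue_volume_mm3,
        mean_radius=mean_radius_mm,
        branch_angles_deg=branch_angles(net),
        cardinality=card,
        node_density=n_junctions / tissue_volume_mm3,
    )


def cylinder_consistency(v_s: float, l_s: float, r_s: float
                         ) -> tuple[float, float]:
    """Internal-consistency check of network descriptors.

    Approximating the network by ideal cylinders, V_c = pi * r_s^2 * L_s
    should reproduce the independently measured volume fraction V_s; the
    returned ratio V_c / V_s is ~1 for self-consistent measurements.
    Units: r_s in mm, L_s in mm/mm^3, V_s dimensionless.
    """
    if v_s <= 0 or l_s <= 0 or r_s <= 0:
        raise ValueError("all inputs must be > 0")
    v_c = np.pi * r_s ** 2 * l_s
    return float(v_c), float(v_c / v_s)


# ---------------------------------------------------------------------------
# CV-PV zonation
# ---------------------------------------------------------------------------

def chi_coordinate(d_cv: float, d_pv: float, D: float) -> float:
    """Lobule coordinate chi = 50 * ((|D - d_pv| - |D - d_cv|) / D + 1).

    0 at the central-vein surface, 100 at the portal-vein surface, 50
    mid-way; clamped to [0, 100].
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    if d_cv < 0 or d_pv < 0:
        raise ValueError("distances must be >= 0")
    chi = 50.0 * ((abs(D - d_pv) - abs(D - d_cv)) / D + 1.0)
    return float(np.clip(chi, 0.0, 100.0))


def chi_field(cv_mask: np.ndarray, pv_mask: np.ndarray,
              spacing: tuple[float, float, float] = (1, 1, 1)) -> np.ndarray:
    """Per-voxel chi from labelled CV and PV vessel masks.

    d_cv and d_pv are Euclidean distances to the nearest vessel surface; the
    CV-PV distance D is taken as d_cv + d_pv along the realized geometry.
    """
    sx, sy, sz = spacing
    d_cv = ndimage.distance_transform_edt(~np.asarray(cv_mask, dtype=bool),
                                          sampling=(sz, sy, sx))
    d_pv = ndimage.distance_transform_edt(~np.asarray(pv_mask, dtype=bool),
                                          sampling=(sz, sy, sx))
    D = d_cv + d_pv
    with np.errstate(invalid="ignore", divide="ignore"):
        chi = 50.0 * ((np.abs(D - d_pv) - np.abs(D - d_cv)) / np.where(D > 0, D, 1)
                      + 1.0)
    return np.clip(chi, 0.0, 100.0)


def zonation_profile(chi: np.ndarray, labels: np.ndarray,
                     n_bins: int = 10,
                     boundary: np.ndarray | None = None) -> dict:
    """Relative density of each population along the chi axis.

    Within each chi bin the population share is divided by the population's
    overall share, so a uniformly distributed population profiles flat at 1.
    Boundary-flagged cells are excluded; empty bins are NaN (missing), not 0.

    Parameters
    ----------
    chi : per-cell lobule coordinate
    labels : per-cell population label
    boundary : optional per-cell boolean exclusion flag
    """
    chi = np.asarray(chi, dtype=float)
    labels = np.asarray(labels)
    if boundary is not None:
        keep = ~np.asarray(boundary, dtype=bool)
        chi, labels = chi[keep], labels[keep]
    edges = np.linspace(0, 100, n_bins + 1)
    idx = np.clip(np.digitize(chi, edges) - 1, 0, n_bins - 1)
    pops = np.unique(labels)
    total_per_bin = np.bincount(idx, minlength=n_bins).astype(float)
    out = {"bin_edges": edges, "profiles": {}}
    n_all = len(chi)
    for p in pops:
        sel = labels == p
        share_overall = sel.sum() / n_all
        cnt = np.bincount(idx[sel], minlength=n_bins).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = (cnt / total_per_bin) / share_overall
        rel[total_per_bin == 0] = np.nan
        out["profiles"][p] = rel
    return out


# ---------------------------------------------------------------------------
# Ploidy clustering and log-normal mixtures
# ---------------------------------------------------------------------------

def ploidy_cluster(volumes: np.ndarray, dapi: np.ndarray,
                   n_nuclei: np.ndarray, min_cells: int = 50) -> np.ndarray:
    """Hierarchical ploidy clustering of cells on (volume, DAPI integral).

    Mono- and bi-nucleated cells are clustered separately (4 and 3 clusters:
    2n/4n/8n/16n and 2x2n/2x4n/2x8n) with Ward linkage on standardized
    Euclidean distance; cluster labels are ordered by ascending mean DAPI
    integral.  Returns string labels per cell ("" where undetermined).
    """
    from sklearn.cluster import AgglomerativeClustering
    volumes = np.asarray(volumes, dtype=float)
    dapi = np.asarray(dapi, dtype=float)
    n_nuclei = np.asarray(n_nuclei)
    labels = np.array([""] * len(volumes), dtype=object)
    plans = [(1, 4, ["2n", "4n", "8n", "16n"]),
             (2, 3, ["2x2n", "2x4n", "2x8n"])]
    for nnuc, k, names in plans:
        sel = n_nuclei == nnuc
        if sel.sum() < max(min_cells, k):
            if sel.any() and sel.sum() < k:
                raise ValueError(f"fewer cells than clusters for {nnuc}-nucleated group")
            continue
        X = np.column_stack([volumes[sel], dapi[sel]])
        Xs = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-12)
        cl = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(Xs)
        order = np.argsort([dapi[sel][cl == c].mean() for c in range(k)])
        remap = {c: names[rank] for rank, c in enumerate(order)}
        labels[np.flatnonzero(sel)] = [remap[c] for c in cl]
    return labels


def fit_lognormal_mixture(values: np.ndarray, k: int, seed: int = 0):
    """EM fit of a k-component log-normal mixture (in log space).

    Returns (means, sds, weights) of the components on the ORIGINAL scale
    (mean and sd of each log-normal component), sorted by ascending mean.
    k-means initialization with a fixed seed makes the fit deterministic.
    """
    from sklearn.mixture import GaussianMixture
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("values must be positive for a log-normal fit")
    if len(x) < 10 * k:
        raise ValueError("need at least 10*k observations")
    lx = np.log(x).reshape(-1, 1)
    if k == 1:
        mu, sd = float(lx.mean()), float(lx.std())
        mean = np.exp(mu + sd ** 2 / 2)
        var = (np.exp(sd ** 2) - 1) * np.exp(2 * mu + sd ** 2)
        return np.array([mean]), np.array([np.sqrt(var)]), np.array([1.0])
    gm = GaussianMixture(n_components=k, random_state=seed, n_init=5,
                        init_params="k-means++").fit(lx)
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    w = gm.weights_.ravel()
    mean = np.exp(mu + sd ** 2 / 2)
    var = (np.exp(sd ** 2) - 1) * np.exp(2 * mu + sd ** 2)
    order = np.argsort(mean)
    return mean[order], np.sqrt(var)[order], w[order]
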